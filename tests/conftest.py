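import numpy as np
import pandas as pd
import pytest

from sctnet import bn, potentials, simdata, simnet
from sctnet.pipeline import make_fixtures


@pytest.fixture(scope="session")
def small_network():
    """100 transcripts / 5 loci system used across learner tests."""
    return simnet.generate_network(
        simnet.NetGenConfig(n_transcripts=100, n_loci=5, n_extra_edges=18, rng_seed=42)
    )


@pytest.fixture(scope="session")
def small_dataset(small_network):
    params = simdata.SimParams.strong(n_segregants=200, rng_seed=43)
    return simdata.simulate_dataset(small_network, params)


@pytest.fixture(scope="session")
def small_background(small_dataset):
    return potentials.fit_background(
        small_dataset, n_background_samples=200, n_cond_sims=3000, seed=44
    )


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=7)


@pytest.fixture(scope="session")
def chain_fixture(fixtures):
    return fixtures["chain"]


@pytest.fixture(scope="session")
def confounder_fixture(fixtures):
    return fixtures["confounder"]


@pytest.fixture(scope="session")
def system20(fixtures):
    return fixtures["system20"]


@pytest.fixture(scope="session")
def three_transcripts():
    """Tiny 3-transcript chain dataset plus full candidate map, for exact
    posterior enumeration."""
    rng = np.random.default_rng(0)
    n = 60
    a = rng.normal(size=n)
    b = 0.8 * a + rng.normal(size=n) * 0.8
    c = 0.8 * b + rng.normal(size=n) * 0.8
    geno = pd.DataFrame({"L1": rng.integers(0, 2, n)}, index=[f"S{i}" for i in range(n)])
    expr = pd.DataFrame({"T1": a, "T2": b, "T3": c}, index=geno.index)
    ds = simdata.EqtlDataset(genotypes=geno, expression=expr)
    disc_all = bn.discretize(ds, seed=1)
    names = ["T1", "T2", "T3"]
    disc = bn.DiscreteDataset(
        codes=disc_all.codes[names],
        arities={k: 3 for k in names},
        loci=[],
        transcripts=names,
    )
    cands = bn.CandidateMap(sets={t: {u for u in names if u != t} for t in names})
    return disc, cands
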