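"""Regression potentials, background model, likelihood formulas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sctnet import potentials, simdata


def ols_r2_oracle(x, y):
    """Two-step OLS oracle via lstsq (independent of the corrcoef path)."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ssr = np.sum((fitted - y.mean()) ** 2)
    ssto = np.sum((y - y.mean()) ** 2)
    return ssr / ssto


def residuals_oracle(x, y):
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def test_pair_potential_perfect_and_orthogonal():
    x = np.arange(10.0)
    assert potentials.pair_potential(x, x) == pytest.approx(1.0)
    y = np.array([1.0, -1.0] * 5)
    y -= y.mean()
    x2 = x - x.mean()
    y_orth = y - (y @ x2) / (x2 @ x2) * x2  # exactly orthogonal to x
    assert potentials.pair_potential(x, y_orth) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_pair_potential_matches_ols_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=50)
    y = rng.normal(size=50) + 0.5 * x
    assert potentials.pair_potential(x, y) == pytest.approx(ols_r2_oracle(x, y), abs=1e-10)


def test_pair_potential_degenerate_inputs():
    with pytest.raises(ValueError):
        potentials.pair_potential(np.ones(10), np.arange(10.0))
    with pytest.warns(UserWarning):
        assert potentials.pair_potential(np.arange(10.0), np.ones(10)) == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_conditional_potential_matches_two_step_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    g = rng.normal(size=80)
    p = 0.7 * g + rng.normal(size=80)
    c = 0.7 * p + 0.3 * g + rng.normal(size=80)
    expected = ols_r2_oracle(g, residuals_oracle(p, c))
    assert potentials.conditional_potential(g, c, p) == pytest.approx(expected, abs=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_conditional_closed_form_agrees_with_two_step(seed):
    rng = np.random.default_rng(200 + seed)
    g = rng.normal(size=60)
    p = rng.normal(size=60) + 0.4 * g
    c = rng.normal(size=60) + 0.6 * p
    r_gc = np.corrcoef(g, c)[0, 1]
    r_pc = np.corrcoef(p, c)[0, 1]
    r_gp = np.corrcoef(g, p)[0, 1]
    closed = float(potentials.conditional_potential_from_corr(r_gc, r_pc, r_gp))
    assert closed == pytest.approx(potentials.conditional_potential(g, c, p), abs=1e-10)


def test_conditional_potential_trivial_cases():
    rng = np.random.default_rng(3)
    p = rng.normal(size=50)
    c = 2.0 * p + rng.normal(size=50)
    # grandparent identical to parent: residuals are orthogonal to it
    assert potentials.conditional_potential(p, c, p) == pytest.approx(0.0, abs=1e-12)
    # noiseless mediation: child is a function of the parent alone
    g = rng.normal(size=50)
    p2 = 0.9 * g + rng.normal(size=50) * 0.1
    c2 = 1.3 * p2
    assert potentials.conditional_potential(g, c2, p2) == pytest.approx(0.0, abs=1e-10)


def test_conditional_potential_vanishes_on_long_chain():
    rng = np.random.default_rng(4)
    n = 10_000
    g = rng.normal(size=n)
    p = 0.8 * g + rng.normal(size=n)
    c = 0.8 * p + rng.normal(size=n)
    assert potentials.conditional_potential(g, c, p) < 0.002


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None)
def test_potentials_bounded(seed):
    rng = np.random.default_rng(seed)
    g, p, c = rng.normal(size=(3, 30))
    pp = potentials.pair_potential(p, c)
    cp = potentials.conditional_potential(g, c, p)
    assert 0.0 <= pp <= 1.0
    assert 0.0 <= cp <= 1.0 + 1e-12
    # symmetry of the pair potential for two continuous vectors
    assert potentials.pair_potential(c, p) == pytest.approx(pp, abs=1e-12)


@pytest.fixture(scope="module")
def bg20(system20):
    _, ds = system20
    return ds, potentials.fit_background(ds, n_background_samples=500,
                                         n_cond_sims=2000, seed=5)


def test_background_loci_have_no_response_role(bg20):
    ds, model = bg20
    for l in ds.loci:
        assert l in model.mu_expl
        assert l not in model.mu_resp
    for t in ds.transcripts:
        assert t in model.mu_resp


def test_background_exhaustive_sampling_matches_enumeration(bg20):
    """With the request exceeding the partner pool the sample is exhaustive,
    so moments must equal the brute-force enumeration."""
    ds, model = bg20
    node = ds.transcripts[0]
    x = ds.values_of(node)
    phis = []
    for t in ds.transcripts:
        if t == node:
            continue
        r = np.corrcoef(x, ds.values_of(t))[0, 1]
        phis.append(r * r)
    assert model.mu_expl[node] == pytest.approx(np.mean(phis), abs=1e-10)
    assert model.sd_expl[node] == pytest.approx(np.std(phis, ddof=1), abs=1e-10)
    phis_resp = []
    for n2 in ds.nodes:
        if n2 == node:
            continue
        r = np.corrcoef(ds.values_of(n2), x)[0, 1]
        phis_resp.append(r * r)
    assert model.mu_resp[node] == pytest.approx(np.mean(phis_resp), abs=1e-10)


def test_background_sd_cond_small_and_positive(bg20):
    _, model = bg20
    assert 0 < model.sd_cond < 0.2


def test_pair_likelihood_formula_oracle(bg20):
    ds, model = bg20
    np_id = ds.transcripts[1]
    nc_id = ds.transcripts[2]
    for phi in (0.0, 0.05, 0.4, 0.9):
        got = potentials.pair_likelihood(model, np_id, nc_id, phi)
        # direct evaluation of the printed bivariate-normal formula
        sp, sc = model.sd_expl[np_id], model.sd_resp[nc_id]
        nu_p = (phi - model.mu_expl[np_id]) / sp
        nu_c = (phi - model.mu_resp[nc_id]) / sc
        z = 2 * np.pi * sp * sc * np.sqrt(1 - model.rho)
        expect = np.exp(-(nu_p**2 - 2 * model.rho * nu_c * nu_p + nu_c**2)
                        / (2 * (1 - model.rho**2))) / z
        assert got == pytest.approx(expect, rel=1e-12)
    # mode at the two background means simultaneously is 1/Z
    # (only exactly attainable when the means coincide; check upper bound)
    assert potentials.pair_likelihood(model, np_id, nc_id, model.mu_expl[np_id]) <= 1.0 / (
        2 * np.pi * model.sd_expl[np_id] * model.sd_resp[nc_id] * np.sqrt(1 - model.rho)
    ) * (1 + 1e-9)


def test_conditional_likelihood_is_scaled_normal_pdf(bg20):
    from scipy import stats

    _, model = bg20
    for v in (0.0, 0.01, -0.01, 0.3):
        got = potentials.conditional_likelihood(model, v)
        assert got == pytest.approx(stats.norm.pdf(v, 0.0, model.sd_cond), rel=1e-12)
    assert potentials.conditional_likelihood(model, 0.02) == pytest.approx(
        potentials.conditional_likelihood(model, -0.02)
    )


def test_log_likelihood_score_composition(bg20):
    ds, model = bg20
    ng, npid, ncid = ds.loci[0], ds.transcripts[0], ds.transcripts[3]
    c1 = 5.0
    got = potentials.log_likelihood_score(model, ng, npid, ncid, ds, c1)
    phi_p = potentials.pair_potential(ds.values_of(npid), ds.values_of(ncid))
    phi_c = potentials.conditional_potential(
        ds.values_of(ng), ds.values_of(ncid), ds.values_of(npid)
    )
    expect = c1 * np.log(potentials.conditional_likelihood(model, phi_c)) - np.log(
        potentials.pair_likelihood(model, npid, ncid, phi_p)
    )
    assert got == pytest.approx(expect, rel=1e-10)
    # c1 = 0 leaves only the pair term
    got0 = potentials.log_likelihood_score(model, ng, npid, ncid, ds, 0.0)
    assert got0 == pytest.approx(
        -np.log(potentials.pair_likelihood(model, npid, ncid, phi_p)), rel=1e-10
    )


def test_chain_prefers_true_ordering():
    """On simulated chains g -> p -> c, the score of attaching c under p
    (with grandparent g) usually beats attaching c directly under g."""
    import pandas as pd

    wins = 0
    reps = 20
    for rep in range(reps):
        rng = np.random.default_rng(300 + rep)
        n = 150
        g = rng.integers(0, 2, n).astype(float)
        p = 0.9 * g + rng.normal(size=n) * 0.6
        c = 0.9 * p + rng.normal(size=n) * 0.6
        extra = rng.normal(size=(n, 6))
        geno = pd.DataFrame({"L1": g.astype(int)}, index=range(n))
        cols = {"Tp": p, "Tc": c}
        cols.update({f"N{i}": extra[:, i] for i in range(6)})
        ds = simdata.EqtlDataset(genotypes=geno, expression=pd.DataFrame(cols, index=range(n)))
        model = potentials.fit_background(ds, n_background_samples=50, n_cond_sims=500,
                                          seed=rep)
        as_child_of_p = potentials.log_likelihood_score(model, "L1", "Tp", "Tc", ds, 5.0)
        as_child_of_g = potentials.log_likelihood_score(model, "Tp", "L1", "Tc", ds, 5.0)
        wins += as_child_of_p > as_child_of_g
    assert wins > reps / 2


def test_background_model_round_trip(tmp_path, bg20):
    _, model = bg20
    path = tmp_path / "bg.tsv"
    model.to_table(path)
    back = potentials.BackgroundModel.from_table(path)
    assert back.sd_cond == pytest.approx(model.sd_cond)
    for k in model.mu_expl:
        assert back.mu_expl[k] == pytest.approx(model.mu_expl[k])
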