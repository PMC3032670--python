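"""End-to-end experiment orchestration.

``run_experiment`` wires the full reconstruction study: generate a
ground-truth network, simulate segregant data, build the selected
structure prior (none / LCMS / SCT), run MCMC structure learning, and
evaluate edge reconstruction and eQTL mapping against the truth.  Every
stage consumes a sub-seed derived deterministically from the global seed,
and all artifacts can be persisted as delimited text with a JSON manifest
so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sctnet import bn, evaluate, lcms, mapping, potentials, sct, simdata, simnet

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "make_fixtures"]


@dataclass
class ExperimentConfig:
    """Configuration for one reconstruction experiment."""

    n_transcripts: int = 100
    n_loci: int = 5
    n_extra_edges: int = 18
    regime: str = "strong"              # "strong" or "weak"
    n_segregants: int = 200
    method: str = "sct"                 # "basic", "lcms" or "sct"
    sct: sct.SctParams = field(default_factory=lambda: sct.SctParams(M=40, I=100))
    beta: float = 16.0
    lcms_n_boot: int = 200
    lcms_linkage_alpha: float = 0.05
    candidate_k: int = 10
    n_iter: int = 100_000
    burn_in: int = 10_000
    sample_every: int = 20
    n_runs: int = 2
    snapshot_every: int = 2_000
    normalizer: str = "formal"
    seed: int = 0

    def sim_params(self, seed: int) -> simdata.SimParams:
        maker = simdata.SimParams.strong if self.regime == "strong" else simdata.SimParams.weak
        return maker(n_segregants=self.n_segregants, rng_seed=seed)


@dataclass
class ExperimentResult:
    """Artifacts of one experiment."""

    config: ExperimentConfig
    network: simnet.GeneNetwork
    dataset: simdata.EqtlDataset
    prior: sct.PriorMatrix | None
    traces: list[bn.McmcTrace]
    edge_frequencies: pd.DataFrame
    edge_curve: evaluate.PrCurve
    linkage_curve: evaluate.PrCurve
    univariate_curve: evaluate.PrCurve
    timings: dict[str, float] = field(default_factory=dict)

    def recall_at(self, precision: float = 0.8) -> dict[str, float]:
        return {
            "edges": evaluate.recall_at_precision(self.edge_curve, precision),
            "linkages": evaluate.recall_at_precision(self.linkage_curve, precision),
            "univariate": evaluate.recall_at_precision(self.univariate_curve, precision),
        }


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _edge_score_map(freq: pd.DataFrame, loci: list[str]) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    arr = freq.to_numpy()
    cols = list(freq.columns)
    locus_set = set(loci)
    for i, u in enumerate(freq.index):
        for j, v in enumerate(cols):
            if i == j or v in locus_set:
                continue
            if arr[i, j] > 0:
                out[(u, v)] = float(arr[i, j])
    return out


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> ExperimentResult:
    """Execute generate -> simulate -> prior -> learn -> evaluate -> map."""
    seeds = _sub_seeds(config.seed, 8)
    timings: dict[str, float] = {}

    def timed(stage):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.time()
            def __exit__(self_inner, *exc):
                timings[stage] = round(time.time() - self_inner.t0, 3)
        return _T()

    with timed("network"):
        net_cfg = simnet.NetGenConfig(
            n_transcripts=config.n_transcripts,
            n_loci=config.n_loci,
            n_extra_edges=config.n_extra_edges,
            rng_seed=seeds[0],
        )
        network = simnet.generate_network(net_cfg)

    with timed("data"):
        params = config.sim_params(seeds[1])
        dataset = simdata.simulate_dataset(network, params)

    prior = None
    if config.method == "sct":
        with timed("prior"):
            model = potentials.fit_background(
                dataset, seed=seeds[2], sim_params=params, n_cond_sims=5000
            )
            sct_params = sct.SctParams(
                M=config.sct.M, I=config.sct.I, c1=config.sct.c1, p=config.sct.p,
                rng_seed=seeds[3],
            )
            prior = sct.build_prior(
                dataset, network.loci, model, sct_params, normalizer=config.normalizer
            )
    elif config.method == "lcms":
        with timed("prior"):
            table = mapping.linkage_table_from_scan(dataset, alpha=config.lcms_linkage_alpha)
            prior = lcms.build_lcms_prior(
                dataset, table, n_boot=config.lcms_n_boot, seed=seeds[2]
            )
    elif config.method != "basic":
        raise ValueError("method must be one of basic/lcms/sct")

    with timed("discretize"):
        disc = bn.discretize(dataset, seed=seeds[4])
        cands = bn.candidate_sets(dataset, k=config.candidate_k)

    beta = config.beta if prior is not None else 0.0
    R = prior.R if prior is not None else None
    traces = []
    run_seeds = _sub_seeds(seeds[5], config.n_runs)
    with timed("mcmc"):
        for rs in run_seeds:
            traces.append(
                bn.mcmc_run(
                    disc, R, beta, cands,
                    n_iter=config.n_iter,
                    burn_in=config.burn_in,
                    sample_every=config.sample_every,
                    seed=rs,
                    snapshot_every=config.snapshot_every,
                )
            )

    with timed("evaluate"):
        tally = sum(t.edge_tally for t in traces)
        n_samples = sum(t.n_samples for t in traces)
        freq = pd.DataFrame(tally / n_samples, index=traces[0].nodes, columns=traces[0].nodes)
        truth_edges = set(network.edges)
        score_map = _edge_score_map(freq, network.loci)
        # ensure every true edge is scored even when never sampled
        for e in truth_edges:
            score_map.setdefault(e, 0.0)
        edge_curve = evaluate.pr_curve(score_map, truth_edges)

    with timed("mapping"):
        truth_links = mapping.network_linkages(network.to_digraph(), loci=network.loci).pairs
        dags = [g for t in traces for g in t.snapshot_digraphs()]
        if dags:
            link_freq = mapping.linkage_frequencies(dags, loci=network.loci)
        else:
            link_freq = mapping.LinkageSet(frequencies={})
        link_scores = dict(link_freq.frequencies)
        for pair in truth_links:
            link_scores.setdefault(pair, 0.0)
        linkage_curve = evaluate.pr_curve(link_scores, truth_links)

        tmat = mapping.univariate_scan(dataset)
        uni_scores = {
            (l, t): abs(float(tmat.loc[t, l]))
            for t in dataset.transcripts
            for l in dataset.loci
        }
        univariate_curve = evaluate.pr_curve(uni_scores, truth_links)

    result = ExperimentResult(
        config=config,
        network=network,
        dataset=dataset,
        prior=prior,
        traces=traces,
        edge_frequencies=freq,
        edge_curve=edge_curve,
        linkage_curve=linkage_curve,
        univariate_curve=univariate_curve,
        timings=timings,
    )
    if out_dir is not None:
        persist_result(result, Path(out_dir))
    return result


def persist_result(result: ExperimentResult, out_dir: Path) -> None:
    """Write all artifacts plus a manifest with config, seeds and hashes."""
    out_dir.mkdir(parents=True, exist_ok=True)
    simnet.write_edge_list(result.network, out_dir / "network.tsv")
    result.dataset.write(out_dir / "genotypes.tsv", out_dir / "expression.tsv")
    if result.prior is not None:
        result.prior.to_sparse_table(out_dir / "prior.tsv")
    result.edge_frequencies.to_csv(out_dir / "edge_frequencies.tsv", sep="\t")
    result.edge_curve.to_frame().to_csv(out_dir / "edge_pr.tsv", sep="\t", index=False)
    result.linkage_curve.to_frame().to_csv(out_dir / "linkage_pr.tsv", sep="\t", index=False)
    result.univariate_curve.to_frame().to_csv(out_dir / "univariate_pr.tsv", sep="\t", index=False)
    manifest = {
        "config": _config_dict(result.config),
        "timings": result.timings,
        "recall_at_0.8": result.recall_at(0.8),
        "edge_auc": result.edge_curve.auc,
        "files": {},
    }
    for f in sorted(out_dir.glob("*.tsv")):
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    return d


def make_fixtures(seed: int = 0) -> dict[str, simdata.EqtlDataset | simnet.GeneNetwork]:
    """Small deterministic bundles for unit tests and demos.

    * ``chain``: noiseless L1 -> Ta -> Tb chain (120 segregants);
    * ``confounder``: L1 drives Ta and Tb independently;
    * ``system20``: a 20-transcript / 2-locus simulated system.
    """
    seeds = _sub_seeds(seed, 4)
    out: dict = {}

    rng = np.random.default_rng(seeds[0])
    n = 120
    idx = [f"S{i+1}" for i in range(n)]
    g = rng.integers(0, 2, n)
    a_vals = 1.0 * g + rng.normal(0, 0.3, n)
    b_vals = 1.0 * a_vals + rng.normal(0, 0.3, n)
    chain_net = simnet.GeneNetwork(
        loci=["L1"], transcripts=["Ta", "Tb"],
        edges={("L1", "Ta"), ("Ta", "Tb")},
        locus_of_tree={"Ta": "L1", "Tb": "L1"},
    )
    chain_ds = simdata.EqtlDataset(
        genotypes=pd.DataFrame({"L1": g}, index=idx),
        expression=pd.DataFrame({"Ta": a_vals, "Tb": b_vals}, index=idx),
    )
    out["chain"] = (chain_net, chain_ds)

    rng = np.random.default_rng(seeds[1])
    g = rng.integers(0, 2, n)
    ta = 1.2 * g + rng.normal(0, 0.5, n)
    tb = 1.2 * g + rng.normal(0, 0.5, n)
    conf_net = simnet.GeneNetwork(
        loci=["L1"], transcripts=["Ta", "Tb"],
        edges={("L1", "Ta"), ("L1", "Tb")},
        locus_of_tree={"Ta": "L1", "Tb": "L1"},
    )
    conf_ds = simdata.EqtlDataset(
        genotypes=pd.DataFrame({"L1": g}, index=idx),
        expression=pd.DataFrame({"Ta": ta, "Tb": tb}, index=idx),
    )
    out["confounder"] = (conf_net, conf_ds)

    net20 = simnet.generate_network(
        simnet.NetGenConfig(n_transcripts=20, n_loci=2, n_extra_edges=4, rng_seed=seeds[2])
    )
    ds20 = simdata.simulate_dataset(
        net20, simdata.SimParams.strong(n_segregants=150, rng_seed=seeds[3])
    )
    out["system20"] = (net20, ds20)
    return out
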