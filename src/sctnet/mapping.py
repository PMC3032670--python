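"""eQTL mapping: network reachability linkages and the univariate t-scan.

Network-based mapping associates a transcript with a locus whenever the
transcript is reachable from the locus by a directed path (a depth-first
search from each head node); over a collection of sampled networks the
per-pair linkage frequency estimates the posterior linkage probability.
The traditional baseline partitions each transcript's expression by the
genotype at each locus and computes a two-sample pooled-variance t
statistic; an experimentwise permutation scheme (expression rows shuffled
against the genotype matrix, null statistics pooled across transcripts)
converts |t| thresholds into false-discovery-rate estimates
FDR(tau) = E[null count >= tau] / observed count >= tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from sctnet.simdata import EqtlDataset

__all__ = [
    "LinkageSet",
    "network_linkages",
    "linkage_frequencies",
    "univariate_scan",
    "permutation_fdr",
    "linkage_table_from_scan",
]


@dataclass
class LinkageSet:
    """(locus, transcript) pairs with optional frequencies.

    ``provenance`` is "network" (frequencies in [0, 1]) or "univariate".
    """

    frequencies: dict[tuple[str, str], float]
    provenance: str = "network"
    threshold: float | None = None

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.frequencies)

    def above(self, threshold: float) -> set[tuple[str, str]]:
        return {k for k, v in self.frequencies.items() if v >= threshold}

    def to_table(self, path) -> None:
        rows = [(l, t, f) for (l, t), f in sorted(self.frequencies.items())]
        pd.DataFrame(rows, columns=["locus", "transcript", "score"]).to_csv(
            path, sep="\t", index=False
        )


def _loci_of(dag: nx.DiGraph, loci: list[str] | None) -> list[str]:
    if loci is not None:
        return [l for l in loci if l in dag]
    return [n for n in dag.nodes if str(n).startswith("L")]


def network_linkages(dag: nx.DiGraph, loci: list[str] | None = None) -> LinkageSet:
    """Linkages implied by one DAG: transcript reachable from locus.

    ``loci`` defaults to nodes named with the "L" prefix.
    """
    freqs: dict[tuple[str, str], float] = {}
    for locus in _loci_of(dag, loci):
        for node in nx.descendants(dag, locus):
            freqs[(locus, node)] = 1.0
    return LinkageSet(frequencies=freqs, provenance="network")


def linkage_frequencies(dags: list[nx.DiGraph], loci: list[str] | None = None) -> LinkageSet:
    """Per-pair fraction of networks containing each linkage."""
    if not dags:
        raise ValueError("need at least one network")
    tally: dict[tuple[str, str], int] = {}
    for dag in dags:
        for pair in network_linkages(dag, loci).pairs:
            tally[pair] = tally.get(pair, 0) + 1
    n = len(dags)
    return LinkageSet(
        frequencies={k: v / n for k, v in tally.items()}, provenance="network"
    )


def _t_statistics(expr: np.ndarray, geno: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per (transcript, locus).

    ``expr``: samples x transcripts; ``geno``: samples x loci in {0, 1}.
    Loci with a single genotype class yield NaN columns with a warning.
    """
    n, n_t = expr.shape
    n_l = geno.shape[1]
    out = np.full((n_t, n_l), np.nan)
    for j in range(n_l):
        mask = geno[:, j] == 1
        n1 = int(mask.sum())
        n0 = n - n1
        if n1 == 0 or n0 == 0:
            warnings.warn(f"locus column {j} has a single genotype class")
            continue
        g1 = expr[mask]
        g0 = expr[~mask]
        m1 = g1.mean(axis=0)
        m0 = g0.mean(axis=0)
        v1 = g1.var(axis=0, ddof=1) if n1 > 1 else np.zeros(n_t)
        v0 = g0.var(axis=0, ddof=1) if n0 > 1 else np.zeros(n_t)
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        with np.errstate(divide="ignore", invalid="ignore"):
            out[:, j] = np.where(se > 0, (m1 - m0) / se, 0.0)
    return out


def univariate_scan(dataset: EqtlDataset) -> pd.DataFrame:
    """t-statistic matrix, transcripts x loci."""
    t = _t_statistics(
        dataset.expression.to_numpy(dtype=float),
        dataset.genotypes.to_numpy(),
    )
    return pd.DataFrame(t, index=dataset.transcripts, columns=dataset.loci)


@dataclass
class FdrCurve:
    """Permutation FDR as a function of the |t| threshold."""

    thresholds: np.ndarray
    fdr_raw: np.ndarray          # raw quotient, NaN where observed count is 0
    fdr_monotone: np.ndarray     # running max downward from strictest threshold
    n_perm: int = 0

    def at(self, tau: float, monotone: bool = True) -> float:
        curve = self.fdr_monotone if monotone else self.fdr_raw
        pos = np.searchsorted(self.thresholds, tau, side="right") - 1
        if pos < 0:
            return 1.0
        return float(curve[pos])


def permutation_fdr(
    dataset: EqtlDataset,
    n_perm: int = 1000,
    seed: int = 0,
    thresholds: np.ndarray | None = None,
) -> FdrCurve:
    """Estimate FDR(tau) for thresholds tau on |t|.

    Each permutation shuffles the expression rows against the genotypes
    (one permutation per replicate for all transcripts jointly); null |t|
    values are pooled across transcripts and loci.  FDR(tau) is the mean
    null exceedance count over the observed exceedance count, capped at 1;
    thresholds where the observed count is zero are NaN in ``fdr_raw`` and
    resolved by the monotone envelope where possible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    expr = dataset.expression.to_numpy(dtype=float)
    geno = dataset.genotypes.to_numpy()
    obs = np.abs(_t_statistics(expr, geno)).ravel()
    obs = obs[~np.isnan(obs)]
    if thresholds is None:
        thresholds = np.linspace(0.0, float(obs.max()) if obs.size else 1.0, 201)
    thresholds = np.asarray(thresholds, dtype=float)

    null_counts = np.zeros_like(thresholds)
    n = expr.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        t_null = np.abs(_t_statistics(expr[perm], geno)).ravel()
        t_null = t_null[~np.isnan(t_null)]
        null_counts += np.searchsorted(np.sort(-t_null), -thresholds, side="right")
    null_mean = null_counts / n_perm

    obs_sorted = np.sort(obs)
    obs_counts = obs.size - np.searchsorted(obs_sorted, thresholds, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(obs_counts > 0, np.minimum(null_mean / obs_counts, 1.0), np.nan)

    mono = raw.copy()
    # running maximum from the strictest (largest) threshold downward
    best = 0.0
    for i in range(len(mono) - 1, -1, -1):
        if np.isnan(mono[i]):
            continue
        best = max(best, mono[i])
        mono[i] = best
    return FdrCurve(thresholds=thresholds, fdr_raw=raw, fdr_monotone=mono, n_perm=n_perm)


def linkage_table_from_scan(
    dataset: EqtlDataset, alpha: float = 0.05
) -> dict[str, set[str]]:
    """Transcript -> loci linked at nominal two-sided p < alpha (t-test)."""
    from scipy import stats

    t = univariate_scan(dataset)
    n = dataset.n_segregants
    crit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    table: dict[str, set[str]] = {}
    arr = np.abs(t.to_numpy())
    for i, tr in enumerate(dataset.transcripts):
        linked = {dataset.loci[j] for j in np.flatnonzero(arr[i] > crit)}
        if linked:
            table[tr] = linked
    return table
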