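"""Simulation of genotype and expression data from a ground-truth network.

Genotypes are i.i.d. Bernoulli(0.5) in {0, 1} per locus (independent loci,
haploid segregants from a two-parent cross).  Expression is generated in
topological order: each transcript is a linear combination of its realized
parent values plus Gaussian noise,

    y = sum_i a_i x_i + eps,        eps ~ N(0, noise_sd^2),

and a fraction of multi-parent transcripts additionally carries pairwise
interaction terms sum_{i<j} k_ij x_i x_j.  Coefficient magnitudes are drawn
from N(a_mean, a_sd) with a 70/30 positive/negative sign split; interaction
coefficients from N(k_mean, k_sd).  Two parameter regimes are bundled: the
"strong" regime (a_mean = 0.75) yields a mean parent-child correlation
magnitude of about 0.68, the "weak" regime (a_mean = 0.6) about 0.55.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from sctnet.simnet import GeneNetwork

__all__ = [
    "SimParams",
    "EqtlDataset",
    "simulate_genotypes",
    "assign_model",
    "simulate_expression",
    "simulate_dataset",
    "correlation_summary",
]


@dataclass
class SimParams:
    """Parameters of the expression-generating regression model."""

    a_mean: float = 0.75
    a_sd: float = 0.2
    sign_pos_prob: float = 0.7
    k_mean: float = 0.5
    k_sd: float = 0.1
    interaction_fraction: float = 0.1
    noise_sd: float = 1.0
    n_segregants: int = 300
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("a_sd", "k_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sign_pos_prob", "interaction_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def strong(cls, **kw) -> "SimParams":
        """Strong-correlation regime (mean parent-child |r| ~= 0.68)."""
        return cls(a_mean=0.75, **kw)

    @classmethod
    def weak(cls, **kw) -> "SimParams":
        """Weak-correlation regime (mean parent-child |r| ~= 0.55)."""
        return cls(a_mean=0.6, **kw)

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, rng_seed=seed)


@dataclass
class EqtlDataset:
    """Paired genotype and expression matrices over the same segregants.

    ``genotypes``: segregants x loci DataFrame with {0, 1} entries.
    ``expression``: segregants x transcripts DataFrame of continuous values.
    """

    genotypes: pd.DataFrame
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.expression):
            raise ValueError("genotype and expression row counts differ")
        vals = self.genotypes.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("genotype entries must be 0/1")
        if self.expression.isna().any().any() or self.genotypes.isna().any().any():
            raise ValueError("missing values are not supported")

    @property
    def n_segregants(self) -> int:
        return len(self.genotypes)

    @property
    def loci(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def transcripts(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def nodes(self) -> list[str]:
        return self.loci + self.transcripts

    def values_of(self, node: str) -> np.ndarray:
        if node in self.genotypes.columns:
            return self.genotypes[node].to_numpy(dtype=float)
        return self.expression[node].to_numpy(dtype=float)

    def as_matrix(self) -> np.ndarray:
        """Segregants x nodes matrix with loci columns first."""
        return np.hstack(
            [self.genotypes.to_numpy(dtype=float), self.expression.to_numpy(dtype=float)]
        )

    def write(self, genotype_path: str | Path, expression_path: str | Path) -> None:
        self.genotypes.to_csv(genotype_path, sep="\t", index_label="segregant")
        self.expression.to_csv(expression_path, sep="\t", index_label="segregant")

    @classmethod
    def read(cls, genotype_path: str | Path, expression_path: str | Path) -> "EqtlDataset":
        geno = pd.read_csv(genotype_path, sep="\t", index_col="segregant")
        expr = pd.read_csv(expression_path, sep="\t", index_col="segregant")
        return cls(genotypes=geno, expression=expr)


def simulate_genotypes(n_segregants: int, n_loci: int, seed: int = 0,
                       loci: list[str] | None = None) -> pd.DataFrame:
    """Independent Bernoulli(0.5) genotypes coded {0, 1}."""
    if n_segregants < 1 or n_loci < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    mat = rng.integers(0, 2, size=(n_segregants, n_loci))
    cols = loci if loci is not None else [f"L{i + 1}" for i in range(n_loci)]
    idx = [f"S{i + 1}" for i in range(n_segregants)]
    return pd.DataFrame(mat, index=idx, columns=cols)


def assign_model(
    network: GeneNetwork, params: SimParams, seed: int = 0
) -> dict[str, tuple[dict[str, float], dict[tuple[str, str], float]]]:
    """Draw regression coefficients for every transcript of the network.

    Returns ``{child: ({parent: a}, {(parent_i, parent_j): k})}`` where the
    interaction dict is empty unless the child was selected as an
    interaction transcript.  The number of interaction transcripts is
    ``round(interaction_fraction * #transcripts with >= 2 parents)``.
    """
    rng = np.random.default_rng(seed)
    parents = network.parents_of()
    coeffs: dict[str, tuple[dict[str, float], dict[tuple[str, str], float]]] = {}
    multi: list[str] = []
    for t in network.transcripts:
        ps = parents[t]
        if not ps:
            raise ValueError(f"transcript {t} has no parents")
        a_map: dict[str, float] = {}
        for p in ps:
            mag = rng.normal(params.a_mean, params.a_sd)
            sign = 1.0 if rng.random() < params.sign_pos_prob else -1.0
            a_map[p] = sign * mag
        coeffs[t] = (a_map, {})
        if len(ps) >= 2:
            multi.append(t)

    n_inter = int(round(params.interaction_fraction * len(multi)))
    if n_inter > 0:
        chosen = rng.choice(len(multi), size=n_inter, replace=False)
        for idx in chosen:
            child = multi[idx]
            ps = parents[child]
            k_map = {
                (ps[i], ps[j]): rng.normal(params.k_mean, params.k_sd)
                for i in range(len(ps))
                for j in range(i + 1, len(ps))
            }
            coeffs[child] = (coeffs[child][0], k_map)
    return coeffs


def simulate_expression(
    network: GeneNetwork,
    genotypes: pd.DataFrame,
    coefficients: dict[str, tuple[dict[str, float], dict[tuple[str, str], float]]],
    params: SimParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Realize expression values in topological order.

    Each transcript column is its (possibly interaction-augmented) linear
    combination of realized parent columns plus independent N(0, noise_sd^2)
    error per segregant.
    """
    rng = np.random.default_rng(seed)
    g = network.to_digraph()
    try:
        topo = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:  # pragma: no cover - guarded upstream
        raise ValueError("network is not acyclic") from exc

    n = len(genotypes)
    values: dict[str, np.ndarray] = {
        l: genotypes[l].to_numpy(dtype=float) for l in network.loci
    }
    # noise drawn in fixed transcript order so realizations do not depend on
    # the particular topological order chosen
    noise = {
        t: rng.normal(0.0, params.noise_sd, size=n) for t in network.transcripts
    }
    for node in topo:
        if node in values:
            continue
        a_map, k_map = coefficients[node]
        y = noise[node]
        for p, a in a_map.items():
            y = y + a * values[p]
        for (pi, pj), k in k_map.items():
            y = y + k * values[pi] * values[pj]
        values[node] = y

    expr = pd.DataFrame(
        {t: values[t] for t in network.transcripts}, index=genotypes.index
    )
    return expr


def simulate_dataset(network: GeneNetwork, params: SimParams) -> EqtlDataset:
    """Convenience wrapper: genotypes + coefficients + expression.

    Sub-seeds for the three stages are derived deterministically from
    ``params.rng_seed``.
    """
    ss = np.random.SeedSequence(params.rng_seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    geno = simulate_genotypes(params.n_segregants, len(network.loci), seeds[0], loci=network.loci)
    coeffs = assign_model(network, params, seeds[1])
    expr = simulate_expression(network, geno, coeffs, params, seeds[2])
    return EqtlDataset(genotypes=geno, expression=expr)


def edge_correlations(network: GeneNetwork, dataset: EqtlDataset) -> np.ndarray:
    """Absolute Pearson correlation for every true edge.

    Point-biserial (ordinary Pearson on the 0/1 coding) when the parent is
    a locus.  Zero-variance columns are skipped with a warning.
    """
    out = []
    for p, c in sorted(network.edges):
        x = dataset.values_of(p)
        y = dataset.values_of(c)
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"zero-variance column on edge ({p}, {c}); skipped")
            continue
        r = np.corrcoef(x, y)[0, 1]
        out.append(abs(r))
    return np.asarray(out)


def correlation_summary(network: GeneNetwork, dataset: EqtlDataset) -> tuple[float, float, float]:
    """(mean, 5th percentile, 95th percentile) of per-edge |Pearson r|.

    The percentile pair delimits the central 90% interval of the edge
    correlation-magnitude distribution.
    """
    r = edge_correlations(network, dataset)
    if r.size == 0:
        raise ValueError("no usable edges")
    return float(r.mean()), float(np.percentile(r, 5)), float(np.percentile(r, 95))
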