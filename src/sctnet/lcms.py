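"""Likelihood-based causal model selection (LCMS) comparator prior.

For a triplet of two transcripts (tx, ty) and one biallelic locus L, three
models are scored: M1 (tx causal for ty), M2 (ty causal for tx) and M3
(tx and ty respond to L independently).  Each model likelihood iterates
over samples and mixes over the two genotype classes with empirical class
frequencies P(Lj):

    M1 = prod_i sum_j P(Lj) l(tx_i | Lj) l(ty_i | tx_i)
    M2 = prod_i sum_j P(Lj) l(ty_i | Lj) l(tx_i | ty_i)
    M3 = prod_i sum_j P(Lj) l(tx_i | Lj) l(ty_i | tx_i, Lj)

Component likelihoods are Gaussian with per-genotype-class maximum
likelihood parameters.  The conditional term of M3 is the conditional
bivariate normal of ty given (tx, Lj) under the independence constraint:
with the partial correlation of tx and ty fixed at zero it reduces to the
per-class marginal l(ty | Lj).  (Realizing it instead as an unconstrained
per-class regression of ty on tx would make M3 the richest model and let
it win on almost any data, destroying the three-way model selection.)
Bootstrapping segregants with replacement and recording which model wins
each resample converts the likelihoods into model probabilities, which the
two-branch prior rule turns into directed pair scores: when any anchoring
locus gives the independence model probability above 0.5 the score is
downweighted to ``1 - sum_j p_m3``, otherwise it is
``sum_j 2 * p_m1 / (p_m1 + p_m2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sctnet.sct import PriorMatrix
from sctnet.simdata import EqtlDataset

__all__ = [
    "TripletResult",
    "triplet_likelihoods",
    "bootstrap_probs",
    "pair_prior",
    "build_lcms_prior",
]

_VAR_FLOOR = 1e-12
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class TripletResult:
    """Bootstrap model probabilities for one (tx, ty, locus) triplet."""

    tx: str
    ty: str
    lj: str
    p_m1: float
    p_m2: float
    p_m3: float

    def __post_init__(self) -> None:
        total = self.p_m1 + self.p_m2 + self.p_m3
        if abs(total - 1.0) > 1e-9:
            raise ValueError("model probabilities must sum to 1")

    def swapped(self) -> "TripletResult":
        """The same triplet with tx and ty exchanged (swaps M1 and M2)."""
        return TripletResult(tx=self.ty, ty=self.tx, lj=self.lj,
                             p_m1=self.p_m2, p_m2=self.p_m1, p_m3=self.p_m3)


def _log_normal(x, mu, var):
    var = np.maximum(var, _VAR_FLOOR)
    return -0.5 * (_LOG2PI + np.log(var) + (x - mu) ** 2 / var)


def _class_moments(v, mask, counts):
    """Masked per-row mean and ML variance; v, mask are (B, n)."""
    s = (v * mask).sum(axis=1)
    mu = s / counts
    ss = (v * v * mask).sum(axis=1)
    var = ss / counts - mu**2
    return mu, np.maximum(var, _VAR_FLOOR)


def _regression(x, y, mask=None, counts=None):
    """Rowwise OLS of y on x (optionally masked): intercept, slope, ML var."""
    if mask is None:
        n = x.shape[1]
        mx, my = x.mean(axis=1), y.mean(axis=1)
        sxx = (x * x).mean(axis=1) - mx**2
        sxy = (x * y).mean(axis=1) - mx * my
        syy = (y * y).mean(axis=1) - my**2
    else:
        mx = (x * mask).sum(axis=1) / counts
        my = (y * mask).sum(axis=1) / counts
        sxx = (x * x * mask).sum(axis=1) / counts - mx**2
        sxy = (x * y * mask).sum(axis=1) / counts - mx * my
        syy = (y * y * mask).sum(axis=1) / counts - my**2
    slope = sxy / np.maximum(sxx, _VAR_FLOOR)
    intercept = my - slope * mx
    resid_var = syy - slope * sxy
    return intercept, slope, np.maximum(resid_var, _VAR_FLOOR)


def _model_logliks(tx, ty, loc):
    """Log-likelihoods of (M1, M2, M3) for batched triplets.

    ``tx``, ``ty`` are (B, n) floats; ``loc`` is (B, n) in {0, 1}.  Rows
    must contain both genotype classes.
    """
    m1 = loc
    m0 = 1.0 - loc
    n = tx.shape[1]
    n1 = m1.sum(axis=1)
    n0 = n - n1
    p1 = (n1 / n)[:, None]
    p0 = (n0 / n)[:, None]

    mu_x0, var_x0 = _class_moments(tx, m0, n0)
    mu_x1, var_x1 = _class_moments(tx, m1, n1)
    mu_y0, var_y0 = _class_moments(ty, m0, n0)
    mu_y1, var_y1 = _class_moments(ty, m1, n1)

    lx0 = _log_normal(tx, mu_x0[:, None], var_x0[:, None])
    lx1 = _log_normal(tx, mu_x1[:, None], var_x1[:, None])
    ly0 = _log_normal(ty, mu_y0[:, None], var_y0[:, None])
    ly1 = _log_normal(ty, mu_y1[:, None], var_y1[:, None])

    mix_x = np.logaddexp(np.log(p0) + lx0, np.log(p1) + lx1)
    mix_y = np.logaddexp(np.log(p0) + ly0, np.log(p1) + ly1)

    a_yx, b_yx, v_yx = _regression(tx, ty)  # ty ~ tx, all samples
    a_xy, b_xy, v_xy = _regression(ty, tx)  # tx ~ ty, all samples
    l_y_given_x = _log_normal(ty, a_yx[:, None] + b_yx[:, None] * tx, v_yx[:, None])
    l_x_given_y = _log_normal(tx, a_xy[:, None] + b_xy[:, None] * ty, v_xy[:, None])

    log_m1 = (mix_x + l_y_given_x).sum(axis=1)
    log_m2 = (mix_y + l_x_given_y).sum(axis=1)

    # M3: under conditional independence the bivariate normal of (tx, ty)
    # given the genotype class has zero partial correlation, so the
    # conditional term l(ty | tx, Lj) reduces to the per-class marginal
    # l(ty | Lj); the two per-class factors stay coupled inside the mixture
    mix3 = np.logaddexp(np.log(p0) + lx0 + ly0, np.log(p1) + lx1 + ly1)
    log_m3 = mix3.sum(axis=1)
    return log_m1, log_m2, log_m3


def triplet_likelihoods(tx_values, ty_values, locus_values):
    """(log M1, log M2, log M3) for a single triplet.

    Raises when either genotype class has fewer than 3 samples (the
    per-class Gaussian fits would be degenerate).
    """
    tx = np.asarray(tx_values, dtype=float)[None, :]
    ty = np.asarray(ty_values, dtype=float)[None, :]
    loc = np.asarray(locus_values, dtype=float)[None, :]
    if not (tx.shape == ty.shape == loc.shape):
        raise ValueError("length mismatch")
    n1 = loc.sum()
    n0 = loc.size - n1
    if n1 < 3 or n0 < 3:
        raise ValueError("each genotype class needs at least 3 samples")
    m1, m2, m3 = _model_logliks(tx, ty, loc)
    return float(m1[0]), float(m2[0]), float(m3[0])


def bootstrap_probs(
    tx: str,
    ty: str,
    lj: str,
    dataset: EqtlDataset,
    n_boot: int = 1000,
    seed: int = 0,
) -> TripletResult:
    """Bootstrap model probabilities for one triplet.

    Segregants are resampled with replacement ``n_boot`` times; each
    model's probability is the fraction of resamples it wins.  Resamples
    with a genotype class below 3 members are redrawn up to 10 times and
    skipped (with a warning) if still degenerate.
    """
    rng = np.random.default_rng(seed)
    x = dataset.values_of(tx)
    y = dataset.values_of(ty)
    l = dataset.values_of(lj)
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))

    lb = l[idx]
    bad = (lb.sum(axis=1) < 3) | ((n - lb.sum(axis=1)) < 3)
    for _ in range(10):
        if not bad.any():
            break
        redraw = rng.integers(0, n, size=(int(bad.sum()), n))
        idx[bad] = redraw
        lb = l[idx]
        bad = (lb.sum(axis=1) < 3) | ((n - lb.sum(axis=1)) < 3)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} degenerate bootstrap resamples skipped")
        idx = idx[~bad]

    m1, m2, m3 = _model_logliks(x[idx], y[idx], l[idx])
    wins = np.argmax(np.stack([m1, m2, m3], axis=1), axis=1)
    total = wins.size
    if total == 0:
        raise ValueError("all bootstrap resamples were degenerate")
    return TripletResult(
        tx=tx, ty=ty, lj=lj,
        p_m1=float((wins == 0).sum() / total),
        p_m2=float((wins == 1).sum() / total),
        p_m3=float((wins == 2).sum() / total),
    )


def pair_prior(results: list[TripletResult]) -> float:
    """Directed prior score for the (tx, ty) orientation of the results.

    First branch (independence downweighting) applies when any anchoring
    locus gives the independence model probability above 0.5; scores are
    unnormalized (second branch per-locus terms lie in (0, 2]).
    """
    if not results:
        raise ValueError("need at least one triplet result")
    if any(r.p_m3 > 0.5 for r in results):
        return 1.0 - sum(r.p_m3 for r in results)
    total = 0.0
    for r in results:
        denom = r.p_m1 + r.p_m2
        total += 2.0 * r.p_m1 / denom if denom > 0 else 1.0
    return total


def build_lcms_prior(
    dataset: EqtlDataset,
    linkage_table: dict[str, set[str]],
    n_boot: int = 1000,
    seed: int = 0,
    rescale: bool = False,
) -> PriorMatrix:
    """Assemble the LCMS prior matrix over all transcript pairs.

    ``linkage_table`` maps each transcript to the loci it links to (from a
    univariate scan); every ordered transcript pair sharing at least one
    linked locus is scored over all shared loci.  Raw pair scores are
    clipped into [0, 1] unless ``rescale`` divides by the maximum positive
    score first (negative scores always floor at 0).
    """
    rng = np.random.default_rng(seed)
    nodes = dataset.nodes
    R = pd.DataFrame(0.0, index=nodes, columns=nodes)
    transcripts = [t for t in dataset.transcripts if linkage_table.get(t)]
    raw: dict[tuple[str, str], float] = {}
    for i, tx in enumerate(transcripts):
        for ty in transcripts[i + 1:]:
            shared = sorted(linkage_table[tx] & linkage_table[ty])
            if not shared:
                continue
            trips = [
                bootstrap_probs(tx, ty, lj, dataset, n_boot=n_boot,
                                seed=int(rng.integers(2**31)))
                for lj in shared
            ]
            raw[(tx, ty)] = pair_prior(trips)
            raw[(ty, tx)] = pair_prior([t.swapped() for t in trips])

    if raw:
        if rescale:
            top = max(v for v in raw.values())
            scale = top if top > 0 else 1.0
        else:
            scale = 1.0
        for (a, b), v in raw.items():
            R.loc[a, b] = min(max(v / scale, 0.0), 1.0)
    return PriorMatrix(R=R, provenance="lcms")
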