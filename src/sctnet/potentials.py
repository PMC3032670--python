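"""Regression potentials and their background likelihood models.

The causal-tree score is built from two potentials measured on a candidate
child ``n_c`` with parent ``n_p`` and grandparent ``n_g``:

* the pair potential ``phi(n_p, n_c)``: the coefficient of determination
  (R^2 = SSR/SSTO) of the simple OLS regression ``n_c ~ n_p``;
* the conditional potential ``phi(n_g, n_c | n_p)``: regress ``n_c`` on
  ``n_p``, take the residuals ``e``, then the R^2 of ``e ~ n_g``.  When
  ``n_p`` sits between ``n_g`` and ``n_c`` on a causal chain the residuals
  carry no further signal from ``n_g``, so this potential is near zero.

Observed pair potentials are judged against per-node background sampling
distributions: for each node the mean and SD of the potential against
randomly drawn partners, separately for the node acting as explanatory
variable and as response (genomic loci only ever act as explanatory
variables).  The pair likelihood is a bivariate Gaussian over the two
standardized scores with covariance rho (zero here); the conditional
likelihood is a zero-mean univariate Gaussian whose SD is estimated by
simulating linear causal chains.  The transition score combines them as

    LLS(n_c; n_p, n_g) = c1 * log l(phi(n_g, n_c | n_p)) - log l(phi(n_p, n_c))

so a transition is favoured when the pair potential is *unusually strong*
for the two nodes (low background density) and the conditional potential is
near its null value of zero (high conditional density).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from sctnet.simdata import EqtlDataset, SimParams

__all__ = [
    "BackgroundModel",
    "pair_potential",
    "conditional_potential",
    "conditional_potential_from_corr",
    "correlation_matrix",
    "fit_background",
    "pair_likelihood",
    "conditional_likelihood",
    "log_likelihood_score",
    "score_from_potentials",
]

#: floor applied to likelihood densities before taking logs
LIKELIHOOD_FLOOR = 1e-300


def _check_variance(x: np.ndarray, role: str) -> None:
    if np.std(x) == 0:
        raise ValueError(f"{role} variable has zero variance")


def pair_potential(parent_values: np.ndarray, child_values: np.ndarray) -> float:
    """R^2 of the OLS regression of child on parent (with intercept).

    Equals the squared Pearson correlation.  A zero-variance parent is an
    error; a zero-variance child returns 0 with a warning.
    """
    x = np.asarray(parent_values, dtype=float)
    y = np.asarray(child_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    _check_variance(x, "explanatory")
    if np.std(y) == 0:
        warnings.warn("zero-variance response; pair potential set to 0")
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def conditional_potential(
    grand_values: np.ndarray, child_values: np.ndarray, parent_values: np.ndarray
) -> float:
    """R^2 of (residuals of child ~ parent) regressed on the grandparent."""
    g = np.asarray(grand_values, dtype=float)
    y = np.asarray(child_values, dtype=float)
    x = np.asarray(parent_values, dtype=float)
    if not (g.shape == y.shape == x.shape):
        raise ValueError("length mismatch")
    _check_variance(x, "parent")
    _check_variance(g, "grandparent")
    xc = x - x.mean()
    beta = float(xc @ (y - y.mean())) / float(xc @ xc)
    resid = y - (y.mean() + beta * xc)
    # a (numerically) perfect first-stage fit leaves no signal to explain
    if np.std(resid) <= 1e-12 * max(1.0, float(np.std(y))):
        return 0.0
    r = np.corrcoef(g, resid)[0, 1]
    return float(r * r)


def conditional_potential_from_corr(r_gc, r_pc, r_gp):
    """Closed form of the conditional potential from pairwise correlations.

    For regressions fitted with intercepts the two-step procedure reduces to
    ``(r_gc - r_pc * r_gp)^2 / (1 - r_pc^2)``; agrees with
    :func:`conditional_potential` to numerical precision (tested property).
    """
    r_gc = np.asarray(r_gc, dtype=float)
    r_pc = np.asarray(r_pc, dtype=float)
    r_gp = np.asarray(r_gp, dtype=float)
    denom = 1.0 - np.square(r_pc)
    num = np.square(r_gc - r_pc * r_gp)
    safe = np.where(denom <= 0, 1.0, denom)
    return np.where(denom <= 0, 0.0, num / safe)


@dataclass
class BackgroundModel:
    """Per-node background distributions of the pair potential.

    ``mu_expl``/``sd_expl`` describe a node acting as explanatory variable,
    ``mu_resp``/``sd_resp`` as response.  Loci have no response entries.
    ``sd_cond`` is the global SD of the conditional potential under the
    null (linear chain) model, with an assumed mean of zero.
    """

    mu_expl: dict[str, float]
    sd_expl: dict[str, float]
    mu_resp: dict[str, float]
    sd_resp: dict[str, float]
    sd_cond: float
    rho: float = 0.0
    n_background_samples: int = 0

    def __post_init__(self) -> None:
        for name, d in (("sd_expl", self.sd_expl), ("sd_resp", self.sd_resp)):
            bad = [k for k, v in d.items() if not v > 0]
            if bad:
                raise ValueError(f"{name} not positive for nodes {bad[:5]}")
        if not self.sd_cond > 0:
            raise ValueError("sd_cond must be positive")

    def to_table(self, path: str | Path) -> None:
        rows = []
        for node in self.mu_expl:
            rows.append(("expl", node, self.mu_expl[node], self.sd_expl[node]))
        for node in self.mu_resp:
            rows.append(("resp", node, self.mu_resp[node], self.sd_resp[node]))
        rows.append(("sd_cond", "*", 0.0, self.sd_cond))
        rows.append(("rho", "*", self.rho, 1.0))
        pd.DataFrame(rows, columns=["role", "node", "mean", "sd"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_table(cls, path: str | Path) -> "BackgroundModel":
        df = pd.read_csv(path, sep="\t")
        mu_e, sd_e, mu_r, sd_r = {}, {}, {}, {}
        sd_cond, rho = 0.0, 0.0
        for _, row in df.iterrows():
            if row.role == "expl":
                mu_e[row.node], sd_e[row.node] = row["mean"], row["sd"]
            elif row.role == "resp":
                mu_r[row.node], sd_r[row.node] = row["mean"], row["sd"]
            elif row.role == "sd_cond":
                sd_cond = row["sd"]
            elif row.role == "rho":
                rho = row["mean"]
        return cls(mu_expl=mu_e, sd_expl=sd_e, mu_resp=mu_r, sd_resp=sd_r,
                   sd_cond=sd_cond, rho=rho)


def _standardized_matrix(dataset: EqtlDataset) -> tuple[np.ndarray, list[str]]:
    mat = dataset.as_matrix()
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    if (sd == 0).any():
        bad = [dataset.nodes[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"degenerate (constant) columns: {bad[:5]}")
    return (mat - mu) / sd, dataset.nodes


def correlation_matrix(dataset: EqtlDataset) -> pd.DataFrame:
    """Pearson correlations between all node pairs (point-biserial vs loci)."""
    z, nodes = _standardized_matrix(dataset)
    c = (z.T @ z) / z.shape[0]
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=nodes, columns=nodes)


def simulate_chain_conditionals(
    n_sims: int, n_samples: int, params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    """Conditional potentials of freshly simulated linear chains x -> y -> z.

    The root is standard normal; each downstream variable is its parent
    scaled by a coefficient drawn like the expression-model coefficients
    (magnitude N(a_mean, a_sd), sign per sign_pos_prob) plus Gaussian noise.
    """
    x = rng.normal(size=(n_sims, n_samples))
    mag = rng.normal(params.a_mean, params.a_sd, size=(n_sims, 2))
    sign = np.where(rng.random(size=(n_sims, 2)) < params.sign_pos_prob, 1.0, -1.0)
    a = mag * sign
    y = a[:, :1] * x + rng.normal(0.0, params.noise_sd, size=(n_sims, n_samples))
    z = a[:, 1:] * y + rng.normal(0.0, params.noise_sd, size=(n_sims, n_samples))

    def std(v):
        return (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)

    xs, ys, zs = std(x), std(y), std(z)
    n = n_samples
    r_gp = np.einsum("ij,ij->i", xs, ys) / n  # grandparent-parent (x, y)
    r_pc = np.einsum("ij,ij->i", ys, zs) / n  # parent-child (y, z)
    r_gc = np.einsum("ij,ij->i", xs, zs) / n  # grandparent-child (x, z)
    return np.asarray(conditional_potential_from_corr(r_gc, r_pc, r_gp))


def fit_background(
    dataset: EqtlDataset,
    n_background_samples: int = 500,
    n_cond_sims: int = 10_000,
    seed: int = 0,
    sim_params: SimParams | None = None,
) -> BackgroundModel:
    """Fit per-node background distributions and the conditional-potential SD.

    For each node, ``n_background_samples`` random interaction partners are
    drawn per role (without replacement; exhaustively when the pool is not
    larger than the request, in which case the sample moments equal the
    exhaustive ones).  Loci are restricted to the explanatory role, so
    explanatory-role partners are always transcripts while response-role
    partners may be any node.  ``sd_cond`` is the root-mean-square of the
    conditional potential over ``n_cond_sims`` simulated linear chains of
    the dataset's sample size (mean assumed zero).
    """
    if dataset.n_segregants < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    z, nodes = _standardized_matrix(dataset)
    n = z.shape[0]
    index = {node: i for i, node in enumerate(nodes)}
    transcript_idx = np.array([index[t] for t in dataset.transcripts])

    def sample_phi(i: int, pool: np.ndarray) -> np.ndarray:
        pool = pool[pool != i]
        if pool.size == 0:
            raise ValueError("no background partners available")
        if pool.size > n_background_samples:
            pool = rng.choice(pool, size=n_background_samples, replace=False)
        r = (z[:, pool].T @ z[:, i]) / n
        return r * r

    mu_e, sd_e, mu_r, sd_r = {}, {}, {}, {}
    all_idx = np.arange(len(nodes))
    for node, i in index.items():
        phis = sample_phi(i, transcript_idx)  # node explains a transcript
        mu_e[node], sd_e[node] = float(phis.mean()), float(phis.std(ddof=1))
    for node in dataset.transcripts:
        i = index[node]
        phis = sample_phi(i, all_idx)  # node responds to any partner
        mu_r[node], sd_r[node] = float(phis.mean()), float(phis.std(ddof=1))

    params = sim_params if sim_params is not None else SimParams()
    cond = simulate_chain_conditionals(n_cond_sims, n, params, rng)
    sd_cond = float(np.sqrt(np.mean(np.square(cond))))

    return BackgroundModel(
        mu_expl=mu_e,
        sd_expl=sd_e,
        mu_resp=mu_r,
        sd_resp=sd_r,
        sd_cond=sd_cond,
        rho=0.0,
        n_background_samples=n_background_samples,
    )


def pair_likelihood(model: BackgroundModel, np_id: str, nc_id: str, phi_value: float) -> float:
    """Bivariate Gaussian background density of an observed pair potential.

    The potential is standardized once against the explanatory background of
    ``np_id`` and once against the response background of ``nc_id``; the
    density is evaluated at that score pair with covariance ``model.rho``.
    """
    try:
        mu_p, sd_p = model.mu_expl[np_id], model.sd_expl[np_id]
        mu_c, sd_c = model.mu_resp[nc_id], model.sd_resp[nc_id]
    except KeyError as exc:
        raise KeyError(f"node missing from background model: {exc}") from exc
    nu_p = (phi_value - mu_p) / sd_p
    nu_c = (phi_value - mu_c) / sd_c
    rho = model.rho
    z_norm = 2.0 * np.pi * sd_p * sd_c * np.sqrt(1.0 - rho)
    expo = -(nu_p**2 - 2.0 * rho * nu_c * nu_p + nu_c**2) / (2.0 * (1.0 - rho**2))
    return float(np.exp(expo) / z_norm)


def conditional_likelihood(model: BackgroundModel, phi_cond_value: float) -> float:
    """Zero-mean Gaussian density of an observed conditional potential."""
    s2 = model.sd_cond**2
    return float(np.exp(-(phi_cond_value**2) / (2.0 * s2)) / np.sqrt(2.0 * np.pi * s2))


def score_from_potentials(
    model: BackgroundModel,
    np_id: str,
    nc_id: str,
    phi_pair: float,
    phi_cond: float,
    c1: float,
) -> float:
    """Transition score from precomputed potentials.

    ``LLS = c1 * log l(phi_cond) - log l(phi_pair)`` with densities floored
    at ``LIKELIHOOD_FLOOR`` to keep the score finite.
    """
    lc = max(conditional_likelihood(model, phi_cond), LIKELIHOOD_FLOOR)
    lp = max(pair_likelihood(model, np_id, nc_id, phi_pair), LIKELIHOOD_FLOOR)
    return float(c1 * np.log(lc) - np.log(lp))


def log_likelihood_score(
    model: BackgroundModel,
    ng_id: str,
    np_id: str,
    nc_id: str,
    data: EqtlDataset,
    c1: float,
) -> float:
    """Transition score for child ``nc`` joining parent ``np`` under ``ng``."""
    xp = data.values_of(np_id)
    xc = data.values_of(nc_id)
    xg = data.values_of(ng_id)
    phi_p = pair_potential(xp, xc)
    phi_c = conditional_potential(xg, xc, xp)
    return score_from_potentials(model, np_id, nc_id, phi_p, phi_c, c1)
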