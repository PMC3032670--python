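"""Stochastic causal trees and their conversion to an edge-prior matrix.

Each genomic locus roots a tree that grows by repeatedly attaching one of
the remaining transcripts as a leaf.  Every current tree member proposes
its best transition -- the unincorporated transcript maximizing the
log-likelihood score ``LLS(n_c; n_p, n_g)`` given the member as parent and
the member's own parent as grandparent -- and one proposal is chosen at
random with probability proportional to ``max(score, eps) ** p``.  Larger
``p`` concentrates the choice on the top-scoring transition; ``p = 0``
picks uniformly.  Root transitions have no grandparent, so their
conditional potential is replaced by a fresh draw from the null
N(0, sd_cond) background.

Growing ``I`` iterations of trees from each of the ``|L|`` loci and
tallying how often node *i* parents node *j* yields the prior matrix
``R[i, j] = f(i, j) / (M * |L| * I)``.  A second normalizer convention,
``f(i, j) / (|L| * I)`` (the tree count), is also supported; the two
differ only by the constant factor ``M``, which the downstream Gibbs prior
absorbs into its inverse-temperature ``beta``.

Scores for a fixed (parent, grandparent) pair do not depend on the tree,
so the engine caches the full descending score ranking of all candidate
transcripts per pair and answers best-transition queries by walking the
ranking past excluded members.  This reproduces exhaustive re-scoring
exactly while making repeated tree growth cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sctnet.potentials import (
    LIKELIHOOD_FLOOR,
    BackgroundModel,
    conditional_potential_from_corr,
    correlation_matrix,
)
from sctnet.simdata import EqtlDataset

__all__ = [
    "SctParams",
    "CausalTree",
    "PriorMatrix",
    "SctEngine",
    "build_prior",
]

#: weight floor for non-positive transition scores in the stochastic choice
SCORE_EPS = 1e-6
_LOG_FLOOR = float(np.log(LIKELIHOOD_FLOOR))


@dataclass
class SctParams:
    """Tree-growth parameters.

    ``M``: leaves added per tree; ``I``: iterations over all loci; ``c1``:
    weight of the conditional potential in the score; ``p``: power of the
    score in the stochastic transition choice.
    """

    M: int = 60
    I: int = 1000
    c1: float = 5.0
    p: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.I < 1:
            raise ValueError("M and I must be >= 1")
        if self.c1 < 0 or self.p < 0:
            raise ValueError("c1 and p must be >= 0")


@dataclass
class CausalTree:
    """A locus-rooted tree over a subset of transcripts."""

    root: str
    members: list[str]
    parent_of: dict[str, str | None]

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, p in self.parent_of.items() if p is not None]

    def validate(self, max_leaves: int | None = None) -> None:
        if self.members[0] != self.root:
            raise ValueError("first member must be the root")
        seen = set()
        for node in self.members:
            if node in seen:
                raise ValueError(f"node {node} appears twice")
            seen.add(node)
            parent = self.parent_of[node]
            if node == self.root:
                if parent is not None:
                    raise ValueError("root must not have a parent")
            elif parent not in seen:
                raise ValueError(f"parent of {node} not already in tree")
        if max_leaves is not None and len(self.members) > max_leaves + 1:
            raise ValueError("tree exceeds M + 1 members")


@dataclass
class PriorMatrix:
    """Node x node matrix of causal-edge prior weights in [0, 1].

    ``counts`` holds the raw directed-edge tallies the weights were derived
    from (empty for priors that are not tally-based).
    """

    R: pd.DataFrame
    provenance: str = "none"
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.R.to_numpy()
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("prior weights must lie in [0, 1]")
        if np.diagonal(vals).any():
            raise ValueError("diagonal must be zero")

    def validate_head_nodes(self, loci: list[str]) -> None:
        sub = self.R[ [l for l in loci if l in self.R.columns] ]
        if (sub.to_numpy() != 0).any():
            raise ValueError("loci columns must be zero (no edges into loci)")

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        M: int,
        n_loci: int,
        I: int,
        normalizer: str = "formal",
        provenance: str = "sct",
    ) -> "PriorMatrix":
        """Convert directed-edge tallies into prior weights.

        ``normalizer='formal'`` divides by ``M * |L| * I``;
        ``normalizer='tree_count'`` divides by ``|L| * I``.
        """
        if normalizer == "formal":
            denom = M * n_loci * I
        elif normalizer == "tree_count":
            denom = n_loci * I
        else:
            raise ValueError("normalizer must be 'formal' or 'tree_count'")
        return cls(R=counts / denom, provenance=provenance, counts=counts)

    def to_sparse_table(self, path: str | Path) -> None:
        rows = []
        arr = self.R.to_numpy()
        nz = np.argwhere(arr > 0)
        for i, j in nz:
            rows.append((self.R.index[i], self.R.columns[j], arr[i, j]))
        pd.DataFrame(rows, columns=["parent", "child", "weight"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_sparse_table(cls, path: str | Path, nodes: list[str], provenance: str = "none") -> "PriorMatrix":
        df = pd.read_csv(path, sep="\t")
        R = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for _, row in df.iterrows():
            R.loc[row.parent, row.child] = row.weight
        return cls(R=R, provenance=provenance)


class SctEngine:
    """Vectorized scorer and sampler for stochastic causal trees."""

    def __init__(
        self,
        dataset: EqtlDataset,
        model: BackgroundModel,
        params: SctParams,
        candidate_map: dict[str, set[str]] | None = None,
    ):
        self.dataset = dataset
        self.model = model
        self.params = params
        self.nodes = dataset.nodes
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.n_loci = len(dataset.loci)
        corr = correlation_matrix(dataset)
        self.C = corr.to_numpy()
        n = len(self.nodes)

        self.mu_e = np.array([model.mu_expl[x] for x in self.nodes])
        self.sd_e = np.array([model.sd_expl[x] for x in self.nodes])
        mu_r = np.full(n, np.nan)
        sd_r = np.full(n, np.nan)
        for t in dataset.transcripts:
            i = self.index[t]
            mu_r[i] = model.mu_resp[t]
            sd_r[i] = model.sd_resp[t]
        self.mu_r, self.sd_r = mu_r, sd_r
        self.sd_cond = model.sd_cond
        self._log_cond_norm = -0.5 * np.log(2.0 * np.pi * self.sd_cond**2)
        # candidate transcripts, optionally restricted per parent node
        self._all_cands = np.array([self.index[t] for t in dataset.transcripts])
        self._cand_map = None
        if candidate_map is not None:
            self._cand_map = {
                self.index[k]: np.array(sorted(self.index[v] for v in vs if v in self.index))
                for k, vs in candidate_map.items()
            }
        self._rank_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self.cache_max_entries = 200_000

    # -- scoring -----------------------------------------------------------

    def _candidates_of(self, p_idx: int) -> np.ndarray:
        if self._cand_map is None:
            return self._all_cands
        return self._cand_map.get(p_idx, self._all_cands)

    def _log_pair_lik(self, p_idx: int, cands: np.ndarray) -> np.ndarray:
        phi = self.C[p_idx, cands] ** 2
        nu_p = (phi - self.mu_e[p_idx]) / self.sd_e[p_idx]
        nu_c = (phi - self.mu_r[cands]) / self.sd_r[cands]
        rho = self.model.rho
        logz = np.log(2.0 * np.pi * self.sd_e[p_idx] * self.sd_r[cands]) + 0.5 * np.log(1.0 - rho)
        expo = -(nu_p**2 - 2.0 * rho * nu_c * nu_p + nu_c**2) / (2.0 * (1.0 - rho**2))
        return np.maximum(expo - logz, _LOG_FLOOR)

    def _log_cond_lik(self, phi_cond: np.ndarray | float) -> np.ndarray | float:
        out = self._log_cond_norm - np.square(phi_cond) / (2.0 * self.sd_cond**2)
        return np.maximum(out, _LOG_FLOOR)

    def scores(self, p_idx: int, g_idx: int | None, cands: np.ndarray,
               root_phi_cond: float | None = None) -> np.ndarray:
        """LLS of every candidate child for parent p and grandparent g.

        For root transitions (``g_idx is None``) the conditional potential
        is the supplied surrogate draw, identical across candidates.
        """
        log_pair = self._log_pair_lik(p_idx, cands)
        if g_idx is None:
            if root_phi_cond is None:
                raise ValueError("root transitions need a surrogate conditional potential")
            log_cond = float(self._log_cond_lik(root_phi_cond))
            return self.params.c1 * log_cond - log_pair
        phi_cond = conditional_potential_from_corr(
            self.C[g_idx, cands], self.C[p_idx, cands], self.C[g_idx, p_idx]
        )
        log_cond = self._log_cond_lik(phi_cond)
        return self.params.c1 * log_cond - log_pair

    def _ranking(self, p_idx: int, g_idx: int | None) -> tuple[np.ndarray, np.ndarray]:
        """Candidates of p sorted by descending score (root: pair term only)."""
        key = (p_idx, -1 if g_idx is None else g_idx)
        hit = self._rank_cache.get(key)
        if hit is not None:
            return hit
        cands = self._candidates_of(p_idx)
        if g_idx is None:
            part = -self._log_pair_lik(p_idx, cands)  # conditional term is constant
        else:
            part = self.scores(p_idx, g_idx, cands)
        order = np.argsort(-part, kind="stable")
        entry = (cands[order], part[order])
        if len(self._rank_cache) >= self.cache_max_entries:
            self._rank_cache.clear()
        self._rank_cache[key] = entry
        return entry

    def best_transition(
        self,
        p_idx: int,
        g_idx: int | None,
        excluded: set[int],
        root_phi_cond: float | None = None,
    ) -> tuple[int, float] | None:
        """Highest-scoring (candidate, score) not yet in the tree, or None."""
        ranked, scores = self._ranking(p_idx, g_idx)
        for cand, sc in zip(ranked, scores):
            if int(cand) not in excluded:
                if g_idx is None:
                    sc = self.params.c1 * float(self._log_cond_lik(root_phi_cond)) + sc
                return int(cand), float(sc)
        return None

    # -- tree growth -------------------------------------------------------

    def stochastic_leaf(
        self, members: list[int], parent_of: dict[int, int | None], rng: np.random.Generator
    ) -> tuple[int, int] | None:
        """One stochastic leaf addition; returns (parent_idx, leaf_idx)."""
        options: list[tuple[int, int]] = []
        weights: list[float] = []
        for s in members:
            g = parent_of[s]
            if g is None:  # root: fresh surrogate conditional potential
                v = rng.normal(0.0, self.sd_cond)
                best = self.best_transition(s, None, set(members), root_phi_cond=v)
            else:
                best = self.best_transition(s, g, set(members))
            if best is None:
                continue
            cand, score = best
            options.append((s, cand))
            weights.append(max(score, SCORE_EPS) ** self.params.p)
        if not options:
            return None
        w = np.asarray(weights)
        probs = w / w.sum()
        choice = rng.choice(len(options), p=probs)
        return options[choice]

    def grow_tree(self, root_locus: str, rng: np.random.Generator) -> CausalTree:
        """Grow one tree of at most M transcripts from the given locus."""
        root = self.index[root_locus]
        members = [root]
        parent_of: dict[int, int | None] = {root: None}
        for _ in range(self.params.M):
            step = self.stochastic_leaf(members, parent_of, rng)
            if step is None:
                break
            parent, leaf = step
            members.append(leaf)
            parent_of[leaf] = parent
        names = [self.nodes[i] for i in members]
        return CausalTree(
            root=root_locus,
            members=names,
            parent_of={self.nodes[c]: (None if p is None else self.nodes[p]) for c, p in parent_of.items()},
        )

    def build_prior(self, normalizer: str = "formal") -> PriorMatrix:
        """Run I x |L| tree growths and tally parent->child edges."""
        rng = np.random.default_rng(self.params.rng_seed)
        n = len(self.nodes)
        counts = np.zeros((n, n), dtype=np.int64)
        for _ in range(self.params.I):
            for locus in self.dataset.loci:
                tree = self.grow_tree(locus, rng)
                for p_name, c_name in tree.edges():
                    counts[self.index[p_name], self.index[c_name]] += 1
        counts_df = pd.DataFrame(counts, index=self.nodes, columns=self.nodes)
        prior = PriorMatrix.from_counts(
            counts_df, self.params.M, self.n_loci, self.params.I, normalizer=normalizer
        )
        prior.validate_head_nodes(self.dataset.loci)
        return prior


def build_prior(
    dataset: EqtlDataset,
    network_loci: list[str],
    model: BackgroundModel,
    params: SctParams,
    normalizer: str = "formal",
    candidate_map: dict[str, set[str]] | None = None,
) -> PriorMatrix:
    """Convenience wrapper: grow I x |L| trees and return the prior matrix."""
    missing = [l for l in network_loci if l not in dataset.loci]
    if missing:
        raise ValueError(f"loci missing from dataset: {missing[:5]}")
    engine = SctEngine(dataset, model, params, candidate_map=candidate_map)
    return engine.build_prior(normalizer=normalizer)
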