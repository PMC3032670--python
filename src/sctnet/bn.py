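"""Bayesian network structure learning over discretized eQTL data.

Expression is discretized per transcript into three levels (down, steady,
up) by k-means; genotypes keep their two raw levels.  Structures are
scored with the BDe marginal likelihood (multinomial families, structure-
equivalent Dirichlet priors, equivalent sample size 1) plus a Gibbs
structure prior log P(G) = beta * sum of prior-matrix entries over the
edges of G (the partition function cancels in the acceptance ratio).

The sampler is Metropolis-Hastings over DAGs: a proposal is drawn
uniformly from the legal move set eta(G) -- single-edge additions,
removals and reversals that keep the graph acyclic, respect the 3-parent
cap, only touch candidate pairs, and never point an edge into a genomic
locus -- and accepted with probability

    A(G' | G) = min{ P(D|G') P(G') |eta(G)| / (P(D|G) P(G) |eta(G')|), 1 }.

The |eta| ratio is the Hastings correction for the asymmetric proposal.
Candidate pairs come from each node's top-k absolute associations with
reciprocity closure, which keeps the move set small while covering nearly
all true edges.  Posterior edge probabilities are estimated by the mean
edge indicator over networks sampled at a fixed interval after burn-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import lgamma

import networkx as nx
import numpy as np
import pandas as pd

from sctnet.potentials import correlation_matrix
from sctnet.simdata import EqtlDataset

__all__ = [
    "DiscreteDataset",
    "CandidateMap",
    "GraphState",
    "McmcTrace",
    "discretize",
    "candidate_sets",
    "family_score",
    "graph_log_prior",
    "legal_moves",
    "mcmc_run",
    "edge_frequencies",
    "greedy_optimize",
]

MAX_PARENTS = 3


# ---------------------------------------------------------------------------
# discretization and candidate sets


@dataclass
class DiscreteDataset:
    """Integer-coded dataset: loci keep 2 levels, transcripts get 3.

    Transcript levels are ordered by ascending cluster centroid, so code 0
    is down-regulated, 1 steady, 2 up-regulated.
    """

    codes: pd.DataFrame
    arities: dict[str, int]
    loci: list[str]
    transcripts: list[str]

    @property
    def nodes(self) -> list[str]:
        return self.loci + self.transcripts

    def __post_init__(self) -> None:
        arr = self.codes.to_numpy()
        for j, node in enumerate(self.codes.columns):
            if arr[:, j].min() < 0 or arr[:, j].max() >= self.arities[node]:
                raise ValueError(f"codes out of range for {node}")


def discretize(dataset: EqtlDataset, seed: int = 0, n_init: int = 10) -> DiscreteDataset:
    """k-means (k=3) discretization of expression; genotypes pass through.

    Labels are re-indexed by ascending centroid.  Constant columns fall
    back to a single level with a warning.  Each column gets its own seed
    derived from the global one so results are order-independent.
    """
    from sklearn.cluster import KMeans

    n_t = len(dataset.transcripts)
    col_seeds = np.random.SeedSequence(seed).generate_state(max(n_t, 1)) % (2**31)
    codes = {}
    arities = {}
    for l in dataset.loci:
        codes[l] = dataset.genotypes[l].to_numpy()
        arities[l] = 2
    for j, t in enumerate(dataset.transcripts):
        x = dataset.expression[t].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"constant expression column {t}; single level")
            codes[t] = np.zeros(x.size, dtype=int)
            arities[t] = 1
            continue
        km = KMeans(n_clusters=3, n_init=n_init, random_state=int(col_seeds[j]))
        labels = km.fit_predict(x[:, None])
        order = np.argsort(km.cluster_centers_.ravel())
        relabel = np.empty(3, dtype=int)
        relabel[order] = np.arange(3)
        codes[t] = relabel[labels]
        arities[t] = 3
    frame = pd.DataFrame(codes, index=dataset.genotypes.index)[dataset.nodes]
    return DiscreteDataset(
        codes=frame, arities=arities, loci=dataset.loci, transcripts=dataset.transcripts
    )


@dataclass
class CandidateMap:
    """Symmetric per-node candidate sets restricting the move space."""

    sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        for x, partners in self.sets.items():
            for y in partners:
                if x not in self.sets.get(y, set()):
                    raise ValueError(f"candidate map not symmetric for ({x}, {y})")

    def mean_size(self) -> float:
        return float(np.mean([len(v) for v in self.sets.values()]))

    def coverage(self, edges: set[tuple[str, str]]) -> float:
        """Fraction of edges whose endpoints are mutual candidates."""
        if not edges:
            return 1.0
        hit = sum(1 for p, c in edges if c in self.sets.get(p, set()))
        return hit / len(edges)


def candidate_sets(dataset: EqtlDataset, k: int = 10) -> CandidateMap:
    """Top-k |Pearson| association partners per node, reciprocity-closed.

    Associations are computed on the continuous data (point-biserial
    against loci); ties break by node index.
    """
    corr = correlation_matrix(dataset)
    nodes = list(corr.index)
    a = np.abs(corr.to_numpy())
    np.fill_diagonal(a, -1.0)
    sets: dict[str, set[str]] = {n: set() for n in nodes}
    kk = min(k, len(nodes) - 1)
    # argsort descending with index tie-break: stable sort on (-assoc, index)
    for i, node in enumerate(nodes):
        top = np.argsort(-a[i], kind="stable")[:kk]
        for j in top:
            sets[node].add(nodes[j])
            sets[nodes[j]].add(node)  # reciprocity closure
    return CandidateMap(sets=sets)


# ---------------------------------------------------------------------------
# BDe scoring


class BdeScorer:
    """Cached BDe family scores over a discrete dataset."""

    def __init__(self, discrete: DiscreteDataset, ess: float = 1.0):
        self.discrete = discrete
        self.ess = ess
        self.nodes = discrete.nodes
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.codes = discrete.codes[self.nodes].to_numpy()
        self.arity = np.array([discrete.arities[n] for n in self.nodes])
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family(self, child: int, parents: tuple[int, ...]) -> float:
        key = (child, tuple(sorted(parents)))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        val = self._compute(child, key[1])
        self._cache[key] = val
        return val

    def _compute(self, child: int, parents: tuple[int, ...]) -> float:
        r = int(self.arity[child])
        q = int(np.prod(self.arity[list(parents)])) if parents else 1
        # encode each sample's parent configuration as one integer
        if parents:
            conf = np.zeros(self.codes.shape[0], dtype=np.int64)
            for p in parents:
                conf = conf * self.arity[p] + self.codes[:, p]
        else:
            conf = np.zeros(self.codes.shape[0], dtype=np.int64)
        flat = conf * r + self.codes[:, child]
        n_jk = np.bincount(flat, minlength=q * r).reshape(q, r)
        n_j = n_jk.sum(axis=1)
        a_jk = self.ess / (q * r)
        a_j = self.ess / q
        score = 0.0
        lg_aj = lgamma(a_j)
        lg_ajk = lgamma(a_jk)
        for j in range(q):
            score += lg_aj - lgamma(a_j + n_j[j])
            row = n_jk[j]
            for k in range(r):
                if row[k]:
                    score += lgamma(a_jk + row[k]) - lg_ajk
        return score


def family_score(
    child: str, parent_set: set[str] | list[str], discrete_data: DiscreteDataset, ess: float = 1.0
) -> float:
    """BDe log marginal likelihood of one family (child given parents)."""
    parents = tuple(parent_set)
    if len(parents) > MAX_PARENTS:
        raise ValueError(f"at most {MAX_PARENTS} parents allowed")
    scorer = BdeScorer(discrete_data, ess=ess)
    return scorer.family(scorer.index[child], tuple(scorer.index[p] for p in parents))


# ---------------------------------------------------------------------------
# graph state and moves

ADD, REMOVE, REVERSE = 0, 1, 2


class GraphState:
    """A DAG with cached family scores, prior and transitive closure."""

    def __init__(
        self,
        discrete: DiscreteDataset,
        R: pd.DataFrame | None,
        beta: float,
        candidates: CandidateMap,
        ess: float = 1.0,
    ):
        self.scorer = BdeScorer(discrete, ess=ess)
        self.nodes = self.scorer.nodes
        self.index = self.scorer.index
        n = len(self.nodes)
        self.n = n
        self.is_locus = np.array([x in discrete.loci for x in self.nodes])
        self.beta = beta
        if R is None:
            self.R = np.zeros((n, n))
        else:
            self.R = R.reindex(index=self.nodes, columns=self.nodes).fillna(0.0).to_numpy()
            self.R = np.clip(self.R, 0.0, 1.0)
        cand = np.zeros((n, n), dtype=bool)
        for x, partners in candidates.sets.items():
            i = self.index[x]
            for y in partners:
                cand[i, self.index[y]] = True
                cand[self.index[y], i] = True
        np.fill_diagonal(cand, False)
        self.cand = cand
        self.adj = np.zeros((n, n), dtype=bool)
        self.reach = np.zeros((n, n), dtype=bool)
        self.indeg = np.zeros(n, dtype=int)
        self.parents: list[set[int]] = [set() for _ in range(n)]
        self.log_family = np.array(
            [self.scorer.family(i, ()) for i in range(n)], dtype=float
        )
        self.log_prior = 0.0

    # -- structure helpers -------------------------------------------------

    def _closure(self, adj: np.ndarray) -> np.ndarray:
        r = adj.astype(np.float32)
        a = r.copy()
        while True:
            nxt = ((r @ a) > 0).astype(np.float32)
            new = np.maximum(r, nxt)
            if (new == r).all():
                break
            r = new
        return r > 0

    def recompute_reach(self) -> None:
        self.reach = self._closure(self.adj)

    def copy_from(self, other: "GraphState") -> None:
        self.adj = other.adj.copy()
        self.reach = other.reach.copy()
        self.indeg = other.indeg.copy()
        self.parents = [set(p) for p in other.parents]
        self.log_family = other.log_family.copy()
        self.log_prior = other.log_prior

    def total_score(self) -> float:
        return float(self.log_family.sum() + self.log_prior)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in zip(*np.nonzero(self.adj)):
            g.add_edge(self.nodes[u], self.nodes[v])
        return g

    def set_edges(self, edges: list[tuple[str, str]]) -> None:
        for p, c in edges:
            self.apply_move((ADD, self.index[p], self.index[c]))

    # -- moves -------------------------------------------------------------

    def move_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """(addition mask, reversal mask); removals are exactly the edges."""
        add = (
            self.cand
            & ~self.adj
            & ~self.reach.T
            & (self.indeg < MAX_PARENTS)[None, :]
            & ~self.is_locus[None, :]
        )
        np.fill_diagonal(add, False)
        # reversal of u->v: u becomes a child of v
        two_step = (self.adj.astype(np.float32) @ self.reach.astype(np.float32)) > 0
        rev = (
            self.adj
            & ~self.is_locus[:, None]
            & (self.indeg <= MAX_PARENTS - 1)[:, None]
            & ~two_step
        )
        return add, rev

    def n_moves(self) -> int:
        add, rev = self.move_masks()
        return int(add.sum() + self.adj.sum() + rev.sum())

    def list_moves(self) -> list[tuple[int, int, int]]:
        add, rev = self.move_masks()
        moves = [(ADD, int(u), int(v)) for u, v in zip(*np.nonzero(add))]
        moves += [(REMOVE, int(u), int(v)) for u, v in zip(*np.nonzero(self.adj))]
        moves += [(REVERSE, int(u), int(v)) for u, v in zip(*np.nonzero(rev))]
        return moves

    def score_delta(self, move: tuple[int, int, int]) -> float:
        """Change in log P(D|G) + log P(G) if the move were applied."""
        kind, u, v = move
        if kind == ADD:
            new_v = self.scorer.family(v, tuple(self.parents[v] | {u}))
            return new_v - self.log_family[v] + self.beta * self.R[u, v]
        if kind == REMOVE:
            new_v = self.scorer.family(v, tuple(self.parents[v] - {u}))
            return new_v - self.log_family[v] - self.beta * self.R[u, v]
        new_v = self.scorer.family(v, tuple(self.parents[v] - {u}))
        new_u = self.scorer.family(u, tuple(self.parents[u] | {v}))
        d = new_v - self.log_family[v] + new_u - self.log_family[u]
        return d + self.beta * (self.R[v, u] - self.R[u, v])

    def apply_move(self, move: tuple[int, int, int]) -> None:
        kind, u, v = move
        if kind == ADD:
            self.adj[u, v] = True
            self.parents[v].add(u)
            self.indeg[v] += 1
            self.log_family[v] = self.scorer.family(v, tuple(self.parents[v]))
            self.log_prior += self.beta * self.R[u, v]
            # incremental closure: ancestors of u (and u) now reach
            # descendants of v (and v)
            src = self.reach[:, u].copy()
            src[u] = True
            dst = self.reach[v, :].copy()
            dst[v] = True
            self.reach |= np.outer(src, dst)
        elif kind == REMOVE:
            self.adj[u, v] = False
            self.parents[v].discard(u)
            self.indeg[v] -= 1
            self.log_family[v] = self.scorer.family(v, tuple(self.parents[v]))
            self.log_prior -= self.beta * self.R[u, v]
            self.recompute_reach()
        else:
            self.adj[u, v] = False
            self.adj[v, u] = True
            self.parents[v].discard(u)
            self.parents[u].add(v)
            self.indeg[v] -= 1
            self.indeg[u] += 1
            self.log_family[v] = self.scorer.family(v, tuple(self.parents[v]))
            self.log_family[u] = self.scorer.family(u, tuple(self.parents[u]))
            self.log_prior += self.beta * (self.R[v, u] - self.R[u, v])
            self.recompute_reach()


def graph_log_prior(graph: nx.DiGraph | GraphState, R: pd.DataFrame, beta: float) -> float:
    """log of the Gibbs structure prior (normalizer omitted):
    beta * sum of R over the edges present in the graph."""
    if isinstance(graph, GraphState):
        edges = [(graph.nodes[u], graph.nodes[v]) for u, v in zip(*np.nonzero(graph.adj))]
    else:
        edges = list(graph.edges())
    return float(beta * sum(R.loc[u, v] for u, v in edges))


def legal_moves(graph: GraphState, candidates: CandidateMap | None = None) -> list[tuple[str, str, str]]:
    """Human-readable enumeration of eta(G): (kind, parent, child) tuples.

    ``candidates`` is part of the graph state; the argument is accepted for
    call-site clarity and must match when provided.
    """
    names = {ADD: "add", REMOVE: "remove", REVERSE: "reverse"}
    return [
        (names[k], graph.nodes[u], graph.nodes[v]) for k, u, v in graph.list_moves()
    ]


# ---------------------------------------------------------------------------
# MCMC


@dataclass
class McmcTrace:
    """Edge-indicator tallies and diagnostics from one MCMC run."""

    nodes: list[str]
    edge_tally: np.ndarray
    n_samples: int
    interval_tallies: list[np.ndarray]
    samples_per_interval: int
    scores: list[float]
    accept_count: int
    n_iter: int
    burn_in: int
    sample_every: int
    seed: int
    snapshots: list[np.ndarray] = field(default_factory=list)

    def snapshot_digraphs(self) -> list[nx.DiGraph]:
        out = []
        for adj in self.snapshots:
            g = nx.DiGraph()
            g.add_nodes_from(self.nodes)
            for u, v in zip(*np.nonzero(adj)):
                g.add_edge(self.nodes[u], self.nodes[v])
            out.append(g)
        return out

    def frequencies(self) -> pd.DataFrame:
        if self.n_samples == 0:
            raise ValueError("no samples collected")
        return pd.DataFrame(
            self.edge_tally / self.n_samples, index=self.nodes, columns=self.nodes
        )

    def interval_frequency_maps(self) -> list[dict[tuple[str, str], float]]:
        out = []
        for tally in self.interval_tallies:
            denom = self.samples_per_interval
            freqs = {}
            for u, v in zip(*np.nonzero(tally)):
                freqs[(self.nodes[u], self.nodes[v])] = tally[u, v] / denom
            out.append(freqs)
        return out


def edge_frequencies(trace: McmcTrace) -> pd.DataFrame:
    """Mean edge indicator over the sampled networks."""
    return trace.frequencies()


def _draw_move(rng, counts, add_mask, adj, rev_mask):
    """Uniform draw from eta(G) without materializing the move list."""
    n_add, n_rem, n_rev = counts
    r = int(rng.integers(n_add + n_rem + n_rev))
    n = adj.shape[0]
    if r < n_add:
        flat = np.flatnonzero(add_mask.ravel())[r]
        kind = ADD
    elif r < n_add + n_rem:
        flat = np.flatnonzero(adj.ravel())[r - n_add]
        kind = REMOVE
    else:
        flat = np.flatnonzero(rev_mask.ravel())[r - n_add - n_rem]
        kind = REVERSE
    return (kind, int(flat // n), int(flat % n))


def _random_init(state: GraphState, n_edges: int, rng: np.random.Generator) -> None:
    placed = 0
    while placed < n_edges:
        add, _ = state.move_masks()
        options = np.argwhere(add)
        if options.size == 0:
            raise RuntimeError(
                f"could only place {placed} of {n_edges} initial edges legally"
            )
        u, v = options[rng.integers(len(options))]
        state.apply_move((ADD, int(u), int(v)))
        placed += 1


def mcmc_run(
    discrete_data: DiscreteDataset,
    R: pd.DataFrame | None,
    beta: float,
    candidates: CandidateMap,
    n_iter: int = 100_000,
    burn_in: int = 10_000,
    sample_every: int = 200,
    n_init_edges: int | None = None,
    seed: int = 0,
    ess: float = 1.0,
    samples_per_interval: int = 100,
    audit_every: int = 0,
    snapshot_every: int = 0,
    engine: str = "numba",
) -> McmcTrace:
    """Metropolis-Hastings structure sampling with Hastings correction.

    ``n_init_edges`` defaults to ``min(2000, floor(0.9 * n_transcripts))``.
    ``audit_every`` > 0 re-derives the cached quantities from scratch every
    that many iterations and raises on disagreement (used by tests).
    ``snapshot_every`` > 0 stores a copy of the adjacency matrix at that
    iteration spacing after burn-in, for downstream linkage mapping.

    ``engine`` selects the compiled kernel ("numba", default) or the
    pure-Python reference implementation ("python"); the two draw
    different random streams but target the identical posterior, and the
    Python path supports ``audit_every``.
    """
    if n_init_edges is None:
        n_init_edges = min(2000, int(0.9 * len(discrete_data.transcripts)))
    if engine == "numba":
        return _mcmc_run_numba(
            discrete_data, R, beta, candidates, n_iter, burn_in, sample_every,
            n_init_edges, seed, ess, samples_per_interval, snapshot_every,
        )
    if engine != "python":
        raise ValueError("engine must be 'numba' or 'python'")
    rng = np.random.default_rng(seed)
    state = GraphState(discrete_data, R, beta, candidates, ess=ess)
    proposal = GraphState(discrete_data, R, beta, candidates, ess=ess)
    proposal.scorer = state.scorer  # share the family-score cache
    _random_init(state, n_init_edges, rng)

    n = state.n
    tally = np.zeros((n, n), dtype=np.int64)
    interval_tallies: list[np.ndarray] = []
    current_interval = np.zeros((n, n), dtype=np.int64)
    in_interval = 0
    scores: list[float] = []
    snapshots: list[np.ndarray] = []
    accept = 0
    n_samples = 0

    add_mask, rev_mask = state.move_masks()
    counts = (int(add_mask.sum()), int(state.adj.sum()), int(rev_mask.sum()))
    for it in range(n_iter):
        n_moves_g = sum(counts)
        move = _draw_move(rng, counts, add_mask, state.adj, rev_mask)
        delta = state.score_delta(move)
        proposal.copy_from(state)
        proposal.apply_move(move)
        p_add, p_rev = proposal.move_masks()
        p_counts = (int(p_add.sum()), int(proposal.adj.sum()), int(p_rev.sum()))
        log_a = delta + np.log(n_moves_g) - np.log(sum(p_counts))
        if np.log(rng.random()) < log_a:
            state, proposal = proposal, state
            add_mask, rev_mask, counts = p_add, p_rev, p_counts
            accept += 1

        if audit_every and (it + 1) % audit_every == 0:
            _audit(state)

        if snapshot_every and it >= burn_in and (it + 1) % snapshot_every == 0:
            snapshots.append(state.adj.copy())

        if it >= burn_in and (it + 1) % sample_every == 0:
            tally += state.adj
            current_interval += state.adj
            in_interval += 1
            n_samples += 1
            scores.append(state.total_score())
            if in_interval == samples_per_interval:
                interval_tallies.append(current_interval)
                current_interval = np.zeros((n, n), dtype=np.int64)
                in_interval = 0

    return McmcTrace(
        nodes=state.nodes,
        edge_tally=tally,
        n_samples=n_samples,
        interval_tallies=interval_tallies,
        samples_per_interval=samples_per_interval,
        scores=scores,
        accept_count=accept,
        n_iter=n_iter,
        burn_in=burn_in,
        sample_every=sample_every,
        seed=seed,
        snapshots=snapshots,
    )


def _mcmc_run_numba(
    discrete_data, R, beta, candidates, n_iter, burn_in, sample_every,
    n_init_edges, seed, ess, samples_per_interval, snapshot_every,
) -> McmcTrace:
    from sctnet._mcmc_kernel import run_chain

    shell = GraphState(discrete_data, R, beta, candidates, ess=ess)
    n = shell.n
    max_intervals = max(1, ((n_iter - burn_in) // sample_every) // samples_per_interval + 1)
    max_snaps = max(1, (n_iter - burn_in) // snapshot_every + 1) if snapshot_every else 1
    n_nodes = shell.n
    counts = shell.cand.sum(axis=1).astype(np.int64)
    cand_list = np.zeros((n_nodes, max(1, int(counts.max()))), dtype=np.int64)
    for i in range(n_nodes):
        idx = np.flatnonzero(shell.cand[i])
        cand_list[i, : idx.size] = idx
    out = run_chain(
        shell.scorer.codes.astype(np.int64),
        shell.scorer.arity.astype(np.int64),
        shell.is_locus,
        cand_list,
        counts,
        shell.R,
        float(beta),
        float(ess),
        int(n_iter),
        int(burn_in),
        int(sample_every),
        int(n_init_edges),
        int(seed) % (2**31),
        int(samples_per_interval),
        int(max_intervals),
        int(snapshot_every),
        int(max_snaps),
    )
    (tally, n_samples, interval_tallies, n_intervals, scores, n_scores,
     accept_count, snapshots, n_snaps, _final) = out
    if n_samples < 0:
        raise RuntimeError(
            f"could not place {n_init_edges} initial edges legally"
        )
    return McmcTrace(
        nodes=shell.nodes,
        edge_tally=np.asarray(tally),
        n_samples=int(n_samples),
        interval_tallies=[np.asarray(interval_tallies[i]) for i in range(int(n_intervals))],
        samples_per_interval=samples_per_interval,
        scores=list(np.asarray(scores[: int(n_scores)])),
        accept_count=int(accept_count),
        n_iter=n_iter,
        burn_in=burn_in,
        sample_every=sample_every,
        seed=seed,
        snapshots=[np.asarray(snapshots[i]) for i in range(int(n_snaps))],
    )


def _audit(state: GraphState) -> None:
    """Check cached reach, scores and prior against fresh recomputation."""
    fresh_reach = state._closure(state.adj)
    if (fresh_reach != state.reach).any():
        raise AssertionError("cached transitive closure diverged")
    for v in range(state.n):
        fresh = state.scorer._compute(v, tuple(sorted(state.parents[v])))
        if abs(fresh - state.log_family[v]) > 1e-8:
            raise AssertionError("cached family score diverged")
    fresh_prior = state.beta * state.R[state.adj].sum()
    if abs(fresh_prior - state.log_prior) > 1e-8:
        raise AssertionError("cached prior diverged")


def greedy_optimize(
    start_graph: GraphState,
    n_iter: int = 200_000,
) -> GraphState:
    """Hill climbing over eta(G): apply the best improving move each step."""
    state = start_graph
    for _ in range(n_iter):
        moves = state.list_moves()
        if not moves:
            break
        deltas = [state.score_delta(m) for m in moves]
        best = int(np.argmax(deltas))
        if deltas[best] <= 1e-12:
            break
        state.apply_move(moves[best])
    return state
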