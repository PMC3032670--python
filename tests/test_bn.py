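"""Discretization, candidate sets, BDe scoring, moves, MCMC, greedy search."""

import itertools
from math import lgamma

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from sctnet import bn, simdata


def lloyd_oracle(x, centers, iters=100):
    """Plain Lloyd's algorithm for 1-D k-means."""
    c = np.array(centers, dtype=float)
    for _ in range(iters):
        labels = np.argmin(np.abs(x[:, None] - c[None, :]), axis=1)
        new = np.array([x[labels == k].mean() if (labels == k).any() else c[k]
                        for k in range(len(c))])
        if np.allclose(new, c):
            break
        c = new
    return np.argmin(np.abs(x[:, None] - c[None, :]), axis=1), c


def test_discretize_well_separated_masses():
    vals = np.array([0.0] * 10 + [5.0] * 10 + [10.0] * 10)
    rng = np.random.default_rng(1)
    geno = pd.DataFrame({"L1": rng.integers(0, 2, 30)}, index=range(30))
    expr = pd.DataFrame({"T1": vals}, index=range(30))
    ds = simdata.EqtlDataset(genotypes=geno, expression=expr)
    disc = bn.discretize(ds, seed=2)
    codes = disc.codes["T1"].to_numpy()
    assert (codes[:10] == 0).all()       # lowest centroid -> code 0
    assert (codes[10:20] == 1).all()
    assert (codes[20:] == 2).all()
    assert (disc.codes["L1"].to_numpy() == geno["L1"].to_numpy()).all()
    assert disc.arities == {"L1": 2, "T1": 3}


def test_discretize_matches_lloyd_oracle():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(-3, 0.5, 10), rng.normal(0, 0.5, 10),
                        rng.normal(3, 0.5, 10)])
    geno = pd.DataFrame({"L1": rng.integers(0, 2, 30)}, index=range(30))
    ds = simdata.EqtlDataset(genotypes=geno,
                             expression=pd.DataFrame({"T1": x}, index=range(30)))
    disc = bn.discretize(ds, seed=4)
    labels, centers = lloyd_oracle(x, [-3, 0, 3])
    order = np.argsort(centers)
    relabel = np.empty(3, dtype=int)
    relabel[order] = np.arange(3)
    assert (disc.codes["T1"].to_numpy() == relabel[labels]).all()


def test_candidate_sets_symmetric_and_sized(small_dataset, small_network):
    cands = bn.candidate_sets(small_dataset, k=10)
    for x, partners in cands.sets.items():
        for y in partners:
            assert x in cands.sets[y]
    assert 10 <= cands.mean_size() <= 25
    assert cands.coverage(set(small_network.edges)) > 0.85


def test_family_score_closed_form_empty_parents():
    """Binary child, one observation of each state, ess = 1: the
    Dirichlet-multinomial closed form gives log(1/8) ... derived as
    G(1)/G(3) * [G(1.5)/G(0.5)]^2 = 1/2 * 1/4 ... wait compute directly."""
    codes = pd.DataFrame({"L1": [0, 1]}, index=["a", "b"])
    disc = bn.DiscreteDataset(codes=codes, arities={"L1": 2}, loci=["L1"], transcripts=[])
    got = bn.family_score("L1", [], disc, ess=1.0)
    # closed form: sum_j [lgamma(a_j) - lgamma(a_j + n_j)]
    #              + sum_k [lgamma(a_jk + n_jk) - lgamma(a_jk)]
    expect = (lgamma(1.0) - lgamma(1.0 + 2)
              + (lgamma(0.5 + 1) - lgamma(0.5)) * 2)
    assert got == pytest.approx(expect, rel=1e-12)


def test_family_score_invariant_to_row_order(three_transcripts):
    disc, _ = three_transcripts
    base = bn.family_score("T2", ["T1"], disc)
    shuffled = disc.codes.sample(frac=1.0, random_state=5)
    disc2 = bn.DiscreteDataset(codes=shuffled, arities=disc.arities,
                               loci=[], transcripts=disc.transcripts)
    assert bn.family_score("T2", ["T1"], disc2) == pytest.approx(base, rel=1e-12)


def test_markov_equivalent_structures_score_identically(three_transcripts):
    disc, _ = three_transcripts
    fwd = bn.family_score("T1", [], disc) + bn.family_score("T2", ["T1"], disc)
    rev = bn.family_score("T2", [], disc) + bn.family_score("T1", ["T2"], disc)
    assert fwd == pytest.approx(rev, rel=1e-9)


def test_graph_log_prior_linearity(three_transcripts):
    disc, cands = three_transcripts
    nodes = disc.nodes
    R = pd.DataFrame(np.zeros((3, 3)), index=nodes, columns=nodes)
    R.loc["T1", "T2"] = 0.7
    state = bn.GraphState(disc, R, beta=4.0, candidates=cands)
    assert state.log_prior == 0.0
    state.apply_move((bn.ADD, state.index["T1"], state.index["T2"]))
    assert state.log_prior == pytest.approx(4.0 * 0.7)
    g = state.to_digraph()
    assert bn.graph_log_prior(g, R, 4.0) == pytest.approx(4.0 * 0.7)
    assert bn.graph_log_prior(g, R, 0.0) == 0.0


def brute_force_moves(state):
    """Enumerate legal moves by direct definition checking on the digraph."""
    g = state.to_digraph()
    nodes = state.nodes
    moves = set()
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            iu, iv = state.index[u], state.index[v]
            if g.has_edge(u, v):
                moves.add(("remove", u, v))
                g2 = g.copy()
                g2.remove_edge(u, v)
                g2.add_edge(v, u)
                if (nx.is_directed_acyclic_graph(g2)
                        and not state.is_locus[iu]
                        and g2.in_degree(u) <= bn.MAX_PARENTS):
                    moves.add(("reverse", u, v))
            else:
                if not state.cand[iu, iv]:
                    continue
                g2 = g.copy()
                g2.add_edge(u, v)
                if (nx.is_directed_acyclic_graph(g2)
                        and not state.is_locus[iv]
                        and g2.in_degree(v) <= bn.MAX_PARENTS):
                    moves.add(("add", u, v))
    return moves


def test_legal_moves_match_brute_force_enumeration(three_transcripts):
    disc, cands = three_transcripts
    state = bn.GraphState(disc, None, 0.0, cands)
    assert set(bn.legal_moves(state)) == brute_force_moves(state)
    state.apply_move((bn.ADD, 0, 1))
    assert set(bn.legal_moves(state)) == brute_force_moves(state)
    state.apply_move((bn.ADD, 1, 2))
    assert set(bn.legal_moves(state)) == brute_force_moves(state)
    state.apply_move((bn.REVERSE, 0, 1))
    assert set(bn.legal_moves(state)) == brute_force_moves(state)


def test_legal_moves_random_walk_audit(three_transcripts):
    """After every accepted random move the enumerated set stays exact and
    the reverse move is available (proposal reversibility)."""
    disc, cands = three_transcripts
    state = bn.GraphState(disc, None, 0.0, cands)
    rng = np.random.default_rng(6)
    kinds = {"add": bn.ADD, "remove": bn.REMOVE, "reverse": bn.REVERSE}
    inverse = {"add": "remove", "remove": "add"}
    for _ in range(200):
        moves = bn.legal_moves(state)
        assert set(moves) == brute_force_moves(state)
        kind, u, v = moves[rng.integers(len(moves))]
        state.apply_move((kinds[kind], state.index[u], state.index[v]))
        after = bn.legal_moves(state)
        if kind == "reverse":
            assert ("reverse", v, u) in after
        else:
            assert (inverse[kind], u, v) in after


def test_empty_graph_two_mutual_candidates():
    codes = pd.DataFrame({"T1": [0, 1, 2, 0], "T2": [0, 1, 2, 1]}, index=range(4))
    disc = bn.DiscreteDataset(codes=codes, arities={"T1": 3, "T2": 3},
                              loci=[], transcripts=["T1", "T2"])
    cands = bn.CandidateMap(sets={"T1": {"T2"}, "T2": {"T1"}})
    state = bn.GraphState(disc, None, 0.0, cands)
    assert sorted(bn.legal_moves(state)) == [("add", "T1", "T2"), ("add", "T2", "T1")]


def enumerate_exact_posterior(disc, beta=0.0, R=None):
    """Exhaustive posterior over all 25 labeled 3-node DAGs."""
    scorer = bn.BdeScorer(disc)
    pairs = [(i, j) for i in range(3) for j in range(3) if i != j]
    dags, logps = [], []
    for subset in itertools.chain.from_iterable(
        itertools.combinations(pairs, r) for r in range(len(pairs) + 1)
    ):
        g = nx.DiGraph()
        g.add_nodes_from(range(3))
        g.add_edges_from(subset)
        if not nx.is_directed_acyclic_graph(g) or g.number_of_edges() != len(subset):
            continue
        dags.append(set(subset))
        s = sum(
            scorer.family(v, tuple(sorted(u for (u, w) in subset if w == v)))
            for v in range(3)
        )
        if R is not None:
            s += beta * sum(R.iloc[u, v] for u, v in subset)
        logps.append(s)
    assert len(dags) == 25
    logps = np.array(logps)
    w = np.exp(logps - logps.max())
    w /= w.sum()
    return dags, w, pairs


@pytest.mark.parametrize("engine", ["numba", "python"])
def test_mcmc_matches_exact_posterior(three_transcripts, engine):
    disc, cands = three_transcripts
    dags, w, pairs = enumerate_exact_posterior(disc)
    n_iter = 200_000 if engine == "numba" else 60_000
    trace = bn.mcmc_run(disc, None, 0.0, cands, n_iter=n_iter, burn_in=10_000,
                        sample_every=10, n_init_edges=1, seed=3, engine=engine,
                        samples_per_interval=500)
    freq = trace.frequencies()
    for (i, j) in pairs:
        exact = sum(wi for wi, d in zip(w, dags) if (i, j) in d)
        series = np.array([t[i, j] / trace.samples_per_interval
                           for t in trace.interval_tallies])
        se = series.std(ddof=1) / np.sqrt(len(series))
        assert abs(freq.iloc[i, j] - exact) < 3 * max(se, 0.004)


def test_mcmc_python_engine_audit_clean(three_transcripts):
    disc, cands = three_transcripts
    bn.mcmc_run(disc, None, 0.0, cands, n_iter=3_000, burn_in=500,
                sample_every=50, n_init_edges=1, seed=4, engine="python",
                audit_every=250)


def test_beta_zero_ignores_prior(three_transcripts):
    disc, cands = three_transcripts
    nodes = disc.nodes
    R = pd.DataFrame(np.full((3, 3), 0.9), index=nodes, columns=nodes)
    np.fill_diagonal(R.values, 0.0)
    t1 = bn.mcmc_run(disc, None, 0.0, cands, n_iter=20_000, burn_in=2_000,
                     sample_every=20, n_init_edges=1, seed=5)
    t2 = bn.mcmc_run(disc, R, 0.0, cands, n_iter=20_000, burn_in=2_000,
                     sample_every=20, n_init_edges=1, seed=5)
    assert (t1.edge_tally == t2.edge_tally).all()


def test_large_beta_forces_preferred_edge(three_transcripts):
    disc, cands = three_transcripts
    nodes = disc.nodes
    R = pd.DataFrame(np.zeros((3, 3)), index=nodes, columns=nodes)
    R.loc["T3", "T1"] = 1.0  # an edge the data do not favour
    trace = bn.mcmc_run(disc, R, 500.0, cands, n_iter=30_000, burn_in=5_000,
                        sample_every=20, n_init_edges=1, seed=6)
    freq = trace.frequencies()
    assert freq.loc["T3", "T1"] > 0.95


def test_edge_frequencies_hand_tally(three_transcripts):
    disc, cands = three_transcripts
    trace = bn.mcmc_run(disc, None, 0.0, cands, n_iter=5_000, burn_in=1_000,
                        sample_every=400, n_init_edges=1, seed=7)
    freq = bn.edge_frequencies(trace)
    assert trace.n_samples == trace.edge_tally.max() or trace.edge_tally.max() <= trace.n_samples
    manual = trace.edge_tally / trace.n_samples
    assert np.allclose(freq.to_numpy(), manual)
    assert freq.to_numpy().max() <= 1.0


def test_greedy_monotone_and_reaches_map(three_transcripts):
    disc, cands = three_transcripts
    dags, w, pairs = enumerate_exact_posterior(disc)
    map_dag = dags[int(np.argmax(w))]
    hits = 0
    for seed in range(7):
        state = bn.GraphState(disc, None, 0.0, cands)
        rng = np.random.default_rng(seed)
        # random legal start
        for _ in range(rng.integers(0, 4)):
            moves = [m for m in state.list_moves() if m[0] == bn.ADD]
            if not moves:
                break
            state.apply_move(moves[rng.integers(len(moves))])
        start_score = state.total_score()
        final = bn.greedy_optimize(state, n_iter=500)
        assert final.total_score() >= start_score - 1e-9
        got = {(u, v) for u, v in zip(*np.nonzero(final.adj))}
        hits += got == map_dag
    assert hits > 3


def test_greedy_at_local_optimum_is_stable(three_transcripts):
    disc, cands = three_transcripts
    state = bn.GraphState(disc, None, 0.0, cands)
    opt = bn.greedy_optimize(state, n_iter=500)
    again = bn.greedy_optimize(opt, n_iter=500)
    assert (again.adj == opt.adj).all()


def test_independent_chains_converge_in_distortion(system20):
    """Two independent chains on a small system reach low inter-run edge
    distortion, and intra-run distortion settles to the same level."""
    from sctnet import evaluate

    net, ds = system20
    disc = bn.discretize(ds, seed=9)
    cands = bn.candidate_sets(ds)
    traces = [
        bn.mcmc_run(disc, None, 0.0, cands, n_iter=300_000, burn_in=50_000,
                    sample_every=50, samples_per_interval=1000, seed=s)
        for s in (100, 200)
    ]
    universe = [
        (u, v) for u in disc.nodes for v in disc.transcripts if u != v
    ]
    f_a = traces[0].interval_frequency_maps()
    f_b = traces[1].interval_frequency_maps()
    inter = evaluate.distortion(f_a[-1], f_b[-1], universe)
    intra = evaluate.distortion(f_a[-2], f_a[-1], universe)
    assert inter < 0.05
    assert intra < 0.05
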