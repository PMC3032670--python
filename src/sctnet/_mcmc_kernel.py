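"""Compiled inner loop for Metropolis-Hastings structure sampling.

Semantically identical to the pure-Python engine in :mod:`sctnet.bn`
(which remains the reference implementation used by the audit tests);
this kernel exists because realistic chain lengths run to millions of
iterations.  State lives in flat numpy arrays: a boolean adjacency
matrix, the transitive closure packed into per-row uint64 bitsets, parent
lists, a BDe family-score cache keyed by packed (child, sorted-parents)
integers, and buffers of the currently legal additions / removals /
reversals.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MAX_PARENTS = 3


@njit(cache=True)
def _family_score(codes, arity, child, parents, n_par, ess):
    """BDe log marginal likelihood of one family."""
    r = arity[child]
    q = 1
    for i in range(n_par):
        q *= arity[parents[i]]
    counts = np.zeros(q * r, dtype=np.int64)
    ns = codes.shape[0]
    for s in range(ns):
        conf = 0
        for i in range(n_par):
            p = parents[i]
            conf = conf * arity[p] + codes[s, p]
        counts[conf * r + codes[s, child]] += 1
    a_jk = ess / (q * r)
    a_j = ess / q
    lg_aj = math.lgamma(a_j)
    lg_ajk = math.lgamma(a_jk)
    score = 0.0
    for j in range(q):
        n_j = 0
        for k in range(r):
            c = counts[j * r + k]
            n_j += c
            if c > 0:
                score += math.lgamma(a_jk + c) - lg_ajk
        score += lg_aj - math.lgamma(a_j + n_j)
    return score


@njit(cache=True)
def _pack_key(n, child, parents, n_par):
    # canonical: sorted parent slots, 0 for unused (node ids shifted by +1)
    p0 = 0
    p1 = 0
    p2 = 0
    if n_par > 0:
        p0 = parents[0] + 1
    if n_par > 1:
        p1 = parents[1] + 1
    if n_par > 2:
        p2 = parents[2] + 1
    if p1 > p0:
        p0, p1 = p1, p0
    if p2 > p1:
        p1, p2 = p2, p1
    if p1 > p0:
        p0, p1 = p1, p0
    base = n + 1
    return ((np.int64(child) * base + p0) * base + p1) * base + p2


@njit(cache=True)
def _cached_family(codes, arity, child, parents, n_par, ess, cache, n):
    key = _pack_key(n, child, parents, n_par)
    if key in cache:
        return cache[key]
    val = _family_score(codes, arity, child, parents, n_par, ess)
    cache[key] = val
    return val


@njit(inline="always")
def _bit(reach, u, v):
    return (reach[u, v >> 6] >> np.uint64(v & 63)) & np.uint64(1)


@njit(cache=True)
def _closure(adj_child_list, child_count, reach, order, indeg_tmp):
    """Transitive closure into row bitsets by reverse-topological DP."""
    n = reach.shape[0]
    w = reach.shape[1]
    for v in range(n):
        indeg_tmp[v] = 0
    for u in range(n):
        for j in range(child_count[u]):
            indeg_tmp[adj_child_list[u, j]] += 1
    head = 0
    tail = 0
    for v in range(n):
        if indeg_tmp[v] == 0:
            order[tail] = v
            tail += 1
    while head < tail:
        u = order[head]
        head += 1
        for j in range(child_count[u]):
            v = adj_child_list[u, j]
            indeg_tmp[v] -= 1
            if indeg_tmp[v] == 0:
                order[tail] = v
                tail += 1
    for i in range(n):
        for k in range(w):
            reach[i, k] = np.uint64(0)
    for i in range(n - 1, -1, -1):
        u = order[i]
        for j in range(child_count[u]):
            c = adj_child_list[u, j]
            for k in range(w):
                reach[u, k] |= reach[c, k]
            reach[u, c >> 6] |= np.uint64(1) << np.uint64(c & 63)


@njit(cache=True)
def _apply_add_reach(reach, u, v):
    """After adding u->v: ancestors of u (and u) reach descendants of v (and v)."""
    n = reach.shape[0]
    w = reach.shape[1]
    vb = np.uint64(1) << np.uint64(v & 63)
    vw = v >> 6
    for a in range(n):
        if a == u or _bit(reach, a, u):
            for k in range(w):
                reach[a, k] |= reach[v, k]
            reach[a, vw] |= vb


@njit(cache=True)
def _child_insert(child_list, child_count, u, v):
    child_list[u, child_count[u]] = v
    child_count[u] += 1


@njit(cache=True)
def _child_remove(child_list, child_count, u, v):
    for i in range(child_count[u]):
        if child_list[u, i] == v:
            child_list[u, i] = child_list[u, child_count[u] - 1]
            child_count[u] -= 1
            return


@njit(cache=True)
def _fill_moves(adj, reach, cand_list, cand_count, indeg, is_locus,
                child_list, child_count, add_buf, rem_buf, rev_buf):
    """Enumerate eta(G) into flat-index buffers; returns the three counts.

    Only candidate pairs can carry edges, so the scan walks each node's
    candidate list rather than all ordered pairs.
    """
    n = adj.shape[0]
    na = 0
    nm = 0
    nv = 0
    for u in range(n):
        for j in range(cand_count[u]):
            v = cand_list[u, j]
            if adj[u, v]:
                rem_buf[nm] = u * n + v
                nm += 1
                # reversal u->v: u becomes a child of v
                if (not is_locus[u]) and indeg[u] <= MAX_PARENTS - 1:
                    two_step = False
                    for jj in range(child_count[u]):
                        k = child_list[u, jj]
                        if k != v and _bit(reach, k, v):
                            two_step = True
                            break
                    if not two_step:
                        rev_buf[nv] = u * n + v
                        nv += 1
            else:
                if (
                    (not is_locus[v])
                    and indeg[v] < MAX_PARENTS
                    and not _bit(reach, v, u)
                ):
                    add_buf[na] = u * n + v
                    na += 1
    return na, nm, nv


@njit(cache=True)
def run_chain(
    codes,
    arity,
    is_locus,
    cand_list,
    cand_count,
    R,
    beta,
    ess,
    n_iter,
    burn_in,
    sample_every,
    n_init_edges,
    seed,
    samples_per_interval,
    max_intervals,
    snapshot_every,
    max_snapshots,
):
    """Full MCMC run; returns tallies, diagnostics and snapshots.

    Returns (tally, n_samples, interval_tallies, n_intervals, scores,
    n_scores, accept_count, snapshots, n_snaps, final_adj).
    """
    np.random.seed(seed)
    n = codes.shape[1]
    w = (n + 63) // 64
    adj = np.zeros((n, n), dtype=np.bool_)
    reach = np.zeros((n, w), dtype=np.uint64)
    reach_bak = np.zeros((n, w), dtype=np.uint64)
    order = np.empty(n, dtype=np.int64)
    indeg_tmp = np.empty(n, dtype=np.int64)
    indeg = np.zeros(n, dtype=np.int64)
    parents = np.full((n, MAX_PARENTS), -1, dtype=np.int64)
    pcount = np.zeros(n, dtype=np.int64)
    child_list = np.zeros((n, n), dtype=np.int64)
    child_count = np.zeros(n, dtype=np.int64)
    cache = {np.int64(0): 0.0}
    del cache[np.int64(0)]
    logfam = np.empty(n, dtype=np.float64)
    scratch = np.empty(MAX_PARENTS, dtype=np.int64)
    for v in range(n):
        logfam[v] = _cached_family(codes, arity, v, scratch, 0, ess, cache, n)
    log_prior = 0.0

    add_buf = np.empty(n * n, dtype=np.int64)
    rem_buf = np.empty(n * n, dtype=np.int64)
    rev_buf = np.empty(n * n, dtype=np.int64)
    add2 = np.empty(n * n, dtype=np.int64)
    rem2 = np.empty(n * n, dtype=np.int64)
    rev2 = np.empty(n * n, dtype=np.int64)

    # random legal initialization
    placed = 0
    while placed < n_init_edges:
        na, nm, nv = _fill_moves(adj, reach, cand_list, cand_count, indeg,
                                 is_locus, child_list, child_count,
                                 add_buf, rem_buf, rev_buf)
        if na == 0:
            return (
                np.zeros((1, 1), dtype=np.int64), -1,
                np.zeros((1, 1, 1), dtype=np.int64), 0,
                np.zeros(1), 0, 0,
                np.zeros((1, 1, 1), dtype=np.bool_), 0, adj,
            )
        pick = add_buf[np.random.randint(na)]
        u = pick // n
        v = pick % n
        adj[u, v] = True
        parents[v, pcount[v]] = u
        pcount[v] += 1
        indeg[v] += 1
        _child_insert(child_list, child_count, u, v)
        _apply_add_reach(reach, u, v)
        logfam[v] = _cached_family(codes, arity, v, parents[v], pcount[v], ess, cache, n)
        log_prior += beta * R[u, v]
        placed += 1

    na, nm, nv = _fill_moves(adj, reach, cand_list, cand_count, indeg, is_locus,
                             child_list, child_count, add_buf, rem_buf, rev_buf)

    tally = np.zeros((n, n), dtype=np.int64)
    interval_tallies = np.zeros((max_intervals, n, n), dtype=np.int64)
    n_intervals = 0
    in_interval = 0
    max_scores = n_iter // sample_every + 1
    scores = np.zeros(max_scores, dtype=np.float64)
    n_scores = 0
    snapshots = np.zeros((max_snapshots, n, n), dtype=np.bool_)
    n_snaps = 0
    accept_count = 0
    n_samples = 0

    ADD = 0
    REMOVE = 1
    REVERSE = 2

    for it in range(n_iter):
        total = na + nm + nv
        r = np.random.randint(total)
        if r < na:
            kind = ADD
            flat = add_buf[r]
        elif r < na + nm:
            kind = REMOVE
            flat = rem_buf[r - na]
        else:
            kind = REVERSE
            flat = rev_buf[r - na - nm]
        u = flat // n
        v = flat % n

        old_fam_v = logfam[v]
        old_fam_u = logfam[u]
        reach_bak[:, :] = reach
        if kind == ADD:
            adj[u, v] = True
            parents[v, pcount[v]] = u
            pcount[v] += 1
            indeg[v] += 1
            _child_insert(child_list, child_count, u, v)
            _apply_add_reach(reach, u, v)
            new_v = _cached_family(codes, arity, v, parents[v], pcount[v], ess, cache, n)
            delta = new_v - old_fam_v + beta * R[u, v]
            logfam[v] = new_v
            log_prior += beta * R[u, v]
        elif kind == REMOVE:
            adj[u, v] = False
            _remove_parent(parents, pcount, v, u)
            indeg[v] -= 1
            _child_remove(child_list, child_count, u, v)
            _closure(child_list, child_count, reach, order, indeg_tmp)
            new_v = _cached_family(codes, arity, v, parents[v], pcount[v], ess, cache, n)
            delta = new_v - old_fam_v - beta * R[u, v]
            logfam[v] = new_v
            log_prior -= beta * R[u, v]
        else:
            adj[u, v] = False
            adj[v, u] = True
            _remove_parent(parents, pcount, v, u)
            parents[u, pcount[u]] = v
            pcount[u] += 1
            indeg[v] -= 1
            indeg[u] += 1
            _child_remove(child_list, child_count, u, v)
            _child_insert(child_list, child_count, v, u)
            _closure(child_list, child_count, reach, order, indeg_tmp)
            new_v = _cached_family(codes, arity, v, parents[v], pcount[v], ess, cache, n)
            new_u = _cached_family(codes, arity, u, parents[u], pcount[u], ess, cache, n)
            delta = new_v - old_fam_v + new_u - old_fam_u + beta * (R[v, u] - R[u, v])
            logfam[v] = new_v
            logfam[u] = new_u
            log_prior += beta * (R[v, u] - R[u, v])

        na2, nm2, nv2 = _fill_moves(adj, reach, cand_list, cand_count, indeg,
                                    is_locus, child_list, child_count,
                                    add2, rem2, rev2)
        log_a = delta + math.log(total) - math.log(na2 + nm2 + nv2)
        if math.log(np.random.random()) < log_a:
            na, nm, nv = na2, nm2, nv2
            add_buf, add2 = add2, add_buf
            rem_buf, rem2 = rem2, rem_buf
            rev_buf, rev2 = rev2, rev_buf
            accept_count += 1
        else:
            # undo
            if kind == ADD:
                adj[u, v] = False
                _remove_parent(parents, pcount, v, u)
                indeg[v] -= 1
                _child_remove(child_list, child_count, u, v)
                logfam[v] = old_fam_v
                log_prior -= beta * R[u, v]
            elif kind == REMOVE:
                adj[u, v] = True
                parents[v, pcount[v]] = u
                pcount[v] += 1
                indeg[v] += 1
                _child_insert(child_list, child_count, u, v)
                logfam[v] = old_fam_v
                log_prior += beta * R[u, v]
            else:
                adj[v, u] = False
                adj[u, v] = True
                _remove_parent(parents, pcount, u, v)
                parents[v, pcount[v]] = u
                pcount[v] += 1
                indeg[u] -= 1
                indeg[v] += 1
                _child_remove(child_list, child_count, v, u)
                _child_insert(child_list, child_count, u, v)
                logfam[v] = old_fam_v
                logfam[u] = old_fam_u
                log_prior -= beta * (R[v, u] - R[u, v])
            reach[:, :] = reach_bak

        if snapshot_every > 0 and it >= burn_in and (it + 1) % snapshot_every == 0:
            if n_snaps < max_snapshots:
                snapshots[n_snaps] = adj
                n_snaps += 1

        if it >= burn_in and (it + 1) % sample_every == 0:
            tally += adj
            n_samples += 1
            if n_intervals < max_intervals:
                interval_tallies[n_intervals] += adj
            in_interval += 1
            scores[n_scores] = logfam.sum() + log_prior
            n_scores += 1
            if in_interval == samples_per_interval:
                in_interval = 0
                n_intervals += 1

    return (
        tally, n_samples, interval_tallies, n_intervals,
        scores, n_scores, accept_count, snapshots, n_snaps, adj,
    )


@njit(cache=True)
def _remove_parent(parents, pcount, v, u):
    for i in range(pcount[v]):
        if parents[v, i] == u:
            parents[v, i] = parents[v, pcount[v] - 1]
            pcount[v] -= 1
            return
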