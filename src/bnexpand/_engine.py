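"""JIT-compiled simulated-annealing kernel over DAG structures.

The kernel operates on integer state matrices and adjacency matrices
(``adj[u, v] == 1`` means an edge u -> v, i.e. u is a parent of v) and is
deliberately self-contained: its own splitmix64 PRNG (so runs are
bit-reproducible across platforms and a longer run shares its proposal
prefix with a shorter run at the same seed), its own per-family score cache,
and an incremental transitive closure for O(1) acyclicity checks during move
enumeration.

Python-level wrappers in :mod:`bnexpand.search` translate between gene ids
and node indices; the pure-numpy scorer in :mod:`bnexpand.scoring` provides
an independent route to the same family scores.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, types
from numba.typed import Dict

_U64 = np.uint64

_MIX1 = _U64(0x9E3779B97F4A7C15)
_MIX2 = _U64(0xBF58476D1CE4E5B9)
_MIX3 = _U64(0x94D4A66395BCF649)


@njit(cache=True, inline="always")
def _next_u64(state):
    state[0] = state[0] + _MIX1
    z = state[0]
    z = (z ^ (z >> _U64(30))) * _MIX2
    z = (z ^ (z >> _U64(27))) * _MIX3
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _rand01(state):
    # 53-bit mantissa in [0, 1)
    return (_next_u64(state) >> _U64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _randint(state, n):
    return int(_next_u64(state) % _U64(n))


@njit(cache=True)
def _closure(adj, reach):
    """reach[u, v] = 1 iff a directed path u -> ... -> v exists (length >= 1)."""
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            reach[i, j] = adj[i, j]
    for k in range(n):
        for i in range(n):
            if reach[i, k]:
                for j in range(n):
                    if reach[k, j]:
                        reach[i, j] = 1


@njit(cache=True)
def _family_score(states, arities, adj, child, lgam, counts, par):
    """Cooper-Herskovits log family score of ``child`` under adj's parents."""
    n, m = states.shape
    n_par = 0
    q = 1
    for u in range(n):
        if adj[u, child]:
            par[n_par] = u
            n_par += 1
            q *= arities[u]
    r = arities[child]
    for j in range(q * r):
        counts[j] = 0
    for s in range(m):
        idx = 0
        for t in range(n_par):
            idx = idx * arities[par[t]] + states[par[t], s]
        counts[idx * r + states[child, s]] += 1
    total = 0.0
    for j in range(q):
        nij = 0
        for k in range(r):
            c = counts[j * r + k]
            nij += c
            total += lgam[c + 1]
        total += lgam[r] - lgam[nij + r]
    return total


@njit(cache=True, inline="always")
def _family_key(adj, child, n):
    mask = _U64(0)
    one = _U64(1)
    for u in range(n):
        if adj[u, child]:
            mask |= one << _U64(u)
    return (_U64(child) << _U64(n)) | mask


@njit(cache=True)
def _cached_family_score(states, arities, adj, child, lgam, counts, par, cache):
    key = _family_key(adj, child, adj.shape[0])
    if key in cache:
        return cache[key]
    val = _family_score(states, arities, adj, child, lgam, counts, par)
    cache[key] = val
    return val


@njit(cache=True)
def _try_insert(topk_adj, topk_score, topk_used, adj, score):
    """Insert a (network, score) pair into the sorted distinct top-k store."""
    k = topk_score.shape[0]
    n = adj.shape[0]
    if topk_used == k and score <= topk_score[topk_used - 1]:
        return topk_used
    # structural dedup: incremental score accumulation can drift by a few
    # ulps between visits, so proximity of scores cannot be trusted
    for i in range(topk_used):
        same = True
        for u in range(n):
            for v in range(n):
                if topk_adj[i, u, v] != adj[u, v]:
                    same = False
                    break
            if not same:
                break
        if same:
            return topk_used
    # find insertion slot (descending score order)
    pos = topk_used
    for i in range(topk_used):
        if score > topk_score[i]:
            pos = i
            break
    if pos == k:
        return topk_used
    last = min(topk_used, k - 1)
    for i in range(last, pos, -1):
        topk_score[i] = topk_score[i - 1]
        topk_adj[i] = topk_adj[i - 1]
    topk_score[pos] = score
    topk_adj[pos] = adj
    if topk_used < k:
        return topk_used + 1
    return topk_used


@njit(cache=True)
def _run_anneal_jit(
    states,
    arities,
    adj,
    n_props,
    max_parents,
    t0,
    cool,
    reheat_after,
    keep_top,
    seed,
):
    n, m = states.shape
    maxr = 2
    for i in range(n):
        if arities[i] > maxr:
            maxr = arities[i]
    lgam = np.empty(m + maxr + 2, dtype=np.float64)
    for i in range(m + maxr + 2):
        lgam[i] = math.lgamma(i) if i > 0 else 0.0
    # counts buffer sized for the worst-case parent configuration count
    cap = min(max_parents, n - 1) if n > 1 else 0
    sorted_ar = np.sort(arities)[::-1]
    qmax = 1
    for t in range(cap):
        qmax *= sorted_ar[t]
    counts = np.zeros(qmax * maxr, dtype=np.int64)
    par = np.zeros(max(n, 1), dtype=np.int64)
    cache = Dict.empty(key_type=types.uint64, value_type=types.float64)

    rng = np.empty(1, dtype=np.uint64)
    rng[0] = seed

    reach = np.zeros((n, n), dtype=np.uint8)
    _closure(adj, reach)
    pc = np.zeros(n, dtype=np.int64)  # parent counts
    for v in range(n):
        c = 0
        for u in range(n):
            if adj[u, v]:
                c += 1
        pc[v] = c

    fam = np.empty(n, dtype=np.float64)
    total = 0.0
    for v in range(n):
        fam[v] = _cached_family_score(
            states, arities, adj, v, lgam, counts, par, cache
        )
        total += fam[v]

    topk_adj = np.zeros((keep_top, n, n), dtype=np.uint8)
    topk_score = np.full(keep_top, -np.inf)
    topk_used = _try_insert(topk_adj, topk_score, 0, adj, total)

    # move tables: type 0 = add u->v, 1 = delete u->v, 2 = reverse u->v
    max_moves = 2 * n * n
    mu = np.empty(max_moves, dtype=np.int64)
    mv = np.empty(max_moves, dtype=np.int64)
    mt = np.empty(max_moves, dtype=np.int64)

    prop_adj = np.empty((n, n), dtype=np.uint8)
    temp = t0
    rejections = 0

    for _prop in range(n_props):
        n_moves = 0
        for u in range(n):
            for v in range(n):
                if u == v:
                    continue
                if adj[u, v]:
                    mu[n_moves] = u
                    mv[n_moves] = v
                    mt[n_moves] = 1  # delete
                    n_moves += 1
                    if pc[u] < max_parents:
                        # reversal is legal iff no u->v path of length >= 2
                        ok = True
                        for w in range(n):
                            if w != v and adj[u, w] and reach[w, v]:
                                ok = False
                                break
                        if ok:
                            mu[n_moves] = u
                            mv[n_moves] = v
                            mt[n_moves] = 2  # reverse
                            n_moves += 1
                else:
                    if pc[v] < max_parents and not reach[v, u]:
                        mu[n_moves] = u
                        mv[n_moves] = v
                        mt[n_moves] = 0  # add
                        n_moves += 1
        if n_moves == 0:
            temp *= cool
            continue
        pick = _randint(rng, n_moves)
        u = mu[pick]
        v = mv[pick]
        t = mt[pick]
        prop_adj[:, :] = adj
        if t == 0:
            prop_adj[u, v] = 1
        elif t == 1:
            prop_adj[u, v] = 0
        else:
            prop_adj[u, v] = 0
            prop_adj[v, u] = 1
        new_fam_v = _cached_family_score(
            states, arities, prop_adj, v, lgam, counts, par, cache
        )
        new_total = total - fam[v] + new_fam_v
        new_fam_u = fam[u]
        if t == 2:
            new_fam_u = _cached_family_score(
                states, arities, prop_adj, u, lgam, counts, par, cache
            )
            new_total += new_fam_u - fam[u]

        topk_used = _try_insert(topk_adj, topk_score, topk_used, prop_adj, new_total)

        delta = new_total - total
        accept = delta >= 0.0
        if not accept and temp > 0.0:
            accept = _rand01(rng) < math.exp(delta / temp)
        if accept:
            adj[:, :] = prop_adj
            fam[v] = new_fam_v
            fam[u] = new_fam_u
            total = new_total
            if t == 0:
                pc[v] += 1
            elif t == 1:
                pc[v] -= 1
            else:
                pc[v] -= 1
                pc[u] += 1
            _closure(adj, reach)
            rejections = 0
        else:
            rejections += 1
            if rejections >= reheat_after:
                temp = t0
                rejections = 0
        temp *= cool

    return topk_adj, topk_score, topk_used


def run_anneal(
    states: np.ndarray,
    arities: np.ndarray,
    start_adj: np.ndarray,
    n_props: int,
    max_parents: int,
    t0: float,
    cool: float,
    reheat_after: int,
    keep_top: int,
    seed: int,
):
    """Run the annealing kernel; returns (adjacencies, scores) of the top-k
    distinct networks visited, best first."""
    states = np.ascontiguousarray(states, dtype=np.int64)
    arities = np.ascontiguousarray(arities, dtype=np.int64)
    n = states.shape[0]
    if n + max(n.bit_length(), 1) > 63:
        raise ValueError(
            f"annealing kernel supports at most ~57 nodes, got {n}"
        )
    cap = min(max_parents, max(n - 1, 0))
    qmax = int(np.prod(np.sort(arities)[::-1][:cap])) if n else 1
    if qmax * int(arities.max(initial=2)) > 50_000_000:
        raise ValueError("max_parents too large for the given arities")
    adj = np.ascontiguousarray(start_adj, dtype=np.uint8).copy()
    topk_adj, topk_score, used = _run_anneal_jit(
        states,
        arities,
        adj,
        int(n_props),
        int(max_parents),
        float(t0),
        float(cool),
        int(reheat_after),
        int(keep_top),
        _U64(int(seed) & 0xFFFFFFFFFFFFFFFF),
    )
    return topk_adj[:used].copy(), topk_score[:used].copy()
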