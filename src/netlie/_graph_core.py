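"""Low-level numba kernels for binary-graph metrics and degree-preserving rewiring.

Two implementations live here:

* dense uint8 adjacency kernels (``bfs_distances``, ``graph_summary``, ...)
  that work for any graph size, and
* single-word bitset kernels (``*_bits``) used when the graph has at most 60
  nodes, where each adjacency row packs into one int64 and BFS reduces to a
  handful of OR/popcount operations.

The null-model normalization evaluates clustering and path length on ~10^6
rewired ~50-node graphs per study, so the bitset path is what makes the
pipeline tractable; the dense path doubles as a slow, independent route in
tests. All kernels assume a symmetric, loop-free adjacency.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "bfs_distances",
    "graph_summary",
    "local_efficiency_kernel",
    "double_edge_swap_kernel",
    "adjacency_to_edges",
    "BITSET_MAX_NODES",
    "to_masks",
    "graph_summary_bits",
    "local_efficiency_bits",
    "double_edge_swap_bits",
    "null_cp_lp_bits",
]

# one int64 word per adjacency row; keep headroom below the sign bit
BITSET_MAX_NODES = 60


# ---------------------------------------------------------------------------
# dense kernels (any size)
# ---------------------------------------------------------------------------

@njit(cache=True)
def bfs_distances(adj):
    """All-pairs unweighted shortest-path lengths; -1 marks unreachable."""
    n = adj.shape[0]
    dist = np.full((n, n), -1, np.int32)
    queue = np.empty(n, np.int32)
    for s in range(n):
        dist[s, s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] != 0 and dist[s, v] < 0:
                    dist[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def graph_summary(adj):
    """Return (Cp, Lp, n_connected_ordered_pairs, E_glob).

    Cp is the Watts–Strogatz node-wise mean clustering coefficient (nodes of
    degree < 2 contribute 0). Lp averages shortest-path length over connected
    ordered pairs only; it is NaN for an edgeless graph. E_glob averages the
    inverse distance over all ordered pairs, counting disconnected pairs as 0.
    """
    n = adj.shape[0]
    cp = 0.0
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j] != 0:
                k += 1
        if k >= 2:
            tri = 0
            for j in range(n):
                if adj[i, j] != 0:
                    for l in range(j + 1, n):
                        if adj[i, l] != 0 and adj[j, l] != 0:
                            tri += 1
            cp += 2.0 * tri / (k * (k - 1))
    cp /= n

    dist = bfs_distances(adj)
    lsum = 0.0
    esum = 0.0
    npairs = 0
    for i in range(n):
        for j in range(n):
            if i != j and dist[i, j] > 0:
                lsum += dist[i, j]
                esum += 1.0 / dist[i, j]
                npairs += 1
    eg = esum / (n * (n - 1))
    lp = lsum / npairs if npairs > 0 else np.nan
    return cp, lp, npairs, eg


@njit(cache=True)
def local_efficiency_kernel(adj):
    """Mean over nodes of the global efficiency of the neighbor-induced subgraph."""
    n = adj.shape[0]
    nb = np.empty(n, np.int32)
    total = 0.0
    for i in range(n):
        m = 0
        for j in range(n):
            if adj[i, j] != 0:
                nb[m] = j
                m += 1
        if m < 2:
            continue
        sub = np.zeros((m, m), np.uint8)
        for a in range(m):
            for b in range(m):
                sub[a, b] = adj[nb[a], nb[b]]
        d = bfs_distances(sub)
        es = 0.0
        for a in range(m):
            for b in range(m):
                if a != b and d[a, b] > 0:
                    es += 1.0 / d[a, b]
        total += es / (m * (m - 1))
    return total / n


# -- tiny counter-free PRNG for the swap loops ------------------------------
# xorshift64* seeded through splitmix64: the swap kernels draw ~10^10 variates
# per study, where a Mersenne generator call would dominate the runtime.

_U64_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)
_XS_MULT = np.uint64(2685821657736338717)
_S12 = np.uint64(12)
_S25 = np.uint64(25)
_S27 = np.uint64(27)
_S30 = np.uint64(30)
_S31 = np.uint64(31)
_S32 = np.uint64(32)


@njit(cache=True)
def _seed_state(seed):
    x = (np.uint64(seed) + _SM_GAMMA) & _U64_MASK
    x = ((x ^ (x >> _S30)) * _SM_M1) & _U64_MASK
    x = ((x ^ (x >> _S27)) * _SM_M2) & _U64_MASK
    x = x ^ (x >> _S31)
    if x == np.uint64(0):
        x = _SM_GAMMA
    return x


@njit(cache=True)
def _next_u64(state):
    state ^= state >> _S12
    state = (state ^ (state << _S25)) & _U64_MASK
    state ^= state >> _S27
    return (state * _XS_MULT) & _U64_MASK, state


@njit(cache=True)
def _bounded(x, n):
    # map a u64 variate to [0, n) via multiply-shift on the high 32 bits
    return np.int64(((x >> _S32) * np.uint64(n)) >> _S32)


@njit(cache=True)
def double_edge_swap_kernel(adj, edges, n_attempts, seed):
    """Maslov–Sneppen double-edge swaps in place; returns the number applied.

    Each attempt draws two distinct edges (a,b),(c,d) and a random orientation
    and proposes (a,c),(b,d); it is rejected if it would create a self-loop or
    a multi-edge, so the degree sequence is preserved exactly.
    """
    state = _seed_state(seed)
    n_edges = edges.shape[0]
    swaps = 0
    for _ in range(n_attempts):
        x, state = _next_u64(state)
        e1 = _bounded(x, n_edges)
        x, state = _next_u64(state)
        e2 = _bounded(x, n_edges)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        x, state = _next_u64(state)
        if (x >> _S31) & np.uint64(1):
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, c] != 0 or adj[b, d] != 0:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, c] = 1
        adj[c, a] = 1
        adj[b, d] = 1
        adj[d, b] = 1
        edges[e1, 0], edges[e1, 1] = a, c
        edges[e2, 0], edges[e2, 1] = b, d
        swaps += 1
    return swaps


@njit(cache=True)
def adjacency_to_edges(adj):
    n = adj.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j] != 0:
                count += 1
    edges = np.empty((count, 2), np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j] != 0:
                edges[k, 0] = i
                edges[k, 1] = j
                k += 1
    return edges


# ---------------------------------------------------------------------------
# bitset kernels (n <= BITSET_MAX_NODES)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _popcount(x):
    # SWAR popcount; safe in int64 for <= 60 set bits (no sign-bit use)
    x = x - ((x >> 1) & 0x5555555555555555)
    x = (x & 0x3333333333333333) + ((x >> 2) & 0x3333333333333333)
    x = (x + (x >> 4)) & 0x0F0F0F0F0F0F0F0F
    return (x * 0x0101010101010101) >> 56


@njit(cache=True)
def _lowest_bit_index(x):
    # index of the least significant set bit (x != 0)
    return _popcount((x & -x) - 1)


@njit(cache=True)
def to_masks(adj):
    """Pack adjacency rows into int64 bitmasks (bit j of masks[i] = adj[i,j])."""
    n = adj.shape[0]
    masks = np.zeros(n, np.int64)
    for i in range(n):
        row = np.int64(0)
        for j in range(n):
            if adj[i, j] != 0:
                row |= np.int64(1) << j
        masks[i] = row
    return masks


@njit(cache=True)
def graph_summary_bits(masks, n):
    """Bitset equivalent of :func:`graph_summary`."""
    cp = 0.0
    for i in range(n):
        k = _popcount(masks[i])
        if k >= 2:
            # ordered neighbor pairs that are themselves adjacent = 2 * triangles
            t = 0
            f = masks[i]
            while f != 0:
                u = _lowest_bit_index(f)
                f &= f - 1
                t += _popcount(masks[i] & masks[u])
            cp += t / (k * (k - 1))
    cp /= n

    lsum = 0.0
    esum = 0.0
    npairs = 0
    for s in range(n):
        reached = np.int64(1) << s
        frontier = masks[s] & ~reached
        d = 1
        while frontier != 0:
            c = _popcount(frontier)
            lsum += d * c
            esum += c / d
            npairs += c
            reached |= frontier
            nxt = np.int64(0)
            f = frontier
            while f != 0:
                u = _lowest_bit_index(f)
                f &= f - 1
                nxt |= masks[u]
            frontier = nxt & ~reached
            d += 1
    eg = esum / (n * (n - 1))
    lp = lsum / npairs if npairs > 0 else np.nan
    return cp, lp, npairs, eg


@njit(cache=True)
def local_efficiency_bits(masks, n):
    """Bitset equivalent of :func:`local_efficiency_kernel`."""
    nb = np.empty(n, np.int32)
    total = 0.0
    for i in range(n):
        m = 0
        f = masks[i]
        while f != 0:
            nb[m] = _lowest_bit_index(f)
            f &= f - 1
            m += 1
        if m < 2:
            continue
        # remap the neighbor-induced subgraph onto bits 0..m-1
        sub = np.zeros(m, np.int64)
        for a in range(m):
            row = np.int64(0)
            ra = masks[nb[a]]
            for b in range(m):
                if (ra >> nb[b]) & 1:
                    row |= np.int64(1) << b
            sub[a] = row
        es = 0.0
        for s in range(m):
            reached = np.int64(1) << s
            frontier = sub[s] & ~reached
            d = 1
            while frontier != 0:
                es += _popcount(frontier) / d
                reached |= frontier
                nxt = np.int64(0)
                ff = frontier
                while ff != 0:
                    u = _lowest_bit_index(ff)
                    ff &= ff - 1
                    nxt |= sub[u]
                frontier = nxt & ~reached
                d += 1
        total += es / (m * (m - 1))
    return total / n


@njit(cache=True)
def double_edge_swap_bits(masks, edges, n_attempts, seed):
    """Bitset equivalent of :func:`double_edge_swap_kernel` (in place)."""
    state = _seed_state(seed)
    n_edges = edges.shape[0]
    swaps = 0
    for _ in range(n_attempts):
        x, state = _next_u64(state)
        e1 = _bounded(x, n_edges)
        x, state = _next_u64(state)
        e2 = _bounded(x, n_edges)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        x, state = _next_u64(state)
        if (x >> _S31) & np.uint64(1):
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if ((masks[a] >> c) & 1) != 0 or ((masks[b] >> d) & 1) != 0:
            continue
        masks[a] ^= (np.int64(1) << b) | (np.int64(1) << c)
        masks[b] ^= (np.int64(1) << a) | (np.int64(1) << d)
        masks[c] ^= (np.int64(1) << d) | (np.int64(1) << a)
        masks[d] ^= (np.int64(1) << c) | (np.int64(1) << b)
        edges[e1, 0], edges[e1, 1] = a, c
        edges[e2, 0], edges[e2, 1] = b, d
        swaps += 1
    return swaps


@njit(cache=True)
def null_cp_lp_bits(masks, n, edges, n_random, rewires_per_edge, seed):
    """Cp and Lp over a degree-preserving random ensemble (fused loop).

    Ensemble member r uses RNG stream ``seed + r``, matching the dense path
    and :func:`netlie.graph_metrics.random_reference_ensemble` exactly.
    """
    n_edges = edges.shape[0]
    cps = np.empty(n_random)
    lps = np.empty(n_random)
    for r in range(n_random):
        m = masks.copy()
        e = edges.copy()
        double_edge_swap_bits(m, e, rewires_per_edge * n_edges, seed + r)
        cp, lp, _, _ = graph_summary_bits(m, n)
        cps[r] = cp
        lps[r] = lp
    return cps, lps
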