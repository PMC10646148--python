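"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here deliberately recomputes quantities from first principles
(explicit loops, full candidate scans, networkx graph walks) so that the
package's vectorized implementations are checked against a separate route.
"""

from __future__ import annotations

import math

import numpy as np


def huang_fuzziness(values: np.ndarray, threshold: float) -> float:
    """Huang & Wang fuzziness of a split, computed with explicit loops."""
    v, c = np.unique(np.asarray(values).ravel(), return_counts=True)
    C = float(v[-1] - v[0])
    bg = [(g, n) for g, n in zip(v, c) if g <= threshold]
    fg = [(g, n) for g, n in zip(v, c) if g > threshold]
    if not bg or not fg:
        return math.inf
    mu0 = sum(g * n for g, n in bg) / sum(n for _, n in bg)
    mu1 = sum(g * n for g, n in fg) / sum(n for _, n in fg)
    total = 0.0
    for g, n in bg + fg:
        mu = mu0 if g <= threshold else mu1
        u = 1.0 / (1.0 + abs(g - mu) / C)
        if 0.0 < u < 1.0:
            total += n * (-u * math.log(u) - (1 - u) * math.log(1 - u))
    return total


def huang_threshold_bruteforce(values: np.ndarray) -> float:
    """Exhaustive scan of every candidate split for the minimum fuzziness."""
    v = np.unique(np.asarray(values).ravel())
    best_t, best_f = None, math.inf
    for t in v[:-1]:
        f = huang_fuzziness(values, float(t))
        if f < best_f:
            best_t, best_f = float(t), f
    return best_t


def moments_threshold_bruteforce(values: np.ndarray) -> float:
    """Tsai threshold by numerically solving the moment equations.

    Solves the 2x2 linear system for the auxiliary coefficients with
    ``np.linalg.solve``, takes the representative levels as polynomial roots
    via ``np.roots``, and scans every candidate threshold for the cumulative
    fraction closest to the derived background fraction.
    """
    flat = np.asarray(values, dtype=np.float64).ravel()
    v, c = np.unique(flat, return_counts=True)
    p = c / c.sum()
    m1, m2, m3 = (np.sum(p * v**k) for k in (1, 2, 3))
    # moments of the two-level image: p0 + p1 = 1; p0 z0^k + p1 z1^k = m_k
    A = np.array([[1.0, m1], [m1, m2]])
    b = np.array([-m2, -m3])
    c0, c1 = np.linalg.solve(A, b)
    roots = np.sort(np.roots([1.0, c1, c0]).real)
    z0, z1 = roots[0], roots[1]
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(p)
    # thresholds must split: the maximum value is not a candidate
    best_i = min(range(len(v) - 1), key=lambda i: abs(cum[i] - p0))
    return float(v[best_i])


def skeleton_morphometry_networkx(skeleton: np.ndarray, pixel_size_um: float):
    """Branch/junction/endpoint counts and total length via a networkx walk.

    Classifies pixels by degree in the 8-connected pixel graph, collapses
    adjacent junction pixels, decomposes the slab subgraph into paths and
    cycles, and accumulates orthogonal/diagonal step lengths.
    """
    import networkx as nx

    sk = np.asarray(skeleton, dtype=bool)
    G = nx.Graph()
    pixels = [tuple(p) for p in np.argwhere(sk)]
    G.add_nodes_from(pixels)
    H, W = sk.shape
    for r, c in pixels:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                q = (r + dr, c + dc)
                if 0 <= q[0] < H and 0 <= q[1] < W and sk[q]:
                    G.add_edge((r, c), q)

    def step(a, b):
        return math.sqrt(2.0) if (a[0] != b[0] and a[1] != b[1]) else 1.0

    deg = dict(G.degree())
    endpoints = [p for p in pixels if deg[p] <= 1]
    junction_px = {p for p in pixels if deg[p] >= 3}
    clusters = list(nx.connected_components(G.subgraph(junction_px)))
    cluster_of = {}
    for i, cl in enumerate(clusters):
        for p in cl:
            cluster_of[p] = i

    def terminal_id(p):
        if p in cluster_of:
            return ("j", cluster_of[p])
        return ("e", p)

    slab = [p for p in pixels if deg[p] == 2]
    S = G.subgraph(slab)
    n_branches = 0
    total = 0.0
    seen_pairs = set()
    # direct terminal-terminal contacts (different terminals only)
    for a, b in G.edges():
        if deg[a] != 2 and deg[b] != 2:
            ta, tb = terminal_id(a), terminal_id(b)
            if ta == tb:
                continue
            key = frozenset((a, b))
            if key not in seen_pairs:
                seen_pairs.add(key)
                n_branches += 1
                total += step(a, b)
    for comp in nx.connected_components(S):
        sub = S.subgraph(comp)
        ends = [p for p in comp if sub.degree(p) <= 1]
        if not ends:  # slab cycle, possibly isolated loop
            cyc = nx.find_cycle(sub)
            attached = any(
                deg[q] != 2 for p in comp for q in G.neighbors(p)
            )
            length = sum(step(a, b) for a, b in cyc)
            if not attached:
                n_branches += 1
                total += length
            continue
        if len(ends) == 1:  # single slab pixel run of length 1
            path = [ends[0]]
        else:
            path = nx.shortest_path(sub, ends[0], ends[1])
        length = sum(step(a, b) for a, b in zip(path[:-1], path[1:]))
        # attach to terminals on both sides (if any)
        for side in (path[0], path[-1]):
            terms = [q for q in G.neighbors(side) if deg[q] != 2]
            if terms:
                length += step(side, terms[0])
        n_branches += 1
        total += length
    return {
        "n_branches": n_branches,
        "n_junctions": len(clusters),
        "n_endpoints": len([p for p in endpoints if deg[p] == 1])
        + len([p for p in endpoints if deg[p] == 0]),
        "total_branch_length_um": total * pixel_size_um,
    }
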