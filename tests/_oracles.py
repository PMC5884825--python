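"""Independent brute-force oracles used to validate the fast implementations.

Everything here enumerates rather than accumulates: simple paths for
centralities, rotation grids for superposition, explicit loops for the
cross-correlation formula. Deliberately slow and deliberately written
without reference to the library code paths they check.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

RTOL = 1e-9


def all_simple_paths_weights(g: nx.Graph, s, t):
    """Every loopless s→t path with its total weight."""
    out = []
    for path in nx.all_simple_paths(g, s, t):
        w = sum(g[u][v]["weight"] for u, v in zip(path[:-1], path[1:]))
        out.append((list(path), w))
    return out


def brute_shortest_distance(g: nx.Graph, s, t):
    paths = all_simple_paths_weights(g, s, t)
    if not paths:
        return math.inf
    return min(w for _, w in paths)


def brute_betweenness(g: nx.Graph, normalization: str = "all-pairs"):
    """Fractional shortest-path counting by full path enumeration."""
    nodes = list(g.nodes)
    n = len(nodes)
    raw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = all_simple_paths_weights(g, s, t)
        if not paths:
            continue
        best = min(w for _, w in paths)
        shortest = [p for p, w in paths if w <= best + RTOL * max(1.0, best)]
        n_st = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            g_v = sum(1 for p in shortest if v in p)
            raw[v] += g_v / n_st
    if normalization == "all-pairs":
        norm = n * (n - 1) / 2
    else:
        norm = (n - 1) * (n - 2) / 2
    if norm <= 0:
        return dict.fromkeys(nodes, 0.0)
    return {v: b / norm for v, b in raw.items()}


def brute_closeness(g: nx.Graph):
    """Wasserman–Faust scaled closeness from enumerated shortest distances."""
    nodes = list(g.nodes)
    n = len(nodes)
    out = {}
    for s in nodes:
        dists = [brute_shortest_distance(g, s, t) for t in nodes if t != s]
        reach = [d for d in dists if math.isfinite(d)]
        if not reach or sum(reach) == 0:
            out[s] = 0.0
            continue
        nr = len(reach)
        out[s] = (nr / sum(reach)) * (nr / (n - 1))
    return out


def brute_k_shortest(g: nx.Graph, s, t, k):
    """All simple paths sorted by (weight, node sequence); first k."""
    paths = all_simple_paths_weights(g, s, t)
    paths.sort(key=lambda pw: (pw[1], pw[0]))
    return paths[:k]


def random_weighted_graph(rng: np.random.Generator, n_max=8, p=0.5):
    """A random connected-ish weighted graph with distinct positive weights."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
    return g


def dccm_reference(coords: np.ndarray) -> np.ndarray:
    """Step-by-step evaluation of the cross-correlation formula.

    ``coords`` is (frames, residues, 3); no superposition, explicit loops.
    """
    n_f, n_r, _ = coords.shape
    mean = np.zeros((n_r, 3))
    for t in range(n_f):
        for i in range(n_r):
            mean[i] += coords[t, i]
    mean /= n_f
    c = np.zeros((n_r, n_r))
    for i in range(n_r):
        for j in range(n_r):
            num = 0.0
            for t in range(n_f):
                di = coords[t, i] - mean[i]
                dj = coords[t, j] - mean[j]
                num += float(di @ dj)
            num /= n_f
            vi = sum(float((coords[t, i] - mean[i]) @ (coords[t, i] - mean[i]))
                     for t in range(n_f)) / n_f
            vj = sum(float((coords[t, j] - mean[j]) @ (coords[t, j] - mean[j]))
                     for t in range(n_f)) / n_f
            c[i, j] = num / math.sqrt(vi * vj)
    return c


def rotation_grid_rmsd(mobile: np.ndarray, reference: np.ndarray, steps=24):
    """Best RMSD over a grid of proper rotations (after centring).

    A coarse independent check that a fitted RMSD is close to the global
    minimum over proper rotations only (no reflections).
    """
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)
    best = math.inf
    angles = np.linspace(0, 2 * math.pi, steps, endpoint=False)
    from scipy.spatial.transform import Rotation

    for a, b, c in itertools.product(angles, repeat=3):
        r = Rotation.from_euler("zyx", [a, b, c]).as_matrix()
        d = p @ r.T - q
        best = min(best, math.sqrt(np.mean(np.sum(d * d, axis=1))))
    return best
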