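"""Residue correlation networks: construction, centralities, communities,
suboptimal paths and wild-type-vs-mutant comparison.

A correlation map C is turned into a weighted graph over residues: an edge
(i, j) survives the threshold C_thr and carries the information distance

    w_ij = -log|C_ij|        (natural log)

which is small when the correlation magnitude is high, so weighted shortest
paths follow chains of strongly correlated residues. The log base only
rescales all distances by a constant, leaving shortest-path trees, degree,
betweenness and every ranking unchanged (closeness rescales accordingly).

Two threshold semantics are exposed. ``magnitude`` (default) disconnects
edges with |C_ij| < C_thr, consistent with the weight using |C|; ``signed``
disconnects edges with C_ij < C_thr, which additionally removes all
anti-correlated pairs.

Betweenness offers two normalisations of the fractional shortest-path count
sum_{s<t} g_i^st / n_st: ``all-pairs`` divides by n(n-1)/2 (all unordered node
pairs, including those touching i), ``standard`` by (n-1)(n-2)/2 (pairs
excluding i, the textbook choice). Rankings are identical; only the scale
differs.
"""

from __future__ import annotations

import heapq
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dccm import DCCMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationNetwork",
    "CentralityReport",
    "CommunityPartition",
    "PathSet",
    "NetworkComparison",
    "build_network",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "shortest_path_lengths",
    "detect_communities",
    "suboptimal_paths",
    "centrality_report",
    "top_residues",
    "compare_networks",
    "write_edge_csv",
    "write_graphml",
    "write_centrality_csv",
    "write_community_csv",
    "write_paths_json",
]

#: A correlation network is a plain undirected networkx graph whose nodes are
#: residue numbers and whose edges carry ``C`` (signed correlation) and
#: ``weight`` (information distance −log|C|); provenance lives in ``G.graph``.
CorrelationNetwork = nx.Graph

#: Relative tolerance for declaring two path weights tied.
WEIGHT_RTOL = 1e-9


# ---------------------------------------------------------------------------
# Construction


def build_network(
    dccm: DCCMatrix,
    c_thr: float = 0.3,
    threshold_mode: str = "magnitude",
) -> CorrelationNetwork:
    """Threshold a correlation map into a −log|C|-weighted residue graph.

    An empty graph is a valid result. Pairs with C_ij == 0 are never
    connected (their information distance is infinite).
    """
    if not (0.0 <= c_thr < 1.0):
        raise ValueError(f"c_thr must lie in [0, 1), got {c_thr}")
    if threshold_mode not in ("magnitude", "signed"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    logger.info("building network: c_thr=%s mode=%s", c_thr, threshold_mode)
    c = dccm.matrix
    n = dccm.n_residues
    g = nx.Graph()
    g.add_nodes_from(int(r) for r in dccm.resnums)
    iu, ju = np.triu_indices(n, k=1)
    vals = c[iu, ju]
    if threshold_mode == "magnitude":
        keep = np.abs(vals) >= c_thr
    else:
        keep = vals >= c_thr
    keep &= np.abs(vals) > 0.0
    for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
        g.add_edge(
            int(dccm.resnums[i]),
            int(dccm.resnums[j]),
            C=float(v),
            weight=float(max(-np.log(abs(v)), 0.0)),
        )
    g.graph["c_thr"] = c_thr
    g.graph["threshold_mode"] = threshold_mode
    if dccm.window is not None:
        g.graph["window"] = dccm.window.name
    return g


# ---------------------------------------------------------------------------
# Centralities


def degree_centrality(net: CorrelationNetwork) -> dict:
    """Edge count per node (row sums of the adjacency indicator)."""
    return {v: int(d) for v, d in net.degree()}


def closeness_centrality(net: CorrelationNetwork) -> dict:
    """Weighted closeness: (n_reach − 1) / Σ_j g(v, v_j), scaled by
    (n_reach − 1)/(n − 1) on disconnected graphs so values remain
    comparable across components. Isolated nodes get 0 (logged)."""
    out = nx.closeness_centrality(net, distance="weight", wf_improved=True)
    isolated = [v for v in net if net.degree(v) == 0]
    if isolated:
        logger.info("%d isolated node(s) assigned closeness 0", len(isolated))
    return {v: float(c) for v, c in out.items()}


def _shortest_path_dag(net, source, rtol=WEIGHT_RTOL):
    """Dijkstra from ``source`` plus the DAG of tied shortest paths.

    Returns ``(dist, order, preds)`` where ``order`` lists reachable nodes in
    Dijkstra settle order and ``preds[v]`` are the predecessors of ``v`` on
    some shortest path. Path-weight ties are declared with relative
    tolerance ``rtol``. Tied edges are oriented by settle order, so a
    zero-weight edge joining two equidistant nodes points away from the
    source and the path count stays finite, acyclic and deterministic.
    """
    dist = {source: 0.0}
    settle: dict = {}
    heap = [(0.0, source)]
    while heap:
        d, v = heapq.heappop(heap)
        if v in settle:
            continue
        settle[v] = len(settle)
        for u, attrs in net[v].items():
            nd = d + attrs["weight"]
            if u not in dist or nd < dist[u] - rtol * max(1.0, abs(dist[u])):
                dist[u] = nd
                heapq.heappush(heap, (nd, u))
    order = sorted(settle, key=settle.get)
    preds: dict = {v: [] for v in dist}
    for v in dist:
        for u, attrs in net[v].items():
            if u not in dist:
                continue
            through = dist[u] + attrs["weight"]
            tied = abs(through - dist[v]) <= rtol * max(1.0, abs(dist[v]))
            if tied and settle[u] < settle[v]:
                preds[v].append(u)
    return dist, order, preds


def betweenness_centrality(
    net: CorrelationNetwork, normalization: str = "all-pairs"
) -> dict:
    """Weighted betweenness by Brandes' dependency accumulation with
    fractional counting of tied shortest paths.

    ``normalization='all-pairs'`` divides the raw pair sum by n(n−1)/2;
    ``'standard'`` by (n−1)(n−2)/2. Ties in path weight use a relative
    tolerance of 1e−9.
    """
    if normalization not in ("all-pairs", "standard"):
        raise ValueError(f"unknown normalization {normalization!r}")
    n = net.number_of_nodes()
    bet = dict.fromkeys(net, 0.0)
    for s in net:
        _dist, order, preds = _shortest_path_dag(net, s)
        sigma = {s: 1.0}
        for v in order:
            if v == s:
                continue
            sigma[v] = sum(sigma[u] for u in preds[v])
        delta = dict.fromkeys(order, 0.0)
        for v in reversed(order):
            for u in preds[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bet[v] += delta[v]
    # each unordered pair was counted from both endpoints
    for v in bet:
        bet[v] *= 0.5
    if normalization == "all-pairs":
        norm = n * (n - 1) / 2.0
    else:
        norm = (n - 1) * (n - 2) / 2.0
    if norm <= 0:
        return dict.fromkeys(net, 0.0)
    return {v: b / norm for v, b in bet.items()}


def shortest_path_lengths(net: CorrelationNetwork, source) -> dict:
    """Dijkstra distances from ``source``; unreachable nodes map to inf."""
    if source not in net:
        raise KeyError(f"source {source!r} not in network")
    dist = nx.single_source_dijkstra_path_length(net, source, weight="weight")
    return {v: dist.get(v, float("inf")) for v in net}


# ---------------------------------------------------------------------------
# Reports


@dataclass
class CentralityReport:
    """Per-residue degree, closeness and betweenness with 1-based ranks.

    Ranks order by descending value; ties break by ascending residue number
    (stable and documented). The backing frame has columns ``residue``,
    the three measures, and ``rank_<measure>``.
    """

    table: pd.DataFrame
    normalization: str = "all-pairs"

    MEASURES = ("degree", "closeness", "betweenness")

    def values(self, measure: str) -> pd.Series:
        if measure not in self.MEASURES:
            raise ValueError(f"unknown measure {measure!r}")
        return self.table.set_index("residue")[measure]


def _rank(df: pd.DataFrame, measure: str) -> np.ndarray:
    order = df.sort_values([measure, "residue"], ascending=[False, True]).index
    ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
    return ranks.reindex(df.index).to_numpy()


def centrality_report(
    net: CorrelationNetwork, normalization: str = "all-pairs"
) -> CentralityReport:
    """Compute all three centralities and their ranks for a network."""
    deg = degree_centrality(net)
    clo = closeness_centrality(net)
    bet = betweenness_centrality(net, normalization=normalization)
    residues = sorted(net.nodes)
    df = pd.DataFrame(
        {
            "residue": residues,
            "degree": [deg[r] for r in residues],
            "closeness": [clo[r] for r in residues],
            "betweenness": [bet[r] for r in residues],
        }
    )
    for m in CentralityReport.MEASURES:
        df[f"rank_{m}"] = _rank(df, m)
    return CentralityReport(table=df, normalization=normalization)


def top_residues(report: CentralityReport, measure: str, k: int) -> pd.DataFrame:
    """Top-``k`` residues by a measure (ties → lower residue number first)."""
    if k < 1:
        raise ValueError("k must be at least 1")
    df = report.table
    if k > len(df):
        warnings.warn(
            f"k={k} exceeds {len(df)} residues; returning all", stacklevel=2
        )
        k = len(df)
    ranked = df.sort_values(f"rank_{measure}").head(k)
    return ranked[["residue", measure, f"rank_{measure}"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Communities


@dataclass
class CommunityPartition:
    """A node → community-label map with its modularity."""

    labels: dict
    modularity: float
    method: str = "girvan-newman+modularity"

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["residue", "community"]
        )


def _most_valuable_edge(g: nx.Graph):
    ebc = nx.edge_betweenness_centrality(g, weight="weight")
    # deterministic tie-break on the edge key
    return max(ebc.items(), key=lambda kv: (kv[1], kv[0]))[0]


def detect_communities(
    net: CorrelationNetwork, patience: int | None = 10
) -> CommunityPartition:
    """Girvan–Newman divisive clustering cut at maximum modularity.

    Edge betweenness is computed with the information distance w as the path
    metric; modularity of each dendrogram level is evaluated on the
    unweighted adjacency, and the best level (including the trivial
    connected-component partition) is returned. Isolated nodes are singleton
    communities. On an edgeless graph every node is its own community with
    modularity 0.

    ``patience`` stops descending the dendrogram after that many consecutive
    levels without a modularity improvement (modularity along the divisive
    sequence is near-unimodal in practice); ``None`` explores every level.
    """
    components = [set(c) for c in nx.connected_components(net)]
    if net.number_of_edges() == 0:
        labels = {v: i for i, c in enumerate(sorted(map(sorted, components))) for v in c}
        return CommunityPartition(labels=labels, modularity=0.0)
    best, best_q = components, nx.community.modularity(net, components, weight=None)
    stale = 0
    for part in nx.community.girvan_newman(
        net, most_valuable_edge=_most_valuable_edge
    ):
        part = [set(c) for c in part]
        q = nx.community.modularity(net, part, weight=None)
        if q > best_q + 1e-12:
            best, best_q = part, q
            stale = 0
        else:
            stale += 1
            if patience is not None and stale >= patience:
                break
    ordered = sorted((sorted(c) for c in best), key=lambda c: c[0])
    labels = {v: i for i, c in enumerate(ordered) for v in c}
    return CommunityPartition(labels=labels, modularity=float(best_q))


# ---------------------------------------------------------------------------
# Suboptimal paths


@dataclass
class PathSet:
    """Loopless paths between one residue pair, best (lowest weight) first."""

    source: object
    sink: object
    paths: list = field(default_factory=list)
    weights: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.paths)


def _path_weight(net, path) -> float:
    return float(sum(net[u][v]["weight"] for u, v in zip(path[:-1], path[1:])))


def suboptimal_paths(net: CorrelationNetwork, source, sink, k: int) -> PathSet:
    """The ``k`` lowest-information-distance loopless paths (Yen's algorithm).

    The first path is a weighted shortest path; weights are non-decreasing.
    Fewer than ``k`` paths are returned if fewer exist; no path at all gives
    an empty :class:`PathSet` rather than an exception.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if source == sink:
        raise ValueError("source and sink must differ")
    for v in (source, sink):
        if v not in net:
            raise KeyError(f"node {v!r} not in network")
    out = PathSet(source=source, sink=sink)
    try:
        gen = nx.shortest_simple_paths(net, source, sink, weight="weight")
        for _ in range(k):
            path = next(gen, None)
            if path is None:
                break
            out.paths.append(list(path))
            out.weights.append(_path_weight(net, path))
    except nx.NetworkXNoPath:
        pass
    return out


# ---------------------------------------------------------------------------
# Network comparison (e.g. wild type vs point mutant)


@dataclass
class NetworkComparison:
    """Differential report between two networks on the same residue set.

    ``per_node`` holds, per residue, centrality differences (b − a) and rank
    shifts for all three measures; edge differences and community counts are
    carried alongside.
    """

    per_node: pd.DataFrame
    edges_only_a: list
    edges_only_b: list
    communities_a: int
    communities_b: int

    def max_shift_residue(self, measure: str = "betweenness"):
        """Residue with the largest |Δ| in a measure."""
        col = f"d_{measure}"
        idx = self.per_node[col].abs().idxmax()
        return self.per_node.loc[idx, "residue"]


def compare_networks(
    a: CorrelationNetwork, b: CorrelationNetwork, normalization: str = "all-pairs"
) -> NetworkComparison:
    """Compare two networks node-by-node; both must share one node set."""
    if set(a.nodes) != set(b.nodes):
        diff = sorted(set(a.nodes) ^ set(b.nodes))
        raise ValueError(f"node sets differ; symmetric difference: {diff}")
    ra = centrality_report(a, normalization=normalization).table.set_index("residue")
    rb = centrality_report(b, normalization=normalization).table.set_index("residue")
    residues = sorted(a.nodes)
    df = pd.DataFrame({"residue": residues})
    for m in CentralityReport.MEASURES:
        df[f"d_{m}"] = (rb[m] - ra[m]).loc[residues].to_numpy()
        df[f"d_rank_{m}"] = (rb[f"rank_{m}"] - ra[f"rank_{m}"]).loc[residues].to_numpy()
    ea = {frozenset(e) for e in a.edges}
    eb = {frozenset(e) for e in b.edges}
    only_a = sorted(tuple(sorted(e)) for e in ea - eb)
    only_b = sorted(tuple(sorted(e)) for e in eb - ea)
    ca = detect_communities(a)
    cb = detect_communities(b)
    return NetworkComparison(
        per_node=df,
        edges_only_a=only_a,
        edges_only_b=only_b,
        communities_a=ca.n_communities,
        communities_b=cb.n_communities,
    )


# ---------------------------------------------------------------------------
# Export


def write_edge_csv(net: CorrelationNetwork, path: str | Path) -> None:
    rows = [
        (u, v, d.get("C", np.nan), d["weight"])
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["res_i", "res_j", "C_ij", "w_ij"]).to_csv(
        path, index=False
    )


def write_graphml(net: CorrelationNetwork, path: str | Path) -> None:
    g = net.copy()
    g.graph = {k: v for k, v in g.graph.items() if isinstance(v, (str, int, float))}
    nx.write_graphml(g, str(path))


def write_centrality_csv(report: CentralityReport, path: str | Path) -> None:
    report.table.to_csv(path, index=False)


def write_community_csv(partition: CommunityPartition, path: str | Path) -> None:
    partition.as_frame().to_csv(path, index=False)


def write_paths_json(paths: PathSet, path: str | Path) -> None:
    obj = {
        "source": paths.source,
        "sink": paths.sink,
        "paths": [
            {"nodes": [int(n) for n in p], "total_weight": w}
            for p, w in zip(paths.paths, paths.weights)
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=1))
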