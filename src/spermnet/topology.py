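"""Topological statistics for directed signed networks.

Everything a topological analyzer reports on a signaling map: degree
histograms and their log-log power-law fits P(k) = a·k^b, the clustering
coefficient CI = 2nI/(kI(kI−1)) and its dependence on degree, shortest-path
statistics (characteristic path length, diameter), closeness centrality
Cc(n) = 1/avg(L(n,m)), hub ranking, and the aggregate summary block.

Conventions
-----------
* Degrees count signed-edge multiplicity (A→B activation and A→B inhibition
  are two links); neighbour counts are direction-blind and distinct.
* Clustering uses the undirected formula even on directed networks; nodes
  with fewer than two neighbours contribute 0 to the mean.  A directed
  variant (nI/(kI(kI−1))) and mean-over-k≥2 are available behind flags.
* Path statistics follow edge direction by default and average over the
  finite ordered pairs only; unreachable pairs are dropped and reported
  via ``finite_pair_count``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sstats

from .records import ACTIVATION, INHIBITION
from .network import SignalingNetwork

__all__ = [
    "DegreeDistribution",
    "PowerLawFit",
    "PowerLawFitError",
    "NodeStat",
    "PathStatistics",
    "TopologySummary",
    "degree_distribution",
    "fit_power_law",
    "node_clustering",
    "mean_clustering",
    "clustering_vs_degree",
    "path_statistics",
    "closeness_centrality",
    "rank_hubs",
    "node_statistics",
    "summarize_topology",
]

DegreeMode = Literal["in", "out", "total"]


class PowerLawFitError(ValueError):
    pass


@dataclass(frozen=True)
class DegreeDistribution:
    """Observed degree histogram for one mode (in / out / total).

    ``points`` lists (k, count) for k ≥ 1 with count > 0, k strictly
    increasing; nodes with degree 0 are tallied separately in ``n_zero``
    because they cannot enter a log-log fit.
    """

    mode: DegreeMode
    points: tuple[tuple[int, int], ...]
    n_zero: int

    def __post_init__(self):
        ks = [k for k, _ in self.points]
        if ks != sorted(set(ks)):
            raise ValueError("k values must be strictly increasing")
        if any(k < 1 or c <= 0 for k, c in self.points):
            raise ValueError("points must have k >= 1 and count > 0")

    @property
    def n_nodes(self) -> int:
        return sum(c for _, c in self.points) + self.n_zero

    @property
    def mean_degree(self) -> float:
        n = self.n_nodes
        if n == 0:
            return 0.0
        return sum(k * c for k, c in self.points) / n

    @property
    def max_degree(self) -> int:
        return self.points[-1][0] if self.points else 0


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares line on (log k, log count): P(k) ≈ a·k^b.

    ``r2`` is the coefficient of determination of the log-log regression;
    ``r`` is the Pearson correlation between observed counts and the fitted
    a·k^b on the original scale — the dual reporting style of network
    analyzer tools.
    """

    a: float
    b: float
    r: float
    r2: float
    n_points: int

    def expected(self, k: Sequence[float]) -> np.ndarray:
        return self.a * np.asarray(k, dtype=float) ** self.b


def degree_distribution(net: SignalingNetwork, mode: DegreeMode = "total") -> DegreeDistribution:
    """Exact histogram of the chosen degree, counting signed multiplicity."""
    if mode not in ("in", "out", "total"):
        raise ValueError(f"unknown degree mode {mode!r}")
    deg = dict.fromkeys(net.nodes, 0)
    for s, t, _ in net.edges:
        if mode in ("out", "total"):
            deg[s] += 1
        if mode in ("in", "total"):
            deg[t] += 1
    counts: dict[int, int] = {}
    n_zero = 0
    for k in deg.values():
        if k == 0:
            n_zero += 1
        else:
            counts[k] = counts.get(k, 0) + 1
    return DegreeDistribution(mode, tuple(sorted(counts.items())), n_zero)


def fit_power_law(dist: DegreeDistribution | Sequence[tuple[float, float]]) -> PowerLawFit:
    """Fit log count = log a + b·log k by ordinary least squares.

    Raw frequency points are used (no binning, no k = 0 class).  At least
    three distinct k are required.
    """
    points = dist.points if isinstance(dist, DegreeDistribution) else tuple(dist)
    if len(points) < 3:
        raise PowerLawFitError(f"need >= 3 points to fit, got {len(points)}")
    k = np.array([p[0] for p in points], dtype=float)
    c = np.array([p[1] for p in points], dtype=float)
    if np.any(k <= 0):
        raise PowerLawFitError("degree values must be positive")
    if np.any(c <= 0):
        raise PowerLawFitError("counts must be positive")
    res = sstats.linregress(np.log(k), np.log(c))
    a = float(np.exp(res.intercept))
    b = float(res.slope)
    fitted = a * k**b
    if np.allclose(c, c[0]) or np.allclose(fitted, fitted[0]):
        r = 1.0 if np.allclose(c, fitted) else 0.0
    else:
        r = float(np.corrcoef(c, fitted)[0, 1])
    return PowerLawFit(a=a, b=b, r=r, r2=float(res.rvalue**2), n_points=len(points))


# ---------------------------------------------------------------------------
# clustering


def _neighbor_sets(net: SignalingNetwork) -> dict[str, set[str]]:
    nbrs: dict[str, set[str]] = {v: set() for v in net.nodes}
    for s, t, _ in net.edges:
        if s != t:
            nbrs[s].add(t)
            nbrs[t].add(s)
    return nbrs


def node_clustering(net: SignalingNetwork, label: str, *, directed: bool = False) -> float:
    """Clustering coefficient of one node.

    Undirected (default): c = 2nI/(kI(kI−1)) with nI the number of
    unordered neighbour pairs joined by at least one edge in either
    direction.  Directed variant: c = nI/(kI(kI−1)) with nI counting
    ordered neighbour pairs joined by a directed edge.
    """
    if label not in net.nodes:
        raise KeyError(f"unknown label {label!r}")
    nbrs = _neighbor_sets(net)[label]
    k = len(nbrs)
    if k < 2:
        return 0.0
    pairs = {(s, t) for s, t, _ in net.edges if s != t}
    nb = sorted(nbrs)
    if directed:
        links = sum(
            1 for u in nb for w in nb if u != w and (u, w) in pairs
        )
        return links / (k * (k - 1))
    links = 0
    for i, u in enumerate(nb):
        for w in nb[i + 1:]:
            if (u, w) in pairs or (w, u) in pairs:
                links += 1
    return 2.0 * links / (k * (k - 1))


def _all_clustering(net: SignalingNetwork) -> dict[str, float]:
    # networkx.clustering on the direction-blind simple view is exactly
    # 2nI/(kI(kI-1)) with c = 0 for k < 2
    return nx.clustering(net.to_undirected_simple())


def mean_clustering(net: SignalingNetwork, *, include_low_degree: bool = True) -> float:
    """Mean clustering coefficient over all nodes.

    Nodes with fewer than two neighbours contribute c = 0 by default;
    ``include_low_degree=False`` averages over k ≥ 2 nodes only.
    """
    cs = _all_clustering(net)
    if not include_low_degree:
        nbrs = _neighbor_sets(net)
        cs = {v: c for v, c in cs.items() if len(nbrs[v]) >= 2}
    if not cs:
        return 0.0
    return float(np.mean(list(cs.values())))


def clustering_vs_degree(
    net: SignalingNetwork,
) -> tuple[tuple[tuple[int, float], ...], PowerLawFit | None]:
    """Mean clustering per neighbour count k, with a power-law fit.

    Only k ≥ 2 points with positive mean clustering can enter the log-log
    fit; with fewer than three usable points the fit is None (unfittable),
    which is itself evidence that clustering does not follow a power law.
    """
    cs = _all_clustering(net)
    nbrs = _neighbor_sets(net)
    by_k: dict[int, list[float]] = {}
    for v in net.nodes:
        by_k.setdefault(len(nbrs[v]), []).append(cs[v])
    points = tuple(
        (k, float(np.mean(vals))) for k, vals in sorted(by_k.items()) if k >= 2
    )
    usable = [(k, c) for k, c in points if c > 0]
    fit = None
    if len(usable) >= 3:
        fit = fit_power_law(usable)
    return points, fit


# ---------------------------------------------------------------------------
# paths


@dataclass(frozen=True)
class PathStatistics:
    """Shortest-path statistics over ordered node pairs (n ≠ m).

    ``char_path_length`` and ``diameter`` are None when no pair is
    connected (an edgeless network has no defined path statistics).
    """

    mode: Literal["directed", "undirected"]
    char_path_length: float | None
    diameter: int | None
    finite_pair_count: int
    lengths: dict[str, dict[str, int]] = field(repr=False, hash=False, compare=False, default_factory=dict)


def path_statistics(
    net: SignalingNetwork, mode: Literal["directed", "undirected"] = "directed"
) -> PathStatistics:
    """Breadth-first all-pairs shortest paths.

    ``directed`` follows edge direction; ``undirected`` symmetrizes.
    The mean is over pairs with a finite length only.
    """
    if mode == "directed":
        g: nx.Graph | nx.DiGraph = net.to_digraph()
    elif mode == "undirected":
        g = net.to_undirected_simple()
    else:
        raise ValueError(f"unknown path mode {mode!r}")
    total = 0
    count = 0
    longest = 0
    table: dict[str, dict[str, int]] = {}
    for src, dists in nx.all_pairs_shortest_path_length(g):
        row = {dst: d for dst, d in dists.items() if dst != src}
        table[src] = row
        for d in row.values():
            total += d
            count += 1
            if d > longest:
                longest = d
    if count == 0:
        return PathStatistics(mode, None, None, 0, table)
    return PathStatistics(mode, total / count, longest, count, table)


def closeness_centrality(net: SignalingNetwork, label: str) -> float:
    """Cc(n) = 1/avg(L(n, m)) over the nodes reachable from n.

    Directed outgoing distances; 0 when nothing is reachable.  Always in
    [0, 1] since shortest paths have length ≥ 1.
    """
    if label not in net.nodes:
        raise KeyError(f"unknown label {label!r}")
    dists = nx.single_source_shortest_path_length(net.to_digraph(), label)
    finite = [d for m, d in dists.items() if m != label]
    if not finite:
        return 0.0
    return 1.0 / (sum(finite) / len(finite))


# ---------------------------------------------------------------------------
# hubs, node table, summary


def rank_hubs(
    net: SignalingNetwork,
    *,
    top_n: int | None = None,
    min_links: int | None = None,
) -> list[tuple[str, int]]:
    """Nodes ranked by total degree (number of links), descending.

    Ties break lexicographically by label so the ranking is deterministic.
    Exactly one of ``top_n`` / ``min_links`` selects the cut.
    """
    if (top_n is None) == (min_links is None):
        raise ValueError("specify exactly one of top_n or min_links")
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    if min_links is not None and min_links < 1:
        raise ValueError("min_links must be >= 1")
    deg = dict.fromkeys(net.nodes, 0)
    for s, t, _ in net.edges:
        deg[s] += 1
        deg[t] += 1
    ranked = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        return ranked[:top_n]
    return [(v, k) for v, k in ranked if k >= min_links]


@dataclass(frozen=True)
class NodeStat:
    """Per-node block: degrees, neighbours, clustering, closeness."""

    label: str
    k_in: int
    k_out: int
    k_total: int
    n_neighbors: int
    c: float
    cc: float


def node_statistics(net: SignalingNetwork) -> list[NodeStat]:
    """Per-node statistics, sorted by label."""
    k_in = dict.fromkeys(net.nodes, 0)
    k_out = dict.fromkeys(net.nodes, 0)
    for s, t, _ in net.edges:
        k_out[s] += 1
        k_in[t] += 1
    nbrs = _neighbor_sets(net)
    cs = _all_clustering(net)
    g = net.to_digraph()
    out = []
    for v in net.sorted_nodes():
        dists = nx.single_source_shortest_path_length(g, v)
        finite = [d for m, d in dists.items() if m != v]
        cc = 1.0 / (sum(finite) / len(finite)) if finite else 0.0
        out.append(
            NodeStat(
                label=v,
                k_in=k_in[v],
                k_out=k_out[v],
                k_total=k_in[v] + k_out[v],
                n_neighbors=len(nbrs[v]),
                c=float(cs[v]),
                cc=cc,
            )
        )
    return out


@dataclass(frozen=True)
class TopologySummary:
    """The aggregate parameter block a topological analyzer reports.

    Mirrors the usual table layout (node/edge counts, clustering, diameter,
    averaged neighbour count, characteristic path length, in/out power-law
    fits) plus hub ranking, degree-fraction and sign-fraction extras, and
    the raw degree distributions the classification stage needs.
    """

    name: str
    n_nodes: int
    n_edges: int
    mean_clustering: float
    diameter: int | None
    avg_neighbors: float
    char_path_length: float | None
    in_fit: PowerLawFit | None
    out_fit: PowerLawFit | None
    ck_points: tuple[tuple[int, float], ...]
    ck_fit: PowerLawFit | None
    hub_list: tuple[tuple[str, int], ...]
    frac_k1: float
    frac_k2: float
    frac_activation: float
    frac_inhibition: float
    frac_other: float
    in_dist: DegreeDistribution | None
    out_dist: DegreeDistribution | None
    total_dist: DegreeDistribution | None
    path_mode: str = "directed"


def summarize_topology(
    net: SignalingNetwork,
    *,
    path_mode: Literal["directed", "undirected"] = "directed",
    top_hubs: int = 10,
) -> TopologySummary:
    """Aggregate every topological parameter for one network."""
    n = net.n_nodes
    if n == 0:
        return TopologySummary(
            name=net.name, n_nodes=0, n_edges=0, mean_clustering=0.0,
            diameter=None, avg_neighbors=0.0, char_path_length=None,
            in_fit=None, out_fit=None, ck_points=(), ck_fit=None, hub_list=(),
            frac_k1=0.0, frac_k2=0.0, frac_activation=0.0, frac_inhibition=0.0,
            frac_other=0.0, in_dist=None, out_dist=None, total_dist=None,
            path_mode=path_mode,
        )
    in_dist = degree_distribution(net, "in")
    out_dist = degree_distribution(net, "out")
    total_dist = degree_distribution(net, "total")

    def try_fit(dist: DegreeDistribution) -> PowerLawFit | None:
        try:
            return fit_power_law(dist)
        except PowerLawFitError:
            return None

    paths = path_statistics(net, path_mode)
    ck_points, ck_fit = clustering_vs_degree(net)
    nbrs = _neighbor_sets(net)
    k_total = dict.fromkeys(net.nodes, 0)
    for s, t, _ in net.edges:
        k_total[s] += 1
        k_total[t] += 1
    n_edges = net.n_edges
    n_act = sum(1 for _, _, sign in net.edges if sign == ACTIVATION)
    n_inh = sum(1 for _, _, sign in net.edges if sign == INHIBITION)
    return TopologySummary(
        name=net.name,
        n_nodes=n,
        n_edges=n_edges,
        mean_clustering=mean_clustering(net),
        diameter=paths.diameter,
        avg_neighbors=float(np.mean([len(nbrs[v]) for v in net.nodes])),
        char_path_length=paths.char_path_length,
        in_fit=try_fit(in_dist),
        out_fit=try_fit(out_dist),
        ck_points=ck_points,
        ck_fit=ck_fit,
        hub_list=tuple(rank_hubs(net, top_n=min(top_hubs, n))),
        frac_k1=sum(1 for k in k_total.values() if k == 1) / n,
        frac_k2=sum(1 for k in k_total.values() if k == 2) / n,
        frac_activation=n_act / n_edges if n_edges else 0.0,
        frac_inhibition=n_inh / n_edges if n_edges else 0.0,
        frac_other=(n_edges - n_act - n_inh) / n_edges if n_edges else 0.0,
        in_dist=in_dist,
        out_dist=out_dist,
        total_dist=total_dist,
        path_mode=path_mode,
    )
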