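"""Directed signed signaling networks and their set/edit operations.

A :class:`SignalingNetwork` is a set of molecule/event labels plus a set of
(source, target, sign) triples.  Antiparallel edges are distinct, as are
edges between the same pair with different signs — the schema is
per-interaction and the analysis treats networks as directed throughout.
Self-loops are permitted but excluded from clustering and neighbour counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .records import ACTIVATION, InteractionRecord

__all__ = [
    "SignalingNetwork",
    "build_network",
    "intersect_networks",
    "remove_nodes",
    "weak_components",
]

Edge = tuple[str, str, str]  # (source, target, sign)


@dataclass(frozen=True)
class SignalingNetwork:
    """Directed graph over labels with signed, deduplicated edges."""

    nodes: frozenset[str]
    edges: frozenset[Edge]
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        for s, t, _ in self.edges:
            if s not in self.nodes or t not in self.nodes:
                raise ValueError(f"edge endpoint not in node set: {(s, t)!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    def equals(self, other: "SignalingNetwork") -> bool:
        """Equality on node set and signed edge set (name ignored)."""
        return self.nodes == other.nodes and self.edges == other.edges

    def to_digraph(self) -> nx.DiGraph:
        """Sign-collapsed directed view (parallel signed edges merge)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.sorted_nodes())
        for s, t, sign in self.sorted_edges():
            if g.has_edge(s, t):
                g[s][t]["signs"] = tuple(sorted(set(g[s][t]["signs"]) | {sign}))
            else:
                g.add_edge(s, t, signs=(sign,))
        return g

    def to_undirected_simple(self) -> nx.Graph:
        """Direction-blind simple view without self-loops.

        This is the neighbourhood structure used for clustering and
        neighbour counts: distinct adjacent labels, self excluded.
        """
        g = nx.Graph()
        g.add_nodes_from(self.sorted_nodes())
        g.add_edges_from((s, t) for s, t, _ in self.sorted_edges() if s != t)
        return g


def build_network(
    records: Iterable[InteractionRecord],
    *,
    exclusion: Iterable[str] = (),
    name: str = "",
) -> SignalingNetwork:
    """Build a network from records, deduplicating signed triples.

    ``exclusion`` drops ubiquitous currency species (H2O, CO2, Pi, ...)
    whose edges would otherwise short-circuit every pathway; an excluded
    endpoint removes the whole edge.
    """
    excluded = {e.strip() for e in exclusion}
    nodes: set[str] = set()
    edges: set[Edge] = set()
    for rec in records:
        if rec.source in excluded or rec.target in excluded:
            continue
        nodes.add(rec.source)
        nodes.add(rec.target)
        edges.add((rec.source, rec.target, rec.interaction or ACTIVATION))
    return SignalingNetwork(frozenset(nodes), frozenset(edges), name=name)


def intersect_networks(
    a: SignalingNetwork,
    b: SignalingNetwork,
    *,
    match_sign: bool = True,
    name: str = "",
) -> SignalingNetwork:
    """Common nodes and common edges of two networks.

    By default edges match on the full (source, target, sign) triple;
    ``match_sign=False`` keeps an edge of ``a`` when ``b`` has any edge
    between the same ordered endpoints.
    """
    nodes = a.nodes & b.nodes
    if match_sign:
        edges = a.edges & b.edges
    else:
        b_pairs = {(s, t) for s, t, _ in b.edges}
        edges = frozenset(e for e in a.edges if (e[0], e[1]) in b_pairs)
    return SignalingNetwork(nodes, edges, name=name or f"{a.name}∩{b.name}")


def remove_nodes(net: SignalingNetwork, labels: Iterable[str]) -> SignalingNetwork:
    """New network without ``labels`` and any incident edge.

    Unknown labels raise, so a mistyped hub name cannot silently turn an
    attack experiment into a no-op.
    """
    to_drop = set(labels)
    unknown = to_drop - net.nodes
    if unknown:
        raise KeyError(f"labels not in network: {sorted(unknown)!r}")
    nodes = net.nodes - to_drop
    edges = frozenset(e for e in net.edges if e[0] not in to_drop and e[1] not in to_drop)
    return SignalingNetwork(nodes, edges, name=net.name)


def weak_components(net: SignalingNetwork) -> list[set[str]]:
    """Connected components ignoring edge direction, largest first.

    Isolated nodes are singleton components.  Ties on size are broken by
    the smallest contained label so the order is deterministic.
    """
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((s, t) for s, t, _ in net.edges)
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))
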