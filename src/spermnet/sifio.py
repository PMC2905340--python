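"""SIF and GraphML interop for signed networks.

SIF (Simple Interaction Format) is the tab-delimited viewer format: one
``source<TAB>relation<TAB>target`` line per edge, with isolated nodes as
single-token lines.  The relation token carries the sign verbatim.
GraphML export stores the label as a node attribute and the sign as an
edge attribute so viewers can style activation/inhibition differently.
"""
from __future__ import annotations

import io
from pathlib import Path

import networkx as nx

from .network import SignalingNetwork

__all__ = ["write_sif", "read_sif", "write_graphml", "read_graphml", "SifError"]


class SifError(ValueError):
    pass


def write_sif(net: SignalingNetwork, path: str | Path | io.TextIOBase) -> None:
    """Write a network as SIF; labels must not contain the tab delimiter."""
    for label in net.nodes:
        if "\t" in label:
            raise SifError(f"label contains the SIF delimiter (tab): {label!r}")
    for _, _, sign in net.edges:
        if "\t" in sign:
            raise SifError(f"sign contains the SIF delimiter (tab): {sign!r}")
    connected = {s for s, _, _ in net.edges} | {t for _, t, _ in net.edges}
    lines = [f"{s}\t{sign}\t{t}" for s, t, sign in net.sorted_edges()]
    lines += [label for label in net.sorted_nodes() if label not in connected]
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(path, (str, Path)):
        Path(path).write_text(text, encoding="utf-8")
    else:
        path.write(text)


def read_sif(path: str | Path | io.TextIOBase, *, name: str = "") -> SignalingNetwork:
    """Parse SIF; 1-token lines are isolated nodes, 3-token lines edges."""
    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = path.read()
    nodes: set[str] = set()
    edges: set[tuple[str, str, str]] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        tokens = line.split("\t")
        if len(tokens) == 1:
            nodes.add(tokens[0].strip())
        elif len(tokens) == 3:
            s, sign, t = (tok.strip() for tok in tokens)
            nodes.update((s, t))
            edges.add((s, t, sign))
        else:
            raise SifError(f"line {lineno}: expected 1 or 3 tab-separated tokens, got {len(tokens)}")
    return SignalingNetwork(frozenset(nodes), frozenset(edges), name=name)


def write_graphml(net: SignalingNetwork, path: str | Path) -> None:
    """GraphML export: node attribute ``label``, edge attribute ``sign``.

    Parallel signed edges between the same ordered pair are preserved via a
    multigraph.
    """
    g = nx.MultiDiGraph(name=net.name)
    for label in net.sorted_nodes():
        g.add_node(label, label=label)
    for s, t, sign in net.sorted_edges():
        g.add_edge(s, t, sign=sign)
    nx.write_graphml(g, path)


def read_graphml(path: str | Path, *, name: str = "") -> SignalingNetwork:
    g = nx.read_graphml(path, force_multigraph=True)
    nodes = frozenset(str(d.get("label", n)) for n, d in g.nodes(data=True))
    relabel = {n: str(d.get("label", n)) for n, d in g.nodes(data=True)}
    edges = frozenset(
        (relabel[s], relabel[t], str(d.get("sign", "activation")))
        for s, t, d in g.edges(data=True)
    )
    return SignalingNetwork(nodes, edges, name=name or str(g.name or ""))
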