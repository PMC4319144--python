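"""Shared-tag app graph construction and serialization.

Vertices are apps; an undirected edge joins two apps that share at
least one tag, weighted by the number of shared tags. The graph is the
input to modularity-based clustering: edge weights feed A_ij, weighted
degrees k_i, and the total weight m of the modularity formula.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from pathlib import Path
from typing import Iterable

import networkx as nx

from .tagging import TagAssignment

__all__ = [
    "GraphFormatError",
    "build_graph",
    "total_weight",
    "write_graph",
    "read_graph",
    "write_edgelist",
    "read_edgelist",
]


class GraphFormatError(ValueError):
    """Raised when a graph file cannot be parsed."""


def build_graph(
    assignments: Iterable[TagAssignment],
    *,
    min_shared: int = 1,
    weighted: bool = True,
) -> nx.Graph:
    """Build the app graph from (included) tag assignments.

    Edge weight equals the shared-tag count ``|tags(a) & tags(b)|``;
    pairs sharing fewer than ``min_shared`` tags get no edge. With
    ``weighted=False`` all edge weights collapse to 1 (sensitivity
    mode). Vertices are inserted in sorted app_id order so downstream
    seeded algorithms see a deterministic graph.
    """
    if min_shared < 1:
        raise ValueError(f"min_shared must be >= 1, got {min_shared}")
    assignments = list(assignments)
    ids = [a.app_id for a in assignments]
    if len(ids) != len(set(ids)):
        dupes = sorted(i for i, c in Counter(ids).items() if c > 1)
        raise ValueError(f"duplicate app_id(s): {dupes}")

    graph = nx.Graph()
    graph.add_nodes_from(sorted(ids))

    tag_index: dict[str, list[str]] = {}
    for a in assignments:
        for tag in a.tags:
            tag_index.setdefault(tag, []).append(a.app_id)

    shared: Counter[tuple[str, str]] = Counter()
    for tag in sorted(tag_index):
        for u, v in combinations(sorted(tag_index[tag]), 2):
            shared[(u, v)] += 1

    for (u, v), w in sorted(shared.items()):
        if w >= min_shared:
            graph.add_edge(u, v, weight=w if weighted else 1)
    return graph


def total_weight(graph: nx.Graph) -> float:
    """Total edge weight m of the graph."""
    return graph.size(weight="weight")


def write_graph(graph: nx.Graph, path: str | Path) -> None:
    """Write the graph as GraphML (lossless for vertices, edges, weights)."""
    nx.write_graphml(graph, str(path))


def read_graph(path: str | Path) -> nx.Graph:
    """Read a GraphML app graph; edge weights come back as integers."""
    try:
        graph = nx.read_graphml(str(path), node_type=str)
    except Exception as exc:  # lxml/xml errors carry line positions
        raise GraphFormatError(f"{path}: cannot parse GraphML: {exc}") from exc
    out = nx.Graph()
    out.add_nodes_from(graph.nodes())
    for u, v, data in graph.edges(data=True):
        out.add_edge(u, v, weight=int(data.get("weight", 1)))
    return out


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Optional 3-column TSV edge list (a, b, weight); isolates are lost."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for u, v, w in sorted(graph.edges(data="weight", default=1)):
            fh.write(f"{u}\t{v}\t{w}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 3:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            graph.add_edge(cols[0], cols[1], weight=int(cols[2]))
    return graph
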