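"""Modularity and an in-house Louvain optimizer with an exhaustive oracle.

Modularity of a weighted partition follows the Newman–Girvan
definition

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] * delta(c_i, c_j)

with A_ij the shared-tag edge weights, k_i the weighted degrees and m
the total edge weight. The Louvain optimizer is implemented in-repo —
rather than delegated to a library — so that vertex visiting order,
tie-breaking (equal-gain moves go to the lowest community id) and the
per-pass modularity trace are fully controlled and testable against the
exhaustive small-graph oracle.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "Partition",
    "LouvainTrace",
    "modularity",
    "louvain",
    "exhaustive_best_partition",
    "recovery_score",
    "write_partition",
    "read_partition",
]

#: per-pass convergence tolerance: a pass improving Q by less stops the run
PASS_TOL = 1e-9
#: strict-improvement margin for a single local move (guards float churn)
_MOVE_EPS = 1e-12


def canonicalize(assignment: Mapping[str, int]) -> dict[str, int]:
    """Relabel clusters 0..C-1, ordered by each cluster's smallest member."""
    members: dict[int, list[str]] = defaultdict(list)
    for node, c in assignment.items():
        members[c].append(node)
    ordered = sorted(members.values(), key=min)
    return {node: i for i, group in enumerate(ordered) for node in group}


@dataclass(frozen=True)
class Partition:
    """A hard assignment of every app to one cluster, with its modularity."""

    assignment: Mapping[str, int]
    q: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster_id: int) -> list[str]:
        return sorted(n for n, c in self.assignment.items() if c == cluster_id)

    def sizes(self) -> dict[int, int]:
        return dict(Counter(self.assignment.values()))


@dataclass(frozen=True)
class LouvainTrace:
    """Per-pass modularity values of one Louvain run; Q never decreases."""

    pass_q: tuple[float, ...]
    seed: int

    @property
    def n_passes(self) -> int:
        return len(self.pass_q)


def modularity(graph: nx.Graph, assignment: Mapping[str, int]) -> float:
    """Weighted Newman–Girvan modularity of a partition (pure function)."""
    missing = [n for n in graph.nodes if n not in assignment]
    if missing:
        raise ValueError(f"vertices missing from partition: {sorted(missing)[:5]}")
    m = graph.size(weight="weight")
    if m == 0:
        warnings.warn("modularity of an edgeless graph is defined as 0", stacklevel=2)
        return 0.0
    deg = dict(graph.degree(weight="weight"))
    internal: Counter = Counter()
    tot: Counter = Counter()
    for node in graph.nodes:
        tot[assignment[node]] += deg[node]
    for u, v, w in graph.edges(data="weight", default=1):
        if assignment[u] == assignment[v]:
            internal[assignment[u]] += w
    two_m = 2.0 * m
    return sum(
        internal[c] / m - (tot[c] / two_m) ** 2 for c in tot
    )


# ---------------------------------------------------------------------------
# Louvain internals. Level graphs are plain adjacency dicts in A-matrix
# terms: adj[i][j] = A_ij for i != j, loops[i] = A_ii (an aggregated
# community's internal weight appears as 2*W_in on the diagonal, so that
# k_i = sum_j A_ij and 2m = sum_i k_i stay consistent across levels).
# ---------------------------------------------------------------------------


def _level_q(
    adj: list[dict[int, float]], loops: list[float], comm: list[int]
) -> float:
    """From-scratch modularity of a level graph, used for validation."""
    k = [sum(a.values()) + loops[i] for i, a in enumerate(adj)]
    two_m = sum(k)
    sig_in: Counter = Counter()
    sig_tot: Counter = Counter()
    for i in range(len(adj)):
        sig_tot[comm[i]] += k[i]
        sig_in[comm[i]] += loops[i]
        for j, w in adj[i].items():
            if comm[i] == comm[j]:
                sig_in[comm[i]] += w  # each i!=j ordered pair counted once here
    return sum(sig_in[c] / two_m - (sig_tot[c] / two_m) ** 2 for c in sig_tot)


def _local_moving(
    adj: list[dict[int, float]],
    loops: list[float],
    rng: np.random.Generator,
    validate: bool,
) -> tuple[list[int], float, bool]:
    """Phase 1: greedily move vertices between communities.

    Returns (community labels, Q of the level graph, whether any vertex
    moved). Vertices are visited in a seed-shuffled order; each moves to
    the neighbouring community with the largest strictly positive gain,
    ties broken toward the lowest community id.
    """
    n = len(adj)
    k = [sum(a.values()) + loops[i] for i, a in enumerate(adj)]
    two_m = sum(k)
    comm = list(range(n))
    sig_tot = k[:]  # per community: sum of member degrees
    sig_in = loops[:]  # per community: sum_{i,j in c} A_ij

    def current_q() -> float:
        return sum(
            sig_in[c] / two_m - (sig_tot[c] / two_m) ** 2
            for c in set(comm)
        )

    order = list(range(n))
    rng.shuffle(order)
    moved_any = False
    while True:
        moves = 0
        for i in order:
            ci = comm[i]
            w2c: dict[int, float] = defaultdict(float)
            for j, w in adj[i].items():
                w2c[comm[j]] += w
            # detach i from its community
            sig_tot[ci] -= k[i]
            sig_in[ci] -= 2.0 * w2c.get(ci, 0.0) + loops[i]
            # community-dependent part of the gain of joining c
            def score(c: int) -> float:
                return 2.0 * w2c.get(c, 0.0) / two_m - 2.0 * sig_tot[c] * k[i] / (
                    two_m * two_m
                )

            best_c, best_s = ci, score(ci)
            for c in sorted(w2c):
                if c == ci:
                    continue
                s = score(c)
                if s > best_s + _MOVE_EPS:
                    best_c, best_s = c, s
            comm[i] = best_c
            sig_tot[best_c] += k[i]
            sig_in[best_c] += 2.0 * w2c.get(best_c, 0.0) + loops[i]
            if best_c != ci:
                moves += 1
                moved_any = True
                if validate:
                    inc, scratch = current_q(), _level_q(adj, loops, comm)
                    if abs(inc - scratch) > 1e-9:
                        raise AssertionError(
                            f"incremental Q {inc} drifted from recomputed {scratch}"
                        )
        if moves == 0:
            break
    return comm, current_q(), moved_any


def _aggregate(
    adj: list[dict[int, float]], loops: list[float], comm: list[int]
) -> tuple[list[dict[int, float]], list[float], dict[int, int]]:
    """Phase 2: contract communities into super-vertices with self-loops."""
    remap = {c: i for i, c in enumerate(sorted(set(comm)))}
    n_new = len(remap)
    new_adj: list[dict[int, float]] = [defaultdict(float) for _ in range(n_new)]
    new_loops = [0.0] * n_new
    for i in range(len(adj)):
        ci = remap[comm[i]]
        new_loops[ci] += loops[i]
        for j, w in adj[i].items():
            cj = remap[comm[j]]
            if ci == cj:
                new_loops[ci] += w  # both ordered (i,j) and (j,i) land here -> 2*W_in
            elif i < j:
                new_adj[ci][cj] += w
                new_adj[cj][ci] += w
    return [dict(a) for a in new_adj], new_loops, remap


def louvain(
    graph: nx.Graph,
    seed: int = 0,
    max_passes: int = 100,
    *,
    validate: bool = False,
) -> tuple[Partition, LouvainTrace]:
    """Two-phase Louvain modularity optimization.

    One pass = local moving until no vertex improves Q, then aggregation
    of communities into super-vertices. Passes repeat until a pass
    improves Q by less than ``PASS_TOL``. The returned partition's ``q``
    is recomputed from scratch on the input graph. ``validate=True``
    cross-checks the incremental Q bookkeeping against a from-scratch
    recomputation after every accepted move (slow; for testing).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    if max_passes <= 0:
        raise ValueError(f"max_passes must be positive, got {max_passes}")

    nodes = sorted(graph.nodes)
    if graph.size(weight="weight") == 0:
        assignment = canonicalize({n: i for i, n in enumerate(nodes)})
        return (
            Partition(assignment=assignment, q=0.0),
            LouvainTrace(pass_q=(0.0,), seed=seed),
        )

    idx = {n: i for i, n in enumerate(nodes)}
    adj: list[dict[int, float]] = [dict() for _ in nodes]
    loops = [0.0] * len(nodes)
    for u, v, w in graph.edges(data="weight", default=1):
        if u == v:
            loops[idx[u]] += 2.0 * float(w)
        else:
            adj[idx[u]][idx[v]] = adj[idx[u]].get(idx[v], 0.0) + float(w)
            adj[idx[v]][idx[u]] = adj[idx[v]].get(idx[u], 0.0) + float(w)

    rng = np.random.default_rng(seed)
    node_comm = list(range(len(nodes)))  # original vertex -> current community
    trace: list[float] = []
    prev_q = -1.0
    for _ in range(max_passes):
        comm, q_now, moved = _local_moving(adj, loops, rng, validate)
        adj, loops, remap = _aggregate(adj, loops, comm)
        node_comm = [remap[comm[c]] for c in node_comm]
        trace.append(q_now)
        if not moved or q_now - prev_q < PASS_TOL:
            break
        prev_q = q_now

    assignment = canonicalize({n: node_comm[idx[n]] for n in nodes})
    q_scratch = modularity(graph, assignment)
    return (
        Partition(assignment=assignment, q=q_scratch),
        LouvainTrace(pass_q=tuple(trace), seed=seed),
    )


def _set_partitions(n: int) -> Iterator[list[int]]:
    """All restricted-growth strings of length n, in lexicographic order."""
    rgs = [0] * n
    maxes = [0] * n
    while True:
        yield rgs[:]
        # find rightmost position that can be incremented
        i = n - 1
        while i > 0 and rgs[i] > maxes[i - 1]:
            i -= 1
        if i == 0:
            return
        rgs[i] += 1
        maxes[i] = max(maxes[i - 1], rgs[i])
        for j in range(i + 1, n):
            rgs[j] = 0
            maxes[j] = maxes[i]


def exhaustive_best_partition(graph: nx.Graph) -> Partition:
    """Globally modularity-optimal partition by set-partition enumeration.

    Only feasible for tiny graphs (Bell-number growth); refuses more
    than 10 vertices. Ties are broken toward the lexicographically
    smallest restricted-growth labeling over sorted vertex ids.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("cannot partition an empty graph")
    if n > 10:
        raise ValueError(f"exhaustive search refused for {n} > 10 vertices")
    m = graph.size(weight="weight")
    if m == 0:
        assignment = canonicalize({v: i for i, v in enumerate(nodes)})
        return Partition(assignment=assignment, q=0.0)

    idx = {v: i for i, v in enumerate(nodes)}
    deg = dict(graph.degree(weight="weight"))
    k = [float(deg[v]) for v in nodes]
    edges = [
        (idx[u], idx[v], float(w)) for u, v, w in graph.edges(data="weight", default=1)
    ]
    two_m = 2.0 * m

    best_rgs: list[int] | None = None
    best_q = -np.inf
    for rgs in _set_partitions(n):
        tot = defaultdict(float)
        internal = defaultdict(float)
        for i, ki in enumerate(k):
            tot[rgs[i]] += ki
        for ui, vi, w in edges:
            if rgs[ui] == rgs[vi]:
                internal[rgs[ui]] += w
        q = sum(internal[c] / m - (tot[c] / two_m) ** 2 for c in tot)
        if q > best_q + _MOVE_EPS:  # strict improvement keeps the lex-smallest tie
            best_q, best_rgs = q, rgs
    assert best_rgs is not None
    assignment = canonicalize({v: best_rgs[idx[v]] for v in nodes})
    return Partition(assignment=assignment, q=float(best_q))


def recovery_score(
    partition: Partition | Mapping[str, int], truth: Mapping[str, int]
) -> float:
    """Adjusted Rand index between a partition and planted labels.

    1.0 for identical partitions up to relabeling; ~0 in expectation for
    independent random partitions.
    """
    assignment = partition.assignment if isinstance(partition, Partition) else partition
    if set(assignment) != set(truth):
        raise ValueError("partition and ground truth cover different vertex sets")
    keys = sorted(assignment)
    return float(
        adjusted_rand_score([truth[k] for k in keys], [assignment[k] for k in keys])
    )


def write_partition(
    partition: Partition,
    path: str | Path,
    *,
    seed: int | None = None,
    trace: LouvainTrace | None = None,
) -> None:
    """Write cluster CSV (app_id, cluster_id) plus a JSON metadata sidecar."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("app_id,cluster_id\n")
        for app_id in sorted(partition.assignment):
            fh.write(f"{app_id},{partition.assignment[app_id]}\n")
    meta = {
        "q": partition.q,
        "n_clusters": partition.n_clusters,
        "seed": seed if seed is not None else (trace.seed if trace else None),
        "passes": trace.n_passes if trace else None,
        "pass_q": list(trace.pass_q) if trace else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_partition(path: str | Path) -> dict[str, int]:
    assignment: dict[str, int] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "app_id,cluster_id":
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            app_id, cluster_id = line.rstrip("\n").split(",")
            assignment[app_id] = int(cluster_id)
    return assignment
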