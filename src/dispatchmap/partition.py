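"""Balanced partitioning of target sequences.

Targets are distributed over P partitions with a best-fit-decreasing greedy
(multiway number partitioning: heaviest item first into the currently
least-loaded partition). When an assembly adjacency graph is supplied, its
connected components are the atomic items, so graph-linked contigs always
land in the same partition and cross-contig alignments stay local to one
index.
"""

from __future__ import annotations

import csv
import heapq
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from dispatchmap.io_formats import TargetSeq, write_fasta

log = logging.getLogger(__name__)


class MalformedGraphError(ValueError):
    pass


@dataclass
class AdjacencyGraph:
    """Undirected contig-adjacency graph; self-loops are ignored."""

    nodes: set[str] = field(default_factory=set)
    edges: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        cleaned = set()
        for e in self.edges:
            pair = frozenset(e)
            if len(pair) == 1:  # self-loop
                continue
            u, v = pair
            if u not in self.nodes or v not in self.nodes:
                raise MalformedGraphError(f"edge ({u},{v}) references unknown node")
            cleaned.add(pair)
        self.edges = cleaned

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "AdjacencyGraph":
        """Load a two-column TSV edge list; '#' lines are comments. Every ID
        appearing in the file becomes a node."""
        nodes: set[str] = set()
        edges: set[frozenset[str]] = set()
        with open(path, encoding="ascii") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise MalformedGraphError(
                        f"{path}:{lineno}: expected 2 tab-separated IDs, got {len(parts)}"
                    )
                u, v = parts
                nodes.update((u, v))
                if u != v:
                    edges.add(frozenset((u, v)))
        return cls(nodes=nodes, edges=edges)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="ascii") as fh:
            fh.write("# adjacency edge list: targetA<TAB>targetB\n")
            for e in sorted(tuple(sorted(x)) for x in self.edges):
                fh.write(f"{e[0]}\t{e[1]}\n")
            # isolated nodes are implicit (any target absent from the graph
            # is a singleton component), so only edges are written


@dataclass
class PartitionPlan:
    """Assignment of every target ID to exactly one of P partitions."""

    P: int
    assignment: dict[str, int]
    loads: list[int]

    def members(self, p: int) -> list[str]:
        return [t for t, q in self.assignment.items() if q == p]

    def makespan(self) -> int:
        return max(self.loads) if self.loads else 0


def best_fit_decreasing(items: Sequence[tuple[str, int]], P: int) -> PartitionPlan:
    """Greedy multiway partitioning: items in decreasing weight order (ties by
    ascending ID), each into the least-loaded partition (ties by lowest index).
    """
    if P < 1:
        raise ValueError(f"partition count must be >= 1, got {P}")
    ids = [i for i, _ in items]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate item IDs")
    for i, w in items:
        if w < 1:
            raise ValueError(f"item {i!r}: weight must be >= 1, got {w}")
    order = sorted(items, key=lambda iw: (-iw[1], iw[0]))
    heap = [(0, p) for p in range(P)]  # already heapified: (load, index)
    assignment: dict[str, int] = {}
    loads = [0] * P
    for item_id, w in order:
        load, p = heapq.heappop(heap)
        assignment[item_id] = p
        loads[p] = load + w
        heapq.heappush(heap, (load + w, p))
    return PartitionPlan(P=P, assignment=assignment, loads=loads)


def connected_components(g: AdjacencyGraph) -> list[set[str]]:
    """Maximal connected sets of the graph, sorted by smallest member ID."""
    nxg = nx.Graph()
    nxg.add_nodes_from(g.nodes)
    nxg.add_edges_from(tuple(e) for e in g.edges)
    comps = [set(c) for c in nx.connected_components(nxg)]
    return sorted(comps, key=min)


def plan_partitions(
    targets: Sequence[TargetSeq],
    P: int,
    graph: Optional[AdjacencyGraph] = None,
) -> PartitionPlan:
    """Partition targets into P balanced sets.

    Without a graph each target is an item; with a graph the items are
    connected components weighted by summed member length, and every member
    of a component receives the same partition index. Graph nodes missing
    from the target set are an error; targets missing from the graph are
    singleton components.
    """
    lengths = {t.id: t.length for t in targets}
    if len(lengths) != len(targets):
        raise ValueError("duplicate target IDs")
    if graph is None:
        return best_fit_decreasing([(t.id, t.length) for t in targets], P)

    unknown = graph.nodes - lengths.keys()
    if unknown:
        raise MalformedGraphError(
            f"graph nodes absent from target set: {sorted(unknown)[:5]}"
        )
    full = AdjacencyGraph(nodes=set(lengths), edges=set(graph.edges))
    comps = connected_components(full)
    items = [(min(c), sum(lengths[t] for t in c)) for c in comps]
    if P > len(items):
        log.warning(
            "P=%d exceeds the %d atomic items; some partitions will be empty",
            P, len(items),
        )
    comp_plan = best_fit_decreasing(items, P)
    assignment = {
        t: comp_plan.assignment[min(c)] for c in comps for t in c
    }
    loads = [0] * P
    for t, p in assignment.items():
        loads[p] += lengths[t]
    return PartitionPlan(P=P, assignment=assignment, loads=loads)


def write_partition_fastas(
    targets: Sequence[TargetSeq],
    plan: PartitionPlan,
    outdir: str | os.PathLike,
) -> list[str]:
    """Write part_<p>.fa (assigned targets in original input order) and the
    partitions.tsv manifest; returns the FASTA paths."""
    missing = {t.id for t in targets} - plan.assignment.keys()
    if missing:
        raise ValueError(f"plan does not cover targets: {sorted(missing)[:5]}")
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for p in range(plan.P):
        path = os.path.join(outdir, f"part_{p}.fa")
        write_fasta((t for t in targets if plan.assignment[t.id] == p), path)
        paths.append(path)
    with open(os.path.join(outdir, "partitions.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["target_id", "partition", "length"])
        for t in targets:
            w.writerow([t.id, plan.assignment[t.id], t.length])
    return paths


def read_manifest(path: str | os.PathLike) -> tuple[PartitionPlan, list[tuple[str, int]]]:
    """Reload partitions.tsv; returns the plan and (target_id, length) rows
    in original target order."""
    assignment: dict[str, int] = {}
    rows: list[tuple[str, int]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            assignment[row["target_id"]] = int(row["partition"])
            rows.append((row["target_id"], int(row["length"])))
    P = max(assignment.values()) + 1 if assignment else 1
    loads = [0] * P
    for tid, ln in rows:
        loads[assignment[tid]] += ln
    return PartitionPlan(P=P, assignment=assignment, loads=loads), rows
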