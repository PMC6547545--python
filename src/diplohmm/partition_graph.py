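"""Directed compatibility graph over column-wise read bipartitions.

A bipartition splits a set of reads into two ordered parts, one per
haplotype.  For each column j the graph holds one vertex per bipartition of
the active rows A_j (the B_j layer) and one per bipartition of the active
non-terminal rows A'_j (the C_j layer), plus start and end vertices.  Edges
connect compatible bipartitions of adjacent layers.  Every start-to-end path
corresponds to exactly one bipartition of all m reads (a "diploid path
bipartition"), and there are exactly 2^m such paths.

This module is intentionally exhaustive: it is the correctness oracle for
the dynamic programs in :mod:`diplohmm.hmm` and :mod:`diplohmm.pruning`,
and is only meant for small instances (coverage below an enumeration cap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .matrix import AlignmentMatrix


@dataclass(frozen=True)
class Bipartition:
    """Ordered two-part split (part1, part2) of a set of row indices."""

    part1: tuple[int, ...]
    part2: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "part1", tuple(sorted(self.part1)))
        object.__setattr__(self, "part2", tuple(sorted(self.part2)))
        if set(self.part1) & set(self.part2):
            raise ValueError("parts must be disjoint")

    @property
    def support(self) -> frozenset[int]:
        return frozenset(self.part1) | frozenset(self.part2)

    def canonical(self) -> "Bipartition":
        """Fix the labeling symmetry: the part holding the lowest row is part1."""
        if self.part2 and (not self.part1 or self.part2[0] < self.part1[0]):
            return Bipartition(self.part2, self.part1)
        return self

    def restrict(self, rows: frozenset[int]) -> "Bipartition":
        return Bipartition(
            tuple(r for r in self.part1 if r in rows),
            tuple(r for r in self.part2 if r in rows),
        )

    def label(self) -> str:
        """Human-readable label in the ``"1,2 /."`` style."""
        p1 = ",".join(str(r + 1) for r in self.part1) or "."
        p2 = ",".join(str(r + 1) for r in self.part2) or "."
        return f"{p1} / {p2}"


def is_compatible(b: Bipartition, c: Bipartition) -> bool:
    """True iff b and c agree on the placement of every shared row.

    Symmetric and reflexive, but not transitive.
    """
    shared = b.support & c.support
    return (
        set(b.part1) & shared <= set(c.part1)
        and set(b.part2) & shared <= set(c.part2)
    )


def _all_bipartitions(rows: frozenset[int]) -> list[Bipartition]:
    rows_sorted = sorted(rows)
    k = len(rows_sorted)
    out = []
    for mask in range(1 << k):
        p1 = tuple(rows_sorted[i] for i in range(k) if not (mask >> i) & 1)
        p2 = tuple(rows_sorted[i] for i in range(k) if (mask >> i) & 1)
        out.append(Bipartition(p1, p2))
    return out


# vertex keys: ("start",), ("end",), ("B", j, idx), ("C", j, idx)
VertexKey = tuple


class PartitionGraph:
    """Compatibility graph G for a small alignment matrix."""

    def __init__(self, matrix: AlignmentMatrix, enumeration_cap: int = 12) -> None:
        if matrix.max_coverage() > enumeration_cap:
            raise ValueError(
                f"maximum coverage {matrix.max_coverage()} exceeds the exact "
                f"enumeration cap {enumeration_cap}; use "
                "diplohmm.pruning.compute_pruned_hmm for high-coverage data"
            )
        self.matrix = matrix
        self.max_cov = matrix.max_coverage()
        n = matrix.n
        self.b_cols: list[list[Bipartition]] = [
            _all_bipartitions(matrix.active_rows(j)) for j in range(n)
        ]
        self.c_cols: list[list[Bipartition]] = [
            _all_bipartitions(matrix.active_nonterminal_rows(j))
            for j in range(n - 1)
        ]
        self.edges: list[tuple[VertexKey, VertexKey]] = []
        for idx, _ in enumerate(self.b_cols[0]):
            self.edges.append((("start",), ("B", 0, idx)))
        for j in range(n - 1):
            for bi, b in enumerate(self.b_cols[j]):
                for ci, c in enumerate(self.c_cols[j]):
                    if is_compatible(b, c):
                        self.edges.append((("B", j, bi), ("C", j, ci)))
            for ci, c in enumerate(self.c_cols[j]):
                for bi, b in enumerate(self.b_cols[j + 1]):
                    if is_compatible(c, b):
                        self.edges.append((("C", j, ci), ("B", j + 1, bi)))
        for idx, _ in enumerate(self.b_cols[n - 1]):
            self.edges.append((("B", n - 1, idx), ("end",)))
        self._out: dict[VertexKey, list[VertexKey]] = {}
        self._in: dict[VertexKey, list[VertexKey]] = {}
        for u, v in self.edges:
            self._out.setdefault(u, []).append(v)
            self._in.setdefault(v, []).append(u)

    @property
    def num_vertices(self) -> int:
        return (
            2
            + sum(len(c) for c in self.b_cols)
            + sum(len(c) for c in self.c_cols)
        )

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def vertex(self, key: VertexKey) -> Bipartition:
        kind, j, idx = key
        return (self.b_cols if kind == "B" else self.c_cols)[j][idx]

    def out_degree(self, key: VertexKey) -> int:
        return len(self._out.get(key, []))

    def in_degree(self, key: VertexKey) -> int:
        return len(self._in.get(key, []))

    def diploid_paths(self) -> Iterator[list[VertexKey]]:
        """Depth-first enumeration of all start-to-end paths."""
        stack: list[list[VertexKey]] = [[("start",)]]
        while stack:
            path = stack.pop()
            if path[-1] == ("end",):
                yield path
                continue
            for nxt in self._out.get(path[-1], []):
                stack.append(path + [nxt])

    def to_dot(self) -> str:
        """DOT dump for debugging/documentation."""
        lines = ["digraph G {"]
        names = {("start",): "start", ("end",): "end"}
        for kind, cols in (("B", self.b_cols), ("C", self.c_cols)):
            for j, col in enumerate(cols):
                for idx, b in enumerate(col):
                    key = (kind, j, idx)
                    names[key] = f"{kind}{j}_{idx}"
                    lines.append(f'  {names[key]} [label="{b.label()}"];')
        for u, v in self.edges:
            lines.append(f"  {names[u]} -> {names[v]};")
        lines.append("}")
        return "\n".join(lines)


def build_graph(matrix: AlignmentMatrix, enumeration_cap: int = 12) -> PartitionGraph:
    return PartitionGraph(matrix, enumeration_cap)


def path_bipartition(graph: PartitionGraph, path: list[VertexKey]) -> Bipartition:
    """The diploid path bipartition B_D: part-wise union along the path."""
    p1: set[int] = set()
    p2: set[int] = set()
    for key in path:
        if key in (("start",), ("end",)):
            continue
        b = graph.vertex(key)
        p1.update(b.part1)
        p2.update(b.part2)
    return Bipartition(tuple(p1), tuple(p2))


def enumerate_diploid_paths(graph: PartitionGraph) -> list[Bipartition]:
    """All diploid path bipartitions; exactly 2^m of them, all distinct."""
    return [path_bipartition(graph, p) for p in graph.diploid_paths()]
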