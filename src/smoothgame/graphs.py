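"""Population structures for the evolutionary simulations.

The same graph serves as interaction and updating structure: two individuals
can play the game, or compare payoffs during strategy updating, only if they
are adjacent. Supported kinds:

* ``complete`` — a randomly-interacting (well-mixed) population;
* ``random_regular`` — random regular graph (default degree 10);
* ``scale_free`` — preferential attachment with 5 edges per arriving vertex
  (mean degree close to 10);
* ``lattice4`` / ``lattice8`` — two-dimensional square lattices with von
  Neumann (4) or Moore (8) neighborhoods and periodic boundary conditions.

Graph construction is delegated to networkx; the result is frozen into a
:class:`PopulationGraph`, a plain adjacency structure optimized for uniform
neighbor sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable

import networkx as nx
import numpy as np

__all__ = [
    "GraphSpec",
    "PopulationGraph",
    "build_graph",
    "neighbors",
    "write_edge_list",
    "read_edge_list",
]

KINDS = ("complete", "random_regular", "scale_free", "lattice4", "lattice8")


@dataclass(frozen=True)
class GraphSpec:
    """Recipe for a population graph.

    ``degree`` is the regular degree for ``random_regular`` and the
    per-arrival attachment count for ``scale_free``; it is ignored for the
    other kinds. Lattice kinds require ``n`` to be a perfect square with side
    at least 3 (smaller tori fold diagonal neighbors onto each other).
    """

    kind: str
    n: int
    degree: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown graph kind {self.kind!r}; choose from {KINDS}")
        if self.n < 2:
            raise ValueError("population graph needs at least 2 vertices")
        if self.kind in ("lattice4", "lattice8"):
            side = math.isqrt(self.n)
            if side * side != self.n or side < 3:
                raise ValueError(
                    f"{self.kind} requires a perfect-square n with side >= 3, got {self.n}"
                )
        if self.kind == "random_regular":
            if self.degree >= self.n or (self.n * self.degree) % 2 != 0:
                raise ValueError(
                    "random_regular needs degree < n and n*degree even"
                )
        if self.kind == "scale_free" and self.degree >= self.n:
            raise ValueError("scale_free attachment count must be < n")


class PopulationGraph:
    """Frozen simple undirected graph with per-vertex neighbor arrays."""

    def __init__(self, edges: Iterable[tuple[int, int]], n: int, kind: str = "custom"):
        adj: list[set[int]] = [set() for _ in range(n)]
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u}, {v}) outside vertex range 0..{n - 1}")
            adj[u].add(v)
            adj[v].add(u)
        self.n = n
        self.kind = kind
        self._adj = [np.array(sorted(s), dtype=np.int64) for s in adj]
        self.degrees = np.array([len(a) for a in self._adj], dtype=np.int64)

    @property
    def edge_count(self) -> int:
        return int(self.degrees.sum()) // 2

    def edges(self) -> list[tuple[int, int]]:
        """Each undirected edge once, as (u, v) with u < v, sorted."""
        return [(u, int(v)) for u in range(self.n) for v in self._adj[u] if u < v]

    def neighbor_arrays(self) -> list[np.ndarray]:
        return self._adj

    def padded_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """(n, max_degree) neighbor matrix padded with -1, plus degree vector."""
        m = int(self.degrees.max())
        mat = np.full((self.n, m), -1, dtype=np.int64)
        for i, a in enumerate(self._adj):
            mat[i, : len(a)] = a
        return mat, self.degrees

    def is_connected(self) -> bool:
        if self.n == 0:
            return False
        seen = np.zeros(self.n, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            u = stack.pop()
            for v in self._adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        return bool(seen.all())


def neighbors(graph: PopulationGraph, i: int) -> set[int]:
    """The adjacency set of vertex ``i`` (never contains ``i``)."""
    if not 0 <= i < graph.n:
        raise IndexError(f"vertex {i} outside 0..{graph.n - 1}")
    return set(int(v) for v in graph._adj[i])


def _lattice_edges(n: int, moore: bool) -> list[tuple[int, int]]:
    side = math.isqrt(n)
    offsets = [(0, 1), (1, 0)]
    if moore:
        offsets += [(1, 1), (1, -1)]
    edges = []
    for r in range(side):
        for c in range(side):
            u = r * side + c
            for dr, dc in offsets:
                v = ((r + dr) % side) * side + (c + dc) % side
                edges.append((u, v))
    return edges


def build_graph(spec: GraphSpec, *, max_retries: int = 100) -> PopulationGraph:
    """Build the population graph; deterministic given the spec's seed.

    Random kinds are resampled with an incremented sub-seed until simple and
    connected (a disconnected component would never equilibrate with the
    rest of the population).
    """
    if spec.kind == "complete":
        g = nx.complete_graph(spec.n)
    elif spec.kind == "lattice4":
        return PopulationGraph(_lattice_edges(spec.n, moore=False), spec.n, spec.kind)
    elif spec.kind == "lattice8":
        return PopulationGraph(_lattice_edges(spec.n, moore=True), spec.n, spec.kind)
    else:
        g = None
        for attempt in range(max_retries):
            s = spec.seed + attempt
            if spec.kind == "random_regular":
                cand = nx.random_regular_graph(spec.degree, spec.n, seed=s)
            else:  # scale_free
                cand = nx.barabasi_albert_graph(spec.n, spec.degree, seed=s)
            if nx.is_connected(cand):
                g = cand
                break
        if g is None:
            raise RuntimeError(
                f"could not generate a connected {spec.kind} graph in {max_retries} tries"
            )
    return PopulationGraph(g.edges(), spec.n, spec.kind)


def write_edge_list(graph: PopulationGraph, sink: IO[str] | str) -> None:
    """Write one undirected edge per line as two 0-based vertex indices."""
    lines = "".join(f"{u} {v}\n" for u, v in graph.edges())
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            fh.write(lines)
    else:
        sink.write(lines)


def read_edge_list(source: IO[str] | str, kind: str = "custom") -> PopulationGraph:
    """Parse a whitespace-separated edge list; strict about malformed input.

    Rejects self-loops and duplicate edges, naming the offending line.
    The vertex count is 1 + the largest index seen.
    """
    if isinstance(source, str):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()

    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {ln}: expected two vertex indices, got {raw!r}")
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"line {ln}: non-integer vertex index in {raw!r}") from exc
        if u < 0 or v < 0:
            raise ValueError(f"line {ln}: negative vertex index in {raw!r}")
        if u == v:
            raise ValueError(f"line {ln}: self-loop {u} {v}")
        key = (min(u, v), max(u, v))
        if key in seen:
            raise ValueError(f"line {ln}: duplicate edge {u} {v}")
        seen.add(key)
        edges.append((u, v))
    if not edges:
        raise ValueError("edge list is empty")
    n = 1 + max(max(u, v) for u, v in edges)
    return PopulationGraph(edges, n, kind)
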