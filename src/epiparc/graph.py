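"""Cortical surface stand-ins: small vertex graphs with hemisphere labels.

Real analyses run on high-resolution surface meshes (tens of thousands of
vertices per hemisphere).  Everything downstream is graph-generic, so a
ring or grid per hemisphere is a faithful desk-scale substrate: it has the
two properties the algorithms rely on (a neighborhood structure for the
spatial smoothness prior and a hemisphere split for laterality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HEMI_L = 0
HEMI_R = 1


@dataclass
class CorticalGraph:
    """Vertex graph with hemisphere labels and an analyzable-cortex mask.

    Edges are undirected, stored once per pair with u < v.  No edge joins
    the two hemispheres.  Vertices with ``cortex_mask == False`` (medial
    wall in real data) carry no network label anywhere downstream.
    """

    n_vertices: int
    edges: np.ndarray          # (E, 2) int, u < v
    hemisphere: np.ndarray     # (V,) int, HEMI_L or HEMI_R
    cortex_mask: np.ndarray    # (V,) bool

    _adjacency: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.hemisphere = np.asarray(self.hemisphere, dtype=np.int64)
        self.cortex_mask = np.asarray(self.cortex_mask, dtype=bool)
        if self.hemisphere.shape != (self.n_vertices,):
            raise ValueError("hemisphere map does not cover the vertex set")
        if self.cortex_mask.shape != (self.n_vertices,):
            raise ValueError("cortex mask does not cover the vertex set")
        if self.edges.size:
            u, v = self.edges[:, 0], self.edges[:, 1]
            if np.any(u == v):
                raise ValueError("self-loop in edge set")
            if np.any(self.hemisphere[u] != self.hemisphere[v]):
                raise ValueError("edge joins the two hemispheres")
        for h in (HEMI_L, HEMI_R):
            if not np.any(self.hemisphere == h):
                raise ValueError("both hemispheres must be non-empty")

    @property
    def adjacency(self) -> list:
        """Neighbor lists (list of int arrays), built lazily."""
        if self._adjacency is None:
            adj: list[list[int]] = [[] for _ in range(self.n_vertices)]
            for u, v in self.edges:
                adj[u].append(int(v))
                adj[v].append(int(u))
            self._adjacency = [np.array(a, dtype=np.int64) for a in adj]
        return self._adjacency

    def neighbors(self, v: int) -> np.ndarray:
        return self.adjacency[v]

    def hemisphere_vertices(self, hemi: int) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)


def _ring_edges(offset: int, n: int) -> list[tuple[int, int]]:
    return [(offset + i, offset + (i + 1) % n) for i in range(n)]


def _grid_edges(offset: int, n: int) -> list[tuple[int, int]]:
    # factor n into the most square rows x cols grid
    rows = int(np.sqrt(n))
    while n % rows:
        rows -= 1
    cols = n // rows
    edges = []
    for r in range(rows):
        for c in range(cols):
            v = offset + r * cols + c
            if c + 1 < cols:
                edges.append((v, v + 1))
            if r + 1 < rows:
                edges.append((v, v + cols))
    return edges


def build_cortical_graph(
    n_per_hemisphere: int,
    topology: str = "ring",
    masked_vertices: list[int] | None = None,
) -> CorticalGraph:
    """Build a two-hemisphere vertex graph (``ring`` or ``grid`` per side).

    Vertices 0..n-1 are left hemisphere, n..2n-1 right. Deterministic for
    fixed inputs.
    """
    if n_per_hemisphere < 4:
        raise ValueError("n_per_hemisphere must be >= 4")
    if topology == "ring":
        maker = _ring_edges
    elif topology == "grid":
        maker = _grid_edges
    else:
        raise ValueError(f"unknown topology: {topology!r}")
    n = n_per_hemisphere
    edges = maker(0, n) + maker(n, n)
    edges = np.array([(min(u, v), max(u, v)) for u, v in edges], dtype=np.int64)
    hemi = np.repeat([HEMI_L, HEMI_R], n)
    mask = np.ones(2 * n, dtype=bool)
    if masked_vertices is not None:
        mask[np.asarray(masked_vertices, dtype=int)] = False
    return CorticalGraph(2 * n, edges, hemi, mask)


def connected_components_of(graph: CorticalGraph, vertex_set: np.ndarray) -> int:
    """Number of connected components of the subgraph induced by vertex_set."""
    vs = set(int(v) for v in np.atleast_1d(vertex_set))
    seen: set[int] = set()
    ncomp = 0
    for start in sorted(vs):
        if start in seen:
            continue
        ncomp += 1
        stack = [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            for w in graph.neighbors(u):
                w = int(w)
                if w in vs and w not in seen:
                    seen.add(w)
                    stack.append(w)
    return ncomp
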