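"""County contiguity graphs and the intrinsic CAR (ICAR) precision structure.

The ICAR prior says each area's spatial effect, given its neighbors, is
normal with mean equal to the neighbor average and variance sigma_w^2 / n_i
where n_i is the neighbor count. Its joint (improper) precision matrix is
Q = D - A: degree matrix minus binary adjacency. Q is positive semidefinite
with rank n - c on a graph with c connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import IntegrityError, PolygonSet

__all__ = [
    "SpatialGraph",
    "PrecisionMatrix",
    "build_queen_adjacency",
    "graph_from_edgelist",
    "connected_components",
    "icar_precision",
    "read_edgelist",
    "write_edgelist",
]


@dataclass(frozen=True)
class SpatialGraph:
    """Symmetric neighbor structure over n areas (no self-loops)."""

    n: int
    neighbors: tuple[tuple[int, ...], ...]  # sorted neighbor indices per area
    component_labels: np.ndarray  # component id per area (isolated areas get their own)

    @property
    def degree(self) -> np.ndarray:
        return np.array([len(d) for d in self.neighbors], dtype=int)

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n else 0

    @property
    def edges(self) -> np.ndarray:
        """Each undirected edge once, as an (E, 2) array with i < j."""
        out = [(i, j) for i, nbrs in enumerate(self.neighbors) for j in nbrs if i < j]
        return np.array(out, dtype=int).reshape(-1, 2)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n, self.n))
        e = self.edges
        A[e[:, 0], e[:, 1]] = 1.0
        A[e[:, 1], e[:, 0]] = 1.0
        return A


@dataclass(frozen=True)
class PrecisionMatrix:
    """ICAR structure matrix Q = D - A with its rank deficiency (= #components)."""

    Q: np.ndarray
    rank_deficiency: int


def _finalize(n: int, edge_set: set[tuple[int, int]]) -> SpatialGraph:
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for i, j in edge_set:
        nbrs[i].add(j)
        nbrs[j].add(i)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edge_set)
    labels = np.empty(n, dtype=int)
    for cid, comp in enumerate(nx.connected_components(g)):
        labels[list(comp)] = cid
    return SpatialGraph(n, tuple(tuple(sorted(s)) for s in nbrs), labels)


def build_queen_adjacency(polygons: PolygonSet, rule: str = "queen") -> SpatialGraph:
    """Contiguity graph from polygons: queen = any shared point, rook = shared border.

    Geometries are used as supplied (contiguity is projection-invariant for
    valid polygons). Raises if no two areas touch, since an edgeless graph
    carries no spatial information — supply an explicit edge list instead.
    """
    if rule not in ("queen", "rook"):
        raise ValueError("rule must be 'queen' or 'rook'")
    n = len(polygons)
    if n < 2:
        raise ValueError("need at least 2 areas to build adjacency")
    geoms = polygons.geometry
    edge_set: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if not geoms[i].intersects(geoms[j]):
                continue
            if rule == "queen":
                edge_set.add((i, j))
            else:
                inter = geoms[i].intersection(geoms[j])
                if inter.length > 0:  # shared segment, not just a corner point
                    edge_set.add((i, j))
    if not edge_set:
        raise ValueError(
            "no two areas are contiguous; supply an explicit edge-list adjacency instead"
        )
    return _finalize(n, edge_set)


def graph_from_edgelist(n: int, edges) -> SpatialGraph:
    """Symmetrize and deduplicate an index-pair edge list into a SpatialGraph."""
    edge_set: set[tuple[int, int]] = set()
    for i, j in edges:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"self-loop ({i},{i}) not allowed")
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i},{j}) out of range for n={n}")
        edge_set.add((min(i, j), max(i, j)))
    return _finalize(n, edge_set)


def connected_components(graph: SpatialGraph) -> np.ndarray:
    """Component labels 0..c-1; areas share a label iff a path connects them."""
    return graph.component_labels.copy()


def icar_precision(graph: SpatialGraph) -> PrecisionMatrix:
    """Q = D - A; every row sums to zero; rank deficiency equals #components."""
    if graph.n_edges == 0:
        raise ValueError("graph has no edges; ICAR structure undefined")
    Q = np.diag(graph.degree.astype(float)) - graph.adjacency()
    return PrecisionMatrix(Q, graph.n_components)


def read_edgelist(path, area_ids: list[str]) -> SpatialGraph:
    """Read a tab-separated id-pair file ('#' comments) into a graph over area_ids."""
    index = {aid: i for i, aid in enumerate(area_ids)}
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'id_i<TAB>id_j', got {line!r}")
            a, b = parts
            if a not in index or b not in index:
                unknown = [x for x in (a, b) if x not in index]
                raise IntegrityError(f"line {lineno}: unknown area id(s) {unknown}")
            edges.append((index[a], index[b]))
    return graph_from_edgelist(len(area_ids), edges)


def write_edgelist(graph: SpatialGraph, area_ids: list[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# adjacency edge list: id_i<TAB>id_j, one undirected edge per line\n")
        for i, j in graph.edges:
            fh.write(f"{area_ids[i]}\t{area_ids[j]}\n")
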