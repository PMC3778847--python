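"""Tract adjacency graphs and the intrinsic CAR (ICAR) structure.

The spatial random effect of the ecological model lives on a symmetric
neighbourhood graph over census tracts: two tracts are neighbours when they
share a border.  This module holds the graph container, readers/writers for
GAL-style neighbour lists, contiguity from polygon geometries, and the ICAR
structure matrix ``Q = D - W`` whose quadratic form penalises differences
between neighbouring effects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "AdjacencyGraph",
    "ICARStructure",
    "make_lattice",
    "read_adjacency",
    "write_adjacency",
    "adjacency_from_polygons",
    "icar_structure",
]


class GraphError(ValueError):
    """Invalid adjacency input (parse failure, unknown ids, bad geometry)."""


@dataclass
class AdjacencyGraph:
    """Symmetric tract neighbourhood structure.

    Parameters
    ----------
    tract_ids : list
        Ordered tract identifiers; all per-tract tables downstream follow
        this ordering.
    neighbors : list of set of int
        ``neighbors[i]`` holds positional indices of the tracts adjacent to
        tract ``i``.  Symmetric, no self-loops.
    """

    tract_ids: list
    neighbors: list[set[int]] = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.tract_ids)
        if len(self.neighbors) != n:
            raise GraphError("neighbors length does not match tract_ids")
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise GraphError(f"self-loop at tract {self.tract_ids[i]}")
            for j in nb:
                if not (0 <= j < n):
                    raise GraphError(f"neighbor index {j} out of range")
                if i not in self.neighbors[j]:
                    raise GraphError(
                        f"asymmetric adjacency between {self.tract_ids[i]} "
                        f"and {self.tract_ids[j]}"
                    )

    @property
    def n(self) -> int:
        return len(self.tract_ids)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.neighbors) // 2

    def degree(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=float)

    def edges(self) -> list[tuple[int, int]]:
        """Unordered neighbour pairs as (i, j) with i < j."""
        return [(i, j) for i, nb in enumerate(self.neighbors) for j in nb if i < j]

    def isolated(self) -> list[int]:
        return [i for i, nb in enumerate(self.neighbors) if not nb]

    def components(self) -> list[np.ndarray]:
        """Connected components as arrays of positional indices."""
        g = self.to_networkx()
        return [np.array(sorted(c)) for c in nx.connected_components(g)]

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Binary 0/1 adjacency W as sparse CSR."""
        rows, cols = [], []
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                rows.append(i)
                cols.append(j)
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, tract_ids=None) -> "AdjacencyGraph":
        nodes = list(g.nodes)
        index = {v: i for i, v in enumerate(nodes)}
        neighbors = [set(index[u] for u in g.neighbors(v)) for v in nodes]
        if tract_ids is None:
            tract_ids = [str(v) for v in nodes]
        return cls(list(tract_ids), neighbors)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AdjacencyGraph):
            return NotImplemented
        return (
            list(map(str, self.tract_ids)) == list(map(str, other.tract_ids))
            and self.neighbors == other.neighbors
        )


def make_lattice(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-adjacency rectangular lattice of ``rows x cols`` tracts.

    Tract ids are ``"r{i}c{j}"`` in row-major order.  Corner cells have two
    neighbours, edge cells three, interior cells four; the graph is
    connected with ``rows*(cols-1) + cols*(rows-1)`` edges.
    """
    if rows < 2 or cols < 2:
        raise GraphError("lattice needs rows >= 2 and cols >= 2")
    g = nx.grid_2d_graph(rows, cols)
    nodes = sorted(g.nodes)  # row-major
    ids = [f"r{i}c{j}" for i, j in nodes]
    index = {v: k for k, v in enumerate(nodes)}
    neighbors = [set(index[u] for u in g.neighbors(v)) for v in nodes]
    return AdjacencyGraph(ids, neighbors)


def write_adjacency(graph: AdjacencyGraph, path) -> None:
    """Write a GAL-style neighbour list: header ``n``; per tract one line
    ``id n_neighbors nb_id ...``."""
    with open(path, "w") as fh:
        fh.write(f"{graph.n}\n")
        for i, tid in enumerate(graph.tract_ids):
            nbs = sorted(graph.neighbors[i])
            ids = " ".join(str(graph.tract_ids[j]) for j in nbs)
            fh.write(f"{tid} {len(nbs)}{' ' if ids else ''}{ids}\n")


def read_adjacency(path) -> AdjacencyGraph:
    """Read a GAL-style neighbour list written by :func:`write_adjacency`.

    Asymmetric entries are symmetrised with a warning; isolated tracts are
    permitted but flagged with a warning.  Unknown neighbour ids raise a
    parse error naming the offending line.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise GraphError(f"{path}: empty adjacency file")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise GraphError(f"{path}: bad header line") from exc
    if len(lines) - 1 != n:
        raise GraphError(f"{path}: header says {n} tracts, found {len(lines) - 1}")
    ids = [ln.split()[0] for ln in lines[1:]]
    index = {tid: i for i, tid in enumerate(ids)}
    neighbors: list[set[int]] = [set() for _ in range(n)]
    asym = False
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        tid, count, nbs = parts[0], int(parts[1]), parts[2:]
        if len(nbs) != count:
            raise GraphError(f"{path}:{lineno}: neighbor count mismatch for {tid}")
        i = index[tid]
        for nb in nbs:
            if nb not in index:
                raise GraphError(f"{path}:{lineno}: unknown neighbor id {nb!r}")
            j = index[nb]
            if j == i:
                raise GraphError(f"{path}:{lineno}: self-loop at {tid}")
            neighbors[i].add(j)
    for i in range(n):
        for j in neighbors[i]:
            if i not in neighbors[j]:
                asym = True
                neighbors[j].add(i)
    if asym:
        warnings.warn("adjacency file was asymmetric; symmetrised", stacklevel=2)
    graph = AdjacencyGraph(ids, neighbors)
    if graph.isolated():
        warnings.warn(
            f"{len(graph.isolated())} isolated tract(s) in adjacency", stacklevel=2
        )
    return graph


def adjacency_from_polygons(source, rule: str = "rook") -> AdjacencyGraph:
    """Contiguity graph from tract polygons.

    Parameters
    ----------
    source : path or GeoJSON-like mapping
        A GeoJSON FeatureCollection (path or already-parsed dict).  Each
        feature needs a tract id under ``properties['tract_id']`` (falling
        back to the feature ``id``).
    rule : {'rook', 'queen'}
        ``rook``: adjacent iff boundaries share a segment of positive
        length (the "share a border" convention).  ``queen``: any touch,
        including single points.
    """
    from shapely.geometry import shape
    from shapely.validation import explain_validity

    if rule not in ("rook", "queen"):
        raise GraphError(f"unknown contiguity rule {rule!r}")
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            data = json.load(fh)
    else:
        data = source
    feats = data["features"]
    ids, geoms = [], []
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        tid = props.get("tract_id", feat.get("id", str(k)))
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise GraphError(
                f"invalid geometry for tract {tid}: {explain_validity(geom)}"
            )
        ids.append(str(tid))
        geoms.append(geom)
    n = len(ids)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    # STRtree would be the right tool beyond a few thousand tracts; a
    # bounding-box prefilter is plenty at study scale.
    bounds = [g.bounds for g in geoms]
    for i in range(n):
        bi = bounds[i]
        for j in range(i + 1, n):
            bj = bounds[j]
            if bi[0] > bj[2] or bj[0] > bi[2] or bi[1] > bj[3] or bj[1] > bi[3]:
                continue
            gi, gj = geoms[i], geoms[j]
            if not gi.intersects(gj):
                continue
            if rule == "queen":
                touch = True  # any non-empty intersection counts
            else:  # rook: shared border of positive length
                touch = gi.boundary.intersection(gj.boundary).length > 0.0
            if touch:
                neighbors[i].add(j)
                neighbors[j].add(i)
    return AdjacencyGraph(ids, neighbors)


@dataclass
class ICARStructure:
    """Structure of the intrinsic CAR prior on a graph.

    ``Q = D - W`` with ``D`` the diagonal of neighbour counts and ``W`` the
    0/1 adjacency.  ``Q`` is symmetric positive semidefinite with one null
    vector (the constant) per connected component; the prior density
    ``p(S) ∝ tau^{(n-k)/2} exp(-tau/2 S'QS)`` is proper on the subspace
    where S sums to zero within each component.
    """

    Q: sp.csr_matrix
    components: list[np.ndarray]
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def rank(self) -> int:
        return self.n - self.n_components

    def constraint_matrix(self) -> np.ndarray:
        """One sum-to-zero constraint row per connected component."""
        A = np.zeros((self.n_components, self.n))
        for k, comp in enumerate(self.components):
            A[k, comp] = 1.0
        return A

    def _eigen(self):
        if self._eig is None:
            w, V = np.linalg.eigh(self.Q.toarray())
            self._eig = (w, V)
        return self._eig

    def marginal_variances(self) -> np.ndarray:
        """Diagonal of the generalised inverse of Q (unit precision)."""
        w, V = self._eigen()
        nz = w > 1e-9 * max(w.max(), 1.0)
        return np.einsum("ij,j,ij->i", V[:, nz], 1.0 / w[nz], V[:, nz])

    @property
    def scale(self) -> float:
        """Geometric mean of the marginal variances (unit precision).

        Used to report the spatial standard deviation on the marginal
        scale, so that sigma_S means 'typical marginal SD of S' for both
        the generator and the fitted model.
        """
        mv = self.marginal_variances()
        pos = mv[mv > 0]
        return float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0

    def quadratic_form(self, x: np.ndarray) -> float:
        """x'Qx = sum over neighbour pairs of (x_i - x_j)^2."""
        return float(x @ (self.Q @ x))

    def draw(self, rng: np.random.Generator, unit_marginal: bool = True) -> np.ndarray:
        """Zero-mean ICAR draw (unit precision), sum-to-zero per component.

        With ``unit_marginal`` the draw is rescaled by 1/sqrt(scale) so its
        typical marginal SD is 1.
        """
        w, V = self._eigen()
        nz = w > 1e-9 * max(w.max(), 1.0)
        z = rng.standard_normal(int(nz.sum()))
        s = V[:, nz] @ (z / np.sqrt(w[nz]))
        if unit_marginal:
            s = s / np.sqrt(self.scale)
        # numerically re-centre within components
        for comp in self.components:
            s[comp] -= s[comp].mean()
        return s


def icar_structure(graph: AdjacencyGraph) -> ICARStructure:
    """Build ``Q = D - W`` and identify connected components."""
    W = graph.adjacency_matrix()
    D = sp.diags(graph.degree())
    Q = (D - W).tocsr()
    return ICARStructure(Q=Q, components=graph.components())
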