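"""Delaunay tessellation of Cα point sets and tessellation-derived features.

The Delaunay tessellation partitions the convex hull of the Cα points into
tetrahedra whose circumspheres contain no other point, so the four vertices
of each tetrahedron identify an objective quadruplet of nearest-neighbor
residues. Edges longer than a cutoff (12 Å by default) usually join
non-interacting surface residues that exist only to close the convex hull;
every tetrahedron using such an edge is removed before any analysis.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import Delaunay as _ScipyDelaunay
from scipy.spatial import QhullError

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 12.0  # Å


@dataclass(frozen=True)
class Tessellation:
    """Delaunay simplices over a point set, optionally edge-filtered.

    ``positions[i]`` maps vertex index ``i`` to its residue sequence number;
    for bare point clouds it defaults to ``0..n-1``.
    """

    points: np.ndarray               # (n, 3)
    simplices: np.ndarray            # (m, 4) vertex indices, each row sorted
    positions: tuple[int, ...]       # vertex index -> residue seq number
    cutoff: float | None = None      # Å; None for the raw tessellation
    joggled: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        s = np.sort(np.asarray(self.simplices, dtype=int), axis=1)
        object.__setattr__(self, "simplices", s)

    @property
    def n_vertices(self) -> int:
        return len(self.points)

    @property
    def n_simplices(self) -> int:
        return len(self.simplices)

    def index_of(self, position: int) -> int:
        try:
            return self.positions.index(position)
        except ValueError:
            raise KeyError(f"position {position} not in tessellation") from None

    def edges(self) -> dict[tuple[int, int], float]:
        """Retained edges as {(i, j): length} with i < j (vertex indices)."""
        out: dict[tuple[int, int], float] = {}
        for simplex in self.simplices:
            for i, j in combinations(simplex.tolist(), 2):
                if (i, j) not in out:
                    out[(i, j)] = float(np.linalg.norm(self.points[i] - self.points[j]))
        return out

    def vertex_edges(self, index: int) -> dict[int, float]:
        """Edges incident to one vertex as {other index: length}."""
        out: dict[int, float] = {}
        for simplex in self.simplices:
            lst = simplex.tolist()
            if index in lst:
                for j in lst:
                    if j != index and j not in out:
                        out[j] = float(np.linalg.norm(self.points[index] - self.points[j]))
        return out

    def incident_simplices(self, index: int) -> np.ndarray:
        mask = (self.simplices == index).any(axis=1)
        return self.simplices[mask]

    def max_edge_lengths(self) -> np.ndarray:
        """Longest edge of each simplex, in Å."""
        return np.array([
            max(np.linalg.norm(self.points[i] - self.points[j])
                for i, j in combinations(s.tolist(), 2))
            for s in self.simplices])


def tessellate(points: np.ndarray, positions: Sequence[int] | None = None,
               joggle_seed: int = 0) -> Tessellation:
    """Raw Delaunay tessellation of ≥4 non-coplanar 3D points.

    Degenerate inputs (coplanar, or heavily co-spherical sets Qhull cannot
    triangulate) are retried once after a deterministic joggle: a uniform
    perturbation of at most 1e-6 Å drawn from a fixed-seed generator. The
    result is flagged ``joggled=True``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(pts) < 4:
        raise ValueError("at least 4 points are required")
    if positions is None:
        positions = tuple(range(len(pts)))
    else:
        positions = tuple(int(p) for p in positions)
        if len(positions) != len(pts):
            raise ValueError("positions must match points in length")
    joggled = False
    try:
        tri = _ScipyDelaunay(pts)
        if tri.simplices.shape[0] == 0:
            raise QhullError("empty triangulation")
    except QhullError:
        rng = np.random.default_rng(joggle_seed)
        jitter = rng.uniform(-1e-6, 1e-6, size=pts.shape)
        logger.warning("degenerate point set: applying deterministic joggle "
                       "(≤1e-6 Å, seed %d)", joggle_seed)
        tri = _ScipyDelaunay(pts + jitter)
        joggled = True
    # co-spherical inputs may include zero-volume cells; they are kept so
    # the simplicial complex stays face-to-face consistent
    return Tessellation(points=pts, simplices=tri.simplices,
                        positions=positions, cutoff=None, joggled=joggled)


def _simplex_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    if len(simplices) == 0:
        return np.zeros(0)
    a, b, c, d = (points[simplices[:, k]] for k in range(4))
    return np.abs(np.einsum("ij,ij->i", b - a, np.cross(c - a, d - a))) / 6.0


def filter_by_edge_length(tess: Tessellation,
                          cutoff: float = DEFAULT_CUTOFF) -> Tessellation:
    """Remove every tetrahedron with an edge strictly longer than ``cutoff``.

    Edges of exactly ``cutoff`` Å are retained ("longer than" is read as a
    strict inequality). Vertices can become simplex-free (isolated); they
    stay in the vertex set.
    """
    keep = tess.max_edge_lengths() <= cutoff if tess.n_simplices else \
        np.zeros(0, dtype=bool)
    return Tessellation(points=tess.points, simplices=tess.simplices[keep],
                        positions=tess.positions, cutoff=cutoff,
                        joggled=tess.joggled)


def tessellate_structure(structure, cutoff: float | None = DEFAULT_CUTOFF,
                         joggle_seed: int = 0) -> Tessellation:
    """Tessellate a :class:`~quadpot.structure_io.ProteinStructure`.

    Applies the edge-length filter unless ``cutoff`` is ``None``.
    """
    tess = tessellate(structure.coords, positions=structure.positions,
                      joggle_seed=joggle_seed)
    if cutoff is not None:
        tess = filter_by_edge_length(tess, cutoff)
    return tess


def residue_neighbors(tess: Tessellation, position: int) -> set[int]:
    """Positions joined to ``position`` by a retained tetrahedral edge."""
    idx = tess.index_of(position)
    return {tess.positions[j] for j in tess.vertex_edges(idx)}


@dataclass(frozen=True)
class TetrahedronGeometry:
    volume: float            # Å³
    tetrahedrality: float    # dimensionless distortion; 0 for a regular tet
    edge_lengths: tuple[float, ...]  # 6 edges, Å
    mean_edge: float         # Å
    degenerate: bool = False


def tetrahedron_geometry(points: np.ndarray) -> TetrahedronGeometry:
    """Volume and tetrahedrality of one tetrahedron (4×3 coordinate array).

    Tetrahedrality is Σ_{i>j} (l_i − l_j)² / (15 l̄²) over the 15 pairs of
    the 6 edge lengths — zero iff all edges are equal.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (4, 3):
        raise ValueError("expected 4 points in 3D")
    a, b, c, d = pts
    volume = abs(np.dot(b - a, np.cross(c - a, d - a))) / 6.0
    lengths = tuple(float(np.linalg.norm(pts[i] - pts[j]))
                    for i, j in combinations(range(4), 2))
    mean_edge = float(np.mean(lengths))
    degenerate = mean_edge < 1e-12
    if degenerate:
        tetra = 0.0
    else:
        tetra = float(sum((li - lj) ** 2 for li, lj in combinations(lengths, 2))
                      / (15.0 * mean_edge ** 2))
    return TetrahedronGeometry(volume=float(volume), tetrahedrality=tetra,
                               edge_lengths=lengths, mean_edge=mean_edge,
                               degenerate=degenerate)


def classify_depth(tess: Tessellation) -> dict[int, str]:
    """Tessellation-based burial class per residue position.

    S (surface): vertex of a triangular facet that belongs to exactly one
    tetrahedron. U (undersurface): not S, but joined to an S position by a
    retained edge. B (buried): everything else. Vertices left simplex-free
    by the edge filter sit on the exterior and are labeled S (with a
    warning).
    """
    facet_count: Counter[tuple[int, int, int]] = Counter()
    for simplex in tess.simplices:
        for facet in combinations(simplex.tolist(), 3):
            facet_count[facet] += 1
    surface_idx: set[int] = set()
    for facet, count in facet_count.items():
        if count == 1:
            surface_idx.update(facet)
    in_simplex = set(int(v) for v in tess.simplices.ravel())
    isolated = set(range(tess.n_vertices)) - in_simplex
    if isolated:
        logger.warning("%d isolated vertices labeled S", len(isolated))
        surface_idx |= isolated
    labels: dict[int, str] = {}
    for i in range(tess.n_vertices):
        if i in surface_idx:
            labels[tess.positions[i]] = "S"
    for i in range(tess.n_vertices):
        if i in surface_idx:
            continue
        nbrs = tess.vertex_edges(i)
        if any(j in surface_idx for j in nbrs):
            labels[tess.positions[i]] = "U"
        else:
            labels[tess.positions[i]] = "B"
    return labels


def surface_edge_count(tess: Tessellation, position: int,
                       depth: Mapping[int, str] | None = None) -> int:
    """Number of retained edges from ``position`` to surface (S) positions.

    Zero by construction for buried positions (no B–S edge exists).
    """
    if depth is None:
        depth = classify_depth(tess)
    idx = tess.index_of(position)
    return sum(1 for j in tess.vertex_edges(idx)
               if depth[tess.positions[j]] == "S")


def tessellation_table(tess: Tessellation) -> "pd.DataFrame":
    """One row per simplex: residue numbers, 6 edges, volume, tetrahedrality."""
    import pandas as pd

    rows = []
    for simplex in tess.simplices:
        geo = tetrahedron_geometry(tess.points[simplex])
        rows.append(
            [*(tess.positions[v] for v in simplex.tolist()),
             *geo.edge_lengths, geo.volume, geo.tetrahedrality])
    cols = (["v1", "v2", "v3", "v4"]
            + [f"edge{k}" for k in range(1, 7)]
            + ["volume", "tetrahedrality"])
    return pd.DataFrame(rows, columns=cols)
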