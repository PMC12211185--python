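"""Persistent homology of localization point clouds (components and holes).

The construction follows the expanding-circle picture: every point grows a
disc of radius r; two components merge when their circles first touch, i.e.
at r = d/2 for points at distance d. Formally this is a Vietoris-Rips
filtration **parameterized by the circle radius**: an edge (i, j) is born at
d_ij / 2 and a triangle at the maximum of its edge births. Note that many
persistence libraries use the *diameter* convention instead; all radii
reported here are half those values.

H0 bars (connected components) all start at radius 0; a component dies when
it merges into an older one, so the finite H0 deaths are exactly the
halved edge lengths of the cloud's Euclidean minimum spanning tree. H1 bars
(holes) are born when a cycle of edges closes an enclosed region and die
when triangles fill it; the distribution of H1 death radii measures hole
sizes. H0 is computed by union-find over edges in birth order (elder rule);
H1 by mod-2 reduction of the triangle boundary matrix in filtration order,
with columns packed into Python integers so column addition is a single XOR.
Zero-persistence H1 pairs (cycle and filling triangle born together) are
omitted from the diagram; all H0 bars are kept so their count equals the
point count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass
class Filtration:
    """Rips filtration up to dimension 2, radius-parameterized.

    Edges and triangles are stored sorted by (birth, vertex tuple); this
    total order (with dimension as secondary key across lists) makes the
    reduction deterministic.
    """

    n_vertices: int
    edges: np.ndarray  # (E, 2) int, i < j
    edge_births: np.ndarray  # (E,) nm
    triangles: np.ndarray  # (T, 3) int, i < j < k
    triangle_births: np.ndarray  # (T,) nm
    max_radius: float
    max_dim: int

    def validate_face_order(self) -> bool:
        """Every simplex is born no earlier than any of its faces."""
        if len(self.triangles) == 0:
            return True
        births = {}
        for (i, j), b in zip(self.edges, self.edge_births):
            births[(int(i), int(j))] = b
        for (i, j, k), b in zip(self.triangles, self.triangle_births):
            faces = [(int(i), int(j)), (int(i), int(k)), (int(j), int(k))]
            if any(f not in births or births[f] > b + 1e-12 for f in faces):
                return False
        return True


@dataclass
class PersistenceDiagram:
    """Bars (dimension, birth, death) with death = inf for essential classes."""

    dims: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    n_points: int

    def bars(self, dim: int) -> np.ndarray:
        """(birth, death) pairs of the given dimension, sorted."""
        sel = self.dims == dim
        out = np.column_stack([self.births[sel], self.deaths[sel]])
        order = np.lexsort((out[:, 1], out[:, 0]))
        return out[order]


@dataclass
class HoleSizeHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_infinite: int
    n_outside: int  # finite deaths falling outside the bin range


def build_rips_filtration(
    points_or_pattern, max_radius: float, max_dim: int = 2
) -> Filtration:
    """Build the radius-parameterized Rips filtration of a point cloud.

    Simplices with birth radius beyond ``max_radius`` are omitted.
    """
    points = getattr(points_or_pattern, "points", points_or_pattern)
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if n < 1:
        raise ValueError("filtration requires at least one point")
    if max_radius <= 0:
        raise ValueError("max_radius must be > 0")
    if max_dim not in (1, 2):
        raise ValueError("max_dim must be 1 or 2")

    if n == 1:
        return Filtration(
            1, np.zeros((0, 2), int), np.zeros(0), np.zeros((0, 3), int),
            np.zeros(0), max_radius, max_dim,
        )

    half = squareform(pdist(points)) / 2.0  # circle-radius convention: d/2
    iu, ju = np.triu_indices(n, k=1)
    births = half[iu, ju]
    keep = births <= max_radius
    edges = np.column_stack([iu[keep], ju[keep]])
    edge_births = births[keep]
    order = np.lexsort((edges[:, 1], edges[:, 0], edge_births))
    edges, edge_births = edges[order], edge_births[order]

    triangles = np.zeros((0, 3), int)
    tri_births = np.zeros(0)
    if max_dim >= 2 and len(edges) > 0:
        adj = np.zeros((n, n), dtype=bool)
        adj[edges[:, 0], edges[:, 1]] = True
        adj[edges[:, 1], edges[:, 0]] = True
        tris = []
        tbs = []
        for (i, j), b in zip(edges, edge_births):
            common = np.nonzero(adj[i] & adj[j])[0]
            common = common[common > j]
            for k in common:
                tb = max(b, half[i, k], half[j, k])
                tris.append((i, j, k))
                tbs.append(tb)
        if tris:
            triangles = np.asarray(tris, dtype=int)
            tri_births = np.asarray(tbs, dtype=float)
            order = np.lexsort(
                (triangles[:, 2], triangles[:, 1], triangles[:, 0], tri_births)
            )
            triangles, tri_births = triangles[order], tri_births[order]

    return Filtration(n, edges, edge_births, triangles, tri_births, max_radius, max_dim)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def compute_persistence(filtration: Filtration) -> PersistenceDiagram:
    """Barcode of the filtration: H0 via union-find, H1 via matrix reduction.

    H0: processing edges in birth order, each edge that merges two components
    kills the younger one at the edge's birth radius (all components are born
    at 0, so any merge emits a bar (0, death)). Unmerged components are
    essential bars (0, inf).

    H1: each triangle's boundary (three edges, mod 2) is reduced against the
    previously reduced columns; a surviving pivot edge e pairs the cycle
    created by e with the triangle, giving the bar (birth_e, birth_triangle).
    Edges that neither merge components nor get paired with a triangle create
    holes that never die within max_radius: essential H1 bars (birth, inf).
    """
    n = filtration.n_vertices
    uf = _UnionFind(n)
    dims: list[int] = []
    births: list[float] = []
    deaths: list[float] = []
    mst_mask = np.zeros(len(filtration.edges), dtype=bool)
    for idx, ((i, j), b) in enumerate(
        zip(filtration.edges, filtration.edge_births)
    ):
        if uf.union(int(i), int(j)):
            mst_mask[idx] = True
            dims.append(0)
            births.append(0.0)
            deaths.append(float(b))
    n_components = n - int(mst_mask.sum())
    for _ in range(n_components):
        dims.append(0)
        births.append(0.0)
        deaths.append(np.inf)

    # H1 reduction: columns are bitmask ints over (sorted) edge indices.
    pivots: dict[int, int] = {}  # pivot edge index -> reduced column
    paired_edges: set[int] = set()
    if len(filtration.triangles):
        edge_index = {
            (int(i), int(j)): idx
            for idx, (i, j) in enumerate(filtration.edges)
        }
        for (i, j, k), tb in zip(
            filtration.triangles, filtration.triangle_births
        ):
            i, j, k = int(i), int(j), int(k)
            try:
                col = (
                    (1 << edge_index[(i, j)])
                    | (1 << edge_index[(i, k)])
                    | (1 << edge_index[(j, k)])
                )
            except KeyError as exc:
                raise ValueError(f"triangle face {exc} missing from filtration")
            while col:
                pivot = col.bit_length() - 1
                if pivot not in pivots:
                    break
                col ^= pivots[pivot]
            if col:
                pivot = col.bit_length() - 1
                pivots[pivot] = col
                paired_edges.add(pivot)
                birth = float(filtration.edge_births[pivot])
                death = float(tb)
                if death > birth:  # zero-persistence pairs are omitted
                    dims.append(1)
                    births.append(birth)
                    deaths.append(death)

    # essential H1 classes: positive edges never filled by a triangle
    for idx in np.nonzero(~mst_mask)[0]:
        if int(idx) not in paired_edges:
            dims.append(1)
            births.append(float(filtration.edge_births[idx]))
            deaths.append(np.inf)

    return PersistenceDiagram(
        np.asarray(dims, int), np.asarray(births), np.asarray(deaths), n
    )


def rips_persistence(
    points_or_pattern,
    max_radius: float,
    max_dim: int = 2,
    subsample_threshold: int = 500,
    seed: int = 0,
) -> PersistenceDiagram:
    """Convenience wrapper: filtration + persistence, with dense-cloud guard.

    Clouds larger than ``subsample_threshold`` points are randomly
    subsampled to that size (seeded) before building the filtration, since
    the triangle count grows cubically.
    """
    points = getattr(points_or_pattern, "points", points_or_pattern)
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) > subsample_threshold:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(points), subsample_threshold, replace=False)
        points = points[np.sort(sel)]
    return compute_persistence(build_rips_filtration(points, max_radius, max_dim))


def bar_endpoint_histogram(
    diagram: PersistenceDiagram, dim: int, bin_edges: np.ndarray
) -> HoleSizeHistogram:
    """Histogram of finite bar death radii (hole/component sizes).

    Infinite bars are excluded and counted separately, as are finite deaths
    outside the bin range.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    sel = diagram.dims == dim
    deaths = diagram.deaths[sel]
    finite = deaths[np.isfinite(deaths)]
    counts, _ = np.histogram(finite, bin_edges)
    n_outside = len(finite) - int(counts.sum())
    return HoleSizeHistogram(
        bin_edges, counts, int(np.sum(~np.isfinite(deaths))), n_outside
    )


def count_features(diagram: PersistenceDiagram, at_radius: float) -> tuple[int, int]:
    """(components, holes) alive at the given radius (birth <= r < death)."""
    if at_radius < 0:
        raise ValueError("radius must be >= 0")
    alive = (diagram.births <= at_radius) & (at_radius < diagram.deaths)
    return int(np.sum(alive & (diagram.dims == 0))), int(
        np.sum(alive & (diagram.dims == 1))
    )


def default_hole_bins(r_max: float = 200.0, step: float = 25.0) -> np.ndarray:
    """Default hole-size bin edges: 0 to 200 nm in 25 nm steps."""
    return np.arange(0.0, r_max + step / 2, step)
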