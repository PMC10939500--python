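"""Low-level triangle-mesh geometry used throughout the pipeline.

Meshes are held as ``trimesh.Trimesh`` objects constructed with
``process=False`` so vertex order and indexing are never silently changed;
vertex indices are 0-based everywhere inside the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import cKDTree

from .exceptions import DegenerateGeometryError

__all__ = [
    "SimilarityTransform",
    "as_mesh",
    "vertex_normals",
    "vertex_rings",
    "graph_distances",
    "closest_points_on_surface",
    "median_edge_length",
    "bounding_box_diagonal",
]


@dataclass(frozen=True)
class SimilarityTransform:
    """x -> scale * R @ x + t with R a proper rotation (det +1)."""

    scale: float
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise DegenerateGeometryError("similarity scale must be positive")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise DegenerateGeometryError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        r_inv = self.rotation.T
        return SimilarityTransform(
            scale=1.0 / self.scale,
            rotation=r_inv,
            translation=-(r_inv @ self.translation) / self.scale,
        )

    @staticmethod
    def identity() -> "SimilarityTransform":
        return SimilarityTransform(1.0, np.eye(3), np.zeros(3))


def as_mesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    """Wrap arrays in a Trimesh without any automatic reprocessing."""
    return trimesh.Trimesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
    )


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Outward unit vertex normals as area-weighted means of incident faces.

    Each face contributes its unnormalised area vector (length twice the
    face area), so the accumulation is exactly area weighting. The area
    vector is assembled from per-edge cross products taken in a canonical
    edge order, and per-vertex accumulation runs in sorted (vertex, face)
    order, so reversing the face winding negates the result *exactly* —
    floating-point summation order is identical for both orientations.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    # centre once (orientation-independent) to keep the position-based cross
    # products well conditioned for meshes far from the origin
    pos = vertices - vertices.mean(axis=0)

    # 2*area vector = cross(v0,v1) + cross(v1,v2) + cross(v2,v0);
    # evaluate each edge term as +-cross(v_min, v_max) and sum the three
    # terms ordered by their canonical (min, max) edge key
    edges = np.stack(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=1
    )  # (F, 3, 2)
    lo = edges.min(axis=2)
    hi = edges.max(axis=2)
    sign = np.where(edges[:, :, 0] == lo, 1.0, -1.0)
    terms = sign[:, :, None] * np.cross(pos[lo], pos[hi])  # (F, 3, 3)
    key = lo * (np.int64(len(vertices)) + 1) + hi
    order = np.argsort(key, axis=1)
    terms = np.take_along_axis(terms, order[:, :, None], axis=1)
    fn = terms[:, 0] + terms[:, 1] + terms[:, 2]

    # accumulate per vertex in (vertex, face) order, independent of which
    # face column the vertex occupies
    flat = faces.ravel()
    contrib = np.repeat(fn, 3, axis=0)
    srt = np.lexsort((np.repeat(np.arange(len(faces)), 3), flat))
    flat = flat[srt]
    contrib = contrib[srt]
    starts = np.flatnonzero(np.r_[True, np.diff(flat) > 0])
    acc = np.zeros_like(vertices)
    acc[flat[starts]] = np.add.reduceat(contrib, starts, axis=0)

    norms = np.linalg.norm(acc, axis=1)
    if np.any(norms < 1e-300):
        bad = int(np.argmin(norms))
        raise DegenerateGeometryError(
            f"vertex {bad} has a zero normal (degenerate incident faces)"
        )
    return acc / norms[:, None]


def _adjacency(faces: np.ndarray, n_vertices: int, lengths: np.ndarray | None = None):
    """Sparse symmetric vertex adjacency, optionally edge-length weighted."""
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    e = np.unique(e, axis=0)
    w = np.ones(len(e)) if lengths is None else lengths
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    data = np.concatenate([w, w])
    return csr_matrix((data, (rows, cols)), shape=(n_vertices, n_vertices)), e


def vertex_rings(faces: np.ndarray, n_vertices: int, seeds, n_rings: int) -> np.ndarray:
    """Vertex indices within ``n_rings`` edge hops of any seed (BFS)."""
    adj, _ = _adjacency(np.asarray(faces, dtype=np.int64), n_vertices)
    reached = np.zeros(n_vertices, dtype=bool)
    frontier = np.zeros(n_vertices, dtype=bool)
    frontier[np.asarray(list(seeds), dtype=np.int64)] = True
    reached |= frontier
    for _ in range(n_rings):
        nxt = (adj @ frontier.astype(np.int8)) > 0
        frontier = nxt & ~reached
        reached |= frontier
        if not frontier.any():
            break
    return np.flatnonzero(reached)


def graph_distances(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances along mesh edges (geodesic proxy)."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    _, edges = _adjacency(faces, len(vertices))
    lengths = np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]], axis=1)
    adj, _ = _adjacency(faces, len(vertices), lengths)
    return shortest_path(adj, method="D", directed=False)


def _closest_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Closest point on each triangle (a,b,c) to each query p (vectorised).

    Standard region-based projection (Ericson, Real-Time Collision
    Detection, §5.1.5): classify the projection of p into the seven
    Voronoi regions of the triangle and clamp accordingly.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[m] = a[m]
    done |= m

    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[m] = b[m]
    done |= m

    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    if m.any():
        v = d1[m] / (d1[m] - d3[m])
        out[m] = a[m] + v[:, None] * ab[m]
        done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    if m.any():
        w = d2[m] / (d2[m] - d6[m])
        out[m] = a[m] + w[:, None] * ac[m]
        done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    if m.any():
        w = (d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m]))
        out[m] = b[m] + w[:, None] * (c[m] - b[m])
        done |= m

    m = ~done  # interior
    if m.any():
        denom = va[m] + vb[m] + vc[m]
        v = vb[m] / denom
        w = vc[m] / denom
        out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


class SurfaceLocator:
    """Point-to-surface queries against a fixed triangulated target.

    Candidate triangles come from a k-d tree over target vertices: for each
    query the faces incident to its ``k_candidates`` nearest target vertices
    are tested exactly. On smooth, reasonably uniform meshes this finds the
    true nearest face; it is the standard candidate-pruning construction.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k_candidates: int = 8):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        if len(self.faces) == 0 or len(self.vertices) == 0:
            raise DegenerateGeometryError("target surface is empty")
        self.k = min(k_candidates, len(self.vertices))
        self._tree = cKDTree(self.vertices)
        # vertex -> incident faces as a padded array for fast gathering
        counts = np.zeros(len(self.vertices), dtype=np.int64)
        for col in range(3):
            np.add.at(counts, self.faces[:, col], 1)
        max_deg = int(counts.max())
        incident = np.full((len(self.vertices), max_deg), -1, dtype=np.int64)
        cursor = np.zeros(len(self.vertices), dtype=np.int64)
        for f_idx in range(len(self.faces)):
            for v in self.faces[f_idx]:
                incident[v, cursor[v]] = f_idx
                cursor[v] += 1
        self._incident = incident

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest surface points, distances) for each query point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, nn = self._tree.query(points, k=self.k)
        nn = np.atleast_2d(nn)
        cand = self._incident[nn].reshape(len(points), -1)  # (Q, k*max_deg)

        q_idx = np.repeat(np.arange(len(points)), cand.shape[1])
        f_idx = cand.ravel()
        keep = f_idx >= 0
        q_idx, f_idx = q_idx[keep], f_idx[keep]

        tri = self.faces[f_idx]
        proj = _closest_on_triangles(
            points[q_idx],
            self.vertices[tri[:, 0]],
            self.vertices[tri[:, 1]],
            self.vertices[tri[:, 2]],
        )
        d2 = np.einsum("ij,ij->i", points[q_idx] - proj, points[q_idx] - proj)

        best_d2 = np.full(len(points), np.inf)
        np.minimum.at(best_d2, q_idx, d2)
        is_best = d2 <= best_d2[q_idx] * (1 + 1e-12)
        closest = np.empty_like(points)
        closest[q_idx[is_best]] = proj[is_best]
        return closest, np.sqrt(best_d2)


def closest_points_on_surface(
    points: np.ndarray, vertices: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One-shot convenience wrapper around :class:`SurfaceLocator`."""
    return SurfaceLocator(vertices, faces).query(points)


def median_edge_length(vertices: np.ndarray, faces: np.ndarray) -> float:
    faces = np.asarray(faces, dtype=np.int64)
    _, edges = _adjacency(faces, int(faces.max()) + 1)
    vertices = np.asarray(vertices, dtype=float)
    return float(
        np.median(np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]], axis=1))
    )


def bounding_box_diagonal(vertices: np.ndarray) -> float:
    vertices = np.asarray(vertices, dtype=float)
    return float(np.linalg.norm(vertices.max(axis=0) - vertices.min(axis=0)))
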