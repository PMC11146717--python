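"""Exact point-to-surface proximity queries.

The directed distance used throughout the pipeline is vertex-of-model ->
surface-of-target: for each query point, the exact Euclidean distance to the
closest point on any triangle of the target mesh. Candidate triangles are
found through a KD-tree over triangle centroids with a rigorous expansion
bound (a triangle whose centroid is farther than ``best + r_max`` cannot
contain a closer point, where ``r_max`` is the largest centroid-to-vertex
radius), so results equal the brute-force minimum over all triangles.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriMesh

__all__ = ["SurfaceQuery", "point_to_surface_distance", "points_to_surface_distance"]


def closest_point_on_triangles(p, a, b, c):
    """Closest point to ``p`` on each triangle (a, b, c), elementwise.

    All inputs (N, 3); returns (N, 3). Ericson's region-based algorithm,
    vectorized. Exact for degenerate query positions (vertices, edges).
    """
    p, a, b, c = (np.asarray(x, dtype=np.float64) for x in (p, a, b, c))
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

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, values):
        m = mask & ~done
        out[m] = values[m] if values.shape == out.shape else values
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)                      # vertex region A
    assign((d3 >= 0) & (d4 <= d3), b)                     # vertex region B
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
    assign((d6 >= 0) & (d5 <= d6), c)                     # vertex region C
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = d2 / (d2 - d6)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))
    # interior
    denom = va + vb + vc
    safe = np.where(denom == 0, 1.0, denom)
    v = vb / safe
    w = vc / safe
    interior = a + v[:, None] * ab + w[:, None] * ac
    out[~done] = interior[~done]
    return out


class SurfaceQuery:
    """Reusable exact closest-point structure for one target mesh."""

    #: below this face count the brute-force path is cheaper than the tree
    _BRUTE_FORCE_MAX = 64

    def __init__(self, mesh: TriMesh):
        if mesh.n_faces == 0:
            raise ValueError("cannot query an empty mesh")
        self.mesh = mesh
        self._tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
        self._centroids = self._tri.mean(axis=1)
        self._r_max = float(
            np.max(np.linalg.norm(self._tri - self._centroids[:, None, :], axis=2))
        )
        self._tree = cKDTree(self._centroids)

    # -- internals ------------------------------------------------------
    def _brute(self, points: np.ndarray, tri_idx: np.ndarray | None = None):
        tri = self._tri if tri_idx is None else self._tri[tri_idx]
        F = len(tri)
        N = len(points)
        rep_p = np.repeat(points, F, axis=0)
        til = np.tile(tri, (N, 1, 1))
        cp = closest_point_on_triangles(rep_p, til[:, 0], til[:, 1], til[:, 2])
        d = np.linalg.norm(rep_p - cp, axis=1).reshape(N, F)
        j = np.argmin(d, axis=1)
        rows = np.arange(N)
        best_cp = cp.reshape(N, F, 3)[rows, j]
        best_idx = j if tri_idx is None else np.asarray(tri_idx)[j]
        return best_cp, d[rows, j], best_idx

    def closest(self, points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Exact closest surface points.

        Returns
        -------
        (closest_points (N,3), distances (N,), triangle_indices (N,))
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        F = len(self._tri)
        if F <= self._BRUTE_FORCE_MAX:
            return self._brute(points)

        N = len(points)
        best_cp = np.zeros((N, 3))
        best_d = np.full(N, np.inf)
        best_i = np.zeros(N, dtype=np.int64)
        pending = np.arange(N)
        k = min(8, F)
        while pending.size:
            cd, ci = self._tree.query(points[pending], k=k)
            cd = np.atleast_2d(cd)
            ci = np.atleast_2d(ci)
            # exact distance over the k candidate triangles
            tri = self._tri[ci.ravel()]
            rep_p = np.repeat(points[pending], k, axis=0)
            cp = closest_point_on_triangles(rep_p, tri[:, 0], tri[:, 1], tri[:, 2])
            d = np.linalg.norm(rep_p - cp, axis=1).reshape(len(pending), k)
            j = np.argmin(d, axis=1)
            rows = np.arange(len(pending))
            cand_d = d[rows, j]
            improve = cand_d < best_d[pending]
            upd = pending[improve]
            best_d[upd] = cand_d[improve]
            best_cp[upd] = cp.reshape(len(pending), k, 3)[rows, j][improve]
            best_i[upd] = ci[rows, j][improve]
            # a farther triangle can still win only if its centroid lies
            # within best + r_max of the query point
            certain = (cd[:, -1] - self._r_max >= best_d[pending]) | (k >= F)
            pending = pending[~certain]
            k = min(4 * k, F)
        return best_cp, best_d, best_i

    def distances(self, points) -> np.ndarray:
        return self.closest(points)[1]


def points_to_surface_distance(points, mesh: TriMesh) -> np.ndarray:
    """Directed distances from each point to the surface of ``mesh``."""
    return SurfaceQuery(mesh).distances(points)


def point_to_surface_distance(point, mesh: TriMesh) -> float:
    """Exact minimum Euclidean distance from one point to the mesh surface.

    Zero iff the point lies on the surface. Raises if the mesh is empty.
    """
    return float(points_to_surface_distance(np.asarray(point).reshape(1, 3), mesh)[0])
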