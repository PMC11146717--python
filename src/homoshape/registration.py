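"""Homologous-model construction by template registration.

A specimen mesh has its own vertex count and numbering, so populations of
raw meshes cannot be compared vertex-by-vertex. This module establishes
dense correspondence by deforming a fixed-topology template onto each
specimen in three stages:

1. closed-form landmark similarity alignment (rotation, translation,
   uniform scale; reflections forbidden),
2. rigid ICP refinement against the specimen surface,
3. Laplacian-regularized non-rigid fitting, minimizing

   E(v) = w_sm ||L (v - v0)||^2 + w_lm sum_a ||v_a - l_a||^2
        + w_d sum_i ||v_i - c(v_i)||^2

   over template vertex positions ``v``, where ``L`` is the row-normalized
   uniform graph Laplacian of the template, ``v0`` the rigidly aligned
   template vertices, ``l_a`` the specimen landmarks and ``c(v_i)`` the
   current closest point on the specimen surface. Each outer iteration
   refreshes the closest points and lowers the smoothness weight
   (coarse-to-fine), and solves a sparse linear system.

The result is a :class:`HomologousModel`: template topology, specimen
geometry, with every vertex index denoting the same surface locus across
all specimens fitted to the same template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import SurfaceQuery
from .mesh import LandmarkSet, SimilarityTransform, TriMesh

if TYPE_CHECKING:  # pragma: no cover
    from .template import Template

__all__ = [
    "FitParams",
    "HomologousModel",
    "ConvergenceError",
    "landmark_similarity_align",
    "icp_rigid",
    "nonrigid_fit",
    "fit_residual",
]


class ConvergenceError(RuntimeError):
    """Raised when the non-rigid fit residual diverges."""


@dataclass
class FitParams:
    """Weights and schedules of the three-stage fit.

    ``smoothness_schedule`` must be non-increasing (coarse-to-fine); its
    length sets the number of outer iterations. Weights are relative —
    the data term is per-vertex, the landmark term per-landmark.
    """

    smoothness_schedule: tuple[float, ...] = (100.0, 10.0, 1.0, 0.1)
    landmark_weight: float = 10.0
    data_weight: float = 1.0
    icp_max_iter: int = 60
    icp_tol: float = 1e-5          # mm, mean-residual change
    outlier_factor: float = 5.0    # drop pairs beyond this multiple of median

    def __post_init__(self):
        sched = tuple(float(w) for w in self.smoothness_schedule)
        if any(w < 0 for w in sched) or self.landmark_weight < 0 or self.data_weight < 0:
            raise ValueError("weights must be non-negative")
        if any(b > a for a, b in zip(sched, sched[1:])):
            raise ValueError("smoothness schedule must be non-increasing")
        self.smoothness_schedule = sched


@dataclass
class HomologousModel:
    """Template-topology mesh fitted onto one specimen.

    ``faces`` is shared with the template (not copied per instance); the
    fit residual is the mean directed vertex-to-target-surface distance.
    """

    vertices: np.ndarray
    faces: np.ndarray
    source_id: str = ""
    group: int | None = None
    residual_mean: float = np.nan
    residual_sd: float = np.nan

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if not np.isnan(self.residual_mean) and self.residual_mean < 0:
            raise ValueError("fit residual must be non-negative")

    @property
    def mesh(self) -> TriMesh:
        return TriMesh(self.vertices, self.faces, name=self.source_id)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def flat(self) -> np.ndarray:
        """Row vector of stacked x, y, z coordinates (length 3V)."""
        return self.vertices.reshape(-1)


# ---------------------------------------------------------------------------
# Closed-form similarity alignment (Umeyama)
# ---------------------------------------------------------------------------

def similarity_from_correspondences(
    source: np.ndarray, target: np.ndarray, with_scale: bool = True
) -> SimilarityTransform:
    """Least-squares similarity transform mapping paired source points to
    target points, reflections forbidden."""
    src = np.asarray(source, dtype=np.float64)
    tgt = np.asarray(target, dtype=np.float64)
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    xs = src - mu_s
    xt = tgt - mu_t
    cov = xt.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if with_scale:
        var_s = (xs**2).sum() / len(src)
        scale = float((D * np.diag(S)).sum() / var_s)
    else:
        scale = 1.0
    t = mu_t - scale * R @ mu_s
    return SimilarityTransform(R, t, scale)


def landmark_similarity_align(
    source_lms: LandmarkSet, target_lms: LandmarkSet, with_scale: bool = True
) -> SimilarityTransform:
    """Similarity transform minimizing the summed squared distance between
    shared landmarks. Requires >= 3 shared, non-collinear names."""
    names = source_lms.shared_names(target_lms)
    if len(names) < 3:
        raise ValueError(f"need >= 3 shared landmarks, have {len(names)}")
    src = source_lms.subset(names)
    tgt = target_lms.subset(names)
    # collinearity check on the source configuration
    c = src - src.mean(axis=0)
    if np.linalg.matrix_rank(c, tol=1e-9 * max(1.0, np.abs(c).max())) < 2:
        raise ValueError("landmark configuration is collinear (degenerate)")
    return similarity_from_correspondences(src, tgt, with_scale=with_scale)


# ---------------------------------------------------------------------------
# Rigid ICP
# ---------------------------------------------------------------------------

def icp_rigid(
    moving: TriMesh,
    fixed: TriMesh,
    init: SimilarityTransform | None = None,
    params: FitParams | None = None,
    with_scale: bool = False,
) -> SimilarityTransform:
    """Iterative closest point, moving-vertex -> fixed-surface pairing with
    closed-form updates. Scale is held at the initial value unless
    ``with_scale``. The mean residual is non-increasing across iterations.
    """
    if moving.n_faces == 0 or fixed.n_faces == 0:
        raise ValueError("ICP requires non-empty meshes")
    params = params or FitParams()
    t = init or SimilarityTransform.identity()
    query = SurfaceQuery(fixed)
    src = moving.vertices
    prev = np.inf
    for _ in range(params.icp_max_iter):
        cur = t.apply(src)
        closest, dist, _ = query.closest(cur)
        mean_res = float(dist.mean())
        if not np.isfinite(mean_res):
            raise ConvergenceError("non-finite ICP residual")
        if prev - mean_res < params.icp_tol:
            break
        prev = mean_res
        if with_scale:
            t = similarity_from_correspondences(src, closest, with_scale=True)
        else:
            # keep the similarity scale from the initial alignment
            t = _rigid_at_scale(src, closest, t.scale)
    return t


def _rigid_at_scale(src: np.ndarray, tgt: np.ndarray, scale: float) -> SimilarityTransform:
    """Best R, t for y ~ scale * R x + t with the scale held fixed."""
    base = similarity_from_correspondences(src, tgt, with_scale=False)
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    t = mu_t - scale * base.rotation @ mu_s
    return SimilarityTransform(base.rotation, t, scale)


# ---------------------------------------------------------------------------
# Non-rigid template fitting
# ---------------------------------------------------------------------------

def _uniform_laplacian(mesh: TriMesh) -> sp.csr_matrix:
    """Row-normalized combinatorial Laplacian: L v = v_i - mean(neighbours)."""
    e = mesh.edges()
    e = np.unique(e, axis=0)
    V = mesh.n_vertices
    i = np.concatenate([e[:, 0], e[:, 1]])
    j = np.concatenate([e[:, 1], e[:, 0]])
    A = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(V, V)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    Dinv = sp.diags(1.0 / deg)
    return (sp.eye(V) - Dinv @ A).tocsr()


def landmark_vertex_indices(mesh: TriMesh, lms: LandmarkSet) -> np.ndarray:
    """Nearest mesh vertex to each landmark (coarse landmark transfer)."""
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.vertices)
    _, idx = tree.query(lms.points)
    return np.asarray(idx, dtype=np.int64)


def landmark_embedding(mesh: TriMesh, points: np.ndarray) -> sp.csr_matrix:
    """Barycentric embedding of surface points into mesh vertices.

    Returns a sparse (n_points, V) matrix B with three barycentric weights
    per row, such that ``B @ vertices`` reproduces each point's closest
    surface location; applied to a homologous model's vertices it
    transfers the landmark to the corresponding locus. Snapping to the
    nearest vertex instead would be off by up to half an edge length,
    which distorts landmark-guided fits near every landmark.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    cp, _, tri_idx = SurfaceQuery(mesh).closest(points)
    tris = mesh.faces[tri_idx]
    a, b, c = (mesh.vertices[tris[:, k]] for k in range(3))
    # barycentric coordinates of cp in (a, b, c)
    v0, v1, v2 = b - a, c - a, cp - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01**2
    denom[denom == 0] = 1.0
    w_b = (d11 * d20 - d01 * d21) / denom
    w_c = (d00 * d21 - d01 * d20) / denom
    w_a = 1.0 - w_b - w_c
    n = len(points)
    rows = np.repeat(np.arange(n), 3)
    cols = tris.ravel()
    vals = np.column_stack([w_a, w_b, w_c]).ravel()
    return sp.coo_matrix((vals, (rows, cols)),
                         shape=(n, mesh.n_vertices)).tocsr()


def nonrigid_fit(
    template: "Template",
    target: TriMesh,
    target_lms: LandmarkSet,
    params: FitParams | None = None,
    source_id: str | None = None,
    group: int | None = None,
) -> HomologousModel:
    """Fit the template onto a target surface, producing a homologous model.

    See the module docstring for the energy. Raises ``ConvergenceError``
    if the mean residual diverges across outer iterations, and
    ``ValueError`` if all weights are zero (singular system).
    """
    params = params or FitParams()
    if params.data_weight == 0 and params.landmark_weight == 0 and \
            all(w == 0 for w in params.smoothness_schedule):
        raise ValueError("all weights zero: singular system")
    tmesh = template.mesh
    tlms = template.landmarks
    names = tlms.shared_names(target_lms)
    if len(names) < 3:
        raise ValueError("template and target share fewer than 3 landmarks")
    if not target.is_watertight:
        import warnings

        warnings.warn(f"target {target.name!r} is not watertight; directed "
                      "residuals may be optimistic", stacklevel=2)

    sim = landmark_similarity_align(tlms, target_lms)
    rigid = icp_rigid(tmesh, target, init=sim, params=params)
    v0 = rigid.apply(tmesh.vertices)

    lm_pos = target_lms.subset(names)
    S = landmark_embedding(tmesh, tlms.subset(names))

    L = _uniform_laplacian(tmesh)
    LtL = (L.T @ L).tocsc()
    StS = (S.T @ S).tocsc()
    St_l = S.T @ lm_pos

    query = SurfaceQuery(target)
    target_face_normals = target.face_normals()
    initial_res = float(query.distances(v0).mean())
    # initialization: landmark-harmonic warp of the rigid alignment.
    # Starting the closest-point loop from the raw rigid pose would let the
    # (tangentially blind) data term freeze the template's tangential
    # positions before the landmark field has propagated.
    w0 = params.smoothness_schedule[0] if params.smoothness_schedule else 1.0
    if params.landmark_weight > 0 and w0 > 0:
        A0 = (w0 * LtL + params.landmark_weight * StS).tocsc()
        rhs0 = w0 * (LtL @ v0) + params.landmark_weight * St_l
        lu0 = splu(A0)
        v = np.column_stack([lu0.solve(rhs0[:, k]) for k in range(3)])
    else:
        v = v0.copy()
    prev_res = np.inf
    for w_sm in params.smoothness_schedule:
        closest, dist, tri_idx = query.closest(v)
        med = np.median(dist)
        keep = dist <= params.outlier_factor * max(med, 1e-12)
        # normal-compatibility guard: on thin structures the closest point
        # can lie on the far side; drop pairs whose surface normals oppose
        cur_normals = TriMesh(v, tmesh.faces).vertex_normals()
        compat = np.einsum("ij,ij->i", cur_normals,
                           target_face_normals[tri_idx]) > 0.0
        keep &= compat
        W = sp.diags(keep.astype(float)).tocsc()
        A = (w_sm * LtL + params.landmark_weight * StS
             + params.data_weight * W).tocsc()
        rhs = (w_sm * (LtL @ v0) + params.landmark_weight * St_l
               + params.data_weight * (W @ closest))
        lu = splu(A)
        v = np.column_stack([lu.solve(rhs[:, k]) for k in range(3)])
        res = float(query.distances(v).mean())
        if not np.isfinite(res):
            raise ConvergenceError("non-finite residual in non-rigid fit")
        # divergence guard; fluctuation below 1e-4 of the target size is
        # numeric noise, not divergence
        if (res > 2.0 * max(initial_res, prev_res)
                and res > 1e-4 * target.bbox_diagonal):
            raise ConvergenceError(
                f"residual diverged: {res:.4g} mm after outer iteration "
                f"(was {prev_res:.4g} mm)"
            )
        prev_res = res

    dist = query.distances(v)
    return HomologousModel(
        vertices=v,
        faces=tmesh.faces,
        source_id=source_id if source_id is not None else target.name,
        group=group,
        residual_mean=float(dist.mean()),
        residual_sd=float(dist.std(ddof=1)) if len(dist) > 1 else 0.0,
    )


def fit_residual(model: HomologousModel, target: TriMesh) -> tuple[float, float]:
    """Mean and SD (mm) over all vertices of the directed vertex-to-surface
    distance from the homologous model to the target."""
    if model.n_vertices == 0 or target.n_faces == 0:
        raise ValueError("empty inputs")
    d = SurfaceQuery(target).distances(model.vertices)
    return float(d.mean()), float(d.std(ddof=1)) if len(d) > 1 else 0.0
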