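"""Template construction and the anterior-pelvic-plane coordinate frame.

The template is a symmetric, isotropically remeshed average of a small set
of specimens, expressed in the anterior pelvic plane (APP) frame: origin at
the midpoint of the two anterior-superior landmarks, +X from the right to
the left anterior-superior landmark, the plane through those two points and
a midline anterior-inferior landmark is the X-Z (coronal) plane with +Z
superior, and +Y anterior (right-handed).

``remesh_isotropic`` is an explicit incremental remesher (edge split /
collapse / flip, tangential smoothing, projection back onto the input
surface) that targets a vertex count and near-uniform edge lengths while
keeping the surface within a small fraction of the bounding-box diagonal
of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .geometry import SurfaceQuery
from .mesh import (
    LandmarkSet,
    SimilarityTransform,
    TriMesh,
    read_landmarks,
    read_mesh,
    write_landmarks,
    write_mesh,
)

__all__ = [
    "Template",
    "place_in_app",
    "symmetrize",
    "remesh_isotropic",
    "build_template",
    "symmetry_residual",
    "APP_LANDMARKS",
]

#: default schema names defining the APP frame:
#: (left anterior-superior, right anterior-superior, midline anterior-inferior)
APP_LANDMARKS = ("L_ASIS", "R_ASIS", "PS")


@dataclass
class Template:
    """Fixed-topology reference mesh with landmarks on its surface."""

    mesh: TriMesh
    landmarks: LandmarkSet
    frame: str = "APP"
    provenance: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices

    def save(self, prefix) -> None:
        """Persist as PLY + landmark CSV + YAML provenance."""
        prefix = Path(prefix)
        write_mesh(self.mesh, prefix.with_suffix(".ply"))
        write_landmarks(self.landmarks, prefix.parent / (prefix.name + ".landmarks.csv"))
        meta = {"frame": self.frame, "n_vertices": self.mesh.n_vertices,
                **self.provenance}
        (prefix.parent / (prefix.name + ".yaml")).write_text(
            yaml.safe_dump(meta, sort_keys=True)
        )

    @classmethod
    def load(cls, prefix, schema: dict | None = None) -> "Template":
        prefix = Path(prefix)
        mesh = read_mesh(prefix.with_suffix(".ply"))
        lms = read_landmarks(prefix.parent / (prefix.name + ".landmarks.csv"), schema)
        meta_path = prefix.parent / (prefix.name + ".yaml")
        meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
        return cls(mesh, lms, frame=meta.pop("frame", "APP"), provenance=meta)


# ---------------------------------------------------------------------------
# APP frame
# ---------------------------------------------------------------------------

def app_transform(landmarks: LandmarkSet,
                  schema: Sequence[str] = APP_LANDMARKS) -> SimilarityTransform:
    """Rigid transform carrying world coordinates into the APP frame."""
    left, right, mid = schema
    for n in schema:
        if n not in landmarks:
            raise ValueError(f"APP landmark {n!r} missing")
    L, R, M = landmarks[left], landmarks[right], landmarks[mid]
    origin = 0.5 * (L + R)
    x = L - R
    nx = np.linalg.norm(x)
    w = M - origin
    if nx == 0:
        raise ValueError("degenerate frame: coincident anterior-superior landmarks")
    x = x / nx
    u = w - (w @ x) * x
    nu = np.linalg.norm(u)
    if nu < 1e-9 * max(nx, 1.0):
        raise ValueError("degenerate frame: collinear APP landmarks")
    z = -u / nu          # the midline landmark is inferior
    y = np.cross(z, x)   # right-handed, +Y anterior
    R_frame = np.column_stack([x, y, z])  # world axes of the APP frame
    # p_app = R_frame^T (p - origin)
    return SimilarityTransform(R_frame.T, -R_frame.T @ origin, 1.0)


def place_in_app(
    mesh: TriMesh,
    landmarks: LandmarkSet,
    schema: Sequence[str] = APP_LANDMARKS,
) -> tuple[TriMesh, LandmarkSet, SimilarityTransform]:
    """Express a mesh and its landmarks in the APP frame.

    Idempotent: input already in the APP frame maps through the identity.
    """
    t = app_transform(landmarks, schema)
    return (
        mesh.with_vertices(t.apply(mesh.vertices)),
        landmarks.with_points(t.apply(landmarks.points)),
        t,
    )


# ---------------------------------------------------------------------------
# Symmetrization
# ---------------------------------------------------------------------------

def _reflected(mesh: TriMesh) -> TriMesh:
    v = mesh.vertices * np.array([-1.0, 1.0, 1.0])
    return TriMesh(v, mesh.faces[:, ::-1], mesh.name)


def symmetry_residual(mesh: TriMesh) -> float:
    """Mean distance (mm) from vertices to the x-reflected surface."""
    return float(SurfaceQuery(_reflected(mesh)).distances(mesh.vertices).mean())


def symmetrize(mesh: TriMesh, landmarks: LandmarkSet | None = None):
    """Average the shape with its x = 0 mirror image.

    Each vertex moves halfway to its nearest point on the reflected
    surface; paired landmarks become exact mirror images and midline
    landmarks land on x = 0. Raises if reflection correspondence fails
    (>10% of vertices farther than 10% of the diagonal).
    """
    diag = mesh.bbox_diagonal
    cp, dist, _ = SurfaceQuery(_reflected(mesh)).closest(mesh.vertices)
    if np.mean(dist > 0.10 * diag) > 0.10:
        raise ValueError("reflection correspondence failed: shape too asymmetric")
    out = mesh.with_vertices(0.5 * (mesh.vertices + cp))
    if landmarks is None:
        return out
    pts = landmarks.points.copy()
    mirror = np.array([-1.0, 1.0, 1.0])
    for Lname, Rname in landmarks.pairs.items():
        li, ri = landmarks.index(Lname), landmarks.index(Rname)
        avg = 0.5 * (pts[li] + pts[ri] * mirror)
        pts[li] = avg
        pts[ri] = avg * mirror
    for m in landmarks.midline:
        mi = landmarks.index(m)
        pts[mi] = 0.5 * (pts[mi] + pts[mi] * mirror)  # x -> 0
    return out, landmarks.with_points(pts)


# ---------------------------------------------------------------------------
# Isotropic remeshing
# ---------------------------------------------------------------------------

def _edge_faces_map(faces: np.ndarray) -> dict[tuple[int, int], list[int]]:
    em: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            em.setdefault((min(u, v), max(u, v)), []).append(fi)
    return em


def _split_long_edges(verts: list, faces: np.ndarray, max_len: float) -> np.ndarray:
    """One pass: insert midpoints on edges longer than ``max_len`` and
    retriangulate the incident faces."""
    V = np.asarray(verts)
    midpoint: dict[tuple[int, int], int] = {}
    lengths = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (min(u, v), max(u, v))
            if key not in lengths:
                lengths[key] = np.linalg.norm(V[key[0]] - V[key[1]])
    for key, ln in lengths.items():
        if ln > max_len:
            midpoint[key] = len(verts)
            verts.append(0.5 * (V[key[0]] + V[key[1]]))
    if not midpoint:
        return faces
    new_faces = []
    for a, b, c in faces:
        m_ab = midpoint.get((min(a, b), max(a, b)))
        m_bc = midpoint.get((min(b, c), max(b, c)))
        m_ca = midpoint.get((min(c, a), max(c, a)))
        n_split = sum(m is not None for m in (m_ab, m_bc, m_ca))
        if n_split == 0:
            new_faces.append((a, b, c))
        elif n_split == 3:
            new_faces += [(a, m_ab, m_ca), (b, m_bc, m_ab), (c, m_ca, m_bc),
                          (m_ab, m_bc, m_ca)]
        elif n_split == 1:
            if m_ab is not None:
                new_faces += [(a, m_ab, c), (m_ab, b, c)]
            elif m_bc is not None:
                new_faces += [(b, m_bc, a), (m_bc, c, a)]
            else:
                new_faces += [(c, m_ca, b), (m_ca, a, b)]
        else:  # two edges split: connect the two midpoints, then the quad
            if m_ab is None:
                new_faces += [(b, m_bc, m_ca), (m_bc, c, m_ca), (a, b, m_ca)]
            elif m_bc is None:
                new_faces += [(c, m_ca, m_ab), (m_ca, a, m_ab), (b, c, m_ab)]
            else:
                new_faces += [(a, m_ab, m_bc), (m_ab, b, m_bc), (c, a, m_bc)]
    return np.array(new_faces, dtype=np.int64)


def _vertex_adjacency(faces: np.ndarray, n_verts: int) -> list[set]:
    adj: list[set] = [set() for _ in range(n_verts)]
    for a, b, c in faces:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    return adj


def _collapse_short_edges(verts: np.ndarray, faces: np.ndarray,
                          min_len: float, max_len: float):
    """One pass of greedy edge collapses honouring the link condition."""
    adj = _vertex_adjacency(faces, len(verts))
    em = _edge_faces_map(faces)
    v2f: list[list[int]] = [[] for _ in range(len(verts))]
    for fi, f in enumerate(faces):
        for v in f:
            v2f[v].append(fi)
    order = sorted(
        (np.linalg.norm(verts[a] - verts[b]), a, b)
        for (a, b) in em.keys()
    )
    alive = np.ones(len(verts), dtype=bool)
    remap = np.arange(len(verts))
    touched = np.zeros(len(verts), dtype=bool)
    for ln, a, b in order:
        if ln >= min_len:
            break
        if touched[a] or touched[b] or not (alive[a] and alive[b]):
            continue
        # link condition: common neighbours must be exactly the two
        # opposite vertices of the edge's incident faces
        common = adj[a] & adj[b]
        opposite = set()
        for fi in em[(min(a, b), max(a, b))]:
            opposite.update(set(faces[fi]) - {a, b})
        if common != opposite or len(em[(min(a, b), max(a, b))]) != 2:
            continue
        mid = 0.5 * (verts[a] + verts[b])
        # reject collapses that would create over-long edges
        others = (adj[a] | adj[b]) - {a, b}
        if any(np.linalg.norm(verts[v] - mid) > max_len for v in others):
            continue
        # reject collapses that would flatten a surviving face to zero area
        removed = set(em[(min(a, b), max(a, b))])
        degenerate = False
        for fi in set(v2f[a]) | set(v2f[b]):
            if fi in removed:
                continue
            p = [mid if v in (a, b) else verts[v] for v in faces[fi]]
            if np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])) == 0.0:
                degenerate = True
                break
        if degenerate:
            continue
        verts[a] = mid
        alive[b] = False
        remap[b] = a
        for v in adj[b]:
            adj[v].discard(b)
            if v != a:
                adj[v].add(a)
                adj[a].add(v)
        adj[a].discard(a)
        touched[a] = True
        for v in others:
            touched[v] = True
    faces = remap[faces]
    keep = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & \
           (faces[:, 0] != faces[:, 2])
    faces = faces[keep]
    # compact vertex array
    used = np.zeros(len(verts), dtype=bool)
    used[faces.ravel()] = True
    new_index = np.cumsum(used) - 1
    return verts[used], new_index[faces]


def _flip_edges(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip interior edges when doing so brings vertex valences closer
    to the regular value of 6."""
    faces = faces.copy()
    em = _edge_faces_map(faces)
    adj = _vertex_adjacency(faces, len(verts))
    valence = np.array([len(s) for s in adj])
    dirty = np.zeros(len(faces), dtype=bool)
    for (a, b), fis in em.items():
        if len(fis) != 2:
            continue
        f0, f1 = fis
        if dirty[f0] or dirty[f1]:
            continue
        c = next(v for v in faces[f0] if v not in (a, b))
        d = next(v for v in faces[f1] if v not in (a, b))
        if c == d or d in adj[c]:
            continue
        before = sum((valence[v] - 6) ** 2 for v in (a, b, c, d))
        # valence after flip: a, b lose one; c, d gain one
        after = ((valence[a] - 1 - 6) ** 2 + (valence[b] - 1 - 6) ** 2
                 + (valence[c] + 1 - 6) ** 2 + (valence[d] + 1 - 6) ** 2)
        if after >= before:
            continue
        # reject geometrically degenerate results (zero-area triangles
        # would be dropped downstream, opening holes)
        n1 = np.cross(verts[d] - verts[a], verts[c] - verts[a])
        n2 = np.cross(verts[c] - verts[b], verts[d] - verts[b])
        if np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
            continue
        # rebuild the two faces preserving orientation of f0 (a->b becomes
        # the flipped diagonal c->d)
        t0 = list(faces[f0])
        i = t0.index(a)
        a_then_b = t0[(i + 1) % 3] == b
        if a_then_b:
            faces[f0] = (a, d, c)
            faces[f1] = (b, c, d)
        else:
            faces[f0] = (a, c, d)
            faces[f1] = (b, d, c)
        dirty[f0] = dirty[f1] = True
        valence[a] -= 1
        valence[b] -= 1
        valence[c] += 1
        valence[d] += 1
        adj[c].add(d)
        adj[d].add(c)
        adj[a].discard(b)
        adj[b].discard(a)
    return faces


def _tangential_smooth(mesh: TriMesh, query: SurfaceQuery,
                       lam: float = 0.6) -> TriMesh:
    adj = _vertex_adjacency(mesh.faces, mesh.n_vertices)
    v = mesh.vertices
    centroid = np.array([v[list(s)].mean(axis=0) if s else v[i]
                         for i, s in enumerate(adj)])
    normals = mesh.vertex_normals()
    d = centroid - v
    d -= np.einsum("ij,ij->i", d, normals)[:, None] * normals  # tangential part
    moved = v + lam * d
    projected, _, _ = query.closest(moved)
    # projection may flatten a sliver triangle to exactly zero area, which
    # TriMesh would drop, opening a hole; fall back per-vertex if so
    cand = projected
    for fallback in (moved, v):
        tri = cand[mesh.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        bad = areas == 0.0
        if not bad.any():
            break
        bad_verts = np.unique(mesh.faces[bad])
        cand = cand.copy()
        cand[bad_verts] = fallback[bad_verts]
    return mesh.with_vertices(cand)


def edge_length_cv(mesh: TriMesh) -> float:
    e = np.unique(mesh.edges(), axis=0)
    ln = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    return float(ln.std() / ln.mean())


def remesh_isotropic(mesh: TriMesh, target_vertex_count: int,
                     n_iter: int = 4, max_outer: int = 8) -> TriMesh:
    """Remesh a watertight surface to near-uniform edge length.

    The target edge length is set from the surface area and the requested
    vertex count, then adjusted until the output count is within +-5% of
    the target. All vertices are re-projected onto the input surface each
    iteration, so the output stays within a small fraction of the
    bounding-box diagonal of the input.
    """
    if target_vertex_count < 100:
        raise ValueError("target vertex count must be >= 100")
    if not mesh.is_watertight:
        raise ValueError("isotropic remeshing requires a watertight input")
    query = SurfaceQuery(mesh)
    from .mesh import triangle_areas

    area = float(triangle_areas(mesh.vertices, mesh.faces).sum())
    # equilateral tiling: F ~ 2V, each triangle (sqrt(3)/4) l^2
    target_len = float(np.sqrt(2.0 * area / (np.sqrt(3.0) * target_vertex_count)))
    out = mesh
    for outer in range(max_outer):
        cur = out
        for _ in range(n_iter):
            verts = list(cur.vertices)
            faces = _split_long_edges(verts, cur.faces, 4.0 / 3.0 * target_len)
            verts, faces = _collapse_short_edges(
                np.asarray(verts, dtype=np.float64), faces,
                0.8 * target_len, 4.0 / 3.0 * target_len)
            faces = _flip_edges(verts, faces)
            cur = TriMesh(verts, faces, mesh.name)
            cur = _tangential_smooth(cur, query)
        ratio = cur.n_vertices / target_vertex_count
        out = cur
        if abs(ratio - 1.0) <= 0.04:
            break
        target_len *= np.sqrt(ratio)
    return out


# ---------------------------------------------------------------------------
# Template building
# ---------------------------------------------------------------------------

def project_landmarks_to_surface(lms: LandmarkSet, mesh: TriMesh) -> LandmarkSet:
    cp, _, _ = SurfaceQuery(mesh).closest(lms.points)
    return lms.with_points(cp)


def build_template(
    specimens: Sequence[tuple[TriMesh, LandmarkSet]],
    reference_index: int = 0,
    target_vertex_count: int = 2000,
    fit_params=None,
    app_schema: Sequence[str] = APP_LANDMARKS,
) -> Template:
    """Build the symmetric template from a set of specimens.

    Pipeline: place every specimen in the APP frame; non-rigidly fit the
    reference specimen onto each of the others to obtain homologous vertex
    sets; average them; symmetrize; remesh isotropically to the target
    count; project the averaged landmarks back onto the template surface.
    """
    from .registration import nonrigid_fit  # deferred: circular import

    if len(specimens) < 1:
        raise ValueError("need at least one specimen")
    placed = [place_in_app(m, l, app_schema)[:2] for m, l in specimens]
    ref_mesh, ref_lms = placed[reference_index]
    pseudo = Template(ref_mesh, ref_lms, frame="APP")

    fitted = []
    for i, (m, l) in enumerate(placed):
        if i == reference_index:
            fitted.append(ref_mesh.vertices)
            continue
        try:
            hm = nonrigid_fit(pseudo, m, l, params=fit_params, source_id=m.name)
        except Exception as exc:
            raise RuntimeError(f"template fit failed on specimen {m.name!r}: {exc}") from exc
        fitted.append(hm.vertices)
    mean_vertices = np.mean(fitted, axis=0)
    mean_lms = placed[0][1].with_points(
        np.mean([l.points for _, l in placed], axis=0)
    )
    avg = TriMesh(mean_vertices, ref_mesh.faces, name="template")
    sym_mesh, sym_lms = symmetrize(avg, mean_lms)
    remeshed = remesh_isotropic(sym_mesh, target_vertex_count)
    lms_on_surface = project_landmarks_to_surface(sym_lms, remeshed)
    res = symmetry_residual(remeshed)
    return Template(
        remeshed,
        lms_on_surface,
        frame="APP",
        provenance={
            "source_ids": [m.name for m, _ in specimens],
            "reference_index": int(reference_index),
            "target_vertex_count": int(target_vertex_count),
            "symmetry_residual_mm": float(res),
        },
    )
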