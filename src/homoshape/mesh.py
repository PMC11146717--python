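"""Triangle-mesh and landmark data types with file I/O.

Coordinates are always millimetres. Meshes are plain vertex/face arrays;
``TriMesh`` validates topology on construction (face indices in range, no
zero-area triangles) and can report watertightness from edge counts.
Supported formats: STL (binary and ASCII, triangle soup welded on read),
PLY (ASCII) and OBJ (triangles only). Landmarks travel as a name -> point
mapping read from CSV, with an optional side-car symmetry schema (YAML)
naming left/right pairs and midline points.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TriMesh",
    "LandmarkSet",
    "SimilarityTransform",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_symmetry_schema",
]


class MeshFormatError(ValueError):
    """Raised for malformed or unsupported mesh files."""


def _as_points(a) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 1:
        a = a.reshape(1, 3)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected (n, 3) point array, got shape {a.shape}")
    return a


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = vertices[faces]
    return 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
    )


class TriMesh:
    """Triangle surface mesh with vertices in mm.

    Parameters
    ----------
    vertices : (V, 3) float array
    faces : (F, 3) int array
        Vertex indices per triangle. Out-of-range indices raise; triangles
        with exactly zero area are dropped on construction.
    name : str
        Identifier carried through the pipeline (specimen id).
    """

    def __init__(self, vertices, faces, name: str = ""):
        self.vertices = _as_points(vertices)
        faces = np.asarray(faces, dtype=np.int64)
        if faces.size == 0:
            faces = faces.reshape(0, 3)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if faces.size and (faces.min() < 0 or faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")
        if faces.size:
            faces = faces[triangle_areas(self.vertices, faces) > 0.0]
        self.faces = faces
        self.name = name

    # -- basic geometry -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bbox_diagonal(self) -> float:
        if self.n_vertices == 0:
            return 0.0
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def edges(self, directed: bool = False) -> np.ndarray:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        if directed:
            return e
        return np.sort(e, axis=1)

    @property
    def is_watertight(self) -> bool:
        """True iff every undirected edge is shared by exactly two faces."""
        if self.n_faces == 0:
            return False
        e = self.edges()
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    @property
    def is_consistently_oriented(self) -> bool:
        """True iff no directed edge is repeated (each edge traversed once
        in each direction by its two incident faces)."""
        e = self.edges(directed=True)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 1))

    def signed_volume(self) -> float:
        v = self.vertices[self.faces]
        return float(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2])) / 6.0)

    def face_normals(self) -> np.ndarray:
        v = self.vertices[self.faces]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals."""
        v = self.vertices[self.faces]
        fn = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])  # area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    def copy(self, name: str | None = None) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(),
                       self.name if name is None else name)

    def with_vertices(self, vertices, name: str | None = None) -> "TriMesh":
        """Same topology, new vertex positions."""
        return TriMesh(vertices, self.faces, self.name if name is None else name)

    def orient_consistently(self) -> "TriMesh":
        """Flip faces so orientation is consistent and, for watertight
        meshes, outward (positive signed volume).

        Raises
        ------
        MeshFormatError
            If the surface is non-orientable.
        """
        faces = _orient_faces(self.faces)
        out = TriMesh(self.vertices, faces, self.name)
        if out.is_watertight and out.signed_volume() < 0:
            out = TriMesh(self.vertices, faces[:, ::-1], self.name)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TriMesh({self.name!r}, V={self.n_vertices}, F={self.n_faces})"


def _orient_faces(faces: np.ndarray) -> np.ndarray:
    """Greedy BFS orientation propagation over face adjacency."""
    F = len(faces)
    if F == 0:
        return faces
    # map undirected edge -> incident faces
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            edge_faces.setdefault(key, []).append(fi)
    out = faces.copy()
    seen = np.zeros(F, dtype=bool)
    for seed in range(F):
        if seen[seed]:
            continue
        seen[seed] = True
        stack = [seed]
        while stack:
            fi = stack.pop()
            f = out[fi]
            dir_edges = {(f[0], f[1]), (f[1], f[2]), (f[2], f[0])}
            for a, b in list(dir_edges):
                key = (min(a, b), max(a, b))
                for fj in edge_faces[key]:
                    if fj == fi:
                        continue
                    g = out[fj]
                    g_edges = {(g[0], g[1]), (g[1], g[2]), (g[2], g[0])}
                    # consistent neighbours traverse the edge opposite ways
                    same_dir = (a, b) in g_edges
                    if not seen[fj]:
                        if same_dir:
                            out[fj] = g[::-1]
                        seen[fj] = True
                        stack.append(fj)
                    elif same_dir:
                        raise MeshFormatError("non-orientable mesh")
    return out


# ---------------------------------------------------------------------------
# Similarity transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityTransform:
    """y = scale * R @ x + translation, with det(R) = +1 (no reflections)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", float(self.scale))
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        return self.scale * p @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        sinv = 1.0 / self.scale
        return SimilarityTransform(Rinv, -sinv * Rinv @ self.translation, sinv)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``other`` first,
        then ``self``."""
        R = self.rotation @ other.rotation
        s = self.scale * other.scale
        t = self.scale * self.rotation @ other.translation + self.translation
        return SimilarityTransform(R, t, s)

    def as_params(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "scale": self.scale,
        }


def apply_transform(obj, t: SimilarityTransform):
    """Apply a similarity transform to a TriMesh, LandmarkSet or point array."""
    if isinstance(obj, TriMesh):
        return obj.with_vertices(t.apply(obj.vertices))
    if isinstance(obj, LandmarkSet):
        return obj.with_points(t.apply(obj.points))
    return t.apply(np.asarray(obj, dtype=np.float64))


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

class LandmarkSet:
    """Ordered mapping of landmark name -> 3D point (mm).

    ``pairs`` maps left-side names to right-side names; ``midline`` lists
    names expected on the sagittal midplane. Both are optional schema
    metadata used by symmetrization and angle measurement.
    """

    def __init__(
        self,
        names: Sequence[str],
        points,
        pairs: Mapping[str, str] | None = None,
        midline: Iterable[str] | None = None,
    ):
        self.names = list(names)
        self.points = _as_points(points)
        if len(self.names) != len(self.points):
            raise ValueError("names and points length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        self.pairs = dict(pairs or {})
        self.midline = list(midline or [])
        known = set(self.names)
        for L, R in self.pairs.items():
            if L not in known or R not in known:
                raise ValueError(f"symmetry pair ({L}, {R}) references unknown landmark")
        for m in self.midline:
            if m not in known:
                raise ValueError(f"midline landmark {m!r} unknown")
        self._index = {n: i for i, n in enumerate(self.names)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[float]], **kw) -> "LandmarkSet":
        return cls(list(d.keys()), np.array(list(d.values()), dtype=np.float64), **kw)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[self._index[name]]

    def index(self, name: str) -> int:
        return self._index[name]

    def subset(self, names: Sequence[str]) -> np.ndarray:
        return self.points[[self._index[n] for n in names]]

    def shared_names(self, other: "LandmarkSet") -> list[str]:
        return [n for n in self.names if n in other]

    def with_points(self, points) -> "LandmarkSet":
        return LandmarkSet(self.names, points, self.pairs, self.midline)

    def validate_schema(self, expected_count: int | None = None) -> None:
        if expected_count is not None and len(self) != expected_count:
            raise ValueError(
                f"landmark count {len(self)} != configured schema count {expected_count}"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LandmarkSet({len(self)} landmarks)"


def read_landmarks(path, schema: Mapping | None = None) -> LandmarkSet:
    """Read landmarks from CSV with required header name,x,y,z (mm)."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if not {"name", "x", "y", "z"}.issubset(cols):
        raise ValueError(f"{path}: landmark CSV must have columns name,x,y,z")
    pairs = dict(schema.get("pairs", {})) if schema else None
    midline = schema.get("midline") if schema else None
    return LandmarkSet(
        df["name"].astype(str).tolist(),
        df[["x", "y", "z"]].to_numpy(dtype=np.float64),
        pairs=pairs,
        midline=midline,
    )


def write_landmarks(lms: LandmarkSet, path) -> None:
    df = pd.DataFrame(
        {"name": lms.names, "x": lms.points[:, 0], "y": lms.points[:, 1],
         "z": lms.points[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_symmetry_schema(path) -> dict:
    """Side-car symmetry config: YAML/JSON with keys ``pairs`` (list of
    [left, right] name pairs) and ``midline`` (list of names)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    pairs = {L: R for L, R in cfg.get("pairs", [])}
    return {"pairs": pairs, "midline": list(cfg.get("midline", []))}


# ---------------------------------------------------------------------------
# Mesh file I/O
# ---------------------------------------------------------------------------

def read_mesh(path, fmt: str | None = None) -> TriMesh:
    """Read a triangle mesh from STL, PLY or OBJ.

    STL triangle soups are welded at exact coordinate matches (tolerance
    zero, so topology is deterministic at any scale). Watertight meshes are
    re-oriented consistently outward on read; non-orientable input raises.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "stl":
        verts, faces = _read_stl(path)
    elif fmt == "ply":
        verts, faces = _read_ply(path)
    elif fmt == "obj":
        verts, faces = _read_obj(path)
    else:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    mesh = TriMesh(verts, faces, name=path.stem)
    if mesh.is_watertight and not mesh.is_consistently_oriented:
        mesh = mesh.orient_consistently()
    elif mesh.is_watertight and mesh.signed_volume() < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1], mesh.name)
    return mesh


def write_mesh(mesh: TriMesh, path, fmt: str | None = None, binary: bool = True) -> None:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "stl":
        _write_stl(mesh, path, binary=binary)
    elif fmt == "ply":
        _write_ply(mesh, path)
    elif fmt == "obj":
        _write_obj(mesh, path)
    else:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")


def _weld(tri_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weld an (F, 3, 3) triangle soup at exact coordinate matches."""
    flat = tri_coords.reshape(-1, 3)
    verts, inv = np.unique(flat, axis=0, return_inverse=True)
    faces = inv.reshape(-1, 3)
    return verts, faces


def _read_stl(path: Path) -> tuple[np.ndarray, np.ndarray]:
    raw = path.read_bytes()
    is_ascii = raw[:5] == b"solid"
    if is_ascii:
        # a binary file may still start with "solid": verify parseability
        try:
            text = raw.decode("ascii")
        except UnicodeDecodeError:
            is_ascii = False
    if is_ascii and "facet" in text:
        coords = []
        for line in text.splitlines():
            parts = line.split()
            if parts and parts[0] == "vertex":
                coords.append([float(x) for x in parts[1:4]])
        tri = np.array(coords, dtype=np.float64)
        if tri.size == 0 or len(tri) % 3:
            raise MeshFormatError(f"{path}: malformed ASCII STL")
        return _weld(tri.reshape(-1, 3, 3))
    if len(raw) < 84:
        raise MeshFormatError(f"{path}: truncated binary STL")
    (n_tri,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * n_tri
    if len(raw) < expected:
        raise MeshFormatError(f"{path}: binary STL size mismatch")
    data = np.frombuffer(raw, dtype=np.uint8, count=50 * n_tri, offset=84)
    data = data.reshape(n_tri, 50)
    tri = (
        data[:, 12:48].copy().view("<f4").reshape(n_tri, 3, 3).astype(np.float64)
    )
    return _weld(tri)


def _write_stl(mesh: TriMesh, path: Path, binary: bool = True) -> None:
    tris = mesh.vertices[mesh.faces].astype(np.float32)
    normals = mesh.face_normals().astype(np.float32)
    if binary:
        buf = io.BytesIO()
        buf.write(b"\0" * 80)
        buf.write(struct.pack("<I", len(tris)))
        for n, t in zip(normals, tris):
            buf.write(n.tobytes())
            buf.write(t.tobytes())
            buf.write(b"\0\0")
        path.write_bytes(buf.getvalue())
    else:
        lines = [f"solid {mesh.name or 'mesh'}"]
        for n, t in zip(normals, tris):
            lines.append(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {mesh.name or 'mesh'}\n")
        path.write_text("\n".join(lines))


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path, "rb") as fh:
        header = []
        while True:
            line = fh.readline().decode("ascii").strip()
            header.append(line)
            if line == "end_header":
                break
        if not header or header[0] != "ply":
            raise MeshFormatError(f"{path}: not a PLY file")
        if not any("format ascii" in h for h in header):
            raise MeshFormatError(f"{path}: only ASCII PLY supported")
        n_vert = n_face = 0
        for h in header:
            parts = h.split()
            if parts[:2] == ["element", "vertex"]:
                n_vert = int(parts[2])
            elif parts[:2] == ["element", "face"]:
                n_face = int(parts[2])
        body = fh.read().decode("ascii").split("\n")
    verts = np.array(
        [[float(x) for x in body[i].split()[:3]] for i in range(n_vert)]
    )
    faces = []
    for i in range(n_vert, n_vert + n_face):
        parts = [int(x) for x in body[i].split()]
        if parts[0] != 3:
            raise MeshFormatError(f"{path}: non-triangular PLY face")
        faces.append(parts[1:4])
    return verts, np.array(faces, dtype=np.int64)


def _write_ply(mesh: TriMesh, path: Path) -> None:
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")


def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = [], []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            if len(idx) != 3:
                raise MeshFormatError(f"{path}: non-triangular OBJ face")
            faces.append(idx)
    return np.array(verts, dtype=np.float64), np.array(faces, dtype=np.int64)


def _write_obj(mesh: TriMesh, path: Path) -> None:
    lines = [f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in mesh.vertices]
    lines += [f"f {f[0]+1} {f[1]+1} {f[2]+1}" for f in mesh.faces]
    path.write_text("\n".join(lines) + "\n")
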