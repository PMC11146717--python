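"""Synthetic two-group populations of pelvis-proxy surface meshes.

The study design this package targets — two groups of ~50 watertight bone
surfaces, independently meshed, with named anatomical landmarks — is
emulated here with a fully known ground truth. The base shape is an
implicit surface blending three Gaussian lobes (left/right lateral "coxal"
lobes and a posterior-central "sacral" lobe), bilaterally symmetric about
the x = 0 plane and polygonized by marching cubes. Fifteen named landmarks
are located analytically by intersecting rays from the lobe centres with
the implicit surface (Brent root finding on the field), so their positions
are independent of any mesh.

Shape variation is produced by three smooth, spatially weighted
deformation modes chosen to mirror the kinds of group differences reported
for dysplastic pelves:

* mode A — inclination of the lateral lobes in the coronal plane
  (weighted rotation about the anteroposterior axis, opposite sense on the
  two sides);
* mode B — sagittal rotation of the posterior lobe (sacral-slope analogue);
* mode C — widening/narrowing of the superior part (smoothly weighted
  mediolateral scaling).

Each specimen is polygonized on its own jittered marching-cubes grid, so
no two specimens share vertex count or correspondence: downstream modules
must establish correspondence themselves, as with real CT meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage import measure

from .mesh import LandmarkSet, SimilarityTransform, TriMesh, write_landmarks, write_mesh

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "GenerationError",
    "implicit_field",
    "make_base_shape",
    "base_landmarks",
    "deform_points",
    "mode_displacement",
    "sample_specimen",
    "sample_population",
    "write_population",
    "N_MODES",
    "SYMMETRY_SCHEMA",
]


class GenerationError(RuntimeError):
    """Raised when a requested synthetic shape cannot be generated safely."""


# ---------------------------------------------------------------------------
# Base implicit shape (units: mm; overall extent ~200 mm like an adult pelvis)
# ---------------------------------------------------------------------------

def _mirror_x(gaussians):
    return [(c * np.array([-1.0, 1.0, 1.0]), s, a) for c, s, a in gaussians]


def _fibonacci_directions(n: int, seed_offset: float = 0.35) -> np.ndarray:
    """Deterministic, roughly uniform unit directions (golden spiral)."""
    i = np.arange(n) + seed_offset
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)
    ])


_LEFT_COXAL = [
    # centre (mm), per-axis sigma (mm), amplitude; the main lobe is
    # elongated superoinferiorly (a plate-like wing, not a ball) so that
    # rotations of the lobe produce surface-normal motion and stay
    # geometrically identifiable, as for real coxal bone
    (np.array([55.0, 0.0, 10.0]), np.array([22.0, 20.0, 46.0]), 1.0),
    # sub-structure: ridges/processes that make the surface geometry
    # informative for correspondence (a featureless blob is rotationally
    # ambiguous in a way real bone is not)
    (np.array([62.0, 12.0, 44.0]), np.array([10.0, 9.0, 14.0]), 0.55),   # ant-sup ridge
    (np.array([46.0, -14.0, 48.0]), np.array([12.0, 10.0, 13.0]), 0.5),  # post-sup ridge
    (np.array([62.0, 8.0, -34.0]), np.array([11.0, 10.0, 10.0]), 0.5),   # inf process
    (np.array([40.0, 20.0, -18.0]), np.array([10.0, 9.0, 10.0]), 0.45),  # ant-inf bump
    # bridge arms connecting the three lobes into one body
    (np.array([25.0, 12.0, -16.0]), np.array([17.0, 11.0, 12.0]), 0.6),  # pubic ramus
    (np.array([25.0, -20.0, 34.0]), np.array([15.0, 12.0, 16.0]), 0.55), # SI joint
]
_SACRAL = [
    # plate-like in the anteroposterior direction
    (np.array([0.0, -35.0, 30.0]), np.array([24.0, 17.0, 40.0]), 1.0),
    (np.array([0.0, -44.0, 64.0]), np.array([12.0, 10.0, 12.0]), 0.5),   # sup spine
    (np.array([0.0, -48.0, -8.0]), np.array([10.0, 10.0, 14.0]), 0.45),  # inf spine
]
def _relief(center, sigmas, n, amp, bump_sigma, radius=1.15, offset=0.15):
    """Deterministic surface relief: alternating bumps/dents spread over an
    ellipsoid shell around a lobe. Smooth featureless surfaces make dense
    correspondence ill-posed; real bone carries ridges and fossae that
    registration can lock onto, and the phantom must too for true modes to
    be recoverable."""
    dirs = _fibonacci_directions(n, seed_offset=offset)
    out = []
    for k, d in enumerate(dirs):
        pos = center + radius * sigmas * d
        sign = 1.0 if k % 2 == 0 else -1.0
        out.append((pos, np.full(3, bump_sigma), sign * amp))
    return out


_LEFT_RELIEF = _relief(_LEFT_COXAL[0][0], _LEFT_COXAL[0][1], 14, 0.22, 8.0)
_SACRAL_RELIEF_HALF = [
    (c, s, a) for c, s, a in _relief(_SACRAL[0][0], _SACRAL[0][1], 10, 0.2, 8.0,
                                     offset=0.45)
    if c[0] > 2.0
]
_SACRAL_RELIEF = _SACRAL_RELIEF_HALF + _mirror_x(_SACRAL_RELIEF_HALF)

#: three blended lobes (left coxal, right coxal, sacral), each a cluster
#: of Gaussians plus surface relief
_LOBES = tuple(
    _LEFT_COXAL + _mirror_x(_LEFT_COXAL) + _SACRAL
    + _LEFT_RELIEF + _mirror_x(_LEFT_RELIEF) + _SACRAL_RELIEF
)
_ISO = 0.35
_L_CENTER = _LEFT_COXAL[0][0]
_R_CENTER = _L_CENTER * np.array([-1.0, 1.0, 1.0])
_S_CENTER = _SACRAL[0][0]

# mode geometry: weight-field radii (mm) and raw per-unit amplitudes.
# Raw amplitudes are rescaled at runtime (see _mode_norms) so every mode
# produces exactly 1.0 mm rms surface displacement per unit score; a score
# SD of s then means s mm rms shape variation, and score variances map
# directly onto PCA eigenvalue ratios.
_RHO_LATERAL = 45.0
_RHO_SACRAL = 40.0
_THETA_A = np.deg2rad(1.5)   # coronal lobe rotation per raw unit
_THETA_B = np.deg2rad(1.5)   # sagittal sacral rotation per raw unit
_GAMMA_C = 0.010             # relative mediolateral scaling per raw unit
_Z0_SUP, _TAU_SUP = 30.0, 15.0  # superior-weight sigmoid (mm)
N_MODES = 3

# amplitude bounds beyond which the smooth maps are no longer safely
# injective (checked, not proven; see docs)
_MAX_ROT = np.deg2rad(45.0)
_MAX_SCALE_CHANGE = 0.5


def implicit_field(points: np.ndarray) -> np.ndarray:
    """Blended-lobe scalar field; the surface is the ``field = 0`` level set
    (positive inside)."""
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    val = np.zeros(len(p))
    for c, s, a in _LOBES:
        val += a * np.exp(-0.5 * np.sum(((p - c) / s) ** 2, axis=1))
    return val - _ISO


_RAYS: dict[str, tuple[np.ndarray, np.ndarray]] = {
    # name: (ray origin, direction); landmark = first surface crossing
    "L_ASIS": (_L_CENTER, np.array([0.1, 1.0, 0.25])),
    "R_ASIS": (_R_CENTER, np.array([-0.1, 1.0, 0.25])),
    "L_lateral": (_L_CENTER, np.array([1.0, 0.0, 0.0])),
    "R_lateral": (_R_CENTER, np.array([-1.0, 0.0, 0.0])),
    "L_crest": (_L_CENTER, np.array([0.4, 0.0, 1.0])),
    "R_crest": (_R_CENTER, np.array([-0.4, 0.0, 1.0])),
    "L_teardrop": (_L_CENTER, np.array([-0.25, 0.6, -0.76])),
    "R_teardrop": (_R_CENTER, np.array([0.25, 0.6, -0.76])),
    "L_rim": (_L_CENTER, np.array([0.7, 0.35, -0.62])),
    "R_rim": (_R_CENTER, np.array([-0.7, 0.35, -0.62])),
    "L_ischium": (_L_CENTER, np.array([0.25, -0.3, -0.95])),
    "R_ischium": (_R_CENTER, np.array([-0.25, -0.3, -0.95])),
    "PS": (np.array([0.0, 10.0, -16.0]), np.array([0.0, 1.0, -0.45])),
    "S1_ant": (_S_CENTER, np.array([0.0, 0.5, 0.87])),
    "S1_post": (_S_CENTER, np.array([0.0, -0.5, 0.87])),
}

def _aux_rays() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """43 auxiliary landmarks bringing the schema to 58 points: a spread of
    analytically defined surface points per lobe, emulating the dense
    landmark protocols used with commercial template-fitting tools."""
    rays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for k, d in enumerate(_fibonacci_directions(16)):
        rays[f"L_aux{k:02d}"] = (_L_CENTER, d)
        rays[f"R_aux{k:02d}"] = (_R_CENTER, d * np.array([-1.0, 1.0, 1.0]))
    for k, d in enumerate(_fibonacci_directions(4, seed_offset=0.6)):
        d = d.copy()
        d[0] = abs(d[0]) + 0.2  # keep off-midline
        rays[f"L_sac{k}"] = (_S_CENTER, d)
        rays[f"R_sac{k}"] = (_S_CENTER, d * np.array([-1.0, 1.0, 1.0]))
    for k, ang in enumerate(np.deg2rad([200.0, 250.0, 320.0])):
        # midline sacral points in the sagittal plane
        rays[f"M_sac{k}"] = (_S_CENTER, np.array([0.0, np.cos(ang), np.sin(ang)]))
    return rays


_RAYS.update(_aux_rays())

SYMMETRY_SCHEMA = {
    "pairs": {
        **{
            "L_ASIS": "R_ASIS",
            "L_lateral": "R_lateral",
            "L_crest": "R_crest",
            "L_teardrop": "R_teardrop",
            "L_rim": "R_rim",
            "L_ischium": "R_ischium",
        },
        **{f"L_aux{k:02d}": f"R_aux{k:02d}" for k in range(16)},
        **{f"L_sac{k}": f"R_sac{k}" for k in range(4)},
    },
    "midline": ["PS", "S1_ant", "S1_post", "M_sac0", "M_sac1", "M_sac2"],
}


def _surface_point(origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    d = direction / np.linalg.norm(direction)

    def f(t):
        return float(implicit_field((origin + t * d)[None, :])[0])

    if f(0.0) <= 0:
        raise GenerationError("landmark ray origin lies outside the surface")
    t_hi = 10.0
    while f(t_hi) > 0:
        t_hi += 10.0
        if t_hi > 500.0:
            raise GenerationError("landmark ray never leaves the surface")
    t = brentq(f, 0.0, t_hi, xtol=1e-10)
    return origin + t * d


def base_landmarks() -> LandmarkSet:
    """The 15 named landmarks of the base shape, located analytically on
    the implicit surface (mesh-independent)."""
    names = list(_RAYS.keys())
    pts = np.array([_surface_point(o, d) for o, d in _RAYS.values()])
    return LandmarkSet(names, pts, pairs=SYMMETRY_SCHEMA["pairs"],
                       midline=SYMMETRY_SCHEMA["midline"])


_BOUNDS_LO = np.array([-110.0, -85.0, -75.0])
_BOUNDS_HI = np.array([110.0, 60.0, 95.0])


def _polygonize(resolution: int, origin_jitter: np.ndarray | None = None,
                name: str = "base") -> TriMesh:
    if resolution < 12:
        raise GenerationError(
            f"resolution {resolution} cannot resolve the lobes (minimum 12)"
        )
    lo = _BOUNDS_LO.copy()
    hi = _BOUNDS_HI.copy()
    if origin_jitter is not None:
        lo += origin_jitter  # shifts the sampling lattice, not the shape
    spacing = (hi - lo) / resolution
    nx, ny, nz = (int(resolution * 1.0) + 1 for _ in range(3))
    xs = lo[0] + spacing[0] * np.arange(nx)
    ys = lo[1] + spacing[1] * np.arange(ny)
    zs = lo[2] + spacing[2] * np.arange(nz)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    vol = implicit_field(grid.reshape(-1, 3)).reshape(grid.shape[:3])
    try:
        verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=tuple(spacing))
    except (ValueError, RuntimeError) as exc:
        raise GenerationError(f"isosurface extraction failed: {exc}") from exc
    verts = verts + lo
    mesh = TriMesh(verts, faces, name=name)
    if mesh.n_vertices < 100:
        raise GenerationError(
            f"resolution {resolution} too coarse ({mesh.n_vertices} vertices)"
        )
    if not mesh.is_watertight:
        raise GenerationError("marching-cubes surface is not watertight")
    if mesh.signed_volume() < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1], mesh.name)
    return mesh


_CAL: dict[str, float] = {}


def _resolution_for_target(target: int) -> float:
    """Marching-cubes vertex count grows ~ resolution^2; calibrate once."""
    if "c" not in _CAL:
        probe = _polygonize(32)
        _CAL["c"] = probe.n_vertices / 32.0**2
    return float(np.sqrt(target / _CAL["c"]))


def make_base_shape(resolution: int = 48) -> tuple[TriMesh, LandmarkSet]:
    """Watertight, bilaterally symmetric base mesh plus analytic landmarks.

    ``resolution`` is the number of marching-cubes cells along each axis;
    the default yields ~7,000 vertices.
    """
    return _polygonize(resolution), base_landmarks()


# ---------------------------------------------------------------------------
# Deformation modes
# ---------------------------------------------------------------------------

def _rot(axis: str, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _weighted_rotation(p, center, rho, axis, angle):
    w = np.exp(-0.5 * np.sum((p - center) ** 2, axis=1) / rho**2)
    rel = p - center
    return w[:, None] * (rel @ _rot(axis, angle).T - rel)


def _superior_weight(z):
    return 1.0 / (1.0 + np.exp(-(z - _Z0_SUP) / _TAU_SUP))


_ANCHOR_SIGMA = 18.0  # mm


def _frame_anchor_mask(p: np.ndarray) -> np.ndarray:
    """Smooth mask vanishing at the three APP-frame landmarks.

    All deformation modes are multiplied by this mask so the frame-defining
    landmarks stay fixed: otherwise per-specimen APP alignment would turn
    every mode into an additional global rotation correlated with its
    score, confounding the stated mode variances.
    """
    mask = np.ones(len(p))
    for name in ("L_ASIS", "R_ASIS", "PS"):
        q = _anchor_point(name)
        mask *= 1.0 - np.exp(-0.5 * np.sum((p - q) ** 2, axis=1) / _ANCHOR_SIGMA**2)
    return mask


_ANCHORS: dict[str, np.ndarray] = {}


def _anchor_point(name: str) -> np.ndarray:
    if name not in _ANCHORS:
        _ANCHORS[name] = _surface_point(*_RAYS[name])
    return _ANCHORS[name]


def _deform_raw(points: np.ndarray, scores: np.ndarray) -> np.ndarray:
    if abs(scores[0]) * _THETA_A > _MAX_ROT or abs(scores[1]) * _THETA_B > _MAX_ROT:
        raise GenerationError("rotation amplitude beyond checked injectivity bound")
    if abs(scores[2]) * _GAMMA_C > _MAX_SCALE_CHANGE:
        raise GenerationError("scaling amplitude beyond checked injectivity bound")
    p = np.atleast_2d(np.asarray(points, dtype=np.float64)).copy()
    anchor = _frame_anchor_mask(p)[:, None]
    # mode A: opposite-sense coronal rotation of the two lateral lobes
    a = scores[0] * _THETA_A
    p += anchor * _weighted_rotation(p, _L_CENTER, _RHO_LATERAL, "y", a)
    p += anchor * _weighted_rotation(p, _R_CENTER, _RHO_LATERAL, "y", -a)
    # mode B: sagittal rotation of the sacral lobe
    p += anchor * _weighted_rotation(p, _S_CENTER, _RHO_SACRAL, "x",
                                     scores[1] * _THETA_B)
    # mode C: superior mediolateral scaling
    dx = p[:, 0] * (scores[2] * _GAMMA_C * _superior_weight(p[:, 2]))
    p[:, 0] += anchor[:, 0] * dx
    return p


def _mode_norms() -> np.ndarray:
    """Raw-unit rms surface displacement of each mode (mm), measured once
    on a fixed mid-resolution base surface and cached."""
    if "norms" not in _CAL:
        verts = _polygonize(40).vertices
        eps = 1e-3
        norms = []
        for j in range(N_MODES):
            s = np.zeros(N_MODES)
            s[j] = eps
            d = (_deform_raw(verts, s) - _deform_raw(verts, -s)) / (2 * eps)
            norms.append(float(np.sqrt(np.mean(np.sum(d**2, axis=1)))))
        _CAL["norms"] = np.array(norms)
    return _CAL["norms"]


def deform_points(points: np.ndarray, scores: Sequence[float]) -> np.ndarray:
    """Apply the three deformation modes at the given scores to points.

    One unit of score on any mode produces 1.0 mm rms displacement over the
    base surface. Smooth everywhere; amplitudes are bounded to keep the map
    injective (GenerationError beyond the bound).
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (N_MODES,):
        raise ValueError(f"expected {N_MODES} mode scores")
    return _deform_raw(points, scores / _mode_norms())


def mode_displacement(points: np.ndarray, mode: int, eps: float = 1e-3) -> np.ndarray:
    """Ground-truth displacement field of one mode, per unit score
    (central finite difference of :func:`deform_points`; used as the
    analytic reference direction for recovery tests)."""
    s = np.zeros(N_MODES)
    s[mode] = eps
    plus = deform_points(points, s)
    s[mode] = -eps
    minus = deform_points(points, s)
    return (plus - minus) / (2 * eps)


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Stated world for the synthetic cohort.

    Defaults emulate the target study design: two groups of 50, three
    deformation modes with score SDs 3:2:1 (variance ratio 9:4:1), a
    case-group mean shift of two SDs on mode A only, smooth surface noise
    well below the mode amplitudes, and moderate per-specimen pose/scale
    jitter. ``remesh_target`` is the approximate vertex count per specimen.
    """

    n_per_group: int = 50
    mode_sds: tuple[float, ...] = (3.0, 2.0, 1.0)     # mm rms per mode
    group_shift: tuple[float, ...] = (6.0, 0.0, 0.0)  # 2 SD on mode A
    noise_sd: float = 0.2          # mm, smooth surface noise amplitude
    rotation_jitter: float = 10.0  # deg, max random rotation
    translation_jitter: float = 20.0  # mm
    scale_jitter: float = 0.05     # scale ~ U(1-j, 1+j)
    remesh_target: int = 1600
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.remesh_target < 100:
            raise ValueError("remesh_target must be >= 100")
        if len(self.mode_sds) != N_MODES or len(self.group_shift) != N_MODES:
            raise ValueError(f"mode_sds and group_shift must have {N_MODES} entries")
        if any(s < 0 for s in self.mode_sds) or self.noise_sd < 0:
            raise ValueError("SDs must be non-negative")


@dataclass
class GroundTruth:
    """Per-specimen generative record: true mode scores, applied similarity
    transform and group label (1 = case, 0 = control)."""

    ids: list[str]
    groups: np.ndarray
    scores: np.ndarray                     # (n, N_MODES)
    transforms: list[SimilarityTransform] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "specimen": self.ids,
            "group": self.groups,
        }
        for j in range(self.scores.shape[1]):
            rows[f"mode_{'ABC'[j]}"] = self.scores[:, j]
        df = pd.DataFrame(rows)
        df["scale"] = [t.scale for t in self.transforms]
        for k, ax in enumerate("xyz"):
            df[f"t{ax}"] = [t.translation[k] for t in self.transforms]
        return df


def _random_similarity(rng: np.random.Generator, cfg: SyntheticConfig) -> SimilarityTransform:
    # uniform random axis, bounded angle
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-cfg.rotation_jitter, cfg.rotation_jitter))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-cfg.translation_jitter, cfg.translation_jitter, size=3)
    s = rng.uniform(1 - cfg.scale_jitter, 1 + cfg.scale_jitter)
    return SimilarityTransform(R, t, s)


def _smooth_noise_field(rng: np.random.Generator, noise_sd: float, n_kernels: int = 6,
                        sigma: float = 35.0):
    """Random smooth vector field with pointwise scale ~ noise_sd (mm)."""
    centers = rng.uniform(_BOUNDS_LO, _BOUNDS_HI, size=(n_kernels, 3))
    # scale so the summed-kernel field has roughly unit variance per axis
    amps = rng.normal(scale=noise_sd / np.sqrt(n_kernels / 2.0), size=(n_kernels, 3))

    def field(p):
        w = np.exp(-0.5 * ((p[:, None, :] - centers) ** 2).sum(axis=2) / sigma**2)
        return w @ amps

    return field


def sample_specimen(
    config: SyntheticConfig,
    mode_scores: Sequence[float],
    rng: np.random.Generator | None = None,
    name: str = "specimen",
) -> tuple[TriMesh, LandmarkSet, SimilarityTransform]:
    """One synthetic specimen at the given mode scores.

    The base surface is polygonized on a jittered grid (independent
    remeshing), then vertices and landmarks are pushed through the same
    smooth mode deformation, smooth noise field and random similarity
    transform. With a fresh ``rng`` of equal state the output is identical.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base_res = _resolution_for_target(config.remesh_target)
    res = max(20, int(round(base_res * rng.uniform(0.92, 1.08))))
    jitter = rng.uniform(-2.0, 2.0, size=3)
    mesh = _polygonize(res, origin_jitter=jitter, name=name)
    lms = base_landmarks()

    verts = deform_points(mesh.vertices, mode_scores)
    lpts = deform_points(lms.points, mode_scores)
    if config.noise_sd > 0:
        noise = _smooth_noise_field(rng, config.noise_sd)
        verts = verts + noise(verts)
        lpts = lpts + noise(lpts)
    t = _random_similarity(rng, config)
    out = TriMesh(t.apply(verts), mesh.faces, name=name)
    if not out.is_watertight:
        raise GenerationError(f"{name}: deformed surface lost watertightness")
    return out, lms.with_points(t.apply(lpts)), t


def sample_population(
    config: SyntheticConfig,
) -> tuple[list[tuple[TriMesh, LandmarkSet]], GroundTruth]:
    """Two-group population: control scores ~ N(0, mode_sds), case scores
    ~ N(group_shift, mode_sds); 2 * n_per_group specimens, reproducible
    from ``config.seed`` alone (per-specimen substreams by counter)."""
    root = np.random.SeedSequence(config.seed)
    score_rng = np.random.default_rng(root.spawn(1)[0])
    n = config.n_per_group
    sds = np.asarray(config.mode_sds)
    shift = np.asarray(config.group_shift)
    groups = np.repeat([0, 1], n)
    scores = score_rng.normal(size=(2 * n, N_MODES)) * sds
    scores[groups == 1] += shift

    specimens: list[tuple[TriMesh, LandmarkSet]] = []
    ids: list[str] = []
    transforms: list[SimilarityTransform] = []
    for i in range(2 * n):
        sid = f"{'ctrl' if groups[i] == 0 else 'case'}_{i:03d}"
        rng_i = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, i)))
        mesh, lms, t = sample_specimen(config, scores[i], rng_i, name=sid)
        specimens.append((mesh, lms))
        ids.append(sid)
        transforms.append(t)
    return specimens, GroundTruth(ids, groups, scores, transforms)


def write_population(specimens, truth: GroundTruth, out_dir) -> None:
    """Persist a population as PLY + landmark CSV per specimen, plus a
    ground-truth table and labels file (the directory-mode input layout)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (mesh, lms), sid in zip(specimens, truth.ids):
        write_mesh(mesh, out / f"{sid}.ply")
        write_landmarks(lms, out / f"{sid}.landmarks.csv")
    truth.to_frame().to_csv(out / "ground_truth.csv", index=False, float_format="%.9g")
    pd.DataFrame({"specimen": truth.ids, "group": truth.groups}).to_csv(
        out / "labels.csv", index=False
    )
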