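"""Group discrimination of shape modes and landmark-based angle measures.

For each principal component, the per-specimen scores are tested for their
ability to separate cases (label 1) from controls (label 0): the ROC curve
is swept over score thresholds, the area under it (AUC) is computed in the
Mann-Whitney form — the probability that a random case outscores a random
control, ties counting one half — and its difference from the no-information
value 0.5 is tested with a chi-squared statistic built from the
Hanley-McNeil standard error of the AUC.

Anatomical angles are measured from landmark-indexed vertices of each
homologous model after placing it in the anterior-pelvic-plane frame
(optionally composed with a configurable functional rotation), projecting
onto a named plane (coronal / sagittal / horizontal) and taking the angle
between two landmark-defined lines or rays. Pearson correlations between
component scores and angles attach anatomical meaning to the modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from .mesh import LandmarkSet, TriMesh
from .registration import HomologousModel, landmark_embedding
from .template import Template, app_transform

__all__ = [
    "ROCResult",
    "roc_curve",
    "auc",
    "auc_chi2_test",
    "score_histograms",
    "measure_angles",
    "correlate_scores_measures",
    "DEFAULT_ANGLE_SCHEMA",
    "load_angle_schema",
]


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _validate_binary(scores, labels):
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if len(scores) != len(labels):
        raise ValueError("scores and labels length mismatch")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1} or len(uniq) != 2:
        raise ValueError("labels must be binary with both classes present")
    return scores, labels.astype(int)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: (#{case > control} + 0.5 #{ties}) / (n1 n0).

    Exact pairwise counting for moderate n; the rank formula (identical in
    exact arithmetic) for large n.
    """
    scores, labels = _validate_binary(scores, labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    n1, n0 = len(cases), len(controls)
    if n1 * n0 <= 250_000:
        gt = (cases[:, None] > controls[None, :]).sum()
        ties = (cases[:, None] == controls[None, :]).sum()
        return float((gt + 0.5 * ties) / (n1 * n0))
    ranks = sps.rankdata(scores)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auc_chi2_test(auc_value: float, n_cases: int, n_controls: int) -> tuple[float, float]:
    """Chi-squared test of AUC = 0.5 with the Hanley-McNeil standard error.

    SE^2 = [A(1-A) + (n1-1)(Q1-A^2) + (n0-1)(Q2-A^2)] / (n1 n0), with
    Q1 = A/(2-A), Q2 = 2A^2/(1+A). The statistic ((A-0.5)/SE)^2 is referred
    to chi-squared with one degree of freedom.
    """
    A = float(auc_value)
    if not 0.0 <= A <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("both groups need at least one member")
    if A == 0.5:
        return 0.0, 1.0
    q1 = A / (2.0 - A)
    q2 = 2.0 * A**2 / (1.0 + A)
    var = (A * (1 - A) + (n_cases - 1) * (q1 - A**2)
           + (n_controls - 1) * (q2 - A**2)) / (n_cases * n_controls)
    if var <= 0.0:
        return float("inf"), 0.0  # perfect separation
    chi2 = (A - 0.5) ** 2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


@dataclass
class ROCResult:
    """ROC curve and AUC significance for one component's scores."""

    component: int
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    se: float
    chi2: float
    p_value: float
    case_positive_direction: bool  # True when cases tend to score higher

    def __post_init__(self):
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC curve must be a monotone staircase")

    @property
    def trapezoidal_area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def roc_curve(scores, labels, component: int = 0) -> ROCResult:
    """Full ROC analysis of one score vector.

    The curve is swept over unique score values (ties form diagonal
    segments) and always contains (0,0) and (1,1); its trapezoidal area
    equals the Mann-Whitney AUC.
    """
    scores, labels = _validate_binary(scores, labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    A = auc(scores, labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    chi2, p = auc_chi2_test(A, n1, n0)
    q1 = A / (2.0 - A)
    q2 = 2.0 * A**2 / (1.0 + A)
    var = (A * (1 - A) + (n1 - 1) * (q1 - A**2) + (n0 - 1) * (q2 - A**2)) / (n1 * n0)
    return ROCResult(
        component=component,
        fpr=fpr,
        tpr=tpr,
        auc=A,
        se=float(np.sqrt(max(var, 0.0))),
        chi2=chi2,
        p_value=p,
        case_positive_direction=bool(A >= 0.5),
    )


def score_histograms(scores, labels, bins: int = 10):
    """Per-group histograms over shared bin edges.

    Returns ``(edges, counts_control, counts_case)``; counts sum to the
    group sizes.
    """
    scores, labels = _validate_binary(scores, labels)
    edges = np.histogram_bin_edges(scores, bins=bins)
    c0, _ = np.histogram(scores[labels == 0], bins=edges)
    c1, _ = np.histogram(scores[labels == 1], bins=edges)
    return edges, c0, c1


# ---------------------------------------------------------------------------
# Angle measurement
# ---------------------------------------------------------------------------

#: Projection planes in the (functional) APP frame: drop the named axis.
_PLANES = {"coronal": 1, "sagittal": 0, "horizontal": 2}

#: Default angle schema for the package's landmark names. Each entry:
#: plane, two line specs; a line spec is either a pair of landmark names,
#: an ``axis:<x|y|z>`` frame axis, or ``app_normal`` (the +Y normal of the
#: specimen's own anterior pelvic plane). ``kind: rays`` measures the full
#: 0-180 degree angle between directed rays (first name = shared vertex);
#: the default ``lines`` kind measures the acute angle between undirected
#: lines.
DEFAULT_ANGLE_SCHEMA: dict[str, dict] = {
    "sharp_angle_L": {
        "plane": "coronal",
        "line1": ["R_teardrop", "L_teardrop"],
        "line2": ["L_teardrop", "L_rim"],
    },
    "sharp_angle_R": {
        "plane": "coronal",
        "line1": ["L_teardrop", "R_teardrop"],
        "line2": ["R_teardrop", "R_rim"],
    },
    "iliac_wing_angle_L": {
        "plane": "coronal",
        "line1": ["axis:z"],
        "line2": ["L_crest", "L_ASIS"],
    },
    "iliac_wing_angle_R": {
        "plane": "coronal",
        "line1": ["axis:z"],
        "line2": ["R_crest", "R_ASIS"],
    },
    "sacral_slope": {
        "plane": "sagittal",
        "line1": ["axis:y"],
        "line2": ["S1_post", "S1_ant"],
    },
    "pelvic_inclination": {
        # angle of the specimen's APP normal to the functional coronal
        # plane; identically zero when the functional frame IS the APP
        # frame (the configuration this package defaults to)
        "plane": "sagittal",
        "line1": ["axis:y"],
        "line2": ["app_normal"],
    },
    "ischiopubic_angle": {
        "plane": "coronal",
        "kind": "rays",
        "line1": ["PS", "L_ischium"],
        "line2": ["PS", "R_ischium"],
    },
}


def load_angle_schema(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _line_vector(spec, lm_points: dict[str, np.ndarray], app_normal: np.ndarray):
    if len(spec) == 1:
        token = spec[0]
        if token == "app_normal":
            return app_normal.copy()
        if token.startswith("axis:"):
            v = np.zeros(3)
            v["xyz".index(token.split(":")[1])] = 1.0
            return v
        raise ValueError(f"bad line spec {spec!r}")
    a, b = spec
    if a not in lm_points or b not in lm_points:
        raise ValueError(f"angle schema references missing landmark in {spec!r}")
    return lm_points[b] - lm_points[a]


def _planar_angle(u, v, plane: str, kind: str) -> float:
    axes = [i for i in range(3) if i != _PLANES[plane]]
    u2, v2 = u[axes], v[axes]
    nu, nv = np.linalg.norm(u2), np.linalg.norm(v2)
    if nu == 0 or nv == 0:
        return float("nan")
    c = float(np.dot(u2, v2) / (nu * nv))
    if kind != "rays":
        c = abs(c)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def measure_angles(
    model: HomologousModel | TriMesh,
    template: Template,
    schema: dict | None = None,
    functional_rotation: np.ndarray | None = None,
) -> dict[str, float]:
    """Anatomical angles (degrees) of one homologous model.

    The template's landmark->vertex indices transfer to the model (shared
    topology); the model is placed in its own APP frame, optionally rotated
    into a functional frame, then each schema angle is measured in its
    projection plane. Values are in [0, 180].
    """
    schema = schema if schema is not None else DEFAULT_ANGLE_SCHEMA
    verts = model.vertices
    B = landmark_embedding(template.mesh, template.landmarks.points)
    lms = LandmarkSet(template.landmarks.names, B @ verts,
                      template.landmarks.pairs, template.landmarks.midline)
    t = app_transform(lms)
    pts = t.apply(lms.points)
    if functional_rotation is not None:
        pts = pts @ np.asarray(functional_rotation).T
    lm_points = {n: pts[i] for i, n in enumerate(lms.names)}
    # the specimen APP normal is +Y after APP placement, rotated if a
    # functional frame is configured
    app_n = np.array([0.0, 1.0, 0.0])
    if functional_rotation is not None:
        app_n = np.asarray(functional_rotation) @ app_n
    out: dict[str, float] = {}
    for name, entry in schema.items():
        u = _line_vector(entry["line1"], lm_points, app_n)
        v = _line_vector(entry["line2"], lm_points, app_n)
        out[name] = _planar_angle(u, v, entry["plane"], entry.get("kind", "lines"))
    return out


def correlate_scores_measures(
    scores: pd.DataFrame, angles: pd.DataFrame, absolute: bool = False
) -> pd.DataFrame:
    """Pearson correlation of each PC score with each angle measurement.

    Tables are matched on the ``specimen`` column; zero-variance columns
    yield NaN with a warning. ``absolute`` reports |r|.
    """
    merged = scores.merge(angles, on="specimen", suffixes=("", "_angle"))
    if len(merged) < 3:
        raise ValueError("need >= 3 matched specimens")
    pc_cols = [c for c in scores.columns if c.startswith("PC")]
    angle_cols = [c for c in angles.columns if c not in ("specimen", "group")]
    out = pd.DataFrame(index=angle_cols, columns=pc_cols, dtype=float)
    for ac in angle_cols:
        y = merged[ac].to_numpy(dtype=float)
        if np.isnan(y).any() or np.std(y) == 0.0:
            warnings.warn(f"angle {ac!r} has zero variance or missing values; "
                          "correlation undefined", stacklevel=2)
            continue
        for pc in pc_cols:
            x = merged[pc].to_numpy(dtype=float)
            if np.std(x) == 0.0:
                warnings.warn(f"score {pc!r} has zero variance", stacklevel=2)
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            out.loc[ac, pc] = abs(r) if absolute else r
    return out
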