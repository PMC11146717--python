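"""Size normalization and vertex-coordinate PCA of homologous models.

Once every specimen is a homologous model (same topology, corresponding
vertices), a population is a matrix of n rows by 3V stacked vertex
coordinates. Size is removed by scaling each model to the template
(closed-form least squares), then PCA of the rows gives the population's
shape modes: each principal component is a 3V displacement field, its
eigenvalue the score variance along it (divisor n-1), and its contribution
ratio the percentage of total shape variance it explains. Virtual morphs
at mean +/- k SD along one component visualize what the mode does.

PCA signs are arbitrary; here each component is oriented so that its
largest single-vertex displacement points toward +Z (superior), falling
back to +Y then +X on exact ties, so morphs and correlations are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mesh import TriMesh
from .registration import HomologousModel
from .template import Template

__all__ = [
    "ShapePopulation",
    "PCAModel",
    "normalize_scale",
    "run_pca",
    "project",
    "reconstruct",
    "morph_at_sd",
]


def normalize_scale(model: HomologousModel, template: Template) -> HomologousModel:
    """Scale a homologous model to minimize the summed squared distance to
    the template's corresponding vertices.

    The model centroid is moved to the template centroid, then the
    closed-form optimum s* = sum(x_i . t_i) / sum(x_i . x_i) over centered
    coordinates is applied; this is the global minimum of
    sum ||s x_i - t_i||^2 over s > 0.
    """
    tv = template.mesh.vertices
    if model.n_vertices != len(tv):
        raise ValueError("model topology does not match template")
    x = model.vertices - model.vertices.mean(axis=0)
    t = tv - tv.mean(axis=0)
    denom = float(np.einsum("ij,ij->", x, x))
    if denom == 0.0:
        raise ValueError("degenerate model: zero spread")
    s = float(np.einsum("ij,ij->", x, t) / denom)
    if s <= 0:
        raise ValueError("degenerate scale normalization (non-positive optimum)")
    return HomologousModel(
        vertices=s * x + tv.mean(axis=0),
        faces=model.faces,
        source_id=model.source_id,
        group=model.group,
        residual_mean=model.residual_mean,
        residual_sd=model.residual_sd,
    )


@dataclass
class ShapePopulation:
    """n x 3V matrix of stacked vertex coordinates plus specimen metadata."""

    rows: np.ndarray
    ids: list[str]
    groups: np.ndarray
    template: Template | None = None

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.float64)
        self.groups = np.asarray(self.groups)
        if self.rows.ndim != 2 or len(self.rows) < 2:
            raise ValueError("population needs >= 2 row vectors")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("non-finite coordinates in population")
        if len(self.ids) != len(self.rows) or len(self.groups) != len(self.rows):
            raise ValueError("metadata length mismatch")

    @classmethod
    def from_models(cls, models: list[HomologousModel],
                    template: Template | None = None) -> "ShapePopulation":
        return cls(
            rows=np.stack([m.flat() for m in models]),
            ids=[m.source_id for m in models],
            groups=np.array([m.group for m in models]),
            template=template,
        )

    @property
    def n(self) -> int:
        return len(self.rows)


@dataclass
class PCAModel:
    """Mean shape, orthonormal components and per-component spread.

    ``sds[j]`` is the sample SD (divisor n-1) of the scores along component
    j; ``ratios[j]`` the component's percentage of total variance.
    """

    mean: np.ndarray
    components: np.ndarray   # (k, 3V), orthonormal rows
    sds: np.ndarray          # (k,), mm
    ratios: np.ndarray       # (k,), percent
    cumulative: np.ndarray   # (k,), percent
    n: int
    n_vertices: int
    faces: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.components)

    def save(self, prefix) -> None:
        """Binary array container + YAML header."""
        prefix = Path(prefix)
        np.savez(
            prefix.with_suffix(".npz"),
            mean=self.mean, components=self.components, sds=self.sds,
            ratios=self.ratios,
            faces=self.faces if self.faces is not None else np.zeros((0, 3), int),
        )
        header = {
            "n": int(self.n), "n_vertices": int(self.n_vertices),
            "k": int(self.k),
            "sds_mm": [float(s) for s in self.sds],
            "contribution_pct": [float(r) for r in self.ratios],
            "cumulative_pct": [float(c) for c in self.cumulative],
        }
        prefix.with_suffix(".yaml").write_text(yaml.safe_dump(header, sort_keys=False))

    @classmethod
    def load(cls, prefix) -> "PCAModel":
        prefix = Path(prefix)
        z = np.load(prefix.with_suffix(".npz"))
        header = yaml.safe_load(prefix.with_suffix(".yaml").read_text())
        faces = z["faces"]
        return cls(
            mean=z["mean"], components=z["components"], sds=z["sds"],
            ratios=z["ratios"], cumulative=np.cumsum(z["ratios"]),
            n=header["n"], n_vertices=header["n_vertices"],
            faces=faces if len(faces) else None,
        )


def _pin_sign(components: np.ndarray) -> np.ndarray:
    """Orient each component so its largest-magnitude vertex displacement
    has a positive +Z (then +Y, then +X) coordinate."""
    out = components.copy()
    for j, comp in enumerate(out):
        if comp.size % 3:
            # not a stacked-coordinate layout: pin by the largest entry
            if comp[int(np.argmax(np.abs(comp)))] < 0:
                out[j] = -comp
            continue
        disp = comp.reshape(-1, 3)
        i = int(np.argmax(np.einsum("ij,ij->i", disp, disp)))
        v = disp[i]
        for axis in (2, 1, 0):
            if v[axis] != 0.0:
                if v[axis] < 0:
                    out[j] = -comp
                break
    return out


def run_pca(population: ShapePopulation, k: int | None = None,
            cumulative_threshold: float = 80.0) -> PCAModel:
    """PCA of stacked vertex coordinates.

    ``k`` defaults to the smallest number of components whose cumulative
    contribution reaches ``cumulative_threshold`` percent, capped at n-1.
    Raises on zero total variance or ``k`` out of range.
    """
    X = population.rows
    n = population.n
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD: at most n-1 meaningful components
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = S**2 / (n - 1)                       # score variances
    total = lam.sum()
    if total == 0.0:
        raise ValueError("zero total variance: all shapes identical")
    ratios_all = 100.0 * lam / total
    max_k = min(n - 1, X.shape[1])
    if k is None:
        k = int(np.searchsorted(np.cumsum(ratios_all), cumulative_threshold) + 1)
        k = min(k, max_k)
    if not 1 <= k <= max_k:
        raise ValueError(f"k={k} out of range [1, {max_k}]")
    components = _pin_sign(Vt[:k])
    faces = population.template.mesh.faces if population.template else None
    return PCAModel(
        mean=mean,
        components=components,
        sds=np.sqrt(lam[:k]),
        ratios=ratios_all[:k],
        cumulative=np.cumsum(ratios_all)[:k],
        n=n,
        n_vertices=X.shape[1] // 3,
        faces=faces,
    )


def project(row: np.ndarray, pca: PCAModel) -> np.ndarray:
    """Scores of one shape row: components . (row - mean)."""
    row = np.asarray(row, dtype=np.float64).reshape(-1)
    if row.shape != pca.mean.shape:
        raise ValueError("row length does not match the PCA model")
    return pca.components @ (row - pca.mean)


def reconstruct(pca: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Shape row at the given scores: mean + sum_j scores_j component_j."""
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    if len(scores) > pca.k:
        raise ValueError("more scores than components")
    return pca.mean + scores @ pca.components[: len(scores)]


def scores_table(population: ShapePopulation, pca: PCAModel) -> pd.DataFrame:
    """Per-specimen principal component scores (id, group, PC1..PCk)."""
    S = (population.rows - pca.mean) @ pca.components.T
    df = pd.DataFrame(S, columns=[f"PC{j+1}" for j in range(pca.k)])
    df.insert(0, "specimen", population.ids)
    df.insert(1, "group", population.groups)
    return df


def morph_at_sd(pca: PCAModel, component: int, k_sd: float,
                faces: np.ndarray | None = None) -> TriMesh:
    """Virtual morph: the mean shape displaced ``k_sd`` standard deviations
    along one component (1-based index). ``k_sd = 0`` is the mean shape;
    +/-3 SD is the conventional pair for visualizing a mode.
    """
    if not 1 <= component <= pca.k:
        raise ValueError(f"component {component} out of range [1, {pca.k}]")
    row = pca.mean + k_sd * pca.sds[component - 1] * pca.components[component - 1]
    f = faces if faces is not None else pca.faces
    if f is None or len(f) == 0:
        raise ValueError("no face topology available for the morph mesh")
    return TriMesh(row.reshape(-1, 3), f, name=f"PC{component}_{k_sd:+g}SD")
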