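"""End-to-end analysis pipeline.

Stages, in order: ingest (or synthesize) specimens -> build template ->
fit homologous models -> size-normalize -> vertex PCA -> per-component
ROC/chi-squared -> score histograms -> +/-k SD morphs for significant
components -> landmark angles and PC correlations -> report bundle.

Everything is reproducible from one seed: rerunning with an identical
configuration writes byte-identical CSV tables. Outputs are plain CSV,
PLY morph meshes, PNG figures and a YAML run record with a content hash.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .discrim import (
    DEFAULT_ANGLE_SCHEMA,
    ROCResult,
    correlate_scores_measures,
    measure_angles,
    roc_curve,
    score_histograms,
)
from .mesh import LandmarkSet, TriMesh, read_landmarks, read_mesh, read_symmetry_schema, write_mesh
from .registration import FitParams, HomologousModel, nonrigid_fit
from .stats import PCAModel, ShapePopulation, morph_at_sd, normalize_scale, run_pca, scores_table
from .synthetic import SyntheticConfig, sample_population
from .template import Template, build_template, place_in_app

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "validate_inputs"]

log = logging.getLogger("homoshape")

_FLOAT_FMT = "%.10g"  # fixed CSV float format => deterministic bytes


@dataclass
class PipelineConfig:
    """Configuration of one full run. ``seed`` is the single source of
    randomness; in synthetic mode it overrides ``synthetic.seed``."""

    mode: str = "synthetic"                      # "synthetic" | "directory"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    input_dir: str | None = None
    template_subset: int = 10                    # specimens averaged into the template
    template_target_vertices: int = 1500
    fit_params: FitParams = field(default_factory=FitParams)
    pca_k: int | None = None                     # None => cumulative threshold
    pca_cumulative_pct: float = 80.0
    alpha: float = 0.05
    morph_sds: tuple[float, ...] = (-3.0, 3.0)
    angle_schema: dict | None = None
    out_dir: str | None = None
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self):
        if self.mode not in ("synthetic", "directory"):
            raise ValueError("mode must be 'synthetic' or 'directory'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("significance level must lie in (0, 1)")
        if not all(np.isfinite(self.morph_sds)):
            raise ValueError("morph SD list must be finite")


@dataclass
class PipelineResult:
    template: Template
    models: list[HomologousModel]
    population: ShapePopulation
    pca: PCAModel
    roc: list[ROCResult]
    residual_table: pd.DataFrame
    component_table: pd.DataFrame
    scores: pd.DataFrame
    angles: pd.DataFrame
    correlations: pd.DataFrame
    ground_truth: pd.DataFrame | None = None
    out_dir: Path | None = None


def _stars(p: float, alpha: float) -> str:
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return ""


def validate_inputs(directory) -> dict:
    """Manifest of a specimen directory.

    Expects ``<id>.ply`` + ``<id>.landmarks.csv`` per specimen and a
    ``labels.csv`` with binary group labels. Fatal problems (missing
    files, non-binary labels) are listed under ``errors``; non-fatal
    observations under ``warnings``.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"not a directory: {directory}")
    manifest: dict = {"specimens": [], "errors": [], "warnings": []}
    labels_path = directory / "labels.csv"
    labels: dict[str, int] = {}
    if not labels_path.exists():
        manifest["errors"].append("labels.csv missing")
    else:
        df = pd.read_csv(labels_path)
        if not {"specimen", "group"}.issubset(df.columns):
            manifest["errors"].append("labels.csv must have columns specimen,group")
        else:
            bad = ~df["group"].isin([0, 1])
            for sid in df.loc[bad, "specimen"]:
                manifest["errors"].append(f"{sid}: non-binary group label")
            labels = dict(zip(df["specimen"].astype(str), df["group"]))
    for ply in sorted(directory.glob("*.ply")):
        sid = ply.stem
        entry = {"id": sid, "mesh": ply.name}
        lm = directory / f"{sid}.landmarks.csv"
        if not lm.exists():
            manifest["errors"].append(f"{sid}: landmark file missing")
        else:
            entry["landmarks"] = lm.name
        if labels and sid not in labels:
            manifest["errors"].append(f"{sid}: no group label")
        elif labels:
            entry["group"] = int(labels[sid])
        manifest["specimens"].append(entry)
    if not manifest["specimens"]:
        manifest["errors"].append("no .ply specimens found")
    return manifest


def _load_directory(directory) -> tuple[list[tuple[TriMesh, LandmarkSet]], np.ndarray, list[str]]:
    manifest = validate_inputs(directory)
    if manifest["errors"]:
        raise ValueError("invalid input directory: " + "; ".join(manifest["errors"]))
    directory = Path(directory)
    schema = None
    sym = directory / "symmetry.yaml"
    if sym.exists():
        schema = read_symmetry_schema(sym)
    specimens, groups, ids = [], [], []
    for entry in manifest["specimens"]:
        mesh = read_mesh(directory / entry["mesh"])
        lms = read_landmarks(directory / entry["landmarks"], schema)
        specimens.append((mesh, lms))
        groups.append(entry["group"])
        ids.append(entry["id"])
    return specimens, np.asarray(groups), ids


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; see the module docstring for the stages.

    On stage failure the output directory receives a ``FAILED`` marker
    naming the stage, partial outputs are retained, and the error is
    re-raised.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        return _run(config, out)
    except Exception as exc:
        if out:
            (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _run(config: PipelineConfig, out: Path | None) -> PipelineResult:
    # ---- ingest -------------------------------------------------------
    truth_df = None
    if config.mode == "synthetic":
        syn = SyntheticConfig(**{**config.synthetic.__dict__, "seed": config.seed})
        log.info("generating synthetic population (n=%d per group, seed=%d)",
                 syn.n_per_group, syn.seed)
        specimens, truth = sample_population(syn)
        groups = truth.groups
        ids = truth.ids
        truth_df = truth.to_frame()
    else:
        if config.input_dir is None:
            raise ValueError("directory mode requires input_dir")
        specimens, groups, ids = _load_directory(config.input_dir)

    # ---- template -----------------------------------------------------
    log.info("building template")
    controls = [s for s, g in zip(specimens, groups) if g == 0]
    subset = (controls or specimens)[: config.template_subset]
    template = build_template(
        subset,
        target_vertex_count=config.template_target_vertices,
        fit_params=config.fit_params,
    )

    # ---- homologous fitting ------------------------------------------
    models: list[HomologousModel] = []
    for (mesh, lms), g, sid in zip(specimens, groups, ids):
        m_app, l_app, _ = place_in_app(mesh, lms)
        hm = nonrigid_fit(template, m_app, l_app, params=config.fit_params,
                          source_id=sid, group=int(g))
        models.append(hm)
        log.debug("fit %s: residual %.3f mm", sid, hm.residual_mean)
    residual_table = pd.DataFrame({
        "specimen": [m.source_id for m in models],
        "group": [m.group for m in models],
        "residual_mean_mm": [m.residual_mean for m in models],
        "residual_sd_mm": [m.residual_sd for m in models],
    })
    log.info("fit residual over cohort: %.3f +/- %.3f mm",
             residual_table["residual_mean_mm"].mean(),
             residual_table["residual_mean_mm"].std(ddof=1))

    # ---- normalization + PCA -----------------------------------------
    normalized = [normalize_scale(m, template) for m in models]
    population = ShapePopulation.from_models(normalized, template)
    pca = run_pca(population, k=config.pca_k,
                  cumulative_threshold=config.pca_cumulative_pct)
    scores = scores_table(population, pca)

    # ---- ROC per component -------------------------------------------
    labels = population.groups.astype(int)
    roc = [roc_curve(scores[f"PC{j+1}"].to_numpy(), labels, component=j + 1)
           for j in range(pca.k)]
    component_table = pd.DataFrame({
        "component": np.arange(1, pca.k + 1),
        "contribution_pct": pca.ratios,
        "cumulative_pct": pca.cumulative,
        "auc": [r.auc for r in roc],
        "chi2": [r.chi2 for r in roc],
        "p_value": [r.p_value for r in roc],
        "significance": [_stars(r.p_value, config.alpha) for r in roc],
    })

    # ---- angles + correlations ---------------------------------------
    schema = config.angle_schema if config.angle_schema is not None else DEFAULT_ANGLE_SCHEMA
    angle_rows = []
    for m in normalized:
        row = {"specimen": m.source_id, "group": m.group}
        row.update(measure_angles(m, template, schema))
        angle_rows.append(row)
    angles = pd.DataFrame(angle_rows)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # constant angles are expected (APP frame)
        correlations = correlate_scores_measures(scores, angles)

    result = PipelineResult(
        template=template, models=models, population=population, pca=pca,
        roc=roc, residual_table=residual_table,
        component_table=component_table, scores=scores, angles=angles,
        correlations=correlations, ground_truth=truth_df, out_dir=out,
    )
    if out:
        _write_outputs(result, config, out)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig, out: Path) -> None:
    tables = {
        "residuals.csv": result.residual_table,
        "components.csv": result.component_table,
        "scores.csv": result.scores,
        "angles.csv": result.angles,
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False, float_format=_FLOAT_FMT)
    result.correlations.to_csv(out / "correlations.csv", float_format=_FLOAT_FMT)
    if result.ground_truth is not None:
        result.ground_truth.to_csv(out / "ground_truth.csv", index=False,
                                   float_format=_FLOAT_FMT)
    result.template.save(out / "template")

    sig = [r for r in result.roc if r.significant(config.alpha)]
    for r in sig:
        for k_sd in config.morph_sds:
            mesh = morph_at_sd(result.pca, r.component, k_sd)
            write_mesh(mesh, out / f"morph_PC{r.component}_{k_sd:+g}SD.ply")

    curves = pd.concat([
        pd.DataFrame({"component": r.component, "fpr": r.fpr, "tpr": r.tpr})
        for r in result.roc
    ])
    curves.to_csv(out / "roc_curves.csv", index=False, float_format=_FLOAT_FMT)

    hist_rows = []
    labels = result.population.groups.astype(int)
    for r in sig or result.roc[:3]:
        s = result.scores[f"PC{r.component}"].to_numpy()
        edges, c0, c1 = score_histograms(s, labels)
        for lo, hi, a, b in zip(edges[:-1], edges[1:], c0, c1):
            hist_rows.append({"component": r.component, "bin_lo": lo,
                              "bin_hi": hi, "control": a, "case": b})
    pd.DataFrame(hist_rows).to_csv(out / "score_histograms.csv", index=False,
                                   float_format=_FLOAT_FMT)

    if config.make_plots:
        _plots(result, config, out)

    digest = hashlib.sha256()
    for name in sorted(["residuals.csv", "components.csv", "scores.csv",
                        "angles.csv", "correlations.csv", "roc_curves.csv",
                        "score_histograms.csv"]):
        digest.update((out / name).read_bytes())
    meta = {
        "seed": int(config.seed),
        "mode": config.mode,
        "n_specimens": len(result.models),
        "template_vertices": result.template.n_vertices,
        "pca_components": int(result.pca.k),
        "significant_components": [int(r.component) for r in sig],
        "mean_fit_residual_mm": float(result.residual_table["residual_mean_mm"].mean()),
        "sd_fit_residual_mm": float(result.residual_table["residual_mean_mm"].std(ddof=1)),
        "tables_sha256": digest.hexdigest(),
    }
    (out / "run.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def _plots(result: PipelineResult, config: PipelineConfig, out: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for r in result.roc:
        kw = {"lw": 2, "color": "crimson"} if r.significant(config.alpha) else \
             {"lw": 0.8, "color": "grey", "alpha": 0.6}
        ax.plot(r.fpr, r.tpr, **kw)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title("per-component ROC (significant in red)")
    fig.savefig(out / "roc_curves.png", dpi=120)
    plt.close(fig)

    sig = [r for r in result.roc if r.significant(config.alpha)] or result.roc[:3]
    fig, axes = plt.subplots(1, len(sig), figsize=(4 * len(sig), 3), squeeze=False)
    labels = result.population.groups.astype(int)
    for ax, r in zip(axes[0], sig):
        s = result.scores[f"PC{r.component}"].to_numpy()
        edges, c0, c1 = score_histograms(s, labels)
        width = np.diff(edges)
        ax.bar(edges[:-1], c0, width=width, align="edge", alpha=0.6,
               label="control", color="steelblue")
        ax.bar(edges[:-1], c1, width=width, align="edge", alpha=0.6,
               label="case", color="crimson")
        ax.set_title(f"PC{r.component} (AUC {r.auc:.3f})")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "score_histograms.png", dpi=120)
    plt.close(fig)
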