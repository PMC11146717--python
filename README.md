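# homoshape

Homologous-model statistical shape analysis of 3D anatomical surfaces.

Skeletal surfaces reconstructed from CT — for instance the pelvis in
studies of developmental hip dysplasia — are triangle meshes with
arbitrary, mutually incompatible vertex numberings, so their shapes
cannot be compared coordinate-by-coordinate. `homoshape` implements the
template-fitting workflow that makes them comparable and the statistics
that extract group differences from the result:

* **Template construction** — average a subset of specimens, mirror the
  average into bilateral symmetry, remesh isotropically, place everything
  in the anterior-pelvic-plane (APP) coordinate frame.
* **Homologous modeling** — landmark-guided similarity alignment, rigid
  ICP, then Laplacian-regularized non-rigid fitting
  (`E = w_sm ||L(v - v0)||² + w_lm Σ||v_a - l_a||² + w_d Σ||v_i - c(v_i)||²`)
  deform the template onto each specimen, so every vertex index denotes
  the same anatomical locus across the cohort; fit fidelity is reported
  as the mean ± SD directed vertex-to-surface distance in mm.
* **Shape statistics** — size normalization to the template (closed-form
  scale), PCA of the stacked vertex coordinates (contribution ratios,
  sample SDs), virtual morphs at mean ± k·SD along any component.
* **Group discrimination** — per-component ROC curves and Mann-Whitney
  AUC with a χ² test against AUC = 0.5 (Hanley–McNeil standard error),
  score histograms, and Pearson correlations between PC scores and
  landmark-derived clinical angles (sharp angle, iliac-wing angle, sacral
  slope, ischiopubic angle, pelvic inclination).
* **Synthetic cohorts** — a pelvis-proxy generator producing two groups
  of watertight, independently meshed specimens with 58 analytically
  placed landmarks and three known deformation modes, so the entire
  pipeline is testable end to end with ground truth and no data
  downloads.

The package is a library: `import homoshape` and the scripts in
`examples/` are the interface. Meshes are read and written as STL
(binary/ASCII), PLY and OBJ; landmarks as `name,x,y,z` CSV.

## Worked example

`examples/roc_discrimination.py` runs the whole pipeline on a small
synthetic cohort (5 cases vs 5 controls, case group shifted by two
standard deviations on the coxal-inclination mode):

```
fit residual over cohort: 0.066 +/- 0.008 mm

 component  contribution_pct  cumulative_pct    auc   chi2  p_value significance
         1           76.3769         76.3769 0.7600 2.6461   0.1038
         2           20.8239         97.2007 0.8400 6.3659   0.0116            *
         3            2.2786         99.4793 0.2800 1.6910   0.1935
         4            0.2518         99.7311 0.4400 0.0998   0.7520

PC score vs angle correlations (Pearson r):
                     PC1   PC2   PC3   PC4
sharp_angle_L      -0.97 +0.11 +0.11 +0.12
sharp_angle_R      -0.99 +0.02 +0.12 +0.02
iliac_wing_angle_L +0.94 +0.09 +0.31 -0.00
...
```

Reading this: the fit residual says every homologous model tracks its
specimen surface to well under a tenth of a millimetre. PC1 carries ~76%
of the shape variance and correlates strongly with the acetabular (sharp)
and iliac-wing angles — it is the coxal-inclination mode. The AUC column
is the probability that a randomly chosen case outscores a randomly
chosen control on that component; the χ² test marks components whose AUC
differs significantly from 0.5. At n = 5 per group the test is
underpowered (the generating mode reaches AUC 0.76 without the star); at
the realistic n = 50/50 of the default configuration the mode-A-aligned
component attains AUC ≈ 0.92–0.94 at p ≪ 0.001. The ±3 SD morph meshes
written alongside visualize what each significant mode does to the
anatomy.

The other examples isolate the stages: `simulate_population.py`
(generate/export a cohort with ground truth), `build_template.py`
(symmetric isotropic template), `fit_homologous.py` (one non-rigid fit
and its residual), `pca_morphs.py` (PCA table and ±3 SD morph export).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline analysis from scratch: it generates the default
synthetic cohort (50 + 50, two-SD shift on one mode) from the given seed,
builds the template, fits all 100 homologous models, runs the PCA/ROC
analysis, prints the component table and cohort fit residual, and writes
the machine-readable target report to `--out`.
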