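"""Full pipeline: which shape modes separate the two groups?

Runs generation -> template -> homologous fitting -> PCA -> per-component
ROC/AUC with the chi-squared test against AUC = 0.5 -> landmark angles and
their correlations with the PC scores. Writes the report bundle (CSV
tables, morph meshes, figures) to ./out_roc/.
"""

import homoshape as hs

config = hs.PipelineConfig(
    synthetic=hs.SyntheticConfig(n_per_group=5),
    template_subset=4,
    template_target_vertices=1200,
    pca_k=4,
    seed=3,
    out_dir="out_roc",
)
result = hs.run_pipeline(config)

print("fit residual over cohort: "
      f"{result.residual_table.residual_mean_mm.mean():.3f} +/- "
      f"{result.residual_table.residual_mean_mm.std(ddof=1):.3f} mm\n")
print(result.component_table.to_string(
    index=False, float_format=lambda x: f"{x:.4f}"))
print("\nAUC is the probability a random case outscores a random control on"
      "\nthat component; '*' = p<0.05, '**' = p<0.01 against AUC = 0.5."
      "\nWith the default 2-SD shift on mode A, the mode-A-aligned component"
      "\nshould be flagged; at n = 5/group the chi-squared test is underpowered,"
      "\nso expect clearer separation at realistic cohort sizes (50/50).\n")
print("PC score vs angle correlations (Pearson r):")
print(result.correlations.to_string(float_format=lambda x: f"{x:+.2f}"))
print("\nreport bundle written to out_roc/ (tables, ROC curves, histograms,"
      "\nmorph meshes, run.yaml with the config hash)")
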