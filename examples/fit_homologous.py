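"""Fit the template onto one specimen to create a homologous model.

The three-stage registration (landmark similarity -> rigid ICP ->
Laplacian-regularized non-rigid fit) outputs a copy of the template whose
vertices lie on the specimen surface, so every vertex index denotes the
same anatomical locus across all fitted specimens. The fit residual is
the mean +/- SD of the directed vertex-to-surface distance in mm — the
fidelity metric this kind of analysis reports for its cohort.
"""

import numpy as np

import homoshape as hs

config = hs.SyntheticConfig(n_per_group=3, seed=7)
specimens, truth = hs.sample_population(config)
template = hs.build_template(specimens[:4], target_vertex_count=1500)

mesh, landmarks = specimens[5]
mesh_app, lms_app, _ = hs.place_in_app(mesh, landmarks)
model = hs.nonrigid_fit(template, mesh_app, lms_app,
                        source_id=truth.ids[5], group=int(truth.groups[5]))

print(f"specimen {model.source_id}: {mesh.n_vertices} vertices")
print(f"homologous model: {model.n_vertices} vertices (template topology)")
print(f"fit residual: {model.residual_mean:.3f} +/- {model.residual_sd:.3f} mm")
print(f"  ({100 * model.residual_mean / mesh_app.bbox_diagonal:.3f}% of the "
      "bounding-box diagonal; sub-0.5% means the surface is tracked closely)")

mean, sd = hs.fit_residual(model, mesh_app)
assert np.isclose(mean, model.residual_mean)
print("recomputed residual matches the stored value — the model is a faithful,"
      "\ncorresponded copy of the specimen surface.")
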