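"""ROC/AUC/chi-squared discrimination, angles, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import homoshape as hs
from homoshape.discrim import DEFAULT_ANGLE_SCHEMA, score_histograms


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


class TestAuc:
    def test_worked_example(self):
        # controls {1,2,3}, cases {2,3,4}: 7 wins + 2 half-ties over 9 pairs
        assert hs.auc([1, 2, 3, 2, 3, 4], [0, 0, 0, 1, 1, 1]) == pytest.approx(7 / 9)

    def test_perfect_separation(self):
        assert hs.auc([0, 1, 2, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_tied_is_half(self):
        assert hs.auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 6), min_size=2, max_size=20),
           st.data())
    def test_matches_pairwise_oracle(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda L: 0 < sum(L) < n
            )
        )
        assert hs.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=20),
           st.data())
    def test_label_swap_antisymmetry(self, scores, data):
        n = len(scores)
        labels = np.array(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda L: 0 < sum(L) < n
            )
        ))
        assert hs.auc(scores, labels) + hs.auc(scores, 1 - labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            hs.auc([1, 2, 3], [1, 1, 1])


class TestRocCurve:
    def test_perfect_separation_passes_corner(self):
        r = hs.roc_curve([0, 1, 2, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        pts = set(zip(r.fpr.tolist(), r.tpr.tolist()))
        assert (0.0, 1.0) in pts
        assert (0.0, 0.0) in pts and (1.0, 1.0) in pts

    def test_all_equal_scores_is_diagonal(self):
        r = hs.roc_curve([3, 3, 3, 3], [0, 1, 0, 1])
        assert r.auc == 0.5
        assert r.trapezoidal_area == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoidal_area_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, size=30).astype(float)  # many ties
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        r = hs.roc_curve(scores, labels)
        assert r.trapezoidal_area == pytest.approx(r.auc, abs=1e-12)


class TestChi2Test:
    def test_null_auc_gives_p_one(self):
        chi2, p = hs.auc_chi2_test(0.5, 50, 50)
        assert chi2 == 0.0
        assert p == 1.0

    def test_reference_cohort_value_highly_significant(self):
        """AUC 0.8692 at 50 cases / 50 controls: p far below 0.001."""
        chi2, p = hs.auc_chi2_test(0.8692, 50, 50)
        assert p < 0.001

    def test_monotone_in_distance_from_half(self):
        grid = np.linspace(0.5, 0.99, 40)
        chis = [hs.auc_chi2_test(a, 50, 50)[0] for a in grid]
        assert all(b > a for a, b in zip(chis, chis[1:]))

    def test_symmetric_below_half(self):
        above = hs.auc_chi2_test(0.7, 40, 60)
        below = hs.auc_chi2_test(0.3, 60, 40)
        assert above[0] == pytest.approx(below[0], rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hs.auc_chi2_test(1.2, 10, 10)


class TestHistograms:
    def test_counts_sum_to_group_sizes(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = np.repeat([0, 1], 20)
        edges, c0, c1 = score_histograms(scores, labels)
        assert c0.sum() == 20 and c1.sum() == 20

    def test_single_specimen_per_group(self):
        edges, c0, c1 = score_histograms([1.0, 2.0], [0, 1], bins=4)
        assert c0.sum() == 1 and c1.sum() == 1

    def test_shift_moves_edges_not_counts(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        e1, a1, b1 = score_histograms(scores, labels)
        e2, a2, b2 = score_histograms(scores + 10.0, labels)
        np.testing.assert_allclose(e2, e1 + 10.0)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)


class TestMeasureAngles:
    def test_analytic_45_degree_configuration(self):
        """A schema whose two lines form an exact 45-degree planar angle."""
        from homoshape.mesh import LandmarkSet
        from homoshape.template import Template

        verts = np.array([
            [-10.0, 0, 0], [10.0, 0, 0], [0.0, 0, -10.0],  # frame: ASIS pair + PS
            [0.0, 0, 0], [5.0, 0, 5.0],
        ])
        faces = np.array([[0, 1, 2], [0, 2, 3], [1, 3, 2], [3, 4, 0], [4, 1, 0],
                          [4, 3, 1]])
        names = ["L_ASIS", "R_ASIS", "PS", "origin", "diag"]
        lms = LandmarkSet(names, verts)
        mesh = hs.TriMesh(verts, faces)
        tpl = Template(mesh, lms, frame="APP")
        model = hs.HomologousModel(verts, faces)
        schema = {"diag_angle": {"plane": "coronal",
                                 "line1": ["origin", "diag"],
                                 "line2": ["axis:z"]}}
        out = hs.measure_angles(model, tpl, schema)
        assert out["diag_angle"] == pytest.approx(45.0, abs=1e-9)

    def test_mirror_symmetric_model_has_equal_sides(self, app_template):
        """Left and right angles agree on the (symmetric) base shape up to
        its isosurfacing asymmetry, and the measurement itself is exactly
        invariant under reflecting the model (frame recomputed)."""
        model = hs.HomologousModel(app_template.mesh.vertices,
                                   app_template.mesh.faces)
        out = hs.measure_angles(model, app_template)
        assert out["sharp_angle_L"] == pytest.approx(out["sharp_angle_R"], abs=0.05)
        assert out["iliac_wing_angle_L"] == pytest.approx(out["iliac_wing_angle_R"],
                                                          abs=0.05)
        mirrored = hs.HomologousModel(
            model.vertices * np.array([-1.0, 1.0, 1.0]), app_template.mesh.faces
        )
        out_m = hs.measure_angles(mirrored, app_template)
        for name in out:
            assert out_m[name] == pytest.approx(out[name], abs=1e-9)

    def test_invariant_under_rigid_motion_with_frame_recomputed(self, app_template):
        model = hs.HomologousModel(app_template.mesh.vertices, app_template.mesh.faces)
        a = hs.measure_angles(model, app_template)
        rng = np.random.default_rng(5)
        q = rng.normal(size=4); q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
        moved = hs.HomologousModel(
            model.vertices @ R.T + [20, -5, 12], app_template.mesh.faces
        )
        b = hs.measure_angles(moved, app_template)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-6)

    def test_missing_schema_landmark_rejected(self, app_template):
        model = hs.HomologousModel(app_template.mesh.vertices, app_template.mesh.faces)
        bad = {"x": {"plane": "coronal", "line1": ["nope", "L_rim"],
                     "line2": ["axis:z"]}}
        with pytest.raises(ValueError):
            hs.measure_angles(model, app_template, bad)

    def test_angles_bounded(self, app_template):
        model = hs.HomologousModel(app_template.mesh.vertices, app_template.mesh.faces)
        out = hs.measure_angles(model, app_template)
        for name, val in out.items():
            assert 0.0 <= val <= 180.0


class TestCorrelations:
    def _tables(self, y):
        import pandas as pd

        n = len(y)
        scores = pd.DataFrame({"specimen": [f"s{i}" for i in range(n)],
                               "group": [0] * n, "PC1": np.arange(n, dtype=float)})
        angles = pd.DataFrame({"specimen": [f"s{i}" for i in range(n)],
                               "group": [0] * n, "alpha": y})
        return scores, angles

    def test_exact_linear_relation(self):
        s, a = self._tables(3.0 * np.arange(8) + 1.0)
        r = hs.correlate_scores_measures(s, a)
        assert r.loc["alpha", "PC1"] == pytest.approx(1.0)

    def test_affine_rescale_invariance(self):
        y = np.array([2.0, -1.0, 5.0, 3.0, 0.0, 4.0])
        s, a = self._tables(y)
        r1 = hs.correlate_scores_measures(s, a).loc["alpha", "PC1"]
        s2, a2 = self._tables(100.0 * y - 7.0)
        r2 = hs.correlate_scores_measures(s2, a2).loc["alpha", "PC1"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(42)
        s, a = self._tables(rng.normal(size=1000))
        r = hs.correlate_scores_measures(s, a)
        assert abs(r.loc["alpha", "PC1"]) < 0.1

    def test_zero_variance_reported_missing_with_warning(self):
        s, a = self._tables(np.full(6, 3.25))
        with pytest.warns(UserWarning):
            r = hs.correlate_scores_measures(s, a)
        assert np.isnan(r.loc["alpha", "PC1"])

    def test_absolute_option(self):
        s, a = self._tables(-2.0 * np.arange(8) + 3.0)
        r = hs.correlate_scores_measures(s, a, absolute=True)
        assert r.loc["alpha", "PC1"] == pytest.approx(1.0)
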