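"""Scale normalization, vertex PCA, morphs."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import homoshape as hs
from homoshape.registration import HomologousModel
from homoshape.stats import ShapePopulation, scores_table


def _model_from(template, vertices):
    return HomologousModel(vertices, template.mesh.faces, source_id="m")


class TestNormalizeScale:
    def test_template_itself_unchanged(self, app_template):
        m = _model_from(app_template, app_template.mesh.vertices.copy())
        out = hs.normalize_scale(m, app_template)
        np.testing.assert_allclose(out.vertices, app_template.mesh.vertices, atol=1e-9)

    def test_double_size_model_halved(self, app_template):
        c = app_template.mesh.vertices.mean(axis=0)
        m = _model_from(app_template, c + 2.0 * (app_template.mesh.vertices - c))
        out = hs.normalize_scale(m, app_template)
        np.testing.assert_allclose(out.vertices, app_template.mesh.vertices, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_closed_form_matches_scalar_minimizer(self, app_template, seed):
        """The closed-form scale equals a 1-D numeric minimizer of the
        summed squared vertex distance."""
        rng = np.random.default_rng(seed)
        verts = app_template.mesh.vertices * rng.uniform(0.5, 2.0) \
            + rng.normal(scale=3.0, size=app_template.mesh.vertices.shape) \
            + rng.normal(scale=20.0, size=3)
        m = _model_from(app_template, verts)
        out = hs.normalize_scale(m, app_template)
        t = app_template.mesh.vertices
        x = verts - verts.mean(axis=0)
        tc = t - t.mean(axis=0)
        res = minimize_scalar(
            lambda s: np.sum((s * x - tc) ** 2), bounds=(1e-3, 1e3), method="bounded",
            options={"xatol": 1e-12},
        )
        s_closed = np.linalg.norm(out.vertices - out.vertices.mean(0)) / np.linalg.norm(x)
        assert s_closed == pytest.approx(res.x, abs=1e-9)

    def test_zero_spread_rejected(self, app_template):
        m = _model_from(app_template, np.zeros_like(app_template.mesh.vertices))
        with pytest.raises(ValueError):
            hs.normalize_scale(m, app_template)


def _toy_population(n=20, p=30, seed=0, groups=None):
    rng = np.random.default_rng(seed)
    rows = rng.normal(size=(n, p))
    g = groups if groups is not None else (np.arange(n) % 2)
    return ShapePopulation(rows, [f"s{i}" for i in range(n)], g)


class TestRunPca:
    def test_identical_rows_rejected(self):
        pop = ShapePopulation(np.ones((5, 9)), [f"s{i}" for i in range(5)],
                              np.array([0, 0, 0, 1, 1]))
        with pytest.raises(ValueError):
            hs.run_pca(pop, k=1)

    def test_two_distinct_rows_single_component(self):
        pop = ShapePopulation(
            np.array([[0.0, 0, 0, 0, 0, 0], [1.0, 2, 0, 0, 0, 1]]),
            ["a", "b"], np.array([0, 1]),
        )
        pca = hs.run_pca(pop, k=1)
        assert pca.ratios[0] == pytest.approx(100.0)

    def test_k_out_of_range(self):
        pop = _toy_population()
        with pytest.raises(ValueError):
            hs.run_pca(pop, k=0)
        with pytest.raises(ValueError):
            hs.run_pca(pop, k=25)

    def test_components_orthonormal_and_sds_match_score_variance(self):
        pop = _toy_population()
        pca = hs.run_pca(pop, k=6)
        np.testing.assert_allclose(pca.components @ pca.components.T, np.eye(6),
                                   atol=1e-8)
        S = (pop.rows - pca.mean) @ pca.components.T
        np.testing.assert_allclose(pca.sds**2, S.var(axis=0, ddof=1), atol=1e-8)
        assert np.all(np.diff(pca.cumulative) >= -1e-12)
        assert pca.ratios.sum() <= 100.0 + 1e-9

    def test_total_variance_conserved(self):
        pop = _toy_population(n=15, p=12, seed=3)
        pca = hs.run_pca(pop, k=12)
        centered = pop.rows - pop.rows.mean(axis=0)
        total = (centered**2).sum() / (len(pop.rows) - 1)
        assert (pca.sds**2).sum() == pytest.approx(total, rel=1e-6)

    def test_default_k_by_cumulative_threshold(self):
        pop = _toy_population(n=30, p=40, seed=1)
        pca = hs.run_pca(pop)
        assert pca.cumulative[-1] >= 80.0
        if pca.k > 1:
            assert pca.cumulative[-2] < 80.0

    def test_sign_convention_deterministic(self):
        pop = _toy_population(seed=4)
        a = hs.run_pca(pop, k=4)
        b = hs.run_pca(pop, k=4)
        np.testing.assert_array_equal(a.components, b.components)
        for comp in a.components:
            disp = comp.reshape(-1, 3)
            i = np.argmax((disp**2).sum(axis=1))
            assert disp[i][2] >= 0 or (disp[i][2] == 0 and disp[i][1] >= 0)

    def test_invariant_to_common_rigid_transform(self):
        """Scores are unchanged when every specimen is moved by one common
        rigid transform (co-aligned population)."""
        pop = _toy_population(n=12, p=30, seed=5)
        rng = np.random.default_rng(0)
        q = rng.normal(size=4); q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
        t = rng.normal(size=3) * 10
        moved = (pop.rows.reshape(12, -1, 3) @ R.T + t).reshape(12, -1)
        pop2 = ShapePopulation(moved, pop.ids, pop.groups)
        p1 = hs.run_pca(pop, k=5)
        p2 = hs.run_pca(pop2, k=5)
        s1 = np.abs((pop.rows - p1.mean) @ p1.components.T)
        s2 = np.abs((pop2.rows - p2.mean) @ p2.components.T)
        np.testing.assert_allclose(s1, s2, atol=1e-6)


@pytest.fixture(scope="module")
def toy_pca():
    return hs.run_pca(_toy_population(seed=2), k=5)


@pytest.fixture(scope="module")
def toy_pca_with_faces():
    p = hs.run_pca(_toy_population(seed=2), k=5)
    p.faces = np.array([[0, 1, 2], [0, 2, 3]])
    return p


class TestProjectReconstruct:
    @pytest.fixture
    def pca(self, toy_pca):
        return toy_pca

    def test_mean_projects_to_zero(self, pca):
        np.testing.assert_allclose(hs.project(pca.mean, pca), 0.0, atol=1e-8)

    def test_unit_sd_displacement_projects_to_sd(self, pca):
        row = pca.mean + pca.sds[2] * pca.components[2]
        s = hs.project(row, pca)
        expect = np.zeros(5)
        expect[2] = pca.sds[2]
        np.testing.assert_allclose(s, expect, atol=1e-8)

    def test_project_reconstruct_identity(self, pca):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=5)
        back = hs.project(hs.reconstruct(pca, scores), pca)
        np.testing.assert_allclose(back, scores, atol=1e-8)

    def test_length_mismatch_rejected(self, pca):
        with pytest.raises(ValueError):
            hs.project(np.zeros(7), pca)


class TestMorphAtSd:
    @pytest.fixture
    def pca(self, toy_pca_with_faces):
        return toy_pca_with_faces

    def test_zero_sd_is_mean_shape(self, pca):
        m = hs.morph_at_sd(pca, 1, 0.0)
        np.testing.assert_array_equal(m.vertices.reshape(-1), pca.mean)

    def test_projection_of_plus_three_sd(self, pca):
        m = hs.morph_at_sd(pca, 2, 3.0)
        s = hs.project(m.vertices.reshape(-1), pca)
        assert s[1] == pytest.approx(3.0 * pca.sds[1], abs=1e-8)
        np.testing.assert_allclose(np.delete(s, 1), 0.0, atol=1e-8)

    def test_plus_minus_pair_averages_to_mean(self, pca):
        plus = hs.morph_at_sd(pca, 3, 3.0).vertices
        minus = hs.morph_at_sd(pca, 3, -3.0).vertices
        np.testing.assert_allclose(
            0.5 * (plus + minus), pca.mean.reshape(-1, 3), atol=1e-9
        )

    def test_component_out_of_range(self, pca):
        with pytest.raises(ValueError):
            hs.morph_at_sd(pca, 6, 3.0)


def test_scores_table_layout():
    pop = _toy_population(n=10, p=12, seed=8)
    pca = hs.run_pca(pop, k=3)
    df = scores_table(pop, pca)
    assert list(df.columns) == ["specimen", "group", "PC1", "PC2", "PC3"]
    assert len(df) == 10
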