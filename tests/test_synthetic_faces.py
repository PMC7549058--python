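import numpy as np
import pytest

from impressionface.landmark_io import LandmarkConfiguration
from impressionface.synthetic_faces import (
    DEFAULT_ITEMS,
    RatingSimConfig,
    ShapeSimConfig,
    build_template,
    default_item_intercepts,
    default_item_loadings,
    default_shape_sim_config,
    planted_component_count,
    render_schematic,
    simulate_ratings,
    simulate_shapes,
    simulate_stimulus_ratings,
)


class TestTemplate:
    def test_default_template_counts_and_symmetry(self, template):
        assert template.scheme.n_landmarks == 72
        assert len(template.scheme.semilandmarks) == 36
        base = template.base.points
        np.testing.assert_allclose(base.mean(axis=0), 0, atol=1e-12)
        assert np.sqrt((base**2).sum()) == pytest.approx(1.0)
        perm = template.scheme.reflection_permutation()
        mirror = base.copy()
        mirror[:, 0] = -mirror[:, 0]
        assert np.abs(mirror[perm] - base).max() < 1e-9

    def test_scheme_pairing_covers_all_indices(self, template):
        s = template.scheme
        covered = sorted([i for p in s.pairs for i in p] + list(s.midline))
        assert covered == list(range(72))
        perm = s.reflection_permutation()
        np.testing.assert_array_equal(perm[perm], np.arange(72))

    def test_every_semilandmark_on_exactly_one_curve(self, template):
        owners = {}
        for ci, curve in enumerate(template.scheme.curves):
            for idx in curve:
                if idx in template.scheme.semilandmarks:
                    assert idx not in owners
                    owners[idx] = ci
        assert sorted(owners) == sorted(template.scheme.semilandmarks)

    def test_odd_outline_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            build_template(n_outline=7)


class TestSimulateShapes:
    def test_noiseless_single_factor_is_exact_linear_model(self, template):
        cfg = default_shape_sim_config(template, n_faces=5, seed=1)
        cfg.factor_fields = cfg.factor_fields[:1]
        cfg.factor_sd = cfg.factor_sd[:1]
        cfg.landmark_noise_sd = 0.0
        configs, z = simulate_shapes(template, cfg)
        for i, c in enumerate(configs):
            expected = template.base.points + z[i, 0] * cfg.factor_sd[0] * cfg.factor_fields[0]
            np.testing.assert_allclose(c.points, expected, atol=1e-12)

    def test_same_seed_is_bit_identical(self, template):
        cfg = default_shape_sim_config(template, n_faces=8, seed=42)
        c1, z1 = simulate_shapes(template, cfg)
        c2, z2 = simulate_shapes(template, cfg)
        np.testing.assert_array_equal(z1, z2)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.points, b.points)

    def test_factor_projection_variance_matches_spread(self, template):
        """Monte-Carlo: projections of simulated deviations onto each planted
        field have variance factor_sd^2 (within 10%)."""
        n = 2000
        cfg = default_shape_sim_config(template, n_faces=n, seed=9)
        configs, _ = simulate_shapes(template, cfg)
        dev = np.stack([c.points - template.base.points for c in configs]).reshape(n, -1)
        for d in range(cfg.factor_sd.size):
            proj = dev @ cfg.factor_fields[d].ravel()
            ratio = proj.var(ddof=1) / cfg.factor_sd[d] ** 2
            assert 0.9 < ratio < 1.1

    def test_orthonormality_validated(self, template):
        cfg = default_shape_sim_config(template, n_faces=3, seed=0)
        flat = cfg.factor_fields.reshape(cfg.factor_fields.shape[0], -1)
        np.testing.assert_allclose(flat @ flat.T, np.eye(flat.shape[0]), atol=1e-8)
        bad = ShapeSimConfig(
            n_faces=3,
            factor_fields=np.stack([cfg.factor_fields[0], cfg.factor_fields[0]]),
            factor_sd=np.array([0.01, 0.01]),
            seed=0,
        )
        with pytest.raises(ValueError, match="orthonormal"):
            simulate_shapes(template, bad)

    def test_planted_component_count_matches_pipeline_selection(self, template):
        from impressionface.shape_pipeline import (
            generalized_procrustes,
            select_components,
            shape_pca,
            slide_semilandmarks,
            symmetrize,
        )

        cfg = default_shape_sim_config(template, n_faces=102, seed=3)
        configs, z = simulate_shapes(template, cfg)
        slid = slide_semilandmarks(configs, template.scheme)
        proc = generalized_procrustes(symmetrize(slid, template.scheme))
        selected = select_components(shape_pca(proc), 0.95)
        assert len(selected) == planted_component_count(cfg, latent=z)


class TestSimulateRatings:
    def test_noiseless_ratings_are_deterministic_affine(self):
        z = np.array([[1.0, -1.0], [0.0, 2.0]])
        cfg = RatingSimConfig(rater_sd=0.0, residual_sd=0.0, n_raters=3, seed=0)
        table = simulate_ratings(z, cfg)
        expected = cfg.item_intercepts[None, :] + z @ cfg.item_loadings.T
        for r in range(3):
            np.testing.assert_allclose(table.values[:, :, r], np.clip(expected, 0, 100), atol=1e-12)

    def test_flat_intercepts_zero_loadings_average_fifty(self):
        z = np.random.default_rng(1).standard_normal((40, 2))
        cfg = RatingSimConfig(
            item_intercepts=np.full(18, 50.0),
            item_loadings=np.zeros((18, 2)),
            rater_sd=2.0,
            residual_sd=3.0,
            n_raters=24,
            seed=4,
        )
        table = simulate_ratings(z, cfg)
        assert np.abs(table.values.mean() - 50.0) < 1.0

    def test_fewer_than_two_raters_rejected(self):
        with pytest.raises(ValueError, match="raters"):
            simulate_ratings(np.zeros((3, 2)), RatingSimConfig(n_raters=1))

    def test_values_respect_scale_bounds(self):
        z = 5 * np.random.default_rng(2).standard_normal((30, 2))
        table = simulate_ratings(z, RatingSimConfig(n_raters=5, seed=3, residual_sd=30.0))
        assert table.values.min() >= 0 and table.values.max() <= 100

    def test_stimulus_ratings_long_format(self):
        levels = [(v, d) for v in (-3, 0, 3) for d in (-3, 0, 3)]
        df = simulate_stimulus_ratings(levels, RatingSimConfig(n_raters=4, seed=1))
        assert len(df) == 4 * 9 * 18
        assert set(df.columns) == {"rater", "item", "valence_level", "dominance_level", "score"}
        assert df["score"].between(0, 100).all()


class TestRenderSchematic:
    def test_symmetric_template_renders_mirror_symmetric(self, template):
        img = render_schematic(template.base, size=128, template=template)
        diff = np.abs(img.astype(int) - img[:, ::-1].astype(int)).max()
        assert diff <= 1

    def test_deterministic(self, template):
        i1 = render_schematic(template.base, size=96, template=template)
        i2 = render_schematic(template.base, size=96, template=template)
        np.testing.assert_array_equal(i1, i2)

    def test_integer_translation_equivariance(self, template):
        pix = template.base.points * 400 + 96
        c1 = LandmarkConfiguration("a", pix)
        c2 = LandmarkConfiguration("b", pix + np.array([6.0, -4.0]))
        i1 = render_schematic(c1, size=192, fit=False, template=template)
        i2 = render_schematic(c2, size=192, fit=False, template=template)
        rolled = np.roll(np.roll(i1, 4, axis=0), 6, axis=1)
        np.testing.assert_array_equal(rolled[20:-20, 20:-20], i2[20:-20, 20:-20])

    def test_degenerate_configuration_rejected(self, template):
        flat = LandmarkConfiguration("x", np.tile([[1.0, 2.0]], (72, 1)))
        with pytest.raises(ValueError, match="zero extent"):
            render_schematic(flat, template=template)


def test_default_item_tables_consistent():
    assert default_item_loadings().shape == (18, 2)
    assert default_item_intercepts().shape == (18,)
    assert len(DEFAULT_ITEMS) == 18
    v, d = default_item_loadings().T
    assert abs(v @ d) < 1e-9  # identifiable planted directions
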