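import numpy as np
import pytest
from scipy.spatial import procrustes as scipy_procrustes

from impressionface.shape_pipeline import (
    LandmarkScheme,
    bending_energy_matrix,
    centroid_size,
    generalized_procrustes,
    select_components,
    shape_pca,
    slide_semilandmarks,
    symmetrize,
)
from impressionface.synthetic_faces import default_shape_sim_config, simulate_shapes


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestGeneralizedProcrustes:
    def test_similarity_transformed_copy_aligns_exactly(self, rng):
        a = rng.standard_normal((7, 2))
        b = 3.2 * a @ _rot(0.7).T + np.array([10.0, -4.0])
        res = generalized_procrustes([a, b] if False else np.stack([a, b]))
        assert np.linalg.norm(res.aligned[0] - res.aligned[1]) < 1e-8

    def test_pure_scale_triangles_align(self):
        t1 = np.array([[0.0, 0], [1, 0], [0, 1]])
        res = generalized_procrustes(np.stack([t1, 2 * t1]))
        np.testing.assert_allclose(res.aligned[0], res.aligned[1], atol=1e-10)

    def test_pairwise_distances_match_two_shape_oracle(self, rng):
        base = rng.standard_normal((5, 2))
        configs = base[None] + 0.02 * rng.standard_normal((3, 5, 2))
        res = generalized_procrustes(configs)
        for i in range(3):
            for j in range(i + 1, 3):
                d_gpa = np.linalg.norm(res.aligned[i] - res.aligned[j])
                # independent two-shape fit (scipy standardizes to unit norm);
                # the two-shape optimum lower-bounds the GPA pairwise distance
                # and nearly attains it for shapes close to the consensus
                _, _, disparity = scipy_procrustes(configs[i], configs[j])
                assert np.sqrt(disparity) <= d_gpa + 1e-9
                assert d_gpa <= np.sqrt(disparity) * 1.02 + 1e-9

    def test_invariant_to_input_transformations_and_order(self, rng):
        configs = rng.standard_normal((4, 6, 2))
        res1 = generalized_procrustes(configs)
        moved = configs.copy()[::-1]
        moved[0] = 0.4 * moved[0] @ _rot(-1.2).T + 7.7
        res2 = generalized_procrustes(moved)
        d1 = np.sort([np.linalg.norm(a - res1.mean_shape) for a in res1.aligned])
        d2 = np.sort([np.linalg.norm(a - res2.mean_shape) for a in res2.aligned])
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_mean_is_coordinate_mean_of_aligned(self, rng):
        configs = rng.standard_normal((5, 8, 2))
        res = generalized_procrustes(configs)
        m = res.aligned.mean(axis=0)
        m /= np.sqrt((m**2).sum())
        np.testing.assert_allclose(m, res.mean_shape, atol=1e-8)
        assert centroid_size(res.mean_shape) == pytest.approx(1.0)

    def test_zero_size_configuration_rejected(self):
        bad = np.stack([np.zeros((4, 2)), np.ones((4, 2))])
        with pytest.raises(ValueError, match="zero centroid size"):
            generalized_procrustes(bad)


class TestBendingEnergy:
    def _oracle_energy(self, ref, v):
        """Bending energy via an explicit TPS fit: w' U w of the fitted weights."""
        k = ref.shape[0]
        d2 = ((ref[:, None] - ref[None]) ** 2).sum(-1)
        U = np.where(d2 > 0, d2 * np.log(np.where(d2 > 0, d2, 1)), 0.0)
        Q = np.column_stack([np.ones(k), ref])
        L = np.zeros((k + 3, k + 3))
        L[:k, :k] = U
        L[:k, k:] = Q
        L[k:, :k] = Q.T
        rhs = np.zeros(k + 3)
        rhs[:k] = v
        w = np.linalg.solve(L, rhs)[:k]
        return float(w @ U @ w)

    def test_affine_null_space(self, rng):
        ref = rng.uniform(0, 10, (9, 2))
        E = bending_energy_matrix(ref)
        np.testing.assert_allclose(E @ np.ones(9), 0, atol=1e-8)
        np.testing.assert_allclose(E @ ref[:, 0], 0, atol=1e-8)
        np.testing.assert_allclose(E @ ref[:, 1], 0, atol=1e-8)

    def test_symmetric_positive_semidefinite(self, rng):
        ref = rng.uniform(0, 10, (8, 2))
        E = bending_energy_matrix(ref)
        np.testing.assert_allclose(E, E.T, atol=1e-10)
        assert np.linalg.eigvalsh(E).min() > -1e-10

    def test_quadratic_form_matches_direct_tps_fit(self, rng):
        ref = rng.uniform(0, 10, (10, 2))
        E = bending_energy_matrix(ref)
        v = np.zeros(10)
        v[3] = 1.0  # localized bump
        assert v @ E @ v == pytest.approx(self._oracle_energy(ref, v), rel=1e-8)
        assert v @ E @ v > 1e-6
        affine = 0.3 * ref[:, 0] - 0.1 * ref[:, 1] + 2.0
        assert affine @ E @ affine == pytest.approx(0.0, abs=1e-8)

    def test_coincident_points_rejected(self):
        ref = np.array([[0.0, 0], [1, 1], [1, 1], [2, 0]])
        with pytest.raises(ValueError, match="singular"):
            bending_energy_matrix(ref)


def _toy_scheme():
    """7 points: a horizontal 5-point curve (3 semis) + 2 anchor points."""
    return LandmarkScheme(
        n_landmarks=7,
        semilandmarks=(1, 2, 3),
        curves=((0, 1, 2, 3, 4),),
        pairs=((0, 4), (1, 3), (5, 6)),
        midline=(2,),
    )


def _toy_configs(n=6, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base = np.array(
        [[-2.0, 0], [-1, 0.3], [0, 0.42], [1, 0.3], [2, 0], [-1.0, -1.5], [1.0, -1.5]]
    )
    return base[None] + noise * rng.standard_normal((n, 7, 2))


class TestSliding:
    def test_consensus_input_slides_are_zero(self):
        configs = _toy_configs(n=4, noise=0.0)
        out = slide_semilandmarks(configs, _toy_scheme(), n_iter=2)
        np.testing.assert_allclose(out[0], out[1], atol=1e-10)
        res = generalized_procrustes(configs)
        np.testing.assert_allclose(out, res.aligned, atol=1e-9)

    def test_tangential_perturbation_is_restored(self):
        scheme = _toy_scheme()
        configs = _toy_configs(n=5, noise=0.0)
        res = generalized_procrustes(configs)
        aligned = res.aligned.copy()
        # displace one semilandmark along its own tangent direction
        tangent = aligned[0, 3] - aligned[0, 1]
        tangent /= np.linalg.norm(tangent)
        aligned[0, 2] += 0.08 * tangent
        out = slide_semilandmarks(aligned, scheme, n_iter=3)
        consensus = out[1:].mean(axis=0)
        resid = np.linalg.norm(out[0, 2] - consensus[2])
        assert resid < 0.01 * np.linalg.norm(consensus[2] - consensus[1] + 1e-12) + 1e-3

    def test_fixed_landmarks_do_not_move_within_configuration(self, rng):
        scheme = _toy_scheme()
        configs = _toy_configs(n=6, noise=0.02, seed=3)
        res = generalized_procrustes(configs)
        out = slide_semilandmarks(res.aligned.copy(), scheme, n_iter=2)
        # fixed landmarks may be rotated/rescaled by the re-run GPA but their
        # positions relative to each other are untouched by sliding itself
        for i in range(6):
            before = res.aligned[i][[0, 4, 5, 6]]
            after = out[i][[0, 4, 5, 6]]
            d_before = np.linalg.norm(before[0] - before[2])
            d_after = np.linalg.norm(after[0] - after[2])
            assert d_after == pytest.approx(d_before, rel=1e-2)

    def test_total_bending_energy_non_increasing(self):
        scheme = _toy_scheme()
        configs = _toy_configs(n=8, noise=0.03, seed=5)

        def total_energy(arr):
            res = generalized_procrustes(arr)
            E = bending_energy_matrix(res.mean_shape)
            tot = 0.0
            for a in res.aligned:
                d = a - res.mean_shape
                tot += d[:, 0] @ E @ d[:, 0] + d[:, 1] @ E @ d[:, 1]
            return tot

        e_init = total_energy(configs)
        e_prev = e_init
        arr = configs
        for _ in range(3):
            arr = slide_semilandmarks(arr, scheme, n_iter=1)
            e_now = total_energy(arr)
            # each sliding pass minimizes against the previous consensus; the
            # GPA re-run can move the consensus slightly, so allow a small
            # relative tolerance while requiring a large overall decrease
            assert e_now <= e_prev * (1 + 1e-3)
            e_prev = e_now
        assert e_prev < 0.9 * e_init

    def test_zero_length_tangent_rejected(self):
        scheme = _toy_scheme()
        configs = _toy_configs(n=3, noise=0.01, seed=8)
        configs[0, 1] = configs[0, 3]  # collapse one config's curve neighbors
        with pytest.raises(ValueError, match="tangent"):
            slide_semilandmarks(configs, scheme, n_iter=1)


def _square_scheme():
    return LandmarkScheme(
        n_landmarks=4,
        semilandmarks=(),
        curves=(),
        pairs=((0, 1), (2, 3)),
        midline=(),
    )


class TestSymmetrize:
    def test_symmetric_configuration_is_a_fixed_point(self):
        sq = np.array([[-1.0, 1], [1, 1], [-1, -1], [1, -1]])
        out = symmetrize(sq[None], _square_scheme())
        np.testing.assert_allclose(out[0], sq, atol=1e-9)

    def test_single_landmark_displacement_is_shared_with_partner(self):
        """Hand computation: square with landmark 0 displaced by (2e, 2e).
        Reflection is taken about the centroid's vertical axis (centroid x is
        e/2), so averaging with the relabeled mirror puts +e on both partners'
        y, and on x the displaced landmark keeps 1.5e while its partner gives
        up e/2 (rotation corrections are second order)."""
        sq = np.array([[-1.0, 1], [1, 1], [-1, -1], [1, -1]])
        eps = 1e-3
        bumped = sq.copy()
        bumped[0] += [2 * eps, 2 * eps]
        out = symmetrize(bumped[None], _square_scheme())[0]
        assert out[0][1] - sq[0][1] == pytest.approx(eps, rel=0.05)
        assert out[1][1] - sq[1][1] == pytest.approx(eps, rel=0.05)
        assert out[0][0] - sq[0][0] == pytest.approx(1.5 * eps, rel=0.05)
        assert out[1][0] - sq[1][0] == pytest.approx(-0.5 * eps, rel=0.05)

    def test_output_is_reflection_invariant_for_random_input(self, template, rng):
        pts = template.base.points + 0.01 * rng.standard_normal((72, 2))
        out = symmetrize(pts[None], template.scheme)[0]
        perm = template.scheme.reflection_permutation()
        c = out.mean(axis=0)
        mirror = out.copy()
        mirror[:, 0] = 2 * c[0] - mirror[:, 0]
        np.testing.assert_allclose(mirror[perm], out, atol=1e-9)

    def test_idempotence(self, template, rng):
        pts = template.base.points + 0.02 * rng.standard_normal((2, 72, 2))
        once = symmetrize(pts, template.scheme)
        twice = symmetrize(once, template.scheme)
        np.testing.assert_allclose(once, twice, atol=1e-8)

    def test_non_involutive_pairing_rejected(self):
        scheme = LandmarkScheme(
            n_landmarks=4, semilandmarks=(), curves=(), pairs=((0, 1), (2, 3)), midline=()
        )
        scheme.pairs = ((0, 1), (1, 2))  # corrupt after validation
        with pytest.raises(ValueError, match="involution"):
            symmetrize(np.zeros((1, 4, 2)) + np.arange(8).reshape(4, 2), scheme)


class TestShapePCA:
    def test_identical_configurations_have_zero_variance(self):
        arr = np.tile(np.random.default_rng(0).standard_normal((5, 2)), (4, 1, 1))
        res = generalized_procrustes(arr)
        space = shape_pca(res)
        np.testing.assert_allclose(space.variance_explained, 0, atol=1e-12)

    def test_noiseless_single_factor_recovery(self, template):
        cfg = default_shape_sim_config(template, n_faces=60, seed=21)
        field = cfg.factor_fields[:1]
        cfg.factor_fields = field
        cfg.factor_sd = np.array([0.005])
        cfg.landmark_noise_sd = 0.0
        configs, _ = simulate_shapes(template, cfg)
        res = generalized_procrustes(configs)
        space = shape_pca(res)
        # superimposition is mildly nonlinear, so "100%" holds to ~sd^2
        assert space.variance_explained[0] == pytest.approx(1.0, abs=1e-4)
        cosine = abs(space.components[0] @ field[0].ravel())
        assert cosine > 0.999

    def test_reconstruction_completeness(self, rng):
        arr = rng.standard_normal((6, 5, 2))
        res = generalized_procrustes(arr)
        space = shape_pca(res)
        rebuilt = space.mean_shape.ravel() + space.scores @ space.components
        np.testing.assert_allclose(rebuilt.reshape(6, 5, 2), res.aligned, atol=1e-8)

    def test_components_orthonormal(self, rng):
        arr = rng.standard_normal((8, 6, 2))
        space = shape_pca(generalized_procrustes(arr))
        gram = space.components @ space.components.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)


@pytest.mark.parametrize(
    "shares,threshold,expected",
    [
        ((0.6, 0.3, 0.1), 0.95, 3),
        ((0.6, 0.3, 0.1), 0.6, 1),
        ((0.6, 0.3, 0.1), 1.0, 3),
        ((0.5, 0.5, 0.0), 1.0, 2),
    ],
)
def test_select_components(shares, threshold, expected):
    from impressionface.shape_pipeline import ShapeSpace

    space = ShapeSpace(
        scores=np.zeros((3, len(shares))),
        components=np.eye(len(shares), 6),
        variance_explained=np.array(shares),
        mean_shape=np.zeros((3, 2)),
    )
    assert len(select_components(space, threshold)) == expected


def test_select_components_rejects_bad_threshold():
    from impressionface.shape_pipeline import ShapeSpace

    space = ShapeSpace(
        scores=np.zeros((3, 2)),
        components=np.eye(2, 6),
        variance_explained=np.array([0.7, 0.3]),
        mean_shape=np.zeros((3, 2)),
    )
    with pytest.raises(ValueError):
        select_components(space, 0.0)
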