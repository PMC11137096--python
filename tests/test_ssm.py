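"""PCA shape model: fit, assessment triad, sampling, cohort enumeration."""

import numpy as np
import pytest

from vertemorph.meshkit import MeshError, Shape, make_fixture_family
from vertemorph.ssm_tri import (
    CohortGrid, compactness, compute_covariance, compute_mean,
    enumerate_cohort, fit_model, generalization_loo, load_model,
    project_shape, reconstruct, sample_shape, save_model, specificity,
)


def shapes_from(matrix: np.ndarray):
    return [Shape.from_vector(v) for v in matrix]


class TestMeanAndCovariance:
    def test_mean_identical_and_midpoint(self, rng):
        p = rng.normal(size=(7, 3))
        q = rng.normal(size=(7, 3))
        np.testing.assert_allclose(compute_mean([Shape(p)] * 4),
                                   p.reshape(-1))
        np.testing.assert_allclose(compute_mean([Shape(p), Shape(q)]),
                                   ((p + q) / 2).reshape(-1))

    def test_mean_matches_direct_summation(self, rng):
        shapes = [Shape(rng.normal(size=(9, 3))) for _ in range(7)]
        oracle = sum(s.as_vector() for s in shapes) / 7
        np.testing.assert_allclose(compute_mean(shapes), oracle)

    def test_identical_shapes_zero_covariance(self, rng):
        p = Shape(rng.normal(size=(6, 3)))
        _, _, trace = compute_covariance([p, p, p])
        assert trace == pytest.approx(0.0, abs=1e-20)

    def test_two_shapes_closed_form(self, rng):
        p = rng.normal(size=(5, 3))
        v = rng.normal(size=(5, 3))
        _, _, trace = compute_covariance([Shape(p), Shape(p + v)])
        # single eigenvalue ||v||^2 / 2
        assert trace == pytest.approx(np.sum(v * v) / 2)

    def test_dual_trace_matches_dense_oracle(self, rng):
        shapes = [Shape(rng.normal(size=(5, 3))) for _ in range(10)]
        _, _, trace = compute_covariance(shapes)
        X = np.stack([s.as_vector() for s in shapes])
        dense = np.cov(X.T, ddof=1)
        assert trace == pytest.approx(np.trace(dense))


class TestFitModel:
    def test_dual_equals_dense_eigendecomposition(self, rng):
        # oracle equivalence on a small instance (P <= 20, n <= 12)
        shapes = [Shape(rng.normal(size=(8, 3)) * 3) for _ in range(9)]
        model = fit_model(shapes, m=5)
        X = np.stack([s.as_vector() for s in shapes])
        dense = np.cov(X.T, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(dense))[::-1]
        np.testing.assert_allclose(model.eigenvalues, evals[:5], rtol=1e-9,
                                   atol=1e-12)
        # eigenvectors agree up to sign
        _, vecs = np.linalg.eigh(dense)
        vecs = vecs[:, ::-1][:, :5]
        overlap = np.abs(np.sum(model.modes * vecs, axis=0))
        np.testing.assert_allclose(overlap, 1.0, atol=1e-8)

    def test_single_direction_family(self, rng):
        u = rng.normal(size=30)
        u /= np.linalg.norm(u)
        coeffs = rng.normal(scale=2.0, size=20)
        shapes = shapes_from(np.outer(coeffs, u))
        model = fit_model(shapes, m=1)
        assert model.eigenvalues[0] == pytest.approx(np.var(coeffs, ddof=1))
        assert abs(np.dot(model.modes[:, 0], u)) == pytest.approx(1.0, abs=1e-9)

    def test_planted_subspace_recovered_noise_free(self):
        shapes, mean, modes, var = make_fixture_family(
            P=25, n=200, planted_variances=(9.0, 4.0, 1.0), noise_sd=0.0,
            seed=11)
        model = fit_model(shapes, m=3)
        # principal angles between fitted and planted 3-D subspaces
        s = np.linalg.svd(model.modes.T @ modes, compute_uv=False)
        angles = np.arccos(np.clip(s, -1, 1))
        assert np.max(angles) < 1e-6

    def test_planted_eigenvalues_within_sampling_error(self):
        # fixed-seed Monte-Carlo check; 15 % covers the chi^2 sampling
        # spread of an eigenvalue estimated from n=200 draws
        shapes, *_ , var = make_fixture_family(
            P=25, n=200, planted_variances=(9.0, 4.0, 1.0), noise_sd=0.0,
            seed=4)
        model = fit_model(shapes, m=3)
        np.testing.assert_allclose(model.eigenvalues, var, rtol=0.15)

    def test_eigenvalue_sum_equals_trace(self, rng):
        shapes = [Shape(rng.normal(size=(10, 3))) for _ in range(8)]
        model = fit_model(shapes, m=7)
        assert np.sum(model.eigenvalues) == pytest.approx(
            model.total_variance, rel=1e-8)

    def test_m_bounds(self, rng):
        shapes = [Shape(rng.normal(size=(4, 3))) for _ in range(5)]
        with pytest.raises(MeshError):
            fit_model(shapes, m=5)

    def test_modes_orthonormal(self, rng):
        shapes = [Shape(rng.normal(size=(12, 3))) for _ in range(10)]
        model = fit_model(shapes, m=6)
        np.testing.assert_allclose(model.modes.T @ model.modes, np.eye(6),
                                   atol=1e-8)


class TestSampling:
    @pytest.fixture()
    def model(self, rng):
        shapes = [Shape(rng.normal(size=(10, 3)) * 2) for _ in range(12)]
        return fit_model(shapes, m=5)

    def test_zero_weights_give_mean(self, model):
        s = sample_shape(model, np.zeros(5))
        np.testing.assert_array_equal(s.as_vector(), model.mean)

    def test_unit_weight_single_mode(self, model):
        w = np.zeros(5)
        w[2] = 1.0
        s = sample_shape(model, w)
        expected = model.mean + np.sqrt(model.eigenvalues[2]) * model.modes[:, 2]
        np.testing.assert_allclose(s.as_vector(), expected)

    def test_sample_project_round_trip(self, model, rng):
        w = rng.normal(size=5)
        s = sample_shape(model, w)
        np.testing.assert_allclose(project_shape(model, s), w, atol=1e-10)

    def test_linearity_superposition(self, model, rng):
        w1, w2 = rng.normal(size=5), rng.normal(size=5)
        s12 = sample_shape(model, w1 + w2).as_vector()
        s1 = sample_shape(model, w1).as_vector()
        s2 = sample_shape(model, w2).as_vector()
        np.testing.assert_allclose(s12 - model.mean,
                                   (s1 - model.mean) + (s2 - model.mean),
                                   atol=1e-9)

    def test_weight_length_checked(self, model):
        with pytest.raises(MeshError):
            sample_shape(model, np.zeros(3))


class TestCompactness:
    def test_arithmetic(self):
        model = fit_model_from_eigs([4.0, 3.0, 2.0, 1.0])
        assert compactness(model, 2) == pytest.approx(0.7)

    def test_full_rank_is_one_and_monotone(self, rng):
        shapes = [Shape(rng.normal(size=(6, 3))) for _ in range(7)]
        model = fit_model(shapes, m=6)
        vals = [compactness(model, m) for m in range(1, 7)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_planted_family_compact(self):
        shapes, *_ = make_fixture_family(P=20, n=30,
                                         planted_variances=(9.0, 4.0, 1.0),
                                         noise_sd=0.0, seed=1)
        model = fit_model(shapes, m=3)
        assert compactness(model, 3) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_m(self, rng):
        shapes = [Shape(rng.normal(size=(6, 3))) for _ in range(5)]
        model = fit_model(shapes, m=3)
        with pytest.raises(MeshError):
            compactness(model, 0)


def fit_model_from_eigs(eigs):
    """Tiny helper: a diagonal model with prescribed eigenvalues."""
    from vertemorph.ssm_tri import ShapeModel
    eigs = np.asarray(eigs, dtype=float)
    m = eigs.size
    d = 3 * max(m, 2)
    modes = np.eye(d)[:, :m]
    return ShapeModel(mean=np.zeros(d), modes=modes, eigenvalues=eigs,
                      n_train=m + 1, total_variance=float(np.sum(eigs)))


class TestGeneralization:
    def test_in_span_shape_reconstructs_exactly(self):
        shapes, *_ = make_fixture_family(P=10, n=10,
                                         planted_variances=(4.0, 1.0),
                                         noise_sd=0.0, seed=3)
        mean_err, _, per = generalization_loo(shapes, m=2, seed=0)
        assert np.max(per) < 1e-8

    def test_noise_band(self):
        # with iid coordinate noise sigma, the per-point Euclidean RMSE of
        # an orthogonal projection onto the true m-dim subspace is about
        # sqrt(3) * sigma * sqrt(1 - m/(3P))
        sigma = 0.3
        P, m = 30, 2
        shapes, *_ = make_fixture_family(P=P, n=40,
                                         planted_variances=(25.0, 9.0),
                                         noise_sd=sigma, seed=8)
        mean_err, sd, _ = generalization_loo(shapes, m=m, seed=0)
        expected = np.sqrt(3.0) * sigma * np.sqrt(1 - m / (3 * P))
        assert 0.8 * expected < mean_err < 1.25 * expected

    def test_error_non_increasing_in_m_noise_free(self):
        shapes, *_ = make_fixture_family(P=15, n=20,
                                         planted_variances=(9.0, 4.0, 1.0),
                                         noise_sd=0.0, seed=6)
        errs = [generalization_loo(shapes, m=m, seed=0)[0] for m in (1, 2, 3)]
        assert errs[0] >= errs[1] - 1e-12 >= errs[2] - 2e-12

    def test_m_too_large(self):
        shapes, *_ = make_fixture_family(P=6, n=5, planted_variances=(1.0,),
                                         seed=0)
        with pytest.raises(MeshError):
            generalization_loo(shapes, m=4)


class TestSpecificity:
    def test_degenerate_model_distance_to_mean(self, rng):
        from vertemorph.ssm_tri import ShapeModel
        training = [Shape(rng.normal(size=(8, 3))) for _ in range(5)]
        mean_vec = training[0].as_vector() + 1.0
        model = ShapeModel(mean=mean_vec, modes=np.eye(24)[:, :2],
                           eigenvalues=np.zeros(2), n_train=5,
                           total_variance=0.0)
        mean_err, sd = specificity(model, training, N=10, seed=0)
        # every sample is the mean; RMSE is the distance to nearest training
        T = np.stack([s.as_vector() for s in training])
        d = np.sqrt(np.mean(((T - mean_vec).reshape(len(training), -1, 3) ** 2)
                            .sum(axis=2), axis=1))
        assert mean_err == pytest.approx(d.min())
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_dense_one_mode_training_bounds_specificity(self):
        # training densely samples one mode; random samples fall between
        # grid points, so specificity is bounded by half the grid spacing
        from vertemorph.ssm_tri import ShapeModel
        u = np.zeros(30)
        u[0] = 1.0
        grid = np.arange(-3, 3.01, 0.25)
        training = [Shape.from_vector(g * u) for g in grid]
        model = ShapeModel(mean=np.zeros(30), modes=u[:, None],
                           eigenvalues=np.array([1.0]), n_train=len(grid),
                           total_variance=1.0)
        mean_err, _ = specificity(model, training, N=200, seed=1)
        assert mean_err <= 0.125  # half the grid spacing, worst case


class TestCohort:
    def test_counts(self, rng):
        shapes = [Shape(rng.normal(size=(5, 3))) for _ in range(10)]
        model = fit_model(shapes, m=5)
        assert sum(1 for _ in enumerate_cohort(
            model, CohortGrid(n_modes=1, levels=(-3, -2, -1, 0, 1, 2, 3)))) == 7
        items = list(enumerate_cohort(model, CohortGrid(n_modes=2, levels=(0,))))
        assert len(items) == 1
        np.testing.assert_array_equal(items[0][2].as_vector(), model.mean)

    def test_full_grid_size_is_16807(self):
        assert CohortGrid(n_modes=5, levels=(-3, -2, -1, 0, 1, 2, 3)).size == 16807

    def test_odometer_order_first_mode_slowest(self, rng):
        shapes = [Shape(rng.normal(size=(5, 3))) for _ in range(8)]
        model = fit_model(shapes, m=2)
        items = list(enumerate_cohort(model, CohortGrid(n_modes=2,
                                                        levels=(-1, 1))))
        ws = [tuple(w.w) for _, w, _ in items]
        assert ws == [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        assert [i for i, _, _ in items] == [1, 2, 3, 4]


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        shapes = [Shape(rng.normal(size=(7, 3))) for _ in range(6)]
        model = fit_model(shapes, m=3)
        save_model(model, tmp_path / "m.npz", provenance="test")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.mean, model.mean)
        np.testing.assert_array_equal(back.modes, model.modes)
        np.testing.assert_array_equal(back.eigenvalues, model.eigenvalues)
        assert back.n_train == model.n_train
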