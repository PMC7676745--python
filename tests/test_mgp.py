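import numpy as np
import pytest
from scipy.stats import multivariate_normal

from aaarisk import CohortGeneratorConfig, generate_cohort, mgp_kernel, model1_cohort_lognormal
from aaarisk.mgp import (
    MGPHyperparams,
    MGPModel,
    PredictiveDistribution,
    _cross_kernel,
    _kernel_matrix,
    loocv_benchmark,
    mgp_fit,
)
from conftest import make_dataset


def _hp(zeta=(0.5, 0.3, 0.8, 0.2), S=(0.1, 0.2, 0.3, 0.15), omega=None):
    if omega is None:
        omega = np.array(
            [[1.0, 0.3, 0.2, 0.1], [0.3, 1.2, 0.1, 0.0], [0.2, 0.1, 0.9, 0.25], [0.1, 0.0, 0.25, 0.8]]
        )
    return MGPHyperparams(zeta=np.array(zeta), S_diag=np.array(S), L=np.linalg.cholesky(omega))


def _dense_cov(hp, X, jitter=0.0):
    K = _kernel_matrix(X, hp, jitter)
    n = len(X)
    return np.kron(hp.Omega, K) + np.kron(np.diag(hp.S_diag), np.eye(n))


class TestKernel:
    def test_at_origin_kernel_is_bias_plus_rbf_amplitude(self):
        hp = _hp(zeta=(2.0, 5.0, 3.0, 1.0))
        x = np.zeros(4)
        assert mgp_kernel(x, x, hp) == pytest.approx(2.0 + 3.0)

    def test_pure_bias_kernel_is_constant(self):
        hp = _hp(zeta=(4.0, 1e-300, 1e-300, 1.0))
        rng = np.random.default_rng(0)
        assert mgp_kernel(rng.normal(size=3), rng.normal(size=3), hp) == pytest.approx(4.0)

    def test_unit_parameters_on_orthogonal_unit_vectors(self):
        hp = _hp(zeta=(1.0, 1.0, 1.0, 1.0))
        xi = np.array([1.0, 0.0, 0.0])
        xj = np.array([0.0, 1.0, 0.0])
        assert mgp_kernel(xi, xj, hp) == pytest.approx(1.0 + 0.0 + np.exp(-2.0))

    def test_non_positive_zeta_rejected(self):
        with pytest.raises(ValueError):
            MGPHyperparams(zeta=[1.0, -1.0, 1.0, 1.0], S_diag=np.ones(4), L=np.eye(4))


class TestLogMarginal:
    def test_single_record_closed_form(self):
        # one record, Omega = I, K = [1], S = I, zero targets:
        # four independent N(0, 2) zeros -> -2 log 2 - 2 log 2pi
        hp = _hp(zeta=(0.5, 1e-300, 0.5, 1.0), S=(1.0,) * 4, omega=np.eye(4))
        X = np.zeros((1, 2))  # k(0,0) = 0.5 + 0.5 = 1
        model = MGPModel(hp, X, np.zeros((1, 4)), jitter=0.0)
        expected = -0.5 * 4 * np.log(2.0) - 2.0 * np.log(2.0 * np.pi)
        assert model.log_marginal() == pytest.approx(expected, abs=1e-12)

    def test_scaling_targets_up_decreases_likelihood(self):
        rng = np.random.default_rng(1)
        X, Y = rng.standard_normal((5, 3)), rng.standard_normal((5, 4))
        hp = _hp()
        assert MGPModel(hp, X, 10 * Y).log_marginal() < MGPModel(hp, X, Y).log_marginal()

    def test_matches_dense_gaussian_logpdf_oracle(self):
        rng = np.random.default_rng(2)
        X, Y = rng.standard_normal((5, 3)), rng.standard_normal((5, 4))
        hp = _hp()
        dense = multivariate_normal(
            mean=np.zeros(20), cov=_dense_cov(hp, X)
        ).logpdf(Y.flatten(order="F"))
        assert MGPModel(hp, X, Y, jitter=0.0).log_marginal() == pytest.approx(dense, abs=1e-8)


class TestPredict:
    def test_matches_dense_matrix_oracle(self):
        rng = np.random.default_rng(3)
        X, Y = rng.standard_normal((3, 2)), rng.standard_normal((3, 4))
        hp = _hp()
        model = MGPModel(hp, X, Y, jitter=0.0)
        x_star = rng.standard_normal(2)

        Sig = _dense_cov(hp, X)
        ks = _cross_kernel(X, x_star, hp)
        Cx = np.kron(hp.Omega, ks.reshape(-1, 1))
        y = Y.flatten(order="F")
        mu_o = Cx.T @ np.linalg.solve(Sig, y)
        cov_o = (
            hp.Omega * mgp_kernel(x_star, x_star, hp)
            + np.diag(hp.S_diag)
            - Cx.T @ np.linalg.solve(Sig, Cx)
        )
        pred = model.predict(x_star)
        np.testing.assert_allclose(pred.mu_log_theta, mu_o, atol=1e-8)
        np.testing.assert_allclose(pred.sigma_log_theta, cov_o, atol=1e-8)

    def test_noise_free_limit_interpolates_training_targets(self):
        rng = np.random.default_rng(4)
        X, Y = rng.standard_normal((4, 3)), rng.standard_normal((4, 4))
        hp = _hp(S=(1e-10,) * 4)
        model = MGPModel(hp, X, Y, jitter=0.0)
        np.testing.assert_allclose(model.predict(X[2]).mu_log_theta, Y[2], atol=1e-6)

    def test_far_field_reverts_to_prior_covariance(self):
        rng = np.random.default_rng(5)
        X, Y = rng.standard_normal((4, 3)), rng.standard_normal((4, 4))
        hp = _hp(zeta=(1e-300, 1e-300, 0.7, 0.5))
        model = MGPModel(hp, X, Y, jitter=0.0)
        far = 100.0 * np.ones(3)
        pred = model.predict(far)
        np.testing.assert_allclose(
            pred.sigma_log_theta, hp.Omega * 0.7 + np.diag(hp.S_diag), atol=1e-10
        )

    def test_duplicating_a_record_never_inflates_predictive_variance(self):
        rng = np.random.default_rng(6)
        X, Y = rng.standard_normal((5, 3)), rng.standard_normal((5, 4))
        hp = _hp()
        base = MGPModel(hp, X, Y, jitter=1e-10)
        dup = MGPModel(hp, np.vstack([X, X[0]]), np.vstack([Y, Y[0]]), jitter=1e-10)
        x_star = rng.standard_normal(3)
        v0 = np.diag(base.predict(x_star).sigma_log_theta)
        v1 = np.diag(dup.predict(x_star).sigma_log_theta)
        assert np.all(v1 <= v0 + 1e-10)

    def test_predictive_covariance_is_psd(self):
        rng = np.random.default_rng(7)
        X, Y = rng.standard_normal((8, 3)), rng.standard_normal((8, 4))
        model = MGPModel(_hp(), X, Y)
        for x in rng.standard_normal((10, 3)):
            w = np.linalg.eigvalsh(model.predict(x).sigma_log_theta)
            assert w.min() >= -1e-10

    def test_dimension_mismatch_raises(self):
        model = MGPModel(_hp(), np.zeros((2, 3)), np.zeros((2, 4)))
        with pytest.raises(ValueError, match="dimension"):
            model.predict(np.zeros(5))


class TestIndependentOutputs:
    def test_diagonal_omega_equals_four_single_output_gps(self):
        """Block-diagonal coupling reduces exactly to per-output GP regression."""
        rng = np.random.default_rng(8)
        X, Y = rng.standard_normal((6, 3)), rng.standard_normal((6, 4))
        omega = np.diag([0.9, 1.1, 0.7, 1.3])
        hp = _hp(omega=omega)
        model = MGPModel(hp, X, Y, jitter=0.0)
        x_star = rng.standard_normal(3)
        pred = model.predict(x_star)

        K = _kernel_matrix(X, hp, 0.0)
        ks = _cross_kernel(X, x_star, hp)
        kss = mgp_kernel(x_star, x_star, hp)
        for d in range(4):
            C = omega[d, d] * K + hp.S_diag[d] * np.eye(6)
            mu_d = omega[d, d] * ks @ np.linalg.solve(C, Y[:, d])
            var_d = omega[d, d] * kss + hp.S_diag[d] - omega[d, d] ** 2 * ks @ np.linalg.solve(C, ks)
            assert pred.mu_log_theta[d] == pytest.approx(mu_d, abs=1e-8)
            assert pred.sigma_log_theta[d, d] == pytest.approx(var_d, abs=1e-8)
        off = pred.sigma_log_theta - np.diag(np.diag(pred.sigma_log_theta))
        assert np.abs(off).max() < 1e-10


class TestModel1:
    def test_population_log_moments_hand_example(self):
        t = np.array([1.0, np.e, np.e**2])
        props = np.column_stack([t, np.ones(3), np.ones(3), np.ones(3)])
        ds = make_dataset(np.ones((3, 2)) * np.arange(3)[:, None], props)
        with pytest.warns(UserWarning, match="degenerate"):
            pred = model1_cohort_lognormal(ds)
        assert pred.mu_log_theta[0] == pytest.approx(1.0)
        assert np.sqrt(pred.sigma_log_theta[0, 0]) == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_identical_records_flagged_degenerate(self):
        ds = make_dataset(np.arange(6, dtype=float).reshape(3, 2), np.full((3, 4), 2.0))
        with pytest.warns(UserWarning, match="degenerate"):
            model1_cohort_lognormal(ds)

    def test_physical_space_mean_uses_lognormal_transform(self):
        mu, sd = np.full(4, 6.704), np.full(4, 0.183)
        pred = PredictiveDistribution(mu, np.diag(sd**2))
        assert pred.physical_mean()[3] == pytest.approx(np.exp(6.704 + 0.5 * 0.183**2))


class TestLoocv:
    def test_identity_covariance_entropy_closed_form(self):
        pred = PredictiveDistribution(np.zeros(4), np.eye(4))
        assert pred.entropy() == pytest.approx(2.0 * np.log(2.0 * np.pi * np.e), abs=1e-12)
        assert pred.entropy() == pytest.approx(5.6758, abs=1e-4)

    def test_correlated_model_has_lower_entropy_than_independent(self, small_cohort):
        """At fixed marginals, correlation shrinks |Sigma|, hence the entropy."""
        from aaarisk.cohort_data import preprocess

        ds, _ = preprocess(small_cohort)
        kwargs = dict(restarts=2, maxiter=60, seed=0)
        m2 = loocv_benchmark(ds, "model2", **kwargs)
        m3 = loocv_benchmark(ds, "model3", **kwargs)
        assert np.isfinite(m2.e_psmse) and np.isfinite(m3.e_psmse)
        assert m3.e_ppe <= m2.e_ppe + 0.05

    def test_model1_benchmark_runs_and_scores_are_finite(self, small_cohort):
        res = loocv_benchmark(small_cohort, "model1")
        assert len(res.per_patient) == small_cohort.n_patients
        assert np.isfinite(res.e_psmse) and np.isfinite(res.e_ppe)

    def test_single_patient_cohort_rejected(self):
        ds = make_dataset(np.ones((2, 2)), np.full((2, 4), 2.0), patient_ids=[1, 1])
        with pytest.raises(ValueError, match="2 patients"):
            loocv_benchmark(ds, "model1")


class TestFitSmoke:
    def test_fit_is_deterministic_given_seed(self, small_cohort):
        from aaarisk.cohort_data import preprocess

        ds, _ = preprocess(small_cohort)
        a = mgp_fit(ds, restarts=2, maxiter=40, seed=3)
        b = mgp_fit(ds, restarts=2, maxiter=40, seed=3)
        np.testing.assert_array_equal(
            a.hyperparams.to_vector(), b.hyperparams.to_vector()
        )

    def test_hyperparameter_vector_round_trip(self):
        hp = _hp()
        back = MGPHyperparams.from_vector(hp.to_vector())
        np.testing.assert_allclose(back.Omega, hp.Omega)
        np.testing.assert_allclose(back.to_vector(), hp.to_vector())

    def test_model_json_round_trip_preserves_predictions(self, small_cohort):
        from aaarisk.cohort_data import preprocess

        ds, _ = preprocess(small_cohort)
        model = mgp_fit(ds, restarts=1, maxiter=30, seed=0)
        back = MGPModel.from_json(model.to_json())
        x = ds.feature_matrix()[0]
        np.testing.assert_allclose(
            back.predict(x).mu_log_theta, model.predict(x).mu_log_theta, atol=1e-12
        )
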