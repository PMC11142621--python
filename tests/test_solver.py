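"""Solver checks: proximal operator exactness, ADMM optimality, diagnostics."""

import logging

import numpy as np
import pytest

from fglinfer import (
    AdmmOptions,
    CovarianceSet,
    GroupDataset,
    PenaltySpec,
    correlation_from_cov,
    fgl_admm,
    fused_prox,
    kkt_residual,
    objective,
    sample_covariance,
    weighted_fgl,
)


def fused_prox_grid_oracle(a, lasso, fusion, refinements=6, points=31):
    """Iteratively refined dense grid search for the entrywise Z-subproblem."""
    a = np.asarray(a, dtype=float)
    K = a.size
    center = a.copy()
    width = 2.0 * (np.abs(a).max() + lasso + fusion + 1.0)
    for _ in range(refinements):
        axes = [np.linspace(c - width, c + width, points) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        z = np.stack([m.ravel() for m in mesh])
        cost = 0.5 * ((z - a[:, None]) ** 2).sum(axis=0) + lasso * np.abs(z).sum(axis=0)
        for i in range(K):
            for j in range(i + 1, K):
                cost += fusion * np.abs(z[i] - z[j])
        center = z[:, np.argmin(cost)]
        width = width * 2.0 / (points - 1) * 1.5
    return center


class TestSampleCovariance:
    def test_single_variable_uncentered(self):
        data = GroupDataset(observations=[np.array([[1.0], [-1.0]])])
        assert np.allclose(sample_covariance(data).covariances[0], [[1.0]])

    def test_centering_removes_constant_column(self):
        x = np.column_stack([np.full(4, 3.0), np.arange(4.0)])
        covs = sample_covariance(GroupDataset(observations=[x]), center=True)
        assert np.allclose(covs.covariances[0][0], 0.0)

    def test_outer_product_sum(self):
        data = GroupDataset(observations=[np.array([[1.0, 0.0], [0.0, 1.0]])])
        expected = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert np.allclose(sample_covariance(data).covariances[0], expected)


class TestCorrelationFromCov:
    def test_direct_computation(self):
        covs = CovarianceSet(np.array([[[4.0, 2.0], [2.0, 4.0]]]), [10])
        corr = correlation_from_cov(covs)
        assert np.allclose(corr.covariances[0], [[1.0, 0.5], [0.5, 1.0]])
        assert np.allclose(corr.scale_roots[0], [2.0, 2.0])

    def test_idempotent_on_correlations(self):
        r = np.array([[1.0, 0.3], [0.3, 1.0]])
        corr = correlation_from_cov(CovarianceSet(r[None], [10]))
        assert np.allclose(corr.covariances[0], r)
        assert np.allclose(corr.scale_roots[0], 1.0)

    def test_zero_variance_rejected(self):
        covs = CovarianceSet(np.array([[[0.0, 0.0], [0.0, 1.0]]]), [10])
        with pytest.raises(ValueError):
            correlation_from_cov(covs)


class TestFusedProx:
    def test_no_penalty_is_identity(self):
        a = [0.4, -1.2, 2.0]
        assert np.allclose(fused_prox(a, 1.0, 0.0, 0.0), a)

    def test_single_group_soft_threshold(self):
        assert fused_prox([2.0], 1.0, 1.0, 0.0)[0] == pytest.approx(1.0)

    def test_two_group_full_fusion(self):
        assert np.allclose(fused_prox([1.0, -1.0], 1.0, 0.0, 1.0), [0.0, 0.0])

    def test_diagonal_passthrough(self):
        a = [3.0, -2.0]
        assert np.allclose(fused_prox(a, 1.0, 5.0, 5.0, is_diagonal=True), a)

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_matches_grid_oracle(self, K):
        rng = np.random.default_rng(K)
        for _ in range(40):
            a = rng.uniform(-2, 2, K)
            lasso, fusion = rng.uniform(0, 1, 2)
            mine = fused_prox(a, 1.0, lasso, fusion)
            oracle = fused_prox_grid_oracle(a, lasso, fusion)
            assert np.abs(mine - oracle).max() < 1e-4

    def test_step_scaling(self):
        # minimizing (mu/2)(z-a)^2 + lam|z| soft-thresholds by lam/mu
        out = fused_prox([2.0], 4.0, 1.0, 0.0)
        assert out[0] == pytest.approx(1.75)


class TestFglAdmm:
    def test_identity_covariances_fixed_point(self, tight_opts):
        covs = CovarianceSet(np.stack([np.eye(6)] * 2), [50, 50])
        fit = fgl_admm(covs, PenaltySpec(0.2, 0.1), tight_opts)
        assert np.abs(fit.estimates - np.eye(6)).max() < 1e-7

    def test_unpenalized_recovers_inverse(self, tight_opts):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((100, 3))
        s = x.T @ x / 100
        fit = fgl_admm(CovarianceSet(s[None], [100]), PenaltySpec(0.0, 0.0), tight_opts)
        assert np.abs(fit.estimates[0] - np.linalg.inv(s)).max() < 1e-5

    def test_fusion_limit_matches_pooled_solve(self, random_cov_pair, tight_opts):
        fit = fgl_admm(random_cov_pair, PenaltySpec(0.1, 1e3), tight_opts)
        pooled = CovarianceSet(
            random_cov_pair.covariances.mean(axis=0)[None], [120]
        )
        fit_pooled = fgl_admm(pooled, PenaltySpec(0.1, 0.0), tight_opts)
        assert np.abs(fit.estimates[0] - fit.estimates[1]).max() < 1e-4
        assert np.abs(fit.estimates[0] - fit_pooled.estimates[0]).max() < 1e-4

    def test_large_lasso_gives_diagonal_fit(self, random_cov_pair, tight_opts):
        lam = float(np.abs(random_cov_pair.covariances).max())
        fit = fgl_admm(random_cov_pair, PenaltySpec(lam, 0.0), tight_opts)
        for k, s in enumerate(random_cov_pair.covariances):
            off = fit.consensus[k] - np.diag(np.diag(fit.consensus[k]))
            assert np.abs(off).max() == 0.0
            assert np.abs(np.diag(fit.estimates[k]) - 1.0 / np.diag(s)).max() < 1e-6

    def test_zero_fusion_decouples_groups(self, random_cov_pair, tight_opts):
        joint = fgl_admm(random_cov_pair, PenaltySpec(0.08, 0.0), tight_opts)
        for k in range(2):
            single = fgl_admm(
                CovarianceSet(random_cov_pair.covariances[k][None], [60]),
                PenaltySpec(0.08, 0.0),
                tight_opts,
            )
            assert np.abs(joint.estimates[k] - single.estimates[0]).max() < 1e-5

    def test_estimates_positive_definite_and_symmetric(self, random_cov_pair):
        fit = fgl_admm(random_cov_pair, PenaltySpec(0.1, 0.1))
        for theta in fit.estimates:
            assert np.allclose(theta, theta.T)
            assert np.linalg.eigvalsh(theta)[0] > 0

    def test_objective_beats_feasible_comparators(self, random_cov_pair, tight_opts):
        penalty = PenaltySpec(0.1, 0.05)
        fit = fgl_admm(random_cov_pair, penalty, tight_opts)
        achieved = objective(random_cov_pair, fit, penalty)
        p = random_cov_pair.dimension
        diag_comp = np.stack(
            [np.diag(1.0 / np.diag(s)) for s in random_cov_pair.covariances]
        )
        eye_comp = np.stack([np.eye(p)] * 2)
        assert achieved <= objective(random_cov_pair, diag_comp, penalty) + 1e-8
        assert achieved <= objective(random_cov_pair, eye_comp, penalty) + 1e-8

    def test_nonconvergence_flagged_not_silent(self, random_cov_pair, caplog):
        opts = AdmmOptions(max_iter=2, tol_primal=1e-14, tol_dual=1e-14)
        with caplog.at_level(logging.WARNING):
            fit = fgl_admm(random_cov_pair, PenaltySpec(0.1, 0.1), opts)
        assert not fit.converged
        assert any("did not converge" in rec.message for rec in caplog.records)

    def test_matches_sklearn_graphical_lasso(self, random_cov_pair, tight_opts):
        # independent single-group oracle for the K=1, rho=0 special case
        from sklearn.covariance import graphical_lasso

        s = random_cov_pair.covariances[0]
        _, prec = graphical_lasso(s, alpha=0.1, tol=1e-10, max_iter=2000)
        fit = fgl_admm(CovarianceSet(s[None], [60]), PenaltySpec(0.1, 0.0), tight_opts)
        # sklearn stops at its own duality-gap tolerance; 5e-4 absorbs that
        assert np.abs(fit.estimates[0] - prec).max() < 5e-4


class TestWeightedFgl:
    def test_unit_variances_match_plain(self, random_cov_pair, tight_opts):
        penalty = PenaltySpec(0.1, 0.05)
        plain = fgl_admm(random_cov_pair, penalty, tight_opts)
        weighted = weighted_fgl(random_cov_pair, penalty, tight_opts)
        assert np.abs(plain.estimates - weighted.estimates).max() < 1e-6

    def test_scaled_identity_covariance(self, tight_opts):
        covs = CovarianceSet(np.stack([4.0 * np.eye(4)] * 2), [30, 30])
        fit = weighted_fgl(covs, PenaltySpec(0.3, 0.2), tight_opts)
        assert np.abs(fit.estimates - 0.25 * np.eye(4)).max() < 1e-7
        assert np.abs(fit.correlation_estimates - np.eye(4)).max() < 1e-7

    def test_back_transform_identity(self, random_cov_pair, tight_opts):
        # Theta_R = W Theta_w W by construction
        covs = CovarianceSet(
            random_cov_pair.covariances * np.array([4.0, 9.0])[:, None, None],
            random_cov_pair.group_sizes,
        )
        fit = weighted_fgl(covs, PenaltySpec(0.1, 0.05), tight_opts)
        w = fit.scale_roots
        rebuilt = fit.estimates * w[:, :, None] * w[:, None, :]
        assert np.abs(rebuilt - fit.correlation_estimates).max() < 1e-10


class TestObjectiveAndKkt:
    def test_identity_value(self):
        covs = CovarianceSet(np.stack([np.eye(4)] * 2), [10, 10])
        thetas = np.stack([np.eye(4)] * 2)
        assert objective(covs, thetas, PenaltySpec(1.0, 1.0)) == pytest.approx(8.0)

    def test_offdiagonal_perturbation_increases_objective(self):
        covs = CovarianceSet(np.stack([np.eye(4)] * 2), [10, 10])
        base = np.stack([np.eye(4)] * 2)
        perturbed = base.copy()
        delta = 0.1
        perturbed[0, 0, 1] = perturbed[0, 1, 0] = delta
        penalty = PenaltySpec(1.0, 1.0)
        gap = objective(covs, perturbed, penalty) - objective(covs, base, penalty)
        # lasso adds 2*lambda*delta, fusion adds 2*rho*delta, likelihood is
        # second order; computed directly for the comparison
        assert gap >= 2 * 1.0 * delta + 2 * 1.0 * delta

    def test_lasso_monotonicity(self, random_cov_pair):
        thetas = np.stack([np.linalg.inv(s) for s in random_cov_pair.covariances])
        low = objective(random_cov_pair, thetas, PenaltySpec(0.1, 0.0))
        high = objective(random_cov_pair, thetas, PenaltySpec(0.2, 0.0))
        assert high > low

    def test_non_pd_rejected(self, random_cov_pair):
        bad = np.stack([np.diag([1.0, -1.0, 1.0, 1.0, 1.0])] * 2)
        with pytest.raises(ValueError):
            objective(random_cov_pair, bad, PenaltySpec(0.1, 0.1))

    def test_exact_stationarity_at_mle(self, random_cov_pair, tight_opts):
        penalty = PenaltySpec(0.0, 0.0)
        fit = fgl_admm(random_cov_pair, penalty, tight_opts)
        assert kkt_residual(random_cov_pair, fit, penalty).max() < 1e-6

    def test_identity_against_correlated_covariance_flags_gap(self):
        from fglinfer.solver import PrecisionSet

        covs = CovarianceSet(np.array([[[1.0, 0.9], [0.9, 1.0]]]), [10])
        penalty = PenaltySpec(0.01, 0.0)
        thetas = PrecisionSet(
            estimates=np.eye(2)[None],
            consensus=np.eye(2)[None],
            penalty=penalty,
        )
        # stationarity gap |0.9| - 0.01 at the off-diagonal entry
        assert kkt_residual(covs, thetas, penalty)[0] == pytest.approx(0.89)
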