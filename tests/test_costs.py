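import numpy as np
import pytest

from momentfit import (CostSpec, ObservationOperator, cost,
                       equidistant_times, lna_system,
                       log_likelihood_mean_only, predict_observed_moments,
                       residuals)
from momentfit.errors import ValidationError
from momentfit.moment_systems import pack_indices

from conftest import surrogate_moments


class TestResiduals:
    def test_zero_at_generating_parameters(self, bd_spec_n1, bd_spec_n2, bd_net):
        c = bd_net.default_params
        assert cost(c, bd_spec_n1) < 1e-14
        assert cost(c, bd_spec_n2) < 1e-12

    def test_cost_is_squared_residual_norm(self, bd_spec_n2):
        c = np.array([0.17, 0.26])
        r = residuals(c, bd_spec_n2)
        assert cost(c, bd_spec_n2) == pytest.approx(float(r @ r), rel=1e-14)

    def test_residual_layout(self, bd_spec_n1, bd_spec_n2):
        k = bd_spec_n1.obs.K
        assert len(residuals(np.array([0.2, 0.3]), bd_spec_n1)) == k
        assert len(residuals(np.array([0.2, 0.3]), bd_spec_n2)) == 2 * k

    def test_cost_equals_brute_force_sum_over_times(self, bd_spec_n2, bd_net):
        """Independently accumulate the weighted squared distances per time."""
        c = np.array([0.14, 0.31])
        mean, cov = predict_observed_moments(bd_spec_n2.system, c,
                                             bd_spec_n2.x0, bd_spec_n2.obs)
        total = 0.0
        data = bd_spec_n2.data
        for k in range(bd_spec_n2.obs.K):
            total += np.sum((data.mean[k] - mean[k]) ** 2)
            for i, j in pack_indices(1):
                total += (data.cov[k][i, j] - cov[k][i, j]) ** 2
        assert cost(c, bd_spec_n2) == pytest.approx(total, rel=1e-12)

    def test_weight_linearity_in_covariance_block(self, bd_system, bd_obs,
                                                  bd_surrogate, bd_net):
        c = np.array([0.14, 0.31])
        def with_w2(w2):
            spec = CostSpec(bd_system, bd_obs, bd_surrogate, bd_net.x0,
                            order=2, weights=(1.0, w2))
            return cost(c, spec)
        base, double = with_w2(1.0), with_w2(2.0)
        mean_only = with_w2(0.0)
        assert double - mean_only == pytest.approx(2 * (base - mean_only),
                                                   rel=1e-10)

    def test_mean_only_ridge(self, bd_spec_n1):
        # exact-mean data: cost depends on c only through c1 - c2
        assert cost(np.array([0.3, 0.4]), bd_spec_n1) == pytest.approx(
            cost(np.array([0.15, 0.25]), bd_spec_n1), abs=1e-12)

    def test_weights_all_zero_rejected(self, bd_system, bd_obs, bd_surrogate,
                                       bd_net):
        with pytest.raises(ValidationError):
            CostSpec(bd_system, bd_obs, bd_surrogate, bd_net.x0, order=2,
                     weights=(0.0, 0.0))


class TestPredictObserved:
    def test_full_observation_is_identity_selection(self, p53_net):
        from momentfit import solve_moment_system
        times = equidistant_times(6, 3)
        lna = lna_system(p53_net)
        c = p53_net.default_params
        full = solve_moment_system(lna, c, p53_net.x0, times)
        obs = ObservationOperator((0, 1, 2), times)
        mean, cov = predict_observed_moments(lna, c, p53_net.x0, obs)
        assert np.allclose(mean, full.mean)
        assert np.allclose(cov, full.cov)

    def test_single_component_selection_commutes(self, p53_net):
        from momentfit import solve_moment_system
        times = equidistant_times(6, 3)
        lna = lna_system(p53_net)
        c = p53_net.default_params
        obs = ObservationOperator((2,), times)
        mean, cov = predict_observed_moments(lna, c, p53_net.x0, obs)
        full = solve_moment_system(lna, c, p53_net.x0, times)
        assert mean.shape == (3, 1) and cov.shape == (3, 1, 1)
        assert np.allclose(mean[:, 0], full.mean[:, 2])
        assert np.allclose(cov[:, 0, 0], full.cov[:, 2, 2])


class TestMeanOnlyLikelihood:
    def test_zero_residual_reduces_to_normalization(self, bd_net, bd_system,
                                                    bd_obs, bd_surrogate):
        c = bd_net.default_params
        ll = log_likelihood_mean_only(c, bd_surrogate, bd_system, bd_net.x0,
                                      bd_obs)
        _, cov = predict_observed_moments(bd_system, c, bd_net.x0, bd_obs)
        v = cov[:, 0, 0] / bd_surrogate.n_replicates
        assert ll == pytest.approx(-0.5 * np.sum(np.log(2 * np.pi * v)),
                                   rel=1e-9)

    def test_monotone_along_mean_preserving_ridge(self, bd_net, bd_system,
                                                  bd_obs, bd_surrogate):
        # with exact-mean data the quadratic term stays zero, so the
        # likelihood only sees the model variance, which grows with c1 + c2:
        # the maximum sits at the positivity boundary, not at the truth
        c = bd_net.default_params
        vals = [log_likelihood_mean_only(c + s, bd_surrogate, bd_system,
                                         bd_net.x0, bd_obs)
                for s in (-0.05, 0.0, 0.1, 0.2)]
        assert np.all(np.diff(vals) < 0)

    def test_replicate_count_sharpens_quadratic_term(self, bd_net, bd_system,
                                                     bd_obs):
        c_off = np.array([0.12, 0.2])
        def quad(n):
            data = surrogate_moments(bd_system, bd_net.default_params,
                                     bd_net.x0, bd_obs, n_replicates=n)
            ll = log_likelihood_mean_only(c_off, data, bd_system, bd_net.x0,
                                          bd_obs)
            _, cov = predict_observed_moments(bd_system, c_off, bd_net.x0, bd_obs)
            norm_gap = -0.5 * np.sum(np.log(2 * np.pi * cov[:, 0, 0] / n))
            return norm_gap - ll   # quadratic part at c_off
        assert quad(4000) == pytest.approx(4 * quad(1000), rel=1e-8)
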