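import numpy as np
import pytest

from momentfit import (NotApplicableError, birth_death_analytic,
                       cme_truncated_moments, equidistant_times,
                       exact_moment_system, lna_system, macroscopic_solve,
                       make_network, normal_closure_1d, solve_moment_system)
from momentfit.moment_systems import pack_matrix, unpack_matrix


class TestExactAffineSystem:
    def test_birth_death_rhs_closed_form(self, bd_net, bd_system):
        # dm/dt = (c1-c2) m ; dv/dt = 2 (c1-c2) v + (c1+c2) m
        rng = np.random.default_rng(0)
        for _ in range(10):
            m, v = rng.uniform(1, 50), rng.uniform(0, 30)
            c1, c2 = rng.uniform(0.05, 0.5, size=2)
            out = bd_system.rhs(np.array([m, v]), np.array([c1, c2]))
            assert out[0] == pytest.approx((c1 - c2) * m)
            assert out[1] == pytest.approx(2 * (c1 - c2) * v + (c1 + c2) * m)

    def test_equal_rates_mean_constant(self, bd_net, bd_system):
        tr = solve_moment_system(bd_system, [0.2, 0.2], [30],
                                 equidistant_times(10, 10))
        assert np.allclose(tr.mean[:, 0], 30.0, rtol=1e-9)

    def test_nonaffine_network_rejected(self, dimer_net, p53_net):
        with pytest.raises(NotApplicableError, match="dimerise"):
            exact_moment_system(dimer_net)
        with pytest.raises(NotApplicableError):
            exact_moment_system(p53_net)


class TestNormalClosure:
    def test_affine_closure_equals_exact_and_lna(self, bd_net, bd_system):
        # for affine drift/diffusion the closure corrections vanish and all
        # three constructions share one right-hand side
        nc = normal_closure_1d(bd_net)
        lna = lna_system(bd_net)
        rng = np.random.default_rng(1)
        for _ in range(10):
            z = rng.uniform(0.1, 40, size=2)
            c = rng.uniform(0.05, 0.6, size=2)
            ref = bd_system.rhs(z, c)
            assert np.allclose(nc.rhs(z, c), ref, rtol=1e-12, atol=1e-12)
            assert np.allclose(lna.rhs(z, c), ref, rtol=1e-12, atol=1e-12)

    def test_dimerisation_closure_rhs(self, dimer_net):
        # A(x) = -c1 x(x-1) + c2 (M-x), B(x) = 2 c1 x(x-1) + 2 c2 (M-x);
        # normal closure: dm = A(m) - c1 v, dv = 2 A'(m) v + B(m) + 2 c1 v
        nc = normal_closure_1d(dimer_net)
        m_, v_, c1, c2, M = 120.0, 55.0, 2e-3, 0.3, 301.0
        A = -c1 * m_ * (m_ - 1) + c2 * (M - m_)
        B = 2 * c1 * m_ * (m_ - 1) + 2 * c2 * (M - m_)
        Ap = -c1 * (2 * m_ - 1) - c2
        out = nc.rhs(np.array([m_, v_]), np.array([c1, c2]))
        assert out[0] == pytest.approx(A - c1 * v_)
        assert out[1] == pytest.approx(2 * Ap * v_ + B + 2 * c1 * v_)

    def test_closure_correction_lowers_mean_below_macroscopic(self, dimer_net):
        times = equidistant_times(8, 16)
        c = dimer_net.default_params
        closure = solve_moment_system(normal_closure_1d(dimer_net), c, [301], times)
        macro = macroscopic_solve(dimer_net, c, [301], times)
        assert np.all(closure.mean[:, 0] <= macro.mean[:, 0] + 1e-9)

    def test_pure_diffusion_variance_linear_in_time(self):
        # +1 / -1 at equal constant rate: zero drift, diffusion B = 2c
        net = make_network({
            "species": ["X"], "params": ["c1"], "x0": [50],
            "reactions": [
                {"reactants": {}, "products": {"X": 1}, "law": "expression",
                 "expr": "c1"},
                {"reactants": {"X": 1}, "products": {}, "law": "expression",
                 "expr": "c1"},
            ]})
        times = equidistant_times(5, 5)
        tr = solve_moment_system(normal_closure_1d(net), [3.0], [50], times)
        assert np.allclose(tr.mean[:, 0], 50.0, rtol=1e-8)
        assert np.allclose(tr.cov[:, 0, 0], 2 * 3.0 * times, rtol=1e-7)

    def test_multivariate_network_rejected(self, p53_net):
        with pytest.raises(NotApplicableError):
            normal_closure_1d(p53_net)


class TestLNA:
    def test_p53_layout_and_psd_covariance(self, p53_net):
        lna = lna_system(p53_net)
        assert lna.dim == 3 + 6
        tr = solve_moment_system(lna, p53_net.default_params, p53_net.x0,
                                 equidistant_times(24, 12))
        assert np.allclose(tr.cov, tr.cov.transpose(0, 2, 1))
        for k in range(12):
            assert np.linalg.eigvalsh(tr.cov[k]).min() > -1e-7

    def test_zero_propensities_freeze_covariance(self):
        net = make_network({
            "species": ["X"], "params": ["c1"], "x0": [10],
            "reactions": [{"reactants": {"X": 1}, "products": {},
                           "law": "expression", "expr": "0*c1"}]})
        tr = solve_moment_system(lna_system(net), [1.0], [10],
                                 equidistant_times(4, 4),
                                 initial_cov=np.array([[7.0]]))
        assert np.allclose(tr.cov[:, 0, 0], 7.0)


class TestSolveAndAnalytic:
    def test_solution_matches_closed_form(self, bd_net, bd_system):
        times = equidistant_times(10, 20)
        for c in ([0.1, 0.2], [0.3, 0.1], [0.2, 0.2]):
            tr = solve_moment_system(bd_system, c, [30], times)
            m, v = birth_death_analytic(c, 30, times)
            assert np.allclose(tr.mean[:, 0], m, rtol=1e-6)
            assert np.allclose(tr.cov[:, 0, 0], v, rtol=1e-6)

    def test_time_zero_returns_initial_moments(self, bd_system):
        tr = solve_moment_system(bd_system, [0.1, 0.2], [30], np.array([0.0]))
        assert tr.mean[0, 0] == 30.0
        assert tr.cov[0, 0, 0] == 0.0

    def test_horizon_split_consistency(self, bd_system):
        c = [0.15, 0.25]
        t_long = equidistant_times(10, 10)
        t_short = t_long[:5]
        a = solve_moment_system(bd_system, c, [30], t_long)
        b = solve_moment_system(bd_system, c, [30], t_short)
        assert np.allclose(a.mean[:5], b.mean, rtol=1e-7)
        assert np.allclose(a.cov[:5], b.cov, rtol=1e-6)

    def test_analytic_limit_and_ridge(self):
        times = np.linspace(0.5, 10, 8)
        m0, v0 = birth_death_analytic([0.2, 0.2], 30, times)
        assert np.allclose(m0, 30.0)
        assert np.allclose(v0, 2 * 0.2 * 30 * times)
        # near-equal rates agree with the exact limit (no catastrophic
        # cancellation)
        m1, v1 = birth_death_analytic([0.2 + 5e-13, 0.2 - 5e-13], 30, times)
        assert np.allclose(v1, v0, rtol=1e-6)
        # the mean depends on the parameters only through their difference
        ma, va = birth_death_analytic([0.1, 0.2], 30, times)
        mb, vb = birth_death_analytic([0.25, 0.35], 30, times)
        assert np.allclose(ma, mb)
        assert not np.allclose(va, vb)

    def test_at_t0(self):
        m, v = birth_death_analytic([0.3, 0.1], 12, np.array([0.0]))
        assert m[0] == 12.0 and v[0] == 0.0


class TestMacroscopic:
    def test_affine_equals_exact_mean(self, bd_net, bd_system):
        times = equidistant_times(10, 10)
        macro = macroscopic_solve(bd_net, [0.1, 0.2], [30], times)
        exact = solve_moment_system(bd_system, [0.1, 0.2], [30], times)
        assert np.allclose(macro.mean, exact.mean, rtol=1e-7)

    def test_dimerisation_equilibrium_is_drift_root(self, dimer_net):
        c = dimer_net.default_params
        tr = macroscopic_solve(dimer_net, c, [301], np.array([400.0]))
        x = tr.mean[-1, 0]
        drift = -c[0] * x * (x - 1) + c[1] * (301 - x)
        assert abs(drift) < 1e-6


class TestTruncatedCME:
    def test_probability_conservation_and_finite_space(self, dimer_net):
        times = equidistant_times(4, 4)
        tr = cme_truncated_moments(dimer_net, dimer_net.default_params, [301],
                                   times, state_cap=301)
        # state space is genuinely finite: no truncation leak at all
        assert np.max(np.abs(tr.leak)) < 1e-10
        assert np.all(tr.mean >= 0) and np.all(tr.mean <= 301)

    def test_closure_error_quantified_against_exact_cme(self, dimer_net):
        times = equidistant_times(8, 8)
        c = dimer_net.default_params
        oracle = cme_truncated_moments(dimer_net, c, [301], times, 301)
        closure = solve_moment_system(normal_closure_1d(dimer_net), c, [301], times)
        rel = np.abs(closure.mean[:, 0] - oracle.mean[:, 0]) / oracle.mean[:, 0]
        assert np.max(rel) < 0.05

    def test_state_space_size_guard(self, p53_net):
        with pytest.raises(Exception, match="states"):
            cme_truncated_moments(p53_net, p53_net.default_params,
                                  p53_net.x0, [1.0], state_cap=400)


def test_packing_round_trip():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(4, 4))
    sym = a + a.T
    assert np.allclose(unpack_matrix(pack_matrix(sym), 4), sym)
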