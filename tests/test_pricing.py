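"""Consumption mapping, utility, the pricing series m and its decomposition."""

from dataclasses import replace

import numpy as np
import pytest

import vaxprice as v

from _oracles import alive_probability, enum_m, sird_path

BASE = dict(delta=0.3, gamma=0.2, rho=0.05)


def world_inputs(scenario, horizon):
    """Aggregate I path and tau schedule feeding the oracles, via the plain recursion."""
    epi = scenario.epidemic
    init = scenario.initial
    path = sird_path(
        init.s, init.i, init.r, init.d, epi.delta, epi.gamma, epi.rho,
        list(epi.tau_schedule), horizon,
    )
    i_path = [p[1] for p in path]
    taus = [epi.tau_at(t) for t in range(horizon)]
    return i_path, taus


class TestConsumption:
    def test_living_states_consume_handout_dividend_and_endowment(self, baseline):
        econ = baseline.economy
        assert v.consumption(econ, "S", 0) == pytest.approx(1.1)
        assert v.consumption(econ, "R", 0) == v.consumption(econ, "S", 0)
        assert v.consumption(econ, "I", 0) == pytest.approx(0.3)

    def test_deceased_consume_nothing(self, baseline):
        assert v.consumption(baseline.economy, "D", 0) == 0.0

    def test_excluded_infected_pinned_at_floor_regardless_of_handout(self, baseline):
        econ = replace(
            baseline.economy, infected_excluded=True, c_floor=1e-3, handout=(5.0,)
        )
        assert v.consumption(econ, "I", 0) == 1e-3
        assert v.consumption(econ, "S", 0) == pytest.approx(6.1)

    def test_handout_schedule_repeats_last_value(self, baseline):
        econ = replace(baseline.economy, handout=(0.0, 0.3))
        assert v.consumption(econ, "S", 5) == pytest.approx(1.4)


class TestUtility:
    @pytest.mark.parametrize(
        "spec, c, expected",
        [
            (v.UtilitySpec("power", 0.5), 0.25, 2.0),
            (v.UtilitySpec("power", 0.5), 1.0, 1.0),
            (v.UtilitySpec("bounded_exponential", 2.0), 0.0, 2.0),
        ],
    )
    def test_marginal_utility_worked_points(self, spec, c, expected):
        assert v.marginal_utility(spec, c) == pytest.approx(expected, abs=1e-14)

    def test_power_marginal_utility_unbounded_at_zero(self):
        with pytest.raises(ValueError):
            v.marginal_utility(v.UtilitySpec("power", 0.5), 0.0)

    @pytest.mark.parametrize(
        "spec", [v.UtilitySpec("power", 0.5), v.UtilitySpec("bounded_exponential", 2.0)]
    )
    def test_u_vanishes_at_zero_increases_and_is_concave(self, spec):
        assert spec.u(0.0) == 0.0
        grid = np.linspace(0.01, 3.0, 50)
        vals = np.array([spec.u(c) for c in grid])
        primes = np.array([spec.u_prime(c) for c in grid])
        assert np.all(np.diff(vals) > 0)
        assert np.all(primes > 0) and np.all(np.diff(primes) < 0)

    def test_include_deceased_requires_finite_marginal_utility_at_zero(self):
        with pytest.raises(ValueError, match="include_deceased"):
            v.EconomyParams(kernel_convention="include_deceased")


class TestPropagate:
    def test_absorbing_point_mass_stays_put(self, baseline):
        kernel = v.transition_matrix(baseline.initial, baseline.epidemic)
        dist = np.array([0.0, 0.0, 1.0, 0.0])
        np.testing.assert_array_equal(v.propagate(dist, kernel), dist)

    def test_point_mass_on_susceptible_reads_off_first_row(self):
        state = v.EpidemicState(s=0.9, i=0.1, r=0.0, d=0.0)
        params = v.EpidemicParams(delta=0.3, gamma=0.1, rho=0.05, tau_schedule=(0.2,))
        kernel = v.transition_matrix(state, params)
        out = v.propagate(np.array([1.0, 0.0, 0.0, 0.0]), kernel)
        np.testing.assert_allclose(out, [0.77, 0.03, 0.2, 0.0], atol=1e-15)

    def test_identity_kernel_is_a_fixed_point(self):
        dist = np.full(4, 0.25)
        np.testing.assert_array_equal(v.propagate(dist, np.eye(4)), dist)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            v.propagate(np.array([0.5, 0.5]), np.eye(4))


class TestMSeries:
    def test_disease_free_constant_dividend_geometric_closed_form(self, disease_free):
        """With no infection risk, m = u'(c_S) d beta/(1-beta) and p = beta d/(1-beta)."""
        res = disease_free.price()
        econ = disease_free.economy
        up = econ.utility.u_prime(v.consumption(econ, "S", 0))
        expected_m = up * 0.1 * 0.95 / 0.05
        assert res.m == pytest.approx(expected_m, abs=1e-10)
        assert res.p_tilde == pytest.approx(1.9, abs=1e-10)
        assert res.tail_bound < disease_free.tol
        assert res.p_tilde * up == pytest.approx(res.m, abs=1e-15)

    @pytest.mark.parametrize("horizon", [1, 2, 3, 4, 5, 6])
    def test_matches_exhaustive_path_enumeration(self, baseline, horizon):
        """Truncated m equals the 4^omega brute-force path sum to 1e-12."""
        i_path, taus = world_inputs(baseline, horizon)
        expected = enum_m(i_path, taus, **BASE, w_S=1.0, w_I=0.2, d=0.1, beta=0.95,
                          horizon=horizon)
        got = v.m_partial_sum(baseline.trajectory(), baseline.economy, 0, horizon)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_first_step_tau_override_matches_enumeration(self, baseline):
        """Partial-mode perturbation touches only the period-t kernel."""
        i_path, taus = world_inputs(baseline, 3)
        taus[0] = 0.11
        expected = enum_m(i_path, taus, **BASE, w_S=1.0, w_I=0.2, d=0.1, beta=0.95,
                          horizon=3)
        got = v.m_partial_sum(baseline.trajectory(), baseline.economy, 0, 3,
                              tau0_override=0.11)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_equal_endowments_reduce_to_discounted_survival_value(self, baseline):
        """With one consumption level for the living, m = u'(c) sum beta^w d P(alive)."""
        econ = replace(baseline.economy, w_I=1.0)
        horizon = 40
        i_path, taus = world_inputs(baseline, horizon)
        alive = alive_probability(i_path, taus, 0.3, 0.2, 0.05, horizon)
        up = econ.utility.u_prime(1.1)
        expected = sum(0.95**w * 0.1 * up * alive[w - 1] for w in range(1, horizon + 1))
        got = v.m_partial_sum(baseline.trajectory(), econ, 0, horizon)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_truncation_is_within_certified_tail_bound(self, baseline):
        res = baseline.price()
        longer = v.m_partial_sum(
            baseline.trajectory(), baseline.economy, 0, res.horizon_used + 300
        )
        assert abs(res.m - longer) <= res.tail_bound
        assert res.tail_bound < baseline.tol

    def test_nonconvergence_reports_achieved_bound(self, baseline):
        with pytest.raises(v.ConvergenceError) as exc:
            v.m_series(baseline.trajectory(), baseline.economy, tol=1e-10, max_horizon=10)
        assert exc.value.horizon == 10
        assert exc.value.achieved_bound > 1e-10

    def test_widening_income_gap_raises_precautionary_weight(self, baseline):
        """Lower w_I means higher infected marginal utility, hence larger m."""
        traj = baseline.trajectory()
        m_wide = v.m_series(traj, replace(baseline.economy, w_I=0.1)).m
        m_narrow = v.m_series(traj, replace(baseline.economy, w_I=0.5)).m
        assert m_wide > m_narrow

    def test_zero_gap_no_mortality_m_invariant_to_epidemic(self, knife_edge):
        """Living states are interchangeable and no mass dies: m ignores delta, tau, gamma."""
        m_ref = knife_edge.price().m
        epi2 = replace(
            knife_edge.epidemic, delta=0.05, gamma=0.6, tau_schedule=(0.25,)
        )
        m_alt = v.price(v.simulate(knife_edge.initial, epi2, 0), knife_edge.economy).m
        assert m_alt == pytest.approx(m_ref, abs=1e-12)


class TestDeltaDecomposition:
    def test_leading_term_vanishes_with_equal_susceptible_recovered_endowments(
        self, baseline
    ):
        dec = v.delta_decomposition(baseline.trajectory(), baseline.economy, 0, horizon=5)
        assert dec.deltas[0] == 0.0

    def test_second_term_matches_hand_formula(self, baseline):
        """Delta_2 = -beta^2 d delta I_1 (u'(c_I) - u'(c_S)) from the kernel algebra."""
        i1 = baseline.trajectory().state_at(1).i
        econ = baseline.economy
        up_S = econ.utility.u_prime(1.1)
        up_I = econ.utility.u_prime(0.3)
        expected = -(0.95**2) * 0.1 * 0.3 * i1 * (up_I - up_S)
        dec = v.delta_decomposition(baseline.trajectory(), econ, 0, horizon=2)
        assert dec.deltas[1] == pytest.approx(expected, rel=1e-12)
        assert dec.deltas[1] < 0

    def test_all_terms_vanish_without_gap_or_mortality(self, knife_edge):
        dec = v.delta_decomposition(
            knife_edge.trajectory(), knife_edge.economy, 0, horizon=30
        )
        np.testing.assert_allclose(dec.deltas, 0.0, atol=1e-15)

    def test_all_terms_negative_under_deceased_inclusive_kernel(self, baseline):
        """The analytic sign argument needs u'(c_D) > u'(c_I) > u'(c_R): include the dead."""
        econ = replace(
            baseline.economy,
            utility=v.UtilitySpec("bounded_exponential", 2.0),
            kernel_convention="include_deceased",
        )
        dec = v.delta_decomposition(baseline.trajectory(), econ, 0, horizon=100)
        assert dec.deltas[0] == 0.0
        assert np.all(dec.deltas[1:] < 0)


class TestEulerResidual:
    def test_disease_free_fixed_point_satisfies_euler_equation(self, disease_free):
        assert v.euler_residual(disease_free.trajectory(), disease_free.economy) <= 1e-9

    def test_baseline_residual_is_finite_diagnostic(self, baseline):
        res = v.euler_residual(baseline.trajectory(), baseline.economy)
        assert np.isfinite(res) and res >= 0

    def test_residual_stable_under_tolerance_halving(self, baseline):
        r1 = v.euler_residual(baseline.trajectory(), baseline.economy, tol=1e-10)
        r2 = v.euler_residual(baseline.trajectory(), baseline.economy, tol=5e-11)
        assert abs(r1 - r2) <= 1e-8


class TestMonteCarlo:
    def test_sampled_paths_bracket_deterministic_m(self, baseline):
        """Seeded path sampling agrees with the distribution recursion within 3 SE."""
        horizon = 4
        det = v.m_partial_sum(baseline.trajectory(), baseline.economy, 0, horizon)
        mc = v.monte_carlo_m(
            baseline.trajectory(), baseline.economy, horizon=horizon,
            n_paths=100_000, seed=v.DEFAULT_SEED,
        )
        assert abs(mc.mean - det) <= 3 * mc.stderr
        assert mc.stderr > 0

    def test_same_seed_reproduces_estimate(self, baseline):
        kw = dict(horizon=5, n_paths=2_000, seed=123)
        a = v.monte_carlo_m(baseline.trajectory(), baseline.economy, **kw)
        b = v.monte_carlo_m(baseline.trajectory(), baseline.economy, **kw)
        assert a == b
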