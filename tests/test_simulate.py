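"""Integration of the four-compartment system and its verification oracles."""

import numpy as np
import pytest

from dermalkin import (
    BACProfile,
    SimulationResult,
    bac_conversion_factor,
    compartment_time_constants,
    compute_metrics,
    mass_balance_residual,
    refine_layers,
    rhs,
    simulate,
    steady_state,
)
from dermalkin.simulate import system_matrices


class TestRhs:
    def test_rest_point(self, params):
        d = rhs(0.0, np.zeros(4), params, lambda t: 0.0)
        assert np.all(d == 0.0)

    def test_equal_interface_pressures_kill_the_coupling_flux(self, params):
        """With P_e == P_s the epidermis/stratum-corneum exchange vanishes."""
        state = np.array([0.0, 0.2, 0.2, 0.0])
        d = rhs(0.0, state, params, lambda t: 0.0)
        # epidermis row sees only the capillary-side flux, stratum corneum
        # only the gas-side flux; verified against the hand-written terms
        g_ce = params.D_e * params.beta_e * params.A_c / (0.5 * params.L_e)
        g_sg = params.D_s * params.beta_s * params.A / (0.5 * params.L_s)
        cap_e = params.beta_e * params.A * params.L_e
        cap_s = params.beta_s * params.A * params.L_s
        assert d[1] == pytest.approx(g_ce * (0.0 - 0.2) / cap_e, rel=1e-12)
        assert d[2] == pytest.approx(g_sg * (0.0 - 0.2) / cap_s, rel=1e-12)

    def test_arterial_input_enters_only_the_capillary_row(self, params):
        """From rest with arterial pressure applied, dP_c/dt = Qdot*P_a/(A_c*L_c)."""
        P_a = 0.1433
        d = rhs(0.0, np.zeros(4), params, lambda t: P_a)
        expected = params.Q_dot * P_a / (params.A_c * params.L_c)  # hand arithmetic
        assert d[0] == pytest.approx(expected, rel=1e-12)
        assert d[0] == pytest.approx(1.0918, rel=1e-3)
        assert np.all(d[1:] == 0.0)

    def test_nonfinite_state_rejected(self, params):
        with pytest.raises(Exception):
            rhs(0.0, np.array([np.nan, 0, 0, 0]), params, lambda t: 0.0)


class TestSteadyState:
    def test_zero_input(self, params):
        ss = steady_state(0.0, params)
        assert ss.as_array() == pytest.approx(np.zeros(4), abs=1e-15)

    def test_dissipative_chain_ordering(self, params):
        """P_a > P_c > P_e > P_s > P_g > 0: the same flux crosses every
        interface on its way to the vented gas compartment."""
        P_a = 0.1433
        ss = steady_state(P_a, params)
        chain = [P_a, ss.P_c, ss.P_e, ss.P_s, ss.P_g, 0.0]
        assert np.all(np.diff(chain) < 0)

    def test_long_time_simulation_converges_to_steady_state(self, params):
        """Holding BAC constant for 50 h drives the system to the closed-form
        fixed point within 0.1%."""
        bac0 = 0.05
        prof = BACProfile.tabulated(np.array([0.0, 60.0, 60.001]),
                                    np.array([bac0, bac0, 0.0]))
        r = simulate(prof, params, horizon_h=61.0, output_dt_h=0.05)
        ss = steady_state(bac0 / bac_conversion_factor(params), params)
        i50 = int(np.argmin(np.abs(r.time_h - 50.0)))
        sim_state = np.array([r.P_c[i50], r.P_e[i50], r.P_s[i50], r.P_g[i50]])
        assert sim_state == pytest.approx(ss.as_array(), rel=1e-3)

    def test_steady_initial_condition_has_no_drift(self, params):
        bac0 = 0.05
        ss = steady_state(bac0 / bac_conversion_factor(params), params)
        prof = BACProfile.tabulated(np.array([0.0, 30.0, 30.001]),
                                    np.array([bac0, bac0, 0.0]))
        r = simulate(prof, params, horizon_h=31.0, output_dt_h=0.1,
                     initial_state=ss.as_array())
        i_hold = r.time_h <= 30.0
        for traj, ref in zip((r.P_c, r.P_e, r.P_s, r.P_g), ss.as_array()):
            assert np.max(np.abs(traj[i_hold] - ref)) < 1e-6 * ref


class TestSimulate:
    def test_headline_attenuation_and_delay(self, headline_result, headline_profile):
        """The supradermal peak is ~2/3 of the blood peak, about an hour later."""
        m = compute_metrics(headline_result, headline_profile)
        assert 0.60 < m.C_g_max_ratio < 0.70
        assert 0.9 < m.T_PD < 1.4

    def test_non_negativity(self, headline_result):
        atol = headline_result.diagnostics["atol"]
        for traj in (headline_result.P_c, headline_result.P_e,
                     headline_result.P_s, headline_result.P_g):
            assert np.min(traj) >= -atol
        assert np.min(headline_result.C_g) >= 0.0

    def test_linearity_in_the_input(self, params):
        """Scaling the whole blood profile scales every trajectory."""
        c = 2.5
        r1 = simulate(BACProfile.triangular(1.0, 0.02, 0.018), params)
        r2 = simulate(BACProfile.triangular(1.0, 0.02 * c, 0.018 * c), params)
        scale = np.max(r1.C_g)
        assert np.allclose(r2.C_g, c * r1.C_g, atol=1e-6 * c * scale)
        assert np.allclose(r2.P_e, c * r1.P_e, rtol=0, atol=1e-6 * c * np.max(r1.P_e))

    def test_output_grid_covers_horizon_uniformly(self, headline_result):
        t = headline_result.time_h
        assert t[0] == 0.0
        assert np.allclose(np.diff(t), t[1] - t[0])
        assert t[-1] >= headline_result.profile.zero_time() + 8.0 - 1e-9

    def test_metrics_insensitive_to_output_dt(self, params, headline_profile):
        r1 = simulate(headline_profile, params)
        r2 = simulate(headline_profile, params,
                      output_dt_h=r1.diagnostics["output_dt_h"] / 2)
        m1 = compute_metrics(r1, headline_profile)
        m2 = compute_metrics(r2, headline_profile)
        for a, b in [(m1.C_g_max, m2.C_g_max), (m1.WO_max, m2.WO_max),
                     (m1.T_PD, m2.T_PD), (m1.T_ZD, m2.T_ZD)]:
            assert a == pytest.approx(b, rel=1e-3)

    def test_short_horizon_rejected(self, params, headline_profile):
        with pytest.raises(ValueError):
            simulate(headline_profile, params, horizon_h=2.0)

    def test_stiffness_is_real_and_handled(self, params, headline_profile):
        """Compartment relaxation times span ~4 orders of magnitude, yet the
        stiff solver completes with a bounded number of evaluations."""
        taus = compartment_time_constants(params)
        assert max(taus.values()) / min(taus.values()) > 1e3
        r = simulate(headline_profile, params)
        assert r.diagnostics["nfev"] < 50_000

    def test_trajectory_csv_round_trip(self, headline_result, tmp_path):
        path = tmp_path / "traj.csv"
        headline_result.write_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape == (headline_result.time_h.size, 6)
        assert np.allclose(data[:, 5], headline_result.C_g, atol=1e-9)
        assert path.with_suffix(".csv.json").exists()


class TestMassBalance:
    def test_residual_small_on_default_run(self, headline_result, params):
        assert mass_balance_residual(headline_result, params) < 1e-6

    def test_zero_input_residual_is_zero(self, params):
        prof = BACProfile.tabulated(np.array([0.0, 1.0, 2.0]), np.zeros(3))
        n = 11
        t = np.linspace(0, 2, n)
        r = SimulationResult(t, *(np.zeros(n),) * 5, prof, params)
        assert mass_balance_residual(r, params) == 0.0

    def test_residual_shrinks_with_tighter_solver_and_finer_grid(self, params, headline_profile):
        coarse = simulate(headline_profile, params, output_dt_h=1 / 60, rtol=1e-6)
        fine = simulate(headline_profile, params, output_dt_h=1 / 240, rtol=1e-10)
        assert mass_balance_residual(fine, params) < mass_balance_residual(coarse, params)


class TestLayerRefinement:
    def test_single_sublayer_matches_base_model(self, params, headline_profile):
        base = simulate(headline_profile, params)
        refined = simulate(headline_profile, params, n_sub=1)
        assert np.max(np.abs(base.C_g - refined.C_g)) < 1e-10

    def test_matrices_reduce_exactly_at_n1(self, params):
        A1, ba1, b01 = system_matrices(params)
        A2, ba2, b02, labels = refine_layers(params, 1)
        assert np.allclose(A1, A2, rtol=1e-14)
        assert np.allclose(ba1, ba2, rtol=1e-14)
        assert labels == ["P_c", "P_e1", "P_s1", "P_g"]

    def test_convergence_is_cauchy(self, params, headline_profile):
        """Successive peak values at n_sub in {8,16,32} approach a limit."""
        peaks = [simulate(headline_profile, params, n_sub=n).C_g.max()
                 for n in (8, 16, 32)]
        d1, d2 = abs(peaks[1] - peaks[0]), abs(peaks[2] - peaks[1])
        assert d2 < d1

    def test_refined_peak_is_earlier_than_lumped(self, params, headline_profile):
        """Resolving the diffusion gradient speeds the response: the lumped
        model under-represents conductance within the stratum corneum."""
        base = simulate(headline_profile, params)
        refined = simulate(headline_profile, params, n_sub=16)
        t_base = base.time_h[int(np.argmax(base.C_g))]
        t_ref = refined.time_h[int(np.argmax(refined.C_g))]
        assert t_ref < t_base

    def test_invalid_subdivision_rejected(self, params):
        with pytest.raises(ValueError):
            refine_layers(params, 0)
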