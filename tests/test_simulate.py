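"""Integration protocols, steady states, scans, pulses and the flux reversal."""

import numpy as np
import pytest

from acekin import (
    State,
    acetate_scan,
    chemostat_scan,
    find_flux_reversal_threshold,
    integrate,
    model_variant,
    pulse_experiment,
    solve_intracellular_steady_state,
)
from acekin.model import all_rates
from acekin.simulate import IntegrationError

V4 = model_variant(4)
V1 = model_variant(1)


def _batch_init(glc=15.0, ace=1.0, x0=0.05):
    return State(GLC=glc, ACE_env=ace, X=x0, ACCOA=1e-4, ACP=1e-4, ACE_cell=1e-4)


class TestIntegrate:
    def test_sterile_culture_leaves_glucose_untouched(self, params):
        traj = integrate(_batch_init(x0=0.0), params, V4, 5.0, output_grid=1.0)
        glc = traj.states["GLC"].to_numpy()
        np.testing.assert_allclose(glc, glc[0], rtol=1e-9)

    def test_blocked_glycolysis_freezes_glucose(self, params):
        p = params.with_updates({"glycolysis.Vmax": 1e-12})
        traj = integrate(_batch_init(), p, V4, 5.0, output_grid=1.0)
        np.testing.assert_allclose(traj.states["GLC"], 15.0, rtol=1e-8)

    def test_batch_growth_curve_shape(self, params):
        """Glucose is exhausted; acetate rises, then is reconsumed."""
        traj = integrate(_batch_init(ace=1.0, x0=0.05), params, V4, 12.0,
                         output_grid=0.1)
        s = traj.states
        assert s["GLC"].iloc[-1] < 0.05            # exhausted
        assert np.all(np.diff(s["GLC"]) <= 1e-9)   # monotone decrease
        peak = s["ACE_env"].idxmax()
        assert s["ACE_env"].iloc[peak] > s["ACE_env"].iloc[0]     # overflow
        assert s["ACE_env"].iloc[-1] < s["ACE_env"].iloc[peak]    # reconsumption
        assert s["X"].iloc[-1] > 10 * s["X"].iloc[0]

    def test_deterministic_and_tolerance_convergent(self, params):
        a = integrate(_batch_init(), params, V4, 4.0, output_grid=1.0)
        b = integrate(_batch_init(), params, V4, 4.0, output_grid=1.0)
        np.testing.assert_array_equal(a.states.to_numpy(), b.states.to_numpy())
        loose = integrate(_batch_init(), params, V4, 4.0, output_grid=1.0,
                          rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(
            a.states.to_numpy(), loose.states.to_numpy(), rtol=1e-4, atol=1e-5
        )

    def test_rejects_nonpositive_horizon(self, params):
        with pytest.raises(ValueError):
            integrate(_batch_init(), params, V4, -1.0)

    def test_flux_frame_consistent_with_states(self, params):
        traj = integrate(_batch_init(), params, V4, 3.0, output_grid=1.0)
        row = traj.totals().iloc[-1]
        st = State(row["GLC"], row["ACE_env"], row["X"], row["ACCOA"],
                   row["ACP"], row["ACE_cell"])
        v = all_rates(st, params, V4)
        assert traj.fluxes["exchange"].iloc[-1] == pytest.approx(v.exchange)


class TestSteadyState:
    def test_balance_identities_hold(self, params):
        ss = solve_intracellular_steady_state(15.0, 0.1, params, V4)
        v = ss.fluxes
        assert 1.4 * v.glycolysis == pytest.approx(v.tca + v.pta, rel=1e-9)
        assert v.pta == pytest.approx(v.acka, rel=1e-9)
        assert v.acka == pytest.approx(v.exchange, rel=1e-9)
        assert v.growth == v.tca * params.Y
        assert ss.residual <= 1e-10
        assert min(ss.pools.ACCOA, ss.pools.ACP, ss.pools.ACE_cell) > 0

    def test_solution_is_a_fixed_point_of_the_dynamics(self, params):
        """Integrating the clamped system from the solution stays put."""
        from scipy.integrate import solve_ivp

        from acekin._kernels import pack_params, rates_from_packed

        ss = solve_intracellular_steady_state(15.0, 0.1, params, V4)
        q = pack_params(params, V4)

        def f(t, y):
            vgly, vtca, ptf, ptr, akf, akr, exf, exr = rates_from_packed(
                15.0, 0.1, y[0], y[1], y[2], q
            )
            return [1.4 * vgly - vtca - (ptf - ptr), (ptf - ptr) - (akf - akr),
                    (akf - akr) - (exf - exr)]

        y0 = np.array([ss.pools.ACCOA, ss.pools.ACP, ss.pools.ACE_cell])
        sol = solve_ivp(f, (0.0, 100.0), y0, method="LSODA", rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(sol.y[:, -1], y0, rtol=1e-6)

    def test_unique_solution_from_random_starts(self, params, rng):
        """The damped root-finder lands on one positive steady state."""
        from scipy.optimize import root

        from acekin._kernels import pack_params
        from acekin.simulate import _intra_rhs

        q = pack_params(params, V4)
        bal = _intra_rhs(q, 15.0, 0.1)
        ref = solve_intracellular_steady_state(15.0, 0.1, params, V4)
        expected = np.array([ref.pools.ACCOA, ref.pools.ACP, ref.pools.ACE_cell])
        found = []
        for _ in range(25):
            y0 = 10 ** rng.uniform(-3, 1, 3)
            sol = root(bal, y0, method="hybr", tol=1e-13)
            if sol.success and (sol.x > 0).all():
                found.append(sol.x)
        assert len(found) > 5
        for y in found:
            np.testing.assert_allclose(y, expected, rtol=1e-6)

    def test_rejects_negative_clamps(self, params):
        with pytest.raises(ValueError):
            solve_intracellular_steady_state(-1.0, 0.1, params, V4)


class TestScans:
    def test_uninhibited_variant_has_flat_glucose_flux(self, params):
        tab = acetate_scan(params, V1, np.array([0.1, 1.0, 10.0, 50.0]))
        np.testing.assert_allclose(
            tab["glucose_flux"], tab["glucose_flux"].iloc[0], rtol=1e-9
        )

    def test_dual_inhibition_monotonically_slows_uptake_and_growth(self, params):
        tab = acetate_scan(params, V4, np.logspace(-1, 2, 8))
        assert np.all(np.diff(tab["glucose_flux"]) < 0)
        assert np.all(np.diff(tab["acetate_flux"]) < 0)

    def test_chemostat_growth_matches_dilution(self, params):
        tab = chemostat_scan(params, V4, [0.1, 0.3, 0.5])
        np.testing.assert_allclose(tab["growth_rate"], tab["D"], rtol=1e-6)
        assert not tab["washout"].any()
        assert np.all(np.diff(tab["acetate_flux"]) > 0)  # overflow grows with D

    def test_chemostat_washout_above_mu_max(self, params):
        tab = chemostat_scan(params, V4, [1.5])
        assert bool(tab["washout"].iloc[0])


class TestPulse:
    def test_water_pulse_is_the_unperturbed_control(self, params):
        pulsed = pulse_experiment(params, V4, _batch_init(ace=0.1), 0.0, 2.0, 4.0,
                                  output_grid=0.5)
        control = integrate(_batch_init(ace=0.1), params, V4, 4.0, output_grid=0.5)
        np.testing.assert_allclose(
            pulsed.states[["GLC", "ACE_env", "X"]].to_numpy(),
            control.states[["GLC", "ACE_env", "X"]].to_numpy(),
            rtol=1e-7, atol=1e-9,
        )

    def test_acetate_pulse_reverses_flux_and_slows_uptake(self, params):
        """After 30 mM acetate: net uptake, and slower glucose consumption."""
        traj = pulse_experiment(params, V4, _batch_init(ace=0.1), 30.0, 2.0, 3.0,
                                output_grid=0.05)
        f = traj.fluxes
        before = f[f["time"] <= 1.95].iloc[-1]
        after = f[f["time"] >= 2.10].iloc[0]
        assert before["exchange"] > 0
        assert after["exchange"] < 0          # reversal to uptake
        assert after["glycolysis"] < before["glycolysis"]

        v1 = pulse_experiment(params, V1, _batch_init(ace=0.1), 30.0, 2.0, 3.0,
                              output_grid=0.05)
        f1 = v1.fluxes
        b1 = f1[f1["time"] <= 1.95].iloc[-1]
        a1 = f1[f1["time"] >= 2.10].iloc[0]
        assert a1["glycolysis"] == pytest.approx(b1["glycolysis"], rel=5e-3)

    def test_pulse_time_must_precede_horizon(self, params):
        with pytest.raises(ValueError):
            pulse_experiment(params, V4, _batch_init(), 30.0, 5.0, 4.0)


class TestFluxReversal:
    def test_flux_vanishes_at_the_threshold(self, params):
        thr = find_flux_reversal_threshold(params, V4)
        assert np.isfinite(thr)
        v = solve_intracellular_steady_state(15.0, thr, params, V4).fluxes.exchange
        assert abs(v) < 1e-3 * abs(
            solve_intracellular_steady_state(15.0, 0.1, params, V4).fluxes.exchange
        )

    def test_no_sign_change_reports_no_reversal(self, params):
        thr = find_flux_reversal_threshold(params, V4, bracket=(30.0, 100.0))
        assert np.isnan(thr)  # both ends are uptake: nothing to bisect


class TestProtocolConfigs:
    def test_yaml_protocol_reproduces_direct_call(self, params, tmp_path):
        cfg = tmp_path / "protocol.yaml"
        cfg.write_text(
            "variant: 4\n"
            "t_end: 3.0\n"
            "output_grid: 0.5\n"
            "initial_conditions: {GLC: 15.0, ACE_env: 1.0, X: 0.05}\n"
        )
        from acekin import run_protocol

        traj = run_protocol(cfg, params)
        direct = integrate(_batch_init(ace=1.0, x0=0.05), params, V4, 3.0,
                           output_grid=0.5)
        np.testing.assert_allclose(
            traj.states.to_numpy(), direct.states.to_numpy(), rtol=1e-10
        )

    def test_json_protocol_with_pulse_and_labelling(self, params, tmp_path):
        import json

        cfg = tmp_path / "protocol.json"
        cfg.write_text(json.dumps({
            "variant": 4,
            "t_end": 3.0,
            "output_grid": 0.5,
            "initial_conditions": {"GLC": 15.0, "ACE_env": 0.5, "X": 0.05,
                                   "glc_enrichment": 1.0},
            "pulses": [{"time": 1.5, "species": "ACE_env", "amount": 30.0}],
        }))
        from acekin import run_protocol

        traj = run_protocol(cfg, params)
        assert traj.labelled
        ace = traj.totals().set_index("time")["ACE_env"]
        assert ace.loc[2.0] - ace.loc[1.0] > 25.0  # the pulse landed

    def test_unsupported_pulse_species_raises(self, params, tmp_path):
        from acekin import run_protocol

        with pytest.raises(ValueError, match="ACE_env"):
            run_protocol({"t_end": 2.0, "pulses": [{"time": 1.0,
                          "species": "GLC", "amount": 5.0}]}, params)
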