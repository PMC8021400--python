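"""Control analysis against closed forms and a symbolic implicit-function oracle.

The oracle rebuilds the five rate laws symbolically, differentiates them
with sympy, and computes flux control coefficients from the implicit
function theorem on the intracellular balances (dS/dVmax = -(N J_S)^-1 N
dv/dVmax).  This path shares no code with the package's finite-difference
machinery, so agreement validates both.
"""

import numpy as np
import pytest
import sympy as sp

from acekin import (
    State,
    control_report,
    elasticity_acetate,
    flux_control_coefficients,
    model_variant,
    partitioned_responses,
    regulation_scan,
    response_coefficient,
    solve_intracellular_steady_state,
)
from acekin.control import contribution_fractions
from acekin.model import REACTIONS

V4 = model_variant(4)
V1 = model_variant(1)

#: intracellular stoichiometry (ACCOA, ACP, ACE_cell) x reactions
N_INTRA = sp.Matrix(
    [
        [sp.Rational(14, 10), -1, -1, 0, 0],
        [0, 0, 1, -1, 0],
        [0, 0, 0, 1, -1],
    ]
)


def _symbolic_rates(p, variant, GLC, ACE):
    """The five rate laws as sympy expressions in the intracellular pools."""
    AC, AP, ACl = sp.symbols("AC AP ACl", positive=True)
    g, t, q, a, e, c = p.glycolysis, p.tca, p.pta, p.acka, p.exchange, p.cofactors
    vgly = sp.Float(g.Vmax) * GLC / (GLC + g.Km_GLC)
    if variant.inhibit_glycolysis:
        vgly /= 1 + sp.Float(ACE) / g.Ki_ACE
    vtca = sp.Float(t.Vmax) * AC / (AC + t.Km_ACCOA)
    if variant.inhibit_tca:
        vtca /= 1 + sp.Float(ACE) / t.Ki_ACE
    vpta = (
        sp.Float(q.Vmax) * (AC * c.P - AP * c.COA / q.Keq) / (q.Km_ACCOA * q.Km_P)
        / (1 + AC / q.Km_ACCOA + c.P / q.Ki_P + AP / q.Ki_ACP + c.COA / q.Km_COA
           + AC * c.P / (q.Km_ACCOA * q.Km_P) + AP * c.COA / (q.Km_ACP * q.Km_COA))
    )
    vacka = (
        sp.Float(a.Vmax) * (AP * c.ADP - ACl * c.ATP / a.Keq) / (a.Km_ACP * a.Km_ADP)
        / ((1 + AP / a.Km_ACP + ACl / a.Km_ACE) * (1 + c.ADP / a.Km_ADP + c.ATP / a.Km_ATP))
    )
    vexch = (
        sp.Float(e.Vmax) * (ACl - sp.Float(ACE) / e.Keq) / e.Km_ACE
        / (1 + ACl / e.Km_ACE + sp.Float(ACE) / e.Km_ACE)
    )
    return (AC, AP, ACl), sp.Matrix([vgly, vtca, vpta, vacka, vexch])


def _oracle_control(p, variant, GLC, ACE, pools):
    """C_E^Jace for each reaction, via the implicit function theorem."""
    syms, v = _symbolic_rates(p, variant, GLC, ACE)
    subs = dict(zip(syms, pools))
    J_S = v.jacobian(sp.Matrix(syms))
    NJ = (N_INTRA * J_S).subs(subs)
    v_num = v.subs(subs)
    J_ace = float(v_num[4])
    dvexch_dS = sp.Matrix([[J_S[4, j].subs(subs) for j in range(3)]])
    C = {}
    for k, name in enumerate(REACTIONS):
        dv_dE = sp.zeros(5, 1)
        dv_dE[k] = v_num[k]  # dv_k/dln Vmax_k = v_k
        dS = -(NJ.inv() * (N_INTRA * dv_dE))
        dJ = v_num[4] if k == 4 else sp.Float(0)
        dJ = dJ + (dvexch_dS * dS)[0]
        C[name] = float(dJ) / J_ace
    return C


class TestOracleEquivalence:
    def test_control_coefficients_match_symbolic_oracle(self, params):
        """Finite-difference C agree with the sympy oracle to 1e-6."""
        ss = solve_intracellular_steady_state(15.0, 0.1, params, V4)
        pools = (ss.pools.ACCOA, ss.pools.ACP, ss.pools.ACE_cell)
        oracle = _oracle_control(params, V4, 15.0, 0.1, pools)
        numeric = flux_control_coefficients(
            params, V4, 15.0, 0.1, delta=1e-4, flux_names=("exchange",)
        )["exchange"]
        for name in REACTIONS:
            assert numeric[name] == pytest.approx(oracle[name], abs=1e-6)

    def test_two_reaction_chain_closed_form(self, params):
        """With the acetate branch silenced the model is a linear two-step
        chain; the producer carries all the control (C = 1) and the
        intermediate-consuming step none (C = 0)."""
        p = params.with_updates({"pta.Vmax": 1e-12})
        C = flux_control_coefficients(
            p, V4, 15.0, 0.1, delta=1e-4, flux_names=("tca",)
        )["tca"]
        assert C["glycolysis"] == pytest.approx(1.0, abs=1e-6)
        assert C["tca"] == pytest.approx(0.0, abs=1e-6)

    def test_analytic_elasticities_match_finite_differences(self, params):
        ss = solve_intracellular_steady_state(15.0, 30.0, params, V4)
        from acekin.control import elasticity_acetate_numeric

        for rx in ("glycolysis", "tca", "exchange"):
            ana = elasticity_acetate(params, V4, rx, ss.pools)
            num = elasticity_acetate_numeric(params, V4, rx, ss.pools)
            assert ana == pytest.approx(num, abs=1e-6)

    def test_exchange_elasticity_under_uptake(self, params):
        """Fixed-state exchange elasticity at 30 mM external acetate."""
        st = State(GLC=15.0, ACE_env=30.0, X=1.0, ACCOA=0.2, ACP=0.05, ACE_cell=1.0)
        from acekin.control import elasticity_acetate_numeric

        ana = elasticity_acetate(params, V4, "exchange", st)
        num = elasticity_acetate_numeric(params, V4, "exchange", st)
        assert ana == pytest.approx(num, rel=1e-6)


class TestElasticityClosedForms:
    def test_inhibition_off_gives_zero(self, params, interior_state):
        assert elasticity_acetate(params, V1, "glycolysis", interior_state) == 0.0
        assert elasticity_acetate(params, V1, "tca", interior_state) == 0.0

    def test_acetate_at_ki_gives_minus_half(self, params):
        st = State(15.0, params.glycolysis.Ki_ACE, 1.0, 0.2, 0.05, 0.3)
        assert elasticity_acetate(params, V4, "glycolysis", st) == pytest.approx(-0.5)
        st = State(15.0, params.tca.Ki_ACE, 1.0, 0.2, 0.05, 0.3)
        assert elasticity_acetate(params, V4, "tca", st) == pytest.approx(-0.5)

    def test_pta_and_acka_do_not_sense_external_acetate(self, params, interior_state):
        assert elasticity_acetate(params, V4, "pta", interior_state) == 0.0
        assert elasticity_acetate(params, V4, "acka", interior_state) == 0.0


class TestTheorems:
    @pytest.mark.parametrize("ace", [0.1, 1.0, 30.0])
    def test_summation_theorem(self, params, ace):
        """Control coefficients on the acetate flux sum to one."""
        C = flux_control_coefficients(
            params, V4, 15.0, ace, flux_names=("exchange",)
        )["exchange"]
        assert sum(C.values()) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("ace", [0.5, 5.0, 30.0])
    def test_partitioned_response_sums_to_direct_response(self, params, ace):
        viR = partitioned_responses(params, V4, 15.0, ace)
        R = response_coefficient(params, V4, 15.0, ace)
        assert sum(viR.values()) == pytest.approx(R, abs=1e-3)

    def test_uninhibited_variant_has_single_route(self, params):
        viR = partitioned_responses(params, V1, 15.0, 1.0)
        assert viR["glycolysis"] == 0.0
        assert viR["tca"] == 0.0
        assert viR["acetate_pathway"] != 0.0

    def test_contribution_fractions_are_a_partition(self):
        frac = contribution_fractions({"a": -0.2, "b": 0.1, "c": 0.3})
        assert sum(frac.values()) == pytest.approx(1.0)
        assert all(0 <= v <= 1 for v in frac.values())

    def test_finite_difference_step_is_converged(self, params):
        """Richardson check: step 1e-3 and 1e-4 agree to 1e-4."""
        a = flux_control_coefficients(params, V4, 15.0, 0.1, delta=1e-3,
                                      flux_names=("exchange",))["exchange"]
        b = flux_control_coefficients(params, V4, 15.0, 0.1, delta=1e-4,
                                      flux_names=("exchange",))["exchange"]
        for name in REACTIONS:
            assert a[name] == pytest.approx(b[name], abs=1e-4)

    def test_blocks_do_not_depend_on_clamped_biomass(self, params):
        r1 = control_report(params, V4, 15.0, 0.5)
        ss = solve_intracellular_steady_state(15.0, 0.5, params, V4, X=7.3)
        assert ss.fluxes.exchange == pytest.approx(
            solve_intracellular_steady_state(15.0, 0.5, params, V4, X=1.0).fluxes.exchange
        )
        C2 = flux_control_coefficients(params, V4, 15.0, 0.5,
                                       flux_names=("exchange",))["exchange"]
        for k, v in r1.control["exchange"].items():
            assert C2[k] == pytest.approx(v, abs=1e-9)


class TestRegulationScan:
    def test_scan_rows_are_consistent(self, params):
        grid = np.array([0.1, 0.5, 2.0, 30.0])
        tab = regulation_scan(params, V4, grid)
        ok = ~tab["masked"]
        assert ok.all()
        np.testing.assert_allclose(
            tab.loc[ok, ["frac_acetate_pathway", "frac_glycolysis", "frac_tca"]].sum(axis=1),
            1.0, rtol=1e-9,
        )
        # acetate-pathway control fades as acetate accumulates
        c = tab["C_acetate_pathway"].to_numpy()
        assert np.all(np.diff(c) < 0)

    def test_reversal_singularity_is_masked(self, params):
        from acekin import find_flux_reversal_threshold

        thr = find_flux_reversal_threshold(params, V4)
        tab = regulation_scan(params, V4, np.array([thr * (1 + 1e-7)]))
        assert bool(tab["masked"].iloc[0])
        assert np.isnan(tab["C_glycolysis"].iloc[0])
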