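"""Rate-law unit tests against trivial identities and a symbolic oracle.

The symbolic oracle builds each rate law independently in sympy from its
algebraic definition and evaluates it exactly; the package implementation
must agree to near machine precision.
"""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

from acekin import (
    ParameterSet,
    State,
    model_variant,
    rate_acka,
    rate_exchange,
    rate_glycolysis,
    rate_pta,
    rate_tca,
    all_rates,
)

V1, V2, V4 = model_variant(1), model_variant(2), model_variant(4)


# ---------------------------------------------------------------------------
# symbolic oracle
# ---------------------------------------------------------------------------

def _sym_pta(p, ACCOA, ACP):
    """Independent sympy evaluation of the Pta rate law."""
    a, b = sp.Float(ACCOA, 30), sp.Float(ACP, 30)
    q = p.pta
    c = p.cofactors
    P, COA = sp.Float(c.P, 30), sp.Float(c.COA, 30)
    num = sp.Float(q.Vmax, 30) * (a * P - b * COA / sp.Float(q.Keq, 30)) / (
        sp.Float(q.Km_ACCOA, 30) * sp.Float(q.Km_P, 30)
    )
    den = (
        1 + a / sp.Float(q.Km_ACCOA, 30) + P / sp.Float(q.Ki_P, 30)
        + b / sp.Float(q.Ki_ACP, 30) + COA / sp.Float(q.Km_COA, 30)
        + a * P / (sp.Float(q.Km_ACCOA, 30) * sp.Float(q.Km_P, 30))
        + b * COA / (sp.Float(q.Km_ACP, 30) * sp.Float(q.Km_COA, 30))
    )
    return float(num / den)


def _sym_acka(p, ACP, ACE_cell):
    a, b = sp.Float(ACP, 30), sp.Float(ACE_cell, 30)
    q = p.acka
    c = p.cofactors
    ADP, ATP = sp.Float(c.ADP, 30), sp.Float(c.ATP, 30)
    num = sp.Float(q.Vmax, 30) * (a * ADP - b * ATP / sp.Float(q.Keq, 30)) / (
        sp.Float(q.Km_ACP, 30) * sp.Float(q.Km_ADP, 30)
    )
    den = (1 + a / sp.Float(q.Km_ACP, 30) + b / sp.Float(q.Km_ACE, 30)) * (
        1 + ADP / sp.Float(q.Km_ADP, 30) + ATP / sp.Float(q.Km_ATP, 30)
    )
    return float(num / den)


def _sym_gly(p, GLC, ACE, inhibited):
    g = p.glycolysis
    expr = sp.Float(g.Vmax, 30) * sp.Float(GLC, 30) / (
        sp.Float(GLC, 30) + sp.Float(g.Km_GLC, 30)
    )
    if inhibited:
        expr /= 1 + sp.Float(ACE, 30) / sp.Float(g.Ki_ACE, 30)
    return float(expr)


# ---------------------------------------------------------------------------
# glycolysis / TCA
# ---------------------------------------------------------------------------

def _state(**kw):
    base = dict(GLC=0.0, ACE_env=0.0, X=0.1, ACCOA=0.0, ACP=0.0, ACE_cell=0.0)
    base.update(kw)
    return State(**base)


class TestIrreversibleRates:
    def test_zero_substrate_gives_zero_rate(self, params):
        assert rate_glycolysis(_state(GLC=0.0), params, V4) == 0.0
        assert rate_tca(_state(ACCOA=0.0), params, V4) == 0.0

    def test_half_saturation_gives_half_vmax(self, params):
        st = _state(GLC=params.glycolysis.Km_GLC)
        assert rate_glycolysis(st, params, V1) == pytest.approx(
            params.glycolysis.Vmax / 2, rel=1e-12
        )
        st = _state(ACCOA=params.tca.Km_ACCOA)
        assert rate_tca(st, params, V1) == pytest.approx(params.tca.Vmax / 2, rel=1e-12)

    def test_inhibition_at_ki_halves_rate(self, params):
        """At ACE = Ki the non-competitive factor is exactly 1/2."""
        st = _state(GLC=15.0, ACE_env=params.glycolysis.Ki_ACE)
        expected = params.glycolysis.Vmax * (15.0 / 15.02) * 0.5
        assert rate_glycolysis(st, params, V4) == pytest.approx(expected, rel=1e-12)
        assert rate_glycolysis(st, params, V4) == pytest.approx(
            _sym_gly(params, 15.0, params.glycolysis.Ki_ACE, True), rel=1e-12
        )
        st = _state(ACCOA=params.tca.Km_ACCOA, ACE_env=params.tca.Ki_ACE)
        assert rate_tca(st, params, V4) == pytest.approx(params.tca.Vmax / 4, rel=1e-12)

    def test_missing_ki_with_inhibition_is_configuration_error(self):
        p = ParameterSet()
        p.glycolysis.Ki_ACE = None
        with pytest.raises(ValueError, match="Ki_ACE"):
            rate_glycolysis(_state(GLC=1.0), p, V2)

    @settings(deadline=None, derandomize=True)
    @given(
        glc=st.floats(0.001, 100.0),
        factor=st.floats(1.01, 10.0),
        ace=st.floats(0.0, 100.0),
    )
    def test_monotone_in_glucose_and_acetate(self, params, glc, factor, ace):
        """Rate increases with glucose; decreases with acetate iff inhibited."""
        lo = rate_glycolysis(_state(GLC=glc, ACE_env=ace), params, V4)
        hi = rate_glycolysis(_state(GLC=glc * factor, ACE_env=ace), params, V4)
        assert hi > lo
        uninhibited = rate_glycolysis(_state(GLC=glc, ACE_env=ace * factor), params, V1)
        assert uninhibited == rate_glycolysis(_state(GLC=glc), params, V1)
        if ace > 1e-6:
            inhibited = rate_glycolysis(_state(GLC=glc, ACE_env=ace * factor), params, V4)
            assert inhibited < lo


# ---------------------------------------------------------------------------
# reversible rates
# ---------------------------------------------------------------------------

class TestReversibleRates:
    def test_net_vanishes_at_equilibrium(self, params):
        c = params.cofactors
        accoa = 0.5
        acp_eq = accoa * c.P * params.pta.Keq / c.COA
        net, _, _ = rate_pta(_state(ACCOA=accoa, ACP=acp_eq), params)
        assert net == pytest.approx(0.0, abs=1e-9)

        acp = 0.1
        ace_eq = acp * c.ADP * params.acka.Keq / c.ATP
        net, _, _ = rate_acka(_state(ACP=acp, ACE_cell=ace_eq), params)
        assert net == pytest.approx(0.0, abs=1e-9)

        net, _, _ = rate_exchange(_state(ACE_cell=3.0, ACE_env=3.0), params)
        assert net == 0.0

    def test_zero_product_means_zero_reverse(self, params):
        net, fwd, rev = rate_pta(_state(ACCOA=0.2, ACP=0.0), params)
        assert rev == 0.0 and net == fwd > 0
        net, fwd, rev = rate_acka(_state(ACP=0.1, ACE_cell=0.0), params)
        assert rev == 0.0 and net == fwd > 0

    @settings(deadline=None, derandomize=True)
    @given(
        accoa=st.floats(1e-6, 50.0),
        acp=st.floats(1e-6, 10.0),
        ace_cell=st.floats(1e-6, 100.0),
        ace_env=st.floats(0.0, 100.0),
    )
    def test_forward_minus_reverse_equals_net(self, params, accoa, acp, ace_cell, ace_env):
        st_ = _state(ACCOA=accoa, ACP=acp, ACE_cell=ace_cell, ACE_env=ace_env)
        for fn in (rate_pta, rate_acka, rate_exchange):
            net, fwd, rev = fn(st_, params)
            assert net == pytest.approx(fwd - rev, abs=1e-9 * max(1.0, abs(fwd), abs(rev)))

    def test_pta_against_symbolic_oracle(self, params):
        accoa, acp = 0.2, 0.7
        net, _, _ = rate_pta(_state(ACCOA=accoa, ACP=acp), params)
        assert net == pytest.approx(_sym_pta(params, accoa, acp), rel=1e-12)

    def test_acka_against_symbolic_oracle(self, params):
        acp, ace = 0.16, 7.0
        net, _, _ = rate_acka(_state(ACP=acp, ACE_cell=ace), params)
        assert net == pytest.approx(_sym_acka(params, acp, ace), rel=1e-12)

    def test_exchange_half_saturation_and_uptake_sign(self, params):
        st_ = _state(ACE_cell=params.exchange.Km_ACE, ACE_env=0.0)
        net, _, _ = rate_exchange(st_, params)
        assert net == pytest.approx(params.exchange.Vmax / 2, rel=1e-12)
        net, _, _ = rate_exchange(_state(ACE_cell=1.0, ACE_env=30.0), params)
        assert net < 0  # high external acetate drives uptake

    def test_vmax_scaling_scales_all_rates(self, params, interior_state):
        """Scaling every Vmax by k scales every metabolic rate by exactly k."""
        k = 3.7
        scaled = params.with_updates(
            {path: params.get_path(path) * k
             for path in ("glycolysis.Vmax", "tca.Vmax", "pta.Vmax",
                          "acka.Vmax", "exchange.Vmax")}
        )
        v0 = all_rates(interior_state, params, V4)
        v1 = all_rates(interior_state, scaled, V4)
        for name in ("glycolysis", "tca", "pta", "acka", "exchange"):
            assert v1[name] == pytest.approx(k * v0[name], rel=1e-12)
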