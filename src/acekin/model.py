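"""Model variants, state containers, rate laws and the ODE right-hand side.

Four nested variants of the same reaction network differ only in whether the
glycolytic and/or TCA blocks are non-competitively inhibited by extracellular
acetate (a ``1/(1 + ACE_env/Ki)`` factor on the Vmax):

=======  ==================  ===========
variant  glycolysis inhib.   TCA inhib.
=======  ==================  ===========
1        no                  no
2        yes                 no
3        no                  yes
4        yes                 yes
=======  ==================  ===========

The inhibition term is a phenomenological stand-in for the integrated
(transcriptional and faster) response of the cell to acetate; the controlling
species is the extracellular pool, the first signal cells sense.

Sign conventions: glycolysis consumes glucose (dGLC/dt carries the negative
sign); positive Pta/AckA/exchange net rates run towards extracellular
acetate (export).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "ModelVariant",
    "State",
    "FluxVector",
    "model_variant",
    "rate_glycolysis",
    "rate_tca",
    "rate_pta",
    "rate_acka",
    "rate_exchange",
    "all_rates",
    "rhs",
    "REACTIONS",
]

logger = logging.getLogger(__name__)

#: metabolic reactions, in kernel order (growth is derived from tca)
REACTIONS = ("glycolysis", "tca", "pta", "acka", "exchange")


@dataclass(frozen=True)
class ModelVariant:
    """Which inhibition terms are active, and the culture mode.

    ``dilution_rate`` (D, /hr) and ``feed_rate`` (mM glucose/hr on the
    environment basis) are only meaningful in chemostat mode and ignored in
    batch mode.
    """

    inhibit_glycolysis: bool = False
    inhibit_tca: bool = False
    mode: str = "batch"  # "batch" | "chemostat"
    dilution_rate: float = 0.0
    feed_rate: float = 0.0
    label_tracking: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("batch", "chemostat"):
            raise ValueError(f"mode must be 'batch' or 'chemostat', got {self.mode!r}")
        if self.dilution_rate < 0 or self.feed_rate < 0:
            raise ValueError("dilution_rate and feed_rate must be >= 0")

    def check_parameters(self, p: ParameterSet) -> None:
        """Inhibited blocks must carry an inhibition constant."""
        if self.inhibit_glycolysis and p.glycolysis.Ki_ACE is None:
            raise ValueError("glycolysis inhibition requested but glycolysis.Ki_ACE is None")
        if self.inhibit_tca and p.tca.Ki_ACE is None:
            raise ValueError("TCA inhibition requested but tca.Ki_ACE is None")

    def with_chemostat(self, D: float, feed_glucose: float) -> "ModelVariant":
        """Chemostat copy with dilution D and feed = D * reservoir glucose."""
        return replace(self, mode="chemostat", dilution_rate=D, feed_rate=D * feed_glucose)

    def with_batch(self) -> "ModelVariant":
        return replace(self, mode="batch", dilution_rate=0.0, feed_rate=0.0)


def model_variant(code: int, **kwargs) -> ModelVariant:
    """Build variant 1-4 by its conventional number."""
    table = {
        1: (False, False),
        2: (True, False),
        3: (False, True),
        4: (True, True),
    }
    if code not in table:
        raise ValueError(f"variant code must be 1-4, got {code}")
    gly, tca = table[code]
    return ModelVariant(inhibit_glycolysis=gly, inhibit_tca=tca, **kwargs)


@dataclass
class State:
    """Concentrations of the six state variables.

    GLC and ACE_env are environment concentrations (mM), X is biomass
    (gDW/L); ACCOA, ACP and ACE_cell are intracellular concentrations (mM).
    """

    GLC: float
    ACE_env: float
    X: float
    ACCOA: float
    ACP: float
    ACE_cell: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.GLC, self.ACE_env, self.X, self.ACCOA, self.ACP, self.ACE_cell]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "State":
        return cls(*map(float, y))

    def validate(self) -> None:
        if any(v < 0 for v in self.to_array()):
            raise ValueError(f"negative concentration in state {self}")


@dataclass
class FluxVector:
    """All reaction rates at one state (mM/hr on the cell basis; growth in /hr).

    ``pta``, ``acka`` and ``exchange`` are net rates; their unidirectional
    components are available as ``*_fwd`` / ``*_rev``.
    """

    glycolysis: float
    tca: float
    pta: float
    acka: float
    exchange: float
    growth: float
    pta_fwd: float = 0.0
    pta_rev: float = 0.0
    acka_fwd: float = 0.0
    acka_rev: float = 0.0
    exchange_fwd: float = 0.0
    exchange_rev: float = 0.0

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def rate_glycolysis(state: State, p: ParameterSet, variant: ModelVariant) -> float:
    """Irreversible MM in glucose, optionally inhibited by extracellular acetate."""
    variant.check_parameters(p)
    g = p.glycolysis
    v = g.Vmax * state.GLC / (state.GLC + g.Km_GLC)
    if variant.inhibit_glycolysis:
        v /= 1.0 + state.ACE_env / g.Ki_ACE
    return v


def rate_tca(state: State, p: ParameterSet, variant: ModelVariant) -> float:
    """Irreversible MM in acetyl-CoA, optionally inhibited by acetate."""
    variant.check_parameters(p)
    t = p.tca
    v = t.Vmax * state.ACCOA / (state.ACCOA + t.Km_ACCOA)
    if variant.inhibit_tca:
        v /= 1.0 + state.ACE_env / t.Ki_ACE
    return v


def rate_pta(state: State, p: ParameterSet) -> tuple[float, float, float]:
    """Phosphotransacetylase net, forward and reverse rates.

    Reversible MM with dead-end inhibition by phosphate and
    acetyl-phosphate; forward and reverse are the two numerator terms over
    the shared denominator, so ``net = forward - reverse`` exactly.
    """
    q = p.pta
    c = p.cofactors
    denom = (
        1.0
        + state.ACCOA / q.Km_ACCOA
        + c.P / q.Ki_P
        + state.ACP / q.Ki_ACP
        + c.COA / q.Km_COA
        + state.ACCOA * c.P / (q.Km_ACCOA * q.Km_P)
        + state.ACP * c.COA / (q.Km_ACP * q.Km_COA)
    )
    k = q.Vmax / (q.Km_ACCOA * q.Km_P) / denom
    fwd = k * state.ACCOA * c.P
    rev = k * state.ACP * c.COA / q.Keq
    return fwd - rev, fwd, rev


def rate_acka(state: State, p: ParameterSet) -> tuple[float, float, float]:
    """Acetate kinase net, forward and reverse rates (reversible MM)."""
    a = p.acka
    c = p.cofactors
    denom = (1.0 + state.ACP / a.Km_ACP + state.ACE_cell / a.Km_ACE) * (
        1.0 + c.ADP / a.Km_ADP + c.ATP / a.Km_ATP
    )
    k = a.Vmax / (a.Km_ACP * a.Km_ADP) / denom
    fwd = k * state.ACP * c.ADP
    rev = k * state.ACE_cell * c.ATP / a.Keq
    return fwd - rev, fwd, rev


def rate_exchange(state: State, p: ParameterSet) -> tuple[float, float, float]:
    """Acetate exchange net, forward (export) and reverse (uptake) rates."""
    e = p.exchange
    denom = 1.0 + state.ACE_cell / e.Km_ACE + state.ACE_env / e.Km_ACE
    k = e.Vmax / e.Km_ACE / denom
    fwd = k * state.ACE_cell
    rev = k * state.ACE_env / e.Keq
    return fwd - rev, fwd, rev


def all_rates(state: State, p: ParameterSet, variant: ModelVariant) -> FluxVector:
    """Evaluate every rate law at one state."""
    vgly = rate_glycolysis(state, p, variant)
    vtca = rate_tca(state, p, variant)
    vpta, ptf, ptr = rate_pta(state, p)
    vacka, akf, akr = rate_acka(state, p)
    vexch, exf, exr = rate_exchange(state, p)
    return FluxVector(
        glycolysis=vgly,
        tca=vtca,
        pta=vpta,
        acka=vacka,
        exchange=vexch,
        growth=vtca * p.Y,
        pta_fwd=ptf,
        pta_rev=ptr,
        acka_fwd=akf,
        acka_rev=akr,
        exchange_fwd=exf,
        exchange_rev=exr,
    )


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

_warned_negative = False


def rhs(t: float, y: np.ndarray, p: ParameterSet, variant: ModelVariant) -> np.ndarray:
    """Time derivative of ``[GLC, ACE_env, X, ACCOA, ACP, ACE_cell]``.

    Rates are evaluated on ``max(y, 0)``: transient tiny negatives are
    integrator artefacts and are clipped (with a one-time warning) rather
    than aborting the solve.  In chemostat mode, glucose feed and medium
    outflow terms (dilution rate D) apply to the extracellular balances.
    """
    global _warned_negative
    y = np.asarray(y, dtype=float)
    if y.min() < 0 and not _warned_negative:
        _warned_negative = True
        logger.warning("negative state entries clipped to zero during rate evaluation")
    yc = np.maximum(y, 0.0)
    state = State.from_array(yc)
    v = all_rates(state, p, variant)
    rho = state.X * p.Vcell / p.Venv
    dGLC = -v.glycolysis * rho
    dACE = v.exchange * rho
    dX = state.X * v.growth
    if variant.mode == "chemostat":
        D = variant.dilution_rate
        dGLC += variant.feed_rate - D * state.GLC
        dACE += -D * state.ACE_env
        dX += -D * state.X
    return np.array(
        [
            dGLC,
            dACE,
            dX,
            p.accoa_per_glc * v.glycolysis - v.tca - v.pta,
            v.pta - v.acka,
            v.acka - v.exchange,
        ]
    )
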