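"""Metabolic control analysis and regulation decomposition.

Scaled flux control coefficients C_E^J = dlnJ/dlnE quantify how much a
steady-state flux J shifts when the activity (Vmax) of reaction E changes.
The response coefficient R = dlnJ_ace/dlnACE measures the dependence of the
acetate flux on the extracellular acetate concentration, and the partitioned
response theorem splits it into routes: R = sum_i C_i * eps_i, where eps_i
is the elasticity of reaction i towards acetate.  Three routes carry the
response here — the acetate pathway itself (through the exchange reaction's
thermodynamic sensitivity to extracellular acetate: direct, metabolic
regulation) and the glycolytic and TCA inhibition terms (indirect,
hierarchical regulation).

All coefficients are evaluated at the clamped intracellular steady state by
central finite differences in log space (relative step 1e-3); elasticities
have closed forms which are used directly.  Near the acetate-flux reversal
the scaled coefficients diverge (J -> 0); scans mask those points instead of
interpolating through the singularity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelVariant, State, REACTIONS, all_rates
from .parameters import ParameterSet
from .simulate import solve_intracellular_steady_state

__all__ = [
    "ControlReport",
    "VMAX_PATHS",
    "flux_control_coefficients",
    "elasticity_acetate",
    "elasticity_acetate_numeric",
    "response_coefficient",
    "partitioned_responses",
    "control_report",
    "regulation_scan",
    "regulatory_range_edge",
]

#: dotted parameter path of each reaction's activity
VMAX_PATHS = {
    "glycolysis": "glycolysis.Vmax",
    "tca": "tca.Vmax",
    "pta": "pta.Vmax",
    "acka": "acka.Vmax",
    "exchange": "exchange.Vmax",
}

FLUXES = ("glycolysis", "tca", "pta", "acka", "exchange", "growth")

#: routes of the partitioned response
ROUTES = ("acetate_pathway", "glycolysis", "tca")


@dataclass
class ControlReport:
    """Control and regulation coefficients at one clamped condition."""

    GLC: float
    ACE_env: float
    fluxes: dict[str, float]
    control: dict[str, dict[str, float]]      # control[J][E]
    blocks: dict[str, float]                   # blocks on the acetate flux
    elasticities: dict[str, float]             # eps_Ace per reaction
    response: float                            # R_Ace^Jace (direct perturbation)
    partitioned: dict[str, float]              # viR per route
    contributions: dict[str, float]            # |viR| shares, sum to 1
    flags: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _plain(obj):
            if isinstance(obj, (np.bool_,)):
                return bool(obj)
            if isinstance(obj, (np.floating, np.integer)):
                return float(obj)
            raise TypeError(f"not JSON serialisable: {type(obj)}")

        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_plain) + "\n")


def _ace_flux(p: ParameterSet, variant: ModelVariant, GLC: float, ACE: float) -> float:
    return solve_intracellular_steady_state(GLC, ACE, p, variant).fluxes.exchange


def flux_control_coefficients(
    p: ParameterSet,
    variant: ModelVariant,
    GLC: float,
    ACE_env: float,
    delta: float = 1e-3,
    flux_names: tuple[str, ...] = FLUXES,
) -> dict[str, dict[str, float]]:
    """Scaled control coefficients ``C[J][E]`` by central log-differences.

    Each reaction's Vmax is perturbed by a relative ``delta`` up and down,
    the clamped steady state re-solved, and C = dlnJ/dlnVmax.  A flux that
    is zero at the condition has no scaled coefficient; NaN is reported
    there (see :func:`regulation_scan` for masking).
    """
    base = solve_intracellular_steady_state(GLC, ACE_env, p, variant)
    J0 = {name: base.fluxes[name] for name in flux_names}
    dln = np.log1p(delta) - np.log1p(-delta)
    out: dict[str, dict[str, float]] = {name: {} for name in flux_names}
    for rx, path in VMAX_PATHS.items():
        v0 = p.get_path(path)
        up = solve_intracellular_steady_state(
            GLC, ACE_env, p.with_updates({path: v0 * (1 + delta)}), variant
        )
        dn = solve_intracellular_steady_state(
            GLC, ACE_env, p.with_updates({path: v0 * (1 - delta)}), variant
        )
        for name in flux_names:
            dJ = up.fluxes[name] - dn.fluxes[name]
            out[name][rx] = (dJ / J0[name]) / dln if J0[name] != 0 else np.nan
    return out


def block_coefficients(control_ace: dict[str, float]) -> dict[str, float]:
    """Sum the per-reaction coefficients on the acetate flux into blocks."""
    return {
        "glycolysis": control_ace["glycolysis"],
        "tca": control_ace["tca"],
        "acetate_pathway": control_ace["pta"] + control_ace["acka"] + control_ace["exchange"],
    }


# ---------------------------------------------------------------------------
# elasticities
# ---------------------------------------------------------------------------

def elasticity_acetate(
    p: ParameterSet, variant: ModelVariant, reaction: str, state: State
) -> float:
    """Scaled sensitivity of one rate law to extracellular acetate (analytic).

    Non-competitive inhibition contributes ``-ACE/(Ki + ACE)``; the exchange
    reaction senses acetate through both its thermodynamic driving force and
    its saturation term; Pta and AckA do not contain extracellular acetate.
    """
    ACE = state.ACE_env
    if reaction == "glycolysis":
        if not variant.inhibit_glycolysis:
            return 0.0
        return -ACE / (p.glycolysis.Ki_ACE + ACE)
    if reaction == "tca":
        if not variant.inhibit_tca:
            return 0.0
        return -ACE / (p.tca.Ki_ACE + ACE)
    if reaction == "exchange":
        e = p.exchange
        C, E = state.ACE_cell, ACE
        denom = 1.0 + C / e.Km_ACE + E / e.Km_ACE
        v = e.Vmax * (C - E / e.Keq) / e.Km_ACE / denom
        dvdE = (
            e.Vmax / e.Km_ACE
            * (-(1.0 / e.Keq) * denom - (C - E / e.Keq) / e.Km_ACE)
            / denom**2
        )
        return E / v * dvdE
    if reaction in ("pta", "acka"):
        return 0.0
    raise KeyError(reaction)


def elasticity_acetate_numeric(
    p: ParameterSet,
    variant: ModelVariant,
    reaction: str,
    state: State,
    delta: float = 1e-6,
) -> float:
    """Finite-difference elasticity at fixed state (cross-check oracle)."""
    def rate_at(ace):
        st = State(state.GLC, ace, state.X, state.ACCOA, state.ACP, state.ACE_cell)
        return getattr(all_rates(st, p, variant), reaction)

    E = state.ACE_env
    up, dn = rate_at(E * (1 + delta)), rate_at(E * (1 - delta))
    v0 = rate_at(E)
    return (up - dn) / (2 * delta) / v0


# ---------------------------------------------------------------------------
# response and partitioned response
# ---------------------------------------------------------------------------

def response_coefficient(
    p: ParameterSet, variant: ModelVariant, GLC: float, ACE_env: float, delta: float = 1e-3
) -> float:
    """R = dlnJ_ace/dlnACE by direct perturbation of the clamped acetate."""
    J0 = _ace_flux(p, variant, GLC, ACE_env)
    up = _ace_flux(p, variant, GLC, ACE_env * (1 + delta))
    dn = _ace_flux(p, variant, GLC, ACE_env * (1 - delta))
    dln = np.log1p(delta) - np.log1p(-delta)
    return (up - dn) / J0 / dln


def partitioned_responses(
    p: ParameterSet,
    variant: ModelVariant,
    GLC: float,
    ACE_env: float,
    delta: float = 1e-3,
    control: dict[str, dict[str, float]] | None = None,
) -> dict[str, float]:
    """Per-route partitioned responses viR = C_i * eps_i.

    Routes: ``acetate_pathway`` (the exchange reaction's direct sensitivity),
    ``glycolysis`` and ``tca`` (inhibition terms).  Their sum equals the
    direct-perturbation response coefficient at any regular condition.
    """
    ss = solve_intracellular_steady_state(GLC, ACE_env, p, variant)
    if control is None:
        control = flux_control_coefficients(
            p, variant, GLC, ACE_env, delta=delta, flux_names=("exchange",)
        )
    C = control["exchange"]
    eps = {rx: elasticity_acetate(p, variant, rx, ss.pools) for rx in REACTIONS}
    return {
        "acetate_pathway": C["exchange"] * eps["exchange"],
        "glycolysis": C["glycolysis"] * eps["glycolysis"],
        "tca": C["tca"] * eps["tca"],
    }


def contribution_fractions(partitioned: dict[str, float]) -> dict[str, float]:
    """|viR| shares per route.

    Absolute-value weighting keeps the shares in [0, 1] and summing to 1
    even when routes pull in opposite directions.
    """
    total = sum(abs(v) for v in partitioned.values())
    if total == 0:
        return {k: np.nan for k in partitioned}
    return {k: abs(v) / total for k, v in partitioned.items()}


def control_report(
    p: ParameterSet,
    variant: ModelVariant,
    GLC: float = 15.0,
    ACE_env: float = 0.1,
    delta: float = 1e-3,
) -> ControlReport:
    """Full control/regulation analysis at one condition."""
    ss = solve_intracellular_steady_state(GLC, ACE_env, p, variant)
    control = flux_control_coefficients(p, variant, GLC, ACE_env, delta=delta)
    eps = {rx: elasticity_acetate(p, variant, rx, ss.pools) for rx in REACTIONS}
    viR = partitioned_responses(p, variant, GLC, ACE_env, delta=delta, control=control)
    R = response_coefficient(p, variant, GLC, ACE_env, delta=delta)
    return ControlReport(
        GLC=GLC,
        ACE_env=ACE_env,
        fluxes={name: ss.fluxes[name] for name in FLUXES},
        control=control,
        blocks=block_coefficients(control["exchange"]),
        elasticities=eps,
        response=R,
        partitioned=viR,
        contributions=contribution_fractions(viR),
        flags={"reversal_singularity": abs(ss.fluxes.exchange) < 1e-9},
    )


# ---------------------------------------------------------------------------
# concentration scan
# ---------------------------------------------------------------------------

def regulation_scan(
    p: ParameterSet,
    variant: ModelVariant,
    ace_grid: np.ndarray,
    GLC: float = 15.0,
    delta: float = 1e-3,
    mask_rel: float = 1e-3,
    reference_ace: float = 0.1,
) -> pd.DataFrame:
    """Control blocks, response and partitioned responses across acetate.

    Scaled coefficients diverge where the acetate flux crosses zero; rows
    with ``|J_ace|`` below ``mask_rel`` times its value at ``reference_ace``
    have their scaled-coefficient columns masked (NaN) and are flagged.
    """
    j_ref = abs(_ace_flux(p, variant, GLC, reference_ace))
    floor = mask_rel * j_ref
    rows = []
    for ace in np.asarray(ace_grid, dtype=float):
        ss = solve_intracellular_steady_state(GLC, ace, p, variant)
        J = ss.fluxes.exchange
        masked = abs(J) < floor
        row = {"ACE_env": ace, "J_ace": J * p.Vcell, "masked": masked}
        if masked:
            for k in ("C_glycolysis", "C_tca", "C_acetate_pathway", "R",
                      "viR_acetate_pathway", "viR_glycolysis", "viR_tca",
                      "frac_acetate_pathway", "frac_glycolysis", "frac_tca"):
                row[k] = np.nan
        else:
            control = flux_control_coefficients(
                p, variant, GLC, ace, delta=delta, flux_names=("exchange",)
            )
            blocks = block_coefficients(control["exchange"])
            viR = partitioned_responses(p, variant, GLC, ace, delta=delta, control=control)
            frac = contribution_fractions(viR)
            row.update(
                C_glycolysis=blocks["glycolysis"],
                C_tca=blocks["tca"],
                C_acetate_pathway=blocks["acetate_pathway"],
                R=response_coefficient(p, variant, GLC, ace, delta=delta),
                viR_acetate_pathway=viR["acetate_pathway"],
                viR_glycolysis=viR["glycolysis"],
                viR_tca=viR["tca"],
                frac_acetate_pathway=frac["acetate_pathway"],
                frac_glycolysis=frac["glycolysis"],
                frac_tca=frac["tca"],
            )
        rows.append(row)
    return pd.DataFrame(rows)


def regulatory_range_edge(
    p: ParameterSet,
    variant: ModelVariant,
    GLC: float = 15.0,
    threshold: float = 0.1,
    bracket: tuple[float, float] = (0.01, 100.0),
    n_grid: int = 60,
    refine: int = 25,
) -> float:
    """Lowest acetate concentration where any |partitioned response| reaches
    the regulatory threshold (default 0.1).

    A logarithmic grid locates the first crossing, then bisection refines
    it.  Returns NaN when the threshold is never reached on the bracket.
    """
    def max_abs_viR(ace):
        viR = partitioned_responses(p, variant, GLC, ace)
        return max(abs(v) for v in viR.values())

    grid = np.logspace(np.log10(bracket[0]), np.log10(bracket[1]), n_grid)
    vals = [max_abs_viR(a) for a in grid]
    idx = next((i for i, v in enumerate(vals) if v >= threshold), None)
    if idx is None:
        return np.nan
    if idx == 0:
        return grid[0]
    lo, hi = grid[idx - 1], grid[idx]
    for _ in range(refine):
        mid = np.sqrt(lo * hi)
        if max_abs_viR(mid) >= threshold:
            hi = mid
        else:
            lo = mid
    return float(np.sqrt(lo * hi))
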