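"""Integration and steady-state protocols.

Covers the four experiment types the model is confronted with: batch growth
(including 13C-labelled cultures), glucose-limited chemostat runs over a
dilution-rate scan, steady-state scans over clamped extracellular acetate,
and instantaneous acetate-pulse experiments.

Steady states for control analysis clamp the boundary species (glucose,
extracellular acetate, biomass) and solve only the three intracellular
balances: a growing batch culture has no full steady state, but the
intracellular pools are intensive and reach a quasi-steady state within
seconds of culture time.  All reported fluxes are intensive (per gDW when
multiplied by the specific cell volume), so they do not depend on the
clamped biomass.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from ._kernels import pack_params, rhs_labelled, rhs_unlabelled, rates_from_packed
from .isotopes import LABELLED_ORDER, LabelledState
from .model import ModelVariant, State, FluxVector, all_rates
from .parameters import ParameterSet

__all__ = [
    "TrajectorySet",
    "SteadyStateResult",
    "IntegrationError",
    "integrate",
    "solve_intracellular_steady_state",
    "steady_state_fluxes",
    "acetate_scan",
    "chemostat_scan",
    "pulse_experiment",
    "find_flux_reversal_threshold",
    "run_protocol",
]

STATE_ORDER = ("GLC", "ACE_env", "X", "ACCOA", "ACP", "ACE_cell")

#: default integrator tolerances (mM-scale state)
RTOL = 1e-8
ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time: {last_time:.4g} hr)")
        self.last_time = last_time


@dataclass
class TrajectorySet:
    """Stored time courses of states and fluxes.

    ``states`` has one row per output time (column ``time`` plus one column
    per state variable; labelled runs carry the pool pairs).  ``fluxes``
    holds every reaction rate recomputed from the stored states, so the two
    frames are consistent by construction.
    """

    states: pd.DataFrame
    fluxes: pd.DataFrame
    variant: ModelVariant
    params_hash: str
    initial: dict = field(default_factory=dict)
    labelled: bool = False

    @property
    def time(self) -> np.ndarray:
        return self.states["time"].to_numpy()

    def totals(self) -> pd.DataFrame:
        """Total-pool view (labelled pool pairs summed)."""
        df = self.states
        if not self.labelled:
            return df[["time", *STATE_ORDER]]
        out = pd.DataFrame({"time": df["time"]})
        out["GLC"] = df["GLC0"] + df["GLC1"]
        out["ACE_env"] = df["ACE_env0"] + df["ACE_env1"]
        out["X"] = df["X"]
        out["ACCOA"] = df["ACCOA0"] + df["ACCOA1"]
        out["ACP"] = df["ACP0"] + df["ACP1"]
        out["ACE_cell"] = df["ACE_cell0"] + df["ACE_cell1"]
        return out

    def observable(self, name: str) -> np.ndarray:
        """Model observables: biomass, glucose, acetate_total, acetate_enrichment."""
        tot = self.totals()
        if name == "biomass":
            return tot["X"].to_numpy()
        if name == "glucose":
            return tot["GLC"].to_numpy()
        if name == "acetate_total":
            return tot["ACE_env"].to_numpy()
        if name == "acetate_enrichment":
            if not self.labelled:
                raise ValueError("enrichment requires a labelled trajectory")
            t = self.states["ACE_env0"] + self.states["ACE_env1"]
            with np.errstate(invalid="ignore", divide="ignore"):
                e = self.states["ACE_env1"] / t.where(t > 0)
            return e.to_numpy()
        raise KeyError(name)

    def final_state(self) -> np.ndarray:
        return self.states.iloc[-1].drop("time").to_numpy(dtype=float)

    def to_csv(self, states_path, fluxes_path=None) -> None:
        tidy = self.states.melt(id_vars="time", var_name="species", value_name="value")
        tidy.to_csv(states_path, index=False)
        if fluxes_path is not None:
            self.fluxes.to_csv(fluxes_path, index=False)


def _params_hash(p: ParameterSet) -> str:
    return hashlib.sha1(json.dumps(p.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _flux_frame(totals: pd.DataFrame, p: ParameterSet, variant: ModelVariant) -> pd.DataFrame:
    rows = []
    for _, r in totals.iterrows():
        st = State(r["GLC"], r["ACE_env"], r["X"], r["ACCOA"], r["ACP"], r["ACE_cell"])
        v = all_rates(st, p, variant)
        rows.append(
            {
                "time": r["time"],
                "glycolysis": v.glycolysis,
                "tca": v.tca,
                "pta": v.pta,
                "acka": v.acka,
                "exchange": v.exchange,
                "growth": v.growth,
                "pta_fwd": v.pta_fwd, "pta_rev": v.pta_rev,
                "acka_fwd": v.acka_fwd, "acka_rev": v.acka_rev,
                "exchange_fwd": v.exchange_fwd, "exchange_rev": v.exchange_rev,
            }
        )
    return pd.DataFrame(rows)


def integrate(
    initial: State | LabelledState,
    p: ParameterSet,
    variant: ModelVariant,
    t_end: float,
    output_grid: np.ndarray | float | None = 0.01,
    rtol: float = RTOL,
    atol: float = ATOL,
    with_fluxes: bool = True,
) -> TrajectorySet:
    """Integrate the model (labelled or not) from ``initial`` to ``t_end``.

    ``output_grid`` is either an explicit array of output times, a grid
    spacing in hours (default 0.01), or None for solver-chosen points.
    Deterministic for fixed inputs.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    labelled = isinstance(initial, LabelledState)
    y0 = initial.to_array()
    q = pack_params(p, variant)
    D = variant.dilution_rate if variant.mode == "chemostat" else 0.0
    vfeed = variant.feed_rate if variant.mode == "chemostat" else 0.0
    if isinstance(output_grid, (int, float)):
        t_eval = np.arange(0.0, t_end + output_grid / 2, output_grid)
    else:
        t_eval = output_grid
    kernel = rhs_labelled if labelled else rhs_unlabelled
    sol = solve_ivp(
        kernel, (0.0, t_end), y0, args=(q, D, vfeed),
        method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(sol.message, sol.t[-1] if len(sol.t) else 0.0)
    cols = LABELLED_ORDER if labelled else STATE_ORDER
    states = pd.DataFrame(np.clip(sol.y.T, 0.0, None), columns=list(cols))
    states.insert(0, "time", sol.t)
    traj = TrajectorySet(
        states=states,
        fluxes=pd.DataFrame(),
        variant=variant,
        params_hash=_params_hash(p),
        initial={k: float(v) for k, v in zip(cols, y0)},
        labelled=labelled,
    )
    if with_fluxes:
        traj.fluxes = _flux_frame(traj.totals(), p, variant)
    return traj


# ---------------------------------------------------------------------------
# clamped intracellular steady state
# ---------------------------------------------------------------------------

@dataclass
class SteadyStateResult:
    """Intracellular steady state at clamped boundary conditions."""

    GLC: float
    ACE_env: float
    X: float
    pools: State
    fluxes: FluxVector
    residual: float
    converged: bool
    dilution_rate: float = 0.0

    def flux(self, name: str) -> float:
        return self.fluxes[name]


def _intra_rhs(q, GLC, ACE):
    def f(y):
        AC, AP, ACl = max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0)
        vgly, vtca, ptf, ptr, akf, akr, exf, exr = rates_from_packed(GLC, ACE, AC, AP, ACl, q)
        return np.array(
            [
                q[30] * vgly - vtca - (ptf - ptr),
                (ptf - ptr) - (akf - akr),
                (akf - akr) - (exf - exr),
            ]
        )
    return f


def solve_intracellular_steady_state(
    GLC: float,
    ACE_env: float,
    p: ParameterSet,
    variant: ModelVariant,
    X: float = 1.0,
    rel_tol: float = 1e-10,
) -> SteadyStateResult:
    """Roots of the three intracellular balances with GLC, ACE_env, X clamped.

    A short relaxation integration provides the basin, a damped root-finder
    polishes it.  The relative residual (balance norm over flux norm) must
    fall below ``rel_tol``.
    """
    if GLC < 0 or ACE_env < 0:
        raise ValueError("clamped concentrations must be >= 0")
    q = pack_params(p, variant)
    bal = _intra_rhs(q, GLC, ACE_env)
    y0 = np.array([0.1, 0.01, max(ACE_env, 0.01)])
    relax = solve_ivp(
        lambda t, y: bal(y), (0.0, 200.0), y0, method="LSODA", rtol=1e-10, atol=1e-12
    )
    y_relax = np.maximum(relax.y[:, -1], 0.0)
    sol = root(bal, y_relax, method="hybr", tol=1e-14)
    pools_arr = np.maximum(sol.x, 0.0)
    st = State(GLC, ACE_env, X, *pools_arr)
    v = all_rates(st, p, variant)
    vnorm = max(abs(v.glycolysis), abs(v.tca), abs(v.pta), abs(v.acka), abs(v.exchange), 1.0)
    res = float(np.max(np.abs(bal(pools_arr)))) / vnorm
    converged = res <= rel_tol and np.all(pools_arr >= 0)
    if not converged and GLC == 0 and ACE_env == 0:
        converged = res <= rel_tol  # all-zero flux solution at the boundary
    if not converged:
        raise RuntimeError(
            f"no positive intracellular steady state at GLC={GLC}, ACE={ACE_env} "
            f"(relative residual {res:.2e}); relaxation endpoint {y_relax}"
        )
    return SteadyStateResult(
        GLC=GLC, ACE_env=ACE_env, X=X, pools=st, fluxes=v, residual=res, converged=True
    )


def steady_state_fluxes(
    GLC: float, ACE_env: float, p: ParameterSet, variant: ModelVariant
) -> FluxVector:
    """Convenience: fluxes at the clamped intracellular steady state."""
    return solve_intracellular_steady_state(GLC, ACE_env, p, variant).fluxes


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def acetate_scan(
    p: ParameterSet,
    variant: ModelVariant,
    ace_grid: np.ndarray,
    GLC: float = 15.0,
    X: float = 1.0,
) -> pd.DataFrame:
    """Steady-state fluxes over a grid of clamped acetate concentrations.

    Fluxes are reported per gDW (mmol/gDW/hr): cell-basis rate x cell
    volume.  Growth rate in /hr.
    """
    rows = []
    for ace in np.asarray(ace_grid, dtype=float):
        ss = solve_intracellular_steady_state(GLC, ace, p, variant, X=X)
        rows.append(
            {
                "ACE_env": ace,
                "acetate_flux": ss.fluxes.exchange * p.Vcell,
                "glucose_flux": ss.fluxes.glycolysis * p.Vcell,
                "growth_rate": ss.fluxes.growth,
            }
        )
    return pd.DataFrame(rows)


def find_flux_reversal_threshold(
    p: ParameterSet,
    variant: ModelVariant,
    GLC: float = 15.0,
    bracket: tuple[float, float] = (1e-4, 1e3),
    xtol: float = 1e-6,
) -> float:
    """Acetate concentration at which the steady-state acetate flux reverses.

    Bisection on the clamped-steady-state net exchange flux.  Returns NaN
    when the flux does not change sign on the bracket (no reversal — the
    expected outcome for variants without both inhibitions or with a
    disabled exchange).
    """
    def f(ace):
        return solve_intracellular_steady_state(GLC, ace, p, variant).fluxes.exchange

    lo, hi = bracket
    try:
        flo, fhi = f(lo), f(hi)
    except RuntimeError:
        return np.nan
    if flo == 0.0:
        return lo
    if np.sign(flo) == np.sign(fhi):
        return np.nan
    return brentq(f, lo, hi, xtol=xtol)


def chemostat_scan(
    p: ParameterSet,
    variant: ModelVariant,
    D_list,
    feed_glucose: float = 15.0,
) -> pd.DataFrame:
    """Steady-state fluxes in a glucose-limited chemostat over dilution rates.

    The feed is parameterised as ``vfeed = D * feed_glucose``.  Rows where
    the culture washes out (biomass below 1e-6 gDW/L) are flagged rather
    than raised.  Fluxes per gDW; at a regular steady state the growth rate
    equals D.
    """
    rows = []
    for D in D_list:
        var = variant.with_chemostat(D, feed_glucose)
        q = pack_params(p, var)

        def fullbal(y):
            return rhs_unlabelled(0.0, y, q, D, var.feed_rate)

        y0 = np.array([feed_glucose * 0.1, 0.01, 0.1, 0.1, 0.01, 0.01])
        relax = solve_ivp(
            lambda t, y: fullbal(y), (0.0, 2000.0), y0,
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        sol = root(fullbal, np.maximum(relax.y[:, -1], 0.0), method="hybr", tol=1e-13)
        y = np.maximum(sol.x, 0.0)
        st = State.from_array(y)
        washout = st.X < 1e-6
        v = all_rates(st, p, variant)
        rows.append(
            {
                "D": D,
                "washout": washout,
                "X": st.X,
                "GLC": st.GLC,
                "ACE_env": st.ACE_env,
                "glucose_flux": np.nan if washout else v.glycolysis * p.Vcell,
                "acetate_flux": np.nan if washout else v.exchange * p.Vcell,
                "growth_rate": np.nan if washout else v.growth,
            }
        )
    return pd.DataFrame(rows)


def pulse_experiment(
    p: ParameterSet,
    variant: ModelVariant,
    pre_culture: State | LabelledState,
    pulse_ace: float,
    t_pulse: float,
    t_end: float,
    output_grid: np.ndarray | float | None = 0.01,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> TrajectorySet:
    """Batch culture with an instantaneous acetate spike at ``t_pulse``.

    ``pulse_ace`` mM of (unlabelled) acetate is added to the environment at
    the pulse time; a water pulse is ``pulse_ace = 0`` and reproduces the
    un-pulsed control exactly.  An explicit ``output_grid`` array is split
    at the pulse time so requested times are hit exactly.
    """
    if not 0 < t_pulse < t_end:
        raise ValueError("need 0 < t_pulse < t_end")
    if isinstance(output_grid, np.ndarray):
        grid = np.asarray(output_grid, dtype=float)
        grid1 = np.unique(np.concatenate([grid[grid <= t_pulse], [0.0, t_pulse]]))
        grid2 = np.unique(np.concatenate([grid[grid > t_pulse] - t_pulse, [0.0]]))
    else:
        grid1 = grid2 = output_grid
    first = integrate(
        pre_culture, p, variant, t_pulse, output_grid=grid1, rtol=rtol, atol=atol,
        with_fluxes=False,
    )
    y_mid = first.final_state()
    labelled = first.labelled
    if labelled:
        mid = LabelledState.from_array(y_mid)
        mid.ACE_env0 += pulse_ace
    else:
        mid = State.from_array(y_mid)
        mid.ACE_env += pulse_ace
    second = integrate(
        mid, p, variant, t_end - t_pulse, output_grid=grid2, rtol=rtol, atol=atol,
        with_fluxes=False,
    )
    s2 = second.states.copy()
    s2["time"] += t_pulse
    states = pd.concat([first.states.iloc[:-1], s2], ignore_index=True)
    traj = TrajectorySet(
        states=states,
        fluxes=pd.DataFrame(),
        variant=variant,
        params_hash=first.params_hash,
        initial=dict(first.initial, pulse_ace=pulse_ace, t_pulse=t_pulse),
        labelled=labelled,
    )
    traj.fluxes = _flux_frame(traj.totals(), p, variant)
    return traj


# ---------------------------------------------------------------------------
# protocol configs
# ---------------------------------------------------------------------------

def run_protocol(config, p: ParameterSet | None = None) -> TrajectorySet:
    """Run a simulation described by a JSON/YAML protocol config.

    ``config`` is a mapping (or a path to a .json/.yaml/.yml file) with::

        variant: 1-4
        initial_conditions: {GLC: mM, ACE_env: mM, X: gDW/L,
                             glc_enrichment: optional, labelled: optional}
        t_end: hours
        output_grid: spacing in hours (optional, default 0.01)
        pulses: [{time: hr, species: ACE_env, amount: mM}]   # optional, one
        chemostat: {D: /hr, feed: mM}                        # optional

    Labelled initial conditions produce a labelled trajectory.
    """
    import json as _json
    from pathlib import Path as _Path

    import yaml

    from .isotopes import LabelledState
    from .model import State, model_variant

    if not isinstance(config, dict):
        text = _Path(config).read_text()
        if str(config).endswith((".yaml", ".yml")):
            config = yaml.safe_load(text)
        else:
            config = _json.loads(text)
    p = p or ParameterSet()
    variant = model_variant(int(config.get("variant", 4)))
    if "chemostat" in config:
        chem = config["chemostat"]
        variant = variant.with_chemostat(float(chem["D"]), float(chem["feed"]))
    ic = dict(config.get("initial_conditions", {}))
    labelled = bool(ic.pop("labelled", False)) or "glc_enrichment" in ic
    glc_enr = float(ic.pop("glc_enrichment", 0.0))
    state = State(
        GLC=float(ic.get("GLC", 15.0)),
        ACE_env=float(ic.get("ACE_env", 0.0)),
        X=float(ic.get("X", 0.02)),
        ACCOA=float(ic.get("ACCOA", 1e-4)),
        ACP=float(ic.get("ACP", 1e-4)),
        ACE_cell=float(ic.get("ACE_cell", 1e-4)),
    )
    initial = (
        LabelledState.from_totals(state, glc_enrichment=glc_enr) if labelled else state
    )
    t_end = float(config["t_end"])
    grid = float(config.get("output_grid", 0.01))
    pulses = config.get("pulses", [])
    if len(pulses) > 1:
        raise ValueError("only a single pulse per protocol is supported")
    if pulses:
        pulse = pulses[0]
        if pulse.get("species", "ACE_env") != "ACE_env":
            raise ValueError("only acetate (ACE_env) pulses are supported")
        return pulse_experiment(
            p, variant, initial, float(pulse["amount"]), float(pulse["time"]),
            t_end, output_grid=grid,
        )
    return integrate(initial, p, variant, t_end, output_grid=grid)
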