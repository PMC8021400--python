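"""Parameter estimation, goodness of fit and model comparison.

The free parameters (10 for the doubly inhibited variant: the five Vmax
values, the TCA Km for acetyl-CoA, the two inhibition constants, the
exchange Km and the biomass yield) are estimated by minimising the
variance-weighted sum of squared residuals

    f(p) = sum_i ((x_i - y_i(p)) / sigma_i)^2

over 13C-labelled batch time courses (biomass, glucose, total extracellular
acetate, acetate enrichment), using a seeded particle-swarm search in log10
parameter space with an optional trust-region polish.  A fitted model is
accepted when its SSR falls below the chi-square quantile with n - p degrees
of freedom (alpha = 0.95): an SSR compatible with the measurement noise.
Because the four variants are nested, the attainable SSR can only decrease
as inhibition terms are added; comparing accepted/rejected status across
variants is the model selection of interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .isotopes import LabelledState
from .model import ModelVariant, State, model_variant
from .parameters import ParameterSet
from .pso import particle_swarm_minimize
from .simulate import (
    IntegrationError,
    TrajectorySet,
    acetate_scan,
    chemostat_scan,
    integrate,
    pulse_experiment,
)

__all__ = [
    "ObservationSet",
    "FitConfig",
    "FitResult",
    "free_parameter_paths",
    "simulate_experiment",
    "objective",
    "fit",
    "chi2_test",
    "compare_models",
    "validation_ssr",
]

OBSERVABLES = ("biomass", "glucose", "acetate_total", "acetate_enrichment")

#: objective value returned when a trial parameterisation cannot be simulated
PENALTY = 1e12

#: initial intracellular pool concentration (mM); dilute pools equilibrate to
#: their quasi-steady state within the first seconds of simulated culture
DILUTE_POOL = 1e-4


class ObservationSet:
    """Measured observables plus the designs needed to re-simulate them.

    ``records`` columns: experiment, time, observable, value, sd.  For
    steady-state experiment kinds the ``time`` column holds the scanned
    condition (dilution rate or acetate concentration).  ``designs`` maps
    experiment id to a plain dict with keys ``kind`` ('batch', 'pulse',
    'chemostat_scan' or 'acetate_scan') and the initial/protocol values.
    """

    def __init__(self, records: pd.DataFrame, designs: dict[str, dict]):
        required = {"experiment", "time", "observable", "value", "sd"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        if (records["sd"] <= 0).any():
            raise ValueError("all standard deviations must be > 0")
        enr = records.loc[records["observable"] == "acetate_enrichment", "value"]
        if ((enr < 0) | (enr > 1)).any():
            raise ValueError("enrichment observations must lie in [0, 1]")
        unknown = set(records["experiment"]) - set(designs)
        if unknown:
            raise ValueError(f"experiments without a design: {sorted(unknown)}")
        self.records = records.reset_index(drop=True)
        self.designs = designs

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def experiments(self) -> list[str]:
        return list(self.designs)

    def subset(self, observables=None, experiments=None) -> "ObservationSet":
        rec = self.records
        if observables is not None:
            rec = rec[rec["observable"].isin(observables)]
        if experiments is not None:
            rec = rec[rec["experiment"].isin(experiments)]
        designs = {k: v for k, v in self.designs.items() if k in set(rec["experiment"])}
        return ObservationSet(rec.copy(), designs)

    def to_csv(self, records_path: str | Path, designs_path: str | Path | None = None):
        self.records.to_csv(records_path, index=False)
        if designs_path is not None:
            Path(designs_path).write_text(json.dumps(self.designs, indent=2) + "\n")

    @classmethod
    def from_csv(cls, records_path: str | Path, designs_path: str | Path):
        records = pd.read_csv(records_path)
        designs = json.loads(Path(designs_path).read_text())
        return cls(records, designs)


def free_parameter_paths(variant: ModelVariant) -> list[str]:
    """Dotted paths of the parameters estimated for a variant (8-10)."""
    paths = [
        "acka.Vmax",
        "pta.Vmax",
        "glycolysis.Vmax",
        "tca.Km_ACCOA",
        "tca.Vmax",
        "Y",
        "exchange.Vmax",
        "exchange.Km_ACE",
    ]
    if variant.inhibit_glycolysis:
        paths.insert(3, "glycolysis.Ki_ACE")
    if variant.inhibit_tca:
        paths.insert(-3, "tca.Ki_ACE")
    return paths


# ---------------------------------------------------------------------------
# forward simulation of one experiment
# ---------------------------------------------------------------------------

def _initial_labelled_state(design: dict) -> LabelledState:
    st = State(
        GLC=design.get("GLC", 15.0),
        ACE_env=design.get("ACE_env", 0.0),
        X=design["X0"],
        ACCOA=DILUTE_POOL,
        ACP=DILUTE_POOL,
        ACE_cell=DILUTE_POOL,
    )
    return LabelledState.from_totals(
        st,
        glc_enrichment=design.get("glc_enrichment", 1.0),
        ace_env_enrichment=design.get("ace_enrichment", 0.0),
    )


def simulate_experiment(
    p: ParameterSet,
    variant: ModelVariant,
    design: dict,
    times: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Simulate one experiment and return observables at the requested times.

    Returns a frame indexed like ``times`` with one column per observable
    applicable to the experiment kind.
    """
    kind = design.get("kind", "batch")
    times = np.asarray(times, dtype=float)
    if kind in ("batch", "pulse"):
        init = _initial_labelled_state(design)
        t_end = float(times.max())
        if kind == "pulse":
            traj = pulse_experiment(
                p, variant, init, design["pulse_ace"], design["t_pulse"], t_end,
                output_grid=times, rtol=rtol, atol=atol,
            )
            out = {}
            for name in OBSERVABLES:
                out[name] = np.interp(times, traj.time, traj.observable(name))
            return pd.DataFrame(out, index=times)
        grid = np.unique(np.concatenate([[0.0], times]))
        traj = integrate(
            init, p, variant, t_end if t_end > 0 else 1e-3,
            output_grid=grid, rtol=rtol, atol=atol, with_fluxes=False,
        )
        sel = np.searchsorted(traj.time, times)
        out = {name: traj.observable(name)[sel] for name in OBSERVABLES}
        return pd.DataFrame(out, index=times)
    if kind == "chemostat_scan":
        tab = chemostat_scan(
            p, model_variant(design["variant_code"]) if "variant_code" in design else variant,
            D_list=times, feed_glucose=design.get("feed_glucose", 15.0),
        )
        return tab.set_index(np.asarray(times))[["glucose_flux", "acetate_flux", "growth_rate"]]
    if kind == "acetate_scan":
        tab = acetate_scan(
            p, variant, ace_grid=times,
            GLC=design.get("GLC", 15.0), X=design.get("X0", 1.0),
        )
        return tab.set_index(np.asarray(times))[["glucose_flux", "acetate_flux", "growth_rate"]]
    raise ValueError(f"unknown experiment kind {kind!r}")


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _batch_observables(
    p: ParameterSet,
    variant: ModelVariant,
    design: dict,
    times: np.ndarray,
    rtol: float,
    atol: float = 1e-9,
) -> dict[str, np.ndarray]:
    """Hot-path batch simulation: observables without trajectory plumbing."""
    from scipy.integrate import solve_ivp

    from ._kernels import pack_params, rhs_labelled

    y0 = _initial_labelled_state(design).to_array()
    q = pack_params(p, variant)
    grid = np.unique(np.concatenate([[0.0], times]))
    sol = solve_ivp(
        rhs_labelled, (0.0, float(grid[-1]) or 1e-3), y0, args=(q, 0.0, 0.0),
        method="LSODA", rtol=rtol, atol=atol, t_eval=grid,
    )
    if not sol.success:
        raise IntegrationError(sol.message, sol.t[-1] if len(sol.t) else 0.0)
    y = np.clip(sol.y, 0.0, None)
    sel = np.searchsorted(sol.t, times)
    ace_tot = y[2] + y[3]
    with np.errstate(invalid="ignore", divide="ignore"):
        enr = np.where(ace_tot > 0, y[3] / ace_tot, 0.0)
    return {
        "biomass": y[4][sel],
        "glucose": (y[0] + y[1])[sel],
        "acetate_total": ace_tot[sel],
        "acetate_enrichment": enr[sel],
    }


def _grouped_records(data: ObservationSet):
    """Per-experiment (times, time_index, observable, value, sd) arrays, cached."""
    cached = getattr(data, "_groups", None)
    if cached is not None:
        return cached
    groups = []
    for exp_id in data.experiments():
        rec = data.records[data.records["experiment"] == exp_id]
        times = np.sort(rec["time"].unique())
        t_idx = np.searchsorted(times, rec["time"].to_numpy())
        groups.append(
            (
                exp_id,
                times,
                t_idx,
                rec["observable"].to_numpy(),
                rec["value"].to_numpy(dtype=float),
                rec["sd"].to_numpy(dtype=float),
            )
        )
    data._groups = groups
    return groups


def _residuals(
    p: ParameterSet,
    data: ObservationSet,
    variant: ModelVariant,
    rtol: float = 1e-6,
) -> np.ndarray:
    """Weighted residual vector (x - y)/sigma across all experiments."""
    res = []
    for exp_id, times, t_idx, obs_names, values, sds in _grouped_records(data):
        design = data.designs[exp_id]
        if design.get("kind", "batch") == "batch":
            sim = _batch_observables(p, variant, design, times, rtol=rtol)
            y = np.empty(len(values))
            for name in np.unique(obs_names):
                mask = obs_names == name
                y[mask] = sim[name][t_idx[mask]]
        else:
            frame = simulate_experiment(p, variant, design, times, rtol=rtol)
            y = np.array(
                [frame.iloc[i][name] for i, name in zip(t_idx, obs_names)]
            )
        y = np.nan_to_num(y, nan=0.0)  # empty-pool enrichment counts as no label
        res.append((values - y) / sds)
    return np.concatenate(res)


def objective(
    p: ParameterSet | dict,
    data: ObservationSet,
    variant: ModelVariant,
    p_fixed: ParameterSet | None = None,
    rtol: float = 1e-6,
) -> float:
    """Weighted SSR of a parameterisation against the data.

    ``p`` is either a full :class:`ParameterSet` or a dict of dotted-path
    updates applied to ``p_fixed``.  Integration failures return a large
    penalty instead of raising, so global optimisers can probe bad regions.
    """
    if isinstance(p, dict):
        if p_fixed is None:
            raise ValueError("dict parameters require p_fixed")
        try:
            p = p_fixed.with_updates(p)
        except ValueError:
            return PENALTY
    try:
        r = _residuals(p, data, variant, rtol=rtol)
    except (IntegrationError, RuntimeError, ValueError):
        return PENALTY
    ssr = float(np.dot(r, r))
    return ssr if np.isfinite(ssr) else PENALTY


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Optimiser settings.

    ``bounds_decades`` sets the log10 half-width of the search box around
    the reference values.  The study-scale preset is 2000 iterations with a
    swarm of 50; scans and tests use reduced budgets.
    """

    seed: int = 0
    n_particles: int = 50
    n_iter: int = 2000
    bounds_decades: float = 2.0
    patience: int | None = 30
    ftol: float = 1e-4
    polish: bool = True
    rtol: float = 1e-6
    start_from_reference: bool = False
    #: 'pso' runs the global search; 'polish' refits locally from a randomly
    #: jittered start near the reference values (the parametric-bootstrap
    #: shortcut used for reduced-budget Monte-Carlo replicates)
    optimiser: str = "pso"
    jitter_decades: float = 0.3


@dataclass
class FitResult:
    variant_code: int
    free_paths: list[str]
    params: dict[str, float]
    ssr: float
    n_obs: int
    n_free: int
    threshold: float
    accepted: bool
    seed: int
    bounds: dict[str, tuple[float, float]]
    n_eval: int = 0
    trace: list[float] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def parameter_set(self, p_fixed: ParameterSet) -> ParameterSet:
        return p_fixed.with_updates(self.params)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["trace"] = d["trace"][:: max(1, len(d["trace"]) // 200)]
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def chi2_test(ssr: float, n: int, p_free: int, alpha: float = 0.95):
    """Chi-square acceptance threshold and verdict for a fitted SSR."""
    dof = n - p_free
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom: n={n}, p={p_free}")
    threshold = float(stats.chi2.ppf(alpha, dof))
    return threshold, bool(ssr <= threshold)


def _variant_code(variant: ModelVariant) -> int:
    return {(False, False): 1, (True, False): 2, (False, True): 3, (True, True): 4}[
        (variant.inhibit_glycolysis, variant.inhibit_tca)
    ]


def fit(
    data: ObservationSet,
    variant: ModelVariant,
    config: FitConfig | None = None,
    p_fixed: ParameterSet | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Estimate the free parameters of one variant against ``data``.

    PSO in log10 space within ``bounds`` (default: ``bounds_decades`` around
    the reference parameter set), then an optional bounded trust-region
    polish of the weighted residuals.  Reproducible for a fixed seed.
    """
    config = config or FitConfig()
    p_fixed = p_fixed or ParameterSet()
    paths = free_parameter_paths(variant)
    ref = np.array([p_fixed.get_path(path) for path in paths])
    if bounds is None:
        half = config.bounds_decades
        bounds = {
            path: (10 ** (np.log10(r) - half), 10 ** (np.log10(r) + half))
            for path, r in zip(paths, ref)
        }
    log_bounds = [tuple(np.log10(bounds[path])) for path in paths]

    def unpack(theta):
        return {path: 10.0 ** t for path, t in zip(paths, theta)}

    def f(theta):
        return objective(unpack(theta), data, variant, p_fixed=p_fixed, rtol=config.rtol)

    lo_arr = np.array([b[0] for b in log_bounds])
    hi_arr = np.array([b[1] for b in log_bounds])
    if config.optimiser == "polish":
        rng = np.random.default_rng(config.seed)
        theta = np.clip(
            np.log10(ref) + rng.uniform(-config.jitter_decades, config.jitter_decades,
                                        len(ref)),
            lo_arr, hi_arr,
        )
        ssr = f(theta)
        n_eval = 1
        trace = [ssr]
        do_polish = True
    else:
        x0 = np.log10(ref) if config.start_from_reference else None
        res = particle_swarm_minimize(
            f, log_bounds, seed=config.seed,
            n_particles=config.n_particles, n_iter=config.n_iter,
            ftol=config.ftol, patience=config.patience, x0=x0,
        )
        if res.fun >= PENALTY:
            raise RuntimeError(
                "every swarm particle hit the infeasibility penalty; widen the bounds"
            )
        theta, ssr, n_eval, trace = res.x, res.fun, res.n_eval, res.trace
        do_polish = config.polish

    if do_polish:
        def resid(th):
            try:
                r = _residuals(
                    p_fixed.with_updates(unpack(th)), data, variant, rtol=config.rtol
                )
            except (IntegrationError, RuntimeError, ValueError):
                return np.full(data.n, 1e6)
            return np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6)

        ls = least_squares(
            resid, np.clip(theta, lo_arr, hi_arr), bounds=(lo_arr, hi_arr),
            diff_step=1e-4, xtol=1e-10, ftol=1e-10, max_nfev=60 * len(theta),
        )
        n_eval += ls.nfev * (len(theta) + 1)
        if 2 * ls.cost < ssr:
            theta, ssr = ls.x, 2 * float(ls.cost)

    threshold, accepted = chi2_test(ssr, data.n, len(paths))
    return FitResult(
        variant_code=_variant_code(variant),
        free_paths=paths,
        params=unpack(theta),
        ssr=float(ssr),
        n_obs=data.n,
        n_free=len(paths),
        threshold=threshold,
        accepted=accepted,
        seed=config.seed,
        bounds={k: (float(v[0]), float(v[1])) for k, v in bounds.items()},
        n_eval=n_eval,
        trace=trace,
        config={
            "n_particles": config.n_particles,
            "n_iter": config.n_iter,
            "bounds_decades": config.bounds_decades,
            "polish": config.polish,
            "rtol": config.rtol,
        },
    )


def compare_models(
    data: ObservationSet,
    config: FitConfig | None = None,
    p_fixed: ParameterSet | None = None,
    codes: tuple[int, ...] = (1, 2, 3, 4),
) -> tuple[pd.DataFrame, dict[int, FitResult]]:
    """Fit every variant on identical data and seed; rank by SSR.

    Returns the ranking table (variant, ssr, threshold, accepted, n_free)
    and the per-variant fit results.
    """
    results: dict[int, FitResult] = {}
    for code in codes:
        results[code] = fit(data, model_variant(code), config=config, p_fixed=p_fixed)
    table = pd.DataFrame(
        [
            {
                "variant": code,
                "ssr": r.ssr,
                "n_free": r.n_free,
                "threshold": r.threshold,
                "accepted": r.accepted,
            }
            for code, r in results.items()
        ]
    ).sort_values("ssr", ignore_index=True)
    return table, results


def validation_ssr(
    fit_result: FitResult | ParameterSet,
    validation: ObservationSet,
    variant: ModelVariant,
    p_fixed: ParameterSet | None = None,
) -> float:
    """Weighted SSR of an already-fitted model on held-out data (no refit)."""
    if isinstance(fit_result, FitResult):
        p = fit_result.parameter_set(p_fixed or ParameterSet())
    else:
        p = fit_result
    return objective(p, validation, variant)
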