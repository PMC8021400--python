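"""Synthetic calibration and validation data.

Emulates the study design the model is calibrated on: three batch cultures
on 15 mM uniformly 13C-labelled glucose plus 1, 10 or 30 mM unlabelled
acetate, observed for biomass, glucose, total extracellular acetate and the
13C enrichment of acetate (~13 sampling times each, ~150 data points in
total), with truncated-Gaussian measurement noise.  Validation data emulate
the held-out perturbation experiments: glucose-limited chemostat steady
states over dilution rates 0.1-0.5 /hr, a steady-state acetate-concentration
scan, and acetate-pulse time courses (30 mM pulse and water control).

Noise magnitudes are design choices recorded in the design metadata:
relative 2 % on biomass, 3 % on concentrations and fluxes (with small
absolute floors so exhausted pools are not weighted infinitely), absolute
0.02 on enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calibrate import ObservationSet, simulate_experiment
from .model import ModelVariant
from .parameters import ParameterSet

__all__ = [
    "ExperimentDesign",
    "default_calibration_designs",
    "generate_calibration_set",
    "generate_validation_set",
    "NOISE_DEFAULTS",
]

#: (mode, scale, floor) per observable; mode 'rel' scales the value
NOISE_DEFAULTS = {
    "biomass": ("rel", 0.02, 0.002),
    "glucose": ("rel", 0.03, 0.05),
    "acetate_total": ("rel", 0.03, 0.05),
    "acetate_enrichment": ("abs", 0.02, 0.02),
    "glucose_flux": ("rel", 0.03, 0.05),
    "acetate_flux": ("rel", 0.03, 0.05),
    "growth_rate": ("rel", 0.03, 0.01),
}

#: truncation bounds per observable
_BOUNDS = {
    "acetate_enrichment": (0.0, 1.0),
    "acetate_flux": (-np.inf, np.inf),  # a flux may legitimately be negative
}


@dataclass
class ExperimentDesign:
    """One batch labelling experiment: initial state, schedule and noise."""

    name: str
    GLC: float = 15.0
    glc_enrichment: float = 1.0
    ACE_env: float = 10.0
    X0: float = 0.02
    times: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 8.0, 13))
    noise: dict = field(default_factory=lambda: dict(NOISE_DEFAULTS))
    kind: str = "batch"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if (self.times < 0).any():
            raise ValueError("sampling times must be >= 0")
        for mode, scale, floor in self.noise.values():
            if scale <= 0 or floor <= 0:
                raise ValueError("noise scales and floors must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["times"] = self.times.tolist()
        return d


def default_calibration_designs() -> list[ExperimentDesign]:
    """The three labelling experiments (1, 10, 30 mM unlabelled acetate)."""
    return [
        ExperimentDesign(name=f"ace_{int(a)}mM", ACE_env=float(a)) for a in (1, 10, 30)
    ]


def _sd_for(observable: str, values: np.ndarray, noise: dict) -> np.ndarray:
    mode, scale, floor = noise[observable]
    if mode == "rel":
        return np.maximum(np.abs(values) * scale, floor)
    return np.full_like(values, scale)


def _truncated_noise(values, sds, observable, rng, max_tries: int = 20):
    """Gaussian noise, resampled into the observable's valid range.

    Samples violating the bounds are redrawn; after ``max_tries`` the value
    is clipped (the tail mass involved is negligible at the default noise
    levels).
    """
    lo, hi = _BOUNDS.get(observable, (0.0, np.inf))
    out = values + rng.normal(0.0, sds)
    for _ in range(max_tries):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = values[bad] + rng.normal(0.0, sds[bad])
    return np.clip(out, lo, hi)


def generate_calibration_set(
    p_true: ParameterSet,
    variant: ModelVariant,
    designs: list[ExperimentDesign] | None = None,
    seed: int = 0,
    noise: bool = True,
) -> ObservationSet:
    """Simulate the labelled model per design and sample noisy observables."""
    designs = designs if designs is not None else default_calibration_designs()
    rng = np.random.default_rng(seed)
    records = []
    design_map = {}
    for design in designs:
        d = design.to_dict()
        design_map[design.name] = d
        sim = simulate_experiment(p_true, variant, d, design.times, rtol=1e-8, atol=1e-11)
        for obs in ("biomass", "glucose", "acetate_total", "acetate_enrichment"):
            values = sim[obs].to_numpy(copy=True)
            values = np.nan_to_num(values, nan=0.0)
            sds = _sd_for(obs, values, design.noise)
            noisy = _truncated_noise(values, sds, obs, rng) if noise else values
            for t, v, s in zip(design.times, noisy, sds):
                records.append(
                    {"experiment": design.name, "time": t, "observable": obs,
                     "value": v, "sd": s}
                )
    return ObservationSet(pd.DataFrame(records), design_map)


def generate_validation_set(
    p_true: ParameterSet,
    variant: ModelVariant,
    seed: int = 0,
    noise: bool = True,
) -> ObservationSet:
    """Held-out perturbation data: chemostat scan, acetate scan, pulses."""
    rng = np.random.default_rng(seed)
    records = []
    designs = {}

    def add_rows(exp, d, times, sim, observables, noise_spec):
        designs[exp] = d
        for obs in observables:
            values = sim[obs].to_numpy(copy=True)
            sds = _sd_for(obs, values, noise_spec)
            noisy = _truncated_noise(values, sds, obs, rng) if noise else values
            for t, v, s in zip(times, noisy, sds):
                records.append(
                    {"experiment": exp, "time": t, "observable": obs, "value": v, "sd": s}
                )

    flux_obs = ("glucose_flux", "acetate_flux", "growth_rate")

    D_grid = np.arange(0.1, 0.51, 0.1).round(6)
    d = {"kind": "chemostat_scan", "feed_glucose": 15.0}
    sim = simulate_experiment(p_true, variant, d, D_grid)
    add_rows("chemostat", d, D_grid, sim, flux_obs, NOISE_DEFAULTS)

    ace_grid = np.logspace(-1, 2, 10).round(6)
    d = {"kind": "acetate_scan", "GLC": 15.0, "X0": 1.0}
    sim = simulate_experiment(p_true, variant, d, ace_grid)
    add_rows("ace_scan", d, ace_grid, sim, flux_obs, NOISE_DEFAULTS)

    pulse_times = np.linspace(0.5, 6.0, 12)
    for name, amount in (("pulse_30mM", 30.0), ("pulse_water", 0.0)):
        d = {
            "kind": "pulse", "GLC": 15.0, "glc_enrichment": 0.0, "ACE_env": 0.1,
            "X0": 0.05, "pulse_ace": amount, "t_pulse": 3.0,
        }
        sim = simulate_experiment(p_true, variant, d, pulse_times, rtol=1e-8, atol=1e-11)
        add_rows(name, d, pulse_times, sim,
                 ("biomass", "glucose", "acetate_total"), NOISE_DEFAULTS)

    return ObservationSet(pd.DataFrame(records), designs)
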