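"""Binary 13C-labelling extension of the kinetic model.

Each carbon pool S is duplicated into an unlabelled (S0) and a labelled (S1)
pool whose sum is the total concentration.  Every unidirectional flux out of
a pool is split in proportion to the enrichment ``e(S) = S1/(S0+S1)`` of its
source pool; reversible reactions are first decomposed into forward and
reverse components, because the bidirectional exchange they carry shapes the
label distribution even when the net flux is small.  The biomass drain is
not isotopically split (growth consumes acetyl-CoA through the lumped TCA
reaction only).

Molecules are treated as either fully labelled or fully unlabelled — the
acetyl unit inherited from uniformly 13C-labelled glucose carries the label
as a unit; positional isotopomers and mass distributions are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelVariant, State, all_rates
from .parameters import ParameterSet

__all__ = ["LabelledState", "labelled_rhs", "enrichment", "acetate_enrichment"]

#: labelled state vector layout
LABELLED_ORDER = (
    "GLC0", "GLC1", "ACE_env0", "ACE_env1", "X",
    "ACCOA0", "ACCOA1", "ACP0", "ACP1", "ACE_cell0", "ACE_cell1",
)


@dataclass
class LabelledState:
    """Unlabelled/labelled pool pair for each carbon species, plus biomass."""

    GLC0: float
    GLC1: float
    ACE_env0: float
    ACE_env1: float
    X: float
    ACCOA0: float
    ACCOA1: float
    ACP0: float
    ACP1: float
    ACE_cell0: float
    ACE_cell1: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in LABELLED_ORDER])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "LabelledState":
        return cls(*map(float, y))

    @classmethod
    def from_totals(
        cls,
        state: State,
        glc_enrichment: float = 1.0,
        ace_env_enrichment: float = 0.0,
        intracellular_enrichment: float = 0.0,
    ) -> "LabelledState":
        """Split a total-pool state into labelled/unlabelled pairs.

        Defaults describe the calibration experiments: fully labelled glucose,
        unlabelled acetate, cells pre-grown on unlabelled substrate.
        """
        eG, eA, eI = glc_enrichment, ace_env_enrichment, intracellular_enrichment
        return cls(
            GLC0=state.GLC * (1 - eG), GLC1=state.GLC * eG,
            ACE_env0=state.ACE_env * (1 - eA), ACE_env1=state.ACE_env * eA,
            X=state.X,
            ACCOA0=state.ACCOA * (1 - eI), ACCOA1=state.ACCOA * eI,
            ACP0=state.ACP * (1 - eI), ACP1=state.ACP * eI,
            ACE_cell0=state.ACE_cell * (1 - eI), ACE_cell1=state.ACE_cell * eI,
        )

    def totals(self) -> State:
        """Collapse pool pairs back to the unlabelled model's state."""
        return State(
            GLC=self.GLC0 + self.GLC1,
            ACE_env=self.ACE_env0 + self.ACE_env1,
            X=self.X,
            ACCOA=self.ACCOA0 + self.ACCOA1,
            ACP=self.ACP0 + self.ACP1,
            ACE_cell=self.ACE_cell0 + self.ACE_cell1,
        )

    def enrichments(self) -> dict[str, float]:
        """e(S) per species; empty pools report NaN."""
        out = {}
        for sp in ("GLC", "ACE_env", "ACCOA", "ACP", "ACE_cell"):
            s0 = getattr(self, sp + "0")
            s1 = getattr(self, sp + "1")
            out[sp] = s1 / (s0 + s1) if s0 + s1 > 0 else np.nan
        return out


def enrichment(labelled: float, unlabelled: float) -> float:
    """Fraction of a pool carrying the label; 0 for an empty pool."""
    tot = labelled + unlabelled
    return labelled / tot if tot > 0 else 0.0


def labelled_rhs(
    t: float, lstate: LabelledState | np.ndarray, p: ParameterSet, variant: ModelVariant
) -> np.ndarray:
    """Reference right-hand side of the isotopically extended model.

    Rates are computed from total pools; each unidirectional flux out of a
    pool is partitioned by the source pool's enrichment.  Summing the pair
    of balances for any species reproduces the unlabelled balance exactly.
    """
    if isinstance(lstate, LabelledState):
        y = lstate.to_array()
    else:
        y = np.asarray(lstate, dtype=float)
    y = np.maximum(y, 0.0)
    ls = LabelledState.from_array(y)
    tot = ls.totals()
    v = all_rates(tot, p, variant)
    rho = tot.X * p.Vcell / p.Venv

    eG1 = enrichment(ls.GLC1, ls.GLC0)
    eA1 = enrichment(ls.ACCOA1, ls.ACCOA0)
    eP1 = enrichment(ls.ACP1, ls.ACP0)
    eC1 = enrichment(ls.ACE_cell1, ls.ACE_cell0)
    eE1 = enrichment(ls.ACE_env1, ls.ACE_env0)
    n = p.accoa_per_glc

    def pair(flux_in0, flux_in1, flux_out, e_self1):
        return flux_in0 - (1 - e_self1) * flux_out, flux_in1 - e_self1 * flux_out

    dGLC0, dGLC1 = -(1 - eG1) * v.glycolysis * rho, -eG1 * v.glycolysis * rho
    dAE0 = ((1 - eC1) * v.exchange_fwd - (1 - eE1) * v.exchange_rev) * rho
    dAE1 = (eC1 * v.exchange_fwd - eE1 * v.exchange_rev) * rho
    dAC0, dAC1 = pair(
        (1 - eG1) * n * v.glycolysis + (1 - eP1) * v.pta_rev,
        eG1 * n * v.glycolysis + eP1 * v.pta_rev,
        v.tca + v.pta_fwd,
        eA1,
    )
    dAP0, dAP1 = pair(
        (1 - eA1) * v.pta_fwd + (1 - eC1) * v.acka_rev,
        eA1 * v.pta_fwd + eC1 * v.acka_rev,
        v.pta_rev + v.acka_fwd,
        eP1,
    )
    dCl0, dCl1 = pair(
        (1 - eP1) * v.acka_fwd + (1 - eE1) * v.exchange_rev,
        eP1 * v.acka_fwd + eE1 * v.exchange_rev,
        v.acka_rev + v.exchange_fwd,
        eC1,
    )
    dX = tot.X * v.growth
    out = np.array([dGLC0, dGLC1, dAE0, dAE1, dX, dAC0, dAC1, dAP0, dAP1, dCl0, dCl1])
    if variant.mode == "chemostat":
        D = variant.dilution_rate
        out[:4] -= D * y[:4]
        out[0] += variant.feed_rate  # feed glucose is unlabelled
        out[4] -= D * tot.X
    return out


def acetate_enrichment(traj: "pd.DataFrame | object") -> pd.Series:
    """Time series of extracellular-acetate enrichment from a trajectory.

    Accepts a :class:`~acekin.simulate.TrajectorySet` or its state frame.
    Times where the acetate pool is empty are reported as NaN (missing), not
    as zero.
    """
    frame = traj.states if hasattr(traj, "states") else traj
    if "ACE_env1" not in frame.columns:
        raise ValueError("trajectory carries no labelled pools (label_tracking off?)")
    tot = frame["ACE_env0"] + frame["ACE_env1"]
    e = frame["ACE_env1"] / tot.where(tot > 0)
    e.name = "acetate_enrichment"
    return e
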