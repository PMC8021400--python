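"""Kinetic parameters of the glucose/acetate model.

The model couples five enzymatic steps around the acetyl-CoA node of
*Escherichia coli* — glycolysis (lumped glucose uptake + Embden-Meyerhof
pathway), the TCA cycle (lumped energy/anabolic drain of acetyl-CoA), the
reversible Pta-AckA pathway (acetyl-CoA <-> acetyl-phosphate <-> acetate) and
a saturable acetate exchange across the membrane — plus a growth reaction
whose rate is proportional to the TCA flux.

Units follow the convention of coarse-grained E. coli models: concentrations
in mM, time in hours, volumes in litres, biomass in grams dry weight (gDW).
All Vmax are expressed on the cell-volume basis (mM per hour of cell volume),
so that metabolic rates couple to the environment through the cell-to-broth
volume ratio ``X * v_cell``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

__all__ = [
    "AckAParams",
    "PtaParams",
    "GlycolysisParams",
    "TcaParams",
    "ExchangeParams",
    "Cofactors",
    "ParameterSet",
    "default_parameters",
    "PARAM_ARRAY_ORDER",
]


@dataclass
class AckAParams:
    """Acetate kinase: ACP + ADP <-> ACE_cell + ATP (reversible MM)."""

    Vmax: float = 3.4e5     # mM/hr, fitted
    Keq: float = 174.0      # [ACE][ATP]/([ACP][ADP]) at equilibrium
    Km_ACP: float = 0.16    # mM
    Km_ADP: float = 0.5     # mM
    Km_ACE: float = 7.0     # mM
    Km_ATP: float = 0.07    # mM


@dataclass
class PtaParams:
    """Phosphotransacetylase: ACCOA + P <-> ACP + CoA.

    Reversible Michaelis-Menten with substrate/product inhibition terms.

    The default equilibrium constant is 0.0281, the literature value used by
    the predecessor kinetic model of the Pta-AckA pathway from which the
    remaining constants of this block are taken.  Only this value is
    consistent with the calibrated model's documented behaviour (distributed
    flux control around the acetyl-CoA node, acetate flux reversal in the
    10 mM range, growth rates near 0.55-0.6 /hr on glucose); see
    docs/methods.md for the analysis.
    """

    Vmax: float = 9.8e5     # mM/hr, fitted
    Keq: float = 0.0281     # [ACP][CoA]/([ACCOA][P]) at equilibrium
    Km_ACCOA: float = 0.2   # mM
    Km_P: float = 6.1       # mM
    Ki_P: float = 13.5      # mM
    Ki_ACP: float = 0.2     # mM
    Km_COA: float = 0.029   # mM
    Km_ACP: float = 0.7     # mM


@dataclass
class GlycolysisParams:
    """Lumped glucose uptake and glycolysis: GLC -> 1.4 ACCOA (irreversible MM).

    ``Ki_ACE`` is the non-competitive inhibition constant of the pathway by
    extracellular acetate; it is only used by model variants that include
    glycolytic inhibition and may be None otherwise.
    """

    Vmax: float = 5.6e3         # mM/hr, fitted
    Km_GLC: float = 0.02        # mM
    Ki_ACE: float | None = 36.7  # mM, fitted (models 2 and 4)


@dataclass
class TcaParams:
    """Lumped TCA cycle / anabolic drain of acetyl-CoA (irreversible MM)."""

    Vmax: float = 7.4e5          # mM/hr, fitted
    Km_ACCOA: float = 24.8       # mM, fitted
    Ki_ACE: float | None = 2.3   # mM, fitted (models 3 and 4)


@dataclass
class ExchangeParams:
    """Saturable acetate exchange ACE_cell <-> ACE_env (reversible MM).

    Keq = 1: intra- and extracellular acetate equilibrate over time.
    Positive net rate means export.
    """

    Vmax: float = 4.8e5     # mM/hr, fitted
    Km_ACE: float = 33.2    # mM, fitted
    Keq: float = 1.0


@dataclass
class Cofactors:
    """Cofactor pools held constant (not state variables)."""

    ADP: float = 0.61   # mM
    ATP: float = 2.40   # mM
    COA: float = 1.22   # mM
    P: float = 10.0     # mM, inorganic phosphate


@dataclass
class ParameterSet:
    """Complete parameterisation of the model.

    ``Y`` is the biomass yield on acetyl-CoA routed through the TCA cycle
    (gDW per mmol), so that the specific growth rate is ``mu = v_TCA * Y``.
    ``Vcell`` is the specific cell volume (L per gDW); ``Venv`` is a
    normalisation constant for the environment volume (L).
    ``accoa_per_glc`` is the stoichiometry of acetyl-CoA produced per glucose
    through lumped glycolysis.
    """

    acka: AckAParams = field(default_factory=AckAParams)
    pta: PtaParams = field(default_factory=PtaParams)
    glycolysis: GlycolysisParams = field(default_factory=GlycolysisParams)
    tca: TcaParams = field(default_factory=TcaParams)
    exchange: ExchangeParams = field(default_factory=ExchangeParams)
    cofactors: Cofactors = field(default_factory=Cofactors)
    Y: float = 1.0e-4           # gDW/mmol AcCoA, fitted
    Vcell: float = 1.77e-3      # L/gDW
    Venv: float = 1.0           # L (normalisation)
    accoa_per_glc: float = 1.4

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Every kinetic constant, concentration and yield must be positive."""
        for block, name, value in self._walk():
            if value is None:
                continue
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"parameter {block}.{name} must be strictly positive, got {value!r}"
                )

    def _walk(self):
        for block_name in ("acka", "pta", "glycolysis", "tca", "exchange", "cofactors"):
            block = getattr(self, block_name)
            for name, value in asdict(block).items():
                yield block_name, name, value
        for name in ("Y", "Vcell", "Venv", "accoa_per_glc"):
            yield "", name, getattr(self, name)

    # -- free-parameter access used by calibration ------------------------

    def get_path(self, path: str) -> float:
        """Read a parameter by dotted path, e.g. ``'glycolysis.Vmax'`` or ``'Y'``."""
        if "." in path:
            block, name = path.split(".", 1)
            return getattr(getattr(self, block), name)
        return getattr(self, path)

    def with_updates(self, updates: dict[str, float]) -> "ParameterSet":
        """Return a copy with dotted-path parameters replaced."""
        new = replace(self)
        new.acka = replace(self.acka)
        new.pta = replace(self.pta)
        new.glycolysis = replace(self.glycolysis)
        new.tca = replace(self.tca)
        new.exchange = replace(self.exchange)
        new.cofactors = replace(self.cofactors)
        for path, value in updates.items():
            if "." in path:
                block, name = path.split(".", 1)
                setattr(getattr(new, block), name, float(value))
            else:
                setattr(new, path, float(value))
        new.validate()
        return new

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(
            acka=AckAParams(**d.get("acka", {})),
            pta=PtaParams(**d.get("pta", {})),
            glycolysis=GlycolysisParams(**d.get("glycolysis", {})),
            tca=TcaParams(**d.get("tca", {})),
            exchange=ExchangeParams(**d.get("exchange", {})),
            cofactors=Cofactors(**d.get("cofactors", {})),
            Y=d.get("Y", 1.0e-4),
            Vcell=d.get("Vcell", 1.77e-3),
            Venv=d.get("Venv", 1.0),
            accoa_per_glc=d.get("accoa_per_glc", 1.4),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_csv(self, path: str | Path) -> None:
        """Flat (reaction, parameter, value) triples."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["reaction", "parameter", "value"])
            for block, name, value in self._walk():
                if value is None:
                    continue
                writer.writerow([block or "global", name, repr(value)])

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterSet":
        d: dict = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                block, name, value = row["reaction"], row["parameter"], float(row["value"])
                if block == "global":
                    d[name] = value
                else:
                    d.setdefault(block, {})[name] = value
        return cls.from_dict(d)

    # -- packing for the compiled ODE kernels -----------------------------

    def to_array(self) -> np.ndarray:
        g, t, p, a, e, c = (
            self.glycolysis, self.tca, self.pta, self.acka, self.exchange, self.cofactors,
        )
        return np.array(
            [
                g.Vmax, g.Km_GLC, g.Ki_ACE if g.Ki_ACE is not None else np.inf,
                t.Vmax, t.Km_ACCOA, t.Ki_ACE if t.Ki_ACE is not None else np.inf,
                p.Vmax, p.Keq, p.Km_ACCOA, p.Km_P, p.Ki_P, p.Ki_ACP, p.Km_COA, p.Km_ACP,
                a.Vmax, a.Keq, a.Km_ACP, a.Km_ADP, a.Km_ACE, a.Km_ATP,
                e.Vmax, e.Km_ACE, e.Keq,
                self.Y, c.ADP, c.ATP, c.COA, c.P, self.Vcell, self.Venv,
                self.accoa_per_glc,
            ],
            dtype=np.float64,
        )


#: layout of :meth:`ParameterSet.to_array`, consumed by the numba kernels
PARAM_ARRAY_ORDER = (
    "gly_Vmax", "gly_Km_GLC", "gly_Ki_ACE",
    "tca_Vmax", "tca_Km_ACCOA", "tca_Ki_ACE",
    "pta_Vmax", "pta_Keq", "pta_Km_ACCOA", "pta_Km_P", "pta_Ki_P", "pta_Ki_ACP",
    "pta_Km_COA", "pta_Km_ACP",
    "acka_Vmax", "acka_Keq", "acka_Km_ACP", "acka_Km_ADP", "acka_Km_ACE", "acka_Km_ATP",
    "exch_Vmax", "exch_Km_ACE", "exch_Keq",
    "Y", "ADP", "ATP", "COA", "P", "Vcell", "Venv", "accoa_per_glc",
)


def default_parameters() -> ParameterSet:
    """The calibrated parameter set (literature constants + fitted values)."""
    return ParameterSet()
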