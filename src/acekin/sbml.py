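"""SBML Level 3 export of the (unlabelled) kinetic model.

Writes the two-compartment network with explicit kinetic laws so the model
can be cross-checked in COPASI or any SBML-aware simulator.  Import is a
non-goal.  Species are in mM, time in hours; intracellular rates carry the
cell-to-environment volume coupling explicitly in the extracellular
balances, as in the ODE system.
"""

from __future__ import annotations

from pathlib import Path

import libsbml

from .model import ModelVariant
from .parameters import ParameterSet

__all__ = ["export_sbml"]


def _check(value, message: str):
    if value is None or (isinstance(value, int) and value < 0):
        raise RuntimeError(f"libsbml error: {message}")
    return value


def export_sbml(
    p: ParameterSet,
    variant: ModelVariant,
    path: str | Path,
    model_id: str = "acetate_overflow",
) -> None:
    """Write the variant as an SBML L3V2 file with full kinetic laws."""
    doc = libsbml.SBMLDocument(3, 2)
    model = _check(doc.createModel(), "create model")
    model.setId(model_id)
    hour = _check(model.createUnitDefinition(), "hour unit")
    hour.setId("hour")
    unit = hour.createUnit()
    unit.setKind(libsbml.UNIT_KIND_SECOND)
    unit.setExponent(1)
    unit.setScale(0)
    unit.setMultiplier(3600.0)
    model.setTimeUnits("hour")

    for cid, size in (("environment", p.Venv), ("cell", p.Vcell)):
        comp = _check(model.createCompartment(), cid)
        comp.setId(cid)
        comp.setConstant(True)
        comp.setSize(size)
        comp.setSpatialDimensions(3)

    species = [
        ("GLC", "environment", 15.0), ("ACE_env", "environment", 0.1),
        ("X", "environment", 0.02), ("ACCOA", "cell", 1e-4),
        ("ACP", "cell", 1e-4), ("ACE_cell", "cell", 1e-4),
    ]
    for sid, comp, init in species:
        sp = _check(model.createSpecies(), sid)
        sp.setId(sid)
        sp.setCompartment(comp)
        sp.setInitialConcentration(init)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    g, t, q, a, e, c = (
        p.glycolysis, p.tca, p.pta, p.acka, p.exchange, p.cofactors,
    )
    params = {
        "Vmax_gly": g.Vmax, "Km_GLC": g.Km_GLC,
        "Vmax_tca": t.Vmax, "Km_ACCOA_tca": t.Km_ACCOA,
        "Vmax_pta": q.Vmax, "Keq_pta": q.Keq, "Km_ACCOA_pta": q.Km_ACCOA,
        "Km_P": q.Km_P, "Ki_P": q.Ki_P, "Ki_ACP": q.Ki_ACP,
        "Km_COA": q.Km_COA, "Km_ACP_pta": q.Km_ACP,
        "Vmax_acka": a.Vmax, "Keq_acka": a.Keq, "Km_ACP_acka": a.Km_ACP,
        "Km_ADP": a.Km_ADP, "Km_ACE_acka": a.Km_ACE, "Km_ATP": a.Km_ATP,
        "Vmax_exch": e.Vmax, "Km_ACE_exch": e.Km_ACE, "Keq_exch": e.Keq,
        "Y": p.Y, "ADP": c.ADP, "ATP": c.ATP, "COA": c.COA, "P": c.P,
        "rho_scale": p.Vcell / p.Venv, "n_accoa": p.accoa_per_glc,
    }
    if variant.inhibit_glycolysis:
        params["Ki_ACE_gly"] = g.Ki_ACE
    if variant.inhibit_tca:
        params["Ki_ACE_tca"] = t.Ki_ACE
    for pid, value in params.items():
        par = _check(model.createParameter(), pid)
        par.setId(pid)
        par.setValue(float(value))
        par.setConstant(True)

    gly_rate = "Vmax_gly * GLC / (GLC + Km_GLC)"
    if variant.inhibit_glycolysis:
        gly_rate += " / (1 + ACE_env / Ki_ACE_gly)"
    tca_rate = "Vmax_tca * ACCOA / (ACCOA + Km_ACCOA_tca)"
    if variant.inhibit_tca:
        tca_rate += " / (1 + ACE_env / Ki_ACE_tca)"
    pta_rate = (
        "Vmax_pta * (ACCOA * P - ACP * COA / Keq_pta) / (Km_ACCOA_pta * Km_P)"
        " / (1 + ACCOA / Km_ACCOA_pta + P / Ki_P + ACP / Ki_ACP + COA / Km_COA"
        " + ACCOA * P / (Km_ACCOA_pta * Km_P) + ACP * COA / (Km_ACP_pta * Km_COA))"
    )
    acka_rate = (
        "Vmax_acka * (ACP * ADP - ACE_cell * ATP / Keq_acka)"
        " / (Km_ACP_acka * Km_ADP)"
        " / ((1 + ACP / Km_ACP_acka + ACE_cell / Km_ACE_acka)"
        " * (1 + ADP / Km_ADP + ATP / Km_ATP))"
    )
    exch_rate = (
        "Vmax_exch * (ACE_cell - ACE_env / Keq_exch) / Km_ACE_exch"
        " / (1 + ACE_cell / Km_ACE_exch + ACE_env / Km_ACE_exch)"
    )

    rho = "X * rho_scale"
    reactions = [
        ("Glycolysis", {"GLC": 1.0}, {"ACCOA": params["n_accoa"]},
         f"({gly_rate}) * cell", {"GLC": f"({gly_rate}) * ({rho})"}),
        ("TCA_cycle", {"ACCOA": 1.0}, {}, f"({tca_rate}) * cell", {}),
        ("Pta", {"ACCOA": 1.0}, {"ACP": 1.0}, f"({pta_rate}) * cell", {}),
        ("AckA", {"ACP": 1.0}, {"ACE_cell": 1.0}, f"({acka_rate}) * cell", {}),
        ("Acetate_exchange", {"ACE_cell": 1.0}, {"ACE_env": 1.0},
         f"({exch_rate}) * cell", {}),
        ("Growth", {}, {"X": 1.0}, f"X * ({tca_rate}) * Y * environment", {}),
    ]
    for rid, reactants, products, formula, _ in reactions:
        rxn = _check(model.createReaction(), rid)
        rxn.setId(rid)
        rxn.setReversible(rid in ("Pta", "AckA", "Acetate_exchange"))
        for sid, stoich in reactants.items():
            ref = rxn.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(stoich)
            ref.setConstant(True)
        for sid, stoich in products.items():
            ref = rxn.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(stoich)
            ref.setConstant(True)
        # species appearing in the law but not consumed/produced are modifiers
        import re

        tokens = set(re.findall(r"[A-Za-z_]\w*", formula))
        for sid, _, _ in species:
            if sid in tokens and sid not in reactants and sid not in products:
                mod = rxn.createModifier()
                mod.setSpecies(sid)
        law = rxn.createKineticLaw()
        ast = libsbml.parseL3Formula(formula)
        _check(ast, f"parse rate law of {rid}")
        law.setMath(ast)

    doc.checkConsistency()
    errors = sum(
        doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        for i in range(doc.getNumErrors())
    )
    if errors:
        raise RuntimeError(doc.getErrorLog().toString())
    libsbml.writeSBMLToFile(doc, str(path))
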