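# acekin

Kinetic modelling of acetate overflow in *Escherichia coli*: model
calibration on dynamic ¹³C-labelling data, metabolic control analysis, and
regulation decomposition, with Monte-Carlo uncertainty quantification.

## The scientific problem

During aerobic growth on glucose, *E. coli* excretes acetate ("overflow
metabolism") — yet at high external acetate it consumes acetate *while
glucose is still abundant*. Neither pure enzyme-capacity arguments nor pure
thermodynamics explain the full concentration dependence of this flux.
`acekin` implements a coarse-grained kinetic model of the acetyl-CoA node
that reconciles the two views:

* **Glycolysis** (lumped): `GLC → 1.4 AcCoA`, irreversible Michaelis–Menten;
* **TCA cycle** (lumped energy + anabolic drain): `AcCoA → ∅`, irreversible
  Michaelis–Menten, with growth rate `μ = v_TCA · Y`;
* **Pta–AckA pathway**: `AcCoA ⇌ AcP ⇌ ACE_cell`, reversible
  Michaelis–Menten kinetics with the literature product/substrate inhibition
  terms;
* **Acetate exchange**: `ACE_cell ⇌ ACE_env`, saturable and reversible
  (`K_eq = 1`);
* optional **non-competitive inhibition** of the glycolytic and TCA blocks
  by extracellular acetate, `v → v / (1 + ACE/K_i)` — the model's
  phenomenological stand-in for the cell's integrated (largely
  transcriptional) response to acetate.

Four nested variants (no inhibition / glycolysis only / TCA only / both)
are calibrated against dynamic ¹³C-labelling batch cultures by weighted
least squares,

```
f(p) = Σ_i ((x_i − y_i(p)) / σ_i)² ,
```

minimised with a seeded particle-swarm optimiser in log₁₀ space and judged
by a χ²(0.95, n−p) goodness-of-fit threshold. Only the doubly inhibited
variant survives. On the calibrated model the package computes scaled flux
control coefficients `C_E^J = ∂lnJ/∂lnE`, elasticities
`ε_Ace^v = ∂ln v/∂ln ACE`, response coefficients `R = ∂lnJ_ace/∂ln ACE`, and
the partitioned responses `viR = C_i · ε_i` that split the flux response
into a direct (metabolic, via the exchange reaction) and two indirect
(hierarchical, via the inhibition terms) regulatory routes.

Because the original culture measurements are not redistributable, a
synthetic-data generator reproduces the study design (three cultures on
15 mM U-¹³C-glucose plus 1/10/30 mM ¹²C-acetate, ~150 observations of
biomass, glucose, total acetate and acetate ¹³C-enrichment, truncated
Gaussian noise), so the whole pipeline is testable end to end.

A note on one constant: the package ships `K_eq(Pta) = 0.0281` (the value
used by the predecessor kinetic model of the Pta–AckA pathway from which
the other Pta constants are taken). See `docs/methods.md` for why this
value — and not a sometimes-quoted smaller one — is the only one consistent
with the calibrated model's documented behaviour.

## A worked example

```python
from acekin import ParameterSet, control_report, model_variant

report = control_report(ParameterSet(), model_variant(4), GLC=15.0, ACE_env=0.1)
for block, c in report.blocks.items():
    print(f"{block:15s} {c:+.2f}")
```

prints

```
glycolysis      +0.89
tca             -0.66
acetate_pathway +0.76
```

i.e. at 15 mM glucose and 0.1 mM acetate the steady-state acetate flux is
*not* controlled from within the acetate pathway alone: glycolysis exerts
strong positive control (it feeds the acetyl-CoA node), the TCA cycle
comparable negative control (it competes for acetyl-CoA), and within the
acetate pathway nearly all control sits on AckA. The three blocks sum to 1
(summation theorem). More narrative walk-throughs live in `examples/`:

* `batch_growth.py` — ¹³C batch culture: overflow, reconsumption, enrichment;
* `control_analysis.py` — the control-coefficient table above;
* `regulation_scan.py` — flux reversal and the 40/20/40 regulation split;
* `calibrate_synthetic.py` — generate → fit → χ² round trip;
* `monte_carlo.py` — confidence intervals on parameters and predictions.

A thin CLI mirrors these capabilities (`acekin simulate | generate-data |
calibrate | compare-models | mca | regulation-scan | montecarlo |
export-sbml | plot`), writing a reproducibility manifest next to every
output.

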