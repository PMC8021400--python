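# Methods

## Model

Two compartments: the environment (volume `Venv`, a 1 L normalisation
constant) and the cell (specific volume `Vcell = 1.77e-3 L/gDW`). Six state
variables: glucose `GLC`, extracellular acetate `ACE_env` and biomass `X`
in the environment; acetyl-CoA `ACCOA`, acetyl-phosphate `ACP` and
intracellular acetate `ACE_cell` in the cell. Units: mM, hours, gDW. All
Vmax values are on the cell-volume basis (mM/hr of cell volume), so
intensive metabolic rates couple to the environment through the
dimensionless volume ratio `rho = X * Vcell / Venv`:

```
dGLC/dt      = -v_gly * rho                [+ v_feed - D*GLC]
dACE_env/dt  =  v_exch * rho               [- D*ACE_env]
dX/dt        =  X * mu                     [- D*X]
dACCOA/dt    =  1.4*v_gly - v_tca - v_pta
dACP/dt      =  v_pta - v_acka
dACE_cell/dt =  v_acka - v_exch
```

with `mu = v_tca * Y` and bracketed dilution/feed terms only in chemostat
mode (`v_feed = D *` reservoir glucose). The glucose balance carries an
explicit negative sign — glycolysis consumes glucose; the stoichiometry of
1.4 acetyl-CoA per glucose is the lumped yield of the glycolytic block.
Rate laws: irreversible Michaelis–Menten for glycolysis (in `GLC`) and the
TCA block (in `ACCOA`); full reversible Michaelis–Menten forms for Pta
(with dead-end inhibition by phosphate and acetyl-phosphate), AckA, and the
acetate exchange (`Keq = 1`: intra- and extracellular acetate equilibrate).
Cofactors (ADP 0.61, ATP 2.40, CoA 1.22, inorganic phosphate 10 mM) are
constants, not state variables.

Model variants 1–4 toggle non-competitive inhibition of the glycolysis
and/or TCA blocks by **extracellular** acetate (`1/(1 + ACE_env/Ki)`); the
controlling species is the first environmental signal cells sense, and the
term stands for the integrated regulatory response (transcriptional and
faster layers), not a specific molecular mechanism. Consequences built into
the model's scope: no acetyl-CoA synthetase (so glucose-limited acetate
assimilation via Acs is out of reach), no lag or delay on the inhibition,
no pH correction of acetate speciation.

### The Pta equilibrium constant

The literature parameter table for Pta cites the predecessor kinetic model
of the Pta–AckA pathway. That lineage uses `Keq(Pta) = 0.0281`, and only a
value in this range is consistent with the calibrated model's documented
behaviour; with the sometimes-quoted `0.005` the thermodynamic gain of the
AcCoA→ACP→ACE_cell chain ((P·Keq_Pta/CoA)·(ADP·Keq_AckA/ATP) ≈ 1.8 instead
of ≈ 10) is too small to sustain acetate export against realistic external
concentrations: the flux reversal would sit near 0.6 mM instead of the
10 mM range, growth rates would exceed 0.9 /hr, and the flux-control
fingerprint at the reference condition would be (1.21, −1.13, 0.92) for the
glycolysis/TCA/acetate-pathway blocks instead of the expected
(0.88, −0.64, 0.76). The package therefore ships 0.0281 as the default,
treating the smaller figure as a misprint; the parameter is an ordinary
field of `PtaParams` for anyone wishing to revisit it.

## Isotope labelling

Binary labelling: each carbon pool S is split into unlabelled S₀ and
labelled S₁ (no positional isotopomers — the acetyl unit inherited from
U-¹³C glucose is treated as fully labelled). Rates are computed from total
pools; every *unidirectional* flux out of a pool is partitioned by the
source pool's enrichment `e(S) = S₁/(S₀+S₁)`, which is why the reversible
rate laws are decomposed into forward/reverse components: bidirectional
exchange moves label even when net fluxes are small. Growth is not
isotopically split. An empty pool has `e = 0` inside the right-hand side
(no flux leaves an empty pool anyway) and reports enrichment as missing in
outputs. Summing each pool pair reproduces the unlabelled balances exactly,
a property the test suite checks both algebraically and on integrated
trajectories. Initial intracellular pools default to unlabelled (cells are
pre-grown on ¹²C substrate) and dilute (1e-4 mM): they relax to their
quasi-steady state within simulated seconds, well before the first
observation, and carry negligible carbon.

## Numerics

* Integration: LSODA via `scipy.integrate.solve_ivp`; default tolerances
  rtol 1e-8 / atol 1e-10 mM, output grid 0.01 hr (calibration uses
  rtol 1e-6 at observation times only). Right-hand sides are evaluated on
  `max(y, 0)`: sub-tolerance negative excursions are integrator artefacts,
  clipped with a one-time warning rather than an abort. The hot loops run
  through numba-compiled kernels that are verified against the scalar
  reference implementation in the test suite.
* Clamped steady states (for control analysis and scans): glucose,
  extracellular acetate and biomass are boundary species; only the three
  intracellular balances are solved — a growing batch culture has no full
  steady state, but the intensive intracellular pools do. A 200 hr
  relaxation integration supplies the basin, a hybrid-Powell root polish
  finishes; the relative residual must be ≤ 1e-10. Reported fluxes are per
  gDW (cell-basis rate × `Vcell`), hence independent of the clamped X — a
  property the tests assert.
* Control coefficients: central differences of the re-solved steady state
  under ±1e-3 relative Vmax perturbations (log-difference form). A
  Richardson check at 1e-4 agrees to 1e-4, and a sympy implicit-function
  oracle (independent symbolic differentiation of the rate laws) agrees to
  1e-6. Elasticities use closed forms, cross-checked by finite differences.
* Near the flux reversal the scaled coefficients diverge (`J → 0`); scans
  mask rows with |J_ace| below 1e-3 of its reference-condition value rather
  than interpolating through the singularity.
* Route contributions are `|viR| / Σ|viR|`: absolute-value weighting is the
  only normalisation that keeps shares in [0, 1] and summing to one when
  routes pull in opposite directions.
* Flux-reversal threshold: Brent bisection of the steady-state exchange
  flux over [1e-4, 1e3] mM; no sign change → "no reversal", reported as
  NaN, not an error.

## Calibration

Free parameters (doubly inhibited variant, 10): the five Vmax values, the
TCA `Km_ACCOA`, both `Ki_ACE`, the exchange `Km_ACE`, and the yield `Y`;
variants 1–3 drop the absent inhibition constants (8–9 free). Optimisation
runs in log₁₀ space — the parameters span ten orders of magnitude — inside
a box of ±2 decades around the reference values (bounds are a design
choice, recorded in every fit report). The global search is a seeded
particle-swarm optimiser (constriction coefficients w = 0.729,
c1 = c2 ≈ 1.494; study-scale preset 2000 iterations × 50 particles, with a
patience-based early stop), followed by a bounded trust-region polish of
the weighted residuals. Integration failures inside the objective return a
1e12 penalty so the swarm can probe infeasible regions. Experiments share
one parameter vector; initial conditions are experiment-specific and fixed.
The χ² test compares the minimised SSR to `qchisq(0.95, n − p)`; the
quantile is checked in the tests against an independent R evaluation.

## Synthetic data

The calibration generator simulates the labelled model for three batch
cultures (15 mM U-¹³C glucose + 1/10/30 mM ¹²C acetate, X₀ = 0.02 gDW/L,
13 samples over 0–8 hr) and observes biomass, glucose, total extracellular
acetate and acetate enrichment — 156 points. Noise defaults (a design
choice recorded in the design metadata): 2 % relative on biomass, 3 % on
concentrations, 0.02 absolute on enrichment, with small absolute floors
(0.002 gDW/L; 0.05 mM) so exhausted pools are not infinitely weighted;
Gaussian, truncated to physical ranges by resampling. The validation
generator emits the held-out perturbation protocols: chemostat steady
states at D = 0.1–0.5 /hr (feed 15 mM glucose), a steady-state acetate scan
over 0.1–100 mM, and 30 mM-acetate/water pulse time courses.

What the generator does *not* emulate: real sampling schedules (the 13-point
grid is a stand-in), correlated errors within a time course, OD-to-biomass
conversion error, NMR spectral processing, lag phases, or any regulation
delay. Tests passing on these data therefore demonstrate the correctness
and statistical calibration of the *pipeline* under the model's own
assumptions — not the biological adequacy of the model, which only the
original measurements can establish.

## Monte-Carlo uncertainty

Each replicate adds independent truncated-Gaussian noise (the stated σ of
every observation) to the data, refits, and recomputes any requested
derived quantity; 2.5/97.5 percentile intervals over replicates are the
95 % CIs. All replicate seeds spawn deterministically from one master seed
(extending n preserves existing replicates). Replicate fits default to a
reduced budget — a bounded trust-region refit from a start log-uniformly
jittered ±0.3 decades around the reference values, the standard
parametric-bootstrap shortcut — because hundreds of full global searches
exceed desk scale; the full PSO budget is one configuration field away and
is the faithful study-scale preset.

## Problem sizes used by the shipped checks

The end-to-end suite runs the model comparison at 200 PSO iterations ×
30 particles on one 156-point synthetic dataset, the noiseless recovery at
120 × 20, and the Monte-Carlo coverage at two datasets × 50 replicates with
the local-refit preset. These scaled-down budgets are the package's default
desk-scale presets; the study-scale settings (2000 × 50, 500 replicates)
are exposed through `FitConfig` and `run_monte_carlo` arguments.

## Known limitations

* The inhibition terms are phenomenological; the model cannot distinguish
  transcriptional from allosteric regulation, only quantify their combined
  effect.
* No acetyl-CoA synthetase: glucose-limited chemostats are comparable only
  to Acs-deficient strains, and stationary-phase acetate re-uptake is out
  of scope.
* With the default parameters the steady-state flux reversal sits at
  ≈15 mM at 15 mM glucose — the right order but sensitive to the rounded,
  strongly correlated published estimates (e.g. the TCA `Km_ACCOA` CI spans
  8–615 mM); several-mM shifts are within the parameter uncertainty, and
  the Monte-Carlo machinery quantifies exactly this.
* Identifiability is uneven: the Vmax of the near-equilibrium Pta reaction
  is constrained only from below (its published CI spans two orders of
  magnitude), so single-point estimates of that parameter should not be
  interpreted.
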