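"""How acetate regulates its own flux across three orders of magnitude.

Scans the clamped extracellular acetate concentration, locating the
thermodynamic flux-reversal point (where the cell switches from producing
to consuming acetate) and decomposing the flux response into its three
regulatory routes: direct metabolic regulation through the exchange
reaction, and indirect (hierarchical) regulation through the inhibition of
glycolysis and of the TCA cycle.
"""

import numpy as np

from acekin import (
    ParameterSet,
    find_flux_reversal_threshold,
    model_variant,
    regulation_scan,
    regulatory_range_edge,
)

p = ParameterSet()
v4 = model_variant(4)

threshold = find_flux_reversal_threshold(p, v4, GLC=15.0)
edge = regulatory_range_edge(p, v4, GLC=15.0)
print(f"acetate flux reverses (production -> consumption) at "
      f"{threshold:.1f} mM extracellular acetate")
print(f"acetate acts as a regulator (any |partitioned response| >= 0.1) "
      f"from {edge:.2f} mM upward\n")

grid = np.array([0.1, 0.5, 1.0, 5.0, 30.0, 100.0])
tab = regulation_scan(p, v4, grid, GLC=15.0)
print("route contributions to the acetate-flux response (% of total):")
print(f"{'ACE (mM)':>9} {'direct':>8} {'glycolysis':>11} {'TCA':>7}")
for _, r in tab.iterrows():
    if r["masked"]:
        print(f"{r['ACE_env']:9.1f}   (masked: flux-reversal singularity)")
    else:
        print(f"{r['ACE_env']:9.1f} {100*r['frac_acetate_pathway']:7.0f}% "
              f"{100*r['frac_glycolysis']:10.0f}% {100*r['frac_tca']:6.0f}%")
print("\nbelow the reversal the direct route dominates; above it the burden")
print("shifts to a roughly 40/20/40 split between direct, glycolytic and TCA routes.")
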