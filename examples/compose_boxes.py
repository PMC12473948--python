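"""Box compositions and dilution ladders for the five study pollutants.

Computes each chemical's apparent saturated octanol solubility from its
water solubility and log K_OW, converts it to a solute count per 1000
octanol molecules, and prints the six-step dilution ladder used in the
concentration study.
"""

from octagg import (compose_box, dilution_series, load_registry,
                    saturated_octanol_solubility)
from octagg.composition import DEFAULT_DILUTION_DIVISORS

registry = load_registry()
print(f"{'chemical':<14} {'S_O (mol/L)':>12} {'ratio':>10}   dilution ladder (mol/L)")
for rec in registry.values():
    s_o = saturated_octanol_solubility(rec.s_w, rec.log_kow)
    box = compose_box(rec, n_octanol=1000)
    ladder = dilution_series(s_o, DEFAULT_DILUTION_DIVISORS)
    print(f"{rec.id:<14} {s_o:12.3e} {box.n_solute:>6}:1000   "
          + ", ".join(f"{c:.3f}" for c in ladder))

# The ratio column is the box recipe: e.g. 24 PCB-4 molecules saturate a
# 1000-molecule octanol box.  The last ladder entry is the concentration at
# which each chemical is expected to be fully monomeric.
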