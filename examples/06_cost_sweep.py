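"""Sweep metabolic cost ratios for the two coexisting (3, 2) circulants.

The basin of attraction is measured on a shared (cp/cr, cd/cr) grid for
[PD,SP,DS] and [PD,SP,RS].  Their coexistence regions never overlap:
the two-PSD circulant coexists at low relative costs, the PSR variant
only in a narrow band at high relative costs.
"""

import numpy as np

from psdcoex import parse_community, sweep_cost_grid

cp_ratios = np.array([2.0, 2.5, 2.7624])
cd_ratios = np.array([1.4, 1.8, 2.2083, 2.25])

grids = {}
for notation in ["[PD,SP,DS]", "[PD,SP,RS]"]:
    grids[notation] = sweep_cost_grid(
        parse_community(notation), cp_ratios, cd_ratios,
        metric="basin_fraction", n_init=50, seed=1,
    )
    print(f"basin fraction of {notation} (rows cp/cr, cols cd/cr):")
    header = "          " + "  ".join(f"{cd:7.4f}" for cd in cd_ratios)
    print(header)
    for i, cp in enumerate(cp_ratios):
        row = "  ".join(f"{v:7.2f}" for v in grids[notation][i])
        print(f"  {cp:7.4f} {row}")

overlap = (grids["[PD,SP,DS]"] > 0) & (grids["[PD,SP,RS]"] > 0)
print(f"\ngrid points where both coexist: {int(overlap.sum())} (regions are disjoint)")
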