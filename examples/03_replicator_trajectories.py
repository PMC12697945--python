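"""Iterate the replicator map for two well-mixed communities.

The one-antibiotic PSD motif always collapses to sensitive fixation in a
well-mixed population, whereas the two-antibiotic circulant [PD,SP,DS]
reaches a stable interior state where all three strains coexist.
"""

import numpy as np

from psdcoex import ModelParams, parse_community, simulate_trajectory

params = ModelParams(
    g=1.0, cr=0.16, cd=1.4 * 0.16, cp=2.5 * 0.16, KP=40, KD=10, jitter_scale=0.0
)
X0 = np.array([0.4, 0.3, 0.3])

for notation in ["[P,S,D]", "[PD,SP,DS]"]:
    res = simulate_trajectory(parse_community(notation), X0, params)
    print(
        f"{notation:12s} terminal state {np.round(res.terminal, 4)} "
        f"after {res.steps} generations "
        f"({'interior: coexistence' if res.is_interior else 'boundary: fixation'})"
    )
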