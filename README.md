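# psdcoex

Which patterns of antibiotic-mediated antagonism let small microbial
communities stably coexist?  `psdcoex` answers this exhaustively for
communities of `N` strains interacting through `M` antibiotics, where each
strain is, per antibiotic, a **p**roducer, **s**ensitive, a **d**egrader, or
intrinsically **r**esistant.  It is a library (plus a thin CLI) for
theoretical ecologists and synthetic-community designers who want to know
which interaction graphs — not which parameter fine-tunings — make
coexistence possible.

The package provides:

* **Interaction graphs** — parse/print the bracket notation (`[PD,SP,DS]`),
  compute PSD-motif coverage, cyclicity (circulant column blocks), canonical
  forms under strain/antibiotic relabelling, and the extension relation.
* **Enumeration** — generate every unique `N x M` community up to
  relabelling, with duplicate strains and duplicate antibiotics removed
  (6 communities at `N=2, M=1`; 6864 at `N=3, M=3`), plus the Stirling-number
  closed-form count for reference.
* **Replicator dynamics** — the discrete-time mixed-inhibition zone model:

  `X_i(t+1) = f_i X_i / Σ_k f_k X_k`,  `f_i = r_i (1 − p_i^kill)`,

  with additive phenotype costs `r_i = g − c_p Σ_j P_ij − c_d Σ_j D_ij − c_r Σ_j R_ij`
  and higher-order kill probabilities
  `p_ij = S_ij e^{−K_D Σ_k D_kj X_k} (1 − e^{−K_P Σ_k P_kj X_k})`,
  combined across antibiotics as independent risks.
* **Stability analysis** — fixed points from 100 Dirichlet(1) starts (damped
  Newton on the simplex chart plus an equal-fitness solve for interior
  points), classification by the spectral radius of the chart Jacobian,
  robustness (1 − spectral radius), and basin-of-attraction fractions.
* **Surveys & sweeps** — exhaustive stability surveys over whole catalogues
  at named cost combinations, structural classification of the stable set,
  and cost-ratio / strength parameter sweeps.
* **Spatial simulation** — a stochastic individual-based model on a periodic
  hexagonal lattice with quasi-static Gaussian plumes of antibiotic and
  degrader enzyme, for studying how spatial structure rescues communities
  (like the one-antibiotic PSD motif) that cannot coexist when well mixed.

## A worked example

```python
import numpy as np
from psdcoex import ModelParams, find_fixed_points, parse_community

community = parse_community("[PD,SP,DS]")   # the circulant 2-PSD community
params = ModelParams(g=1.0, cr=0.16, cd=1.4 * 0.16, cp=2.5 * 0.16,
                     KP=40, KD=10, jitter_scale=0.0)
for rec in find_fixed_points(community, params, rng=np.random.default_rng(0)):
    print(np.round(rec.location, 4), rec.is_interior,
          round(rec.spectral_radius, 4), rec.is_stable)
```

prints

```
[0.0663 0.8425 0.0912] True 0.9496 True
[0. 0. 1.] False 0.7732 True
[0.     0.0064 0.9936] False 1.2556 False
[0. 1. 0.] False 0.6267 True
[0.0117 0.9883 0.    ] False 1.4619 False
[1. 0. 0.] False 2.0638 False
```

The first line is the coexistence state: an interior fixed point at
frequencies (0.066, 0.843, 0.091) whose Jacobian spectral radius 0.9496 < 1
makes it stable — all three strains persist, with the sensitive strain most
abundant.  The remaining lines are boundary fixed points (single-strain
fixation and two-strain faces); stable vertices coexist with the interior
attractor, which captures ~95% of random initial conditions here.

The `examples/` directory has one short script per capability (notation and
descriptors, enumeration, trajectories, fixed points, surveys, sweeps, the
spatial lattice); each prints its results with a line of interpretation.

## Command line

```bash
psdcoex enumerate --n 3 --m 3 --out results/
psdcoex survey  --config survey.yml  --out results/
psdcoex sweep   --config sweep.yml   --out results/
psdcoex spatial --config spatial.yml --out results/
```

Each run writes CSV outputs plus a `manifest.json` recording the exact
configuration, master seed and tool version; reruns with the same manifest
are byte-identical.

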