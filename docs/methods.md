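# Methods

## The model

A community is an `N x M` matrix of discrete phenotypes: strain `i` is,
with respect to antibiotic `j`, a producer (P), sensitive (S), a degrader
(D), or intrinsically resistant (R).  Writing `P`, `S`, `D`, `R` for the
0/1 indicator matrices (which partition the cells), the well-mixed dynamics
is a discrete-time replicator map for relative abundances `X` on the
`(N-1)`-simplex:

    X_i(t+1) = f_i(t) X_i(t) / Σ_k f_k(t) X_k(t),
    f_i = r_i (1 - p_i^kill),
    r_i = g - c_p Σ_j P_ij - c_d Σ_j D_ij - c_r Σ_j R_ij.

Costs are ordered `c_r ≤ c_d ≤ c_p` (private resistance is cheapest,
production dearest); violating this in a sweep is legal and only triggers a
warning.  The kill term is the higher-order interaction.  Individuals are
modelled as a planar Poisson process; each producer (degrader) of
antibiotic `j` projects an effective killing (degradation) zone of area
`K_P` (`K_D`), so at relative abundances `X`,

    p_ij^kill = S_ij · exp(-K_D Σ_k D_kj X_k) · (1 - exp(-K_P Σ_k P_kj X_k)),

i.e. a sensitive individual dies through antibiotic `j` if it sits inside
at least one producer zone and outside all degrader zones.  Antibiotics act
independently, so the per-strain kill probability is
`1 - Π_j (1 - p_ij^kill)`.  This product form is algebraically identical to
the inclusion-exclusion alternating sum (kept as a test oracle) but is
`O(M)` and numerically stable.  The per-antibiotic survival factor is
evaluated as `(1-u) + u·v` with `u = e^{-K_D(...)}`, `v = e^{-K_P(...)}`,
which stays strictly positive where the naive `1 - kill` underflows to zero
(kill within machine epsilon of 1 occurs already at `K_P = 40`).

### Cost jitter

Exactly identical costs across antibiotics create symmetry-induced
edge cases (continua of fixed points, knife-edge eigenvalues).  Surveys
therefore perturb the realized cost of resistance independently per
antibiotic, `c_r^{(j)} = c_r + 0.0005·U(-1,1)`, while `c_d` and `c_p` stay
at their base values.  We deliberately do **not** scale `c_d, c_p` with the
jittered `c_r`: perturbing all three costs moves several knife-edge
communities' leading eigenvalues across 1, making the survey outcome depend
on the jitter draw, whereas jittering only the resistance cost leaves every
classification in the exhaustive surveys invariant across seeds (verified
for the full `(3,3)` survey at three master seeds).  Sweeps that compare
communities switch the jitter off so that only the interaction graph
differs.

## Enumeration

Communities are identified up to relabelling of strains (row permutations)
and antibiotics (column permutations).  The canonical representative of an
orbit is the row-major lexicographic minimum under the frozen letter order
P < S < D < R; since sorting rows minimizes the row-major order for any
fixed column order, only the `M!` column orders are searched.  Catalogues
are generated by building strain sets as sorted combinations of the `4^M`
possible rows (which enforces pairwise-distinct strains and quotients out
row permutations for free), discarding matrices with duplicate columns
(two identical antibiotics are one interaction channel counted twice),
canonicalizing, and deduplicating.  Both redundancy rules are on by
default and pluggable; with them the catalogue has 6 members at
`(N,M) = (2,1)` and 6864 at `(3,3)`.

The closed-form count `(1/N!M!) Σ_{i,j} c(N,i) c(M,j) 4^{ij}` with unsigned
Stirling numbers `c` is exposed as an exact rational.  It is a cycle-count
approximation, not the exact orbit count (Burnside's lemma needs gcds of
cycle lengths, not products of cycle counts), and is reported for reference
only; the enumeration itself is validated against a vectorized brute-force
orbit count for `N, M ≤ 3`.

## Fixed points and stability

Because the map conserves the simplex, all stability analysis happens in
the `(N-1)`-dimensional chart that drops the last coordinate; this removes
the neutral direction induced by normalization from the Jacobian spectrum.

Fixed points are searched from `n_init = 100` Dirichlet(1) draws (uniform
on the simplex) in two batched passes:

1. **Map residual solve** — damped Newton on `G(y) = F_c(y) - y` with
   central-difference Jacobians (step `1e-7`), step halving (up to six
   times), and projection (clip + renormalize) back onto the simplex;
   starts that stall are nudged by direct map iteration, and persistent
   non-converging starts fall back to 500 map iterations followed by a
   fresh Newton attempt.  This pass finds boundary fixed points and
   well-conditioned interior ones.
2. **Equal-fitness solve** — on the interior of the simplex `F(X) = X` is
   equivalent to all fitnesses being equal, and the system
   `f_i(X) - f_N(X) = 0` is far better conditioned near the boundary, where
   the map's Newton basins collapse onto the faces.  This pass reliably
   recovers interior fixed points that hug a face (several stable
   coexistence states have a strain frequency near 0.02).

The `N` vertices are exact fixed points and are always included.
Candidates are deduplicated at sup-norm distance `1e-6` and must satisfy
the residual contract `|F(x*) - x*|_∞ < 1e-10`.  Each fixed point is
classified by the spectral radius ρ of the chart Jacobian (central
differences, step `1e-7`): *stable* iff `ρ < 1 - 1e-6`.  The margin is set
above the finite-difference noise floor (~`1e-7`) because several
communities possess non-isolated continua of interior fixed points whose
exact ρ is 1; with a smaller margin, numerical noise sprinkles spurious
"stable" classifications across these continua.  The smallest genuine
stable gap observed at the survey combinations is `1 - ρ ≈ 0.015`, three
orders of magnitude above the margin.  Borderline points
(`|ρ - 1| < 1e-6`) are reported with a flag.

A fixed point is *interior* when every frequency exceeds `1e-6`.
Robustness is `max(0, 1 - ρ)` for stable interior points and 0 otherwise.
The basin fraction is the share of Dirichlet(1)-started trajectories whose
terminal state (iterated until the per-step change drops below `1e-12`,
capped at `1e5` steps) lies within `1e-4` (sup-norm) of a stable interior
fixed point.  Trajectory iteration uses convergence tolerance `1e-13`
(sup-norm step change) and `1e5` max steps by default; none of these
tolerances are externally prescribed, so they are frozen here.

## Surveys, classification, and reproducibility

A survey enumerates the `(N, M)` catalogue and runs the fixed-point
analysis for every member at a named parameter combination.  The two
built-in combinations share `g = 1, c_r = 0.16, K_P = 40, K_D = 10` and
differ in relative costs: *low* (`c_d = 1.4 c_r, c_p = 2.5 c_r`) and *high*
(`c_d = 2.2083 c_r, c_p = 2.7624 c_r`).  Stable `(3,3)` communities are
classified into four structural categories, in precedence order: full PSD
coverage and fully circulant (`circulant-3PSD`); full coverage but not
fully circulant (`acirculant-3PSD`); extensions of the circulant 2-PSD
community `[PD,SP,DS]`; extensions of the near-circulant `[PD,SP,RS]`.
Full-coverage communities are classified by coverage even when they are
also extensions, matching the convention that the acirculant 3-PSD
community is its own category.

Per-community random substreams are derived by hashing the canonical
notation (SHA-256) together with the master seed through a `SeedSequence`,
so adding or removing communities never shifts another community's draws,
and results are independent of execution order.  Surveys evaluate the basin
fraction only for communities that have a stable interior fixed point (it
is zero by definition otherwise).

One surveyed quantity is knowingly contentious: at the high-cost
combination the survey reports four stable `(3,3)` communities, not three.
The fourth is `[PSS,SSR,DSP]`, which is `[PD,SP,RS]` plus an all-sensitive
antibiotic column; such a column has no producer and carries no cost, so
this community's dynamics are *identical* to those of `[PD,SP,RS]`, which
is stable at the high-cost combination.  Its interior fixed point hugs the
simplex boundary (smallest frequency ≈ 0.025), which is exactly the regime
the equal-fitness pass exists for; solvers without such a pass can miss it.
The analogous all-sensitive extension of `[PD,SP,DS]` is a perfectly
ordinary member of the low-cost stable set.

## The spatial model

The lattice model emulates a surface-grown community: microbes occupy a
rhombic `L x L` torus of hexagonal sites (axial coordinates; six neighbours
each), with birth, death, local dispersal, and explicitly diffusing
chemicals.  Chemical kinetics are assumed fast relative to cell division
(quasi-static): each generation the fields are recomputed from scratch as

    field_j = amount · (source map) ∗ G_K,   G_K(r) = exp(-r² / 2K),

an unnormalized Gaussian plume truncated at `3√K` (periodic FFT
convolution; distances are Euclidean in the hexagonal embedding with
minimum-image wrap).  Leaving the kernel unnormalized makes a larger
diffusivity `K` widen the plume *and* raise total exposure, so `K_P` plays
the same qualitative role as the well-mixed antibiotic strength.  At `K = 0`
the kernel is a point mass: the chemical never leaves its source site.

Sites are visited once per generation in a fresh random order.  An occupied
site first risks death: the local effective antibiotic concentration is
`a_eff = a · e^{-e}` (the enzyme field `e` attenuates exponentially), the
per-antibiotic kill probability for a sensitive strain is `1 - e^{-a_eff}`,
kills compose across antibiotics as independent events, and the result
composes with the baseline death probability `d` as independent risks,
`p_death = 1 - (1-d)(1-q)`.  A survivor gives birth with probability equal
to its net growth rate (`g` minus additive phenotype costs, validated to
lie in `(0, 1]`) into a uniformly chosen empty neighbour; newborns are not
visited in the generation of their birth.  All randomness is pre-drawn from
one numpy generator per run, so runs are bit-reproducible given seed and
parameters; the inner site loop is compiled with numba.

Default demography follows the regime used throughout the spatial
experiments: `g = 0.7, d = 0.3, c_r = 0.05, c_d = 0.105, c_p = 0.15`,
secretion amounts `u_p = u_d = 10`, grid 200 x 200 (interpreting "grid
size 200" as the side length — single-strain patches and refugia only make
sense with thousands of sites), initial occupancy `p = 0.5` with uniformly
random strain labels.  The initial occupancy fraction is not externally
specified; 0.5 leaves room for the contact process to expand and is held
constant across replicates.  Phase diagrams run replicate simulations per
`(K_P, K_D)` grid point and average per-strain site fractions over the last
`tail` generations (default 500) and across replicates.

### What the reduced-scale checks do and do not show

The test suite exercises the spatial model at 50 x 50 sites, 1000
generations, 5 replicates — roughly a sixteenth of the full spatial scale —
on the one-antibiotic PSD motif, asserting the three-regime structure of
the diffusivity plane: degrader fixation at small enzyme reach, sensitive
dominance at moderate reach, and three-strain coexistence beyond
(`K_P ∈ {2, 4}`, `K_D ∈ {0.25, 0.75, 1.25}`).  Near regime boundaries the
long-term outcome is genuinely bimodal across replicates (whether a patch
of sensitive individuals outlives the producers decides the winner), so
assertions are placed at points comfortably inside each regime and on
replicate means.  Passing these checks demonstrates the mechanism —
spatial structure rescues a motif that deterministically collapses when
well mixed — not the quantitative phase boundaries of a full-scale run,
which shift with lattice size and horizon.

The synthetic setting idealizes real communities in the usual ways: discrete
non-overlapping generations, identical per-capita parameters within a
strain, no mutation or gene transfer, chemicals with a single diffusivity
each, and no nutrient limitation.  Conclusions about which *graphs* admit
coexistence are exact within the model; the mapping to any particular
organism's parameters is not calibrated.

## Numerical and design choices (summary)

- Canonical letter order frozen as P < S < D < R; any fixed order works,
  one must be frozen for reproducible canonical strings.
- Cyclicity of a single column is 1 (vacuously circulant); the measure is
  maximized over row orderings because communities are defined only up to
  strain permutation, and is invariant to the rotation direction.
- Enumeration guarded at `N, M ≤ 5`.
- Stability margin `1e-6`, dedup `1e-6`, residual `1e-10`, FD step `1e-7`,
  interiority `1e-6`, basin match `1e-4` — all frozen as above.
- Exhaustive surveys use 100 starts per community and jitter on; sweeps use
  jitter off.  Survey results at `(3,3)` are invariant across master seeds.
- The spatial kernel, dose-response (`1 - e^{-a_eff}`), exponential enzyme
  attenuation, and independent-risk death composition are this package's
  concrete instantiation of "explicit diffusion with fast chemistry"; they
  were chosen for consistency with the exponential zone model of the
  well-mixed dynamics.
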