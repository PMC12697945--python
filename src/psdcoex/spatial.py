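"""Stochastic individual-based simulation on a hexagonal lattice.

Microbes live on a rhombic ``L x L`` torus of hexagonal sites (axial
coordinates ``(q, r)`` with periodic wrap; every site has exactly six
neighbours).  Each generation:

1. Antibiotic and degrader-enzyme concentration fields are recomputed from
   scratch from the current cell positions (quasi-static assumption:
   chemical kinetics are fast relative to cell division).  Every producer
   (resp. degrader) of antibiotic j deposits an unnormalized isotropic
   Gaussian plume ``u * exp(-r^2 / (2K))`` truncated at ``3 sqrt(K)``, where
   ``r`` is the Euclidean distance in the hexagonal embedding and ``K`` the
   diffusivity.  Unnormalized, so a larger ``K`` simultaneously widens the
   plume and raises total exposure.
2. Sites are visited in a fresh random order.  An occupied site first risks
   death: the local effective antibiotic concentration is attenuated
   exponentially by the local enzyme field, ``a_eff = a * exp(-e)``, the
   per-antibiotic kill probability is ``1 - exp(-a_eff)`` for sensitive
   strains (zero otherwise), kill events for different antibiotics are
   independent, and the antibiotic risk composes with the baseline death
   probability ``d`` as independent risks.  A survivor then gives birth with
   probability equal to its net growth rate (base rate minus additive
   phenotype costs) into a uniformly chosen empty neighbour, if any.
   Newborns are not visited in the generation of their birth.

All randomness is drawn from a single numpy Generator per run; the update
loop itself is deterministic given those draws, so whole runs are
bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit

from .community import Community, Phenotype

__all__ = [
    "SpatialParams",
    "LatticeState",
    "NEIGHBOR_OFFSETS",
    "hex_min_image_distance",
    "diffusion_kernel",
    "init_lattice",
    "compute_fields",
    "step_generation",
    "run_simulation",
    "run_phase_diagram",
    "SimulationResult",
]

#: Axial-coordinate offsets of the six hexagonal neighbours.
NEIGHBOR_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))

EMPTY = -1


@dataclass(frozen=True)
class SpatialParams:
    """Demography, chemistry and geometry of the lattice model.

    ``g`` is the per-generation birth probability scale, ``d`` the baseline
    death probability; ``cr, cd, cp`` the additive phenotype costs
    (probability units); ``KP, KD`` the antibiotic and enzyme diffusivities
    (squared lattice units per generation); ``up, ud`` the per-individual
    secretion amounts (concentration units).
    """

    g: float = 0.7
    d: float = 0.3
    cr: float = 0.05
    cd: float = 0.105
    cp: float = 0.15
    KP: float = 4.0
    KD: float = 4.0
    up: float = 10.0
    ud: float = 10.0
    grid_size: int = 200
    p_init: float = 0.5
    generations: int = 6000
    replicates: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("baseline death probability d must be in [0, 1]")
        if self.grid_size < 2:
            raise ValueError("grid_size must be at least 2")
        if not 0.0 <= self.p_init <= 1.0:
            raise ValueError("initial occupancy p_init must be in [0, 1]")
        if self.KP < 0 or self.KD < 0:
            raise ValueError("diffusivities must be nonnegative")

    def birth_probabilities(self, community: Community) -> np.ndarray:
        """Net growth rate per strain, g minus additive phenotype costs."""
        P = community.indicator(Phenotype.P)
        D = community.indicator(Phenotype.D)
        R = community.indicator(Phenotype.R)
        r = self.g - P.sum(1) * self.cp - D.sum(1) * self.cd - R.sum(1) * self.cr
        if np.any(r <= 0) or np.any(r > 1):
            raise ValueError(
                "birth probabilities g - costs must lie in (0, 1] for every strain"
            )
        return r


@dataclass
class LatticeState:
    """Occupancy grid plus per-antibiotic chemical fields."""

    occupancy: np.ndarray  # (L, L) int8, EMPTY or strain index
    antibiotic_fields: np.ndarray  # (M, L, L) float64, >= 0
    enzyme_fields: np.ndarray  # (M, L, L) float64, >= 0
    generation: int = 0

    @property
    def grid_size(self) -> int:
        return self.occupancy.shape[0]

    def strain_counts(self, n_strains: int) -> np.ndarray:
        return np.bincount(
            self.occupancy[self.occupancy >= 0].ravel(), minlength=n_strains
        )

    def occupied_fraction(self) -> float:
        return float(np.mean(self.occupancy >= 0))


def hex_min_image_distance(L: int) -> np.ndarray:
    """Euclidean distance from the origin to every (dq, dr) offset.

    Axial coordinates embed as x = q + r/2, y = r*sqrt(3)/2; periodicity is
    independent in q and r (rhombic torus), so the minimum is taken over the
    four periodic images of each offset.
    """
    dq = np.arange(L)
    dr = np.arange(L)
    best = None
    for sq in (0, -L):
        for sr in (0, -L):
            q = (dq + sq)[:, None].astype(np.float64)
            r = (dr + sr)[None, :].astype(np.float64)
            x = q + r / 2.0
            y = r * (np.sqrt(3.0) / 2.0)
            dist = np.sqrt(x * x + y * y)
            best = dist if best is None else np.minimum(best, dist)
    return best


@lru_cache(maxsize=32)
def _kernel_fft(L: int, K: float) -> np.ndarray:
    return np.fft.rfft2(diffusion_kernel(L, K))


def diffusion_kernel(L: int, K: float) -> np.ndarray:
    """Unnormalized Gaussian plume kernel on the hexagonal torus.

    ``exp(-r^2 / (2K))`` truncated at ``3 sqrt(K)``; for K = 0 the kernel is
    a unit point mass at the origin (the chemical does not leave its source
    site).
    """
    dist = hex_min_image_distance(L)
    if K == 0.0:
        kern = np.zeros((L, L))
        kern[0, 0] = 1.0
        return kern
    kern = np.exp(-(dist**2) / (2.0 * K))
    kern[dist > 3.0 * np.sqrt(K)] = 0.0
    return kern


def init_lattice(
    sp: SpatialParams, community: Community, rng: np.random.Generator
) -> LatticeState:
    """Bernoulli(p_init) occupancy with uniformly random strain labels."""
    L, n, m = sp.grid_size, community.n_strains, community.n_antibiotics
    occupied = rng.random((L, L)) < sp.p_init
    labels = rng.integers(0, n, size=(L, L))
    occ = np.where(occupied, labels, EMPTY).astype(np.int8)
    zeros = np.zeros((m, L, L))
    return LatticeState(occ, zeros, zeros.copy(), generation=0)


def compute_fields(
    state: LatticeState, community: Community, sp: SpatialParams
) -> LatticeState:
    """Recompute the chemical fields from the current occupancy (in place).

    For each antibiotic, the field is the secretion amount times the
    periodic convolution of the producer (resp. degrader) source map with
    the Gaussian plume kernel.  Linear in the sources; deterministic.
    """
    L = state.grid_size
    arr = community.as_array()
    kp_fft = _kernel_fft(L, float(sp.KP))
    kd_fft = _kernel_fft(L, float(sp.KD))
    for j in range(community.n_antibiotics):
        producers = np.flatnonzero(arr[:, j] == int(Phenotype.P))
        degraders = np.flatnonzero(arr[:, j] == int(Phenotype.D))
        src_p = np.isin(state.occupancy, producers).astype(np.float64)
        src_d = np.isin(state.occupancy, degraders).astype(np.float64)
        if src_p.any():
            conv = np.fft.irfft2(np.fft.rfft2(src_p) * kp_fft, s=(L, L))
            state.antibiotic_fields[j] = sp.up * np.maximum(conv, 0.0)
        else:
            state.antibiotic_fields[j] = 0.0
        if src_d.any():
            conv = np.fft.irfft2(np.fft.rfft2(src_d) * kd_fft, s=(L, L))
            state.enzyme_fields[j] = sp.ud * np.maximum(conv, 0.0)
        else:
            state.enzyme_fields[j] = 0.0
    return state


def _death_probabilities(
    state: LatticeState, community: Community, sp: SpatialParams
) -> np.ndarray:
    """Per-strain, per-site death probability (N, L, L)."""
    S = community.indicator(Phenotype.S)  # (N, M)
    a_eff = state.antibiotic_fields * np.exp(-state.enzyme_fields)  # (M, L, L)
    kill_j = -np.expm1(-a_eff)  # (M, L, L), in [0, 1)
    # survival of strain i against antibiotic j: 1 - S_ij * kill_j
    surv = 1.0 - S[:, :, None, None] * kill_j[None, :, :, :]
    q = 1.0 - np.prod(surv, axis=1)  # (N, L, L)
    return 1.0 - (1.0 - sp.d) * (1.0 - q)


@njit(cache=True)
def _update_sites(occ, death_prob, birth_prob, order, u_death, u_birth, u_nbr, born):
    L = occ.shape[0]
    for t in range(order.shape[0]):
        site = order[t]
        q = site // L
        r = site - q * L
        s = occ[q, r]
        if s < 0 or born[q, r] == 1:
            continue
        if u_death[t] < death_prob[s, q, r]:
            occ[q, r] = -1
            continue
        if u_birth[t] < birth_prob[s]:
            # collect empty neighbours (hexagonal, periodic)
            n_empty = 0
            eq = np.empty(6, dtype=np.int64)
            er = np.empty(6, dtype=np.int64)
            for k in range(6):
                if k == 0:
                    nq, nr = q + 1, r
                elif k == 1:
                    nq, nr = q - 1, r
                elif k == 2:
                    nq, nr = q, r + 1
                elif k == 3:
                    nq, nr = q, r - 1
                elif k == 4:
                    nq, nr = q + 1, r - 1
                else:
                    nq, nr = q - 1, r + 1
                nq %= L
                nr %= L
                if occ[nq, nr] < 0:
                    eq[n_empty] = nq
                    er[n_empty] = nr
                    n_empty += 1
            if n_empty > 0:
                pick = int(u_nbr[t] * n_empty)
                if pick == n_empty:  # guard u == 1.0
                    pick = n_empty - 1
                occ[eq[pick], er[pick]] = s
                born[eq[pick], er[pick]] = 1


def step_generation(
    state: LatticeState,
    community: Community,
    sp: SpatialParams,
    rng: np.random.Generator,
    birth_prob: np.ndarray | None = None,
) -> LatticeState:
    """Advance the lattice by one generation (in place).

    Fields are recomputed for the current occupancy, then every site is
    visited once in a fresh random order; deaths are decided before births
    at each visited site, and newborns are skipped until the next
    generation.
    """
    if birth_prob is None:
        birth_prob = sp.birth_probabilities(community)
    compute_fields(state, community, sp)
    death_prob = _death_probabilities(state, community, sp)
    L = state.grid_size
    order = rng.permutation(L * L)
    u = rng.random((3, L * L))
    born = np.zeros((L, L), dtype=np.uint8)
    _update_sites(
        state.occupancy, death_prob, birth_prob, order, u[0], u[1], u[2], born
    )
    state.generation += 1
    return state


@dataclass
class SimulationResult:
    """Abundance time series of one lattice run."""

    abundances: np.ndarray  # (generations + 1, N) site fractions
    occupied: np.ndarray  # (generations + 1,) occupied fraction
    final_state: LatticeState


def run_simulation(
    community: Community,
    sp: SpatialParams,
    rng: np.random.Generator | None = None,
    generations: int | None = None,
) -> SimulationResult:
    """Run one replicate and record per-strain site fractions over time."""
    if rng is None:
        rng = np.random.default_rng(sp.seed)
    if generations is None:
        generations = sp.generations
    n = community.n_strains
    L2 = sp.grid_size**2
    birth_prob = sp.birth_probabilities(community)
    state = init_lattice(sp, community, rng)
    abundances = np.zeros((generations + 1, n))
    occupied = np.zeros(generations + 1)
    abundances[0] = state.strain_counts(n) / L2
    occupied[0] = state.occupied_fraction()
    for t in range(1, generations + 1):
        step_generation(state, community, sp, rng, birth_prob)
        abundances[t] = state.strain_counts(n) / L2
        occupied[t] = state.occupied_fraction()
    return SimulationResult(abundances, occupied, state)


def run_phase_diagram(
    community: Community,
    sp: SpatialParams,
    KP_values: np.ndarray,
    KD_values: np.ndarray,
    replicates: int | None = None,
    generations: int | None = None,
    seed: int | None = None,
    tail: int = 500,
) -> np.ndarray:
    """Mean terminal abundances across a (KP, KD) diffusivity grid.

    For each grid point, ``replicates`` independent runs are performed with
    different initial configurations (same occupancy fraction); per-strain
    site fractions are averaged over the last ``tail`` recorded generations
    of each run and across replicates.  Returns an array of shape
    ``(len(KP_values), len(KD_values), N)``.
    """
    from dataclasses import replace

    if replicates is None:
        replicates = sp.replicates
    if generations is None:
        generations = sp.generations
    if seed is None:
        seed = sp.seed
    tail = min(tail, generations)
    n = community.n_strains
    out = np.zeros((len(KP_values), len(KD_values), n))
    for a, kp in enumerate(KP_values):
        for b, kd in enumerate(KD_values):
            spl = replace(sp, KP=float(kp), KD=float(kd))
            acc = np.zeros(n)
            for rep in range(replicates):
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, a, b, rep])
                )
                res = run_simulation(community, spl, rng, generations)
                acc += res.abundances[-tail:].mean(axis=0)
            out[a, b] = acc / replicates
    return out
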