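"""Well-mixed population dynamics: the mixed-inhibition zone model.

Strain frequencies evolve by a discrete-time replicator map

    X_i(t+1) = f_i(t) X_i(t) / sum_k f_k(t) X_k(t),

with fitness f_i = r_i (1 - p_i^kill).  The growth rate r_i is a base rate g
reduced additively by the metabolic costs of the strain's phenotypes
(production cp, degradation cd, intrinsic resistance cr, summed over
antibiotics).  The kill probability encodes the higher-order interaction:
strain i can only be killed by antibiotic j if it is sensitive to j, lies
inside the inhibition zone of at least one producer, and outside every
degradation zone.  Modelling individuals as a spatial Poisson process, zone
areas K_P and K_D turn frequencies into exposure probabilities:

    p_ij = S_ij * exp(-K_D * sum_k D_kj X_k) * (1 - exp(-K_P * sum_k P_kj X_k)).

Deaths by different antibiotics are independent, so the probability of dying
by at least one antibiotic is 1 - prod_j (1 - p_ij); this product form is
algebraically identical to the inclusion-exclusion alternating sum and is
numerically stabler (and O(M) instead of O(2^M)).

All state-dependent functions accept batched inputs: ``X`` may carry any
number of leading axes, with strains on the last axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .community import Community, Phenotype

__all__ = [
    "ModelParams",
    "RealizedCosts",
    "ExtinctionError",
    "NonviableStrainError",
    "realized_costs",
    "growth_rates",
    "kill_probabilities",
    "fitness",
    "replicator_step",
    "update_map",
    "simulate_trajectory",
    "TrajectoryResult",
    "INTERIOR_THRESHOLD",
]

#: A frequency below this is treated as an extinct strain when deciding
#: whether a state is interior (full coexistence).
INTERIOR_THRESHOLD = 1e-6


class ExtinctionError(RuntimeError):
    """Total weighted fitness vanished: the whole community went extinct."""


class NonviableStrainError(ValueError):
    """A strain's phenotype costs exceed its base growth rate."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the mixed-inhibition zone model.

    g is the base growth rate per generation; cr, cd, cp the costs of
    intrinsic resistance, degradation, and production (growth-rate units);
    KP and KD the effective killing and degradation areas (dimensionless
    strengths); jitter_scale the half-width of the per-antibiotic uniform
    perturbation applied to the realized cost of resistance.
    """

    g: float = 1.0
    cr: float = 0.16
    cd: float = 0.224  # 1.4 * 0.16, the low-relative-cost default
    cp: float = 0.4  # 2.5 * 0.16
    KP: float = 40.0
    KD: float = 10.0
    jitter_scale: float = 0.0005

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("base growth rate g must be positive")
        if self.KP < 0 or self.KD < 0:
            raise ValueError("strengths KP, KD must be nonnegative")
        if not (0 <= self.cr <= self.cd <= self.cp):
            # sweeps legitimately cross the expected ordering, so warn only
            warnings.warn(
                "cost ordering 0 <= cr <= cd <= cp violated", stacklevel=3
            )

    def with_ratios(self, cd_over_cr: float, cp_over_cr: float) -> "ModelParams":
        """Same parameters with cd, cp set from ratios to cr."""
        return replace(
            self, cd=cd_over_cr * self.cr, cp=cp_over_cr * self.cr
        )


@dataclass(frozen=True)
class RealizedCosts:
    """Per-antibiotic cost vectors (length M), possibly jittered."""

    cr_j: np.ndarray
    cd_j: np.ndarray
    cp_j: np.ndarray

    @property
    def n_antibiotics(self) -> int:
        return len(self.cr_j)


def realized_costs(
    params: ModelParams, n_antibiotics: int, rng: np.random.Generator | None = None
) -> RealizedCosts:
    """Draw the per-antibiotic realized costs.

    The realized cost of resistance for antibiotic j is
    cr + jitter_scale * Uniform(-1, 1), drawn independently per antibiotic;
    the degradation and production costs are kept at their base values, so
    the perturbation breaks exact cost degeneracies between antibiotics
    without moving the swept cd and cp.  With jitter_scale = 0 the base
    costs are reproduced exactly and no random numbers are consumed.
    """
    if n_antibiotics < 1:
        raise ValueError("need at least one antibiotic")
    if params.cr == 0.0 and (params.cd != 0.0 or params.cp != 0.0):
        raise ValueError(
            "cr = 0 with nonzero cd or cp breaks the assumed cost ordering"
        )
    if params.jitter_scale == 0.0:
        cr_j = np.full(n_antibiotics, params.cr)
    else:
        if rng is None:
            raise ValueError("jittered costs need a random generator")
        cr_j = params.cr + params.jitter_scale * rng.uniform(-1, 1, n_antibiotics)
    return RealizedCosts(
        cr_j=cr_j,
        cd_j=np.full(n_antibiotics, params.cd),
        cp_j=np.full(n_antibiotics, params.cp),
    )


def growth_rates(
    community: Community, costs: RealizedCosts, g: float
) -> np.ndarray:
    """Effective growth rates r_i = g - sum_j (cp_j P_ij + cd_j D_ij + cr_j R_ij).

    Sensitivity carries no cost.  Raises :class:`NonviableStrainError` if any
    strain's costs drive its growth rate to zero or below.
    """
    if costs.n_antibiotics != community.n_antibiotics:
        raise ValueError("cost vectors must have length M")
    P = community.indicator(Phenotype.P)
    D = community.indicator(Phenotype.D)
    R = community.indicator(Phenotype.R)
    r = g - P @ costs.cp_j - D @ costs.cd_j - R @ costs.cr_j
    if np.any(r <= 0):
        bad = int(np.argmin(r))
        raise NonviableStrainError(
            f"strain {bad} of {community.notation} has growth rate "
            f"{r[bad]:.4f} <= 0 at these costs"
        )
    return r


def kill_probabilities(
    community: Community, X: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Per-strain probability of death by at least one antibiotic.

    ``X`` has strains on the last axis; any leading batch axes are allowed.
    Returns an array of the same shape.
    """
    X = np.asarray(X, dtype=np.float64)
    P = community.indicator(Phenotype.P)
    D = community.indicator(Phenotype.D)
    S = community.indicator(Phenotype.S)
    s_j = _survival_factors(X, P, D, params.KP, params.KD)
    surv = np.prod(np.where(S > 0, s_j[..., None, :], 1.0), axis=-1)
    return 1.0 - surv


def _survival_factors(
    X: np.ndarray, P: np.ndarray, D: np.ndarray, KP: float, KD: float
) -> np.ndarray:
    """Per-antibiotic survival probability of a sensitive strain, shape (..., M).

    Computed as (1 - u) + u v with u = exp(-KD * degrader zone) and
    v = exp(-KP * producer zone).  This form stays strictly positive even
    when the kill probability u (1 - v) is within machine epsilon of 1,
    where the naive 1 - kill would underflow to exactly zero.
    """
    u = np.exp(-KD * (X @ D))
    v = np.exp(-KP * (X @ P))
    return (1.0 - u) + u * v


def fitness(
    community: Community,
    X: np.ndarray,
    params: ModelParams,
    costs: RealizedCosts | None = None,
    r: np.ndarray | None = None,
) -> np.ndarray:
    """Fitness f_i = r_i (1 - p_i^kill) at state X (batched)."""
    if r is None:
        if costs is None:
            costs = realized_costs(
                replace(params, jitter_scale=0.0), community.n_antibiotics
            )
        r = growth_rates(community, costs, params.g)
    return r * (1.0 - kill_probabilities(community, X, params))


def replicator_step(X: np.ndarray, f: np.ndarray) -> np.ndarray:
    """One step of the discrete replicator map, X' = f X / sum(f X).

    Batched over leading axes.  Raises :class:`ExtinctionError` when the
    weighted fitness sum vanishes (total extinction).
    """
    X = np.asarray(X, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("fitness must be entrywise nonnegative")
    w = f * X
    total = w.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ExtinctionError("all strains extinct: fitness-weighted sum is zero")
    return w / total


def update_map(
    community: Community,
    params: ModelParams,
    costs: RealizedCosts | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Compile the one-generation update F: X(t) -> X(t+1) for repeated use.

    Precomputes the phenotype indicator matrices and growth rates; the
    returned callable is batched over leading axes of X.
    """
    if costs is None:
        costs = realized_costs(
            replace(params, jitter_scale=0.0), community.n_antibiotics
        )
    r = growth_rates(community, costs, params.g)
    P = community.indicator(Phenotype.P)
    D = community.indicator(Phenotype.D)
    S = community.indicator(Phenotype.S)
    KP, KD = params.KP, params.KD

    S_mask = S > 0

    def F(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        s_j = _survival_factors(X, P, D, KP, KD)
        surv = np.prod(np.where(S_mask, s_j[..., None, :], 1.0), axis=-1)
        w = (r * surv) * X
        total = w.sum(axis=-1, keepdims=True)
        if np.any(total <= 0):
            # fitness is strictly positive, so a non-positive total can only
            # happen at off-simplex probe points (finite-difference steps
            # across the boundary); treat those as mapping to zero rather
            # than aborting the solve
            on_simplex = (np.abs(X.sum(-1) - 1.0) < 1e-9) & (X.min(-1) >= 0.0)
            if np.any((total[..., 0] <= 0) & on_simplex):
                raise ExtinctionError(
                    "all strains extinct: fitness-weighted sum is zero"
                )
            total = np.where(total <= 0, np.inf, total)
        return w / total

    return F


def fitness_map(
    community: Community,
    params: ModelParams,
    costs: RealizedCosts | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Compile the fitness function X -> f(X) = r * (1 - p^kill) for reuse.

    Like :func:`update_map` but without the replicator normalization;
    batched over leading axes of X.
    """
    if costs is None:
        costs = realized_costs(
            replace(params, jitter_scale=0.0), community.n_antibiotics
        )
    r = growth_rates(community, costs, params.g)
    P = community.indicator(Phenotype.P)
    D = community.indicator(Phenotype.D)
    S_mask = community.indicator(Phenotype.S) > 0
    KP, KD = params.KP, params.KD

    def fit(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        s_j = _survival_factors(X, P, D, KP, KD)
        return r * np.prod(np.where(S_mask, s_j[..., None, :], 1.0), axis=-1)

    return fit


@dataclass
class TrajectoryResult:
    """Iterates of the replicator map from one initial condition."""

    states: np.ndarray  # (n_recorded, N)
    terminal: np.ndarray  # (N,)
    converged: bool
    steps: int
    is_interior: bool


def simulate_trajectory(
    community: Community,
    X0: np.ndarray,
    params: ModelParams,
    costs: RealizedCosts | None = None,
    max_steps: int = 100_000,
    tol: float = 1e-13,
    record_every: int = 1,
) -> TrajectoryResult:
    """Iterate the replicator map until the sup-norm step change is < tol.

    Returns the recorded states (every ``record_every`` steps plus the
    terminal state), the terminal state, whether the iteration converged
    before ``max_steps``, and whether the terminal state is interior (all
    frequencies above :data:`INTERIOR_THRESHOLD`).
    """
    X = np.asarray(X0, dtype=np.float64)
    if X.ndim != 1:
        raise ValueError("X0 must be a single state vector")
    if np.any(X < 0) or abs(X.sum() - 1.0) > 1e-12:
        raise ValueError("X0 must lie on the probability simplex")
    F = update_map(community, params, costs)
    states = [X.copy()]
    converged = False
    step = 0
    for step in range(1, max_steps + 1):
        X_new = F(X)
        delta = np.max(np.abs(X_new - X))
        X = X_new
        if step % record_every == 0:
            states.append(X.copy())
        if delta < tol:
            converged = True
            break
    if step % record_every != 0 or not states:
        states.append(X.copy())
    return TrajectoryResult(
        states=np.asarray(states),
        terminal=X,
        converged=converged,
        steps=step,
        is_interior=bool(np.all(X > INTERIOR_THRESHOLD)),
    )
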