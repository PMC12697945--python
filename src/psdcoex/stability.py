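"""Fixed points of the replicator map and their stability.

The replicator map conserves the probability simplex, so fixed points are
located in the (N-1)-dimensional simplex chart obtained by dropping the last
coordinate; the trivial direction induced by normalization then cannot
pollute the Jacobian spectrum.  A fixed point is stable when the spectral
radius of the chart Jacobian is below 1 (discrete-time criterion), and its
robustness to dynamical perturbations is 1 minus that spectral radius
(clamped to [0, 1]; zero for unstable or boundary points).

Fixed points are found by damped Newton iteration started from Dirichlet(1)
draws on the simplex (uniform sampling), batched across starts; starts that
leave the simplex are projected back by clipping and renormalization, and
starts that fail to converge fall back to direct map iteration.  Vertices
(single-strain fixation) are exact fixed points of the map and are always
included in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import Community
from .dynamics import (
    INTERIOR_THRESHOLD,
    ModelParams,
    RealizedCosts,
    fitness_map,
    update_map,
)

__all__ = [
    "FixedPointRecord",
    "find_fixed_points",
    "jacobian_spectral_radius",
    "basin_fraction",
]

#: Residual contract: |F(x*) - x*|_inf must be below this for a reported
#: fixed point.
RESIDUAL_TOL = 1e-10
#: Sup-norm distance below which two fixed-point candidates are the same.
DEDUP_TOL = 1e-6
#: Finite-difference step for chart Jacobians.
FD_STEP = 1e-7
#: Stability margin: stable iff spectral radius < 1 - STABILITY_MARGIN.
#: Set above the finite-difference noise floor (~1e-7) so that neutral
#: continua of fixed points, whose exact spectral radius is 1, are never
#: misclassified as stable by numerical jitter.
STABILITY_MARGIN = 1e-6
#: Terminal-match tolerance for basin-of-attraction counting.
BASIN_MATCH_TOL = 1e-4


@dataclass(frozen=True)
class FixedPointRecord:
    """One fixed point of the update map with its stability classification."""

    location: np.ndarray  # (N,), on the simplex
    is_interior: bool
    spectral_radius: float
    is_stable: bool
    robustness: float
    residual: float
    borderline: bool = False  # spectral radius within the margin of 1

    @property
    def is_stable_interior(self) -> bool:
        return self.is_stable and self.is_interior


def _lift(Y: np.ndarray) -> np.ndarray:
    """Chart -> simplex: append the complementary coordinate."""
    return np.concatenate([Y, 1.0 - Y.sum(axis=-1, keepdims=True)], axis=-1)


def _project_chart(Y: np.ndarray) -> np.ndarray:
    """Clip + renormalize back onto the simplex, in chart coordinates."""
    X = np.clip(_lift(Y), 0.0, None)
    total = X.sum(axis=-1, keepdims=True)
    total = np.where(total <= 0, 1.0, total)
    X = X / total
    return X[..., :-1]


def _chart_map(F):
    def Fc(Y: np.ndarray) -> np.ndarray:
        return F(_lift(Y))[..., :-1]

    return Fc


def _chart_jacobian(Fc, Y: np.ndarray, step: float = FD_STEP) -> np.ndarray:
    """Central-difference Jacobian of the chart map, batched over rows of Y."""
    d = Y.shape[-1]
    cols = []
    for k in range(d):
        e = np.zeros(d)
        e[k] = step
        cols.append((Fc(Y + e) - Fc(Y - e)) / (2.0 * step))
    return np.stack(cols, axis=-1)  # (..., d_out, d_in)


def _newton_batch(
    G_fun,
    Y0: np.ndarray,
    max_iter: int = 60,
    gtol: float = 1e-13,
    iterate_fallback=None,
    stall_limit: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped Newton solve of G(y) = 0 from a batch of chart starts.

    The Jacobian of G is formed by central differences.  Steps are damped
    (up to six halvings) and projected back onto the simplex.  Returns
    (Y, converged_mask).  Starts whose Newton system is singular or that
    never reduce the residual are nudged by ``iterate_fallback`` (if
    given); without a fallback they are abandoned after ``stall_limit``
    consecutive non-improving iterations (typically: no root exists in
    their region).
    """
    Y = Y0.copy()
    B, d = Y.shape
    active = np.ones(B, dtype=bool)
    converged = np.zeros(B, dtype=bool)
    stalls = np.zeros(B, dtype=np.int64)
    for _ in range(max_iter):
        if not active.any():
            break
        Ya = Y[active]
        G = G_fun(Ya)
        normG = np.max(np.abs(G), axis=-1)
        done = normG < gtol
        if done.any():
            idx = np.flatnonzero(active)[done]
            converged[idx] = True
            active[idx] = False
            keep = ~done
            Ya, G, normG = Ya[keep], G[keep], normG[keep]
            if Ya.size == 0:
                continue
        A = _chart_jacobian(G_fun, Ya)
        det = np.abs(np.linalg.det(A))
        solvable = det > 1e-14
        delta = np.zeros_like(Ya)
        if solvable.any():
            delta[solvable] = np.linalg.solve(
                A[solvable], G[solvable][..., None]
            )[..., 0]
        # damped update with projection back to the simplex
        best = Ya.copy()
        best_norm = normG.copy()
        improved = np.zeros(len(Ya), dtype=bool)
        factor = 1.0
        for _halving in range(6):
            cand = _project_chart(Ya - factor * delta)
            cn = np.max(np.abs(G_fun(cand)), axis=-1)
            take = solvable & (cn < best_norm) & ~improved
            best[take] = cand[take]
            best_norm[take] = cn[take]
            improved |= take
            factor *= 0.5
            if improved.all():
                break
        # starts that could not improve are nudged off the bad region, or
        # abandoned once they have stalled repeatedly
        stuck = ~improved
        idx_active = np.flatnonzero(active)
        if stuck.any() and iterate_fallback is not None:
            best[stuck] = iterate_fallback(Ya[stuck])
        stalls[idx_active[improved]] = 0
        stalls[idx_active[stuck]] += 1
        Y[idx_active] = best
        if iterate_fallback is None:
            dead = stalls[idx_active] >= stall_limit
            active[idx_active[dead]] = False
    # final convergence sweep for anything that landed on a solution late
    rem = active & ~converged
    if rem.any():
        Yr = Y[rem]
        ok = np.max(np.abs(G_fun(Yr)), axis=-1) < gtol
        converged[np.flatnonzero(rem)[ok]] = True
    return Y, converged


def _spectral_radius_at(Fc, y: np.ndarray) -> float:
    J = _chart_jacobian(Fc, y[None, :])[0]
    return float(np.max(np.abs(np.linalg.eigvals(J))))


def find_fixed_points(
    community: Community,
    params: ModelParams,
    n_init: int = 100,
    rng: np.random.Generator | None = None,
    costs: RealizedCosts | None = None,
    fallback_iterations: int = 500,
) -> list[FixedPointRecord]:
    """Locate and classify fixed points from Dirichlet(1) random starts.

    Every vertex of the simplex (single-strain fixation) is included in
    addition to the Newton solutions.  Candidates are deduplicated at
    sup-norm distance 1e-6 and must satisfy the residual contract
    |F(x*) - x*|_inf < 1e-10.  Results are deterministically ordered
    (interior points first, then lexicographically by location).
    """
    n = community.n_strains
    F = update_map(community, params, costs)
    fit = fitness_map(community, params, costs)
    Fc = _chart_map(F)
    if rng is None:
        rng = np.random.default_rng()
    starts = rng.dirichlet(np.ones(n), size=n_init)
    Y0 = starts[:, :-1]

    def G_map(Ya: np.ndarray) -> np.ndarray:
        return Fc(Ya) - Ya

    def map_nudge(Ya: np.ndarray) -> np.ndarray:
        return _project_chart(Fc(Ya))

    Y, conv = _newton_batch(G_map, Y0, iterate_fallback=map_nudge)
    # fallback: iterate the map directly, then re-run Newton from there
    if (~conv).any():
        Yf = Y[~conv]
        for _ in range(fallback_iterations):
            Yf = _project_chart(Fc(Yf))
        Yf, cf = _newton_batch(G_map, Yf, max_iter=30, iterate_fallback=map_nudge)
        Y[~conv] = Yf
        conv_idx = np.flatnonzero(~conv)
        conv[conv_idx] = cf

    # second pass aimed at interior fixed points: on the interior of the
    # simplex, F(X) = X is equivalent to all fitnesses being equal, and the
    # equal-fitness system is far better conditioned near the boundary
    # (the map's Newton basins collapse onto faces there)
    def G_eq(Ya: np.ndarray) -> np.ndarray:
        f = fit(_lift(Ya))
        return f[..., :-1] - f[..., -1:]

    # the equal-fitness system is smooth and has few roots, so a subset of
    # the starts suffices
    Y2, conv2 = _newton_batch(G_eq, Y0[: min(32, len(Y0))], max_iter=40, gtol=1e-12)

    candidates = [_lift(Y[i]) for i in np.flatnonzero(conv)]
    candidates += [_lift(Y2[i]) for i in np.flatnonzero(conv2)]
    # vertices are always fixed points of the replicator map
    for i in range(n):
        v = np.zeros(n)
        v[i] = 1.0
        candidates.append(v)

    records: list[FixedPointRecord] = []
    kept: list[np.ndarray] = []
    for X in candidates:
        if any(np.max(np.abs(X - K)) < DEDUP_TOL for K in kept):
            continue
        residual = float(np.max(np.abs(F(X) - X)))
        if residual > RESIDUAL_TOL:
            continue
        kept.append(X)
        rho = _spectral_radius_at(Fc, X[:-1])
        stable = rho < 1.0 - STABILITY_MARGIN
        borderline = (not stable) and rho < 1.0 + STABILITY_MARGIN
        interior = bool(np.all(X > INTERIOR_THRESHOLD))
        robustness = max(0.0, 1.0 - rho) if (stable and interior) else 0.0
        records.append(
            FixedPointRecord(
                location=X,
                is_interior=interior,
                spectral_radius=rho,
                is_stable=stable,
                robustness=robustness,
                residual=residual,
                borderline=borderline,
            )
        )
    records.sort(
        key=lambda rec: (not rec.is_interior, tuple(np.round(rec.location, 9)))
    )
    return records


def jacobian_spectral_radius(
    community: Community,
    params: ModelParams,
    x_star: np.ndarray,
    costs: RealizedCosts | None = None,
) -> float:
    """Spectral radius of the chart Jacobian of the update map at a fixed point.

    Computed by central finite differences (step 1e-7) on the
    (N-1)-dimensional simplex chart.  Raises if ``x_star`` violates the
    fixed-point residual contract.
    """
    x_star = np.asarray(x_star, dtype=np.float64)
    F = update_map(community, params, costs)
    residual = float(np.max(np.abs(F(x_star) - x_star)))
    if residual > RESIDUAL_TOL:
        raise ValueError(
            f"not a fixed point: residual {residual:.2e} exceeds {RESIDUAL_TOL:.0e}"
        )
    return _spectral_radius_at(_chart_map(F), x_star[:-1])


def basin_fraction(
    community: Community,
    params: ModelParams,
    n_init: int = 100,
    rng: np.random.Generator | None = None,
    costs: RealizedCosts | None = None,
    fixed_points: list[FixedPointRecord] | None = None,
    max_steps: int = 100_000,
) -> float:
    """Fraction of random trajectories attracted to stable interior coexistence.

    Trajectories start from Dirichlet(1) draws and are iterated until the
    per-step sup-norm change falls below 1e-12 (or ``max_steps``); a
    trajectory counts when its terminal state is within 1e-4 (sup-norm) of a
    stable interior fixed point.  Returns 0 when no such point exists.
    """
    if rng is None:
        rng = np.random.default_rng()
    if fixed_points is None:
        fp_rng = np.random.default_rng(rng.integers(2**31))
        fixed_points = find_fixed_points(
            community, params, n_init=n_init, rng=fp_rng, costs=costs
        )
    targets = [r.location for r in fixed_points if r.is_stable_interior]
    if not targets:
        return 0.0
    T = np.stack(targets)
    n = community.n_strains
    F = update_map(community, params, costs)
    X = rng.dirichlet(np.ones(n), size=n_init)
    active = np.ones(n_init, dtype=bool)
    for _ in range(max_steps):
        if not active.any():
            break
        Xa = X[active]
        Xn = F(Xa)
        delta = np.max(np.abs(Xn - Xa), axis=-1)
        X[active] = Xn
        # settled trajectories stop; matching against targets happens below
        settled = delta < 1e-12
        # trajectories already glued to a target can stop early too
        near = (
            np.min(np.max(np.abs(Xn[:, None, :] - T[None, :, :]), axis=-1), axis=-1)
            < BASIN_MATCH_TOL * 1e-2
        )
        idx = np.flatnonzero(active)
        active[idx[settled | near]] = False
    dist = np.min(np.max(np.abs(X[:, None, :] - T[None, :, :]), axis=-1), axis=-1)
    return float(np.mean(dist < BASIN_MATCH_TOL))
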