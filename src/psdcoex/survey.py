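"""Exhaustive stability surveys and parameter sweeps over community space.

A survey walks a community catalogue, runs the fixed-point analysis for
every member at a named parameter combination, and records which topologies
support stable coexistence.  Two canonical combinations are built in:

==========  =====================================
low_cost    cd = 1.4 cr,    cp = 2.5 cr
high_cost   cd = 2.2083 cr, cp = 2.7624 cr
==========  =====================================

both with g = 1.0, cr = 0.16, KP = 40, KD = 10.  Surveys jitter the realized
per-antibiotic costs (scale 5e-4) to remove knife-edge degeneracies of
exactly identical costs; sweeps, which compare communities, switch the
jitter off so only the interaction graph differs.

Per-community random substreams are derived by hashing the canonical
notation together with the master seed, so results are independent of
catalogue order and of which other communities are surveyed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import (
    Community,
    cyclicity,
    is_extension,
    parse_community,
    psd_coverage,
)
from .dynamics import ModelParams, NonviableStrainError, realized_costs
from .enumeration import CommunityCatalogue, enumerate_communities
from .stability import basin_fraction, find_fixed_points

__all__ = [
    "ParameterCombination",
    "LOW_COST",
    "HIGH_COST",
    "SurveyRecord",
    "community_rng",
    "survey_topologies",
    "classify_stable",
    "sweep_cost_grid",
    "sweep_strength_grid",
    "CATEGORIES",
]

CATEGORIES = (
    "circulant-3PSD",
    "extension-of-2PSD-circulant",
    "extension-of-PDSPRS",
    "acirculant-3PSD",
    "other",
)


@dataclass(frozen=True)
class ParameterCombination:
    """A named point in cost/strength space used for exhaustive surveys."""

    label: str
    g: float = 1.0
    cr: float = 0.16
    KP: float = 40.0
    KD: float = 10.0
    cd_over_cr: float = 1.4
    cp_over_cr: float = 2.5

    def model_params(self, jitter_scale: float = 0.0005) -> ModelParams:
        return ModelParams(
            g=self.g,
            cr=self.cr,
            cd=self.cd_over_cr * self.cr,
            cp=self.cp_over_cr * self.cr,
            KP=self.KP,
            KD=self.KD,
            jitter_scale=jitter_scale,
        )


LOW_COST = ParameterCombination("low_cost", cd_over_cr=1.4, cp_over_cr=2.5)
HIGH_COST = ParameterCombination("high_cost", cd_over_cr=2.2083, cp_over_cr=2.7624)


@dataclass
class SurveyRecord:
    """Fixed-point analysis outcome for one community at one combination."""

    community: str  # canonical notation
    combo: str
    n_stable_interior: int
    n_interior: int
    basin_fraction: float
    psd_coverage: int
    cyclicity: int
    max_robustness: float
    category: str = "other"


def community_rng(master_seed: int, notation: str) -> np.random.Generator:
    """Deterministic per-community substream.

    Hashes the canonical notation (SHA-256, stable across processes) and
    mixes it with the master seed through a SeedSequence, so adding or
    removing communities from a survey never shifts another community's
    random draws.
    """
    digest = hashlib.sha256(notation.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))


def _analyse_one(
    community: Community,
    combo: ParameterCombination,
    n_init: int,
    master_seed: int,
    jitter_scale: float,
    compute_basin: str,
) -> SurveyRecord:
    notation = community.canonical().notation
    rng = community_rng(master_seed, f"{combo.label}:{notation}")
    params = combo.model_params(jitter_scale)
    costs = realized_costs(params, community.n_antibiotics, rng)
    try:
        records = find_fixed_points(
            community, params, n_init=n_init, rng=rng, costs=costs
        )
    except NonviableStrainError:
        # costs exceed the growth rate of some strain: no dynamics to run
        return SurveyRecord(
            community=notation,
            combo=combo.label,
            n_stable_interior=0,
            n_interior=0,
            basin_fraction=0.0,
            psd_coverage=psd_coverage(community),
            cyclicity=cyclicity(community),
            max_robustness=0.0,
        )
    stable_interior = [r for r in records if r.is_stable_interior]
    basin = 0.0
    if stable_interior and compute_basin in ("stable", "all"):
        basin = basin_fraction(
            community,
            params,
            n_init=n_init,
            rng=rng,
            costs=costs,
            fixed_points=records,
        )
    return SurveyRecord(
        community=notation,
        combo=combo.label,
        n_stable_interior=len(stable_interior),
        n_interior=sum(r.is_interior for r in records),
        basin_fraction=basin,
        psd_coverage=psd_coverage(community),
        cyclicity=cyclicity(community),
        max_robustness=max((r.robustness for r in stable_interior), default=0.0),
    )


def survey_topologies(
    n_strains: int,
    n_antibiotics: int,
    combo: ParameterCombination,
    n_init: int = 100,
    seed: int = 0,
    jitter_scale: float = 0.0005,
    catalogue: CommunityCatalogue | None = None,
    compute_basin: str = "stable",
) -> list[SurveyRecord]:
    """Fixed-point survey of every unique (N, M) community at one combination.

    ``compute_basin`` controls the basin-of-attraction column: ``"stable"``
    (default) evaluates it only for communities that have a stable interior
    fixed point (it is zero by definition otherwise), ``"none"`` skips it,
    ``"all"`` forces evaluation everywhere.  Results are ordered by
    canonical notation and are independent of execution order.
    """
    if catalogue is None:
        catalogue = enumerate_communities(n_strains, n_antibiotics)
    records = [
        _analyse_one(member, combo, n_init, seed, jitter_scale, compute_basin)
        for member in catalogue
    ]
    for rec in records:
        rec.category = _categorize(parse_community(rec.community)) if (
            rec.n_stable_interior > 0
        ) else "other"
    return records


_PARENT_2PSD = parse_community("[PD,SP,DS]")
_PARENT_PDSPRS = parse_community("[PD,SP,RS]")


def _categorize(c: Community) -> str:
    """Four-way classification of a stable (3, 3) community.

    Communities with full PSD coverage are split by cyclicity into the
    circulant and the acirculant class (the acirculant one is also an
    extension of the two-motif circulant, but full coverage takes
    precedence); the remainder are classified by which smaller circulant
    community they extend.
    """
    if c.n_antibiotics <= 2:
        return "other"
    cov = psd_coverage(c)
    cyc = cyclicity(c)
    if cov == c.n_antibiotics:
        return "circulant-3PSD" if cyc == c.n_antibiotics else "acirculant-3PSD"
    if is_extension(c, _PARENT_2PSD):
        return "extension-of-2PSD-circulant"
    if is_extension(c, _PARENT_PDSPRS):
        return "extension-of-PDSPRS"
    return "other"


def classify_stable(records: list[SurveyRecord]) -> dict[str, int]:
    """Tally of stable communities by structural category."""
    tally = {cat: 0 for cat in CATEGORIES}
    for rec in records:
        if rec.n_stable_interior > 0:
            tally[_categorize(parse_community(rec.community))] += 1
    return tally


def records_to_frame(records: list[SurveyRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def _sweep(
    community: Community,
    param_list: list[tuple[int, int, ModelParams]],
    shape: tuple[int, int],
    metric: str,
    n_init: int,
    seed: int,
) -> np.ndarray:
    if metric not in ("basin_fraction", "robustness"):
        raise ValueError(f"unknown metric {metric!r}")
    out = np.zeros(shape)
    notation = community.canonical().notation
    for a, b, params in param_list:
        rng = community_rng(seed, f"sweep:{notation}:{a}:{b}")
        costs = realized_costs(params, community.n_antibiotics, rng)
        try:
            fps = find_fixed_points(
                community, params, n_init=n_init, rng=rng, costs=costs
            )
        except NonviableStrainError:
            out[a, b] = 0.0
            continue
        stable = [r for r in fps if r.is_stable_interior]
        if not stable:
            out[a, b] = 0.0
        elif metric == "robustness":
            out[a, b] = max(r.robustness for r in stable)
        else:
            out[a, b] = basin_fraction(
                community, params, n_init=n_init, rng=rng, costs=costs,
                fixed_points=fps,
            )
    return out


def sweep_cost_grid(
    community: Community,
    cp_ratios: np.ndarray,
    cd_ratios: np.ndarray,
    base: ParameterCombination = LOW_COST,
    metric: str = "basin_fraction",
    n_init: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Stability metric on a (cp/cr) x (cd/cr) grid, jitter off.

    Returns an array of shape (len(cp_ratios), len(cd_ratios)).  Costs are
    identical across antibiotics so that only the interaction graph and the
    swept ratios matter.
    """
    plist = []
    for a, cp_r in enumerate(np.asarray(cp_ratios, dtype=float)):
        for b, cd_r in enumerate(np.asarray(cd_ratios, dtype=float)):
            params = ModelParams(
                g=base.g, cr=base.cr, cd=cd_r * base.cr, cp=cp_r * base.cr,
                KP=base.KP, KD=base.KD, jitter_scale=0.0,
            )
            plist.append((a, b, params))
    return _sweep(
        community, plist, (len(cp_ratios), len(cd_ratios)), metric, n_init, seed
    )


def sweep_strength_grid(
    community: Community,
    KP_values: np.ndarray,
    KD_values: np.ndarray,
    base: ParameterCombination = LOW_COST,
    metric: str = "robustness",
    n_init: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Stability metric on a KP x KD grid at the base combination's costs.

    Returns an array of shape (len(KP_values), len(KD_values)); jitter off.
    """
    plist = []
    for a, kp in enumerate(np.asarray(KP_values, dtype=float)):
        for b, kd in enumerate(np.asarray(KD_values, dtype=float)):
            params = ModelParams(
                g=base.g, cr=base.cr, cd=base.cd_over_cr * base.cr,
                cp=base.cp_over_cr * base.cr, KP=kp, KD=kd, jitter_scale=0.0,
            )
            plist.append((a, b, params))
    return _sweep(
        community, plist, (len(KP_values), len(KD_values)), metric, n_init, seed
    )
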