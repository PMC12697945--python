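"""Reproducible experiment orchestration: config schema, seeds, writers.

Every experiment is described by a YAML (or plain dict) configuration with
an ``experiment`` kind and a single master seed; all module substreams are
derived deterministically from that seed (per-community streams hash the
canonical notation, spatial replicates extend the seed sequence with grid
indices), so a manifest plus the code version reproduces every output file
bit-for-bit.  Unknown configuration keys are rejected with the offending
key path so that typos cannot silently change an experiment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import parse_community
from .enumeration import DEFAULT_RULES, enumerate_communities
from .spatial import SpatialParams, run_phase_diagram, run_simulation
from .survey import (
    HIGH_COST,
    LOW_COST,
    ParameterCombination,
    records_to_frame,
    survey_topologies,
    sweep_cost_grid,
    sweep_strength_grid,
)

__all__ = ["RunManifest", "ConfigError", "load_config", "validate_config", "execute"]


class ConfigError(ValueError):
    """Configuration does not match the experiment schema."""


@dataclass
class RunManifest:
    """Provenance record written alongside every experiment's outputs."""

    experiment: str
    config: dict
    master_seed: int
    tool_version: str
    outputs: list[str]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


_COMBOS = {"low_cost": LOW_COST, "high_cost": HIGH_COST}

#: allowed keys per experiment kind (besides "experiment"); values are
#: defaults, REQUIRED marks mandatory keys
REQUIRED = object()
_SCHEMAS: dict[str, dict[str, Any]] = {
    "enumerate": {"N": REQUIRED, "M": REQUIRED, "rules": sorted(DEFAULT_RULES)},
    "survey": {
        "N": REQUIRED,
        "M": REQUIRED,
        "combo": "low_cost",
        "n_init": 100,
        "seed": 0,
        "jitter_scale": 0.0005,
        "compute_basin": "stable",
    },
    "sweep": {
        "community": REQUIRED,
        "grid": "cost",  # "cost" or "strength"
        "metric": "basin_fraction",
        "base_combo": "low_cost",
        "cp_ratios": [1.0, 2.0, 3.0, 4.0],
        "cd_ratios": [1.0, 1.7, 2.4, 3.0],
        "KP_values": [10.0, 40.0],
        "KD_values": [2.0, 10.0],
        "n_init": 100,
        "seed": 0,
    },
    "spatial": {
        "community": REQUIRED,
        "g": 0.7,
        "d": 0.3,
        "cr": 0.05,
        "cd": 0.105,
        "cp": 0.15,
        "up": 10.0,
        "ud": 10.0,
        "grid_size": 200,
        "p_init": 0.5,
        "generations": 6000,
        "replicates": 15,
        "seed": 0,
        "KP": 4.0,
        "KD": 4.0,
        "KP_values": None,  # a list switches to phase-diagram mode
        "KD_values": None,
        "tail": 500,
    },
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration file must contain a mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    """Check keys against the schema and fill defaults.

    Raises :class:`ConfigError` naming the offending key (as
    ``<experiment>.<key>``) for unknown keys, and listing missing required
    keys.
    """
    if "experiment" not in cfg:
        raise ConfigError("missing required key: experiment")
    kind = cfg["experiment"]
    if kind not in _SCHEMAS:
        raise ConfigError(
            f"unknown experiment kind {kind!r}; expected one of {sorted(_SCHEMAS)}"
        )
    schema = _SCHEMAS[kind]
    out = {"experiment": kind}
    for key in cfg:
        if key != "experiment" and key not in schema:
            raise ConfigError(f"unknown configuration key: {kind}.{key}")
    for key, default in schema.items():
        if key in cfg:
            out[key] = cfg[key]
        elif default is REQUIRED:
            raise ConfigError(f"missing required key: {kind}.{key}")
        else:
            out[key] = default
    return out


def _combo(name_or_map) -> ParameterCombination:
    if isinstance(name_or_map, str):
        try:
            return _COMBOS[name_or_map]
        except KeyError:
            raise ConfigError(
                f"unknown parameter combination {name_or_map!r}; "
                f"expected one of {sorted(_COMBOS)}"
            ) from None
    return ParameterCombination(**name_or_map)


def execute(cfg: dict, outdir: str | Path) -> RunManifest:
    """Validate, dispatch, and write outputs plus a run manifest."""
    cfg = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kind = cfg["experiment"]
    outputs: list[str] = []

    if kind == "enumerate":
        cat = enumerate_communities(cfg["N"], cfg["M"], frozenset(cfg["rules"]))
        path = outdir / f"catalogue_N{cfg['N']}_M{cfg['M']}.csv"
        cat.export(path, version=__version__)
        outputs += [path.name, path.with_suffix(".json").name]
        seed = 0
    elif kind == "survey":
        combo = _combo(cfg["combo"])
        records = survey_topologies(
            cfg["N"],
            cfg["M"],
            combo,
            n_init=cfg["n_init"],
            seed=cfg["seed"],
            jitter_scale=cfg["jitter_scale"],
            compute_basin=cfg["compute_basin"],
        )
        path = outdir / f"survey_N{cfg['N']}_M{cfg['M']}_{combo.label}.csv"
        records_to_frame(records).to_csv(path, index=False)
        outputs.append(path.name)
        seed = cfg["seed"]
    elif kind == "sweep":
        community = parse_community(cfg["community"])
        base = _combo(cfg["base_combo"])
        if cfg["grid"] == "cost":
            grid = sweep_cost_grid(
                community,
                np.asarray(cfg["cp_ratios"], dtype=float),
                np.asarray(cfg["cd_ratios"], dtype=float),
                base=base,
                metric=cfg["metric"],
                n_init=cfg["n_init"],
                seed=cfg["seed"],
            )
            rows, cols = cfg["cp_ratios"], cfg["cd_ratios"]
            row_name, col_name = "cp_over_cr", "cd_over_cr"
        elif cfg["grid"] == "strength":
            grid = sweep_strength_grid(
                community,
                np.asarray(cfg["KP_values"], dtype=float),
                np.asarray(cfg["KD_values"], dtype=float),
                base=base,
                metric=cfg["metric"],
                n_init=cfg["n_init"],
                seed=cfg["seed"],
            )
            rows, cols = cfg["KP_values"], cfg["KD_values"]
            row_name, col_name = "KP", "KD"
        else:
            raise ConfigError(f"sweep.grid must be 'cost' or 'strength', got {cfg['grid']!r}")
        frame = pd.DataFrame(
            [
                {row_name: rv, col_name: cv, cfg["metric"]: grid[i, j]}
                for i, rv in enumerate(rows)
                for j, cv in enumerate(cols)
            ]
        )
        path = outdir / f"sweep_{cfg['grid']}_{cfg['metric']}.csv"
        frame.to_csv(path, index=False)
        outputs.append(path.name)
        seed = cfg["seed"]
    else:  # spatial
        community = parse_community(cfg["community"])
        sp = SpatialParams(
            g=cfg["g"], d=cfg["d"], cr=cfg["cr"], cd=cfg["cd"], cp=cfg["cp"],
            KP=cfg["KP"], KD=cfg["KD"], up=cfg["up"], ud=cfg["ud"],
            grid_size=cfg["grid_size"], p_init=cfg["p_init"],
            generations=cfg["generations"], replicates=cfg["replicates"],
            seed=cfg["seed"],
        )
        if cfg["KP_values"] is not None:
            result = run_phase_diagram(
                community, sp,
                np.asarray(cfg["KP_values"], dtype=float),
                np.asarray(cfg["KD_values"], dtype=float),
                tail=cfg["tail"],
            )
            frame = pd.DataFrame(
                [
                    {
                        "KP": kp, "KD": kd,
                        **{
                            f"abundance_{s}": result[i, j, s]
                            for s in range(community.n_strains)
                        },
                    }
                    for i, kp in enumerate(cfg["KP_values"])
                    for j, kd in enumerate(cfg["KD_values"])
                ]
            )
            path = outdir / "spatial_phase_diagram.csv"
        else:
            res = run_simulation(community, sp)
            frame = pd.DataFrame(
                res.abundances,
                columns=[f"abundance_{s}" for s in range(community.n_strains)],
            )
            frame.insert(0, "generation", range(len(frame)))
            frame["occupied_fraction"] = res.occupied
            path = outdir / "spatial_abundances.csv"
        frame.to_csv(path, index=False)
        outputs.append(path.name)
        seed = cfg["seed"]

    manifest = RunManifest(
        experiment=kind,
        config=cfg,
        master_seed=seed,
        tool_version=__version__,
        outputs=outputs,
    )
    manifest.write(outdir / "manifest.json")
    return manifest
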