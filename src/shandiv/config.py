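"""YAML configuration for the simulation experiment.

A config file may override any subset of the built-in study defaults; a
``preset`` selects the full-size design (1000 replicates) or a scaled one
(100 replicates) before file/flag overrides are applied.
"""

from __future__ import annotations

import math
from dataclasses import asdict

import yaml

from .coalsim import (
    Demography,
    SimulationConfig,
    default_loci,
    default_scenarios,
)
from .popdata import LocusSpec

PRESETS = {"paper": 1000, "scaled": 100}

_KNOWN_KEYS = {
    "loci", "scenarios", "pop_size", "sample_sizes", "n_resamples",
    "n_replicates", "sd_comparison_pairs", "master_seed", "boundary",
}

__all__ = ["PRESETS", "load_config", "build_config", "config_snapshot"]


def build_config(
    preset: str = "paper",
    overrides: dict | None = None,
) -> SimulationConfig:
    """Construct a SimulationConfig from a preset plus override mapping."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    data = dict(overrides or {})
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict = {"n_replicates": PRESETS[preset]}
    if "loci" in data:
        kwargs["loci"] = [
            LocusSpec(name=str(l["name"]), mu=float(l["mu"]), k_max=int(l["k_max"]))
            for l in data.pop("loci")
        ]
    if "scenarios" in data:
        kwargs["scenarios"] = {
            str(name): Demography(
                epochs=tuple(
                    (math.inf if d in ("inf", ".inf", None) else float(d), int(n))
                    for d, n in epochs
                )
            )
            for name, epochs in data.pop("scenarios").items()
        }
    if "sample_sizes" in data:
        kwargs["sample_sizes"] = tuple(int(x) for x in data.pop("sample_sizes"))
    for key in ("pop_size", "n_resamples", "n_replicates",
                "sd_comparison_pairs", "master_seed"):
        if key in data:
            kwargs[key] = int(data.pop(key))
    if "boundary" in data:
        kwargs["boundary"] = str(data.pop("boundary"))
    cfg = SimulationConfig(**kwargs)
    if "loci" not in kwargs:
        cfg.loci = default_loci()
    if "scenarios" not in kwargs:
        cfg.scenarios = default_scenarios(cfg.pop_size)
    return cfg


def load_config(path, preset: str = "paper", **flag_overrides) -> SimulationConfig:
    """Load YAML config; flags override the file, the file overrides the
    preset defaults."""
    overrides: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        overrides.update(loaded)
    overrides.update({k: v for k, v in flag_overrides.items() if v is not None})
    return build_config(preset=preset, overrides=overrides)


def config_snapshot(cfg: SimulationConfig) -> dict:
    """JSON-serialisable snapshot of a config (for the run manifest)."""
    snap = asdict(cfg)
    snap["loci"] = [
        {"name": l.name, "mu": l.mu, "k_max": l.k_max} for l in cfg.loci
    ]
    snap["scenarios"] = {
        name: [["inf" if math.isinf(d) else d, n] for d, n in demog.epochs]
        for name, demog in cfg.scenarios.items()
    }
    snap["sample_sizes"] = list(cfg.sample_sizes)
    return snap
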