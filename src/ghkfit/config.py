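"""Pipeline configuration: a single YAML document drives every stage.

A stored config plus a master seed reproduces every output byte-for-byte.
The master seed spawns per-stage substreams through numpy's SeedSequence
(stage keys: simulate=0, bootstrap=1), so each stage is individually
reproducible from the same master seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .ghk import ChannelModel, PhysicalContext
from .simulate import KineticsSpec, NoiseSpec, VoltageProtocol
from .solutions import ActivityModel, Solution, get_solution, solutions_from_yaml

__all__ = [
    "default_config",
    "load_config",
    "validate_config",
    "config_hash",
    "stage_seed",
    "build_channel",
    "build_protocol",
    "build_kinetics",
    "build_noise",
    "build_activity_model",
    "build_context",
    "resolve_conditions",
]

_DEFAULTS: dict[str, Any] = {
    "channel": {
        "reference_ion": "Na",
        "permeabilities": {"Na": 1.0, "Cl": 18.8},
        "conductance_scale": 0.1,
    },
    "conditions": [
        {"id": "dil_1.00", "external": "1NaCl", "internal": "I2",
         "dilution_factor": 1.0, "reference": True},
        {"id": "dil_0.50", "external": "0.5NaCl", "internal": "I2",
         "dilution_factor": 0.5},
        {"id": "dil_0.25", "external": "0.25NaCl", "internal": "I2",
         "dilution_factor": 0.25},
    ],
    "protocol": {
        "holding_potentials_mV": [-60, -40, -20, 0, 20, 40, 60],
        "agonist_duration_ms": 250.0,
        "sample_interval_ms": 1.0,
        "baseline_duration_ms": 50.0,
    },
    "kinetics": {"tau_d_ms": 100.0, "plateau_fraction": 0.3, "rise_time_ms": 0.0},
    "noise": {"trace_noise_sd": 2.0, "replicate_amplitude_cv": 0.2},
    "n_replicates": 4,
    "analysis": {
        "n_avg": 3,
        "qc_threshold": 0.80,
        "erev_method": "interp",
        "n_bootstrap": 1000,
        "pool_cations": True,
    },
    "activity_model": "unity",
    "temperature_C": 22.0,
    "seed": 0,
    "solutions": None,  # optional inline YAML solution definitions
}

_KNOWN_KEYS = set(_DEFAULTS)


def default_config() -> dict[str, Any]:
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config, filling unspecified fields with defaults."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        cfg = _merge(cfg, user)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict[str, Any]) -> None:
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    if not cfg["conditions"]:
        raise ValueError("config field 'conditions' must list at least one condition")
    for cond in cfg["conditions"]:
        for req in ("id", "external", "internal"):
            if req not in cond:
                raise ValueError(f"condition entry missing field {req!r}: {cond}")
    if cfg["analysis"]["erev_method"] not in ("interp", "quad"):
        raise ValueError("analysis.erev_method must be 'interp' or 'quad'")
    if cfg["activity_model"] not in ("unity", "davies"):
        raise ValueError("activity_model must be 'unity' or 'davies'")


def config_hash(cfg: dict[str, Any]) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2^31) derived from the master seed."""
    stages = {"simulate": 0, "bootstrap": 1, "shift": 2}
    ss = np.random.SeedSequence([int(master_seed), stages[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def build_channel(cfg: dict[str, Any]) -> ChannelModel:
    ch = cfg["channel"]
    return ChannelModel(
        relative_permeabilities=dict(ch["permeabilities"]),
        reference_ion=ch.get("reference_ion", "Na"),
        conductance_scale=float(ch.get("conductance_scale", 1.0)),
    )


def build_protocol(cfg: dict[str, Any]) -> VoltageProtocol:
    p = cfg["protocol"]
    return VoltageProtocol(
        tuple(float(v) for v in p["holding_potentials_mV"]),
        float(p["agonist_duration_ms"]),
        float(p["sample_interval_ms"]),
        float(p["baseline_duration_ms"]),
    )


def build_kinetics(cfg: dict[str, Any]) -> KineticsSpec:
    k = cfg["kinetics"]
    return KineticsSpec(
        float(k["tau_d_ms"]), float(k["plateau_fraction"]), float(k["rise_time_ms"])
    )


def build_noise(cfg: dict[str, Any], seed: int | None = None) -> NoiseSpec:
    n = cfg["noise"]
    master = cfg["seed"] if seed is None else seed
    return NoiseSpec(
        float(n["trace_noise_sd"]),
        float(n["replicate_amplitude_cv"]),
        stage_seed(int(master), "simulate"),
    )


def build_activity_model(cfg: dict[str, Any]) -> ActivityModel:
    return ActivityModel(mode=cfg["activity_model"])


def build_context(cfg: dict[str, Any]) -> PhysicalContext:
    return PhysicalContext.from_celsius(float(cfg["temperature_C"]))


def resolve_conditions(
    cfg: dict[str, Any]
) -> list[tuple[str, Solution, Solution, dict[str, Any]]]:
    """(condition_id, extracellular, intracellular, raw entry) per condition."""
    inline: dict[str, Solution] = {}
    if cfg.get("solutions"):
        inline = solutions_from_yaml(yaml.safe_dump({"solutions": cfg["solutions"]}))

    def lookup(name: str) -> Solution:
        return inline[name] if name in inline else get_solution(name)

    out = []
    for cond in cfg["conditions"]:
        out.append((cond["id"], lookup(cond["external"]), lookup(cond["internal"]), cond))
    return out
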