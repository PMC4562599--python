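"""Seeded simulation of agonist-evoked whole-cell macrocurrents.

The generator emulates the statistical structure of tyramine-evoked
voltage-clamp experiments on a ligand-gated channel: at each holding
potential the peak current is set by the channel's GHK flux for the chosen
solutions, the current then desensitizes mono-exponentially toward a plateau,
replicates vary by a lognormal amplitude factor (one factor per cell and
condition), and every sample carries additive Gaussian instrument noise.

Reproducibility: a run is fully determined by (channel, solutions, protocol,
kinetics, NoiseSpec.seed) — same inputs, bit-identical traces and CSV output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ghk import ChannelModel, PhysicalContext, ghk_current_density
from .solutions import ActivityModel, Solution

__all__ = [
    "VoltageProtocol",
    "KineticsSpec",
    "NoiseSpec",
    "CurrentTrace",
    "RecordingSet",
    "simulate_trace",
    "simulate_experiment",
]

DEFAULT_POTENTIALS = tuple(range(-60, 61, 20))


@dataclass(frozen=True)
class VoltageProtocol:
    """Holding potentials and timing of the agonist application."""

    holding_potentials_mV: tuple[float, ...] = DEFAULT_POTENTIALS
    agonist_duration_ms: float = 250.0
    sample_interval_ms: float = 1.0
    baseline_duration_ms: float = 50.0

    def __post_init__(self) -> None:
        v = self.holding_potentials_mV
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("holding potentials must be strictly increasing")
        if self.sample_interval_ms <= 0 or self.agonist_duration_ms <= 0:
            raise ValueError("sample interval and agonist duration must be positive")

    @property
    def total_duration_ms(self) -> float:
        return self.baseline_duration_ms + self.agonist_duration_ms

    def time_axis(self) -> np.ndarray:
        n = int(round(self.total_duration_ms / self.sample_interval_ms)) + 1
        return np.arange(n) * self.sample_interval_ms

    def agonist_window(self, time_ms: np.ndarray) -> np.ndarray:
        """Boolean mask of samples within the agonist application."""
        return (time_ms >= self.baseline_duration_ms) & (
            time_ms <= self.total_duration_ms
        )


@dataclass(frozen=True)
class KineticsSpec:
    """Desensitization kinetics: decay constant, plateau fraction, optional rise.

    No kinetic constants are dictated by the selectivity analysis itself; the
    defaults (tau_d = 100 ms, plateau fraction 0.3, instantaneous rise) are
    arbitrary round numbers of the right order for a desensitizing Cys-loop
    receptor macrocurrent.
    """

    tau_d_ms: float = 100.0
    plateau_fraction: float = 0.3
    rise_time_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_d_ms <= 0:
            raise ValueError("tau_d must be positive")
        if not (0 <= self.plateau_fraction <= 1):
            raise ValueError("plateau_fraction must lie in [0, 1]")
        if self.rise_time_ms < 0:
            raise ValueError("rise_time must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument and biological variability: trace noise sd (pA), replicate CV, seed."""

    trace_noise_sd: float = 2.0
    replicate_amplitude_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trace_noise_sd < 0 or self.replicate_amplitude_cv < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class CurrentTrace:
    condition_id: str
    replicate_id: int
    holding_mV: float
    time_ms: np.ndarray
    current_pA: np.ndarray

    def __post_init__(self) -> None:
        if self.time_ms.shape != self.current_pA.shape:
            raise ValueError("time and current series must have equal length")
        if not np.all(np.isfinite(self.current_pA)):
            raise ValueError("current trace contains non-finite samples")


@dataclass
class RecordingSet:
    """Traces grouped by (condition, holding potential, replicate) + provenance."""

    traces: list[CurrentTrace]
    provenance: dict = field(default_factory=dict)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.traces:
            seen.setdefault(t.condition_id, None)
        return list(seen)

    def select(
        self, condition_id: str, holding_mV: float | None = None
    ) -> list[CurrentTrace]:
        out = [t for t in self.traces if t.condition_id == condition_id]
        if holding_mV is not None:
            out = [t for t in out if t.holding_mV == holding_mV]
        return out

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for t in self.traces:
            frames.append(
                pd.DataFrame(
                    {
                        "condition_id": t.condition_id,
                        "replicate_id": t.replicate_id,
                        "holding_mV": t.holding_mV,
                        "time_ms": t.time_ms,
                        "current_pA": t.current_pA,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    def write_provenance(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.provenance, indent=2, sort_keys=True))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: dict | None = None) -> "RecordingSet":
        required = {"condition_id", "replicate_id", "holding_mV", "time_ms", "current_pA"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"trace table missing columns: {sorted(missing)}")
        traces = []
        keys = ["condition_id", "replicate_id", "holding_mV"]
        for (cond, rep, v), grp in frame.groupby(keys, sort=False):
            traces.append(
                CurrentTrace(
                    str(cond),
                    int(rep),
                    float(v),
                    grp["time_ms"].to_numpy(dtype=float),
                    grp["current_pA"].to_numpy(dtype=float),
                )
            )
        return cls(traces, provenance or {})


def _waveform(
    time_ms: np.ndarray,
    protocol: VoltageProtocol,
    kinetics: KineticsSpec,
    peak_pA: float,
) -> np.ndarray:
    """Noise-free current template: baseline zero, rise to peak, exponential decay.

    The decay is I(t') = I_o exp(-t'/tau_d) + I_inf with t' measured from the
    peak, I_inf = plateau_fraction * peak and I_o = peak - I_inf, so the trace
    attains exactly ``peak_pA`` at the peak sample.
    """
    onset = protocol.baseline_duration_ms
    i_inf = kinetics.plateau_fraction * peak_pA
    i_o = peak_pA - i_inf
    out = np.zeros_like(time_ms)
    t_rel = time_ms - onset
    rise = kinetics.rise_time_ms
    if rise > 0:
        ramp = (t_rel >= 0) & (t_rel < rise)
        out[ramp] = peak_pA * (t_rel[ramp] / rise)
    decaying = t_rel >= rise
    out[decaying] = i_o * np.exp(-(t_rel[decaying] - rise) / kinetics.tau_d_ms) + i_inf
    return out


def simulate_trace(
    channel: ChannelModel,
    holding_mV: float,
    sol_out: Solution,
    sol_in: Solution,
    protocol: VoltageProtocol,
    kinetics: KineticsSpec,
    noise: NoiseSpec,
    rng: np.random.Generator,
    *,
    amplitude_factor: float = 1.0,
    activity_model: ActivityModel | None = None,
    ctx: PhysicalContext | None = None,
    condition_id: str = "cond",
    replicate_id: int = 0,
) -> CurrentTrace:
    """Simulate one sweep at one holding potential.

    The analytic peak is ``conductance_scale * GHK current * amplitude_factor``;
    with ``trace_noise_sd = 0`` the trace is exactly the waveform template.
    """
    activity_model = activity_model or ActivityModel()
    ctx = ctx or PhysicalContext()
    drive = ghk_current_density(channel, holding_mV, sol_out, sol_in, activity_model, ctx)
    peak = channel.conductance_scale * drive * amplitude_factor
    time_ms = protocol.time_axis()
    current = _waveform(time_ms, protocol, kinetics, peak)
    if noise.trace_noise_sd > 0:
        current = current + rng.normal(0.0, noise.trace_noise_sd, size=time_ms.shape)
    return CurrentTrace(condition_id, replicate_id, holding_mV, time_ms, current)


def _amplitude_factors(
    rng: np.random.Generator, n: int, cv: float
) -> np.ndarray:
    """Unit-mean lognormal draws with the requested coefficient of variation."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def simulate_experiment(
    channel: ChannelModel,
    conditions: Sequence[tuple[str, Solution, Solution]],
    protocol: VoltageProtocol,
    kinetics: KineticsSpec,
    noise: NoiseSpec,
    n_replicates: int = 4,
    *,
    activity_model: ActivityModel | None = None,
    ctx: PhysicalContext | None = None,
) -> RecordingSet:
    """Simulate a full recording set over conditions, potentials and replicates.

    ``conditions`` is a sequence of (condition_id, extracellular, intracellular)
    triples. One amplitude factor is drawn per (condition, replicate) — a
    replicate models one cell, whose channel density is shared across the
    voltage protocol. Deterministic under ``noise.seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    activity_model = activity_model or ActivityModel()
    ctx = ctx or PhysicalContext()
    root = np.random.SeedSequence(noise.seed)
    traces: list[CurrentTrace] = []
    cond_seeds = root.spawn(len(conditions))
    for (cond_id, sol_out, sol_in), cond_ss in zip(conditions, cond_seeds):
        amp_rng = np.random.default_rng(cond_ss)
        factors = _amplitude_factors(amp_rng, n_replicates, noise.replicate_amplitude_cv)
        rep_seeds = cond_ss.spawn(n_replicates)
        for rep, (factor, rep_ss) in enumerate(zip(factors, rep_seeds)):
            rng = np.random.default_rng(rep_ss)
            for v in protocol.holding_potentials_mV:
                traces.append(
                    simulate_trace(
                        channel,
                        v,
                        sol_out,
                        sol_in,
                        protocol,
                        kinetics,
                        noise,
                        rng,
                        amplitude_factor=float(factor),
                        activity_model=activity_model,
                        ctx=ctx,
                        condition_id=cond_id,
                        replicate_id=rep,
                    )
                )
    provenance = {
        "channel": {
            "reference_ion": channel.reference_ion,
            "relative_permeabilities": dict(channel.relative_permeabilities),
            "conductance_scale": channel.conductance_scale,
        },
        "conditions": [
            {"id": cid, "extracellular": so.name, "intracellular": si.name}
            for cid, so, si in conditions
        ],
        "protocol": {
            "holding_potentials_mV": list(protocol.holding_potentials_mV),
            "agonist_duration_ms": protocol.agonist_duration_ms,
            "sample_interval_ms": protocol.sample_interval_ms,
            "baseline_duration_ms": protocol.baseline_duration_ms,
        },
        "kinetics": {
            "tau_d_ms": kinetics.tau_d_ms,
            "plateau_fraction": kinetics.plateau_fraction,
            "rise_time_ms": kinetics.rise_time_ms,
        },
        "noise": {
            "trace_noise_sd": noise.trace_noise_sd,
            "replicate_amplitude_cv": noise.replicate_amplitude_cv,
            "seed": noise.seed,
        },
        "activity_model": activity_model.mode,
        "temperature_K": ctx.temperature_K,
        "n_replicates": n_replicates,
    }
    return RecordingSet(traces, provenance)
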