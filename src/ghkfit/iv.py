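"""Peak extraction, decay fitting, replicate QC and reversal-potential estimation.

The analysis chain mirrors standard whole-cell I-V practice: baseline-subtract
each sweep, take the signed peak within the agonist window, discard an
experiment when replicate peaks disagree by more than 80%, average the first
three acceptable replicates per potential, normalize to the largest mean
response (I_max), and read the reversal potential off the zero crossing of
the normalized I-V relationship by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .ghk import ErevEstimate
from .simulate import CurrentTrace, RecordingSet, VoltageProtocol

__all__ = [
    "DecayFit",
    "DecayFitError",
    "IVCurve",
    "QCReport",
    "peak_current",
    "fit_decay",
    "qc_replicates",
    "average_normalize",
    "estimate_erev",
    "analyze_condition",
    "analyze_recording_set",
]


class DecayFitError(RuntimeError):
    """Raised when the mono-exponential decay fit cannot be identified."""


@dataclass(frozen=True)
class DecayFit:
    """I(t) = I_o exp(-t/tau_d) + I_inf fitted to the post-peak segment."""

    i_o_pA: float
    i_inf_pA: float
    tau_d_ms: float
    rmse_pA: float

    def __post_init__(self) -> None:
        if self.tau_d_ms <= 0:
            raise ValueError("tau_d must be positive")
        if self.rmse_pA < 0:
            raise ValueError("rmse must be >= 0")


@dataclass(frozen=True)
class IVCurve:
    """Mean normalized peak current per holding potential."""

    potentials_mV: tuple[float, ...]
    normalized_peaks: tuple[float, ...]
    i_max_pA: float
    n_replicates_used: tuple[int, ...]
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.i_max_pA <= 0:
            raise ValueError("I_max must be positive")
        if not (
            len(self.potentials_mV)
            == len(self.normalized_peaks)
            == len(self.n_replicates_used)
        ):
            raise ValueError("I-V curve arrays must have equal length")


@dataclass(frozen=True)
class QCReport:
    keep: bool
    max_relative_difference: float | None
    reason: str
    flags: tuple[str, ...] = ()


def _baseline(trace: CurrentTrace, protocol: VoltageProtocol) -> float:
    pre = trace.current_pA[trace.time_ms < protocol.baseline_duration_ms]
    return float(pre.mean()) if pre.size else 0.0


def peak_current(trace: CurrentTrace, protocol: VoltageProtocol) -> float:
    """Signed extremum of the baseline-subtracted current in the agonist window."""
    window = protocol.agonist_window(trace.time_ms)
    if not window.any():
        raise ValueError("agonist window contains no samples")
    corrected = trace.current_pA[window] - _baseline(trace, protocol)
    return float(corrected[np.argmax(np.abs(corrected))])


def fit_decay(trace: CurrentTrace, protocol: VoltageProtocol) -> DecayFit:
    """Least-squares mono-exponential fit of the desensitizing segment.

    Time is re-zeroed at the peak sample; the fit covers peak-to-end of the
    agonist window and needs at least 10 samples. A flat segment (constant
    current) leaves tau_d unidentifiable and raises :class:`DecayFitError`.
    """
    window = protocol.agonist_window(trace.time_ms)
    base = _baseline(trace, protocol)
    t_win = trace.time_ms[window]
    i_win = trace.current_pA[window] - base
    peak_idx = int(np.argmax(np.abs(i_win)))
    t = t_win[peak_idx:] - t_win[peak_idx]
    i = i_win[peak_idx:]
    if t.size < 10:
        raise ValueError(f"need >= 10 samples after the peak, got {t.size}")
    span = float(i[0] - i[-1])
    if abs(span) < 1e-12 and float(np.std(i)) < 1e-12:
        raise DecayFitError(
            "decay segment is constant: tau_d is unidentifiable (plateau-only trace)"
        )

    def model(tt: np.ndarray, i_o: float, tau: float, i_inf: float) -> np.ndarray:
        return i_o * np.exp(-tt / tau) + i_inf

    p0 = (span, max(float(t[-1]) / 5.0, 1.0), float(i[-1]))
    try:
        popt, _ = curve_fit(
            model,
            t,
            i,
            p0=p0,
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        resid = float(np.sqrt(np.mean((model(t, *p0) - i) ** 2)))
        raise DecayFitError(
            f"decay fit did not converge (p0={p0}, rmse at p0={resid:.4g} pA)"
        ) from exc
    i_o, tau, i_inf = map(float, popt)
    rmse = float(np.sqrt(np.mean((model(t, i_o, tau, i_inf) - i) ** 2)))
    return DecayFit(i_o, i_inf, tau, rmse)


def qc_replicates(
    peaks: list[float],
    threshold: float = 0.80,
    noise_floor_pA: float = 1e-9,
) -> QCReport:
    """Discard an experiment when replicate peaks differ by more than *threshold*.

    The disagreement measure is the maximum pairwise relative difference
    |p_i - p_j| / max(|p_i|, |p_j|). All-zero peaks mean no response and the
    experiment is discarded outright; a single replicate passes vacuously.
    """
    if not peaks:
        raise ValueError("no peaks supplied")
    mags = [abs(p) for p in peaks]
    if max(mags) <= noise_floor_pA:
        return QCReport(False, None, "no response (all peaks at noise floor)")
    if len(peaks) == 1:
        return QCReport(True, None, "single replicate", flags=("single_replicate",))
    worst = 0.0
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            denom = max(mags[i], mags[j])
            worst = max(worst, abs(peaks[i] - peaks[j]) / denom)
    if worst > threshold:
        return QCReport(
            False,
            worst,
            f"max pairwise relative difference {worst:.1%} exceeds {threshold:.0%}",
        )
    return QCReport(True, worst, "replicates consistent")


def average_normalize(
    peaks_by_potential: dict[float, list[float]],
    n_avg: int = 3,
) -> IVCurve:
    """Average up to *n_avg* replicate peaks per potential and normalize to I_max.

    I_max is the largest |mean peak| across potentials; all means are divided
    by it so the curve spans [-1, 1] up to noise. Potentials with fewer than
    n_avg replicates use what is available and are flagged.
    """
    if not peaks_by_potential:
        raise ValueError("no peaks supplied")
    potentials = sorted(peaks_by_potential)
    means, n_used, flags = [], [], []
    for v in potentials:
        reps = peaks_by_potential[v]
        if not reps:
            raise ValueError(f"no replicate peaks at {v} mV")
        use = reps[:n_avg]
        if len(use) < n_avg:
            flags.append(f"only {len(use)} replicate(s) at {v:g} mV (wanted {n_avg})")
        means.append(float(np.mean(use)))
        n_used.append(len(use))
    i_max = max(abs(m) for m in means)
    if i_max == 0:
        raise ValueError("all mean peaks are zero; cannot normalize")
    return IVCurve(
        tuple(potentials),
        tuple(m / i_max for m in means),
        i_max,
        tuple(n_used),
        tuple(flags),
    )


def estimate_erev(iv: IVCurve, refine: str = "interp") -> ErevEstimate:
    """Zero-current potential from the I-V curve.

    Linear interpolation between the sign-change bracketing pair; with several
    sign changes (noisy curves) the pair nearest 0 mV is used and flagged.
    ``refine="quad"`` fits a local quadratic through the bracketing pair and
    one neighbor and uses its root inside the bracket.
    """
    v = np.asarray(iv.potentials_mV, dtype=float)
    i = np.asarray(iv.normalized_peaks, dtype=float)
    flags: list[str] = []
    zeros = np.flatnonzero(i == 0.0)
    brackets = [
        k for k in range(len(v) - 1) if i[k] * i[k + 1] < 0
    ]
    if zeros.size and not brackets:
        k = int(zeros[np.argmin(np.abs(v[zeros]))])
        return ErevEstimate(float(v[k]), "interpolated", flags=("exact_zero_sample",))
    if not brackets:
        raise ValueError(
            f"no zero crossing: normalized currents span "
            f"[{i.min():.3g}, {i.max():.3g}] over [{v[0]:g}, {v[-1]:g}] mV; "
            f"the reversal potential lies outside the protocol"
        )
    if len(brackets) > 1:
        flags.append(f"{len(brackets)} sign changes; using the bracket nearest 0 mV")
        brackets.sort(key=lambda k: min(abs(v[k]), abs(v[k + 1])))
    k = brackets[0]
    erev = v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k])
    if refine == "quad" and len(v) >= 3:
        idx = [k - 1, k, k + 1] if k > 0 else [k, k + 1, k + 2]
        coeffs = np.polyfit(v[idx], i[idx], 2)
        roots = np.roots(coeffs)
        real = roots[np.isreal(roots)].real
        inside = [r for r in real if v[k] - 1e-9 <= r <= v[k + 1] + 1e-9]
        if inside:
            erev = min(inside, key=lambda r: abs(r - erev))
            flags.append("quadratic_refined")
    return ErevEstimate(float(erev), "interpolated", flags=tuple(flags))


# ---------------------------------------------------------------------------
# Condition-level orchestration


@dataclass
class ConditionResult:
    condition_id: str
    qc: QCReport
    iv: IVCurve | None
    erev: ErevEstimate | None
    peaks_by_potential: dict[float, list[float]] = field(default_factory=dict)


def _qc_peaks(
    peaks_by_potential: dict[float, dict[int, float]]
) -> tuple[list[float], float]:
    """Per-replicate peaks at the potential with the largest mean |response|."""
    best_v, best_mag = None, -1.0
    for v, reps in peaks_by_potential.items():
        mag = float(np.mean([abs(p) for p in reps.values()]))
        if mag > best_mag:
            best_v, best_mag = v, mag
    return list(peaks_by_potential[best_v].values()), best_v


def analyze_condition(
    recordings: RecordingSet,
    condition_id: str,
    protocol: VoltageProtocol,
    *,
    n_avg: int = 3,
    qc_threshold: float = 0.80,
    erev_method: str = "interp",
) -> ConditionResult:
    """Run peaks -> QC -> average/normalize -> E_rev for one condition.

    The QC rule compares replicate peaks at the potential with the largest
    mean response (where the rule has the most power); a failed QC discards
    the whole condition, mirroring whole-experiment discard in practice.
    An E_rev standard error is attached when at least two replicates yield
    an individual zero crossing.
    """
    traces = recordings.select(condition_id)
    if not traces:
        raise ValueError(f"no traces for condition {condition_id!r}")
    by_pot: dict[float, dict[int, float]] = {}
    for t in traces:
        by_pot.setdefault(t.holding_mV, {})[t.replicate_id] = peak_current(t, protocol)
    qc_values, _ = _qc_peaks(by_pot)
    qc = qc_replicates(qc_values, threshold=qc_threshold)
    if not qc.keep:
        return ConditionResult(condition_id, qc, None, None)
    ordered = {
        v: [reps[r] for r in sorted(reps)] for v, reps in sorted(by_pot.items())
    }
    iv = average_normalize(ordered, n_avg=n_avg)
    erev = estimate_erev(iv, refine="quad" if erev_method == "quad" else "interp")
    rep_erevs = []
    rep_ids = sorted({t.replicate_id for t in traces})
    for rid in rep_ids:
        single = {v: [reps[rid]] for v, reps in by_pot.items() if rid in reps}
        try:
            rep_iv = average_normalize(single, n_avg=1)
            rep_erevs.append(estimate_erev(rep_iv).value_mV)
        except ValueError:
            continue
    if len(rep_erevs) >= 2:
        sem = float(np.std(rep_erevs, ddof=1) / np.sqrt(len(rep_erevs)))
        erev = ErevEstimate(
            erev.value_mV,
            erev.method,
            standard_error_mV=sem,
            n_replicates=len(rep_erevs),
            flags=erev.flags,
        )
    return ConditionResult(condition_id, qc, iv, erev, ordered)


def analyze_recording_set(
    recordings: RecordingSet,
    protocol: VoltageProtocol,
    **kwargs,
) -> dict[str, ConditionResult]:
    """Analyze every condition in the set; discarded conditions carry qc.keep=False."""
    return {
        cid: analyze_condition(recordings, cid, protocol, **kwargs)
        for cid in recordings.conditions()
    }
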