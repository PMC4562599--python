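"""Dilution-potential curves and P_Cl/P_Na estimation.

The selectivity inference: measure the reversal potential under symmetric
NaCl and after diluting the bath NaCl (0.5x, 0.25x), plot the E_rev shift
against the extracellular Cl- activity, and fit the two-ion GHK voltage
equation for the single free parameter P_Cl/P_Na. Shifts (rather than
absolute potentials) are fitted, which cancels any condition-independent
offset such as a junction potential. The search runs in log-ratio space
(positivity, symmetric treatment of anion- and cation-favoring channels)
via a coarse grid scan plus bounded local refinement; confidence intervals
come from a seeded parametric bootstrap over the E_rev standard errors.

Also here: the monovalent/divalent shift analysis (bath K+ or Ca2+ swaps,
difference of means with a percentile-bootstrap CI) used to show that a
cation-converted channel conducts K+ like Na+ but not Ca2+.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .ghk import ErevEstimate, PhysicalContext, ghk_erev_two_ion
from .solutions import ION_TABLE, ActivityModel, Solution, activity

__all__ = [
    "DilutionExperiment",
    "DilutionPoint",
    "PermeabilityFitResult",
    "ShiftResult",
    "monovalent_cation_activity",
    "build_dilution_curve",
    "fit_pcl_pna",
    "classify_selectivity",
    "shift_analysis",
]

LOG_RATIO_BOUNDS = (-12.0, 12.0)


def monovalent_cation_activity(
    sol: Solution, model: ActivityModel, pool_cations: bool = True
) -> float:
    """Permeant monovalent cation activity (mM): Na+ plus, optionally, K+.

    Pooling K+ with Na+ at equal permeability is the standard treatment for a
    channel that does not distinguish the two; NMDG+ is impermeant and never
    pooled.
    """
    ions = ("Na", "K") if pool_cations else ("Na",)
    total = 0.0
    for ion in ions:
        if ion in sol.ion_totals and ION_TABLE[ion].permeant:
            total += activity(sol, ion, model)
    return total


@dataclass(frozen=True)
class DilutionPoint:
    dilution_factor: float
    a_cl_out_mM: float
    delta_erev_mV: float
    standard_error_mV: float | None = None


@dataclass(frozen=True)
class DilutionExperiment:
    """E_rev estimates for a NaCl dilution series against a symmetric reference."""

    internal: Solution
    externals: tuple[tuple[float, Solution], ...]  # (dilution factor, bath)
    erev_estimates: dict[float, ErevEstimate]  # keyed by dilution factor
    reference_factor: float = 1.0

    def __post_init__(self) -> None:
        factors = {f for f, _ in self.externals}
        if self.reference_factor not in factors:
            raise ValueError(
                f"reference condition (factor {self.reference_factor}) missing "
                f"from externals {sorted(factors)}"
            )
        missing = factors - set(self.erev_estimates)
        if missing:
            raise ValueError(f"missing E_rev estimates for factors {sorted(missing)}")

    def external(self, factor: float) -> Solution:
        for f, sol in self.externals:
            if f == factor:
                return sol
        raise ValueError(f"no external solution at dilution factor {factor}")


@dataclass(frozen=True)
class PermeabilityFitResult:
    p_cl_over_p_na: float
    ci_low: float | None
    ci_high: float | None
    fit_log_ratio: float
    residual_rmse_mV: float
    n_points: int
    classification: str
    limit_curve_anion: tuple[tuple[float, float], ...] = ()
    limit_curve_cation: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.p_cl_over_p_na < 0:
            raise ValueError("permeability ratio must be >= 0")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.p_cl_over_p_na <= self.ci_high):
                raise ValueError("CI must contain the point estimate")


@dataclass(frozen=True)
class ShiftResult:
    delta_mV: float
    ci_low_mV: float | None
    ci_high_mV: float | None
    direction: str  # "positive" | "negative" | "none" | "undetermined"
    n_a: int
    n_b: int


def build_dilution_curve(
    experiment: DilutionExperiment,
    model: ActivityModel,
) -> list[DilutionPoint]:
    """Reversal-potential shifts against extracellular Cl- activity.

    ΔE_rev = E_rev(dilution) − E_rev(reference); the x-coordinate is the Cl-
    activity of each bath under *model*. The activity model moves only the
    x-coordinates — the measured shifts are unchanged.
    """
    ref = experiment.erev_estimates[experiment.reference_factor]
    points = []
    for factor, sol in experiment.externals:
        est = experiment.erev_estimates[factor]
        se = None
        if est.standard_error_mV is not None and ref.standard_error_mV is not None:
            se = math.hypot(est.standard_error_mV, ref.standard_error_mV)
        elif est.standard_error_mV is not None:
            se = est.standard_error_mV
        points.append(
            DilutionPoint(
                factor,
                activity(sol, "Cl", model),
                est.value_mV - ref.value_mV,
                se,
            )
        )
    points.sort(key=lambda p: -p.dilution_factor)
    return points


class _ShiftPredictor:
    """Vectorized GHK ΔE_rev prediction for a dilution series at a given ratio."""

    def __init__(
        self,
        internal: Solution,
        externals: Sequence[tuple[float, Solution]],
        reference_factor: float,
        model: ActivityModel,
        ctx: PhysicalContext,
        pool_cations: bool = True,
    ) -> None:
        self.ctx = ctx
        self.a_na_in = monovalent_cation_activity(internal, model, pool_cations)
        self.a_cl_in = activity(internal, "Cl", model)
        self.factors = [f for f, _ in externals]
        self.a_na_out = [
            monovalent_cation_activity(sol, model, pool_cations) for _, sol in externals
        ]
        self.a_cl_out = [activity(sol, "Cl", model) for _, sol in externals]
        k = self.factors.index(reference_factor)
        self.ref_idx = k

    def absolute(self, ratio: float) -> np.ndarray:
        return np.array(
            [
                ghk_erev_two_ion(
                    ratio, ao, self.a_na_in, co, self.a_cl_in, self.ctx
                )
                for ao, co in zip(self.a_na_out, self.a_cl_out)
            ]
        )

    def shifts(self, ratio: float) -> np.ndarray:
        e = self.absolute(ratio)
        return e - e[self.ref_idx]


def _fit_log_ratio(
    observed: np.ndarray,
    predictor: _ShiftPredictor,
    point_factors: Sequence[float],
    bounds: tuple[float, float] = LOG_RATIO_BOUNDS,
    n_grid: int = 49,
) -> float:
    """Least-squares log-ratio: coarse grid scan, then bounded refinement."""
    idx = [predictor.factors.index(f) for f in point_factors]

    def sse(x: float) -> float:
        pred = predictor.shifts(math.exp(x))[idx]
        r = observed - pred
        return float(r @ r)

    grid = np.linspace(bounds[0], bounds[1], n_grid)
    best = min(grid, key=sse)
    step = (bounds[1] - bounds[0]) / (n_grid - 1)
    lo = max(bounds[0], best - 2 * step)
    hi = min(bounds[1], best + 2 * step)
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x) if res.fun <= sse(best) else float(best)


def fit_pcl_pna(
    curve: Sequence[DilutionPoint],
    internal: Solution,
    externals: Sequence[tuple[float, Solution]],
    model: ActivityModel,
    ctx: PhysicalContext,
    *,
    reference_factor: float = 1.0,
    n_bootstrap: int = 1000,
    seed: int = 0,
    pool_cations: bool = True,
    classify_hi: float = 5.0,
    classify_lo: float = 0.5,
) -> PermeabilityFitResult:
    """Fit P_Cl/P_Na to the dilution-potential shift curve.

    Nonlinear least squares in log(P_Cl/P_Na) against the GHK-predicted
    shifts. The reference point (ΔE_rev ≡ 0) carries no information and does
    not affect the estimate. The bootstrap CI resamples each observed shift
    from N(obs, se) — se from the E_rev estimates, or the residual rmse when
    absent — and refits; percentile 95% bounds are reported. Hypothetical
    limit curves for P_Cl/P_Na → ∞ (pure Cl- Nernst shifts) and → 0 (pure
    Na+ Nernst shifts) are attached for plotting.
    """
    pts = [p for p in curve if p.dilution_factor != reference_factor]
    if len(pts) < 2:
        raise ValueError("need at least 2 dilution points beyond the reference")
    predictor = _ShiftPredictor(
        internal, externals, reference_factor, model, ctx, pool_cations
    )
    factors = [p.dilution_factor for p in pts]
    observed = np.array([p.delta_erev_mV for p in pts])
    x_hat = _fit_log_ratio(observed, predictor, factors)
    ratio = math.exp(x_hat)
    idx = [predictor.factors.index(f) for f in factors]
    resid = observed - predictor.shifts(ratio)[idx]
    rmse = float(np.sqrt(np.mean(resid**2)))

    ci_low = ci_high = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        ses = np.array(
            [p.standard_error_mV if p.standard_error_mV else max(rmse, 1e-6) for p in pts]
        )
        samples = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            resampled = observed + rng.normal(0.0, ses)
            samples[b] = _fit_log_ratio(resampled, predictor, factors)
        lo, hi = np.percentile(samples, [2.5, 97.5])
        ci_low, ci_high = float(math.exp(lo)), float(math.exp(hi))
        ci_low = min(ci_low, ratio)
        ci_high = max(ci_high, ratio)

    all_factors = predictor.factors
    inf_shifts = predictor.shifts(math.exp(LOG_RATIO_BOUNDS[1] + 10))
    zero_shifts = predictor.shifts(math.exp(LOG_RATIO_BOUNDS[0] - 10))
    limit_anion = tuple(
        (predictor.a_cl_out[k], float(inf_shifts[k])) for k in range(len(all_factors))
    )
    limit_cation = tuple(
        (predictor.a_cl_out[k], float(zero_shifts[k])) for k in range(len(all_factors))
    )
    return PermeabilityFitResult(
        ratio,
        ci_low,
        ci_high,
        x_hat,
        rmse,
        len(pts),
        classify_selectivity(ratio, hi=classify_hi, lo=classify_lo),
        limit_anion,
        limit_cation,
    )


def classify_selectivity(
    ratio: float, hi: float = 5.0, lo: float = 0.5
) -> str:
    """Label a fitted P_Cl/P_Na: above *hi* anion-selective, below *lo* cation-selective."""
    if ratio > hi:
        return "anion_selective"
    if ratio < lo:
        return "cation_selective"
    return "nonselective"


def shift_analysis(
    erev_a: Sequence[ErevEstimate | float],
    erev_b: Sequence[ErevEstimate | float],
    *,
    n_bootstrap: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ShiftResult:
    """Reversal-potential shift between two condition sets (b minus a).

    Difference of means with a seeded percentile bootstrap CI; the direction
    label is assigned only when the CI excludes zero. With fewer than two
    estimates per side no CI is formed and the direction is "undetermined"
    unless both sides are single analytic (noise-free) values.
    """

    def values(xs) -> np.ndarray:
        return np.array(
            [x.value_mV if isinstance(x, ErevEstimate) else float(x) for x in xs]
        )

    a, b = values(erev_a), values(erev_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both condition sets must be non-empty")
    delta = float(b.mean() - a.mean())
    if a.size < 2 or b.size < 2:
        if a.size == b.size == 1:
            direction = "positive" if delta > 0 else "negative" if delta < 0 else "none"
            return ShiftResult(delta, None, None, direction, 1, 1)
        return ShiftResult(delta, None, None, "undetermined", a.size, b.size)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for k in range(n_bootstrap):
        boots[k] = rng.choice(b, b.size).mean() - rng.choice(a, a.size).mean()
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    if lo > 0:
        direction = "positive"
    elif hi < 0:
        direction = "negative"
    else:
        direction = "none"
    return ShiftResult(delta, float(lo), float(hi), direction, a.size, b.size)


def analytic_dilution_experiment(
    channel_ratio: float,
    internal: Solution,
    externals: Sequence[tuple[float, Solution]],
    model: ActivityModel,
    ctx: PhysicalContext,
    *,
    reference_factor: float = 1.0,
    pool_cations: bool = True,
) -> DilutionExperiment:
    """Noise-free dilution experiment with closed-form E_rev values.

    Useful as a round-trip oracle: curves built from it refit to exactly
    ``channel_ratio``.
    """
    predictor = _ShiftPredictor(
        internal, externals, reference_factor, model, ctx, pool_cations
    )
    erevs = predictor.absolute(channel_ratio)
    estimates = {
        f: ErevEstimate(float(e), "closed_form")
        for (f, _), e in zip(externals, erevs)
    }
    return DilutionExperiment(internal, tuple(externals), estimates, reference_factor)
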