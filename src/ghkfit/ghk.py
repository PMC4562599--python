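"""Goldman–Hodgkin–Katz electrodiffusion computations.

The constant-field (GHK) framework links the reversal potential of a channel
to the relative permeabilities and inside/outside activities of the permeant
ions. Three layers are provided:

* :func:`nernst` — single-ion equilibrium potential (the limiting case).
* :func:`ghk_erev_two_ion` — the closed-form Na+/Cl- reversal potential

      E_rev = (RT/F) ln[(P_Na (a_Na)_o + P_Cl (a_Cl)_i) /
                        (P_Na (a_Na)_i + P_Cl (a_Cl)_o)]

  used to fit dilution-potential data for P_Cl/P_Na.
* :func:`ghk_current_density` / :func:`ghk_erev_multi` — per-ion constant-field
  flux currents summed over an arbitrary permeability map, with the reversal
  potential found numerically. Divalents (Ca2+) enter through the flux
  equation's z^2 weighting; no closed voltage form exists with divalents.

Sign conventions: membrane potential is inside minus outside; outward cation
flux is positive current. Temperatures are kelvin internally; RT/F is always
computed from scipy's CODATA constants, never hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from scipy.constants import R as GAS_CONSTANT
from scipy.constants import physical_constants
from scipy.optimize import brentq

from .solutions import ION_TABLE, ActivityModel, Solution, activity

FARADAY = physical_constants["Faraday constant"][0]

__all__ = [
    "PhysicalContext",
    "ChannelModel",
    "ErevEstimate",
    "nernst",
    "ghk_erev_two_ion",
    "ghk_current_density",
    "ghk_erev_multi",
]


@dataclass(frozen=True)
class PhysicalContext:
    """Temperature and physical constants; RT/F ≈ 25.4 mV at 22 °C."""

    temperature_K: float = 295.15
    R: float = GAS_CONSTANT
    F: float = FARADAY

    @property
    def vt_mV(self) -> float:
        """Thermal voltage RT/F in millivolts."""
        return 1000.0 * self.R * self.temperature_K / self.F

    @classmethod
    def from_celsius(cls, temperature_C: float) -> "PhysicalContext":
        return cls(temperature_K=temperature_C + 273.15)


@dataclass(frozen=True)
class ChannelModel:
    """Relative-permeability map of an open pore.

    Permeabilities are dimensionless ratios to the reference ion (Na+ by
    convention, P_ref = 1 by construction). ``conductance_scale`` converts the
    GHK driving term to simulated current (pA per activity-mM unit).
    """

    relative_permeabilities: Mapping[str, float]
    reference_ion: str = "Na"
    conductance_scale: float = 1.0

    def __post_init__(self) -> None:
        perms = dict(self.relative_permeabilities)
        for ion, p in perms.items():
            if ion not in ION_TABLE:
                raise ValueError(f"unknown ion {ion!r} in channel permeabilities")
            if p < 0:
                raise ValueError(f"permeability for {ion!r} must be >= 0, got {p}")
        if not any(p > 0 for p in perms.values()):
            raise ValueError("at least one permeability must be positive")
        ref = perms.get(self.reference_ion)
        if ref:
            perms = {ion: p / ref for ion, p in perms.items()}
        object.__setattr__(self, "relative_permeabilities", perms)

    def permeability(self, ion: str) -> float:
        return self.relative_permeabilities.get(ion, 0.0)


@dataclass(frozen=True)
class ErevEstimate:
    """A reversal potential with provenance of how it was obtained."""

    value_mV: float
    method: str  # "closed_form" | "root_find" | "interpolated"
    standard_error_mV: float | None = None
    n_replicates: int | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method == "closed_form" and self.standard_error_mV is not None:
            raise ValueError("closed-form reversal potentials carry no standard error")


def nernst(a_out_mM: float, a_in_mM: float, charge: int, ctx: PhysicalContext) -> float:
    """Equilibrium potential (RT/zF) ln(a_out/a_in), in mV."""
    if a_out_mM <= 0 or a_in_mM <= 0:
        raise ValueError(
            f"activities must be positive, got a_out={a_out_mM}, a_in={a_in_mM}"
        )
    if charge == 0:
        raise ValueError("charge must be nonzero")
    return ctx.vt_mV / charge * math.log(a_out_mM / a_in_mM)


def ghk_erev_two_ion(
    p_ratio: float,
    a_na_out: float,
    a_na_in: float,
    a_cl_out: float,
    a_cl_in: float,
    ctx: PhysicalContext,
) -> float:
    """Closed-form Na+/Cl- GHK reversal potential in mV.

    ``p_ratio`` is P_Cl/P_Na. Note the anion bookkeeping: the intracellular
    Cl- activity appears in the numerator and the extracellular in the
    denominator. ``p_ratio = 0`` reduces to the Na+ Nernst potential; the
    ``p_ratio -> inf`` limit is the Cl- Nernst potential.
    """
    if p_ratio < 0:
        raise ValueError(f"p_ratio must be >= 0, got {p_ratio}")
    for label, a in (
        ("(a_Na)_o", a_na_out),
        ("(a_Na)_i", a_na_in),
        ("(a_Cl)_o", a_cl_out),
        ("(a_Cl)_i", a_cl_in),
    ):
        if a <= 0:
            raise ValueError(f"{label} must be positive, got {a}")
    if math.isinf(p_ratio):
        return -ctx.vt_mV * math.log(a_cl_out / a_cl_in)
    num = a_na_out + p_ratio * a_cl_in
    den = a_na_in + p_ratio * a_cl_out
    return ctx.vt_mV * math.log(num / den)


def _flux_factor(u: float) -> float:
    """u / (1 - exp(-u)), continuous through u = 0."""
    if u == 0.0:
        return 1.0
    return u / (-math.expm1(-u))


def ghk_current_density(
    channel: ChannelModel,
    v_mV: float,
    sol_out: Solution,
    sol_in: Solution,
    model: ActivityModel,
    ctx: PhysicalContext,
) -> float:
    """Total GHK flux current at holding potential ``v_mV`` (outward positive).

    Per permeant ion S with charge z and u = zV/(RT/F):

        I_S = P_S * z * f(u) * (a_in - a_out * exp(-u)),   f(u) = u/(1-e^-u)

    in arbitrary units (the shared physical prefactor F^2/RT is absorbed into
    the channel's ``conductance_scale`` by callers). The removable singularity
    at V = 0 is handled exactly: f(0) = 1 gives I_S = P_S z (a_in - a_out).
    """
    total = 0.0
    seen = False
    for ion, p in channel.relative_permeabilities.items():
        if p == 0:
            continue
        spec = ION_TABLE[ion]
        if not spec.permeant:
            continue
        a_out = (
            activity(sol_out, ion, model) if ion in sol_out.ion_totals else 0.0
        )
        a_in = activity(sol_in, ion, model) if ion in sol_in.ion_totals else 0.0
        if a_out == 0.0 and a_in == 0.0:
            continue
        seen = True
        z = spec.charge
        u = z * v_mV / ctx.vt_mV
        total += p * z * _flux_factor(u) * (a_in - a_out * math.exp(-u))
    if not seen:
        raise ValueError(
            f"no permeant ion shared between channel and solutions "
            f"{sol_out.name!r}/{sol_in.name!r}"
        )
    return total


def ghk_erev_multi(
    channel: ChannelModel,
    sol_out: Solution,
    sol_in: Solution,
    model: ActivityModel,
    ctx: PhysicalContext,
    bracket_mV: tuple[float, float] = (-150.0, 150.0),
) -> ErevEstimate:
    """Reversal potential of the summed GHK flux current, by bracketed root search."""

    def current(v: float) -> float:
        return ghk_current_density(channel, v, sol_out, sol_in, model, ctx)

    lo, hi = bracket_mV
    f_lo, f_hi = current(lo), current(hi)
    if f_lo == 0.0:
        return ErevEstimate(lo, "root_find")
    if f_hi == 0.0:
        return ErevEstimate(hi, "root_find")
    if f_lo * f_hi > 0:
        raise ValueError(
            f"GHK current does not change sign on [{lo}, {hi}] mV "
            f"(I({lo}) = {f_lo:.4g}, I({hi}) = {f_hi:.4g}); "
            f"the reversal potential lies outside the bracket"
        )
    root = brentq(current, lo, hi, xtol=1e-10, rtol=1e-14)
    return ErevEstimate(float(root), "root_find")
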