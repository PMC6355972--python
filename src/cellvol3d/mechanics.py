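"""Hydrogel mechanics and osmotic-pressure calculators.

* Initial elastic modulus E: least-squares slope of the stress–strain curve
  over the 5–10% strain window (kPa per unit strain).
* Stress-relaxation half-time τ½: the time for the hold-phase stress to fall
  to half its initial value σ0 (σ0 taken at the first hold sample), with the
  crossing linearly interpolated between samples; ``None`` when the trace
  never halves within the record.
* PEG-400 osmotic pressure: empirical quartic in the wt/vol concentration c,

      y(atm) = 0.00002·c⁴ − 0.0007·c³ + 0.0311·c² + 0.5596·c

  converted to kPa at 101.325 kPa/atm.  Osmolarity treats PEG 400 as a
  single 400 g/mol osmolyte: (10·c g/L)/(0.4 kg/mol) = 25·c mOsm/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .stack_io import TraceRecord

__all__ = [
    "OsmoticCondition",
    "initial_modulus",
    "tau_half",
    "peg_pressure",
    "peg_osmolarity",
    "hypoosmotic_factor",
    "ATM_TO_KPA",
    "PEG_COEFFS",
]

ATM_TO_KPA = 101.325

#: quartic coefficients (c⁴, c³, c², c¹) for y in atm, c in % wt/vol
PEG_COEFFS = (0.00002, -0.0007, 0.0311, 0.5596)


@dataclass(frozen=True)
class OsmoticCondition:
    """One PEG-400 dose: concentration, pressure, osmolarity."""

    c_percent_wt_vol: float
    pressure_atm: float
    pressure_kPa: float
    osmolarity_mOsm_L: float


# ---------------------------------------------------------------------------
# rheology

def initial_modulus(
    strain, stress_kPa=None,
    window=(0.05, 0.10),
) -> float:
    """Slope (kPa) of the stress–strain curve within the strain window.

    Accepts either a :class:`TraceRecord` (its ramp phase is used) or two
    arrays ``strain, stress_kPa``.
    """
    if isinstance(strain, TraceRecord):
        tr = strain
        sel = tr.phase == "ramp"
        eps = tr.strain[sel]
        sig = tr.stress_kPa[sel]
    else:
        eps = np.asarray(strain, dtype=float)
        sig = np.asarray(stress_kPa, dtype=float)
    lo, hi = window
    inwin = (eps >= lo) & (eps <= hi)
    if inwin.sum() < 2:
        cov = (f"[{eps.min():.3g}, {eps.max():.3g}]" if eps.size else "empty")
        raise ValueError(
            f"fewer than 2 samples in the {lo:.0%}-{hi:.0%} strain window; "
            f"strain coverage found: {cov}"
        )
    fit = stats.linregress(eps[inwin], sig[inwin])
    return float(fit.slope)


def tau_half(trace: TraceRecord) -> tuple[float | None, float]:
    """Stress-relaxation half-time of the hold phase.

    Returns ``(tau_half_s, final_fraction)``: the first time after hold
    onset at which stress crosses σ0/2 (linear interpolation between the
    bracketing samples), or ``None`` with the final stress fraction when the
    record never halves.
    """
    hold = trace.hold()
    if hold.time_s.size < 2:
        raise ValueError("hold phase absent or too short")
    t = hold.time_s - hold.time_s[0]
    s = hold.stress_kPa
    sigma0 = float(s[0])
    if sigma0 <= 0:
        raise ValueError("non-positive initial hold stress")
    target = sigma0 / 2.0
    below = s <= target
    if not below.any():
        return None, float(s[-1] / sigma0)
    i = int(np.argmax(below))
    if i == 0:
        return 0.0, float(s[-1] / sigma0)
    t0, t1 = t[i - 1], t[i]
    s0, s1 = s[i - 1], s[i]
    frac = (s0 - target) / (s0 - s1)
    return float(t0 + frac * (t1 - t0)), float(s[-1] / sigma0)


# ---------------------------------------------------------------------------
# osmotics

def peg_pressure(c: float) -> OsmoticCondition:
    """Osmotic condition for a PEG-400 concentration ``c`` (% wt/vol)."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    a4, a3, a2, a1 = PEG_COEFFS
    y_atm = a4 * c**4 + a3 * c**3 + a2 * c**2 + a1 * c
    return OsmoticCondition(
        c_percent_wt_vol=float(c),
        pressure_atm=float(y_atm),
        pressure_kPa=float(y_atm * ATM_TO_KPA),
        osmolarity_mOsm_L=peg_osmolarity(c),
    )


def peg_osmolarity(c: float) -> float:
    """mOsm/L of ``c`` % wt/vol PEG 400 as a single osmolyte: 25·c."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    grams_per_L = 10.0 * c
    return grams_per_L / 0.400  # 400 g/mol → mmol/L = mOsm/L


def hypoosmotic_factor(water_fraction: float) -> float:
    """Osmolarity scale factor after diluting medium with pure water.

    Diluting with a fraction ``w`` of deionized water scales every solute
    concentration by ``1 − w``.
    """
    if not (0.0 <= water_fraction < 1.0):
        raise ValueError("water_fraction must be in [0, 1)")
    return 1.0 - water_fraction
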