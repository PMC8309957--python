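"""Calibration of kinetic parameters from measured concentration data.

Clearance comes from an ordinary least-squares fit of log-concentration on
time during the intradialytic decline (the single-exponential assumption
makes the log-linear slope ``−K/V``). Generation comes from the linear
interdialytic rise. The distribution volume is resolved from anthropometry
through a pluggable resolver, because published anthropometric total-body-
water formulas are institution choices rather than part of this model.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .core import (
    ConcentrationSeries,
    DistributionVolume,
    PatientAnthropometry,
    SamplePhase,
    SampleSite,
    Sex,
    VolumeSource,
)
from .errors import (
    ClippedClearanceWarning,
    ConfigurationError,
    DegenerateIntervalError,
    InsufficientDataError,
    NegativeGenerationWarning,
)

__all__ = [
    "FitResult",
    "TBWResolver",
    "fit_clearance_loglinear",
    "estimate_generation",
    "resolve_distribution_volume",
    "reference_fraction_lookup",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitResult:
    """Result of the log-linear intradialytic clearance fit."""

    clearance_hat: float      # mL/min
    c0_hat: float             # µmol/L, back-transformed intercept
    r_squared: float
    n_points: int
    residual_sd_log: float    # SD of log-scale residuals (0 for saturated fits)


@dataclass(frozen=True)
class TBWResolver:
    """Strategy for turning anthropometry into a distribution volume (mL).

    ``explicit_volume`` passes ``volume`` through unchanged;
    ``weight_fraction`` multiplies body weight by ``fraction``;
    ``formula_plugin`` delegates to a registered callable (e.g. an
    institutional total-body-water formula).
    """

    mode: VolumeSource
    volume: float | None = None
    fraction: float | None = None
    plugin: Callable[[PatientAnthropometry], float] | None = None


def fit_clearance_loglinear(series: ConcentrationSeries, volume: float,
                            window: tuple[float, float] | None = None) -> FitResult:
    """Fit dialyzer clearance from an intradialytic concentration decline.

    OLS of ``ln(C)`` on ``t`` over systemic intradialytic samples (optionally
    restricted to a time ``window``); the slope ``s`` (1/min) gives
    ``K̂ = −s·V`` and the intercept gives ``Ĉ0``. Non-positive
    concentrations cannot enter the log fit and are excluded with a logged
    warning; a positive slope (rising concentrations) yields ``K̂`` clipped
    to zero with a :class:`ClippedClearanceWarning`.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    samples = series.filtered(site=SampleSite.systemic,
                              phase=SamplePhase.intradialytic)
    if window is not None:
        lo, hi = window
        samples = [s for s in samples if lo <= s.time <= hi]
    usable = [s for s in samples if s.concentration > 0]
    n_dropped = len(samples) - len(usable)
    if n_dropped:
        logger.warning("excluded %d non-positive concentration(s) from log fit",
                       n_dropped)
    if len(usable) < 2:
        raise InsufficientDataError(
            f"need >= 2 usable intradialytic systemic samples, have {len(usable)}"
        )
    t = np.array([s.time for s in usable])
    y = np.log([s.concentration for s in usable])
    res = stats.linregress(t, y)
    slope, intercept = res.slope, res.intercept
    fitted = intercept + slope * t
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    n = len(usable)
    residual_sd_log = math.sqrt(ss_res / (n - 2)) if n > 2 else 0.0
    clearance_hat = -slope * volume
    if clearance_hat < 0:
        warnings.warn(
            "fitted slope is positive (concentrations rising); clearance "
            "clipped to 0", ClippedClearanceWarning, stacklevel=2,
        )
        clearance_hat = 0.0
    return FitResult(clearance_hat=clearance_hat, c0_hat=float(np.exp(intercept)),
                     r_squared=r_squared, n_points=n,
                     residual_sd_log=residual_sd_log)


def estimate_generation(series: ConcentrationSeries, volume: float) -> float:
    """Ammonia generation G (µmol/min) from the interdialytic rise.

    ``G = (C_end − C_start)·(V/1000)/Δt`` using the first and last
    interdialytic samples; V in mL is converted to litres so µmol/L × L/min
    gives µmol/min. A negative result (net removal off dialysis, e.g. under
    scavenger therapy) is returned unmodified with a warning.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    samples = series.filtered(phase=SamplePhase.interdialytic)
    if len(samples) < 2:
        raise InsufficientDataError(
            f"need >= 2 interdialytic samples, have {len(samples)}"
        )
    first, last = samples[0], samples[-1]
    dt = last.time - first.time
    if dt == 0:
        raise DegenerateIntervalError("interdialytic interval has zero length")
    g = (last.concentration - first.concentration) * (volume / 1000.0) / dt
    if g < 0:
        warnings.warn(f"estimated generation is negative ({g:.3g} µmol/min)",
                      NegativeGenerationWarning, stacklevel=2)
    return g


def resolve_distribution_volume(patient: PatientAnthropometry,
                                resolver: TBWResolver) -> DistributionVolume:
    """Resolve the ammonia distribution volume for a patient (mL)."""
    if resolver.mode is VolumeSource.explicit_volume:
        if resolver.volume is None:
            raise ConfigurationError("explicit_volume resolver needs a volume")
        return DistributionVolume(volume=resolver.volume,
                                  source=VolumeSource.explicit_volume)
    if resolver.mode is VolumeSource.weight_fraction:
        if resolver.fraction is None:
            raise ConfigurationError("weight_fraction resolver needs a fraction")
        volume = resolver.fraction * patient.weight * 1000.0
        return DistributionVolume(volume=volume,
                                  source=VolumeSource.weight_fraction,
                                  fraction=resolver.fraction)
    if resolver.mode is VolumeSource.formula_plugin:
        if resolver.plugin is None:
            raise ConfigurationError("formula_plugin resolver has no plugin registered")
        volume = float(resolver.plugin(patient))
        logger.info("plugin resolved distribution volume: %.0f mL", volume)
        return DistributionVolume(volume=volume, source=VolumeSource.formula_plugin)
    raise ConfigurationError(f"unknown resolver mode {resolver.mode!r}")


#: total-body-water fractions for the two reference simulation infants
#: (3 kg → 72 %, 4 kg → 63 %; both 50 cm, 3 days, male)
_REFERENCE_FRACTIONS: dict[tuple[float, float, float, Sex], float] = {
    (3.0, 50.0, 3.0, Sex.male): 0.72,
    (4.0, 50.0, 3.0, Sex.male): 0.63,
}


def reference_fraction_lookup(patient: PatientAnthropometry) -> float:
    """Lookup-table plugin holding only the two reference infants' TBW.

    Anthropometric TBW formulas carry institution-specific coefficients and
    are deliberately not hard-coded; this plugin exists so the reference
    simulations are runnable out of the box. Any other anthropometry raises
    :class:`ConfigurationError` — register your own formula plugin instead.
    """
    key = (patient.weight, patient.height, patient.age, patient.sex)
    try:
        fraction = _REFERENCE_FRACTIONS[key]
    except KeyError:
        raise ConfigurationError(
            "reference TBW lookup only covers the 3 kg and 4 kg reference "
            "infants (50 cm, 3 days, male); register a formula plugin or use "
            "an explicit volume / weight fraction"
        ) from None
    return fraction * patient.weight * 1000.0
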