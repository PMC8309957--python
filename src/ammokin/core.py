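"""Domain types and closed-form solutions of the one-compartment ammonia model.

The model treats the patient as a single well-mixed compartment of volume
``V`` (the ammonia distribution volume, taken equal to total body water)
with a constant endogenous ammonia generation rate ``G`` and, during
dialysis, a constant dialyzer clearance ``K``:

    dC/dt = 1000·G/V − (K/V)·C        (on dialysis)
    dC/dt = 1000·G/V                  (off dialysis)

Units are fixed package-wide and never mixed:

=============  ==========
quantity       unit
=============  ==========
time           min
volume V       mL
clearance K    mL/min
blood flow Qb  mL/min
concentration  µmol/L
generation G   µmol/min
=============  ==========

The factor 1000 converts the mL volume to litres so that G (µmol/min)
feeds a concentration in µmol/L. With ``G = 0`` the on-dialysis solution
reduces to the classic single-exponential decay ``C(t) = C0·exp(−K·t/V)``,
and the time to fall from ``C_start`` to ``C_target`` is
``T = (V/K)·ln(C_start/C_target)``. Clearance itself can be measured from a
single paired sample at the dialyzer ports:
``K = Qb·(C_inlet − C_outlet)/C_inlet``.
"""

from __future__ import annotations

import math
import warnings
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import (
    DegenerateInputWarning,
    InconsistencyError,
    InvalidMeasurementError,
    NoSteadyStateError,
    UndefinedExtractionError,
    UnreachableTargetError,
)

__all__ = [
    "Sex",
    "SampleSite",
    "SamplePhase",
    "VolumeSource",
    "PatientAnthropometry",
    "DistributionVolume",
    "DialysisSetup",
    "KineticParameters",
    "ConcentrationSample",
    "ConcentrationSeries",
    "clearance_from_paired_samples",
    "extraction_ratio",
    "concentration_at",
    "time_to_target",
    "steady_state_concentration",
    "round_minutes",
]


class Sex(str, Enum):
    female = "female"
    male = "male"


class SampleSite(str, Enum):
    """Where a blood sample was drawn."""

    systemic = "systemic"
    dialyzer_inlet = "dialyzer_inlet"
    dialyzer_outlet = "dialyzer_outlet"


class SamplePhase(str, Enum):
    """Whether a sample (or model phase) is on or off dialysis."""

    intradialytic = "intradialytic"
    interdialytic = "interdialytic"


class VolumeSource(str, Enum):
    """How a distribution volume was obtained."""

    explicit_volume = "explicit_volume"
    weight_fraction = "weight_fraction"
    formula_plugin = "formula_plugin"


class PatientAnthropometry(BaseModel):
    """Neonatal anthropometry used to resolve the distribution volume.

    ``weight`` kg, ``height`` cm, ``age`` days.
    """

    model_config = ConfigDict(frozen=True)

    weight: float = Field(gt=0)
    height: float = Field(gt=0)
    age: float = Field(ge=0)
    sex: Sex


class DistributionVolume(BaseModel):
    """A resolved ammonia distribution volume in mL, with its provenance."""

    model_config = ConfigDict(frozen=True)

    volume: float = Field(gt=0, description="mL")
    source: VolumeSource
    fraction: float | None = Field(default=None, gt=0, le=1)

    @model_validator(mode="after")
    def _fraction_iff_weight_fraction(self) -> "DistributionVolume":
        if self.source is VolumeSource.weight_fraction and self.fraction is None:
            raise ValueError("weight_fraction volume requires the fraction used")
        return self


class DialysisSetup(BaseModel):
    """One concrete treatment configuration (machine, dialyzer, flows).

    At least one of ``extraction_ratio`` and ``clearance`` must be given;
    when both are given they must agree via ``clearance = ER × blood_flow``.
    """

    model_config = ConfigDict(frozen=True)

    machine: str
    dialyzer: str
    surface_area: float | None = Field(default=None, gt=0, description="m²")
    blood_flow: float = Field(gt=0, description="mL/min")
    dialysate_flow: float | None = Field(default=None, gt=0, description="mL/min")
    extraction_ratio: float | None = Field(default=None, ge=0, le=1)
    clearance: float | None = Field(default=None, ge=0, description="mL/min")

    @model_validator(mode="after")
    def _check_clearance(self) -> "DialysisSetup":
        if self.extraction_ratio is None and self.clearance is None:
            raise ValueError("give at least one of extraction_ratio or clearance")
        if self.clearance is not None:
            if self.clearance > self.blood_flow * (1 + 1e-9):
                raise ValueError("clearance cannot exceed blood flow")
            if self.extraction_ratio is not None:
                implied = self.extraction_ratio * self.blood_flow
                scale = max(abs(implied), abs(self.clearance), 1e-300)
                if abs(implied - self.clearance) > 1e-9 * scale:
                    raise ValueError(
                        "clearance and extraction_ratio × blood_flow disagree"
                    )
        return self

    @property
    def resolved_clearance(self) -> float:
        """Clearance in mL/min, from the explicit value or ER × Qb."""
        if self.clearance is not None:
            return self.clearance
        return self.extraction_ratio * self.blood_flow  # type: ignore[operator]

    @property
    def resolved_extraction_ratio(self) -> float:
        if self.extraction_ratio is not None:
            return self.extraction_ratio
        return self.clearance / self.blood_flow  # type: ignore[operator]

    @classmethod
    def from_clearance(cls, clearance: float, blood_flow: float | None = None,
                       label: str = "unspecified") -> "DialysisSetup":
        """Minimal setup carrying only a clearance (for simulation phases)."""
        qb = blood_flow if blood_flow is not None else max(clearance, 1.0)
        return cls(machine=label, dialyzer=label, blood_flow=qb, clearance=clearance)


class KineticParameters(BaseModel):
    """The (K, V, G, C0) tuple governing one compartment-model trajectory."""

    model_config = ConfigDict(frozen=True)

    clearance: float = Field(ge=0, description="K, mL/min")
    volume: float = Field(gt=0, description="V, mL")
    generation: float = Field(default=0.0, ge=0, description="G, µmol/min")
    start_concentration: float = Field(ge=0, description="C0, µmol/L")


class ConcentrationSample(BaseModel):
    model_config = ConfigDict(frozen=True)

    time: float = Field(description="min from the series origin", allow_inf_nan=False)
    concentration: float = Field(ge=0, description="µmol/L")
    site: SampleSite = SampleSite.systemic
    phase: SamplePhase = SamplePhase.intradialytic


class ConcentrationSeries(BaseModel):
    """Ordered timestamped ammonia samples (site/phase labelled per sample)."""

    model_config = ConfigDict(frozen=True)

    samples: tuple[ConcentrationSample, ...]

    @model_validator(mode="after")
    def _strictly_increasing(self) -> "ConcentrationSeries":
        if len(self.samples) == 0:
            raise ValueError("series must contain at least one sample")
        times = [s.time for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        return self

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.samples], dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([s.concentration for s in self.samples], dtype=float)

    def filtered(self, site: SampleSite | None = None,
                 phase: SamplePhase | None = None) -> list[ConcentrationSample]:
        out = list(self.samples)
        if site is not None:
            out = [s for s in out if s.site is site]
        if phase is not None:
            out = [s for s in out if s.phase is phase]
        return out

    def shifted(self, delta: float) -> "ConcentrationSeries":
        """Same series with every timestamp moved by ``delta`` minutes."""
        return ConcentrationSeries(samples=tuple(
            s.model_copy(update={"time": s.time + delta}) for s in self.samples
        ))

    @staticmethod
    def from_arrays(times: Iterable[float], concentrations: Iterable[float],
                    site: SampleSite = SampleSite.systemic,
                    phase: SamplePhase | Sequence[SamplePhase] = SamplePhase.intradialytic,
                    ) -> "ConcentrationSeries":
        times = list(times)
        concentrations = list(concentrations)
        if isinstance(phase, SamplePhase):
            phases = [phase] * len(times)
        else:
            phases = list(phase)
        return ConcentrationSeries(samples=tuple(
            ConcentrationSample(time=t, concentration=c, site=site, phase=p)
            for t, c, p in zip(times, concentrations, phases)
        ))


# ---------------------------------------------------------------------------
# closed-form operations


def clearance_from_paired_samples(blood_flow: float, c_inlet: float,
                                  c_outlet: float) -> float:
    """Dialyzer clearance from one inlet/outlet concentration pair.

    ``K = Qb·(C_inlet − C_outlet)/C_inlet`` (mL/min). The result is bounded
    by ``[0, Qb]`` for any physically valid pair.

    Raises
    ------
    UndefinedExtractionError
        If the inlet concentration is zero (extraction undefined).
    InvalidMeasurementError
        If the outlet exceeds the inlet, or either concentration is
        negative — a sampling or labeling fault, not a kinetic state.
    """
    if blood_flow <= 0:
        raise ValueError("blood_flow must be positive")
    if c_inlet == 0:
        raise UndefinedExtractionError("inlet concentration is zero")
    if c_inlet < 0 or c_outlet < 0:
        raise InvalidMeasurementError("concentrations cannot be negative")
    if c_outlet > c_inlet:
        raise InvalidMeasurementError(
            f"outlet ({c_outlet}) exceeds inlet ({c_inlet}): "
            "check sampling sites / labels"
        )
    return blood_flow * (c_inlet - c_outlet) / c_inlet


def extraction_ratio(clearance: float, blood_flow: float) -> float:
    """Single-pass extraction ratio ``ER = K/Qb`` (dimensionless, in [0, 1])."""
    if blood_flow <= 0:
        raise ValueError("blood_flow must be positive")
    if clearance < 0:
        raise ValueError("clearance cannot be negative")
    if clearance > blood_flow:
        raise InconsistencyError(
            f"clearance {clearance} mL/min exceeds blood flow {blood_flow} mL/min"
        )
    return clearance / blood_flow


def steady_state_concentration(clearance: float, generation: float) -> float:
    """Concentration at which dialytic removal balances generation.

    ``C∞ = 1000·G/K`` µmol/L (the 1000 converts V-referenced clearance in
    mL/min to L/min). On-dialysis trajectories converge to this value.
    """
    if clearance <= 0:
        raise NoSteadyStateError(
            "no steady state without dialytic clearance (K must be > 0)"
        )
    if generation < 0:
        raise ValueError("generation cannot be negative")
    return 1000.0 * generation / clearance


def concentration_at(params: KineticParameters, t, phase: SamplePhase = SamplePhase.intradialytic):
    """Concentration (µmol/L) at time(s) ``t`` minutes into a phase.

    On dialysis with ``K > 0``:
        ``C(t) = C∞ + (C0 − C∞)·exp(−K·t/V)`` with ``C∞ = 1000·G/K``.
    Off dialysis (or ``K = 0``): linear rise ``C(t) = C0 + 1000·G·t/V``.

    With ``G = 0`` the on-dialysis form reduces exactly to
    ``C0·exp(−K·t/V)``. Accepts a scalar or array of times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    k, v, g, c0 = (params.clearance, params.volume,
                   params.generation, params.start_concentration)
    if phase is SamplePhase.intradialytic and k > 0:
        c_inf = 1000.0 * g / k
        out = c_inf + (c0 - c_inf) * np.exp(-k * t_arr / v)
    else:
        out = c0 + 1000.0 * g * t_arr / v
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def time_to_target(c_start: float, c_target: float, clearance: float,
                   volume: float, generation: float = 0.0) -> float:
    """Minutes of dialysis needed to fall from ``c_start`` to ``c_target``.

    With ``G = 0`` this is ``T = (V/K)·ln(C_start/C_target)``; with ongoing
    generation the decay asymptote shifts to ``C∞ = 1000·G/K`` and
    ``T = (V/K)·ln((C_start − C∞)/(C_target − C∞))``.

    Returns 0.0 with a :class:`DegenerateInputWarning` when the start is
    already at or below the target. Raises
    :class:`UnreachableTargetError` when the target lies at or below the
    steady state — no amount of dialysis at this clearance reaches it.
    """
    if c_target <= 0:
        raise ValueError("c_target must be positive")
    if clearance <= 0:
        raise ValueError("clearance must be positive to remove ammonia")
    if volume <= 0:
        raise ValueError("volume must be positive")
    if generation < 0:
        raise ValueError("generation cannot be negative")
    if c_start <= c_target:
        warnings.warn(
            f"start concentration {c_start} is already at/below target {c_target}",
            DegenerateInputWarning, stacklevel=2,
        )
        return 0.0
    c_inf = 1000.0 * generation / clearance
    if c_target <= c_inf:
        raise UnreachableTargetError(
            f"target {c_target} µmol/L is at or below the steady state "
            f"{c_inf:.1f} µmol/L sustained by generation"
        )
    return (volume / clearance) * math.log((c_start - c_inf) / (c_target - c_inf))


def round_minutes(t: float) -> int:
    """Round a time in minutes to an integer, halves away from zero.

    Used for table/report output only; internal values stay float.
    """
    return int(math.copysign(math.floor(abs(t) + 0.5), t))
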