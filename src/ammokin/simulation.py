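"""Forward simulation of concentration profiles over multi-phase schedules.

A schedule is an ordered list of phases (dialysis sessions and off-dialysis
gaps). Within each phase the model is autonomous, so the profile is
evaluated with the exact closed forms from :mod:`ammokin.core`, chaining
each phase's end concentration into the next. A fixed-step numerical
integrator of the same ODE is provided as an independent oracle for
validating the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .core import (
    DialysisSetup,
    KineticParameters,
    SamplePhase,
    concentration_at,
)

__all__ = [
    "SchedulePhase",
    "SimulationResult",
    "simulate_schedule",
    "integrate_oracle",
    "evaluate_at",
]


class SchedulePhase(BaseModel):
    """One schedule segment: a dialysis session (with setup) or a gap."""

    model_config = ConfigDict(frozen=True)

    duration: float = Field(gt=0, description="min")
    setup: DialysisSetup | None = None
    label: str = ""

    @property
    def kind(self) -> SamplePhase:
        return (SamplePhase.intradialytic if self.setup is not None
                else SamplePhase.interdialytic)

    @property
    def clearance(self) -> float:
        return self.setup.resolved_clearance if self.setup is not None else 0.0

    @property
    def display_label(self) -> str:
        if self.label:
            return self.label
        if self.setup is not None:
            return f"{self.setup.machine}/{self.setup.dialyzer}"
        return "off-dialysis"


@dataclass
class SimulationResult:
    """A simulated trajectory on a time grid.

    ``phase_boundaries[i]`` is the grid index at which phase ``i`` starts;
    the shared boundary point belongs to the ending phase in
    :meth:`to_frame`. Concentration is continuous across boundaries by
    construction.
    """

    times: np.ndarray
    concentrations: np.ndarray
    phase_boundaries: list[int]
    phase_labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: time_min, concentration_umol_L, phase_label."""
        labels = np.empty(len(self.times), dtype=object)
        bounds = self.phase_boundaries + [len(self.times)]
        for i, lab in enumerate(self.phase_labels):
            lo = bounds[i]
            hi = bounds[i + 1]
            labels[lo:hi] = lab
        # boundary points carry the ending phase's label
        for i in range(1, len(self.phase_labels)):
            labels[bounds[i]] = self.phase_labels[i - 1]
        return pd.DataFrame({
            "time_min": self.times,
            "concentration_umol_L": self.concentrations,
            "phase_label": labels,
        })


def _phase_grid(duration: float, dt: float) -> np.ndarray:
    """Local grid [0, dt, 2dt, ..., duration]; final step may be short."""
    grid = np.arange(0.0, duration, dt)
    return np.append(grid, duration)


def _chain_start_concentrations(params: KineticParameters,
                                phases: list[SchedulePhase]) -> list[float]:
    """Concentration entering each phase, by closed-form chaining."""
    starts = [params.start_concentration]
    c = params.start_concentration
    for phase in phases:
        p = params.model_copy(update={"clearance": phase.clearance,
                                      "start_concentration": c})
        c = concentration_at(p, phase.duration, phase.kind)
        starts.append(c)
    return starts  # length len(phases)+1; last entry is the final value


def simulate_schedule(params: KineticParameters, phases: list[SchedulePhase],
                      dt: float = 1.0) -> SimulationResult:
    """Piecewise closed-form trajectory over a schedule.

    The grid has step ``dt`` within each phase plus the exact phase end
    point, so phase boundaries are always on the grid. V and G come from
    ``params``; each phase's clearance comes from its setup (0 for gaps).
    """
    if not phases:
        raise ValueError("schedule needs at least one phase")
    if dt <= 0:
        raise ValueError("dt must be positive")
    starts = _chain_start_concentrations(params, phases)
    times: list[np.ndarray] = [np.array([0.0])]
    concs: list[np.ndarray] = [np.array([starts[0]])]
    boundaries = [0]
    labels = []
    offset = 0.0
    n_points = 1
    for i, phase in enumerate(phases):
        if i > 0:
            boundaries.append(n_points - 1)
        local = _phase_grid(phase.duration, dt)[1:]  # skip shared start point
        p = params.model_copy(update={"clearance": phase.clearance,
                                      "start_concentration": starts[i]})
        c_local = concentration_at(p, local, phase.kind)
        times.append(offset + local)
        concs.append(np.asarray(c_local))
        labels.append(phase.display_label)
        offset += phase.duration
        n_points += len(local)
    return SimulationResult(times=np.concatenate(times),
                            concentrations=np.concatenate(concs),
                            phase_boundaries=boundaries,
                            phase_labels=labels)


def integrate_oracle(params: KineticParameters, phases: list[SchedulePhase],
                     dt: float = 0.1) -> SimulationResult:
    """Fixed-step explicit (Heun) integration of the compartment ODE.

    Integrates ``dC/dt = 1000·G/V − (K/V)·C`` on the same grid layout as
    :func:`simulate_schedule`, independently of the closed forms, as a
    validation oracle. Discrepancy shrinks as ``dt → 0``.
    """
    if not phases:
        raise ValueError("schedule needs at least one phase")
    if dt <= 0:
        raise ValueError("dt must be positive")
    v, g = params.volume, params.generation
    times: list[np.ndarray] = [np.array([0.0])]
    concs: list[np.ndarray] = [np.array([params.start_concentration])]
    boundaries = [0]
    labels = []
    offset = 0.0
    n_points = 1
    c = params.start_concentration
    for i, phase in enumerate(phases):
        if i > 0:
            boundaries.append(n_points - 1)
        k = phase.clearance
        local = _phase_grid(phase.duration, dt)
        out = np.empty(len(local) - 1)
        t_prev = local[0]
        for j, t_next in enumerate(local[1:]):
            h = t_next - t_prev
            f0 = 1000.0 * g / v - k * c / v
            c_pred = c + h * f0
            f1 = 1000.0 * g / v - k * c_pred / v
            c = c + 0.5 * h * (f0 + f1)
            out[j] = c
            t_prev = t_next
        times.append(offset + local[1:])
        concs.append(out)
        labels.append(phase.display_label)
        offset += phase.duration
        n_points += len(out)
    return SimulationResult(times=np.concatenate(times),
                            concentrations=np.concatenate(concs),
                            phase_boundaries=boundaries,
                            phase_labels=labels)


def evaluate_at(params: KineticParameters, phases: list[SchedulePhase],
                times) -> np.ndarray:
    """Closed-form concentrations at arbitrary times within a schedule."""
    if not phases:
        raise ValueError("schedule needs at least one phase")
    t = np.atleast_1d(np.asarray(times, dtype=float))
    phase_starts = np.concatenate([[0.0], np.cumsum([p.duration for p in phases])])
    if np.any(t < 0) or np.any(t > phase_starts[-1] * (1 + 1e-12)):
        raise ValueError("times must lie within the schedule span")
    starts = _chain_start_concentrations(params, phases)
    idx = np.clip(np.searchsorted(phase_starts, t, side="right") - 1,
                  0, len(phases) - 1)
    out = np.empty_like(t)
    for i, phase in enumerate(phases):
        mask = idx == i
        if not np.any(mask):
            continue
        p = params.model_copy(update={"clearance": phase.clearance,
                                      "start_concentration": starts[i]})
        out[mask] = concentration_at(p, t[mask] - phase_starts[i], phase.kind)
    return out
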