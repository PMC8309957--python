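"""Synthetic patients, sessions and dialyzer samples with known truth.

Emulates the measurement structure the estimators consume: noisy
exponential intradialytic decay, linear interdialytic rise (hourly sampling
by default) and paired inlet/outlet dialyzer samples. Noise is
multiplicative lognormal with median 1 — assay error scales with
concentration over the 100–3000 µmol/L clinical range — with a default
coefficient of variation of 5 %. Everything is reproducible from an
integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    ConcentrationSample,
    ConcentrationSeries,
    DialysisSetup,
    KineticParameters,
    SampleSite,
)
from .simulation import SchedulePhase, evaluate_at

__all__ = [
    "SyntheticScenario",
    "single_session_scenario",
    "generate_session",
    "generate_paired_dialyzer_samples",
]


def _lognormal_multipliers(rng: np.random.Generator, n: int, cv: float
                           ) -> np.ndarray:
    """Median-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(n))


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground truth plus sampling design for one synthetic session."""

    truth: KineticParameters
    sampling_times: tuple[float, ...]
    phases: tuple[SchedulePhase, ...]
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv cannot be negative")
        if not self.phases:
            raise ValueError("scenario needs at least one phase")
        span = sum(p.duration for p in self.phases)
        times = self.sampling_times
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sampling_times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] > span):
            raise ValueError("sampling_times must lie within the schedule span")


def single_session_scenario(clearance: float, volume: float,
                            start_concentration: float,
                            duration: float = 240.0, interval: float = 60.0,
                            noise_cv: float = 0.05, seed: int = 0,
                            generation: float = 0.0) -> SyntheticScenario:
    """One dialysis session sampled every ``interval`` minutes (hourly default)."""
    truth = KineticParameters(clearance=clearance, volume=volume,
                              generation=generation,
                              start_concentration=start_concentration)
    times = tuple(np.arange(0.0, duration + 1e-9, interval))
    phase = SchedulePhase(duration=duration,
                          setup=DialysisSetup.from_clearance(clearance),
                          label="session")
    return SyntheticScenario(truth=truth, sampling_times=times,
                             phases=(phase,), noise_cv=noise_cv, seed=seed)


def generate_session(scenario: SyntheticScenario) -> ConcentrationSeries:
    """Noisy systemic concentration series for a scenario.

    The noiseless trajectory is the closed-form schedule evaluation at the
    sampling times; each sample is multiplied by an independent lognormal
    factor. ``noise_cv = 0`` returns the exact trajectory; a fixed seed
    returns an identical series.
    """
    times = np.asarray(scenario.sampling_times)
    clean = evaluate_at(scenario.truth, list(scenario.phases), times)
    rng = np.random.default_rng(scenario.seed)
    noisy = clean * _lognormal_multipliers(rng, len(times), scenario.noise_cv)
    phase_starts = np.concatenate(
        [[0.0], np.cumsum([p.duration for p in scenario.phases])])
    idx = np.clip(np.searchsorted(phase_starts, times, side="right") - 1,
                  0, len(scenario.phases) - 1)
    samples = tuple(
        ConcentrationSample(time=float(t), concentration=float(c),
                            site=SampleSite.systemic,
                            phase=scenario.phases[i].kind)
        for t, c, i in zip(times, noisy, idx)
    )
    return ConcentrationSeries(samples=samples)


def generate_paired_dialyzer_samples(truth_clearance: float, blood_flow: float,
                                     c_systemic: float, noise_cv: float = 0.0,
                                     seed: int = 0) -> tuple[float, float]:
    """Noisy (inlet, outlet) pair consistent with a true clearance.

    The noiseless outlet is ``inlet·(1 − K/Qb)``, so
    :func:`~ammokin.core.clearance_from_paired_samples` applied to a
    noiseless pair returns the true clearance exactly. Inlet and outlet
    receive independent lognormal factors.
    """
    if not 0 <= truth_clearance <= blood_flow:
        raise ValueError("need 0 <= truth_clearance <= blood_flow")
    rng = np.random.default_rng(seed)
    m = _lognormal_multipliers(rng, 2, noise_cv)
    c_inlet = c_systemic * m[0]
    c_outlet = c_inlet * (1.0 - truth_clearance / blood_flow) * m[1]
    return float(c_inlet), float(c_outlet)
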