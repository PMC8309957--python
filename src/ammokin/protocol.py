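"""Time-to-threshold tables and staged treatment-protocol synthesis.

The table answers "how many minutes of dialysis does setup X at blood flow
Qb need to bring a start concentration down to a threshold" for a whole
grid of setups × thresholds × starts × flows, with the sentinel conventions
used in the published reference tables: "-" where the start is already at
or below the threshold (or the flow is outside the machine's operating
range) and ">>" where the computed time exceeds the reporting horizon.

Protocol synthesis turns an institution's machine menu and treatment goals
into an ordered list of concentration-banded stages: for each band the
least-intensive setup (smallest clearance) that still meets the band's
time goal is selected, so patients are stepped down to gentler circuits as
ammonia falls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import (
    DialysisSetup,
    DistributionVolume,
    PatientAnthropometry,
    round_minutes,
    steady_state_concentration,
    time_to_target,
)
from .errors import ConfigurationError, UnreachableTargetError

__all__ = [
    "TableSentinel",
    "SetupOption",
    "TimeTable",
    "TreatmentGoals",
    "ProtocolStage",
    "ProtocolPlan",
    "build_time_table",
    "recommend_setup",
    "synthesize_plan",
    "export_flowchart",
    "parse_structured_plan",
    "reference_setup_menu",
    "DEFAULT_HORIZON_MIN",
]

#: default reporting horizon: 24 h
DEFAULT_HORIZON_MIN = 1440.0


class TableSentinel(Enum):
    """Non-numeric table cells."""

    NOT_APPLICABLE = "-"
    EXCEEDS_HORIZON = ">>"


class SetupOption(BaseModel):
    """A machine/dialyzer menu entry with its operating blood-flow range."""

    model_config = ConfigDict(frozen=True)

    label: str
    machine: str
    dialyzer: str
    surface_area: float | None = Field(default=None, gt=0, description="m²")
    extraction_ratio: float = Field(gt=0, le=1)
    blood_flow_range: tuple[float, float] = Field(description="mL/min (min, max)")
    dialysate_flow: float | None = Field(default=None, gt=0, description="mL/min")
    priming_volume: float | None = Field(default=None, gt=0, description="mL")

    @model_validator(mode="after")
    def _range_ok(self) -> "SetupOption":
        lo, hi = self.blood_flow_range
        if not (0 < lo <= hi):
            raise ValueError("blood_flow_range must satisfy 0 < min <= max")
        return self

    def allows_flow(self, blood_flow: float) -> bool:
        lo, hi = self.blood_flow_range
        return lo <= blood_flow <= hi

    def clamp_flow(self, blood_flow: float) -> float:
        lo, hi = self.blood_flow_range
        return min(max(blood_flow, lo), hi)

    def at_flow(self, blood_flow: float) -> DialysisSetup:
        """Concrete setup at a given blood flow (ER assumed flow-independent)."""
        return DialysisSetup(
            machine=self.machine, dialyzer=self.dialyzer,
            surface_area=self.surface_area, blood_flow=blood_flow,
            dialysate_flow=self.dialysate_flow,
            extraction_ratio=self.extraction_ratio,
        )


def reference_setup_menu() -> list[SetupOption]:
    """The three neonatal setups the model was calibrated on.

    Extraction ratios are the measured means (45 % for the 4008/FXPaed,
    15 % and 13 % for the CarpeDiem 0.25 m² and 0.15 m² dialyzers); flow
    ranges, dialysate flows and priming volumes are the machines' published
    operating characteristics.
    """
    return [
        SetupOption(label="4008/FXPaed", machine="4008", dialyzer="FXPaed",
                    surface_area=0.20, extraction_ratio=0.45,
                    blood_flow_range=(30, 100), dialysate_flow=300,
                    priming_volume=53),
        SetupOption(label="CD025", machine="CarpeDiem", dialyzer="HCD 025",
                    surface_area=0.29, extraction_ratio=0.15,
                    blood_flow_range=(5, 50), dialysate_flow=10,
                    priming_volume=41),
        SetupOption(label="CD015", machine="CarpeDiem", dialyzer="HCD 015",
                    surface_area=0.17, extraction_ratio=0.13,
                    blood_flow_range=(5, 50), dialysate_flow=10,
                    priming_volume=32),
    ]


@dataclass(frozen=True)
class TimeTable:
    """Rows (setup, threshold) × columns (start concentration, blood flow)."""

    setups: tuple[SetupOption, ...]
    thresholds: tuple[float, ...]
    start_concentrations: tuple[float, ...]
    blood_flows: tuple[float, ...]
    volume: float
    horizon: float
    cells: dict[tuple[str, float, float, float], int | TableSentinel]

    def cell(self, setup_label: str, threshold: float, start: float,
             blood_flow: float) -> int | TableSentinel:
        return self.cells[(setup_label, threshold, start, blood_flow)]

    def to_frame(self, sentinels: dict[TableSentinel, str] | None = None
                 ) -> pd.DataFrame:
        """Formatted table with sentinel strings, ready for CSV export."""
        if sentinels is None:
            sentinels = {s: s.value for s in TableSentinel}
        rows = pd.MultiIndex.from_tuples(
            [(s.label, int(th)) for s in self.setups for th in self.thresholds],
            names=["setup", "threshold_umol_L"])
        cols = pd.MultiIndex.from_tuples(
            [(int(c0), int(qb)) for c0 in self.start_concentrations
             for qb in self.blood_flows],
            names=["start_umol_L", "blood_flow_mL_min"])
        data = []
        for s in self.setups:
            for th in self.thresholds:
                row = []
                for c0 in self.start_concentrations:
                    for qb in self.blood_flows:
                        v = self.cell(s.label, th, c0, qb)
                        row.append(sentinels[v] if isinstance(v, TableSentinel)
                                   else str(v))
                data.append(row)
        return pd.DataFrame(data, index=rows, columns=cols)

    def to_csv(self, path, sentinels: dict[TableSentinel, str] | None = None
               ) -> None:
        self.to_frame(sentinels).to_csv(path)


def build_time_table(patient_volume: float, setups: Sequence[SetupOption],
                     start_concentrations: Sequence[float],
                     thresholds: Sequence[float],
                     blood_flows: Sequence[float],
                     horizon: float = DEFAULT_HORIZON_MIN) -> TimeTable:
    """Time (integer minutes) for each setup/flow to reach each threshold.

    Cells are ``round(time_to_target(...))`` with G = 0;
    ``NOT_APPLICABLE`` where the start is at/below the threshold or the
    blood flow is outside the machine's operating range;
    ``EXCEEDS_HORIZON`` where the exact time exceeds ``horizon``.
    """
    if patient_volume <= 0:
        raise ValueError("patient_volume must be positive")
    if not setups:
        raise ConfigurationError("empty setup menu")
    cells: dict[tuple[str, float, float, float], int | TableSentinel] = {}
    for option in setups:
        for threshold in thresholds:
            for start in start_concentrations:
                for qb in blood_flows:
                    key = (option.label, threshold, start, qb)
                    if not option.allows_flow(qb) or start <= threshold:
                        cells[key] = TableSentinel.NOT_APPLICABLE
                        continue
                    k = option.extraction_ratio * qb
                    t = time_to_target(start, threshold, k, patient_volume)
                    cells[key] = (TableSentinel.EXCEEDS_HORIZON if t > horizon
                                  else round_minutes(t))
    return TimeTable(setups=tuple(setups), thresholds=tuple(thresholds),
                     start_concentrations=tuple(start_concentrations),
                     blood_flows=tuple(blood_flows), volume=patient_volume,
                     horizon=horizon, cells=cells)


class TreatmentGoals(BaseModel):
    """Ordered time goals (threshold µmol/L, max minutes) plus rebound cap."""

    model_config = ConfigDict(frozen=True)

    goals: tuple[tuple[float, float], ...] = Field(min_length=1)
    rebound_limit: float = Field(gt=0, description="µmol/L")

    @model_validator(mode="after")
    def _strictly_decreasing(self) -> "TreatmentGoals":
        thresholds = [g[0] for g in self.goals]
        if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("goal thresholds must be strictly decreasing")
        if any(t <= 0 or m <= 0 for t, m in self.goals):
            raise ValueError("thresholds and time limits must be positive")
        return self


class ProtocolStage(BaseModel):
    """One protocol stage: a concentration band (low, high] and its setup."""

    model_config = ConfigDict(frozen=True)

    band_low: float = Field(ge=0, description="µmol/L, exclusive lower edge")
    band_high: float = Field(gt=0, description="µmol/L, inclusive upper edge (inf allowed)")
    setup: DialysisSetup
    blood_flow_rule: float = Field(gt=0, description="mL/kg/min")
    rationale: str = ""
    feasible: bool = True
    predicted_minutes: float | None = None

    @model_validator(mode="after")
    def _band_ok(self) -> "ProtocolStage":
        if not self.band_low < self.band_high:
            raise ValueError("band_low must be below band_high")
        return self

    def contains(self, concentration: float) -> bool:
        return self.band_low < concentration <= self.band_high


class ProtocolPlan(BaseModel):
    """Ordered stages (highest band first) partitioning (0, ∞)."""

    model_config = ConfigDict(frozen=True)

    stages: tuple[ProtocolStage, ...] = Field(min_length=1)
    goals: TreatmentGoals
    patient_band: tuple[float, float] = Field(description="weight range, kg")

    @model_validator(mode="after")
    def _partition(self) -> "ProtocolPlan":
        if not math.isinf(self.stages[0].band_high):
            raise ValueError("first stage band must be open above (high = inf)")
        if self.stages[-1].band_low != 0:
            raise ValueError("last stage band must reach down to 0")
        for a, b in zip(self.stages, self.stages[1:]):
            if b.band_high != a.band_low:
                raise ValueError("stage bands must tile (0, inf) without gaps")
        return self

    @property
    def feasible(self) -> bool:
        return all(s.feasible for s in self.stages)


def recommend_setup(current_concentration: float, plan: ProtocolPlan
                    ) -> ProtocolStage:
    """The stage whose band contains the current concentration.

    Bands are (low, high], so an exact boundary value belongs to the lower
    band.
    """
    for stage in plan.stages:
        if stage.contains(current_concentration):
            return stage
    raise ConfigurationError(
        f"no stage band contains {current_concentration} µmol/L"
    )


def _pick_least_intensive(candidates):
    """Smallest clearance; ties by priming volume, then label."""
    return min(candidates, key=lambda c: (
        c["clearance"],
        c["option"].priming_volume if c["option"].priming_volume is not None
        else float("inf"),
        c["option"].label,
    ))


def synthesize_plan(patient: PatientAnthropometry, volume: DistributionVolume,
                    c_start: float, goals: TreatmentGoals,
                    available_setups: Sequence[SetupOption],
                    generation: float = 0.0,
                    qb_per_kg_initial: float = 15.0,
                    qb_per_kg_maintenance: float = 10.0) -> ProtocolPlan:
    """Derive a staged plan from a machine menu and treatment goals.

    Per-kg blood-flow rules (default 15 mL/kg/min for the initial stage,
    10 mL/kg/min thereafter) are converted to absolute flows and clamped to
    each machine's operating range before any kinetic computation. For each
    goal band the least-intensive setup meeting the goal via
    :func:`time_to_target` is chosen; if none does, the fastest is chosen
    and the stage flagged infeasible. Below the last goal threshold a
    maintenance stage is added, preferring the least-intensive setup whose
    generation steady state stays under the rebound limit. Deterministic
    for identical inputs.
    """
    if not available_setups:
        raise ConfigurationError("empty setup menu")
    v = volume.volume
    stages: list[ProtocolStage] = []
    band_high = math.inf
    seg_start = c_start
    for i, (threshold, max_time) in enumerate(goals.goals):
        rule = qb_per_kg_initial if i == 0 else qb_per_kg_maintenance
        candidates = []
        for option in available_setups:
            qb = option.clamp_flow(rule * patient.weight)
            k = option.extraction_ratio * qb
            if seg_start <= threshold:
                t = 0.0
            else:
                try:
                    t = time_to_target(seg_start, threshold, k, v, generation)
                except UnreachableTargetError:
                    t = math.inf
            candidates.append({"option": option, "qb": qb, "clearance": k,
                               "time": t})
        feasible = [c for c in candidates if c["time"] <= max_time]
        if feasible:
            chosen = _pick_least_intensive(feasible)
            ok = True
            why = (f"least-intensive setup reaching <{threshold:g} µmol/L in "
                   f"{chosen['time']:.0f} min (goal {max_time:g} min)")
        else:
            chosen = min(candidates, key=lambda c: (c["time"],
                                                    c["option"].label))
            ok = False
            why = (f"no menu setup reaches <{threshold:g} µmol/L within "
                   f"{max_time:g} min; fastest available recommended")
        stages.append(ProtocolStage(
            band_low=threshold, band_high=band_high,
            setup=chosen["option"].at_flow(chosen["qb"]),
            blood_flow_rule=rule, rationale=why, feasible=ok,
            predicted_minutes=None if math.isinf(chosen["time"]) else chosen["time"],
        ))
        band_high = threshold
        seg_start = threshold
    # maintenance band below the last goal threshold
    candidates = []
    for option in available_setups:
        qb = option.clamp_flow(qb_per_kg_maintenance * patient.weight)
        k = option.extraction_ratio * qb
        c_inf = steady_state_concentration(k, generation) if generation > 0 else 0.0
        candidates.append({"option": option, "qb": qb, "clearance": k,
                           "steady_state": c_inf})
    controlled = [c for c in candidates
                  if c["steady_state"] < goals.rebound_limit]
    if controlled:
        chosen = _pick_least_intensive(controlled)
        ok = True
        why = ("maintenance: least-intensive setup keeping steady state "
               f"({chosen['steady_state']:.0f} µmol/L) below the rebound limit "
               f"{goals.rebound_limit:g} µmol/L")
    else:
        chosen = max(candidates, key=lambda c: (c["clearance"],
                                                c["option"].label))
        ok = False
        why = ("maintenance: no menu setup keeps the generation steady state "
               f"below {goals.rebound_limit:g} µmol/L; highest clearance "
               "recommended")
    stages.append(ProtocolStage(
        band_low=0.0, band_high=band_high,
        setup=chosen["option"].at_flow(chosen["qb"]),
        blood_flow_rule=qb_per_kg_maintenance, rationale=why, feasible=ok,
    ))
    return ProtocolPlan(stages=tuple(stages), goals=goals,
                        patient_band=(patient.weight, patient.weight))


# ---------------------------------------------------------------------------
# serialization

_SCHEMA_KIND = "ammonia-dialysis-protocol"


def export_flowchart(plan: ProtocolPlan, format: str = "structured"):
    """Serialize a plan as a machine-readable document or a DOT graph.

    ``structured`` returns a JSON-serializable dict of ordered decision
    nodes that :func:`parse_structured_plan` round-trips; ``dot`` returns
    directed-graph source with one node per stage and edges labelled by the
    concentration condition that moves the patient to the next stage.
    """
    if format == "structured":
        return {
            "kind": _SCHEMA_KIND,
            "schema_version": 1,
            "patient_band_kg": list(plan.patient_band),
            "goals": [{"threshold_umol_L": t, "max_time_min": m}
                      for t, m in plan.goals.goals],
            "rebound_limit_umol_L": plan.goals.rebound_limit,
            "stages": [
                {
                    "band_low_umol_L": s.band_low,
                    "band_high_umol_L": (None if math.isinf(s.band_high)
                                         else s.band_high),
                    "machine": s.setup.machine,
                    "dialyzer": s.setup.dialyzer,
                    "surface_area_m2": s.setup.surface_area,
                    "blood_flow_mL_min": s.setup.blood_flow,
                    "dialysate_flow_mL_min": s.setup.dialysate_flow,
                    "extraction_ratio": s.setup.resolved_extraction_ratio,
                    "blood_flow_rule_mL_kg_min": s.blood_flow_rule,
                    "feasible": s.feasible,
                    "predicted_minutes": s.predicted_minutes,
                    "rationale": s.rationale,
                }
                for s in plan.stages
            ],
        }
    if format == "dot":
        lines = ["digraph protocol {", "    rankdir=TB;",
                 "    node [shape=box];"]
        for i, s in enumerate(plan.stages):
            if math.isinf(s.band_high):
                band = f"C > {s.band_low:g} umol/L"
            elif s.band_low == 0:
                band = f"C <= {s.band_high:g} umol/L"
            else:
                band = f"{s.band_low:g} < C <= {s.band_high:g} umol/L"
            label = (f"{band}\\n{s.setup.machine}/{s.setup.dialyzer}\\n"
                     f"Qb {s.blood_flow_rule:g} mL/kg/min")
            if not s.feasible:
                label += "\\n[goal not attainable]"
            lines.append(f'    stage{i} [label="{label}"];')
        for i in range(len(plan.stages) - 1):
            cond = f"C <= {plan.stages[i].band_low:g}"
            lines.append(f'    stage{i} -> stage{i + 1} [label="{cond}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown flowchart format {format!r}; "
                     "use 'structured' or 'dot'")


def parse_structured_plan(document) -> ProtocolPlan:
    """Inverse of ``export_flowchart(plan, 'structured')``."""
    if isinstance(document, str):
        document = json.loads(document)
    if document.get("kind") != _SCHEMA_KIND:
        raise ConfigurationError("document is not a protocol plan")
    goals = TreatmentGoals(
        goals=tuple((g["threshold_umol_L"], g["max_time_min"])
                    for g in document["goals"]),
        rebound_limit=document["rebound_limit_umol_L"],
    )
    stages = []
    for s in document["stages"]:
        setup = DialysisSetup(
            machine=s["machine"], dialyzer=s["dialyzer"],
            surface_area=s["surface_area_m2"],
            blood_flow=s["blood_flow_mL_min"],
            dialysate_flow=s["dialysate_flow_mL_min"],
            extraction_ratio=s["extraction_ratio"],
        )
        high = s["band_high_umol_L"]
        stages.append(ProtocolStage(
            band_low=s["band_low_umol_L"],
            band_high=math.inf if high is None else high,
            setup=setup, blood_flow_rule=s["blood_flow_rule_mL_kg_min"],
            rationale=s["rationale"], feasible=s["feasible"],
            predicted_minutes=s["predicted_minutes"],
        ))
    return ProtocolPlan(stages=tuple(stages), goals=goals,
                        patient_band=tuple(document["patient_band_kg"]))
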