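"""File I/O: measurement CSV, institution configuration, table export.

One CSV dialect only (comma separator, dot decimal, mandatory header,
UTF-8). The institution config is a YAML document validated against a
versioned schema; it declares the machine menu (with operating blood-flow
ranges), the treatment goals, the total-body-water resolver and the
sentinel strings used in exported tables.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .core import (
    ConcentrationSample,
    ConcentrationSeries,
    SamplePhase,
    SampleSite,
    VolumeSource,
)
from .errors import ConfigurationError, MeasurementParseError
from .estimation import TBWResolver, reference_fraction_lookup
from .protocol import SetupOption, TableSentinel, TimeTable, TreatmentGoals

__all__ = [
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "InstitutionConfig",
    "load_institution_config",
    "write_time_table_csv",
]

MEASUREMENT_COLUMNS = ("time_min", "concentration_umol_L", "site", "phase")


def read_measurements(path) -> ConcentrationSeries:
    """Parse a measurement CSV into a :class:`ConcentrationSeries`.

    Errors carry the 1-based line number of the offending row (header is
    line 1).
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MeasurementParseError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementParseError(
            f"missing required column(s): {', '.join(missing)}", line=1)
    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            samples.append(ConcentrationSample(
                time=float(row.time_min),
                concentration=float(row.concentration_umol_L),
                site=SampleSite(row.site),
                phase=SamplePhase(row.phase),
            ))
        except (ValueError, ValidationError) as exc:
            raise MeasurementParseError(str(exc), line=line) from exc
    try:
        return ConcentrationSeries(samples=tuple(samples))
    except ValidationError as exc:
        raise MeasurementParseError(f"invalid series: {exc}") from exc


def write_measurements(series: ConcentrationSeries, path) -> None:
    df = pd.DataFrame({
        "time_min": [s.time for s in series.samples],
        "concentration_umol_L": [s.concentration for s in series.samples],
        "site": [s.site.value for s in series.samples],
        "phase": [s.phase.value for s in series.samples],
    })
    df.to_csv(path, index=False)


class MachineEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str
    machine: str
    dialyzer: str
    surface_area_m2: float | None = Field(default=None, gt=0)
    extraction_ratio: float = Field(gt=0, le=1)
    blood_flow_range: tuple[float, float]
    dialysate_flow_ml_min: float | None = Field(default=None, gt=0)
    priming_volume_ml: float | None = Field(default=None, gt=0)


class GoalStage(BaseModel):
    model_config = ConfigDict(frozen=True)

    threshold_umol_l: float = Field(gt=0)
    max_time_min: float = Field(gt=0)


class GoalsSection(BaseModel):
    model_config = ConfigDict(frozen=True)

    stages: tuple[GoalStage, ...] = Field(min_length=1)
    rebound_limit_umol_l: float = Field(gt=0)


class TBWSection(BaseModel):
    model_config = ConfigDict(frozen=True)

    mode: VolumeSource = VolumeSource.weight_fraction
    fraction: float | None = Field(default=None, gt=0, le=1)
    volume_ml: float | None = Field(default=None, gt=0)


class SentinelSection(BaseModel):
    model_config = ConfigDict(frozen=True)

    not_applicable: str = "-"
    exceeds_horizon: str = ">>"


class TableSection(BaseModel):
    model_config = ConfigDict(frozen=True)

    start_concentrations: tuple[float, ...] = (3000, 1500, 800, 400, 200)
    thresholds: tuple[float, ...] = (400, 200, 100)
    blood_flows: tuple[float, ...] = (30, 50)
    horizon_min: float = Field(default=1440.0, gt=0)


class InstitutionConfig(BaseModel):
    """Validated institution configuration (schema version 1)."""

    model_config = ConfigDict(frozen=True)

    schema_version: int
    machines: tuple[MachineEntry, ...] = Field(min_length=1)
    goals: GoalsSection
    tbw: TBWSection = TBWSection()
    sentinels: SentinelSection = SentinelSection()
    table: TableSection = TableSection()

    def setup_menu(self) -> list[SetupOption]:
        return [SetupOption(label=m.label, machine=m.machine,
                            dialyzer=m.dialyzer, surface_area=m.surface_area_m2,
                            extraction_ratio=m.extraction_ratio,
                            blood_flow_range=m.blood_flow_range,
                            dialysate_flow=m.dialysate_flow_ml_min,
                            priming_volume=m.priming_volume_ml)
                for m in self.machines]

    def treatment_goals(self) -> TreatmentGoals:
        return TreatmentGoals(
            goals=tuple((g.threshold_umol_l, g.max_time_min)
                        for g in self.goals.stages),
            rebound_limit=self.goals.rebound_limit_umol_l,
        )

    def tbw_resolver(self) -> TBWResolver:
        if self.tbw.mode is VolumeSource.formula_plugin:
            # the only plugin shipped with the package
            return TBWResolver(mode=self.tbw.mode,
                               plugin=reference_fraction_lookup)
        return TBWResolver(mode=self.tbw.mode, fraction=self.tbw.fraction,
                           volume=self.tbw.volume_ml)

    def sentinel_map(self) -> dict[TableSentinel, str]:
        return {TableSentinel.NOT_APPLICABLE: self.sentinels.not_applicable,
                TableSentinel.EXCEEDS_HORIZON: self.sentinels.exceeds_horizon}


def load_institution_config(path) -> InstitutionConfig:
    """Load and validate a YAML institution config.

    Schema violations raise :class:`ConfigurationError` naming the
    offending field.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    if "schema_version" not in raw:
        raise ConfigurationError("config field 'schema_version' is required")
    try:
        return InstitutionConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigurationError(
            f"config field '{loc}': {first['msg']}") from exc


def write_time_table_csv(table: TimeTable, path,
                         sentinels: dict[TableSentinel, str] | None = None
                         ) -> None:
    table.to_csv(path, sentinels)
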