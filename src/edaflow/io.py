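"""Readers, writers and run configuration.

Formats are deliberately plain: recordings are two-column CSV
(``time_s,value``) with a JSON sidecar carrying sampling rate, unit and
identifiers; schedules are JSON event lists; feature tables and CV
results are CSV; trees are nested JSON.  Every CLI run also writes a
manifest (config + seed + package version) sufficient to reproduce its
outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .acquisition import EDARecording, SensorConfig
from .decomposition import Decomposition, StimulusSchedule

__all__ = [
    "RunConfig", "read_recording", "write_recording",
    "read_schedule", "write_schedule",
    "write_decomposition", "read_feature_table", "write_feature_table",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SensorSection(_Strict):
    vdd: float = 3.3
    rref: float = 825e3
    electrode_diameter: float = 0.010
    adc_bits: int = 12
    adc_vref: Optional[float] = None
    fs: float = 10.0
    gain: float = 1.0

    def build(self) -> SensorConfig:
        return SensorConfig(**self.model_dump())


class FilterSection(_Strict):
    order: int = 32
    cutoff: float = 1.5
    compensate_delay: bool = True


class DecompositionSection(_Strict):
    latency_s: float = 1.0
    width_s: float = 5.0
    knot_spacing_s: float = 1.0
    eps: Optional[float] = None
    method: str = "additive"


class FeatureSection(_Strict):
    derivative_scale: str = "per_sample"
    elsc_numerator: str = "rmsc"
    moment_order: int = 3


class EvaluationSection(_Strict):
    k: int = 10
    repeats: int = 5
    alpha: float = 0.05
    group_by_subject: bool = False


class TreeSection(_Strict):
    min_fraction: float = 0.20


class SyntheticSection(_Strict):
    n_pictures: int = 10
    picture_duration_s: float = 6.0
    blank_duration_s: float = 1.0
    distractor_gap_s: float = 60.0
    lead_in_s: float = 5.0
    tail_s: float = 5.0
    n_enrolled: int = 50
    n_screening_failures: int = 4
    n_technical_failures: int = 1


class RunConfig(_Strict):
    """Schema-validated configuration for the whole pipeline.

    Unknown keys are rejected.  Numeric defaults are the device and
    protocol values: 10 Hz / 12-bit acquisition, order-32 FIR at 1.5 Hz,
    +1 to +6 s SCR windows, 10-fold CV repeated 5 times, 20% tree
    stopping bound, alpha 0.05.
    """

    sensor: SensorSection = Field(default_factory=SensorSection)
    filter: FilterSection = Field(default_factory=FilterSection)
    decomposition: DecompositionSection = Field(default_factory=DecompositionSection)
    features: FeatureSection = Field(default_factory=FeatureSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)
    tree: TreeSection = Field(default_factory=TreeSection)
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)
    seed: int = 0
    out_dir: str = "edaflow_out"

    @classmethod
    def from_json_file(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())


def write_recording(rec: EDARecording, path: str | Path) -> None:
    """CSV with ``time_s,value`` columns plus a ``.json`` sidecar."""
    path = Path(path)
    # %.17g keeps binary64 values exact across the round trip
    pd.DataFrame({"time_s": rec.time_s, "value": rec.samples}).to_csv(
        path, index=False, float_format="%.17g")
    sidecar = {"fs": rec.fs, "unit": rec.unit,
               "subject_id": rec.subject_id, "condition": rec.condition}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_recording(path: str | Path, fs: Optional[float] = None) -> EDARecording:
    """Read a recording CSV; validates uniform sampling within 1% jitter.

    The sampling rate comes from the sidecar if present, else from ``fs``,
    else it is inferred from the median time step.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: expected header columns time_s,value")
    t = df["time_s"].to_numpy(float)
    v = df["value"].to_numpy(float)
    for col, arr in (("time_s", t), ("value", v)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if len(bad):
            raise ValueError(f"{path}: NaN in column {col} at row {bad[0] + 2}")
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if len(t) > 1:
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if len(bad):
            raise ValueError(f"{path}: non-monotone time at row {bad[0] + 2}")
        med = np.median(dt)
        if np.any(np.abs(dt - med) > 0.01 * med):
            raise ValueError(f"{path}: sampling jitter exceeds 1%")
        inferred = 1.0 / med
    else:
        inferred = None
    rate = meta.get("fs") or fs or inferred
    if rate is None:
        raise ValueError(f"{path}: cannot determine sampling rate")
    return EDARecording(samples=v, fs=float(rate), unit=meta.get("unit", "microsiemens"),
                        subject_id=meta.get("subject_id"), condition=meta.get("condition"))


def write_schedule(schedule: StimulusSchedule, path: str | Path) -> None:
    Path(path).write_text(json.dumps(schedule.to_json_obj(), indent=2))


def read_schedule(path: str | Path) -> StimulusSchedule:
    return StimulusSchedule.from_json_obj(json.loads(Path(path).read_text()))


def write_decomposition(dec: Decomposition, path: str | Path) -> None:
    """CSV with time, tonic (μS) and phasic columns, plus a JSON sidecar."""
    path = Path(path)
    t = np.arange(len(dec.tonic)) / dec.fs
    pd.DataFrame({"time_s": t, "tonic_uS": dec.tonic, "phasic": dec.phasic}).to_csv(
        path, index=False, float_format="%.17g")
    sidecar = {"fs": dec.fs,
               "windows": [{"start_s": w.start_s, "end_s": w.end_s, "event_index": w.event_index}
                           for w in dec.windows]}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
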