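"""Delimited-text I/O and conversion between tables and domain objects.

All tabular interfaces are plain CSV with a header row:

* patients: ``patient_id, procedure, weight_kg, age, sex``
* doses:    ``patient_id, time_min, dose_ug, duration_min``
* samples:  ``patient_id, time_min, measured_ng_ml`` (empty or ``BLQ``
  marks a below-LLOQ sample)

Writers use a fixed float format so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .engine import DoseEvent, DosingSchedule
from .protocol import MeasuredSample

__all__ = [
    "read_patients",
    "read_doses",
    "read_samples",
    "write_table",
    "schedules_from_doses",
    "samples_from_table",
    "parse_times",
]

_FLOAT_FMT = "%.6g"
BLQ_TOKEN = "BLQ"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV deterministically (fixed float format, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "procedure", "weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"patients table missing columns: {sorted(missing)}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def read_doses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "time_min", "dose_ug"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"doses table missing columns: {sorted(missing)}")
    if "duration_min" not in df.columns:
        df["duration_min"] = 0.0
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"measured_ng_ml": str})
    required = {"patient_id", "time_min", "measured_ng_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"samples table missing columns: {sorted(missing)}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def schedules_from_doses(
    doses: pd.DataFrame, patients: pd.DataFrame
) -> dict[str, DosingSchedule]:
    """Build one DosingSchedule per patient (patients without doses get an
    empty schedule so pre-dose accounting still works)."""
    weights = dict(zip(patients["patient_id"], patients["weight_kg"].astype(float)))
    schedules: dict[str, DosingSchedule] = {
        pid: DosingSchedule(patient_id=pid, weight=w, events=[])
        for pid, w in weights.items()
    }
    for row in doses.itertuples(index=False):
        pid = str(row.patient_id)
        if pid not in schedules:
            raise KeyError(f"dose references unknown patient {pid!r}")
        schedules[pid].events.append(
            DoseEvent(
                time=float(row.time_min),
                amount=float(row.dose_ug),
                duration=float(row.duration_min),
            )
        )
    for sched in schedules.values():
        sched.events.sort(key=lambda e: e.time)
    return schedules


def samples_from_table(samples: pd.DataFrame) -> list[MeasuredSample]:
    out: list[MeasuredSample] = []
    for row in samples.itertuples(index=False):
        raw = row.measured_ng_ml
        blq = (
            raw is None
            or (isinstance(raw, float) and np.isnan(raw))
            or str(raw).strip() in ("", BLQ_TOKEN)
        )
        out.append(
            MeasuredSample(
                patient_id=str(row.patient_id),
                time=float(row.time_min),
                value=None if blq else float(raw),
            )
        )
    return out


def parse_times(spec: str) -> np.ndarray:
    """Parse a time grid 'start:stop:step' (minutes) or a comma list."""
    if ":" in spec:
        parts = [float(x) for x in spec.split(":")]
        if len(parts) != 3:
            raise ValueError("grid spec must be start:stop:step")
        start, stop, step = parts
        if step <= 0 or stop < start:
            raise ValueError("invalid time grid")
        return np.arange(start, stop + step / 2, step)
    return np.array(sorted(float(x) for x in spec.split(",")))
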