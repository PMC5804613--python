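"""Study sampling and exclusion rules.

Measured plasma samples become usable measured/predicted pairs only after
three exclusions, applied in order:

1. samples drawn before the patient's first fentanyl dose (assay controls);
2. samples drawn within 10 min after a bolus (mixing/distribution artefact;
   "within" is read as strictly less than the window, so a sample exactly
   10.0 min after a bolus is retained);
3. samples below the assay's lower limit of quantitation (LLOQ,
   0.05 ng/mL by default).

Usable samples are then paired with the engine's point predictions,
timed from the patient's *first fentanyl dose* (the elapsed-time clock of
the stage analysis), and binned into 90-min sampling stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import DosingSchedule, PKParameters, predict_concentration

__all__ = [
    "MeasuredSample",
    "PairedSample",
    "ExclusionReport",
    "filter_samples",
    "assign_stage",
    "pair_with_predictions",
    "POST_BOLUS_EXCLUSION_MIN",
    "DEFAULT_LLOQ",
    "STAGE_WIDTH_MIN",
]

POST_BOLUS_EXCLUSION_MIN = 10.0
DEFAULT_LLOQ = 0.05  # ng/mL
STAGE_WIDTH_MIN = 90.0


@dataclass(frozen=True)
class MeasuredSample:
    """One measured plasma sample; ``value`` is None when below the LLOQ."""

    patient_id: str
    time: float  # minutes from anesthesia induction
    value: float | None  # ng/mL, or None for a below-LLOQ sample

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("sample time must be non-negative")
        if self.value is not None and self.value < 0:
            raise ValueError("quantified value must be non-negative")


@dataclass(frozen=True)
class PairedSample:
    """A usable measured/predicted pair entering the accuracy statistics."""

    patient_id: str
    procedure: str  # 'mastectomy' | 'prostatectomy'
    elapsed: float  # minutes since the first fentanyl dose
    measured: float  # ng/mL
    predicted: float  # ng/mL
    stage: int  # 1..4

    def __post_init__(self) -> None:
        if self.elapsed < 0:
            raise ValueError("elapsed time must be non-negative")
        if self.predicted <= 0:
            raise ValueError("predicted concentration must be positive")
        if self.stage != assign_stage(self.elapsed):
            raise ValueError("stage inconsistent with elapsed time")


@dataclass(frozen=True)
class ExclusionReport:
    n_raw: int
    n_pre_dose_excluded: int
    n_post_bolus_excluded: int
    n_below_lloq: int
    n_usable: int

    def __post_init__(self) -> None:
        counts = (
            self.n_raw,
            self.n_pre_dose_excluded,
            self.n_post_bolus_excluded,
            self.n_below_lloq,
            self.n_usable,
        )
        if any(c < 0 for c in counts):
            raise ValueError("exclusion counts must be non-negative")
        expected = (
            self.n_raw
            - self.n_pre_dose_excluded
            - self.n_post_bolus_excluded
            - self.n_below_lloq
        )
        if self.n_usable != expected:
            raise ValueError("exclusion counts do not reconcile")


def filter_samples(
    samples: list[MeasuredSample],
    schedules: dict[str, DosingSchedule] | list[DosingSchedule],
    lloq: float = DEFAULT_LLOQ,
    post_bolus_window: float = POST_BOLUS_EXCLUSION_MIN,
) -> tuple[list[MeasuredSample], ExclusionReport]:
    """Apply the exclusion rules and return (usable samples, accounting).

    Rules are applied in order (pre-dose, post-bolus window, LLOQ) so each
    sample is counted in exactly one category and the report reconciles:
    ``n_usable = n_raw - n_pre_dose - n_post_bolus - n_below_lloq``.
    """
    if not isinstance(schedules, dict):
        schedules = {s.patient_id: s for s in schedules}
    usable: list[MeasuredSample] = []
    n_pre = n_post = n_blq = 0
    for s in samples:
        if s.patient_id not in schedules:
            raise KeyError(f"sample references unknown patient {s.patient_id!r}")
        sched = schedules[s.patient_id]
        first = sched.first_dose_time()
        if first is None or s.time < first:
            n_pre += 1
            continue
        bolus_times = [e.time for e in sched.events if e.amount > 0 and e.duration == 0]
        if any(0 < s.time - bt < post_bolus_window for bt in bolus_times):
            n_post += 1
            continue
        if s.value is None or s.value < lloq:
            n_blq += 1
            continue
        usable.append(s)
    report = ExclusionReport(
        n_raw=len(samples),
        n_pre_dose_excluded=n_pre,
        n_post_bolus_excluded=n_post,
        n_below_lloq=n_blq,
        n_usable=len(usable),
    )
    return usable, report


def assign_stage(elapsed: float) -> int:
    """Sampling stage of an elapsed time since the first fentanyl dose.

    Half-open 90-min bins: [0, 90) -> 1, [90, 180) -> 2, [180, 270) -> 3,
    [270, inf) -> 4.
    """
    if elapsed < 0 or not math.isfinite(elapsed):
        raise ValueError(f"elapsed time must be finite and non-negative, got {elapsed}")
    return min(int(elapsed // STAGE_WIDTH_MIN) + 1, 4)


def pair_with_predictions(
    usable: list[MeasuredSample],
    schedules: dict[str, DosingSchedule] | list[DosingSchedule],
    procedures: dict[str, str],
    params: PKParameters | dict[str, PKParameters],
) -> list[PairedSample]:
    """Join usable samples with engine predictions at the sample times.

    ``params`` may be a single parameter set (shared by all patients) or a
    per-patient mapping (needed when the central volume is weight-scaled).
    Raises if the model predicts a non-positive concentration at a usable
    sample time, since the performance error is then undefined.
    """
    if not isinstance(schedules, dict):
        schedules = {s.patient_id: s for s in schedules}

    def params_of(pid: str) -> PKParameters:
        return params[pid] if isinstance(params, dict) else params

    by_patient: dict[str, list[MeasuredSample]] = {}
    for s in usable:
        by_patient.setdefault(s.patient_id, []).append(s)

    pairs: list[PairedSample] = []
    for pid, group in by_patient.items():
        sched = schedules[pid]
        first = sched.first_dose_time()
        if first is None:
            raise ValueError(f"patient {pid!r} has usable samples but no dose")
        times = sorted({s.time for s in group})
        series = predict_concentration(sched, params_of(pid), times)
        pred_at = dict(zip(times, series.values))
        for s in sorted(group, key=lambda s: s.time):
            pred = pred_at[s.time]
            if pred <= 0:
                raise ValueError(
                    f"non-positive prediction ({pred:g} ng/mL) for patient "
                    f"{pid!r} at t={s.time:g} min; performance error undefined"
                )
            elapsed = s.time - first
            pairs.append(
                PairedSample(
                    patient_id=pid,
                    procedure=procedures[pid],
                    elapsed=elapsed,
                    measured=float(s.value),
                    predicted=float(pred),
                    stage=assign_stage(elapsed),
                )
            )
    return pairs
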