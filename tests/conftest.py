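from __future__ import annotations

import numpy as np
import pytest

from pkbias import DoseEvent, DosingSchedule, MeasuredSample, PKParameters


@pytest.fixture
def generic_params() -> PKParameters:
    """Self-contained three-compartment set with well-separated eigenvalues."""
    return PKParameters(
        name="generic_3cpt", v1=10.0, k10=0.10, k12=0.30, k21=0.15, k13=0.05, k31=0.01
    )


@pytest.fixture
def one_cpt_params() -> PKParameters:
    return PKParameters(name="generic_1cpt", v1=10.0, k10=0.10)


@pytest.fixture
def typical_schedule() -> DosingSchedule:
    """Induction bolus plus three maintenance boluses."""
    return DosingSchedule(
        patient_id="p1",
        weight=60.0,
        events=[
            DoseEvent(time=0.0, amount=120.0),
            DoseEvent(time=35.0, amount=50.0),
            DoseEvent(time=65.0, amount=100.0),
            DoseEvent(time=95.0, amount=25.0),
        ],
    )


def random_params(rng: np.random.Generator) -> PKParameters:
    """A random valid, non-degenerate three-compartment parameter set."""
    return PKParameters(
        name="random",
        v1=rng.uniform(3.0, 30.0),
        k10=rng.uniform(0.02, 0.3),
        k12=rng.uniform(0.05, 0.6),
        k21=rng.uniform(0.02, 0.4),
        k13=rng.uniform(0.01, 0.3),
        k31=rng.uniform(0.002, 0.05),
    )


def random_schedule(rng: np.random.Generator, pid: str = "p") -> DosingSchedule:
    events = [DoseEvent(time=0.0, amount=float(rng.uniform(50, 200)))]
    t = 0.0
    for _ in range(rng.integers(1, 6)):
        t += float(rng.uniform(10, 60))
        if rng.uniform() < 0.25:
            events.append(
                DoseEvent(
                    time=t,
                    amount=float(rng.uniform(25, 100)),
                    duration=float(rng.uniform(5, 30)),
                )
            )
        else:
            events.append(DoseEvent(time=t, amount=float(rng.choice([25.0, 50.0, 100.0]))))
    return DosingSchedule(patient_id=pid, weight=float(rng.uniform(45, 80)), events=events)


def exact_moment_sample(mean: float, sd: float, n: int) -> np.ndarray:
    """n values whose sample mean and sample SD (ddof=1) are exactly as given."""
    base = np.linspace(-1.0, 1.0, n)
    base = base - base.mean()
    base = base / base.std(ddof=1)
    return mean + sd * base


def study_fixture_410():
    """A 410-sample fixture mirroring the study's exclusion accounting.

    50 patients; 48 pre-dose assay controls, 4 samples within 10 min of a
    bolus, no below-LLOQ samples, and 358 retained samples.
    """
    schedules: dict[str, DosingSchedule] = {}
    samples: list[MeasuredSample] = []
    for i in range(50):
        pid = f"pt{i:02d}"
        schedules[pid] = DosingSchedule(
            patient_id=pid,
            weight=60.0,
            events=[DoseEvent(time=10.0, amount=100.0), DoseEvent(time=100.0, amount=50.0)],
        )
    # 48 pre-dose controls (patients 0..47, one each, drawn before t=10)
    for i in range(48):
        samples.append(MeasuredSample(patient_id=f"pt{i:02d}", time=2.0, value=0.8))
    # 4 samples within 10 min of the t=100 bolus
    for i in range(4):
        samples.append(MeasuredSample(patient_id=f"pt{i:02d}", time=105.0, value=1.5))
    # 358 usable samples at safe times (>= 10 min after every bolus)
    k = 0
    while k < 358:
        pid = f"pt{k % 50:02d}"
        t = 40.0 + 30.0 * (k // 50)
        samples.append(MeasuredSample(patient_id=pid, time=t, value=1.2))
        k += 1
    assert len(samples) == 410
    return samples, schedules
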