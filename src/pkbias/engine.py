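"""Linear three-compartment (mammillary) pharmacokinetic engine.

Drug amounts live in a central compartment (volume ``v1``, litres) that
exchanges with two peripheral compartments; elimination is first-order from
the central compartment.  With micro rate constants ``k10, k12, k21, k13,
k31`` (1/min) the disposition matrix is

    A = [[-(k10+k12+k13), k21,  k31],
         [ k12,          -k21,  0  ],
         [ k13,           0,   -k31]]

and the unit-bolus plasma concentration is a sum of three exponentials
("hybrid" form) ``c(t) = sum_i a_i * exp(-lambda_i t)`` whose decay rates
are the negated eigenvalues of ``A``.  Doses are in micrograms and
concentrations in ng/mL; because ug/L == ng/mL no unit conversion appears
anywhere.

Two independent prediction paths are provided: the closed-form
superposition of hybrid exponentials (:func:`predict_concentration`) and a
numerical ODE integration (:func:`ode_oracle`) used for cross-validation
and as a fallback on degenerate (repeated-eigenvalue) parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "PKParameters",
    "HybridCoefficients",
    "DoseEvent",
    "DosingSchedule",
    "ConcentrationSeries",
    "DegenerateParametersError",
    "micro_to_hybrid",
    "predict_concentration",
    "ode_oracle",
    "load_pk_models",
    "resolve_parameters",
]


class DegenerateParametersError(ValueError):
    """Raised when the disposition eigenvalues are too close to separate."""


@dataclass(frozen=True)
class PKParameters:
    """Micro-constant parameterisation of a three-compartment model.

    ``v1`` is the central volume in litres *after* any per-kg scaling;
    rate constants are in 1/min.
    """

    name: str
    v1: float
    k10: float
    k12: float = 0.0
    k21: float = 0.0
    k13: float = 0.0
    k31: float = 0.0

    def __post_init__(self) -> None:
        if not self.v1 > 0:
            raise ValueError(f"v1 must be positive, got {self.v1}")
        if not self.k10 > 0:
            raise ValueError(f"k10 must be positive, got {self.k10}")
        for attr in ("k12", "k21", "k13", "k31"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")

    def disposition_matrix(self) -> np.ndarray:
        k10, k12, k21, k13, k31 = self.k10, self.k12, self.k21, self.k13, self.k31
        return np.array(
            [
                [-(k10 + k12 + k13), k21, k31],
                [k12, -k21, 0.0],
                [k13, 0.0, -k31],
            ]
        )


@dataclass(frozen=True)
class HybridCoefficients:
    """Tri-exponential impulse response: ``c(t) = sum a_i exp(-lambda_i t)``.

    ``coefficients`` are amplitudes in (ng/mL) per ug of bolus dose;
    ``exponents`` are the decay rates in 1/min, sorted descending.  The
    amplitudes sum to ``1/v1`` (a unit bolus instantly raises the central
    concentration by ``1/v1``).  Terms of a structurally collapsed model
    (a disconnected peripheral compartment) carry amplitude zero.
    """

    coefficients: tuple[float, float, float]
    exponents: tuple[float, float, float]

    def __post_init__(self) -> None:
        lam = self.exponents
        if any(l <= 0 for l in lam):
            raise ValueError("hybrid exponents must be strictly positive")
        if not (lam[0] >= lam[1] >= lam[2]):
            raise ValueError("hybrid exponents must be sorted descending")


@dataclass(frozen=True)
class DoseEvent:
    """A dose: instantaneous bolus (``duration == 0``) or zero-order infusion."""

    time: float  # minutes from anesthesia induction
    amount: float  # micrograms
    duration: float = 0.0  # minutes; 0 denotes a bolus

    def __post_init__(self) -> None:
        if self.time < 0 or self.amount < 0 or self.duration < 0:
            raise ValueError("dose event fields must be non-negative")


@dataclass
class DosingSchedule:
    """Ordered dose events for one patient."""

    patient_id: str
    weight: float  # kg
    events: list[DoseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError("weight must be positive")
        times = [e.time for e in self.events]
        if times != sorted(times):
            self.events = sorted(self.events, key=lambda e: e.time)

    def first_dose_time(self) -> float | None:
        """Time of the first event with a positive amount, or None."""
        for e in self.events:
            if e.amount > 0:
                return e.time
        return None


@dataclass
class ConcentrationSeries:
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


# ---------------------------------------------------------------------------
# micro constants -> hybrid (tri-exponential) form


def _collapse_order(params: PKParameters) -> list[int]:
    """Indices of compartments actually reachable from the central one."""
    reachable = [0]
    if params.k12 > 0:
        reachable.append(1)
    if params.k13 > 0:
        reachable.append(2)
    return reachable


def micro_to_hybrid(params: PKParameters, *, gap_tol: float = 1e-9) -> HybridCoefficients:
    """Convert micro rate constants to the hybrid exponential form.

    The exponents are the negated eigenvalues of the disposition matrix and
    the amplitudes follow from the partial-fraction expansion of the
    Laplace-domain unit-bolus response

        a_i = (k21 - l_i)(k31 - l_i) / (v1 * prod_{j!=i} (l_j - l_i)).

    A peripheral compartment with zero inflow (``k12 == 0`` or ``k13 == 0``)
    never sees drug and is dropped before the eigen-decomposition, so the
    one- and two-compartment limits are handled exactly; the returned
    coefficient triple is padded with zero amplitudes in that case.

    Raises
    ------
    DegenerateParametersError
        If two retained eigenvalues coincide to within relative ``gap_tol``;
        callers may fall back to :func:`ode_oracle`.
    """
    keep = _collapse_order(params)
    A = params.disposition_matrix()[np.ix_(keep, keep)]
    eig = np.linalg.eigvals(A)
    if np.max(np.abs(eig.imag)) > 1e-9 * max(1.0, np.max(np.abs(eig.real))):
        raise DegenerateParametersError("complex disposition eigenvalues")
    lam = np.sort(-eig.real)[::-1]  # decay rates, descending

    # pairwise separation check on the genuine eigenvalues only
    for i in range(len(lam)):
        for j in range(i + 1, len(lam)):
            scale = max(abs(lam[i]), abs(lam[j]), 1e-300)
            if abs(lam[i] - lam[j]) / scale < gap_tol:
                raise DegenerateParametersError(
                    f"near-repeated eigenvalues {lam[i]:g} and {lam[j]:g}"
                )

    k21, k31 = params.k21, params.k31
    amps = []
    for i, li in enumerate(lam):
        num = 1.0
        if 1 in keep:
            num *= k21 - li
        if 2 in keep:
            num *= k31 - li
        den = params.v1
        for j, lj in enumerate(lam):
            if j != i:
                den *= lj - li
        amps.append(num / den)

    # pad collapsed terms: amplitude zero, exponent tied to the fastest rate
    # so the container invariant (positive, descending) always holds
    lam_list = list(lam)
    while len(lam_list) < 3:
        lam_list.append(lam_list[0])
        amps.append(0.0)
    # a structurally present but zero-amplitude term may sit on lambda == 0
    # (e.g. k21 == 0 sink); repair its exponent the same way
    for i in range(3):
        if amps[i] == 0.0 and lam_list[i] <= 0:
            lam_list[i] = max(lam_list)
    order = np.argsort([-l for l in lam_list], kind="stable")
    return HybridCoefficients(
        coefficients=tuple(float(amps[i]) for i in order),
        exponents=tuple(float(lam_list[i]) for i in order),
    )


# ---------------------------------------------------------------------------
# analytic superposition


def _event_contribution(
    event: DoseEvent, hybrid: HybridCoefficients, times: np.ndarray
) -> np.ndarray:
    """Concentration contribution of one dose event at the requested times.

    A bolus at time t0 contributes from t0 onward, inclusive
    (right-continuous).  An infusion of duration d contributes its running
    integral during [t0, t0+d] and the washed-out integral afterwards.
    """
    out = np.zeros_like(times, dtype=float)
    if event.amount == 0:
        return out
    dt = times - event.time
    if event.duration == 0:
        active = dt >= 0
        for a, lam in zip(hybrid.coefficients, hybrid.exponents):
            if a == 0:
                continue
            out[active] += event.amount * a * np.exp(-lam * dt[active])
    else:
        rate = event.amount / event.duration  # ug/min
        during = (dt >= 0) & (dt <= event.duration)
        after = dt > event.duration
        for a, lam in zip(hybrid.coefficients, hybrid.exponents):
            if a == 0:
                continue
            out[during] += rate * a / lam * (1.0 - np.exp(-lam * dt[during]))
            out[after] += (
                rate
                * a
                / lam
                * (np.exp(-lam * (dt[after] - event.duration)) - np.exp(-lam * dt[after]))
            )
    return out


def predict_concentration(
    schedule: DosingSchedule,
    params: PKParameters,
    times: Sequence[float] | np.ndarray,
) -> ConcentrationSeries:
    """Predicted plasma concentration (ng/mL) at the requested times.

    Superposition of the tri-exponential response of every dose event; the
    system is linear so contributions simply add.  Falls back to the
    numerical ODE path if the parameter set has (near-)repeated
    eigenvalues.
    """
    t = np.asarray(times, dtype=float)
    if t.size and t.min() < 0:
        raise ValueError("requested times must be non-negative")
    if not schedule.events:
        return ConcentrationSeries(times=t, values=np.zeros_like(t))
    try:
        hybrid = micro_to_hybrid(params)
    except DegenerateParametersError:
        return ode_oracle(schedule, params, t)
    values = np.zeros_like(t)
    for event in schedule.events:
        values += _event_contribution(event, hybrid, t)
    return ConcentrationSeries(times=t, values=values)


# ---------------------------------------------------------------------------
# numerical ODE oracle


def ode_oracle(
    schedule: DosingSchedule,
    params: PKParameters,
    times: Sequence[float] | np.ndarray,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> ConcentrationSeries:
    """Integrate the compartment ODEs numerically (independent check path).

    The state is the amount vector (ug) in the three compartments.  Boluses
    enter as instantaneous jumps of the central amount; infusions as
    zero-order source terms.  A requested time equal to a bolus time
    reports the post-bolus value, matching the analytic path's
    right-continuity convention.
    """
    t_req = np.asarray(times, dtype=float)
    if t_req.size and t_req.min() < 0:
        raise ValueError("requested times must be non-negative")
    A = params.disposition_matrix()

    # breakpoints: every event start, infusion end, plus the request range
    breaks = {0.0}
    for e in schedule.events:
        breaks.add(e.time)
        if e.duration > 0:
            breaks.add(e.time + e.duration)
    if t_req.size:
        breaks.add(float(t_req.max()))
    breaks = sorted(b for b in breaks if t_req.size and b <= t_req.max() or not t_req.size)
    if not breaks:
        breaks = [0.0]

    values = np.full_like(t_req, np.nan)
    x = np.zeros(3)

    def infusion_rate(t: float) -> float:
        r = 0.0
        for e in schedule.events:
            if e.duration > 0 and e.time <= t < e.time + e.duration:
                r += e.amount / e.duration
        return r

    def rhs(t, x):
        dx = A @ x
        dx[0] += infusion_rate(t)
        return dx

    for i, b in enumerate(breaks):
        for e in schedule.events:
            if e.duration == 0 and e.time == b:
                x[0] += e.amount
        exact = t_req == b
        values[exact] = x[0] / params.v1
        b_next = breaks[i + 1] if i + 1 < len(breaks) else None
        if b_next is None:
            break
        inside = (t_req > b) & (t_req < b_next)
        t_eval = np.concatenate([t_req[inside], [b_next]])
        sol = solve_ivp(
            rhs, (b, b_next), x, t_eval=np.sort(t_eval), rtol=rtol, atol=atol,
            method="LSODA", dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{b}, {b_next}]: {sol.message}")
        if np.any(inside):
            values[inside] = sol.sol(t_req[inside])[0] / params.v1
        x = sol.y[:, -1].copy()

    # times beyond the last breakpoint can only occur with an empty schedule
    values[np.isnan(values)] = 0.0
    return ConcentrationSeries(times=t_req, values=np.maximum(values, 0.0))


# ---------------------------------------------------------------------------
# named parameter sets


def _default_model_path() -> Path:
    return Path(str(resources.files("pkbias").joinpath("data/pk_models.yaml")))


@lru_cache(maxsize=8)
def _load_models_cached(path: str) -> dict[str, dict]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"malformed parameter file {path}")
    return raw


def load_pk_models(path: str | Path | None = None) -> dict[str, dict]:
    """Load named PK parameter blocks from a key-value (YAML) file.

    Parsed files are cached by path for the lifetime of the process.
    """
    p = Path(path) if path is not None else _default_model_path()
    return _load_models_cached(str(p))


def resolve_parameters(
    name: str,
    weight: float | None = None,
    path: str | Path | None = None,
) -> PKParameters:
    """Build :class:`PKParameters` from a named block, applying per-kg scaling.

    A block specifies either ``v1`` (litres) or ``v1_per_kg`` (L/kg, scaled
    by the patient weight at load time); rate constants are
    weight-invariant.
    """
    models = load_pk_models(path)
    if name not in models:
        raise KeyError(f"unknown PK model {name!r}; available: {sorted(models)}")
    block = dict(models[name])
    block.pop("comment", None)
    if "v1_per_kg" in block:
        if weight is None:
            raise ValueError(f"model {name!r} is per-kg scaled; a weight is required")
        v1 = float(block.pop("v1_per_kg")) * weight
    else:
        v1 = float(block.pop("v1"))
    return PKParameters(
        name=name,
        v1=v1,
        k10=float(block.get("k10", 0.0)),
        k12=float(block.get("k12", 0.0)),
        k21=float(block.get("k21", 0.0)),
        k13=float(block.get("k13", 0.0)),
        k31=float(block.get("k31", 0.0)),
    )
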