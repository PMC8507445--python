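"""Equal-risk protocol optimization for bone scintigraphy.

With an all-linear dose response the LAR is proportional to administered
activity, so the activity that gives every patient the same radiation risk is
a simple rescaling of a reference administration (500 MBq for adult
scintigraphy). Because, at fixed image quality, administration is inversely
proportional to acquisition time, each equal-risk activity maps to an age-
and sex-specific acquisition time around the 4-minute reference; times are
clamped to the clinically recommended 3–5 minute window, recomputing the
activity from the clamped time so the detected counts are preserved.

The operations take a ``lar_fn(sex, age, activity) -> probability`` callable
so the module stays independent of how the model stack is assembled; see
:func:`larisk.io.make_lar_fn`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .errors import ComputationError, DataValidationError

__all__ = [
    "A_REF_MBQ",
    "T_REF_MIN",
    "TIME_WINDOW_MIN",
    "ProtocolPoint",
    "AcquisitionTime",
    "target_risk",
    "equal_risk_activity",
    "acquisition_time",
    "protocol_table",
]

LarFn = Callable[[str, float, float], float]

A_REF_MBQ = 500.0
T_REF_MIN = 4.0
TIME_WINDOW_MIN = (3.0, 5.0)


@dataclass(frozen=True)
class ProtocolPoint:
    """One row of the equal-risk protocol table."""

    sex: str
    age: float
    activity: float  # MBq actually administered (after any clamping)
    acquisition_time: float  # minutes (after any clamping)
    achieved_lar: float
    clamped: bool
    unclamped_time: float  # minutes, t_ref * A_ref / A_equal_risk

    def __post_init__(self):
        if self.activity <= 0 or self.acquisition_time <= 0:
            raise DataValidationError("activity and acquisition time must be positive")


class AcquisitionTime(NamedTuple):
    time: float  # minutes, clamped to the window
    clamped: bool
    unclamped_time: float
    activity: float  # MBq consistent with `time` at fixed counts


def target_risk(lar_fn: LarFn, sexes: Sequence[str], ages: Sequence[float],
                A_ref: float = A_REF_MBQ) -> float:
    """Average LAR at the reference administration over a (sex, age) grid."""
    grid = [(sex, age) for sex in sexes for age in ages]
    if not grid:
        raise DataValidationError("empty (sex, age) grid")
    return float(np.mean([lar_fn(sex, age, A_ref) for sex, age in grid]))


def equal_risk_activity(lar_fn: LarFn, target: float, sex: str, age: float,
                        A_ref: float = A_REF_MBQ) -> float:
    """Administered activity at which LAR equals ``target``.

    Exploits linearity of LAR in activity: A = A_ref * target / LAR(A_ref).
    """
    lar_ref = lar_fn(sex, age, A_ref)
    if lar_ref <= 0:
        raise ComputationError(
            f"risk saturated at zero for {sex} age {age:g}; "
            "no finite equal-risk activity")
    return A_ref * target / lar_ref


def acquisition_time(A: float, A_ref: float = A_REF_MBQ, t_ref: float = T_REF_MIN,
                     window: tuple[float, float] = TIME_WINDOW_MIN) -> AcquisitionTime:
    """Acquisition time preserving counts: t = t_ref * A_ref / A.

    Outside the recommended window the time is clamped to the boundary and
    the activity recomputed from the clamped time, so A * t stays at
    A_ref * t_ref in either case.
    """
    if A <= 0:
        raise DataValidationError(f"activity must be positive, got {A!r}")
    t = t_ref * A_ref / A
    lo, hi = window
    clamped_t = min(max(t, lo), hi)
    clamped = clamped_t != t
    activity = t_ref * A_ref / clamped_t if clamped else A
    return AcquisitionTime(time=clamped_t, clamped=clamped,
                           unclamped_time=t, activity=activity)


def protocol_table(lar_fn: LarFn, sexes: Sequence[str], ages: Sequence[float],
                   A_ref: float = A_REF_MBQ, t_ref: float = T_REF_MIN,
                   window: tuple[float, float] = TIME_WINDOW_MIN,
                   target_scope: str = "per_sex") -> list[ProtocolPoint]:
    """Equal-risk activities and acquisition times for every (sex, age).

    ``target_scope`` selects whether the average risk target is computed per
    sex or over the combined grid.
    """
    if target_scope not in ("per_sex", "combined"):
        raise DataValidationError(
            f"target_scope must be per_sex or combined, got {target_scope!r}")
    targets: dict[str, float] = {}
    if target_scope == "combined":
        t = target_risk(lar_fn, sexes, ages, A_ref)
        targets = {sex: t for sex in sexes}
    else:
        targets = {sex: target_risk(lar_fn, [sex], ages, A_ref) for sex in sexes}

    points = []
    for sex in sexes:
        for age in ages:
            A = equal_risk_activity(lar_fn, targets[sex], sex, age, A_ref)
            acq = acquisition_time(A, A_ref, t_ref, window)
            points.append(ProtocolPoint(
                sex=sex, age=float(age), activity=acq.activity,
                acquisition_time=acq.time,
                achieved_lar=lar_fn(sex, age, acq.activity),
                clamped=acq.clamped, unclamped_time=acq.unclamped_time))
    return points
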