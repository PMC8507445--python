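"""Administered activity to per-organ absorbed dose.

Dose coefficients (mGy per MBq administered) are tabulated for the five
reference phantom ages 1, 5, 10, 15 and adult. The adult phantom represents a
20-year-old person except for its bone composition, so for bone-seeking
radiopharmaceuticals the age-dependent interpolation extends to 25 years
(anchor ages 1, 5, 10, 15, 25) while for other agents the adult value applies
from age 20. Coefficients are interpolated linearly in age between anchors,
held constant below age 1 and above the adult anchor.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataValidationError

__all__ = [
    "AGE_GROUPS",
    "DoseCoefficientTable",
    "OrganDoseVector",
    "coefficient_at_age",
    "organ_doses",
]

AGE_GROUPS = ("1", "5", "10", "15", "adult")
ADULT_ANCHOR_BONE_SEEKER = 25.0
ADULT_ANCHOR_DEFAULT = 20.0


@dataclass(frozen=True)
class DoseCoefficientTable:
    """Organ × phantom-age-group dose coefficients for one radiopharmaceutical."""

    radiopharmaceutical: str
    coefficients: dict[str, np.ndarray] = field(repr=False)  # organ -> 5 values, mGy/MBq
    bone_seeker: bool = False

    def __post_init__(self):
        coeffs = {}
        for organ, values in self.coefficients.items():
            v = np.asarray(values, dtype=float)
            if v.shape != (5,):
                raise DataValidationError(
                    f"organ {organ!r}: need one coefficient per age group "
                    f"{AGE_GROUPS}, got shape {v.shape}")
            if np.any(v <= 0):
                raise DataValidationError(f"organ {organ!r}: coefficients must be positive")
            coeffs[organ] = v
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def organs(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    @property
    def adult_anchor_age(self) -> float:
        return ADULT_ANCHOR_BONE_SEEKER if self.bone_seeker else ADULT_ANCHOR_DEFAULT


@dataclass(frozen=True)
class OrganDoseVector:
    """Absorbed dose per organ, Gy, for one administration."""

    doses: dict[str, float]
    activity: float  # MBq
    age: float  # years

    def __post_init__(self):
        if any(d < 0 for d in self.doses.values()):
            raise DataValidationError("organ doses must be non-negative")

    def __getitem__(self, organ: str) -> float:
        return self.doses[organ]


def coefficient_at_age(table: DoseCoefficientTable, organ: str, age: float) -> float:
    """Dose coefficient (mGy/MBq) for one organ at a patient age in years."""
    if age < 0:
        raise DataValidationError(f"age must be non-negative, got {age!r}")
    try:
        values = table.coefficients[organ]
    except KeyError:
        raise DataValidationError(
            f"unknown organ {organ!r}; table has {', '.join(table.organs)}") from None
    anchors = np.array([1.0, 5.0, 10.0, 15.0, table.adult_anchor_age])
    # np.interp holds the end values outside the anchor range
    return float(np.interp(age, anchors, values))


def organ_doses(table: DoseCoefficientTable, activity: float, age: float) -> OrganDoseVector:
    """Absorbed dose (Gy) to every organ for an administered activity in MBq."""
    if activity <= 0:
        raise DataValidationError(f"administered activity must be positive, got {activity!r}")
    doses = {organ: activity * coefficient_at_age(table, organ, age) * 1e-3
             for organ in table.organs}
    return OrganDoseVector(doses=doses, activity=activity, age=age)
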