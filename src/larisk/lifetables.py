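"""Life tables and cohort-specific survival modification.

A :class:`LifeTable` holds the survivorship function l(a) = N(a)/N(0) of a
population on an integer age grid starting at 0 — the probability of being
alive at age ``a``. Patient cohorts with reduced life expectancy (e.g.
Paget's disease, prostate cancer with bone metastases) are described by a
published k-year survival fraction, converted to a constant annual survival
probability (ASP) and applied multiplicatively to the population table over a
window after exposure. The cohort is never modelled as healthier than the
general population: each year inside the window the cohort's conditional
annual survival is the minimum of the population's and the ASP.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import ComputationError, DataValidationError

__all__ = [
    "LifeTable",
    "CohortSurvivalSpec",
    "COHORT_PRESETS",
    "lifetable_from_survivorship",
    "survival_at",
    "conditional_survival",
    "annual_survival_probability",
    "apply_cohort_modification",
]

_MONOTONE_TOL = 1e-12


@dataclass(frozen=True)
class LifeTable:
    """Sex-specific survivorship l(a) on a contiguous integer age grid 0..A_max."""

    sex: str
    ages: np.ndarray = field(repr=False)
    survivorship: np.ndarray = field(repr=False)

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        lx = np.asarray(self.survivorship, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "survivorship", lx)
        if ages.ndim != 1 or lx.shape != ages.shape:
            raise DataValidationError("ages and survivorship must be 1-D and equal length")
        if ages.size < 2:
            raise DataValidationError("life table needs at least two ages")
        if ages[0] != 0 or not np.array_equal(ages, np.arange(ages.size)):
            missing = sorted(set(range(int(ages.max()) + 1)) - set(ages.tolist()))
            raise DataValidationError(
                f"age grid must be contiguous integers starting at 0; missing ages {missing[:5]}"
            )
        if abs(lx[0] - 1.0) > 1e-12:
            raise DataValidationError(f"l(0) must be 1, got {lx[0]!r}")
        if np.any(lx < -_MONOTONE_TOL) or np.any(lx > 1 + _MONOTONE_TOL):
            raise DataValidationError("survivorship values must lie in [0, 1]")
        bad = np.nonzero(np.diff(lx) > _MONOTONE_TOL)[0]
        if bad.size:
            a = int(ages[bad[0] + 1])
            raise DataValidationError(
                f"survivorship must be non-increasing; increases at age {a} "
                f"(l({a - 1})={lx[bad[0]]:.6g} < l({a})={lx[bad[0] + 1]:.6g})"
            )

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def survival_at(self, a) -> float | np.ndarray:
        return survival_at(self, a)

    def conditional_survival(self, a, e0) -> float | np.ndarray:
        return conditional_survival(self, a, e0)


class CohortSurvivalSpec(BaseModel):
    """A patient cohort defined by a published k-year survival fraction.

    The annual survival probability ASP = k_year_fraction**(1/k) reproduces
    the stated k-year survival when compounded over k years. ``window`` is
    the number of years after exposure over which the ASP modification is
    applied; it defaults to max(k, 5) so that it reaches the start of the
    solid-cancer risk integration.
    """

    name: str
    k_year_fraction: float = Field(gt=0.0, le=1.0)
    k: int = Field(ge=1)
    window: int | None = Field(default=None, ge=1)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _default_window(self):
        if self.window is None:
            object.__setattr__(self, "window", max(self.k, 5))
        return self

    @property
    def asp(self) -> float:
        return annual_survival_probability(self)


#: The three patient cohorts considered for bone scintigraphy: Paget's disease
#: (5-year survival 93%) and prostate cancer with bone metastases (2-year
#: survival 68% for one lesion, 22% for more than one lesion).
COHORT_PRESETS: dict[str, CohortSurvivalSpec] = {
    "pagets": CohortSurvivalSpec(name="pagets", k_year_fraction=0.93, k=5),
    "one_lesion": CohortSurvivalSpec(name="one_lesion", k_year_fraction=0.68, k=2),
    "multi_lesion": CohortSurvivalSpec(name="multi_lesion", k_year_fraction=0.22, k=2),
}


def lifetable_from_survivorship(sex, ages, survivorship) -> LifeTable:
    """Build a validated LifeTable; raw counts N(a) are normalized by N(0)."""
    lx = np.asarray(survivorship, dtype=float)
    if lx.size == 0:
        raise DataValidationError("empty survivorship")
    if lx[0] <= 0:
        raise DataValidationError(f"value at age 0 must be positive, got {lx[0]!r}")
    return LifeTable(sex=sex, ages=np.asarray(ages), survivorship=lx / lx[0])


def survival_at(table: LifeTable, a) -> float | np.ndarray:
    """l(a); fractional ages by linear interpolation between grid points."""
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < 0) or np.any(a_arr > table.max_age):
        raise DataValidationError(
            f"age {a!r} outside life-table grid [0, {table.max_age}]"
        )
    out = np.interp(a_arr, table.ages, table.survivorship)
    return float(out) if np.isscalar(a) or a_arr.ndim == 0 else out


def conditional_survival(table: LifeTable, a, e0) -> float | np.ndarray:
    """S(a)/S(e0): probability of reaching age a given alive at age e0 ≤ a."""
    if np.any(np.asarray(a, dtype=float) < e0):
        raise DataValidationError("attained age a must be >= conditioning age e0")
    s_e0 = survival_at(table, e0)
    if s_e0 <= 0:
        raise ComputationError(f"cohort extinct at normalization age {e0}")
    return survival_at(table, a) / s_e0


def annual_survival_probability(spec: CohortSurvivalSpec) -> float:
    """Constant annual survival probability reproducing the k-year fraction."""
    return spec.k_year_fraction ** (1.0 / spec.k)


def apply_cohort_modification(table: LifeTable, spec: CohortSurvivalSpec,
                              e: int) -> LifeTable:
    """Reduced-life-expectancy survivorship l*(a) for a cohort exposed at age e.

    For ages in (e, e+window] the conditional annual survival is
    min(l(a)/l(a-1), ASP) — the cohort is never healthier than the general
    population; beyond the window the cohort resumes the population's
    conditional survival.
    """
    e = int(e)
    if not 0 <= e <= table.max_age:
        raise DataValidationError(f"exposure age {e} outside grid [0, {table.max_age}]")
    lx = table.survivorship
    if lx[e] <= 0:
        raise ComputationError(f"population extinct at exposure age {e}")
    asp = annual_survival_probability(spec)
    out = lx.copy()
    end = min(e + spec.window, table.max_age)
    for a in range(e + 1, end + 1):
        pop_annual = lx[a] / lx[a - 1] if lx[a - 1] > 0 else 0.0
        out[a] = out[a - 1] * min(pop_annual, asp)
    if end < table.max_age:
        tail = lx[end + 1:] / lx[end] if lx[end] > 0 else np.zeros(table.max_age - end)
        out[end + 1:] = out[end] * tail
    return LifeTable(sex=table.sex, ages=table.ages, survivorship=out)
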