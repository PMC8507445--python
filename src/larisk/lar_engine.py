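"""Lifetime attributable risk (LAR) evaluation.

The LAR of a radiation exposure is the survival-weighted integral of the
excess cancer rate over attained age, from the end of the latency period to
age 110:

    LAR(D, e) = sum over a in [e+L, 110) of  M(D, e, a) * S(a) / S(e+L)

evaluated as an annual left-endpoint sum on integer attained ages (life
tables and baseline rates are annual), per cancer site and summed to a
total. When the exposed person belongs to a reduced-life-expectancy cohort,
S is the cohort-modified survivorship — including the S(e+L) normalisation,
so the result is the risk conditional on surviving the latency period. A
finer internal step is supported for convergence checks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dosimetry import OrganDoseVector
from .errors import ComputationError, DataValidationError
from .lifetables import LifeTable, apply_cohort_modification, survival_at
from .risk_models import (BaselineRateTable, ExposureScenario,
                          RiskModelParams, excess_rate)
from .sites import get_site, sites_for_sex

__all__ = [
    "LARResult",
    "AGE_LIMIT",
    "EFFECTIVE_DOSE_COEFFICIENTS",
    "lar_site",
    "lar_total",
    "lar_mortality",
    "lifetime_baseline_risk",
    "effective_dose_risk",
]

AGE_LIMIT = 110.0

#: ICRP nominal stochastic risk coefficients per Sv effective dose.
EFFECTIVE_DOSE_COEFFICIENTS = {"whole": 0.055, "worker": 0.041}


@dataclass(frozen=True)
class LARResult:
    """Per-site and total LAR for one exposure scenario."""

    scenario: ExposureScenario
    kind: str  # incidence | mortality
    per_site: dict[str, float] = field(repr=False)
    total: float = 0.0
    inputs_digest: str = ""

    def __post_init__(self):
        if any(v < 0 for v in self.per_site.values()):
            raise ComputationError("negative per-site LAR")
        if abs(self.total - sum(self.per_site.values())) > 1e-12:
            raise ComputationError("total LAR does not equal the sum over sites")
        if self.total >= 1.0:
            raise ComputationError(f"total LAR {self.total:.3g} is not a probability")

    def one_in(self) -> float | None:
        """Risk as '1 in N', N rounded to two significant figures."""
        if self.total <= 0:
            return None
        n = 1.0 / self.total
        mag = 10.0 ** np.floor(np.log10(n) - 1)
        return float(round(n / mag) * mag)


def lar_site(params: RiskModelParams, baseline: BaselineRateTable,
             table: LifeTable, D: float, e: float, *, step: float = 1.0) -> float:
    """LAR for a single cancer site (probability, dimensionless).

    Annual left-endpoint sum over the half-open range [e+L, 110); ``step``
    refines the grid for convergence checks only. The table passed in must
    already carry any cohort modification.
    """
    start = e + params.latency
    if start >= AGE_LIMIT:
        warnings.warn(
            f"exposure age {e:g} + latency {params.latency} reaches the "
            f"age-{AGE_LIMIT:g} integration limit; LAR is 0", stacklevel=2)
        return 0.0
    denom = survival_at(table, start)
    if denom <= 0:
        raise ComputationError(
            f"cohort extinct before latency end (S({start:g}) = 0)")
    ages = np.arange(start, min(AGE_LIMIT, table.max_age), step)
    m = excess_rate(params, baseline, D, e, ages)
    s = survival_at(table, ages)
    return float(np.sum(m * s) * step / denom)


def _resolve_table(scenario: ExposureScenario, table: LifeTable,
                   cohorts: Mapping | None) -> LifeTable:
    if scenario.cohort is None:
        return table
    if cohorts is None or scenario.cohort not in cohorts:
        raise DataValidationError(f"scenario names unknown cohort {scenario.cohort!r}")
    return apply_cohort_modification(table, cohorts[scenario.cohort], int(scenario.e))


def lar_total(scenario: ExposureScenario,
              model_set: Mapping[tuple[str, str], RiskModelParams],
              baselines: Mapping[tuple[str, str, str], BaselineRateTable],
              table: LifeTable, doses: OrganDoseVector, *,
              kind: str = "incidence",
              cohorts: Mapping[str, object] | None = None,
              inputs_digest: str = "") -> LARResult:
    """Per-site and total LAR for one scenario across the full site registry."""
    if table.sex != scenario.sex:
        raise DataValidationError(
            f"life table is for {table.sex!r}, scenario for {scenario.sex!r}")
    sex = scenario.sex
    gaps = []
    for site in sites_for_sex(sex):
        if (site.name, sex) not in model_set:
            gaps.append(f"risk model for ({site.name}, {sex})")
        if (site.name, sex, kind) not in baselines:
            gaps.append(f"{kind} baseline for ({site.name}, {sex})")
        organ = model_set.get((site.name, sex), site).target_organ or site.target_organ
        if organ not in doses.doses:
            gaps.append(f"dose for organ {organ!r} ({site.name})")
    if gaps:
        raise DataValidationError("missing inputs: " + "; ".join(gaps))

    eff_table = _resolve_table(scenario, table, cohorts)
    per_site: dict[str, float] = {}
    for site in sites_for_sex(sex):
        params = model_set[(site.name, sex)]
        organ = params.target_organ or site.target_organ
        per_site[site.name] = lar_site(
            params, baselines[(site.name, sex, kind)], eff_table,
            doses[organ], scenario.e)
    return LARResult(scenario=scenario, kind=kind, per_site=per_site,
                     total=sum(per_site.values()), inputs_digest=inputs_digest)


def lar_mortality(scenario, model_set, baselines, table, doses, *,
                  cohorts=None, inputs_digest: str = "") -> LARResult:
    """LAR of radiation-induced cancer death (mortality baseline rates)."""
    return lar_total(scenario, model_set, baselines, table, doses,
                     kind="mortality", cohorts=cohorts, inputs_digest=inputs_digest)


def lifetime_baseline_risk(baseline: BaselineRateTable, table: LifeTable,
                           e0: float = 0.0) -> float:
    """Unexposed lifetime risk: sum of lambda(a) * S(a) / S(e0) over [e0, 110)."""
    denom = survival_at(table, e0)
    if denom <= 0:
        raise ComputationError(f"population extinct at age {e0:g}")
    ages = np.arange(e0, min(AGE_LIMIT, table.max_age), 1.0)
    lam = np.asarray(baseline.rate_at(ages), dtype=float) / 1e5
    return float(np.sum(lam * survival_at(table, ages)) / denom)


def effective_dose_risk(E: float, population: str = "whole") -> float:
    """Nominal stochastic risk from an effective dose E in Sv.

    Uses the ICRP coefficients 5.5%/Sv (whole population) or 4.1%/Sv
    (radiation workers); not age- or sex-specific, reported side by side
    with LAR for context.
    """
    if E < 0:
        raise DataValidationError(f"effective dose must be non-negative, got {E!r}")
    try:
        coeff = EFFECTIVE_DOSE_COEFFICIENTS[population]
    except KeyError:
        raise DataValidationError(
            f"population must be one of {tuple(EFFECTIVE_DOSE_COEFFICIENTS)}, "
            f"got {population!r}") from None
    return E * coeff
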