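"""Parametric excess-risk models for radiogenic cancer.

The age-specific excess rate M(D, e, a) at attained age ``a`` for an organ
dose ``D`` received at age-at-exposure ``e`` follows the standard BEIR
VII-style two-scale family. Both the excess relative risk (ERR, multiplier on
the baseline rate) and the excess absolute risk (EAR, additive rate per
10,000 person-years) take the form

    beta * exp(gamma * e*) * (a / 60) ** eta,      e* = (min(e, 30) - 30) / 10

i.e. a log-linear decline per decade of age at exposure (capped at 30) and a
power of attained age pivoted at 60. The two scales are mixed additively on
the excess-rate scale with a per-site transport weight w, the dose response is
linear (solid cancers, divided by a DDREF) or linear-quadratic (leukaemia),
and no excess risk is attributed during the latency period (5 years for solid
cancers, 2 for leukaemia).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field

from .errors import DataValidationError
from .sites import SITE_NAMES, get_site

__all__ = [
    "BaselineRateTable",
    "RiskModelParams",
    "ExposureScenario",
    "err",
    "ear",
    "excess_rate",
]

PER_100K = 1e5
EAR_SCALE = 1e4  # EAR coefficients are excess cases per 10,000 person-years per Gy


@dataclass(frozen=True)
class BaselineRateTable:
    """Sex/site-specific baseline cancer rate, events per 100,000 person-years.

    Rates between tabulated ages are linearly interpolated; beyond the last
    tabulated age the last value is held (and symmetrically before the first).
    """

    site: str
    sex: str
    kind: Literal["incidence", "mortality"]
    ages: np.ndarray = field(repr=False)
    rates: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.site not in SITE_NAMES:
            raise DataValidationError(
                f"unknown site {self.site!r}; expected one of {', '.join(SITE_NAMES)}")
        if self.kind not in ("incidence", "mortality"):
            raise DataValidationError(f"kind must be incidence or mortality, got {self.kind!r}")
        ages = np.asarray(self.ages, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        if ages.ndim != 1 or rates.shape != ages.shape or ages.size == 0:
            raise DataValidationError("ages and rates must be 1-D and equal length")
        if np.any(np.diff(ages) <= 0):
            raise DataValidationError("baseline ages must be strictly increasing")
        if np.any(rates < 0):
            a = float(ages[np.argmax(rates < 0)])
            raise DataValidationError(f"negative baseline rate at age {a:g}")

    def rate_at(self, a) -> float | np.ndarray:
        """Rate per 100,000 person-years at (possibly fractional) age a."""
        out = np.interp(np.asarray(a, dtype=float), self.ages, self.rates)
        return float(out) if np.ndim(a) == 0 else out


class RiskModelParams(BaseModel):
    """Per-site, per-sex excess-risk model parameters."""

    site: str
    sex: str
    beta_err: float = Field(ge=0.0, description="ERR per Gy at reference ages")
    beta_ear: float = Field(ge=0.0, description="EAR per 10^4 PY per Gy at reference ages")
    gamma: float = 0.0
    eta: float = 0.0
    transport_weight: float = Field(default=0.5, ge=0.0, le=1.0)
    ddref: float = Field(default=1.5, ge=1.0)
    latency: int = Field(default=5, ge=0)
    dose_response: Literal["linear", "linear_quadratic"] = "linear"
    theta: float = Field(default=0.0, ge=0.0, description="curvature per Gy (LQ only)")
    target_organ: str = ""

    model_config = {"frozen": True}


class ExposureScenario(BaseModel):
    """One exposure: who, at what age, with how much administered activity."""

    sex: Literal["male", "female"]
    e: float = Field(ge=0.0, le=110.0, description="age at exposure, years")
    administered_activity: float = Field(gt=0.0, description="MBq")
    cohort: str | None = None

    model_config = {"frozen": True}


def _age_profile(beta: float, gamma: float, eta: float, e: float, a):
    estar = (min(e, 30.0) - 30.0) / 10.0
    return beta * np.exp(gamma * estar) * (np.asarray(a, dtype=float) / 60.0) ** eta


def _check_latency(params: RiskModelParams, e: float, a) -> None:
    if np.any(np.asarray(a, dtype=float) < e + params.latency):
        raise DataValidationError(
            f"attained age below end of latency (e + {params.latency} = {e + params.latency:g})"
        )


def err(params: RiskModelParams, e: float, a) -> float | np.ndarray:
    """Excess relative risk per Gy at attained age a for exposure at age e."""
    _check_latency(params, e, a)
    out = _age_profile(params.beta_err, params.gamma, params.eta, e, a)
    return float(out) if np.ndim(a) == 0 else out


def ear(params: RiskModelParams, e: float, a) -> float | np.ndarray:
    """Excess absolute risk (per 10,000 person-years per Gy) at attained age a."""
    _check_latency(params, e, a)
    out = _age_profile(params.beta_ear, params.gamma, params.eta, e, a)
    return float(out) if np.ndim(a) == 0 else out


def excess_rate(params: RiskModelParams, baseline: BaselineRateTable,
                D: float, e: float, a) -> float | np.ndarray:
    """Excess cancer rate M(D, e, a), events per person-year.

    ``D`` is the absorbed dose (Gy) to the site's target organ. The dose term
    is f(D) = D (linear) or D(1 + theta*D) (linear-quadratic), divided by the
    DDREF; the ERR pathway multiplies the baseline rate, the EAR pathway adds
    an absolute rate, mixed by the transport weight w:

        M = f(D)/DDREF * [ w * ERR(e,a) * lambda(a) + (1-w) * EAR(e,a)/10^4 ]
    """
    if D < 0:
        raise DataValidationError(f"dose must be non-negative, got {D!r}")
    get_site(params.site)
    if baseline.site != params.site:
        raise DataValidationError(
            f"baseline table is for site {baseline.site!r}, params for {params.site!r}")
    if params.dose_response == "linear_quadratic":
        f = D * (1.0 + params.theta * D)
    else:
        f = D
    w = params.transport_weight
    lam = np.asarray(baseline.rate_at(a), dtype=float) / PER_100K
    m = f / params.ddref * (w * err(params, e, a) * lam
                            + (1.0 - w) * ear(params, e, a) / EAR_SCALE)
    return float(m) if np.ndim(a) == 0 else m
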