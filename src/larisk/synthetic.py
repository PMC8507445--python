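"""Synthetic national-statistics generator.

The risk pipeline consumes national life tables, registry cancer rates and
tabulated dose coefficients. None of those ship with the package, so this
module generates stand-ins with known ground truth that reproduce their
qualitative structure:

* mortality follows a Gompertz–Makeham hazard h(u) = c + alpha * exp(beta*u),
  giving monotone survivorship and a life expectancy near 80 years;
* baseline cancer incidence follows a per-site power law
  lambda(a) = base * max(0, a - onset)**p (per 100,000 person-years),
  rising with age from a site-specific onset; mortality rates are the
  incidence rates scaled by a per-site lethality in (0, 1];
* dose coefficients decrease monotonically from the age-1 phantom to the
  adult phantom, as internal dosimetry tables do;
* risk-model coefficients are drawn from BEIR VII-magnitude ranges, with the
  drawn values recorded for parameter-recovery tests.

Everything is deterministic under the configured seed, with independent
streams per generator so the outputs do not depend on call order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field

from .dosimetry import DoseCoefficientTable
from .lifetables import COHORT_PRESETS, CohortSurvivalSpec, LifeTable
from .risk_models import BaselineRateTable, RiskModelParams
from .sites import SEXES, SITE_REGISTRY

__all__ = [
    "GompertzMakeham",
    "SyntheticConfig",
    "SyntheticBundle",
    "make_lifetable",
    "make_baseline_rates",
    "make_dose_coefficients",
    "make_risk_params",
    "make_bundle",
]

MAX_AGE = 110

# independent RNG sub-streams per generator
_STREAM_RATES = 1
_STREAM_DOSE = 2
_STREAM_RISK = 3


class GompertzMakeham(BaseModel):
    """Hazard h(u) = makeham_c + alpha * exp(beta * u), per year."""

    alpha: float = Field(default=5e-5, ge=0.0)
    beta: float = Field(default=0.09, gt=0.0)
    makeham_c: float = Field(default=5e-4, ge=0.0)

    model_config = {"frozen": True}


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic population, registry and dosimetry tables."""

    seed: int = 0
    gompertz_male: GompertzMakeham = GompertzMakeham(alpha=3.2e-5)
    gompertz_female: GompertzMakeham = GompertzMakeham(alpha=2.0e-5)
    n_sites: int = Field(default=15, ge=1, le=15)
    # incidence power law: lambda(a) = base * max(0, a - onset)**p per 100k
    incidence_base_range: tuple[float, float] = (0.02, 0.08)
    incidence_power_range: tuple[float, float] = (1.5, 2.5)
    incidence_onset_range: tuple[float, float] = (20.0, 40.0)
    # leukaemia rates are flatter and present from birth
    leukaemia_base_range: tuple[float, float] = (3.0, 8.0)
    leukaemia_power_range: tuple[float, float] = (0.2, 0.5)
    lethality_range: tuple[float, float] = (0.15, 0.9)
    # dose coefficients, mGy/MBq
    adult_coeff_range: tuple[float, float] = (0.0008, 0.008)
    age1_adult_ratio_range: tuple[float, float] = (2.0, 10.0)
    bone_seeker: bool = True
    radiopharmaceutical: str = "99mTc-phosphonate"
    # risk-model coefficient ranges
    beta_err_range: tuple[float, float] = (0.1, 1.0)
    beta_ear_range: tuple[float, float] = (0.5, 5.0)
    gamma_range: tuple[float, float] = (-0.4, -0.1)
    eta_range: tuple[float, float] = (-1.5, 0.5)
    transport_weight_range: tuple[float, float] = (0.3, 0.7)
    ddref_solid: float = 1.5
    theta_leukaemia: float = 0.7

    model_config = {"frozen": True}

    def sites(self):
        return SITE_REGISTRY[: self.n_sites]


@dataclass(frozen=True)
class SyntheticBundle:
    """Everything the pipeline needs, generated from one config."""

    config: SyntheticConfig
    lifetables: dict[str, LifeTable]
    baselines: dict[tuple[str, str, str], BaselineRateTable]
    dose_table: DoseCoefficientTable
    risk_params: dict[tuple[str, str], RiskModelParams]
    ground_truth: dict[str, dict[str, float]] = field(repr=False, default_factory=dict)
    cohorts: dict[str, CohortSurvivalSpec] = field(default_factory=lambda: dict(COHORT_PRESETS))


def make_lifetable(config: SyntheticConfig, sex: str = "male") -> LifeTable:
    """Gompertz–Makeham survivorship l(a) = exp(-sum of hazards below a)."""
    gm = config.gompertz_male if sex == "male" else config.gompertz_female
    ages = np.arange(MAX_AGE + 1)
    hazard = gm.makeham_c + gm.alpha * np.exp(gm.beta * ages[:-1].astype(float))
    lx = np.concatenate([[1.0], np.exp(-np.cumsum(hazard))])
    table = LifeTable(sex=sex, ages=ages, survivorship=lx)
    life_expectancy = float(np.sum(lx[1:]) + 0.5)
    if lx[-1] > 0.05 or not 40.0 <= life_expectancy <= 100.0:
        warnings.warn(
            f"implausible synthetic population ({sex}): life expectancy "
            f"{life_expectancy:.1f} y, l(110) = {lx[-1]:.3g}", stacklevel=2)
    return table


def _site_rate_draws(config: SyntheticConfig):
    """Per-site power-law parameters, in fixed registry order."""
    rng = np.random.default_rng([config.seed, _STREAM_RATES])
    draws = {}
    for site in config.sites():
        if site.leukaemia:
            base = rng.uniform(*config.leukaemia_base_range)
            power = rng.uniform(*config.leukaemia_power_range)
            onset = 0.0
        else:
            base = rng.uniform(*config.incidence_base_range)
            power = rng.uniform(*config.incidence_power_range)
            onset = rng.uniform(*config.incidence_onset_range)
        lethality = rng.uniform(*config.lethality_range)
        sex_ratio = rng.uniform(0.8, 1.25)  # male/female rate ratio
        draws[site.name] = dict(base=base, power=power, onset=onset,
                                lethality=lethality, sex_ratio=sex_ratio)
    return draws


def make_baseline_rates(config: SyntheticConfig) -> dict[tuple[str, str, str], BaselineRateTable]:
    """Incidence and mortality rate tables for every (site, sex)."""
    draws = _site_rate_draws(config)
    ages = np.arange(MAX_AGE + 1, dtype=float)
    out: dict[tuple[str, str, str], BaselineRateTable] = {}
    for site in config.sites():
        d = draws[site.name]
        rates = d["base"] * np.maximum(0.0, ages - d["onset"]) ** d["power"]
        for sex in site.sexes:
            mult = d["sex_ratio"] if sex == "male" else 1.0
            inc = rates * mult
            out[(site.name, sex, "incidence")] = BaselineRateTable(
                site=site.name, sex=sex, kind="incidence", ages=ages, rates=inc)
            out[(site.name, sex, "mortality")] = BaselineRateTable(
                site=site.name, sex=sex, kind="mortality", ages=ages,
                rates=inc * d["lethality"])
    return out


def make_dose_coefficients(config: SyntheticConfig) -> DoseCoefficientTable:
    """Organ dose coefficients, strictly decreasing from age-1 to adult phantom."""
    rng = np.random.default_rng([config.seed, _STREAM_DOSE])
    organs = []
    for site in SITE_REGISTRY:
        if site.target_organ not in organs:
            organs.append(site.target_organ)
    organs.append("bone_surfaces")
    coeffs = {}
    for organ in organs:
        adult = rng.uniform(*config.adult_coeff_range)
        ratio = rng.uniform(*config.age1_adult_ratio_range)
        coeffs[organ] = adult * ratio ** np.array([1.0, 0.75, 0.5, 0.25, 0.0])
    return DoseCoefficientTable(radiopharmaceutical=config.radiopharmaceutical,
                                coefficients=coeffs, bone_seeker=config.bone_seeker)


def make_risk_params(config: SyntheticConfig
                     ) -> tuple[dict[tuple[str, str], RiskModelParams],
                                dict[str, dict[str, float]]]:
    """Risk-model parameter set plus the ground-truth record of the draws.

    Coefficients are drawn once per site and shared across the applicable
    sexes; leukaemia gets the linear-quadratic dose response with a 2-year
    latency, solid sites the linear response with the solid-cancer DDREF and
    a 5-year latency.
    """
    rng = np.random.default_rng([config.seed, _STREAM_RISK])
    params: dict[tuple[str, str], RiskModelParams] = {}
    truth: dict[str, dict[str, float]] = {}
    for site in config.sites():
        draw = dict(
            beta_err=rng.uniform(*config.beta_err_range),
            beta_ear=rng.uniform(*config.beta_ear_range),
            gamma=rng.uniform(*config.gamma_range),
            eta=rng.uniform(*config.eta_range),
            transport_weight=rng.uniform(*config.transport_weight_range),
        )
        truth[site.name] = dict(draw)
        common = dict(
            draw,
            ddref=1.0 if site.leukaemia else config.ddref_solid,
            latency=2 if site.leukaemia else 5,
            dose_response="linear_quadratic" if site.leukaemia else "linear",
            theta=config.theta_leukaemia if site.leukaemia else 0.0,
            target_organ=site.target_organ,
        )
        for sex in site.sexes:
            params[(site.name, sex)] = RiskModelParams(site=site.name, sex=sex, **common)
    return params, truth


def make_bundle(config: SyntheticConfig | None = None, *, seed: int | None = None
                ) -> SyntheticBundle:
    """Generate the full input stack from one config (or just a seed)."""
    if config is None:
        config = SyntheticConfig(seed=seed if seed is not None else 0)
    risk_params, truth = make_risk_params(config)
    return SyntheticBundle(
        config=config,
        lifetables={sex: make_lifetable(config, sex) for sex in SEXES},
        baselines=make_baseline_rates(config),
        dose_table=make_dose_coefficients(config),
        risk_params=risk_params,
        ground_truth=truth,
    )
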