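import numpy as np
import pytest

from larisk.lifetables import LifeTable
from larisk.risk_models import BaselineRateTable, RiskModelParams
from larisk.synthetic import SyntheticConfig, make_bundle

MAX_AGE = 110


def constant_hazard_table(h: float, sex: str = "male") -> LifeTable:
    ages = np.arange(MAX_AGE + 1)
    return LifeTable(sex=sex, ages=ages, survivorship=np.exp(-h * ages))


@pytest.fixture(scope="session")
def immortal_table():
    return LifeTable(sex="male", ages=np.arange(MAX_AGE + 1),
                     survivorship=np.ones(MAX_AGE + 1))


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic input stack (leukaemia linear-quadratic)."""
    return make_bundle(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def linear_bundle():
    """All-linear configuration (leukaemia curvature off) for linearity-based ops."""
    return make_bundle(SyntheticConfig(seed=1, theta_leukaemia=0.0))


def flat_params(site="lung", sex="male", *, beta_err=0.0, beta_ear=0.0,
                w=0.5, ddref=1.0, latency=5, **kw) -> RiskModelParams:
    """Age-independent model: gamma = eta = 0 unless overridden."""
    return RiskModelParams(site=site, sex=sex, beta_err=beta_err,
                           beta_ear=beta_ear, gamma=kw.pop("gamma", 0.0),
                           eta=kw.pop("eta", 0.0), transport_weight=w,
                           ddref=ddref, latency=latency, **kw)


def flat_baseline(rate=200.0, site="lung", sex="male", kind="incidence"):
    ages = np.arange(MAX_AGE + 1, dtype=float)
    return BaselineRateTable(site=site, sex=sex, kind=kind, ages=ages,
                             rates=np.full_like(ages, rate))
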