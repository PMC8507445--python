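"""LAR quadrature against closed forms, additivity and context quantities."""
import math

import numpy as np
import pytest

from larisk.errors import ComputationError, DataValidationError
from larisk.io import compute_lar
from larisk.lar_engine import (LARResult, effective_dose_risk, lar_mortality,
                               lar_site, lar_total, lifetime_baseline_risk)
from larisk.lifetables import LifeTable
from larisk.risk_models import BaselineRateTable, ExposureScenario

from conftest import constant_hazard_table, flat_baseline, flat_params


def constant_m_params(m, *, latency=5):
    """Configuration whose excess rate is exactly m per person-year at D=1 Gy."""
    return flat_params(beta_ear=m * 1e4, w=0.0, ddref=1.0, latency=latency)


class TestLarSite:
    def test_immortal_population_closed_form(self, immortal_table):
        m = 1e-5
        lar = lar_site(constant_m_params(m), flat_baseline(0.0),
                       immortal_table, 1.0, 40)
        assert lar == pytest.approx(m * (110 - 45), rel=1e-12)

    def test_constant_hazard_analytic_limit(self):
        # continuous limit m(1-exp(-h(110-e-L)))/h; fine grid converges to it
        m, h, e, L = 1e-5, 0.05, 40, 5
        exact = m * (1 - math.exp(-h * (110 - e - L))) / h
        assert exact == pytest.approx(1.923e-4, rel=1e-3)
        t = constant_hazard_table(h)
        p = constant_m_params(m)
        coarse = lar_site(p, flat_baseline(0.0), t, 1.0, e)
        fine = lar_site(p, flat_baseline(0.0), t, 1.0, e, step=0.01)
        assert fine == pytest.approx(exact, rel=1e-3)
        assert coarse == pytest.approx(exact, rel=0.03)
        assert abs(fine - exact) < abs(coarse - exact)

    def test_quadrature_converges_under_refinement(self):
        m, h, e = 1e-5, 0.05, 40
        exact = m * (1 - math.exp(-h * 65)) / h
        t = constant_hazard_table(h)
        p = constant_m_params(m)
        errors = [abs(lar_site(p, flat_baseline(0.0), t, 1.0, e, step=s) - exact)
                  for s in (1.0, 0.5, 0.25, 0.125)]
        assert all(a > b for a, b in zip(errors, errors[1:]))

    def test_zero_dose_gives_zero(self, immortal_table):
        lar = lar_site(flat_params(beta_err=1, beta_ear=1), flat_baseline(),
                       immortal_table, 0.0, 40)
        assert lar == 0.0

    def test_latency_reaching_age_limit_warns_and_returns_zero(self, immortal_table):
        with pytest.warns(UserWarning, match="integration limit"):
            assert lar_site(flat_params(beta_err=1), flat_baseline(),
                            immortal_table, 1.0, 106) == 0.0

    def test_cohort_extinct_before_latency_end(self):
        lx = np.concatenate([np.linspace(1, 0, 43), np.zeros(68)])
        t = LifeTable(sex="male", ages=np.arange(111), survivorship=lx)
        with pytest.raises(ComputationError, match="extinct"):
            lar_site(flat_params(beta_err=1), flat_baseline(), t, 1.0, 40)

    def test_integrand_normalized_at_latency_end(self):
        # the first rectangle contributes exactly M(D,e,e+L): S-ratio is 1 there
        t = constant_hazard_table(0.1)
        m = 2e-5
        p = constant_m_params(m)
        near = lar_site(p, flat_baseline(0.0), t, 1.0, 104)  # ages 109 only
        assert near == pytest.approx(m, rel=1e-12)

    def test_smaller_survival_never_increases_lar(self, bundle):
        t = bundle.lifetables["male"]
        smaller = LifeTable(sex="male", ages=t.ages,
                            survivorship=t.survivorship * np.linspace(1, 0.4, 111))
        p = bundle.risk_params[("lung", "male")]
        b = bundle.baselines[("lung", "male", "incidence")]
        assert lar_site(p, b, smaller, 0.002, 30) <= lar_site(p, b, t, 0.002, 30)


class TestLarTotal:
    def test_per_site_sums_to_total(self, bundle):
        res = compute_lar(bundle, "male", 40, 500.0)
        assert res.total == pytest.approx(sum(res.per_site.values()), abs=1e-15)
        assert len(res.per_site) == 12  # male registry: 11 shared + prostate
        assert all(v >= 0 for v in res.per_site.values())

    def test_female_registry_has_fourteen_sites(self, bundle):
        res = compute_lar(bundle, "female", 40, 500.0)
        assert len(res.per_site) == 14
        assert {"breast", "uterus", "ovary"} <= set(res.per_site)

    def test_doubling_activity_doubles_total_when_all_linear(self, linear_bundle):
        r1 = compute_lar(linear_bundle, "male", 40, 500.0)
        r2 = compute_lar(linear_bundle, "male", 40, 1000.0)
        assert r2.total == pytest.approx(2.0 * r1.total, rel=1e-12)

    def test_missing_inputs_listed(self, bundle, immortal_table):
        scenario = ExposureScenario(sex="male", e=40, administered_activity=500)
        from larisk.dosimetry import OrganDoseVector
        doses = OrganDoseVector(doses={"lung": 0.001}, activity=500, age=40)
        with pytest.raises(DataValidationError, match="missing inputs"):
            lar_total(scenario, {}, {}, immortal_table, doses)

    def test_unknown_cohort_rejected(self, bundle):
        with pytest.raises(DataValidationError, match="unknown cohort"):
            compute_lar(bundle, "male", 40, 500.0, cohort="nope")

    def test_total_must_be_probability(self, immortal_table):
        scenario = ExposureScenario(sex="male", e=0, administered_activity=1)
        with pytest.raises(ComputationError):
            LARResult(scenario=scenario, kind="incidence",
                      per_site={"lung": 1.5}, total=1.5)


class TestLarMortality:
    def test_equal_baselines_give_equal_lar(self, immortal_table):
        p = flat_params(beta_err=0.5, w=1.0)
        b_inc = flat_baseline(200.0, kind="incidence")
        b_mort = flat_baseline(200.0, kind="mortality")
        assert lar_site(p, b_mort, immortal_table, 0.01, 40) == \
            lar_site(p, b_inc, immortal_table, 0.01, 40)

    def test_halved_mortality_baseline_halves_lar_under_pure_err(self, immortal_table):
        p = flat_params(beta_err=0.5, w=1.0)
        full = lar_site(p, flat_baseline(200.0, kind="mortality"),
                        immortal_table, 0.01, 40)
        half = lar_site(p, flat_baseline(100.0, kind="mortality"),
                        immortal_table, 0.01, 40)
        assert half == pytest.approx(0.5 * full, rel=1e-12)

    def test_mortality_kind_flagged(self, bundle):
        res = compute_lar(bundle, "male", 40, 500.0, kind="mortality")
        assert res.kind == "mortality"
        inc = compute_lar(bundle, "male", 40, 500.0)
        # synthetic mortality rates are incidence times lethality <= 0.9
        assert res.total < inc.total

    def test_lar_mortality_wrapper_matches_kind(self, bundle):
        from larisk.dosimetry import organ_doses
        scenario = ExposureScenario(sex="male", e=40, administered_activity=500)
        doses = organ_doses(bundle.dose_table, 500.0, 40)
        res = lar_mortality(scenario, bundle.risk_params, bundle.baselines,
                            bundle.lifetables["male"], doses)
        assert res.kind == "mortality"
        assert res.total == pytest.approx(
            compute_lar(bundle, "male", 40, 500.0, kind="mortality").total, rel=1e-12)


class TestLifetimeBaselineRisk:
    def test_zero_rates(self, immortal_table):
        assert lifetime_baseline_risk(flat_baseline(0.0), immortal_table) == 0.0

    def test_immortal_closed_form(self, immortal_table):
        # lambda = c per person-year over [0, 110)
        risk = lifetime_baseline_risk(flat_baseline(100.0), immortal_table)
        assert risk == pytest.approx(110 * 1e-3, rel=1e-12)

    def test_constant_hazard_analytic_limit(self):
        t = constant_hazard_table(0.02)
        risk = lifetime_baseline_risk(flat_baseline(400.0), t)
        exact = 0.004 * (1 - math.exp(-2.2)) / 0.02
        assert exact == pytest.approx(0.1778, rel=1e-3)
        assert risk == pytest.approx(exact, rel=0.02)


class TestEffectiveDoseRisk:
    def test_zero_dose(self):
        assert effective_dose_risk(0.0) == 0.0

    def test_whole_population_coefficient(self):
        assert effective_dose_risk(0.003, "whole") == pytest.approx(1.65e-4, rel=1e-12)

    def test_worker_coefficient(self):
        assert effective_dose_risk(1.0, "worker") == pytest.approx(0.041, rel=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(DataValidationError):
            effective_dose_risk(-0.1)

    def test_unknown_population_rejected(self):
        with pytest.raises(DataValidationError):
            effective_dose_risk(0.1, "children")


class TestOneInRendering:
    def test_two_significant_figures(self, bundle):
        res = compute_lar(bundle, "male", 40, 500.0)
        n = res.one_in()
        assert n == pytest.approx(1 / res.total, rel=0.05)
        # two significant figures: n / 10^(digits-2) is an integer
        import math as _m
        mag = 10 ** _m.floor(_m.log10(n) - 1)
        assert n % mag == 0
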