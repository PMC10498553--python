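import numpy as np
import pytest

from perspecta.disease import HealthState
from perspecta.economics import CostModel
from perspecta.engine import (
    accrue_daly,
    discount,
    simulate_cohort,
    simulate_person,
)
from perspecta.params import DistributionSpec

from conftest import zero_hazard_params


class TestDiscount:
    def test_time_zero(self):
        assert discount(100.0, 0.0, 0.05) == pytest.approx(100.0)

    def test_one_year(self):
        assert discount(100.0, 1.0, 0.05) == pytest.approx(95.238, abs=5e-4)

    def test_half_value_time(self):
        # log(2)/log(1.05) years halves the value
        assert discount(1.0, 14.2067, 0.05) == pytest.approx(0.5, abs=1e-5)

    def test_zero_rate_is_identity(self):
        assert discount(42.0, 13.0, 0.0) == pytest.approx(42.0)

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            discount(1.0, 1.0, -0.01)


class TestAccrueDaly:
    def test_on_art_high_cd4(self, moz_params):
        state = HealthState("gt500", "on_first_line")
        assert accrue_daly(state, True, moz_params, 1.0) == pytest.approx(0.078)

    def test_off_art_low_cd4(self, moz_params):
        state = HealthState("lt200", "off_art_first_line_eligible")
        assert accrue_daly(state, False, moz_params, 1.0) == pytest.approx(0.58)

    def test_zero_weight(self, degenerate_params):
        params = degenerate_params.replace(
            daly_weight_on_art={
                b: DistributionSpec.point(0.0)
                for b in degenerate_params.daly_weight_on_art
            }
        )
        state = HealthState("gt500", "on_first_line")
        assert accrue_daly(state, True, params, 1.0) == 0.0

    def test_additive_over_disjoint_intervals(self, moz_params):
        state = HealthState("c200_349", "on_first_line")
        whole = accrue_daly(state, True, moz_params, 1.0)
        parts = sum(accrue_daly(state, True, moz_params, 1 / 12) for _ in range(12))
        assert parts == pytest.approx(whole, abs=1e-12)


def _zeroed_costs(params):
    zero = DistributionSpec.point(0.0)
    return params.replace(
        facility_cost_1m_annual=zero,
        community_cost_3m_annual=zero,
        arv_cost_monthly_dtg=zero,
        arv_cost_monthly_efv=zero,
        arv_cost_monthly_second_line=zero,
        vl_test_cost_annual=zero,
        case_mgmt_cost_monthly=zero,
        chapa_cost_per_hour=zero,
        walk_roundtrip_hours=zero,
        wait_time_hours=zero,
        net_national_income_pc=zero,
        daly_weight_on_art={b: zero for b in params.daly_weight_on_art},
        daly_weight_off_art={b: zero for b in params.daly_weight_off_art},
    )


class TestSimulatePerson:
    def test_degenerate_person(self, degenerate_params, strategies):
        params = _zeroed_costs(degenerate_params)
        res = simulate_person(
            params, strategies["clinical_1m"], horizon_years=10, seed=3
        )
        assert res.survival_years == pytest.approx(10.0)
        assert res.years_on_art == pytest.approx(10.0)
        assert res.discounted_cost_patient == 0.0
        assert res.discounted_cost_health_sector == 0.0
        assert res.discounted_dalys == 0.0
        assert res.final_state is not None and res.final_state.on_art

    def test_deterministic_given_seed(self, moz_params, strategies):
        a = simulate_person(moz_params, strategies["clinical_3m"], horizon_years=20, seed=11)
        b = simulate_person(moz_params, strategies["clinical_3m"], horizon_years=20, seed=11)
        assert a == b

    def test_initial_state_override(self, degenerate_params, strategies):
        res = simulate_person(
            degenerate_params,
            strategies["clinical_1m"],
            horizon_years=1,
            seed=0,
            initial_state=HealthState("lt200", "on_first_line"),
        )
        # forced 1-month band (CD4<200) with zero drift: stays put
        assert res.final_state == HealthState("lt200", "on_first_line")


class TestClosedFormOracles:
    def test_death_only_geometric_lifetime(self, degenerate_params, strategies):
        # constant hazard r=30/100py => mean lifetime ~ 100/30 years
        r = 30.0
        params = _zeroed_costs(degenerate_params).replace(
            mortality_rate_by_cd4_untreated={
                b: DistributionSpec.point(r)
                for b in degenerate_params.mortality_rate_by_cd4_untreated
            }
        )
        res = simulate_cohort(
            params, strategies["clinical_1m"], n=20_000, horizon_years=100, seed=5
        )
        mean = res.survival_years.mean()
        se = res.survival_years.std(ddof=1) / np.sqrt(res.n)
        assert abs(mean - 100.0 / r) < 3 * se

    def test_annuity_equivalence(self, degenerate_params, strategies):
        # no transitions, constant per-cycle costs: engine must equal the
        # closed-form mid-cycle annuity to 1e-9
        params = degenerate_params
        horizon, d = 30.0, params.discount_rate.base
        n_cycles = int(horizon * 12)
        res = simulate_cohort(
            params,
            strategies["clinical_1m"],
            n=3,
            horizon_years=horizon,
            seed=9,
            init={"band": 0, "status": 0, "regimen": 0},
        )
        cm = CostModel.build(params, strategies["clinical_1m"])
        c_patient = cm.patient_table[0, 0]
        c_hs = cm.hs_table[0, 0, 0]
        w = params.daly_weight_on_art["gt500"].base / 12.0
        t_mid = (np.arange(1, n_cycles + 1) - 0.5) / 12.0
        factor = (1 + d) ** (-t_mid)
        assert np.allclose(res.discounted_cost_patient, c_patient * factor.sum(), atol=1e-9)
        assert np.allclose(res.discounted_cost_health_sector, c_hs * factor.sum(), atol=1e-9)
        assert np.allclose(res.discounted_dalys, w * factor.sum(), atol=1e-9)
        assert np.allclose(res.undiscounted_cost_patient, c_patient * n_cycles, atol=1e-9)

    def test_forced_period_uses_clinic_costs(self, degenerate_params, strategies):
        # first 3 months of a 6-month strategy accrue monthly clinic visits
        params = degenerate_params
        res = simulate_cohort(
            params,
            strategies["clinical_6m"],
            n=1,
            horizon_years=0.25,
            seed=1,
            init={"band": 0, "status": 0, "regimen": 0},
        )
        cm = CostModel.build(params, strategies["clinical_6m"])
        d = params.discount_rate.base
        t_mid = (np.arange(1, 4) - 0.5) / 12.0
        expected = cm.patient_table[0, 1] * ((1 + d) ** (-t_mid)).sum()
        assert res.discounted_cost_patient[0] == pytest.approx(expected, abs=1e-9)


class TestCohort:
    def test_reproducible(self, moz_params, strategies):
        a = simulate_cohort(moz_params, strategies["community_3m"], n=200,
                            horizon_years=15, seed=21)
        b = simulate_cohort(moz_params, strategies["community_3m"], n=200,
                            horizon_years=15, seed=21)
        for field in ("discounted_cost_patient", "discounted_dalys", "survival_years"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_rejects_empty(self, moz_params, strategies):
        with pytest.raises(ValueError):
            simulate_cohort(moz_params, strategies["clinical_1m"], n=0,
                            horizon_years=10, seed=1)

    def test_discounted_le_undiscounted(self, moz_params, strategies):
        res = simulate_cohort(moz_params, strategies["clinical_3m"], n=500,
                              horizon_years=40, seed=2)
        assert np.all(res.discounted_cost_patient <= res.undiscounted_cost_patient + 1e-12)
        assert np.all(
            res.discounted_cost_health_sector <= res.undiscounted_cost_health_sector + 1e-12
        )
        assert np.all(res.discounted_dalys <= res.undiscounted_dalys + 1e-12)

    def test_bounds(self, moz_params, strategies):
        res = simulate_cohort(moz_params, strategies["clinical_6m"], n=500,
                              horizon_years=30, seed=4)
        assert np.all(res.survival_years <= 30.0 + 1e-12)
        assert np.all(res.years_on_art <= res.survival_years + 1e-12)
        for f in ("discounted_cost_patient", "discounted_cost_health_sector",
                  "discounted_dalys", "years_on_art", "survival_years"):
            assert np.all(getattr(res, f) >= 0)

    def test_summary_means_bracketed(self, moz_params, strategies):
        res = simulate_cohort(moz_params, strategies["clinical_3m"], n=300,
                              horizon_years=25, seed=8)
        summ = res.summary()
        for f, mean in summ.means.items():
            arr = getattr(res, f)
            assert arr.min() - 1e-12 <= mean <= arr.max() + 1e-12

    def test_no_death_survival_equals_horizon(self, degenerate_params, strategies):
        res = simulate_cohort(degenerate_params, strategies["clinical_1m"], n=50,
                              horizon_years=12, seed=3)
        assert np.allclose(res.survival_years, 12.0)

    def test_seed_change_stability_under_doubling(self, moz_params, strategies):
        a = simulate_cohort(moz_params, strategies["clinical_6m"], n=3000,
                            horizon_years=100, seed=101).summary()
        b = simulate_cohort(moz_params, strategies["clinical_6m"], n=6000,
                            horizon_years=100, seed=202).summary()
        for f in ("survival_years", "discounted_cost_patient", "discounted_dalys"):
            se = np.hypot(a.standard_errors[f], b.standard_errors[f])
            assert abs(a.means[f] - b.means[f]) < 3 * se, f

    def test_6m_survival_exceeds_1m(self, moz_params, strategies):
        # lower LTFU -> more time on ART -> lower mortality
        one = simulate_cohort(moz_params, strategies["clinical_1m"], n=20_000,
                              horizon_years=100, seed=31).summary()
        six = simulate_cohort(moz_params, strategies["clinical_6m"], n=20_000,
                              horizon_years=100, seed=32).summary()
        se = np.hypot(one.standard_errors["survival_years"],
                      six.standard_errors["survival_years"])
        assert six.mean_survival_years - one.mean_survival_years > 3 * se

    def test_person_frame_and_accessors(self, moz_params, strategies):
        res = simulate_cohort(moz_params, strategies["clinical_1m"], n=20,
                              horizon_years=10, seed=77)
        df = res.to_frame()
        assert len(df) == 20
        assert df["strategy"].eq("clinical_1m").all()
        p = res.person(0)
        assert p.discounted_cost_patient == pytest.approx(
            res.discounted_cost_patient[0]
        )

    def test_dalys_fall_when_weights_zeroed(self, moz_params, strategies):
        zero = DistributionSpec.point(0.0)
        params = moz_params.replace(
            daly_weight_on_art={b: zero for b in moz_params.daly_weight_on_art},
            daly_weight_off_art={b: zero for b in moz_params.daly_weight_off_art},
        )
        full = simulate_cohort(moz_params, strategies["clinical_3m"], n=400,
                               horizon_years=30, seed=12)
        yll_only = simulate_cohort(params, strategies["clinical_3m"], n=400,
                                   horizon_years=30, seed=12)
        assert np.all(yll_only.discounted_dalys <= full.discounted_dalys + 1e-12)
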