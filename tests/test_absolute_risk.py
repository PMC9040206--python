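import numpy as np
import pytest

from riskstrat import (GailParams, RatesTable, RiskFactorProfile,
                       calibrate_baseline_hazard, five_year_absolute_risk,
                       gail_absolute_risk, gail_relative_risk,
                       population_five_year_risk, prs_five_year_risk)
from conftest import euler_absolute_risk


def grid_calibration(rates, beta, n_grid=100_000):
    """Independent fine-grid oracle for the survivor-depletion calibration."""
    z = np.linspace(-10, 10, n_grid)
    w = np.exp(-0.5 * z ** 2)
    w /= w.sum()
    rr = np.exp(beta * z)
    h0 = []
    for lam, width in zip(rates.incidence, rates.age_high - rates.age_low):
        h = lam / float(w @ rr)
        h0.append(h)
        w = w * np.exp(-h * rr * width)
        w /= w.sum()
    return np.array(h0)


class TestRatesTable:
    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            RatesTable([30, 40], [35, 45], [1e-4, 1e-4], [1e-4, 1e-4])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="incidence"):
            RatesTable([30], [35], [-1e-4], [1e-4])

    def test_interval_lookup(self, singapore_rates):
        assert singapore_rates.interval_index(30.0) == 0
        assert singapore_rates.interval_index(52.5) == 4
        with pytest.raises(ValueError, match="coverage"):
            singapore_rates.interval_index(80.0)


class TestCalibration:
    def test_beta_zero_returns_population_incidence(self, singapore_rates):
        calib = calibrate_baseline_hazard(singapore_rates, beta=0.0)
        np.testing.assert_array_equal(calib.h0, singapore_rates.incidence)

    def test_first_interval_lognormal_identity(self):
        # before depletion, E[exp(beta Z)] = exp(beta^2/2)
        rates = RatesTable([30], [35], [0.002], [0.01])
        calib = calibrate_baseline_hazard(rates, beta=0.6)
        assert calib.h0[0] == pytest.approx(0.002 * np.exp(-0.18), rel=1e-10)

    def test_survivor_mean_rr_strictly_decreases(self, singapore_rates):
        calib = calibrate_baseline_hazard(singapore_rates, beta=0.6)
        means = [calib.mean_rr_at_start(k)
                 for k in range(singapore_rates.n_intervals)]
        assert all(a > b for a, b in zip(means, means[1:]))

    @pytest.mark.parametrize("beta", [0.0, 0.3, 0.6, 1.0, 1.2])
    def test_conservation_of_population_incidence(self, singapore_rates, beta):
        calib = calibrate_baseline_hazard(singapore_rates, beta)
        rr = np.exp(beta * calib.nodes)
        for k in range(singapore_rates.n_intervals):
            reproduced = calib.h0[k] * float(calib.start_weights[k] @ rr)
            assert reproduced == pytest.approx(singapore_rates.incidence[k],
                                               rel=1e-6)

    def test_quadrature_matches_fine_grid_oracle(self, singapore_rates):
        calib = calibrate_baseline_hazard(singapore_rates, beta=0.6,
                                          quadrature_size=64)
        oracle = grid_calibration(singapore_rates, beta=0.6)
        np.testing.assert_allclose(calib.h0, oracle, rtol=1e-8)


class TestFiveYearAbsoluteRisk:
    def test_zero_hazard_gives_zero_risk(self, constant_rates):
        assert five_year_absolute_risk(1.0, 50, [0.0], constant_rates) == 0.0

    def test_constant_hazard_closed_form(self, constant_rates):
        # h/(h+m) * (1 - exp(-5(h+m)))
        want = (0.002 / 0.012) * (1 - np.exp(-0.06))
        got = five_year_absolute_risk(1.0, 50, constant_rates.incidence,
                                      constant_rates)
        assert got == pytest.approx(want, abs=1e-10)

    def test_exponential_limit_without_mortality(self):
        rates = RatesTable([50], [55], [0.004], [0.0])
        got = five_year_absolute_risk(1.0, 50, rates.incidence, rates)
        assert got == pytest.approx(1 - np.exp(-5 * 0.004), abs=1e-12)

    def test_euler_oracle_randomized(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            h, m = rng.uniform(1e-4, 5e-3, size=2)
            r = rng.uniform(0.3, 3.0)
            rates = RatesTable([50], [55], [h], [m])
            got = five_year_absolute_risk(r, 50, rates.incidence, rates)
            assert got == pytest.approx(euler_absolute_risk(h, m, r), abs=1e-6)

    def test_off_boundary_age_splits_intervals(self, singapore_rates):
        # manual two-piece evaluation for a window [47, 52)
        h1 = singapore_rates.incidence[3]  # [45,50)
        m1 = singapore_rates.mortality[3]
        h2 = singapore_rates.incidence[4]  # [50,55)
        m2 = singapore_rates.mortality[4]
        p1 = h1 / (h1 + m1) * (1 - np.exp(-3 * (h1 + m1)))
        s1 = np.exp(-3 * (h1 + m1))
        p2 = h2 / (h2 + m2) * (1 - np.exp(-2 * (h2 + m2))) * s1
        got = five_year_absolute_risk(1.0, 47, singapore_rates.incidence,
                                      singapore_rates)
        assert got == pytest.approx(p1 + p2, rel=1e-12)

    def test_monotone_in_relative_risk(self, singapore_rates):
        risks = [five_year_absolute_risk(r, 50, singapore_rates.incidence,
                                         singapore_rates)
                 for r in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(risks, risks[1:]))

    def test_age_outside_coverage_rejected(self, singapore_rates):
        with pytest.raises(ValueError, match="not covered"):
            five_year_absolute_risk(1.0, 78, singapore_rates.incidence,
                                    singapore_rates)

    def test_prs_risk_monotone_and_population_consistent(self, singapore_rates):
        beta = 0.6
        calib = calibrate_baseline_hazard(singapore_rates, beta)
        zs = np.linspace(-3, 3, 13)
        risks = [prs_five_year_risk(z, 30, calib) for z in zs]
        assert all(a < b for a, b in zip(risks, risks[1:]))
        # averaging over a standard-normal z sample at the youngest age
        # reproduces the population 5-year risk
        rng = np.random.default_rng(7)
        z = rng.standard_normal(4000)
        mean_risk = np.mean([prs_five_year_risk(zi, 30, calib) for zi in z])
        pop = population_five_year_risk(30, singapore_rates)
        assert mean_risk == pytest.approx(pop, rel=0.05)


class TestGailModel:
    def test_reference_profile_rr_is_one(self, gail_params):
        prof = RiskFactorProfile()
        assert gail_relative_risk(prof, 45, gail_params) == pytest.approx(1.0)
        assert gail_relative_risk(prof, 65, gail_params) == pytest.approx(1.0)

    def test_family_history_hand_evaluation(self, gail_params):
        prof = RiskFactorProfile(n_relatives_breast=1)
        c = gail_params.coef["lt50"]
        want = np.exp(c["relatives"] + c["fb_rel_interaction"] * 0)
        assert gail_relative_risk(prof, 45, gail_params) == pytest.approx(want)

    def test_full_profile_hand_evaluation(self, gail_params):
        prof = RiskFactorProfile(menarche="<12", first_birth=">=30",
                                 biopsy="yes", n_relatives_breast=1)
        c = gail_params.coef["ge50"]
        lp = (2 * c["menarche"] + c["biopsy"] + 3 * c["first_birth"]
              + c["relatives"] + 3 * c["fb_rel_interaction"])
        assert gail_relative_risk(prof, 60, gail_params) == pytest.approx(np.exp(lp))

    def test_unknowns_map_to_reference(self, gail_params):
        prof = RiskFactorProfile(menarche="unknown", first_birth="unknown",
                                 biopsy="unknown")
        assert gail_relative_risk(prof, 45, gail_params) == pytest.approx(1.0)

    def test_monotone_in_menarche_category(self, gail_params):
        rrs = [gail_relative_risk(RiskFactorProfile(menarche=c), 45, gail_params)
               for c in (">=14", "12-13", "<12")]
        assert rrs[0] <= rrs[1] <= rrs[2]

    def test_below_model_domain_rejected(self, gail_params):
        with pytest.raises(ValueError, match="age 20"):
            gail_relative_risk(RiskFactorProfile(), 19, gail_params)

    def test_ar_zero_reference_equals_population_risk(self, singapore_rates):
        params = GailParams(
            coef={s: dict.fromkeys(GailParams._FACTORS, 0.3)
                  for s in ("lt50", "ge50")},
            ar={"lt50": 0.0, "ge50": 0.0})
        got = gail_absolute_risk(RiskFactorProfile(), 52, singapore_rates, params)
        assert got == pytest.approx(population_five_year_risk(52, singapore_rates),
                                    rel=1e-12)

    def test_constant_hazard_closed_form(self, constant_rates, gail_params):
        prof = RiskFactorProfile(n_relatives_breast=1)
        r = gail_relative_risk(prof, 50, gail_params)
        h = 0.002 * (1 - gail_params.ar["ge50"])
        want = euler_absolute_risk(h, 0.01, r)
        got = gail_absolute_risk(prof, 50, constant_rates, gail_params)
        assert got == pytest.approx(want, abs=1e-6)

    def test_rr_reevaluated_at_age_50_crossing(self, singapore_rates):
        # segments differ only in the relatives coefficient; window [47, 52)
        coef = dict.fromkeys(GailParams._FACTORS, 0.0)
        params = GailParams(
            coef={"lt50": {**coef, "relatives": np.log(3.0)},
                  "ge50": {**coef, "relatives": np.log(1.5)}},
            ar={"lt50": 0.0, "ge50": 0.0})
        prof = RiskFactorProfile(n_relatives_breast=1)
        got = gail_absolute_risk(prof, 47, singapore_rates, params)
        # manual: RR=3 on [47,50) over the [45,50) rates, RR=1.5 on [50,52)
        h1 = 3.0 * singapore_rates.incidence[3]
        m1 = singapore_rates.mortality[3]
        h2 = 1.5 * singapore_rates.incidence[4]
        m2 = singapore_rates.mortality[4]
        p1 = h1 / (h1 + m1) * (1 - np.exp(-3 * (h1 + m1)))
        want = p1 + np.exp(-3 * (h1 + m1)) * h2 / (h2 + m2) * (1 - np.exp(-2 * (h2 + m2)))
        assert got == pytest.approx(want, rel=1e-12)

    def test_average_woman_threshold_on_white_rates(self, white_rates):
        risk = population_five_year_risk(50, white_rates)
        assert 0.0115 <= risk <= 0.0145
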