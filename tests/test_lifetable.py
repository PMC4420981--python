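"""Life-table engine: hazards, projections, closed forms, invariants."""

import numpy as np
import pytest

import dietshift as ds
from dietshift.lags import CARDIOMETABOLIC_LAG, INSTANT_LAG, default_lags
from dietshift.lifetable import (
    health_impact,
    life_expectancy,
    life_expectancy_change,
    modified_hazard,
    project_yll_single,
)
from tests.conftest import make_population


def _toy_pop(m=0.1, md=0.05, n_ages=1, n=1000.0, sex="male"):
    all_cause = np.full(n_ages, m)
    return make_population(all_cause, {"disease": np.full(n_ages, md)},
                           population=np.full(n_ages, n), sex=sex)


class TestModifiedHazard:
    def test_null_multipliers_exact_identity(self, inputs):
        pop = inputs.population
        lags = default_lags(list(pop.disease_names))
        mults = {d: 1.0 for d in pop.disease_names}
        for t in (0.0, 5.0, 30.0):
            got = modified_hazard(pop, "male", mults, lags, t)
            expected = pop.for_sex("male")["all_cause"].to_numpy()
            np.testing.assert_array_equal(got, expected)

    def test_zero_time_is_baseline(self, inputs):
        pop = inputs.population
        lags = default_lags(list(pop.disease_names))
        mults = {d: 0.5 for d in pop.disease_names}
        got = modified_hazard(pop, "female", mults, lags, 0.0)
        np.testing.assert_allclose(
            got, pop.for_sex("female")["all_cause"].to_numpy())

    def test_direct_substitution(self):
        # one disease at 40% of all-cause, full effect, multiplier 0.5
        pop = _toy_pop(m=0.1, md=0.04)
        got = modified_hazard(pop, "male", {"disease": 0.5},
                              {"disease": INSTANT_LAG}, t=1.0)
        assert got[0] == pytest.approx(0.1 + 0.04 * (0.5 - 1.0))
        assert got[0] == pytest.approx(0.8 * 0.1)

    def test_unknown_disease_rejected(self, inputs):
        lags = {"not_modelled": INSTANT_LAG}
        with pytest.raises(ValueError):
            modified_hazard(inputs.population, "male", {"not_modelled": 0.5},
                            lags, 0.0)

    def test_extreme_multiplier_clips_at_zero(self, caplog):
        pop = _toy_pop(m=0.01, md=0.01)
        with caplog.at_level("WARNING"):
            got = modified_hazard(pop, "male", {"disease": 1e-9},
                                  {"disease": INSTANT_LAG}, t=1.0)
        assert (got >= 0).all()


class TestLifeExpectancy:
    def test_constant_hazard_converges_to_inverse_rate(self):
        m = 0.2
        hazard = np.full(60, m)
        errors = []
        for dt in (1.0, 0.5, 0.25, 0.125):
            e = life_expectancy(hazard, dt=dt)
            errors.append(abs(e - 1.0 / m))
        # discretisation error at least halves when the step halves
        for coarse, fine in zip(errors, errors[1:]):
            assert fine <= 0.51 * coarse

    def test_open_interval_residual(self):
        # with the open interval the expectation is dt-accurate even when
        # survival past the last age is substantial
        m = 0.05
        e = life_expectancy(np.full(5, m), dt=0.01)
        assert e == pytest.approx(1.0 / m, rel=1e-3)

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            life_expectancy(np.array([0.1]), dt=0.3)


class TestProjectYll:
    def test_null_scenario_exact_zero(self, inputs):
        pop = inputs.population
        lags = default_lags(list(pop.disease_names))
        mults = {d: 1.0 for d in pop.disease_names}
        cum = project_yll_single(pop, "male", mults, lags, 30)
        assert (cum == 0.0).all()

    def test_two_year_hand_enumeration(self):
        # cohort of 1000 at one age, m = 0.1, disease at 0.05, multiplier
        # 0.5, no lag: person-years follow directly from exponential
        # survival and the half-year convention
        pop = _toy_pop(m=0.1, md=0.05, n=1000.0)
        cum = project_yll_single(pop, "male", {"disease": 0.5},
                                 {"disease": INSTANT_LAG}, horizon=2)
        sb = np.exp(-0.1)
        ss = np.exp(-0.075)
        py_b = 1000 * (1 + sb) / 2 + 1000 * sb * (1 + sb) / 2
        py_s = 1000 * (1 + ss) / 2 + 1000 * ss * (1 + ss) / 2
        assert cum[1] == pytest.approx(py_s - py_b, rel=1e-12)
        assert cum[0] == pytest.approx(1000 * (ss - sb) / 2, rel=1e-12)

    def test_linearity_in_population(self, inputs):
        pop = inputs.population
        lags = default_lags(list(pop.disease_names))
        mults = {d: 0.9 for d in pop.disease_names}
        cum1 = project_yll_single(pop, "female", mults, lags, 10)
        doubled = ds.PopulationTable(
            pop.data.assign(population=2 * pop.data["population"]),
            pop.disease_names)
        cum2 = project_yll_single(doubled, "female", mults, lags, 10)
        np.testing.assert_allclose(cum2, 2 * cum1, rtol=1e-12)

    def test_beneficial_scenario_monotone_in_horizon(self, inputs):
        pop = inputs.population
        lags = default_lags(list(pop.disease_names))
        mults = {d: 0.85 for d in pop.disease_names}
        cum = project_yll_single(pop, "male", mults, lags, 30)
        assert (cum >= 0).all()
        assert (np.diff(cum) >= 0).all()


class TestLifeExpectancyChange:
    def test_null_change_is_zero(self, inputs):
        pop = inputs.population
        lags = default_lags(list(pop.disease_names))
        mults = {d: 1.0 for d in pop.disease_names}
        assert life_expectancy_change(pop, "male", mults, lags) == 0.0

    def test_exponential_closed_form(self):
        # constant hazard m, permanent multiplier M on all of it: the gain
        # approaches 1/(mM) - 1/m in the exponential-survival limit
        m, M = 0.05, 0.8
        pop = _toy_pop(m=m, md=m, n_ages=200)
        got = life_expectancy_change(pop, "male", {"disease": M},
                                     {"disease": INSTANT_LAG})
        expected = 12.0 * (1.0 / (m * M) - 1.0 / m)
        assert got == pytest.approx(expected, rel=2e-3)

    def test_protective_multiplier_strictly_positive(self, inputs):
        pop = inputs.population
        lags = default_lags(list(pop.disease_names))
        mults = {d: 1.0 for d in pop.disease_names}
        mults["coronary_heart_disease"] = 0.9
        assert life_expectancy_change(pop, "female", mults, lags) > 0


class TestHealthImpact:
    def test_attributions_approximately_additive(self, inputs):
        pop = inputs.population
        lags = default_lags(list(pop.disease_names))
        mults = {s: {d: 0.9 for d in pop.disease_names} for s in pop.sexes}
        res = health_impact(pop, mults, lags)
        for h in res.horizons:
            parts = res.yll_by_disease[h].sum()
            total = res.yll_total[h]
            assert parts == pytest.approx(total, rel=0.05)

    def test_horizons_nested_for_beneficial_scenario(self, inputs):
        pop = inputs.population
        lags = default_lags(list(pop.disease_names))
        mults = {s: {d: 0.9 for d in pop.disease_names} for s in pop.sexes}
        res = health_impact(pop, mults, lags)
        assert 0 < res.yll_total[20] <= res.yll_total[30]
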