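"""Microsimulation engine: accounting, common random numbers, calibration."""

import numpy as np
import pandas as pd
import pytest

import ssbtax as st
from ssbtax.microsim import CHANNELS, _ChannelBank, calibrate_mortality
from ssbtax.policy import preset
from ssbtax.synthpop import AGE_MAX, AGE_MIN, EpidemiologyInputs

from conftest import make_history


def zero_epi():
    shape = (2, AGE_MAX - AGE_MIN + 1)
    z = np.zeros(shape)
    return EpidemiologyInputs(
        incidence={d: z.copy() for d in ("t2dm", "chd", "stroke")},
        prevalence={d: z.copy() for d in ("t2dm", "chd", "stroke")},
        case_fatality={d: z.copy() for d in ("t2dm", "chd", "stroke")},
        other_mortality=z.copy())


class TestRunArm:
    def test_no_events_population_changes_only_by_demography(self):
        pop = st.generate_population(st.PopulationConfig(n_individuals=500), seed=1)
        for d in ("t2dm", "chd", "stroke"):
            pop[d] = False
        pop["entry_year"] = 2023
        sim = st.Microsimulation(pop, zero_epi(), horizon=10)
        hist = sim.run_arm("baseline", seed=2)
        assert (hist.death_year == -1).all()
        for d in ("t2dm", "chd", "stroke"):
            assert (hist.onset_year[d] == -1).all()
        # everyone under 81 at entry survives all 10 person-years
        always_in = pop["age"] <= 80
        for t in range(10):
            assert hist.person_year_mask(2023 + t)[always_in.to_numpy()].all()

    def test_certain_incidence_from_year_one(self):
        epi = zero_epi()
        epi.incidence["t2dm"][:, :] = 50.0  # p = 1 - exp(-50) ~ 1
        pop = pd.DataFrame({
            "sex": ["male"], "age": [40], "birth_year": [1983], "bmi": [25.0],
            "ssb_ml": [0.0], "juice_ml": [0.0], "sugar_density_ssb": [0.09],
            "sugar_density_juice": [0.10], "entry_year": [2023]})
        sim = st.Microsimulation(pop, epi, horizon=5)
        hist = sim.run_arm("baseline", seed=3)
        assert hist.onset_year["t2dm"][0] == 2023
        assert all(hist.prevalent_mask("t2dm", 2023 + t)[0] for t in range(5))

    def test_demographic_accounting_each_year(self, small_sim):
        hist = small_sim.run_arm("baseline", seed=4)
        for t in range(small_sim.horizon):
            year = hist.start_year + t
            entered = int((hist.entry_year <= year).sum())
            alive = int(hist.person_year_mask(year).sum())
            dead = int(((hist.death_year != -1) & (hist.death_year <= year)).sum())
            out = int(((hist.aged_out_year != -1) & (hist.aged_out_year < year)).sum())
            assert alive + dead + out == entered

    def test_open_cohort_admits_entrants(self, small_sim):
        hist = small_sim.run_arm("baseline", seed=4)
        assert (hist.entry_year > hist.start_year).any()
        entrants = hist.entry_year == hist.start_year + 3
        assert (hist.age_entry[entrants] == AGE_MIN).all()

    def test_nobody_exceeds_age_90_in_person_years(self, small_sim):
        hist = small_sim.run_arm("baseline", seed=4)
        for t in range(small_sim.horizon):
            year = hist.start_year + t
            assert hist.age_at(year)[hist.person_year_mask(year)].max() <= AGE_MAX

    def test_event_history_frame_layout(self, small_sim):
        df = small_sim.run_arm("baseline", seed=4).to_frame()
        assert {"id", "year", "age", "sex", "bmi", "t2dm", "alive"} <= set(df.columns)
        assert df["alive"].all()


class TestCommonRandomNumbers:
    def test_null_invariance_is_exact(self, small_sim):
        a = small_sim.run_arm("baseline", seed=7)
        b = small_sim.run_arm("baseline", seed=7)
        cmp = st.compare_arms(a, b)
        assert all(v == 0 for v in cmp.outcome_vector().values())
        assert (cmp.yearly.drop(columns=["year", "sex"]) == 0).all().all()

    def test_channel_double_draw_raises(self):
        bank = _ChannelBank(0, len(CHANNELS), 3, 10)
        bank.draw(0, 1)
        with pytest.raises(RuntimeError, match="double draw"):
            bank.draw(0, 1)

    def test_mismatched_populations_rejected(self, small_sim):
        a = small_sim.run_arm("baseline", seed=7)
        other = st.Microsimulation.from_configs(
            st.PopulationConfig(n_individuals=4000), seed=12)
        b = other.run_arm("baseline", seed=7)
        with pytest.raises(ValueError):
            st.compare_arms(a, b)


class TestCompareArms:
    def test_delayed_onset_counts_case_years_not_cases(self):
        # scenario delays one T2DM onset by 2 years within the horizon:
        # lifetime cases equal, case-years differ by 2
        onset_base = {"t2dm": np.array([2025, -1, -1]), "chd": np.full(3, -1),
                      "stroke": np.full(3, -1)}
        onset_cf = {"t2dm": np.array([2027, -1, -1]), "chd": np.full(3, -1),
                    "stroke": np.full(3, -1)}
        base = make_history(n=3, onset_year=onset_base, horizon=10)
        cf = make_history(n=3, onset_year=onset_cf, horizon=10)
        cmp = st.compare_arms(base, cf)
        assert cmp.cases_prevented["t2dm"] == 0
        assert cmp.case_years_prevented["t2dm"] == 2

    def test_onset_delayed_past_horizon_counts_as_prevented(self):
        onset_base = {"t2dm": np.array([2030]), "chd": np.array([-1]),
                      "stroke": np.array([-1])}
        onset_cf = {"t2dm": np.array([-1]), "chd": np.array([-1]),
                    "stroke": np.array([-1])}
        base = make_history(onset_year=onset_base, horizon=10)
        cf = make_history(onset_year=onset_cf, horizon=10)
        cmp = st.compare_arms(base, cf)
        assert cmp.cases_prevented["t2dm"] == 1

    def test_beneficial_scenario_gains_qalys_in_expectation(self, small_sim):
        sc = preset("max_impact")
        gains = []
        for s in range(8):
            b = small_sim.run_arm("baseline", seed=200 + s)
            c = small_sim.run_arm(sc, seed=200 + s)
            gains.append(st.compare_arms(b, c).qalys_gained)
        assert np.mean(gains) > 0


class TestCalibrateMortality:
    def test_identity_when_rates_match(self):
        rates = np.full((2, 5), 0.01)
        np.testing.assert_allclose(calibrate_mortality(rates, rates), 1.0)

    def test_ratio_oracle(self):
        raw = np.full((2, 5), 0.005)
        target = np.full((2, 5), 0.010)
        np.testing.assert_allclose(calibrate_mortality(raw, target), 2.0)

    def test_bounds_applied_with_warning(self):
        raw = np.array([[1e-6]])
        target = np.array([[1.0]])
        with pytest.warns(UserWarning, match="clipped"):
            f = calibrate_mortality(raw, target)
        assert f[0, 0] == 10.0

    def test_calibrated_rates_reproduce_target_mortality(self):
        """Verification run: with factors mapping raw onto doubled target
        rates, one-year simulated deaths match the target expectation
        within 3 binomial SE."""
        cfg = st.PopulationConfig(n_individuals=20_000)
        epi = st.generate_epidemiology()
        pop = st.generate_population(cfg, seed=3)
        for d in ("t2dm", "chd", "stroke"):
            pop[d] = False
        pop["entry_year"] = 2023
        epi2 = EpidemiologyInputs(
            {d: np.zeros_like(v) for d, v in epi.incidence.items()},
            {d: np.zeros_like(v) for d, v in epi.prevalence.items()},
            {d: np.zeros_like(v) for d, v in epi.case_fatality.items()},
            epi.other_mortality, mort_trend=0.0)
        target = 2 * epi.other_mortality
        factors = calibrate_mortality(epi.other_mortality, target)
        sim = st.Microsimulation(pop, epi2, horizon=1, mortality_factors=factors)
        deaths = (sim.run_arm("baseline", seed=5).death_year != -1).sum()
        sex = (pop["sex"] == "female").to_numpy().astype(int)
        p = 1 - np.exp(-target[sex, pop["age"].to_numpy() - AGE_MIN])
        expected, sd = p.sum(), np.sqrt((p * (1 - p)).sum())
        assert abs(deaths - expected) < 3 * sd
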