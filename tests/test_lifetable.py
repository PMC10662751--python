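"""Multistate life-table model: recursions, conservation, cross-validation."""

import numpy as np
import pytest

import ssbtax as st
from ssbtax.lifetable import (LifetableInputs, build_lifetable_inputs,
                              cross_validate, lifetable_compare, run_lifetable)
from ssbtax.policy import preset
from ssbtax.synthpop import AGE_MAX, AGE_MIN, EpidemiologyInputs

N_AGES = AGE_MAX - AGE_MIN + 1


def simple_inputs(horizon=10, pifs=None, counts=None):
    z = np.zeros((2, N_AGES, horizon))
    pifs = pifs or {}
    counts_arr = np.zeros((2, N_AGES))
    if counts is None:
        counts_arr[0, 10] = 100.0  # 100 men aged 40
    else:
        counts_arr = counts
    return LifetableInputs(
        pifs={d: pifs.get(d, z.copy()) for d in ("t2dm", "chd", "stroke")},
        excess_bmi={"baseline": z.copy(), "scenario": z.copy()},
        initial_counts=counts_arr, entrant_counts=np.zeros((2, horizon)),
        start_year=2023, horizon=horizon, scenario_name="test")


def flat_epi(mortality=0.0, t2dm_inc=0.0):
    shape = (2, N_AGES)
    z = np.zeros(shape)
    inc = {d: z.copy() for d in ("t2dm", "chd", "stroke")}
    inc["t2dm"] = np.full(shape, t2dm_inc)
    return EpidemiologyInputs(
        incidence=inc, prevalence={d: z.copy() for d in ("t2dm", "chd", "stroke")},
        case_fatality={d: z.copy() for d in ("t2dm", "chd", "stroke")},
        other_mortality=np.full(shape, mortality))


class TestRunLifetable:
    def test_zero_pifs_equal_baseline_exactly(self, epi):
        inputs = simple_inputs()
        base = run_lifetable(epi, inputs, "baseline")
        scen = run_lifetable(epi, inputs, "scenario")
        assert base.totals == scen.totals

    def test_full_pif_removes_t2dm_incidence(self):
        horizon = 15
        pif_one = {"t2dm": np.ones((2, N_AGES, horizon))}
        inputs = simple_inputs(horizon, pifs=pif_one)
        epi = flat_epi(t2dm_inc=0.05)
        scen = run_lifetable(epi, inputs, "scenario")
        assert scen.totals["incident_t2dm"] == 0.0
        assert scen.totals["case_years_t2dm"] == 0.0
        base = run_lifetable(epi, inputs, "baseline")
        assert base.totals["incident_t2dm"] > 0

    def test_constant_mortality_life_expectancy_closed_form(self):
        m, horizon = 0.02, 20
        inputs = simple_inputs(horizon)
        table = run_lifetable(flat_epi(mortality=m), inputs, "baseline")
        ly = table.totals["person_years"] / 100.0
        exact = (1 - np.exp(-m * horizon)) / m
        assert ly == pytest.approx(exact, abs=0.5 * (1 - np.exp(-m * horizon)) + 1e-9)

    def test_survivorship_non_increasing_and_conserved(self, epi):
        inputs = simple_inputs()
        table = run_lifetable(epi, inputs, "baseline").table
        surv = table["survivorship"].to_numpy()
        assert np.all(np.diff(surv) <= 1e-12)
        assert np.all((surv >= 0) & (surv <= 1.0 + 1e-12))
        for col in ("prev_t2dm", "prev_chd", "prev_stroke"):
            assert table[col].between(0, 1).all()

    def test_deterministic(self, epi):
        inputs = simple_inputs()
        a = run_lifetable(epi, inputs, "scenario")
        b = run_lifetable(epi, inputs, "scenario")
        assert a.totals == b.totals

    def test_pif_above_one_rejected(self, epi):
        horizon = 5
        bad = {"t2dm": np.full((2, N_AGES, horizon), 1.5)}
        with pytest.raises(ValueError, match="PIF"):
            run_lifetable(epi, simple_inputs(horizon, pifs=bad), "scenario")


class TestBuildInputs:
    def test_direct_effects_rejected(self, small_sim):
        with pytest.raises(ValueError, match="BMI-mediated"):
            build_lifetable_inputs(small_sim, preset("tiered"))

    def test_baseline_scenario_pifs_are_zero(self, small_sim):
        sc = preset("baseline").with_overrides(direct_effects_enabled=False)
        inputs = build_lifetable_inputs(small_sim, sc)
        for d in ("t2dm", "chd", "stroke"):
            np.testing.assert_allclose(inputs.pifs[d], 0.0, atol=1e-12)

    def test_tiered_pifs_positive_after_phase_in(self, small_sim):
        sc = preset("tiered").with_overrides(direct_effects_enabled=False)
        inputs = build_lifetable_inputs(small_sim, sc)
        late = inputs.pifs["t2dm"][:, :30, -1]  # ages with members, final year
        assert (late > 0).mean() > 0.9

    def test_cohort_weights_match_population(self, small_sim):
        sc = preset("baseline").with_overrides(direct_effects_enabled=False)
        inputs = build_lifetable_inputs(small_sim, sc)
        init = (small_sim.entry_year == small_sim.start_year).sum()
        assert inputs.initial_counts.sum() == init
        assert inputs.entrant_counts.sum() == small_sim.n - init


class TestCrossValidation:
    def test_identical_outputs_zero_relative_difference(self):
        from ssbtax.microsim import ArmComparison
        import pandas as pd
        vals = {"cases_prevented_t2dm": 10.0, "cases_prevented_chd": 5.0,
                "cases_prevented_stroke": 2.0, "qalys_gained": 100.0}
        cmp = ArmComparison(
            cases_prevented={"t2dm": 10.0, "chd": 5.0, "stroke": 2.0, "obesity": 0.0},
            case_years_prevented={"t2dm": 0, "chd": 0, "stroke": 0, "obesity": 0},
            deaths_prevented=0.0, life_years_gained=0.0, qalys_gained=100.0,
            cost_savings={"healthcare": 0.0, "societal": 0.0},
            delta_cost={"healthcare": 0.0, "societal": 0.0}, delta_qalys=100.0,
            icer={}, yearly=pd.DataFrame(), scenario_name="x", direct_effects=False)
        rep = cross_validate([cmp, cmp], {**vals, "scenario": "x"})
        assert (rep["relative_difference"] == 0).all()
        assert rep["overlap"].all()

    def test_null_scenario_both_models_zero(self, small_sim):
        sc = preset("baseline").with_overrides(direct_effects_enabled=False)
        inputs = build_lifetable_inputs(small_sim, sc)
        lt = lifetable_compare(small_sim.epi, inputs)
        assert all(abs(v) < 1e-9 for k, v in lt.items() if k != "scenario")
        b = small_sim.run_arm("baseline", seed=3, direct_effects=False)
        c = small_sim.run_arm(sc, seed=3)
        rep = cross_validate([st.compare_arms(b, c)] * 2, lt)
        assert rep["overlap"].all()

    def test_mixed_scenarios_rejected(self, small_sim):
        sc = preset("tiered").with_overrides(direct_effects_enabled=False)
        b = small_sim.run_arm("baseline", seed=3)
        c = small_sim.run_arm(sc, seed=3)
        cmp = st.compare_arms(b, c)
        with pytest.raises(ValueError, match="scenario"):
            cross_validate([cmp, cmp], {"scenario": "other", "qalys_gained": 0.0,
                                        "cases_prevented_t2dm": 0.0,
                                        "cases_prevented_chd": 0.0,
                                        "cases_prevented_stroke": 0.0})
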