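"""Proportional multistate life-table cohort model for cross-validation.

A deterministic cohort counterpart of the microsimulation: closed 1-year
birth cohorts (everyone alive at the simulation start, plus the
30-year-old entrant cohorts admitted in later years) are advanced through
annual recursions of survivorship and disease-state occupancy with
remission fixed at zero.  Policy effects enter as potential impact
fractions (scenario incidence = baseline incidence x (1 - PIF)) and as
stratum-mean excess-BMI series for the utility weights, both computed from
the *same* synthetic population the microsimulation runs on.

To aggregate the microsimulation's event model exactly, each cohort
carries the joint distribution over the eight (T2DM x CHD x stroke) state
combinations rather than three independent disease tables: within a year,
T2DM incidence runs first (so incident diabetes raises same-year CHD and
stroke risk through the prevalent-T2DM multiplier, normalised by the
expected baseline prevalence), then CHD and stroke incidence, then
mortality composed of CHD/stroke case fatality and the T2DM-adjusted
other-cause rate.  Person-years count survivors of each year.

The life-table arm equals the microsimulation's expectation up to
second-order selection terms, which is the basis of the cross-model
agreement check: microsimulation means over replicate seeds should fall
within Monte-Carlo error of the life-table values.  Only BMI-mediated
pathways are supported here; scenarios with direct SSB effects enabled
are rejected, matching the condition under which the two models are
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .econ import EconParameters, UtilityParameters, discount_weight, _premature_death_cost
from .policy import PolicyScenario
from .risk import RiskParameters, exposure_rr, pif as _pif
from .synthpop import AGE_MAX, AGE_MIN, DISEASES, EpidemiologyInputs

N_AGES = AGE_MAX - AGE_MIN + 1


@dataclass
class LifetableInputs:
    """Aggregate inputs distilled from a synthetic population + scenario.

    pifs[d] and the excess-BMI tables have shape (sex, age, year-index);
    ``initial_counts`` is the (sex, age) head count at the start year and
    ``entrant_counts`` the (sex, year-index) counts of 30-year-old
    entrants (zero in year 0).
    """

    pifs: dict
    excess_bmi: dict              # arm -> (2, N_AGES, T) mean max(0, bmi - ref)
    initial_counts: np.ndarray
    entrant_counts: np.ndarray
    start_year: int
    horizon: int
    scenario_name: str


def build_lifetable_inputs(sim, scenario: PolicyScenario,
                           utility_params: UtilityParameters | None = None) -> LifetableInputs:
    """Compute PIFs and utility inputs from a microsimulation's population.

    ``sim`` is a :class:`~ssbtax.microsim.Microsimulation`; its full
    population (initial members and entrant cohorts, without mortality
    selection) supplies the per-stratum relative-risk distributions.
    """
    if scenario.direct_effects_enabled and (scenario.has_price_mechanism
                                            or scenario.has_reformulation):
        raise ValueError("the life-table model covers only BMI-mediated pathways; "
                         "disable direct effects on the scenario")
    up = utility_params or UtilityParameters()
    rp: RiskParameters = sim.rp
    T = sim.horizon
    pifs = {d: np.zeros((2, N_AGES, T)) for d in DISEASES}
    exbmi = {arm: np.zeros((2, N_AGES, T)) for arm in ("baseline", "scenario")}

    from .microsim import _lag_ramp
    from .policy import scenario_volumes  # deferred to keep import order simple

    n_strata = 2 * N_AGES
    sugar0 = sim.ssb0 * sim.dens_ssb + sim.juice0 * sim.dens_juice
    for t in range(T):
        year = sim.start_year + t
        age = sim.age_entry + (year - sim.entry_year)
        present = (sim.entry_year <= year) & (age <= AGE_MAX)
        strat = ((np.where(present, age, AGE_MIN) - AGE_MIN) * 2 + sim.sex_code)[present]
        counts = np.maximum(np.bincount(strat, minlength=n_strata), 1)

        def smean(values):
            return (np.bincount(strat, weights=values[present], minlength=n_strata)
                    / counts).reshape(N_AGES, 2).T  # -> (sex, age)

        ssb_v, juice_v = scenario_volumes(sim.ssb0, sim.juice0, scenario, sim.E, year)
        rho = scenario.reformulation_factor(year)
        sugar_cf = ssb_v * sim.dens_ssb * (1.0 - rho) + juice_v * sim.dens_juice

        bmi_util = sim.bmi0 + rp.beta_sugar * (sugar_cf - sugar0) * _lag_ramp(t, rp.bmi_lag_years)
        exbmi["baseline"][:, :, t] = smean(np.maximum(sim.bmi0 - up.bmi_reference, 0.0))
        exbmi["scenario"][:, :, t] = smean(np.maximum(bmi_util - up.bmi_reference, 0.0))

        for d in DISEASES:
            ramp = _lag_ramp(t, rp.lag_years[d])
            bmi_eff = sim.bmi0 + rp.beta_sugar * (sugar_cf - sugar0) * ramp
            mean_base = smean(exposure_rr(sim.bmi0, sim.ssb0, d, rp, False))
            mean_cf = smean(exposure_rr(bmi_eff, sim.ssb0, d, rp, False))
            with np.errstate(invalid="ignore", divide="ignore"):
                pifs[d][:, :, t] = np.where(mean_base > 0, 1.0 - mean_cf / mean_base, 0.0)

    counts = np.zeros((2, N_AGES))
    init = sim.entry_year == sim.start_year
    np.add.at(counts, (sim.sex_code[init], sim.age_entry[init] - AGE_MIN), 1.0)
    entrants = np.zeros((2, T))
    late = ~init
    np.add.at(entrants, (sim.sex_code[late], sim.entry_year[late] - sim.start_year), 1.0)
    return LifetableInputs(pifs, exbmi, counts, entrants, sim.start_year, T,
                           scenario.name)


@dataclass
class CohortTable:
    """Per-cohort life-table columns and horizon totals for one arm."""

    table: pd.DataFrame
    totals: dict
    arm: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_lifetable(epi: EpidemiologyInputs, inputs: LifetableInputs, arm: str = "scenario",
                  econ_params: EconParameters | None = None,
                  utility_params: UtilityParameters | None = None,
                  risk_params: RiskParameters | None = None,
                  discount_rate: float | None = None) -> CohortTable:
    """Advance every cohort through the multistate recursion for one arm.

    ``arm`` is "baseline" (all PIFs zero, baseline BMI) or "scenario".
    Returns per-cohort columns (survivorship, disease prevalence,
    person-years, discounted QALYs/costs) and horizon totals.
    """
    if arm not in ("baseline", "scenario"):
        raise ValueError("arm must be 'baseline' or 'scenario'")
    econ = econ_params or EconParameters()
    up = utility_params or UtilityParameters()
    rp = risk_params or RiskParameters()
    r = econ.discount_rate if discount_rate is None else discount_rate
    T = inputs.horizon
    for d in DISEASES:
        if np.any(inputs.pifs[d] > 1.0):
            raise ValueError("PIF above 1 is not a valid incidence reduction")

    rr_m = rp.rr_t2dm["non_cvd_mortality"].value
    rr_t2 = {d: rp.rr_t2dm[d].value for d in ("chd", "stroke")}

    totals = {
        **{f"incident_{d}": 0.0 for d in DISEASES},
        **{f"case_years_{d}": 0.0 for d in DISEASES},
        "deaths": 0.0, "person_years": 0.0, "qalys": 0.0,
        "cost_healthcare": 0.0, "cost_societal": 0.0,
    }
    rows = []

    cohorts = []
    for s in range(2):
        for a0 in range(AGE_MIN, AGE_MAX + 1):
            w = inputs.initial_counts[s, a0 - AGE_MIN]
            if w > 0:
                cohorts.append((s, a0, 0, w))
        for t0 in range(1, T):
            w = inputs.entrant_counts[s, t0]
            if w > 0:
                cohorts.append((s, AGE_MIN, t0, w))

    idx = np.arange(2)
    for s, a0, t0, w in cohorts:
        cells = np.zeros((2, 2, 2))
        prev0 = {d: float(epi.prevalence[d][s, a0 - AGE_MIN]) if t0 == 0 else 0.0
                 for d in DISEASES}
        for i in range(2):
            for j in range(2):
                for k3 in range(2):
                    cells[i, j, k3] = (
                        (prev0["t2dm"] if i else 1 - prev0["t2dm"])
                        * (prev0["chd"] if j else 1 - prev0["chd"])
                        * (prev0["stroke"] if k3 else 1 - prev0["stroke"]))

        for t in range(t0, T):
            a = a0 + (t - t0)
            if a > AGE_MAX:
                break
            k = a - AGE_MIN
            wdisc = discount_weight(t, r)
            pif_of = (lambda d: inputs.pifs[d][s, k, t]) if arm == "scenario" else (lambda d: 0.0)
            exb = inputs.excess_bmi[arm if arm == "scenario" else "baseline"][s, k, t]

            # T2DM incidence
            q = np.clip((1 - np.exp(-epi.incidence["t2dm"][s, k])) * (1 - pif_of("t2dm")), 0, 1)
            flux_t2 = cells[0] * q
            cells[0] -= flux_t2
            cells[1] += flux_t2
            inc = {"t2dm": flux_t2.sum()}

            # CHD / stroke incidence, T2DM-dependent
            denom_prev = epi.prevalence["t2dm"][s, k]
            for d, axis in (("chd", 1), ("stroke", 2)):
                p0 = 1 - np.exp(-epi.incidence[d][s, k])
                qd = np.clip(p0 * (1 - pif_of(d))
                             * np.where(idx == 1, rr_t2[d], 1.0)
                             / (1.0 + (rr_t2[d] - 1.0) * denom_prev), 0, 1)
                if d == "chd":
                    flux = cells[:, 0, :] * qd[:, None]
                    cells[:, 0, :] -= flux
                    cells[:, 1, :] += flux
                else:
                    flux = cells[:, :, 0] * qd[:, None]
                    cells[:, :, 0] -= flux
                    cells[:, :, 1] += flux
                inc[d] = flux.sum()

            # mortality: case fatality then T2DM-adjusted other-cause
            p_cfc = 1 - np.exp(-epi.case_fatality["chd"][s, k])
            p_cfs = 1 - np.exp(-epi.case_fatality["stroke"][s, k])
            m0 = epi.other_mortality_rate(s, a, t)
            p_oth = 1 - np.exp(-m0 * np.where(idx == 1, rr_m, 1.0)
                               / (1.0 + (rr_m - 1.0) * denom_prev))
            surv = ((1 - p_cfc * idx)[None, :, None]
                    * (1 - p_cfs * idx)[None, None, :]
                    * (1 - p_oth)[:, None, None])
            deaths = float((cells * (1 - surv)).sum())
            cells *= surv
            alive = float(cells.sum())

            prev = {"t2dm": float(cells[1].sum()), "chd": float(cells[:, 1, :].sum()),
                    "stroke": float(cells[:, :, 1].sum())}

            # utility per joint state, with the stratum-mean excess-BMI term
            util = np.zeros((2, 2, 2))
            base = float(up.baseline(s, a))
            for i in range(2):
                for j in range(2):
                    for k3 in range(2):
                        u = (base - up.bmi_decrement * exb
                             - up.disease_decrement["t2dm"] * i
                             - up.disease_decrement["chd"] * j
                             - up.disease_decrement["stroke"] * k3)
                        util[i, j, k3] = min(max(u, 0.0), 1.0)
            q_year = float((cells * util).sum())

            # costs (same category model as the microsimulation economics)
            ch = 0.0
            for d in DISEASES:
                ch += prev[d] * econ.prevalent_cost[d] + inc[d] * econ.incident_surcharge[d]
            ch += alive * econ.background_cost
            soc = ch
            soc += prev["t2dm"] * (econ.t2dm_self_management_cost
                                   + econ.t2dm_health_service_time_cost)
            soc += alive * econ.other_time_cost
            if a < econ.retirement_age:
                soc += (prev["t2dm"] * econ.sick_leave_cost["t2dm"]
                        + prev["stroke"] * econ.sick_leave_cost["stroke"])
                soc += (inc["t2dm"] * econ.early_retirement_cost["t2dm"]
                        + inc["stroke"] * econ.early_retirement_cost["stroke"])
            # premature-death cost is already a discounted sum over wage years
            pdc = deaths * _premature_death_cost(a, t, econ, r) if a < econ.retirement_age else 0.0

            totals["person_years"] += w * alive
            totals["deaths"] += w * deaths
            totals["qalys"] += w * wdisc * q_year
            for d in DISEASES:
                totals[f"incident_{d}"] += w * inc[d]
                totals[f"case_years_{d}"] += w * prev[d]
            totals["cost_healthcare"] += w * wdisc * ch
            totals["cost_societal"] += w * wdisc * soc + w * pdc

            rows.append({
                "sex": ("male", "female")[s], "cohort_entry_age": a0,
                "cohort_entry_year": inputs.start_year + t0, "age": a,
                "year": inputs.start_year + t, "survivorship": alive,
                "prev_t2dm": prev["t2dm"] / alive if alive > 0 else 0.0,
                "prev_chd": prev["chd"] / alive if alive > 0 else 0.0,
                "prev_stroke": prev["stroke"] / alive if alive > 0 else 0.0,
                "person_years": w * alive, "qalys": w * wdisc * q_year,
            })

    table = pd.DataFrame(rows)
    if len(table) and (table.groupby(["sex", "cohort_entry_age", "cohort_entry_year"])
                       ["survivorship"].first() > 1 + 1e-9).any():
        raise AssertionError("survivorship exceeded cohort size")
    return CohortTable(table, totals, arm)


def lifetable_compare(epi: EpidemiologyInputs, inputs: LifetableInputs,
                      econ_params: EconParameters | None = None,
                      utility_params: UtilityParameters | None = None,
                      risk_params: RiskParameters | None = None,
                      discount_rate: float | None = None) -> dict:
    """Baseline-vs-scenario outcome differences from the life-table model,
    in the same sign conventions as the microsimulation ArmComparison."""
    base = run_lifetable(epi, inputs, "baseline", econ_params, utility_params,
                         risk_params, discount_rate)
    scen = run_lifetable(epi, inputs, "scenario", econ_params, utility_params,
                         risk_params, discount_rate)
    out = {}
    for d in DISEASES:
        out[f"cases_prevented_{d}"] = base.totals[f"incident_{d}"] - scen.totals[f"incident_{d}"]
        out[f"case_years_prevented_{d}"] = (base.totals[f"case_years_{d}"]
                                            - scen.totals[f"case_years_{d}"])
    out["deaths_prevented"] = base.totals["deaths"] - scen.totals["deaths"]
    out["life_years_gained"] = scen.totals["person_years"] - base.totals["person_years"]
    out["qalys_gained"] = scen.totals["qalys"] - base.totals["qalys"]
    out["cost_savings_healthcare"] = base.totals["cost_healthcare"] - scen.totals["cost_healthcare"]
    out["cost_savings_societal"] = base.totals["cost_societal"] - scen.totals["cost_societal"]
    out["scenario"] = inputs.scenario_name
    return out


def cross_validate(microsim_comparisons, lifetable_outcomes: dict,
                   outcomes: tuple = ("cases_prevented_t2dm", "cases_prevented_chd",
                                      "cases_prevented_stroke", "qalys_gained")) -> pd.DataFrame:
    """Compare replicate microsimulation outcomes with the life-table values.

    ``microsim_comparisons`` is a sequence of ArmComparison objects from
    replicate seeds (identical inputs, BMI-mediated effects only).  The
    report lists, per outcome, the microsimulation mean and Monte-Carlo
    standard error, the life-table value, their relative difference and
    whether the life-table value lies within mean +/- 3 SE.
    """
    if getattr(microsim_comparisons[0], "scenario_name", None) is not None:
        name = microsim_comparisons[0].scenario_name
        if any(c.scenario_name != name for c in microsim_comparisons):
            raise ValueError("mixed scenarios in microsimulation replicates")
        if lifetable_outcomes.get("scenario", name) != name:
            raise ValueError("life-table output is for a different scenario")
    rows = []
    k = len(microsim_comparisons)
    for oc in outcomes:
        vals = np.array([c.outcome_vector()[oc] for c in microsim_comparisons], float)
        mean = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(k) if k > 1 else 0.0
        lt = float(lifetable_outcomes[oc])
        denom = lt if lt != 0 else (mean if mean != 0 else 1.0)
        tol = 3.0 * se + 1e-8 * (1.0 + abs(lt))  # numerical guard for exact nulls
        rows.append({
            "outcome": oc, "microsim_mean": mean, "microsim_se": se,
            "lifetable": lt, "relative_difference": (mean - lt) / denom,
            "overlap": bool(abs(mean - lt) <= tol),
        })
    return pd.DataFrame(rows)
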