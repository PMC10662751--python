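"""Discounted QALYs and costs from healthcare and societal perspectives.

Quality-adjusted life years weight each completed person-year by a health
utility in [0, 1]: a baseline utility by age and sex minus additive
decrements for excess BMI, T2DM, CHD and stroke, clamped to [0, 1].

Costs follow the category structure of a health-economic evaluation with a
human-capital approach:

* healthcare perspective: disease-specific medical costs (an annual cost
  per prevalent case-year plus a surcharge in the incident year) and a
  background other-care cost per person-year alive;
* societal perspective adds patient time costs (T2DM self-management and
  health-service use, plus other health-service time for every person-year),
  productivity costs (sick leave per prevalent T2DM/stroke year and a lump
  sum per early-retirement-inducing incident case, both only below the
  retirement age of 65) and premature-death costs valuing every wage year
  lost between death and age 65 at the average annual gross wage including
  fringe benefits.

Everything is discounted at 3% per year (year-of-event convention; the
first simulated year is undiscounted).  Cost and utility magnitudes are
plausible placeholder configuration values, not national estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DISEASES = ("t2dm", "chd", "stroke")

HEALTHCARE_CATEGORIES = ("medical_t2dm", "medical_chd", "medical_stroke", "medical_other")
TIME_CATEGORIES = ("time_t2dm_self_management", "time_t2dm_health_service", "time_other")
PRODUCTIVITY_CATEGORIES = ("sick_leave_t2dm", "sick_leave_stroke",
                           "early_retirement_t2dm", "early_retirement_stroke",
                           "premature_death")
SOCIETAL_CATEGORIES = HEALTHCARE_CATEGORIES + TIME_CATEGORIES + PRODUCTIVITY_CATEGORIES


@dataclass
class EconParameters:
    """Cost parameters (EUR, per year unless stated) and the discount rate."""

    discount_rate: float = 0.03
    retirement_age: int = 65
    prevalent_cost: dict = field(default_factory=lambda: {
        "t2dm": 3000.0, "chd": 2500.0, "stroke": 5000.0})
    incident_surcharge: dict = field(default_factory=lambda: {
        "t2dm": 1000.0, "chd": 8000.0, "stroke": 15000.0})
    background_cost: float = 2000.0          # other care, per person-year alive
    t2dm_self_management_cost: float = 600.0
    t2dm_health_service_time_cost: float = 750.0
    other_time_cost: float = 200.0           # per person-year alive
    sick_leave_cost: dict = field(default_factory=lambda: {"t2dm": 900.0, "stroke": 300.0})
    early_retirement_cost: dict = field(default_factory=lambda: {
        "t2dm": 20000.0, "stroke": 25000.0})
    annual_gross_wage: float = 45000.0       # incl. fringe benefits

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        costs = ([self.background_cost, self.t2dm_self_management_cost,
                  self.t2dm_health_service_time_cost, self.other_time_cost,
                  self.annual_gross_wage]
                 + list(self.prevalent_cost.values())
                 + list(self.incident_surcharge.values())
                 + list(self.sick_leave_cost.values())
                 + list(self.early_retirement_cost.values()))
        if any(c < 0 for c in costs):
            raise ValueError("costs must be >= 0")


@dataclass
class UtilityParameters:
    """Health utility: baseline by age/sex with additive decrements."""

    base_at30: dict = field(default_factory=lambda: {"male": 0.95, "female": 0.94})
    age_slope: float = 0.0018                # utility loss per year of age
    bmi_decrement: float = 0.006             # per kg/m^2 above the reference
    bmi_reference: float = 25.0
    disease_decrement: dict = field(default_factory=lambda: {
        "t2dm": 0.05, "chd": 0.06, "stroke": 0.12})

    def baseline(self, sex_code, age):
        base = np.where(np.asarray(sex_code) == 0,
                        self.base_at30["male"], self.base_at30["female"])
        return np.clip(base - self.age_slope * (np.asarray(age) - 30), 0.0, 1.0)

    def utility(self, sex_code, age, bmi, t2dm, chd, stroke):
        u = self.baseline(sex_code, age)
        u = u - self.bmi_decrement * np.maximum(np.asarray(bmi) - self.bmi_reference, 0.0)
        u = (u - self.disease_decrement["t2dm"] * np.asarray(t2dm)
             - self.disease_decrement["chd"] * np.asarray(chd)
             - self.disease_decrement["stroke"] * np.asarray(stroke))
        return np.clip(u, 0.0, 1.0)


def discount_weight(t, r: float):
    """Discount weight 1/(1+r)^t; t = 0 (the first year) is undiscounted."""
    if r < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    w = (1.0 + r) ** -t
    return float(w) if w.ndim == 0 else w


def _premature_death_cost(age_at_death: int, t: int, params: EconParameters, r: float) -> float:
    """Human-capital value of wage-years lost from death until retirement."""
    lost = params.retirement_age - age_at_death
    if lost <= 0:
        return 0.0
    ts = t + np.arange(lost)
    return float(np.sum(params.annual_gross_wage * discount_weight(ts, r)))


def yearly_qalys_costs(history, utility_params: UtilityParameters,
                       econ_params: EconParameters, r: float | None = None):
    """Discounted QALYs and costs per (year, sex) for one simulation arm.

    Returns two DataFrames keyed by (year, sex): one with a ``qalys``
    column, one with per-category discounted costs plus ``cost_healthcare``
    and ``cost_societal`` totals.
    """
    r = econ_params.discount_rate if r is None else r
    q_rows, c_rows = [], []
    for t in range(history.horizon):
        year = history.start_year + t
        w = discount_weight(t, r)
        py = history.person_year_mask(year)
        age = history.age_at(year)
        _, _, _, bmi = history.scenario_exposures(year)
        prev = {d: history.prevalent_mask(d, year) for d in DISEASES}
        util = utility_params.utility(history.sex_code, age, bmi,
                                      prev["t2dm"], prev["chd"], prev["stroke"])
        for s, sex in enumerate(("male", "female")):
            m = py & (history.sex_code == s)
            q_rows.append({"year": year, "sex": sex,
                           "qalys": float(np.sum(util[m]) * w)})

            c = {k: 0.0 for k in SOCIETAL_CATEGORIES}
            for d in DISEASES:
                n_prev = int(np.sum(prev[d] & m))
                incident = (history.onset_year[d] == year) & (history.sex_code == s)
                c[f"medical_{d}"] = w * (n_prev * econ_params.prevalent_cost[d]
                                         + int(incident.sum()) * econ_params.incident_surcharge[d])
            c["medical_other"] = w * int(m.sum()) * econ_params.background_cost

            working = m & (age < econ_params.retirement_age)
            c["time_t2dm_self_management"] = (w * int(np.sum(prev["t2dm"] & m))
                                              * econ_params.t2dm_self_management_cost)
            c["time_t2dm_health_service"] = (w * int(np.sum(prev["t2dm"] & m))
                                             * econ_params.t2dm_health_service_time_cost)
            c["time_other"] = w * int(m.sum()) * econ_params.other_time_cost
            for d in ("t2dm", "stroke"):
                c[f"sick_leave_{d}"] = (w * int(np.sum(prev[d] & working))
                                        * econ_params.sick_leave_cost[d])
                incident = ((history.onset_year[d] == year) & (history.sex_code == s)
                            & (age < econ_params.retirement_age))
                c[f"early_retirement_{d}"] = (w * int(incident.sum())
                                              * econ_params.early_retirement_cost[d])
            died = (history.death_year == year) & (history.sex_code == s)
            pd_cost = 0.0
            for a in np.unique(age[died]):
                if a < econ_params.retirement_age:
                    n_d = int(np.sum(died & (age == a)))
                    pd_cost += n_d * _premature_death_cost(int(a), t, econ_params, r)
            c["premature_death"] = pd_cost

            c["cost_healthcare"] = sum(c[k] for k in HEALTHCARE_CATEGORIES)
            c["cost_societal"] = sum(c[k] for k in SOCIETAL_CATEGORIES)
            c_rows.append({"year": year, "sex": sex, **c})
    return pd.DataFrame(q_rows), pd.DataFrame(c_rows)


def qalys(history, utility_params: UtilityParameters | None = None,
          r: float | None = None) -> float:
    """Total discounted QALYs of one simulation arm."""
    utility_params = utility_params or UtilityParameters()
    econ = EconParameters() if r is None else EconParameters(discount_rate=r)
    q, _ = yearly_qalys_costs(history, utility_params, econ, econ.discount_rate)
    return float(q["qalys"].sum())


def costs(history, params: EconParameters | None = None,
          perspective: str = "societal", r: float | None = None) -> dict:
    """Total discounted costs by category for one simulation arm.

    The healthcare perspective contains only formal health-sector
    categories; the societal perspective adds time and productivity
    categories.  Returns a dict of category totals plus ``"total"``.
    """
    params = params or EconParameters()
    if perspective not in ("healthcare", "societal"):
        raise ValueError("perspective must be 'healthcare' or 'societal'")
    r = params.discount_rate if r is None else r
    _, c = yearly_qalys_costs(history, UtilityParameters(), params, r)
    cats = HEALTHCARE_CATEGORIES if perspective == "healthcare" else SOCIETAL_CATEGORIES
    out = {k: float(c[k].sum()) for k in cats}
    # societal total is healthcare total plus the extra categories, exactly
    hc_total = sum(out[k] for k in HEALTHCARE_CATEGORIES)
    if perspective == "healthcare":
        out["total"] = hc_total
    else:
        out["total"] = hc_total + sum(out[k] for k in TIME_CATEGORIES + PRODUCTIVITY_CATEGORIES)
    return out


def icer(delta_cost: float, delta_qaly: float):
    """Incremental cost-effectiveness ratio with dominance labelling.

    Cost savings with health gains have no trade-off ("Dominant"); health
    losses at non-negative cost are "Dominated"; otherwise the ratio
    delta_cost / delta_qaly in EUR per QALY.
    """
    if delta_cost == 0 and delta_qaly == 0:
        return "Undefined"
    if delta_cost <= 0 and delta_qaly > 0:
        return "Dominant"
    if delta_qaly <= 0 and delta_cost >= 0:
        return "Dominated"
    return float(delta_cost / delta_qaly)
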