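"""Open-cohort NCD microsimulation with paired counterfactual arms.

The engine simulates each adult's life course in annual steps over the
policy horizon: exposures are updated from the policy operators (with
lagged BMI response), disease incidence is drawn with individualised
attributable fractions (each person's relative risk rescaled by the
stratum-mean baseline RR, so stratum incidence is preserved in the null
and realises the potential impact fraction under policy), and mortality
combines CHD/stroke case fatality with calibrated other-cause mortality
(prevalent T2DM multiplies the non-CVD rate, normalised by expected
prevalence).  Individuals age out at 90 and new 30-year-old entrants are
admitted every year.

Counterfactual arms share *common random numbers*: uniforms are pre-drawn
per (individual, year, event channel) from the arm seed, so a baseline
arm compared with itself differs nowhere, and arm differences isolate the
policy.  Event order within a year is exposures -> T2DM incidence -> CHD
-> stroke -> CHD fatality -> stroke fatality -> other-cause mortality,
letting incident T2DM raise same-year cardiovascular risk; CHD and stroke
are absorbing first-ever-event states and remission is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import risk as _risk
from .demand import ElasticityMatrix, default_elasticity_matrix
from .policy import PolicyScenario, preset, scenario_volumes
from .risk import RiskParameters, exposure_rr
from .synthpop import (AGE_MAX, AGE_MIN, DISEASES, EpidemiologyConfig,
                       EpidemiologyInputs, PopulationConfig,
                       assign_baseline_diseases, generate_epidemiology,
                       generate_population)

CHANNELS = ("t2dm_inc", "chd_inc", "stroke_inc", "chd_fat", "stroke_fat", "other_mort")
N_STRATA = 2 * (AGE_MAX - AGE_MIN + 1)


def _stratum(sex_code, age):
    return (age - AGE_MIN) * 2 + sex_code


def _stratum_mean(strat, values, mask):
    """Mean of ``values`` per stratum over ``mask`` members (1 where empty)."""
    counts = np.bincount(strat[mask], minlength=N_STRATA)
    sums = np.bincount(strat[mask], weights=values[mask], minlength=N_STRATA)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 1.0)
    return means


class _ChannelBank:
    """Pre-drawn uniforms per (channel, year, individual); each (channel,
    year) slice may be consumed once — a second request is a double-draw
    bug and raises."""

    def __init__(self, seed, n_channels, horizon, n_individuals):
        self._u = np.random.default_rng(seed).random((n_channels, horizon, n_individuals))
        self._consumed = set()

    def draw(self, channel: int, year_index: int) -> np.ndarray:
        key = (channel, year_index)
        if key in self._consumed:
            raise RuntimeError(
                f"random-number channel {CHANNELS[channel]} already consumed "
                f"for year index {year_index} (double draw)")
        self._consumed.add(key)
        return self._u[channel, year_index]


@dataclass
class History:
    """Per-individual event history of one simulation arm.

    Disease states are absorbing, so the full history is the set of onset,
    death and exit years per individual; per-year states and exposures are
    reconstructed on demand (exposure trajectories are deterministic given
    the scenario).
    """

    sex_code: np.ndarray          # 0 = male, 1 = female
    entry_year: np.ndarray
    age_entry: np.ndarray
    bmi0: np.ndarray
    ssb0: np.ndarray
    juice0: np.ndarray
    dens_ssb: np.ndarray
    dens_juice: np.ndarray
    onset_year: dict              # disease -> int array (-1 = never)
    death_year: np.ndarray       # -1 = alive at horizon end
    death_cause: np.ndarray      # 0 none, 1 chd, 2 stroke, 3 other
    aged_out_year: np.ndarray    # -1 = never
    scenario: PolicyScenario
    elasticities: ElasticityMatrix
    risk_params: RiskParameters
    start_year: int
    horizon: int
    n_capped: int = 0

    @property
    def n(self) -> int:
        return self.sex_code.size

    def age_at(self, year: int) -> np.ndarray:
        return self.age_entry + (year - self.entry_year)

    def person_year_mask(self, year: int) -> np.ndarray:
        """People who lived (the whole of) calendar ``year`` in simulation."""
        entered = self.entry_year <= year
        not_dead = (self.death_year == -1) | (self.death_year > year)
        not_out = (self.aged_out_year == -1) | (self.aged_out_year >= year)
        return entered & not_dead & not_out

    def prevalent_mask(self, disease: str, year: int) -> np.ndarray:
        onset = self.onset_year[disease]
        return (onset != -1) & (onset <= year)

    def scenario_exposures(self, year: int):
        """(ssb_ml, juice_ml, sugar_g/day, bmi) under this arm's scenario at
        ``year``, with the BMI lag ramp applied."""
        sc = self.scenario
        ssb, juice = scenario_volumes(self.ssb0, self.juice0, sc, self.elasticities, year)
        rho = sc.reformulation_factor(year)
        sugar = ssb * self.dens_ssb * (1.0 - rho) + juice * self.dens_juice
        sugar0 = self.ssb0 * self.dens_ssb + self.juice0 * self.dens_juice
        ramp = _lag_ramp(year - self.start_year, self.risk_params.bmi_lag_years)
        bmi = self.bmi0 + self.risk_params.beta_sugar * (sugar - sugar0) * ramp
        return ssb, juice, sugar, bmi

    def to_frame(self) -> pd.DataFrame:
        """Long-format event history (one row per person-year)."""
        rows = []
        for t in range(self.horizon):
            year = self.start_year + t
            mask = self.person_year_mask(year)
            if not mask.any():
                continue
            ssb, juice, sugar, bmi = self.scenario_exposures(year)
            df = pd.DataFrame({
                "id": np.nonzero(mask)[0],
                "year": year,
                "age": self.age_at(year)[mask],
                "sex": np.where(self.sex_code[mask] == 0, "male", "female"),
                "bmi": bmi[mask],
                "ssb_ml": ssb[mask] if ssb.ndim else np.repeat(ssb, mask.sum()),
                "juice_ml": juice[mask],
                "sugar_g": sugar[mask],
                "t2dm": self.prevalent_mask("t2dm", year)[mask],
                "chd": self.prevalent_mask("chd", year)[mask],
                "stroke": self.prevalent_mask("stroke", year)[mask],
                "alive": True,
            })
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def _lag_ramp(t_since_start, lag_years: float) -> float:
    """Linear exposure ramp: fraction of the sustained shift attained
    ``t_since_start`` years after the policy starts (full after the lag)."""
    if lag_years <= 0:
        return 1.0 if t_since_start >= 0 else 0.0
    return float(np.clip((t_since_start + 1) / lag_years, 0.0, 1.0))


class Microsimulation:
    """Discrete-time stochastic open-cohort simulation of T2DM, CHD, stroke.

    Parameters
    ----------
    population : DataFrame from the synthetic-population generator with
        baseline disease columns and an ``entry_year`` column (initial
        members plus the pre-generated entrant cohorts; pre-generating
        entrants keeps them identical across counterfactual arms).
    epidemiology : consistent incidence/prevalence/fatality inputs.
    risk_params, elasticities : pathway parameters and demand matrix.
    mortality_factors : optional (2, n_ages) multiplicative calibration of
        other-cause mortality (see :func:`calibrate_mortality`).
    """

    def __init__(self, population: pd.DataFrame, epidemiology: EpidemiologyInputs,
                 risk_params: RiskParameters | None = None,
                 elasticities: ElasticityMatrix | None = None, *,
                 start_year: int = 2023, horizon: int = 20,
                 mortality_factors: np.ndarray | None = None):
        self.epi = epidemiology
        self.rp = risk_params or RiskParameters()
        self.E = elasticities or default_elasticity_matrix()
        self.start_year = int(start_year)
        self.horizon = int(horizon)
        pop = population
        self.sex_code = (pop["sex"].to_numpy() == "female").astype(np.int64)
        self.entry_year = (pop["entry_year"].to_numpy().astype(np.int64)
                           if "entry_year" in pop else np.full(len(pop), start_year))
        self.age_entry = pop["age"].to_numpy().astype(np.int64)
        self.bmi0 = pop["bmi"].to_numpy().astype(float)
        self.ssb0 = pop["ssb_ml"].to_numpy().astype(float)
        self.juice0 = pop["juice_ml"].to_numpy().astype(float)
        self.dens_ssb = pop["sugar_density_ssb"].to_numpy().astype(float)
        self.dens_juice = pop["sugar_density_juice"].to_numpy().astype(float)
        self.baseline_disease = {}
        for d in DISEASES:
            self.baseline_disease[d] = (pop[d].to_numpy().astype(bool)
                                        if d in pop else np.zeros(len(pop), bool))
        self.mortality_factors = (np.ones((2, AGE_MAX - AGE_MIN + 1))
                                  if mortality_factors is None else np.asarray(mortality_factors))
        self.n = len(pop)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_configs(cls, pop_config: PopulationConfig | None = None,
                     epi_config: EpidemiologyConfig | None = None,
                     risk_params: RiskParameters | None = None,
                     elasticities: ElasticityMatrix | None = None,
                     seed: int = 0, horizon: int | None = None) -> "Microsimulation":
        """Generate population, entrants and epidemiology from configuration."""
        pop_config = pop_config or PopulationConfig()
        risk_params = risk_params or RiskParameters()
        horizon = pop_config.horizon_years if horizon is None else horizon
        start = pop_config.start_year
        ss = np.random.SeedSequence(seed)
        s_pop, s_dis, s_ent = ss.spawn(3)

        epi = generate_epidemiology(epi_config, risk_params)
        pop = generate_population(pop_config, seed=s_pop)
        pop = assign_baseline_diseases(pop, epi, s_dis, start_year=start)
        pop["entry_year"] = start

        n_entrants = int(round(pop_config.n_individuals * pop_config.age_weights()[0]))
        frames = [pop]
        if n_entrants > 0:
            for k, child in enumerate(s_ent.spawn(horizon - 1), start=1):
                ent = generate_population(pop_config, seed=child, year=start + k,
                                          n=n_entrants, age=AGE_MIN)
                for d in DISEASES:
                    ent[d] = False
                    ent[f"{d}_onset_year"] = -1
                ent["entry_year"] = start + k
                frames.append(ent)
        full = pd.concat(frames, ignore_index=True)
        full["id"] = np.arange(len(full))
        return cls(full, epi, risk_params, elasticities,
                   start_year=start, horizon=horizon)

    # -- the annual engine -------------------------------------------------

    def run_arm(self, scenario: PolicyScenario | str, seed: int,
                direct_effects: bool | None = None) -> History:
        """Simulate one arm under ``scenario`` with arm seed ``seed``.

        The same seed must be used for the paired baseline arm so both
        arms consume identical uniforms per (individual, year, channel).
        ``direct_effects`` overrides the scenario's flag (None = keep).
        """
        if isinstance(scenario, str):
            scenario = preset(scenario, start_year=self.start_year)
        if direct_effects is not None:
            scenario = scenario.with_overrides(direct_effects_enabled=direct_effects)
        direct = scenario.direct_effects_enabled
        rp, epi = self.rp, self.epi
        n, T = self.n, self.horizon
        bank = _ChannelBank(seed, len(CHANNELS), T, n)
        ch = {name: k for k, name in enumerate(CHANNELS)}

        alive = np.ones(n, bool)
        t2dm = self.baseline_disease["t2dm"].copy()
        chd = self.baseline_disease["chd"].copy()
        stroke = self.baseline_disease["stroke"].copy()
        onset = {d: np.where(self.baseline_disease[d], self.start_year - 1, -1).astype(np.int64)
                 for d in DISEASES}
        death_year = np.full(n, -1, np.int64)
        death_cause = np.zeros(n, np.int64)
        aged_out = np.full(n, -1, np.int64)
        n_capped = 0

        sugar0 = self.ssb0 * self.dens_ssb + self.juice0 * self.dens_juice
        state = {"t2dm": t2dm, "chd": chd, "stroke": stroke}

        for t in range(T):
            year = self.start_year + t
            active = alive & (self.entry_year <= year)
            if not active.any():
                continue
            age = np.where(active, self.age_entry + (year - self.entry_year), AGE_MIN)
            strat = _stratum(self.sex_code, age)
            aidx = age - AGE_MIN

            # (1) exposures under the scenario, with disease-specific lag ramps
            ssb_v, juice_v = scenario_volumes(self.ssb0, self.juice0, scenario, self.E, year)
            rho = scenario.reformulation_factor(year)
            sugar_cf = ssb_v * self.dens_ssb * (1.0 - rho) + juice_v * self.dens_juice
            # direct effects are driven by SSB sugar, so reformulated drinks
            # count as sugar-equivalent volume at the baseline density
            ssb_eq = ssb_v * (1.0 - rho)

            def effective(disease):
                ramp = _lag_ramp(t, rp.lag_years[disease])
                bmi = self.bmi0 + rp.beta_sugar * (sugar_cf - sugar0) * ramp
                ssb = self.ssb0 + (ssb_eq - self.ssb0) * ramp
                return bmi, ssb

            # (2)-(3) disease incidence with individualised attributable fractions
            for disease in DISEASES:
                sus = active & ~state[disease]
                if not sus.any():
                    continue
                bmi_eff, ssb_eff = effective(disease)
                rr_cf = exposure_rr(bmi_eff, ssb_eff, disease, rp, direct)
                rr_base = exposure_rr(self.bmi0, self.ssb0, disease, rp, direct)
                denom = _stratum_mean(strat, rr_base, sus)
                p0 = 1.0 - np.exp(-epi.rate("incidence", disease, self.sex_code, age))
                p = p0 * rr_cf / denom[strat]
                if disease in ("chd", "stroke"):
                    rr_t2 = rp.rr_t2dm[disease].value
                    prev_ref = epi.rate("prevalence", "t2dm", self.sex_code, age)
                    p = p * np.where(t2dm, rr_t2, 1.0) / (1.0 + (rr_t2 - 1.0) * prev_ref)
                n_capped += int(np.sum(p[sus] > 1.0))
                p = np.minimum(p, 1.0)
                events = sus & (bank.draw(ch[f"{disease}_inc"], t) < p)
                state[disease][events] = True
                onset[disease][events] = year

            # (4) mortality: case fatality for prevalent CHD/stroke, then
            # calibrated other-cause mortality with the T2DM multiplier
            for disease, cause in (("chd", 1), ("stroke", 2)):
                at_risk = active & alive & state[disease]
                p_cf = 1.0 - np.exp(-epi.rate("case_fatality", disease, self.sex_code, age))
                die = at_risk & (bank.draw(ch[f"{disease}_fat"], t) < p_cf)
                alive[die] = False
                death_year[die] = year
                death_cause[die] = cause

            rem = active & alive
            rr_m = rp.rr_t2dm["non_cvd_mortality"].value
            prev_ref = epi.rate("prevalence", "t2dm", self.sex_code, age)
            m = (epi.other_mortality_rate(self.sex_code, age, t)
                 * self.mortality_factors[self.sex_code, aidx]
                 * np.where(t2dm, rr_m, 1.0) / (1.0 + (rr_m - 1.0) * prev_ref))
            die = rem & (bank.draw(ch["other_mort"], t) < 1.0 - np.exp(-m))
            alive[die] = False
            death_year[die] = year
            death_cause[die] = 3

            # (5)-(6) person-year recorded implicitly; age and retire the oldest
            out = active & alive & (age >= AGE_MAX)
            aged_out[out] = year
            alive[out] = False

        return History(self.sex_code, self.entry_year, self.age_entry, self.bmi0,
                       self.ssb0, self.juice0, self.dens_ssb, self.dens_juice,
                       onset, death_year, death_cause, aged_out, scenario, self.E,
                       rp, self.start_year, T, n_capped)


def calibrate_mortality(raw_rates, target_rates, population: pd.DataFrame | None = None,
                        bounds=(0.1, 10.0)) -> np.ndarray:
    """Multiplicative factors aligning raw other-cause mortality with targets.

    Elementwise ``target / raw`` per age/sex cell, bounded to ``bounds``
    with a warning when clipping occurs.  If ``population`` is supplied,
    cells without any members keep factor 1 and a cell with members but a
    non-positive target raises.
    """
    raw = np.asarray(raw_rates, dtype=float)
    target = np.asarray(target_rates, dtype=float)
    if raw.shape != target.shape:
        raise ValueError("raw and target rate arrays must have the same shape")
    occupied = np.ones_like(raw, dtype=bool)
    if population is not None:
        occupied = np.zeros_like(raw, dtype=bool)
        sex_code = (population["sex"].to_numpy() == "female").astype(int)
        age = population["age"].to_numpy()
        np.add.at(occupied, (sex_code, age - AGE_MIN), True)
        if not occupied.any():
            raise ValueError("empty stratum: population covers no rate cells")
        if np.any(occupied & (target <= 0)):
            raise ValueError("non-positive target rate in an occupied stratum")
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(occupied & (raw > 0), target / np.maximum(raw, 1e-300), 1.0)
        factors = np.where(occupied & (raw <= 0) & (target > 0), bounds[1], factors)
    clipped = (factors < bounds[0]) | (factors > bounds[1])
    if clipped.any():
        warnings.warn(f"{int(clipped.sum())} mortality calibration factors "
                      f"clipped to {bounds}", stacklevel=2)
    return np.clip(factors, *bounds)


# ---------------------------------------------------------------------------
# arm comparison
# ---------------------------------------------------------------------------

OUTCOME_DISEASES = ("t2dm", "chd", "stroke", "obesity")


@dataclass
class ArmComparison:
    """Baseline-vs-scenario differences over the horizon.

    Sign conventions: ``cases_prevented``/``case_years_prevented``/
    ``deaths_prevented`` are baseline minus scenario (positive = health
    gain); ``qalys_gained``/``life_years_gained`` are scenario minus
    baseline; ``cost_savings`` baseline minus scenario (positive = money
    saved); ``delta_cost``/``delta_qalys`` follow the incremental
    (scenario minus baseline) convention used for the ICER.
    """

    cases_prevented: dict
    case_years_prevented: dict
    deaths_prevented: float
    life_years_gained: float
    qalys_gained: float
    cost_savings: dict
    delta_cost: dict
    delta_qalys: float
    icer: dict
    yearly: pd.DataFrame
    scenario_name: str
    direct_effects: bool

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario_name,
            "direct_effects": self.direct_effects,
            "cases_prevented": self.cases_prevented,
            "case_years_prevented": self.case_years_prevented,
            "deaths_prevented": self.deaths_prevented,
            "life_years_gained": self.life_years_gained,
            "qalys_gained": self.qalys_gained,
            "cost_savings": self.cost_savings,
            "icer": self.icer,
        }

    def outcome_vector(self) -> dict:
        """Flat outcome -> value mapping (for uncertainty summaries)."""
        out = {}
        for d, v in self.cases_prevented.items():
            out[f"cases_prevented_{d}"] = v
        for d, v in self.case_years_prevented.items():
            out[f"case_years_prevented_{d}"] = v
        out["deaths_prevented"] = self.deaths_prevented
        out["life_years_gained"] = self.life_years_gained
        out["qalys_gained"] = self.qalys_gained
        for p, v in self.cost_savings.items():
            out[f"cost_savings_{p}"] = v
        return out


def _arm_yearly(history: History, utility_params, econ_params, r) -> pd.DataFrame:
    """Per (year, sex) outcome aggregates for one arm."""
    from .econ import yearly_qalys_costs  # local import to avoid a cycle

    rows = []
    for t in range(history.horizon):
        year = history.start_year + t
        py = history.person_year_mask(year)
        _, _, _, bmi = history.scenario_exposures(year)
        obese = bmi >= 30.0
        for s, sex in enumerate(("male", "female")):
            m = py & (history.sex_code == s)
            row = {"year": year, "sex": sex, "person_years": int(m.sum()),
                   "deaths": int(np.sum((history.death_year == year)
                                        & (history.sex_code == s)))}
            for d in DISEASES:
                row[f"incident_{d}"] = int(np.sum((history.onset_year[d] == year)
                                                  & (history.sex_code == s)))
                row[f"prevalent_{d}"] = int(np.sum(history.prevalent_mask(d, year) & m))
            row["prevalent_obesity"] = int(np.sum(obese & m))
            rows.append(row)
    df = pd.DataFrame(rows)
    q, c = yearly_qalys_costs(history, utility_params, econ_params, r)
    return df.merge(q, on=["year", "sex"]).merge(c, on=["year", "sex"])


def compare_arms(baseline: History, counterfactual: History,
                 utility_params=None, econ_params=None,
                 discount_rate: float | None = None) -> ArmComparison:
    """Difference two arms run on the same population with the same seed."""
    from .econ import EconParameters, UtilityParameters, icer

    if baseline.n != counterfactual.n or baseline.horizon != counterfactual.horizon:
        raise ValueError("mismatched populations or horizons between arms")
    if not (np.array_equal(baseline.entry_year, counterfactual.entry_year)
            and np.array_equal(baseline.sex_code, counterfactual.sex_code)
            and np.array_equal(baseline.bmi0, counterfactual.bmi0)):
        raise ValueError("arms were not run on the same population")
    econ_params = econ_params or EconParameters()
    utility_params = utility_params or UtilityParameters()
    r = econ_params.discount_rate if discount_rate is None else discount_rate

    yb = _arm_yearly(baseline, utility_params, econ_params, r)
    yc = _arm_yearly(counterfactual, utility_params, econ_params, r)
    keys = ["year", "sex"]
    diff = yb.set_index(keys).subtract(yc.set_index(keys))  # baseline - scenario

    cases, case_years = {}, {}
    for d in DISEASES:
        cases[d] = float(diff[f"incident_{d}"].sum())
        case_years[d] = float(diff[f"prevalent_{d}"].sum())
    # obesity "incidence" is not an event channel; cases are counted as the
    # peak yearly difference in prevalent obese persons (BMI >= 30 crossings
    # induced by the policy), case-years as the prevalence difference.
    ob = diff["prevalent_obesity"].groupby("year").sum()
    cases["obesity"] = float(ob.max()) if len(ob) else 0.0
    case_years["obesity"] = float(ob.sum())

    deaths = float(diff["deaths"].sum())
    ly = -float(diff["person_years"].sum())
    qalys = -float(diff["qalys"].sum())
    savings, delta_cost, icers = {}, {}, {}
    for p in ("healthcare", "societal"):
        savings[p] = float(diff[f"cost_{p}"].sum())
        delta_cost[p] = -savings[p]
    dq = qalys
    for p in ("healthcare", "societal"):
        if delta_cost[p] == 0.0 and dq == 0.0:
            icers[p] = "Undefined"
        else:
            icers[p] = icer(delta_cost[p], dq)
    yearly = diff.reset_index()
    return ArmComparison(cases, case_years, deaths, ly, qalys, savings,
                         delta_cost, dq, icers, yearly,
                         counterfactual.scenario.name,
                         counterfactual.scenario.direct_effects_enabled)
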