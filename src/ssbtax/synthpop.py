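"""Synthetic inputs: population, household expenditure panels, epidemiology.

Real analyses of this kind run on restricted cohort/survey microdata; this
module generates stand-ins with the same statistical structure so every
downstream component can be exercised and tested end to end:

* an adult population (ages 30-90) with an age/sex structure, log-normal BMI
  with a secular trend, and zero-inflated beverage intakes (Bernoulli
  consumer indicator x Gamma positive part) -- men drink more SSBs than
  women, younger adults more than older ones, while fruit-juice intake is
  relatively higher among women;
* household budget-share panels simulated from a known LA-AIDS parameter set,
  used for demand-estimation recovery experiments;
* age/sex-specific incidence, case fatality and other-cause mortality for
  type 2 diabetes, CHD and stroke whose prevalence columns are produced by a
  three-state illness-death solver, so incidence, prevalence and mortality
  are mutually consistent by construction (remission is zero throughout).

All generators are deterministic given an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .demand import GOODS, DemandParameters

SEXES = ("male", "female")
AGE_MIN, AGE_MAX = 30, 90
AGES = np.arange(AGE_MIN, AGE_MAX + 1)
N_AGES = AGES.size

DISEASES = ("t2dm", "chd", "stroke")


@dataclass
class Individual:
    """One simulated person (scalar convenience view; the engines work on
    DataFrames with the same fields)."""

    id: int
    sex: str
    birth_year: int
    age: int
    bmi: float
    ssb_ml: float
    juice_ml: float
    sugar_density_ssb: float = 0.09
    sugar_density_juice: float = 0.10
    t2dm: bool = False
    chd: bool = False
    stroke: bool = False
    alive: bool = True

    @property
    def sugar_g_ssb(self) -> float:
        return self.ssb_ml * self.sugar_density_ssb

    @property
    def sugar_g_juice(self) -> float:
        return self.juice_ml * self.sugar_density_juice


def _by_sex(male, female):
    return {"male": male, "female": female}


@dataclass
class PopulationConfig:
    """Parameters of the synthetic adult population.

    Age/sex patterns are parametric: the age pyramid is flat up to
    ``age_weight_knee`` then decays exponentially; BMI is log-normal with an
    age gradient (plateau at 65) and a linear secular trend on the log scale;
    beverage intakes are Bernoulli(consumer) x Gamma mixtures whose consumer
    probability and positive-part mean decay exponentially with age.
    Intake parameters are placeholders calibrated to plausible German adult
    magnitudes, not to any survey microdata.
    """

    n_individuals: int = 10_000
    start_year: int = 2023
    horizon_years: int = 20
    seed: int = 0
    p_male: float = 0.5
    age_weight_knee: float = 60.0
    age_weight_scale: float = 15.0
    # BMI (kg/m^2)
    bmi_mean_at30: dict = field(default_factory=lambda: _by_sex(25.5, 24.0))
    bmi_age_slope: float = 0.05          # kg/m^2 per year of age, up to 65
    bmi_log_sd: float = 0.15
    bmi_log_trend: float = 0.002         # per calendar year, on the log scale
    # SSB intake (ml/day)
    ssb_consumer_p_at30: dict = field(default_factory=lambda: _by_sex(0.80, 0.65))
    ssb_consumer_decay: float = 0.012    # exponential decline per year of age
    ssb_pos_mean_at30: dict = field(default_factory=lambda: _by_sex(420.0, 260.0))
    ssb_pos_mean_decay: float = 0.02
    ssb_shape: float = 1.2               # Gamma shape of the positive part
    # fruit juice intake (ml/day)
    juice_consumer_p_at30: dict = field(default_factory=lambda: _by_sex(0.65, 0.72))
    juice_consumer_decay: float = 0.005
    juice_pos_mean_at30: dict = field(default_factory=lambda: _by_sex(160.0, 190.0))
    juice_pos_mean_decay: float = 0.008
    juice_shape: float = 1.4
    # beverage sugar densities (g sugar per ml)
    sugar_density_ssb: float = 0.09
    sugar_density_juice: float = 0.10

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        for p in (self.p_male, *self.ssb_consumer_p_at30.values(),
                  *self.juice_consumer_p_at30.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.ssb_shape <= 0 or self.juice_shape <= 0 or self.bmi_log_sd <= 0:
            raise ValueError("dispersion parameters must be > 0")

    def age_weights(self) -> np.ndarray:
        w = np.where(AGES <= self.age_weight_knee, 1.0,
                     np.exp(-(AGES - self.age_weight_knee) / self.age_weight_scale))
        return w / w.sum()

    def consumer_probability(self, beverage: str, sex, age):
        p30 = _sex_lookup(getattr(self, f"{beverage}_consumer_p_at30"), sex)
        decay = getattr(self, f"{beverage}_consumer_decay")
        return p30 * np.exp(-decay * (np.asarray(age) - AGE_MIN))

    def positive_mean(self, beverage: str, sex, age):
        m30 = _sex_lookup(getattr(self, f"{beverage}_pos_mean_at30"), sex)
        decay = getattr(self, f"{beverage}_pos_mean_decay")
        return m30 * np.exp(-decay * (np.asarray(age) - AGE_MIN))

    def bmi_log_mean(self, sex, age, year):
        mean = (_sex_lookup(self.bmi_mean_at30, sex)
                + self.bmi_age_slope * (np.minimum(np.asarray(age), 65) - AGE_MIN))
        return np.log(mean) - 0.5 * self.bmi_log_sd**2 + self.bmi_log_trend * (year - self.start_year)

    # flat key-value (YAML) round trip -------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)

    @classmethod
    def from_yaml(cls, path) -> "PopulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sex_lookup(d: dict, sex):
    if np.isscalar(sex) or isinstance(sex, str):
        return d[sex]
    arr = np.asarray(sex)
    return np.where(arr == "male", d["male"], d["female"]).astype(float)


def generate_population(config: PopulationConfig, seed: int | None = None,
                        year: int | None = None, n: int | None = None,
                        age: int | None = None) -> pd.DataFrame:
    """Draw a synthetic population as a tidy DataFrame (one row per person).

    ``year`` (default ``config.start_year``) controls the secular BMI trend;
    fixing ``age`` generates an entrant cohort (all the same age, e.g. the
    30-year-olds admitted each simulated year).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_individuals if n is None else int(n)
    if n <= 0:
        raise ValueError("n must be positive")
    year = config.start_year if year is None else int(year)

    if age is None:
        ages = rng.choice(AGES, size=n, p=config.age_weights())
    else:
        ages = np.full(n, int(age))
    sex = np.where(rng.random(n) < config.p_male, "male", "female")

    bmi = np.exp(rng.normal(config.bmi_log_mean(sex, ages, year), config.bmi_log_sd))
    bmi = np.clip(bmi, 12.0, 80.0)

    def mixture(beverage, shape):
        p = config.consumer_probability(beverage, sex, ages)
        mean_pos = config.positive_mean(beverage, sex, ages)
        consumer = rng.random(n) < p
        pos = rng.gamma(shape, mean_pos / shape, size=n)
        return np.where(consumer, pos, 0.0)

    ssb = mixture("ssb", config.ssb_shape)
    juice = mixture("juice", config.juice_shape)

    return pd.DataFrame({
        "id": np.arange(n),
        "sex": sex,
        "age": ages.astype(int),
        "birth_year": year - ages.astype(int),
        "bmi": bmi,
        "ssb_ml": ssb,
        "juice_ml": juice,
        "sugar_density_ssb": config.sugar_density_ssb,
        "sugar_density_juice": config.sugar_density_juice,
    })


# ---------------------------------------------------------------------------
# household expenditure panel
# ---------------------------------------------------------------------------

def default_demand_parameters() -> DemandParameters:
    """A plausible LA-AIDS parameter set (adding-up, homogeneity, symmetry)
    used as ground truth in demand-recovery experiments."""
    alpha = np.array([0.15, 0.20, 0.65])
    beta = np.array([0.010, -0.005, -0.005])
    gamma = np.array([
        [0.020, 0.005, -0.025],
        [0.005, -0.010, 0.005],
        [-0.025, 0.005, 0.020],
    ])
    params = DemandParameters(alpha, beta, gamma)
    params.validate()
    return params


def generate_household_panel(n_households: int, true_params: DemandParameters,
                             noise_sd: float, seed: int,
                             price_sd: float = 0.10,
                             expenditure_sd: float = 0.50) -> pd.DataFrame:
    """Simulate a household budget-share panel from the LA-AIDS share equation.

    Log prices and log expenditure are normal around 0 (normalised units);
    the Stone index is resolved by fixed-point iteration on the sample mean
    shares, mirroring how the estimator deflates expenditure.  Zero-mean
    noise (projected to sum to zero per household) is added to the shares,
    which therefore still sum to one exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    true_params.validate()
    rng = np.random.default_rng(seed)
    g = len(true_params.goods)
    lnp = rng.normal(0.0, price_sd, size=(n_households, g))
    lnx = rng.normal(0.0, expenditure_sd, size=n_households)

    wbar = true_params.alpha.copy()
    for _ in range(50):
        z = lnx - lnp @ wbar
        w = true_params.alpha + lnp @ true_params.gamma.T + np.outer(z, true_params.beta)
        new = w.mean(axis=0)
        if np.abs(new - wbar).max() < 1e-14:
            break
        wbar = new

    if noise_sd > 0:
        eps = rng.normal(0.0, noise_sd, size=(n_households, g))
        eps -= eps.mean(axis=1, keepdims=True)
        w = w + eps
    bad = np.mean(np.any((w < 0) | (w > 1), axis=1))
    if bad > 0.01:
        raise ValueError(
            f"noise_sd={noise_sd} pushes shares outside [0, 1] in "
            f"{100 * bad:.1f}% of households (> 1%); reduce the noise"
        )
    w = np.clip(w, 0.0, 1.0)
    w = w / w.sum(axis=1, keepdims=True)

    out = {"hh_id": np.arange(n_households)}
    for j, good in enumerate(true_params.goods):
        out[f"p_{good}"] = np.exp(lnp[:, j])
    out["expenditure"] = np.exp(lnx)
    for j, good in enumerate(true_params.goods):
        out[f"w_{good}"] = w[:, j]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# illness-death consistency solver
# ---------------------------------------------------------------------------

def _as_schedule(x) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (N_AGES,)).copy()
    if np.any(arr < 0):
        raise ValueError("rates must be non-negative")
    return arr


def solve_illness_death(incidence, case_fatality, other_mortality) -> np.ndarray:
    """Prevalence among the living by age from a well->diseased->dead model.

    Annual forward integration on ages 30..90 with remission fixed at zero.
    Rates (per person-year; scalars or length-61 schedules) are converted to
    probabilities via 1 - exp(-rate).  ``case_fatality`` is the *excess*
    mortality hazard of the diseased over ``other_mortality``.  Incident
    cases are exposed to diseased mortality in their onset year.  Returns
    prevalence among the living at each age (zero at age 30).
    """
    inc = _as_schedule(incidence)
    cf = _as_schedule(case_fatality)
    om = _as_schedule(other_mortality)
    well, dis = 1.0, 0.0
    prev = np.zeros(N_AGES)
    for k in range(N_AGES - 1):
        p_inc = 1.0 - np.exp(-inc[k])
        new = well * p_inc
        well = (well - new) * np.exp(-om[k])
        dis = (dis + new) * np.exp(-(om[k] + cf[k]))
        alive = well + dis
        prev[k + 1] = dis / alive if alive > 1e-300 else (1.0 if cf[k] < np.inf else 0.0)
    return prev


# ---------------------------------------------------------------------------
# disease epidemiology
# ---------------------------------------------------------------------------

@dataclass
class EpidemiologyConfig:
    """Parametric (exponential-in-age) rate shapes per disease and sex.

    ``*_rate30`` is the rate at age 30 (per person-year), ``*_slope`` the
    exponential age gradient.  ``mort_trend`` is the relative annual change
    in other-cause mortality (negative = secular improvement).
    """

    t2dm_inc_rate30: dict = field(default_factory=lambda: _by_sex(2.0e-3, 1.5e-3))
    t2dm_inc_slope: dict = field(default_factory=lambda: _by_sex(0.045, 0.047))
    chd_inc_rate30: dict = field(default_factory=lambda: _by_sex(0.8e-3, 0.4e-3))
    chd_inc_slope: dict = field(default_factory=lambda: _by_sex(0.055, 0.060))
    chd_cf_rate30: dict = field(default_factory=lambda: _by_sex(0.010, 0.009))
    chd_cf_slope: dict = field(default_factory=lambda: _by_sex(0.040, 0.040))
    stroke_inc_rate30: dict = field(default_factory=lambda: _by_sex(0.30e-3, 0.25e-3))
    stroke_inc_slope: dict = field(default_factory=lambda: _by_sex(0.065, 0.065))
    stroke_cf_rate30: dict = field(default_factory=lambda: _by_sex(0.015, 0.013))
    stroke_cf_slope: dict = field(default_factory=lambda: _by_sex(0.045, 0.045))
    other_mort_rate30: dict = field(default_factory=lambda: _by_sex(0.8e-3, 0.5e-3))
    other_mort_slope: dict = field(default_factory=lambda: _by_sex(0.088, 0.090))
    mort_trend: float = -0.01

    def schedule(self, prefix: str, sex: str) -> np.ndarray:
        r30 = getattr(self, f"{prefix}_rate30")[sex]
        slope = getattr(self, f"{prefix}_slope")[sex]
        return r30 * np.exp(slope * (AGES - AGE_MIN))


@dataclass
class EpidemiologyInputs:
    """Age/sex rate schedules for the three diseases, mutually consistent.

    Arrays have shape (2, 61): sex (male=0, female=1) by age 30..90.
    ``case_fatality['t2dm']`` is not a drawn event channel but the derived
    excess-mortality schedule of the diseased (diabetes raises non-CVD
    mortality and, through higher CHD/stroke incidence, CVD fatality); it is
    what makes the T2DM prevalence column consistent under the illness-death
    solver.  Remission is zero for all diseases.
    """

    incidence: dict
    prevalence: dict
    case_fatality: dict
    other_mortality: np.ndarray
    mort_trend: float = 0.0

    def __post_init__(self):
        for d in DISEASES:
            for table in (self.incidence, self.prevalence, self.case_fatality):
                if np.any(np.asarray(table[d]) < 0):
                    raise ValueError(f"negative rates for {d}")
            if np.any(self.prevalence[d] > 1):
                raise ValueError(f"prevalence > 1 for {d}")
        if np.any(self.other_mortality < 0):
            raise ValueError("negative other-cause mortality")

    def rate(self, table: str, disease: str, sex_code, age):
        arr = getattr(self, table)[disease]
        return arr[sex_code, np.asarray(age) - AGE_MIN]

    def other_mortality_rate(self, sex_code, age, years_from_start=0):
        base = self.other_mortality[sex_code, np.asarray(age) - AGE_MIN]
        return base * (1.0 + self.mort_trend) ** years_from_start

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in DISEASES:
            for s, sex in enumerate(SEXES):
                for k, a in enumerate(AGES):
                    rows.append({
                        "disease": d, "sex": sex, "age": int(a),
                        "incidence": self.incidence[d][s, k],
                        "prevalence": self.prevalence[d][s, k],
                        "case_fatality": self.case_fatality[d][s, k],
                        "remission": 0.0,
                        "other_mortality": self.other_mortality[s, k],
                    })
        return pd.DataFrame(rows)


def generate_epidemiology(config: EpidemiologyConfig | None = None,
                          risk_params=None) -> EpidemiologyInputs:
    """Build internally consistent disease inputs from parametric rate shapes.

    Prevalence columns are produced by :func:`solve_illness_death`, so the
    inputs satisfy the illness-death consistency check by construction.  For
    T2DM the excess mortality of the diseased combines the relative risk on
    non-CVD mortality with the extra CVD fatality implied by the higher
    CHD/stroke incidence of diabetics (two-pass construction).
    """
    from .risk import RiskParameters  # deferred: risk imports nothing from here

    config = config or EpidemiologyConfig()
    rp = risk_params or RiskParameters()

    incidence, prevalence, case_fatality = {}, {}, {}
    other = np.stack([config.schedule("other_mort", s) for s in SEXES])

    for d in ("chd", "stroke"):
        incidence[d] = np.stack([config.schedule(f"{d}_inc", s) for s in SEXES])
        case_fatality[d] = np.stack([config.schedule(f"{d}_cf", s) for s in SEXES])
        prevalence[d] = np.stack([
            solve_illness_death(incidence[d][s], case_fatality[d][s], other[s])
            for s in range(2)
        ])

    incidence["t2dm"] = np.stack([config.schedule("t2dm_inc", s) for s in SEXES])

    # pass 1: T2DM prevalence from non-CVD excess mortality alone
    rr_m = rp.rr_t2dm["non_cvd_mortality"].value
    excess0 = [None, None]
    for s in range(2):
        denom = None  # filled below once prevalence is known; iterate twice
        prev = solve_illness_death(incidence["t2dm"][s], other[s] * (rr_m - 1.0), other[s])
        for _ in range(2):
            denom = 1.0 + (rr_m - 1.0) * prev
            excess0[s] = other[s] * (rr_m - 1.0) / denom
            prev = solve_illness_death(incidence["t2dm"][s], excess0[s], other[s])
        excess0[s] = (excess0[s], prev)

    # pass 2: add the CVD-fatality differential of diabetics
    case_fatality["t2dm"] = np.zeros((2, N_AGES))
    prevalence["t2dm"] = np.zeros((2, N_AGES))
    for s in range(2):
        excess, prev_t2dm = excess0[s]
        cvd_diff = np.zeros(N_AGES)
        for d in ("chd", "stroke"):
            rr_d = rp.rr_t2dm[d].value
            denom_d = 1.0 + (rr_d - 1.0) * prev_t2dm
            prev_with = solve_illness_death(incidence[d][s] * rr_d / denom_d,
                                            case_fatality[d][s], other[s])
            prev_without = solve_illness_death(incidence[d][s] / denom_d,
                                               case_fatality[d][s], other[s])
            cvd_diff += case_fatality[d][s] * (prev_with - prev_without)
        case_fatality["t2dm"][s] = excess + cvd_diff
        prevalence["t2dm"][s] = solve_illness_death(
            incidence["t2dm"][s], case_fatality["t2dm"][s], other[s])

    return EpidemiologyInputs(incidence, prevalence, case_fatality, other,
                              mort_trend=config.mort_trend)


def assign_baseline_diseases(population: pd.DataFrame, epi: EpidemiologyInputs,
                             seed: int, start_year: int = 2023) -> pd.DataFrame:
    """Assign prevalent disease states at simulation start.

    Each disease is assigned independently with the stratum (sex x age)
    prevalence; onset years of prevalent cases are set to the year before the
    simulation starts (they count as prevalent, never incident).
    """
    rng = np.random.default_rng(seed)
    pop = population.copy()
    sex_code = (pop["sex"].to_numpy() == "female").astype(int)
    age = pop["age"].to_numpy()
    for d in DISEASES:
        p = epi.rate("prevalence", d, sex_code, age)
        has = rng.random(len(pop)) < p
        pop[d] = has
        pop[f"{d}_onset_year"] = np.where(has, start_year - 1, -1)
    return pop
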