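"""Two-level Monte Carlo uncertainty analysis and scenario batch running.

Each iteration of the probabilistic uncertainty analysis (PUA) draws one
set of uncertain parameters (second-order uncertainty: elasticities and
pass-through from normal distributions derived from printed confidence
intervals, relative risks log-normal, the sugar->BMI slope normal, cost
and utility-decrement multipliers normal truncated at zero) and runs a
fresh paired baseline/scenario simulation with a new first-order seed
(stochastic uncertainty: event draws and population sampling).  Outcomes
are summarised as the median and the 2.5th/97.5th percentiles across
iterations.  Within an iteration the same parameter draw is shared across
scenarios so that scenario contrasts difference out parameter noise.

The reference analysis uses 500 iterations; the package default is a
desk-scale 50, raised via ``n_iter``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .demand import (DEFAULT_PASS_THROUGH, DEFAULT_PASS_THROUGH_CI,
                     ElasticityMatrix, ci_to_se, default_elasticity_matrix)
from .econ import EconParameters, UtilityParameters
from .microsim import ArmComparison, Microsimulation, compare_arms
from .policy import PolicyScenario, preset
from .risk import LogNormalRR, RiskParameters
from .synthpop import EpidemiologyConfig, PopulationConfig


@dataclass
class ParameterDraw:
    """One joint draw of the uncertain parameters (reproducible from
    (seed, index))."""

    seed: int
    index: int
    elasticities: ElasticityMatrix
    pass_through: float
    risk_params: RiskParameters
    cost_multiplier: float
    utility_decrement_multiplier: float
    truncations: list = field(default_factory=list)


def sample_parameters(seed: int, index: int,
                      base_elasticities: ElasticityMatrix | None = None,
                      base_risk: RiskParameters | None = None,
                      cost_multiplier_sd: float = 0.10,
                      utility_multiplier_sd: float = 0.10) -> ParameterDraw:
    """Draw one parameter set; zero SEs reproduce the point estimates."""
    E = base_elasticities or default_elasticity_matrix()
    rp = base_risk or RiskParameters()
    rng = np.random.default_rng(np.random.SeedSequence([seed, index]))
    truncations = []

    values = rng.normal(E.values, E.se)
    pt_se = ci_to_se(*DEFAULT_PASS_THROUGH_CI)
    pass_through = float(rng.normal(DEFAULT_PASS_THROUGH, pt_se))
    if not 0.0 <= pass_through <= 1.5:
        pass_through = float(np.clip(pass_through, 0.0, 1.5))
        truncations.append("pass_through")

    def draw_rr(d: dict) -> dict:
        return {k: LogNormalRR(float(np.exp(rng.normal(np.log(v.value), v.log_sd))), v.log_sd)
                for k, v in d.items()}

    beta = float(rng.normal(rp.beta_sugar, rp.beta_sugar_sd))
    if beta < 0:
        beta = 0.0
        truncations.append("beta_sugar")
    risk = replace(rp, beta_sugar=beta, rr_bmi=draw_rr(rp.rr_bmi),
                   rr_ssb_direct=draw_rr(rp.rr_ssb_direct), rr_t2dm=draw_rr(rp.rr_t2dm))

    def trunc_mult(sd, name):
        v = float(rng.normal(1.0, sd))
        if v < 0:
            truncations.append(name)
            return 0.0
        return v

    return ParameterDraw(seed, index, ElasticityMatrix(values, E.se), pass_through,
                         risk, trunc_mult(cost_multiplier_sd, "cost_multiplier"),
                         trunc_mult(utility_multiplier_sd, "utility_multiplier"),
                         truncations)


def _scaled_econ(base: EconParameters, mult: float) -> EconParameters:
    return EconParameters(
        discount_rate=base.discount_rate, retirement_age=base.retirement_age,
        prevalent_cost={k: v * mult for k, v in base.prevalent_cost.items()},
        incident_surcharge={k: v * mult for k, v in base.incident_surcharge.items()},
        background_cost=base.background_cost * mult,
        t2dm_self_management_cost=base.t2dm_self_management_cost * mult,
        t2dm_health_service_time_cost=base.t2dm_health_service_time_cost * mult,
        other_time_cost=base.other_time_cost * mult,
        sick_leave_cost={k: v * mult for k, v in base.sick_leave_cost.items()},
        early_retirement_cost={k: v * mult for k, v in base.early_retirement_cost.items()},
        annual_gross_wage=base.annual_gross_wage * mult)


def _scaled_utils(base: UtilityParameters, mult: float) -> UtilityParameters:
    return UtilityParameters(
        base_at30=dict(base.base_at30), age_slope=base.age_slope,
        bmi_decrement=base.bmi_decrement * mult, bmi_reference=base.bmi_reference,
        disease_decrement={k: v * mult for k, v in base.disease_decrement.items()})


@dataclass
class UncertaintyResult:
    """Percentile summary of outcomes across PUA iterations."""

    summary: pd.DataFrame          # index: outcome; columns median, p2_5, p97_5
    draws: pd.DataFrame            # one row per iteration
    metadata: dict

    def __post_init__(self):
        bad = (self.summary["p2_5"] > self.summary["median"] + 1e-12) | \
              (self.summary["median"] > self.summary["p97_5"] + 1e-12)
        if bad.any():
            raise AssertionError("percentile ordering violated")


def _summarise(records: list[dict], metadata: dict) -> UncertaintyResult:
    draws = pd.DataFrame(records)
    summary = pd.DataFrame({
        "median": draws.median(),
        "p2_5": draws.quantile(0.025),
        "p97_5": draws.quantile(0.975),
    })
    return UncertaintyResult(summary, draws, metadata)


def run_pua(scenario: PolicyScenario | str, n_iter: int = 50,
            n_individuals: int = 2000, seed: int = 0,
            horizon: int | None = None,
            pop_config: PopulationConfig | None = None,
            epi_config: EpidemiologyConfig | None = None,
            econ_params: EconParameters | None = None,
            utility_params: UtilityParameters | None = None,
            direct_effects: bool | None = None,
            discount_rate: float | None = None) -> UncertaintyResult:
    """Probabilistic uncertainty analysis for one scenario."""
    res = run_batch([scenario], n_iter=n_iter, n_individuals=n_individuals,
                    seed=seed, horizon=horizon, pop_config=pop_config,
                    epi_config=epi_config, econ_params=econ_params,
                    utility_params=utility_params, direct_effects=direct_effects,
                    discount_rate=discount_rate)
    return next(iter(res.values()))


def run_batch(scenarios, n_iter: int = 50, n_individuals: int = 2000,
              seed: int = 0, horizon: int | None = None,
              pop_config: PopulationConfig | None = None,
              epi_config: EpidemiologyConfig | None = None,
              econ_params: EconParameters | None = None,
              utility_params: UtilityParameters | None = None,
              direct_effects: bool | None = None,
              discount_rate: float | None = None) -> dict:
    """PUA over several scenarios with parameter draws shared per iteration."""
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    pop_config = pop_config or PopulationConfig()
    pop_config = replace(pop_config, n_individuals=n_individuals)
    base_econ = econ_params or EconParameters()
    base_utils = utility_params or UtilityParameters()
    scenarios = [preset(s, pop_config.start_year) if isinstance(s, str) else s
                 for s in scenarios]

    records = {sc.name: [] for sc in scenarios}
    for it in range(n_iter):
        draw = sample_parameters(seed, it)
        sim = Microsimulation.from_configs(
            pop_config, epi_config, draw.risk_params, draw.elasticities,
            seed=np.random.SeedSequence([seed, it, 1]).generate_state(1)[0] % (2**31),
            horizon=horizon)
        arm_seed = np.random.SeedSequence([seed, it, 2]).generate_state(1)[0] % (2**31)
        econ = _scaled_econ(base_econ, draw.cost_multiplier)
        utils = _scaled_utils(base_utils, draw.utility_decrement_multiplier)
        base_hist = sim.run_arm("baseline", arm_seed)
        for sc in scenarios:
            sc_it = sc.with_overrides(pass_through=draw.pass_through) \
                if sc.has_price_mechanism else sc
            hist = sim.run_arm(sc_it, arm_seed, direct_effects=direct_effects)
            cmp = compare_arms(base_hist, hist, utils, econ, discount_rate)
            records[sc.name].append(cmp.outcome_vector())

    out = {}
    for sc in scenarios:
        meta = {"scenario": sc.name, "n_iter": n_iter,
                "n_individuals": n_individuals, "seed": seed,
                "direct_effects": (sc.direct_effects_enabled
                                   if direct_effects is None else direct_effects)}
        out[sc.name] = _summarise(records[sc.name], meta)
    return out


def structural_rerun(scenario: PolicyScenario | str, **kwargs) -> UncertaintyResult:
    """Re-run a scenario with direct SSB effects forced off (BMI-mediated
    pathways only), for side-by-side structural-uncertainty reporting."""
    kwargs["direct_effects"] = False
    result = run_pua(scenario, **kwargs)
    result.metadata["structural_rerun"] = True
    return result
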