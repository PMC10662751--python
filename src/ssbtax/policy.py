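"""Tax scenarios as operators on baseline beverage exposures.

Two mechanisms are modelled.  A *price* mechanism (ad valorem taxation)
raises consumer prices by statutory rate x pass-through and shifts beverage
volumes once, at the policy start, through the demand elasticity matrix
(optionally with SSB->juice substitution); volumes stay at the shifted
level for as long as the tax is in force.  A *reformulation* mechanism
(tiered taxation, or voluntary industry commitments) lowers the sugar
density of SSBs without changing volumes, phased in linearly.  Sugar intake
is always recomputed as volume x density.

The preset scenarios:

===================== ======================================================
baseline              no intervention
ad_valorem            20% tax on SSBs, 82% pass-through, substitution on
extended_ad_valorem   20% tax on SSBs and fruit juice, 82% pass-through
tiered                30% SSB sugar reduction phased in over 3 years
voluntary_reformulation  observed industry commitments: 2% per 6 years,
                      linearised and continuing over the horizon
max_impact            tiered reformulation plus the ad valorem price effect
===================== ======================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .demand import (DEFAULT_PASS_THROUGH, GOODS, ElasticityMatrix,
                     apply_demand_response, consumer_price_change,
                     default_elasticity_matrix)

PRESET_NAMES = ("baseline", "ad_valorem", "extended_ad_valorem", "tiered",
                "voluntary_reformulation", "max_impact")


@dataclass(frozen=True)
class PolicyScenario:
    """A tax scenario: which mechanism, how strong, from when."""

    name: str
    taxed_goods: frozenset = frozenset()
    statutory_rate: float = 0.0
    pass_through: float = DEFAULT_PASS_THROUGH
    reformulation_fraction: float = 0.0
    phase_in_years: int = 0
    reformulation_ongoing: bool = False  # linear decline continues past phase-in
    substitution_enabled: bool = True
    direct_effects_enabled: bool = True
    start_year: int = 2023
    elasticity_override: ElasticityMatrix | None = None

    def __post_init__(self):
        if not 0.0 <= self.reformulation_fraction <= 1.0:
            raise ValueError("reformulation fraction must lie in [0, 1]")
        if self.statutory_rate < 0 or self.pass_through < 0:
            raise ValueError("tax rate and pass-through must be >= 0")
        if self.phase_in_years < 0:
            raise ValueError("phase_in_years must be >= 0")

    @property
    def has_price_mechanism(self) -> bool:
        return self.statutory_rate > 0 and bool(self.taxed_goods)

    @property
    def has_reformulation(self) -> bool:
        return self.reformulation_fraction > 0

    def price_changes(self) -> np.ndarray:
        """Relative consumer price change per good (Δp/p)."""
        dp = np.zeros(len(GOODS))
        if self.has_price_mechanism:
            change = consumer_price_change(self.statutory_rate, self.pass_through)
            for good in self.taxed_goods:
                dp[GOODS.index(good)] = change
        return dp

    def reformulation_factor(self, year) -> np.ndarray:
        """Fraction of SSB sugar content removed by calendar ``year``."""
        t = np.asarray(year) - self.start_year
        if not self.has_reformulation:
            return np.zeros_like(t, dtype=float)
        phase = max(self.phase_in_years, 1)
        ramp = np.clip(t, 0, None) / phase
        if not self.reformulation_ongoing:
            ramp = np.minimum(ramp, 1.0)
        return np.minimum(self.reformulation_fraction * ramp, 1.0)

    def with_overrides(self, **kwargs) -> "PolicyScenario":
        return replace(self, **kwargs)


def preset(name: str, start_year: int = 2023) -> PolicyScenario:
    """Build one of the six preset scenarios."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {PRESET_NAMES}")
    if name == "baseline":
        return PolicyScenario("baseline", start_year=start_year)
    if name == "ad_valorem":
        return PolicyScenario("ad_valorem", taxed_goods=frozenset({"ssb"}),
                              statutory_rate=0.20, substitution_enabled=True,
                              start_year=start_year)
    if name == "extended_ad_valorem":
        # both goods taxed: both prices rise, cross-substitution switched off
        return PolicyScenario("extended_ad_valorem",
                              taxed_goods=frozenset({"ssb", "juice"}),
                              statutory_rate=0.20, substitution_enabled=False,
                              start_year=start_year)
    if name == "tiered":
        return PolicyScenario("tiered", reformulation_fraction=0.30,
                              phase_in_years=3, start_year=start_year)
    if name == "voluntary_reformulation":
        return PolicyScenario("voluntary_reformulation",
                              reformulation_fraction=0.02, phase_in_years=6,
                              reformulation_ongoing=True, start_year=start_year)
    # max_impact: tiered reformulation combined with the ad valorem price shift
    return PolicyScenario("max_impact", taxed_goods=frozenset({"ssb"}),
                          statutory_rate=0.20, substitution_enabled=True,
                          reformulation_fraction=0.30, phase_in_years=3,
                          start_year=start_year)


def _effective_elasticities(scenario: PolicyScenario,
                            elasticities: ElasticityMatrix | None) -> ElasticityMatrix:
    E = scenario.elasticity_override or elasticities or default_elasticity_matrix()
    if not scenario.substitution_enabled:
        E = E.without_substitution()
    return E


def scenario_volumes(ssb_ml, juice_ml, scenario: PolicyScenario,
                     elasticities: ElasticityMatrix | None = None,
                     year: int | None = None):
    """Beverage volumes under the scenario (price mechanism only).

    The demand response applies immediately and in full from the policy
    start year onward; reformulation leaves volumes untouched.
    """
    ssb = np.asarray(ssb_ml, dtype=float)
    juice = np.asarray(juice_ml, dtype=float)
    if not scenario.has_price_mechanism or (year is not None and year < scenario.start_year):
        return ssb.copy(), juice.copy()
    E = _effective_elasticities(scenario, elasticities)
    q = np.stack([ssb, juice, np.zeros_like(ssb)], axis=-1)
    shifted = apply_demand_response(q, scenario.price_changes(), E)
    return shifted[..., 0], shifted[..., 1]


def exposure_trajectory(individual, scenario: PolicyScenario,
                        elasticities: ElasticityMatrix | None = None,
                        years: int = 20, start_year: int | None = None):
    """Per-year counterfactual exposures for one individual or a population.

    Returns a dict of arrays over the horizon (leading axis = year):
    ``ssb_ml``, ``juice_ml``, ``sugar_g_ssb``, ``sugar_g_juice``.  The
    operator is pure: identical inputs give identical trajectories.
    """
    start_year = scenario.start_year if start_year is None else start_year
    if scenario.start_year < start_year:
        raise ValueError("scenario cannot start before the simulation start")
    get = (lambda f: getattr(individual, f)) if hasattr(individual, "ssb_ml") and \
        not hasattr(individual, "columns") else (lambda f: individual[f].to_numpy())
    ssb0, juice0 = np.asarray(get("ssb_ml"), float), np.asarray(get("juice_ml"), float)
    dens_ssb = np.asarray(get("sugar_density_ssb"), float)
    dens_juice = np.asarray(get("sugar_density_juice"), float)

    out = {k: [] for k in ("ssb_ml", "juice_ml", "sugar_g_ssb", "sugar_g_juice")}
    for t in range(years):
        year = start_year + t
        ssb, juice = scenario_volumes(ssb0, juice0, scenario, elasticities, year)
        rho = scenario.reformulation_factor(year)
        out["ssb_ml"].append(ssb)
        out["juice_ml"].append(juice)
        out["sugar_g_ssb"].append(ssb * dens_ssb * (1.0 - rho))
        out["sugar_g_juice"].append(juice * dens_juice)
    return {k: np.array(v) for k, v in out.items()}
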