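"""Exposure-to-disease risk translation.

Three pathways link the policy-induced exposure changes to disease risk:

1. BMI-mediated: sustained changes in beverage sugar intake shift BMI
   (linear dose-response, kg/m^2 per g/day), and BMI carries a per-unit
   relative risk for T2DM, CHD and stroke;
2. direct (BMI-independent) effects of SSB volume on T2DM and CHD risk,
   expressed per 250 ml serving/day and toggleable for structural
   uncertainty analyses;
3. prevalent T2DM as a risk factor for CHD, stroke and non-CVD mortality.

The pathways combine multiplicatively on the relative-risk scale.  Disease
probabilities for individuals are obtained by rescaling the stratum
incidence with individualised attributable fractions (each person's RR
relative to the stratum-mean RR), which preserves the stratum mean; the
potential impact fraction 1 - E[RR']/E[RR] summarises the same shift for
the cohort model.

All relative-risk defaults are placeholder point estimates with log-normal
uncertainty in the range reported by meta-analyses of prospective cohorts;
they are configuration, not fitted values, and should be confirmed against
the primary literature before substantive use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class LogNormalRR:
    """A relative risk with log-normal parameter uncertainty."""

    value: float
    log_sd: float = 0.0

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("relative risks must be > 0")
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")


def _rr(value, log_sd=0.0):
    return LogNormalRR(value, log_sd)


@dataclass
class RiskParameters:
    """Dose-response and relative-risk parameters of the exposure pathways.

    beta_sugar : kg/m^2 BMI change per 1 g/day sustained sugar-intake change.
    rr_bmi     : RR per 1 kg/m^2 of BMI, per disease.
    rr_ssb_direct : RR per serving/day of SSBs (T2DM and CHD only).
    rr_t2dm    : RR conferred by prevalent T2DM on CHD, stroke and non-CVD
                 mortality.
    lag_years  : exposure-to-outcome lag per disease; the exposure shift
                 ramps linearly across the lag window.
    bmi_ref    : reference (theoretical-minimum-risk) BMI for the RR scale.
    """

    beta_sugar: float = 0.02
    beta_sugar_sd: float = 0.005
    serving_ml: float = 250.0
    bmi_ref: float = 23.0
    ssb_ref_servings: float = 0.0
    rr_bmi: dict = field(default_factory=lambda: {
        "t2dm": _rr(1.15, 0.015), "chd": _rr(1.06, 0.010), "stroke": _rr(1.04, 0.010)})
    rr_ssb_direct: dict = field(default_factory=lambda: {
        "t2dm": _rr(1.13, 0.034), "chd": _rr(1.17, 0.030)})
    rr_t2dm: dict = field(default_factory=lambda: {
        "chd": _rr(2.0, 0.05), "stroke": _rr(2.0, 0.06), "non_cvd_mortality": _rr(1.7, 0.04)})
    lag_years: dict = field(default_factory=lambda: {"t2dm": 5, "chd": 5, "stroke": 5})
    bmi_lag_years: float = 5.0  # ramp used for the BMI itself (utility, obesity)

    def __post_init__(self):
        if self.beta_sugar < 0:
            raise ValueError("beta_sugar must be >= 0")
        if any(v < 0 for v in self.lag_years.values()):
            raise ValueError("lags must be >= 0")


def bmi_delta(sugar_delta, params: RiskParameters):
    """BMI change (kg/m^2) for a sustained sugar-intake change (g/day)."""
    return params.beta_sugar * np.asarray(sugar_delta, dtype=float)


def exposure_rr(bmi, ssb_ml, disease: str, params: RiskParameters,
                direct_effects: bool = True):
    """Exposure-only relative risk (BMI and, optionally, direct SSB effect).

    Excludes the prevalent-T2DM multiplier, which the simulation engines
    apply separately so it can be normalised against expected prevalence.
    """
    if disease not in params.rr_bmi:
        raise KeyError(f"no BMI relative risk for disease {disease!r}")
    rr = params.rr_bmi[disease].value ** (np.asarray(bmi, dtype=float) - params.bmi_ref)
    if direct_effects and disease in params.rr_ssb_direct:
        servings = np.asarray(ssb_ml, dtype=float) / params.serving_ml
        rr = rr * params.rr_ssb_direct[disease].value ** (servings - params.ssb_ref_servings)
    return rr


def individual_rr(ind, disease: str, params: RiskParameters,
                  direct_effects: bool = True, bmi_ref: float | None = None):
    """Full relative risk of one individual for ``disease``.

    Combines the BMI pathway, the direct SSB pathway (if enabled) and the
    prevalent-T2DM multiplier for CHD/stroke.  ``ind`` may be an
    :class:`~ssbtax.synthpop.Individual` or any object with ``bmi``,
    ``ssb_ml`` and ``t2dm`` attributes.
    """
    if bmi_ref is not None:
        params = RiskParameters(**{**params.__dict__, "bmi_ref": bmi_ref})
    rr = exposure_rr(ind.bmi, ind.ssb_ml, disease, params, direct_effects)
    if disease in ("chd", "stroke") and getattr(ind, "t2dm", False):
        rr = rr * params.rr_t2dm[disease].value
    return float(rr)


def calibrated_probability(p0: float, rr, reference_mean: float | None = None):
    """Per-individual probabilities from stratum incidence and relative risks.

    p_i = p0 * rr_i / mean(rr), capped at 1.  By default the mean is taken
    over the supplied RRs (so probabilities average exactly to ``p0``); the
    simulation engines pass the stratum-mean RR at baseline exposures as
    ``reference_mean`` so that a counterfactual arm realises the potential
    impact fraction in expectation.
    """
    rr = np.asarray(rr, dtype=float)
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if rr.size == 0:
        raise ValueError("empty stratum")
    mean = float(np.mean(rr)) if reference_mean is None else float(reference_mean)
    if mean <= 0:
        raise ValueError("mean relative risk must be > 0")
    p = p0 * rr / mean
    n_capped = int(np.sum(p > 1.0))
    if n_capped:
        warnings.warn(f"{n_capped} calibrated probabilities capped at 1", stacklevel=2)
    return np.minimum(p, 1.0)


def pif(baseline_rrs, counterfactual_rrs) -> float:
    """Potential impact fraction: 1 - mean(RR_counterfactual)/mean(RR_baseline)."""
    base = np.mean(np.asarray(baseline_rrs, dtype=float))
    cf = np.mean(np.asarray(counterfactual_rrs, dtype=float))
    if base == 0:
        raise ZeroDivisionError("baseline mean relative risk is zero")
    return 1.0 - cf / base
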