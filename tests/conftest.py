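"""Shared fixtures: small simulations and synthetic inputs built at test time."""

import numpy as np
import pytest

import ssbtax as st


@pytest.fixture(scope="session")
def epi():
    return st.generate_epidemiology()


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulation shared by read-only engine tests."""
    return st.Microsimulation.from_configs(
        st.PopulationConfig(n_individuals=4000), seed=11)


@pytest.fixture(scope="session")
def true_demand_params():
    from ssbtax.synthpop import default_demand_parameters
    return default_demand_parameters()


def make_history(**overrides):
    """A hand-built single-person History for economics arithmetic tests."""
    from ssbtax.microsim import History
    from ssbtax.policy import preset

    n = overrides.pop("n", 1)
    defaults = dict(
        sex_code=np.zeros(n, int),
        entry_year=np.full(n, 2023),
        age_entry=np.full(n, 40),
        bmi0=np.full(n, 24.0),
        ssb0=np.zeros(n),
        juice0=np.zeros(n),
        dens_ssb=np.full(n, 0.09),
        dens_juice=np.full(n, 0.10),
        onset_year={d: np.full(n, -1) for d in ("t2dm", "chd", "stroke")},
        death_year=np.full(n, -1),
        death_cause=np.zeros(n, int),
        aged_out_year=np.full(n, -1),
        scenario=preset("baseline"),
        elasticities=st.default_elasticity_matrix(),
        risk_params=st.RiskParameters(),
        start_year=2023,
        horizon=1,
    )
    defaults.update(overrides)
    return History(**defaults)
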