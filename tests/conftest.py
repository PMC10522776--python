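"""Shared fixtures: small synthetic studies and a quick model fit."""

import numpy as np
import pandas as pd
import pytest

import sexmort as sm


@pytest.fixture(scope="session")
def tiny_sim():
    """A small synthetic study: 8 countries, 12 years, one age group."""
    cfg = sm.SimulationConfig(n_countries=8, year_start=2000, year_end=2011, seed=123)
    totals = sm.simulate_total_mortality(cfg)
    truth = sm.simulate_truth(totals, cfg)
    obs = sm.simulate_observations(truth, cfg)
    return cfg, totals, truth, obs


@pytest.fixture(scope="session")
def tiny_fit(tiny_sim):
    """A short-chain fit of the tiny study (for structural checks, not accuracy)."""
    _, totals, _, obs = tiny_sim
    mc = sm.ModelConfig(seed=5, n_walkers=26, n_burn=200, n_steps=150)
    return sm.fit_model(obs, totals, mc)


@pytest.fixture()
def obs_frame():
    """A hand-written three-row observation frame with mixed source types."""
    return pd.DataFrame(
        {
            "country_code": ["AAA", "AAB", "AAC"],
            "ref_year": [1995.0, 2003.5, 2010.0],
            "age_group": ["0-4", "5-14", "15-24"],
            "source_type": ["VR", "FBH", "SBH"],
            "series_id": ["vr1", "dhs-2003", "sib-2010"],
            "sex_ratio_obs": [1.08, 1.21, 1.55],
            "log_se_sampling": [0.02, 0.09, 0.12],
            "deaths_male": [540.0, np.nan, np.nan],
            "deaths_female": [500.0, np.nan, np.nan],
        }
    )
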