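import numpy as np
import pandas as pd
import pytest

import heatqm as hq
from heatqm import health, series, synthdata

HIST = ("1993-01-01", "2004-12-31")
PROJ = ("2050-01-01", "2099-12-31")


@pytest.fixture(scope="session")
def obs_config():
    return hq.ObsTempConfig(seed=3)


@pytest.fixture(scope="session")
def obs(obs_config):
    """12 years of synthetic observed daily minimum temperature."""
    return hq.gen_observed_temperature(obs_config)


@pytest.fixture(scope="session")
def biased_pair(obs_config):
    """Hindcast/projection pair with additive -2 degC and 1.1x scale bias."""
    bias = hq.ModelBiasConfig(additive_bias=-2.0, scale_bias=1.1,
                              warming_trend=0.5, seed=7)
    return hq.gen_model_series(obs_config, bias, HIST, PROJ)


@pytest.fixture(scope="session")
def health_fit(obs):
    """Quasi-Poisson fit on counts generated with a known linear log-RR."""
    slope = 0.01
    gen = hq.HealthGenConfig(true_erf=lambda x: slope * (x - 7.0),
                             dispersion=1.3, seed=11)
    gen = synthdata.calibrate_baseline(obs, gen)
    counts = series.warm_season(hq.gen_ed_counts(obs, gen))
    spec = hq.HealthModelSpec(use_holidays=False)
    exposure = health.moving_average(obs, spec.lag_window)
    design = health.build_design(exposure, counts.index, spec)
    fit = health.fit_quasipoisson(counts, design)
    return {"fit": fit, "counts": counts, "slope": slope, "design": design}
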