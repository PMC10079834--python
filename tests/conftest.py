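import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from chamberflux.fluxfit import Deployment
from chamberflux.synthetic import CampaignConfig, TrueFluxModel, generate_campaign

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_deployment(
    slope_ppm_s=0.001,
    intercept_ppm=0.33,
    n=300,
    gas="n2o",
    noise_sd=0.0,
    seed=0,
    temp_k=313.15,
    press_kpa=20.0,
    area=0.05,
    volume=0.02,
    dep_id="T000",
    trace=None,
):
    if trace is not None:
        n = len(trace)
    t = np.arange(n, dtype=float)
    conc = np.asarray(trace, dtype=float) if trace is not None else intercept_ppm + slope_ppm_s * t
    if noise_sd:
        conc = conc + np.random.default_rng(seed).standard_normal(n) * noise_sd
    return Deployment(
        deployment_id=dep_id,
        chamber_id="CH1",
        gas=gas,
        time_s=t,
        mole_fraction_ppm=conc,
        cavity_temp_k=np.full(n, temp_k),
        cavity_press_kpa=np.full(n, press_kpa),
        collar_area_m2=area,
        volume_m3=volume,
        start_time=pd.Timestamp("2018-06-01 12:00:00"),
    )


@pytest.fixture(scope="session")
def reduced_campaign_config():
    """~10 deployments/day, one site year fragment, coarse sampling."""
    return CampaignConfig(
        seed=7,
        n_chambers=1,
        idle_minutes_per_cycle=132.5,
        start_date="2018-01-27",
        end_date="2018-03-27",
        sample_hz=0.2,
    )


@pytest.fixture(scope="session")
def noise_free_campaign(reduced_campaign_config):
    model = TrueFluxModel().flux_noise_free()
    return generate_campaign(reduced_campaign_config, model)


@pytest.fixture(scope="session")
def noisy_campaign(reduced_campaign_config):
    return generate_campaign(reduced_campaign_config, TrueFluxModel())
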