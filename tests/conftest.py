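import numpy as np
import pytest

from riversubsidy.metabolism import MetabolismParams, o2_saturation, simulate_diel_do
from riversubsidy.synthdata import ExperimentDesign, generate_drivers


@pytest.fixture(scope="session")
def one_day_drivers():
    """One day of 5-min light/temperature drivers."""
    t, light, temp = generate_drivers(1, 5.0)
    return t, temp, light


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


def simulate_day(gpp, er20, k, theta=1.045, noise_sd=0.0, seed=0, dt_min=5.0):
    """Forward-simulate one noisy mesocosm-day (shared test helper)."""
    t, light, temp = generate_drivers(1, dt_min)
    params = MetabolismParams(gpp_daily=gpp, er20=er20, theta=theta, k=k)
    sim = simulate_diel_do(params, t, temp, light, o0=o2_saturation(temp[0]))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sim.do_mgL = sim.do_mgL + rng.normal(0, noise_sd, sim.do_mgL.size)
    return sim
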