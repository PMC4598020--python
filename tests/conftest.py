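import pytest

import chamberflux as cf


@pytest.fixture
def noise_free_sim():
    """One colony, one light + one dark 3 h cycle, no noise, no drift."""
    colony = cf.ColonyTruth(
        colony_id="c0", surface_area_m2=0.0012,
        G_light=12.0, G_dark=6.0, P_N=5.0, R=4.0,
    )
    config = cf.SimulationConfig(colonies=[colony], noise_ta=0.0, noise_o2=0.0)
    return cf.simulate_incubation(config)


@pytest.fixture
def sample_interval():
    start = cf.WaterSample("ch1", "treatment", "light", 0.0, 2300.0, 200.0, 35.0, 28.0)
    end = cf.WaterSample("ch1", "treatment", "light", 3.0, 2280.0, 220.0, 35.0, 28.0)
    return cf.IncubationInterval(
        chamber_id="ch1", role="treatment", phase="light",
        start=start, end=end, V=1.0, rho=1.025, SA=0.0012,
    )
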