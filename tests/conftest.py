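import warnings

import numpy as np
import pytest

from eict import (
    AcquisitionSettings,
    choose_working_point,
    load_config,
    simulate_illumination_curve,
)

# the Gaussian fit to a near-trapezoid curve can report a poorly conditioned
# covariance; only the point estimate is used
warnings.filterwarnings("ignore", message="Covariance of the parameters")


@pytest.fixture(scope="session")
def cfg():
    return load_config()


@pytest.fixture(scope="session")
def geom(cfg):
    return cfg.geometry


@pytest.fixture(scope="session")
def detector(cfg):
    return cfg.detector


@pytest.fixture(scope="session")
def band20(cfg):
    return cfg.band("20um_slits")


@pytest.fixture(scope="session")
def band10(cfg):
    return cfg.band("10um_slits")


@pytest.fixture(scope="session")
def band5(cfg):
    return cfg.band("5um_slits")


I0_RATE = 1.0e4


@pytest.fixture(scope="session")
def curve_wp(cfg):
    """Illumination curve and 50% working point per band name (cached)."""
    cache = {}

    def get(band_name):
        if band_name not in cache:
            c = simulate_illumination_curve(
                cfg.geometry, cfg.band(band_name), cfg.detector, i0_rate=I0_RATE
            )
            wp = choose_working_point(c, cfg.working_point_fraction, cfg.flank)
            cache[band_name] = (c, wp)
        return cache[band_name]

    return get


@pytest.fixture()
def settings_clean():
    return AcquisitionSettings(i0_rate=I0_RATE, noise="none")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240507)
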