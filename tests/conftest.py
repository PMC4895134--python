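import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from skyillum.extension import extend_cie
from skyillum.fitting import load_cie_basis
from skyillum.pipeline import calibrate_campaign
from skyillum.spectra import Spectrum, Units
from skyillum.synthetic import SkySimConfig, generate_campaign

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20140701)


@pytest.fixture
def flat_spectrum():
    grid = np.arange(360.0, 831.0)
    return Spectrum(grid, np.full(grid.size, 5.0), Units.RELATIVE)


@pytest.fixture(scope="session")
def small_cfg():
    """A thinned campaign (5-minute cadence) for unit-level pipeline tests."""
    return SkySimConfig(seed=11, cadence_s=300.0, ephemeris_cadence_s=600.0)


@pytest.fixture(scope="session")
def small_campaign(small_cfg):
    return generate_campaign(small_cfg)


@pytest.fixture(scope="session")
def small_records(small_campaign):
    records, _ = calibrate_campaign(small_campaign)
    return records


@pytest.fixture(scope="session")
def default_campaign():
    """The full default study conditions (per-minute cadence, both sites)."""
    return generate_campaign(SkySimConfig(seed=0))


@pytest.fixture(scope="session")
def default_records(default_campaign):
    records, _ = calibrate_campaign(default_campaign)
    return records


@pytest.fixture(scope="session")
def extended_bases(default_records):
    cie = load_cie_basis()
    cie3r, cie3c, stages = extend_cie(default_records["rural"],
                                      default_records["city"], cie)
    return {"CIE": cie, "CIE+3R": cie3r, "CIE+3C": cie3c, "stages": stages}
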