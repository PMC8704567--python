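import numpy as np
import pytest
from hypothesis import settings

import windborne as wb

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uniform_field():
    """10 m/s westerly, 25 degC, calm vertical motion, equatorial box."""
    return wb.make_uniform_field(10.0, 0.0, 25.0, 0.0,
                                 extent=(140.0, 148.0, -2.0, 2.0), duration_h=48.0)


@pytest.fixture(scope="session")
def land_mask(uniform_field):
    return wb.LandMask.all_land(uniform_field.lats, uniform_field.lons)


@pytest.fixture(scope="session")
def smooth_field():
    return wb.make_smooth_field(seed=7, duration_h=48.0)


@pytest.fixture(scope="session")
def monsoon_one_leg():
    return wb.make_monsoon_scenario(seed=1, leg_count=1)


@pytest.fixture(scope="session")
def monsoon_two_leg():
    return wb.make_monsoon_scenario(seed=1, leg_count=2)


@pytest.fixture(scope="session")
def monsoon_two_leg_paths(monsoon_two_leg):
    field, truth, mask = monsoon_two_leg
    paths = wb.run_multileg_backward(*truth.expected_arrival_site,
                                     truth.expected_arrival_night, field, mask)
    return paths, truth, mask


@pytest.fixture(scope="session")
def climatology_decade():
    field = wb.make_climatology_field(seed=0)
    samples = wb.nightly_level_samples(field, wb.CLIMATOLOGY_SITES)
    return field, samples


def dusk_release(lon, lat, alt=1000.0, date="2021-01-10", direction="forward",
                 params=None):
    """ReleaseSpec at the nominal local takeoff time of `date` at `lon`."""
    params = params or wb.FlightParams()
    takeoff, _ = wb.night_window(date, lon, params)
    return wb.ReleaseSpec(lon, lat, takeoff, alt, direction)
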