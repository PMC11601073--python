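import numpy as np
import pandas as pd
import pytest

from dvmtrack import Cast, CastSeries, SimulationConfig
from dvmtrack.calibration import BinnedProfile

TZ = "-04:00"


def make_cast(cast_id, hour, depths, chl, day=6):
    """Cast on 2021-08-<day> at <hour>:00 local with chl as both channels."""
    return Cast(
        cast_id=cast_id,
        time=pd.Timestamp(f"2021-08-{day:02d}T{hour:02d}:00:00{TZ}"),
        depth_m=np.asarray(depths, dtype=float),
        fluorescence=np.asarray(chl, dtype=float),
        chl_ug_L=np.asarray(chl, dtype=float),
    )


def make_binned(values, bin_width=0.2, cast_id="p", hour=12):
    values = np.asarray(values, dtype=float)
    centers = (np.arange(values.size) + 0.5) * bin_width
    return BinnedProfile(
        cast_id=cast_id,
        time=pd.Timestamp(f"2021-08-06T{hour:02d}:00:00{TZ}"),
        bin_width_m=bin_width,
        bin_centers_m=centers,
        chl_ug_L=values,
        bottom_depth_m=values.size * bin_width,
    )


@pytest.fixture
def toy_series():
    """Two 3-depth casts an hour apart over a 6 m column."""
    casts = [
        make_cast("c0", 10, [0.5, 3.0, 5.5], [2.0, 5.0, 20.0]),
        make_cast("c1", 11, [0.5, 3.0, 5.5], [3.0, 6.0, 18.0]),
    ]
    return CastSeries(casts=casts, site_depth_m=6.0)


@pytest.fixture
def quiet_sim_config():
    """Noise-free default-world simulation."""
    return SimulationConfig(seed=0, obs_noise_cv=0.0, heterogeneity_cv=0.0)
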