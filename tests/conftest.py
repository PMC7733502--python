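import numpy as np
import pandas as pd
import pytest

from midwater.hydrography import DepthStrata, MeanProfile
from midwater.io import TransectMeta


def make_profile(depth_m, oxy=None, temp=None, sal=None, chla=None,
                 bin_width_m=5.0) -> MeanProfile:
    """Assemble a MeanProfile directly from value arrays (sd = 0, n = 1)."""
    depth_m = np.asarray(depth_m, dtype=float)
    data = {}
    for name, values in (
        ("oxy_umol_kg", oxy), ("temp_C", temp), ("sal_psu", sal),
        ("chla_mg_m3", chla),
    ):
        vals = (
            np.full_like(depth_m, np.nan)
            if values is None
            else np.asarray(values, dtype=float)
        )
        data[f"{name}_mean"] = vals
        data[f"{name}_sd"] = np.zeros_like(depth_m)
        data[f"{name}_n"] = np.ones_like(depth_m)
    table = pd.DataFrame(data, index=pd.Index(depth_m, name="depth_m"))
    return MeanProfile(bin_width_m=bin_width_m, table=table)


@pytest.fixture
def paper_strata() -> DepthStrata:
    """The published four-layer partition of the 0-1000 m column."""
    return DepthStrata(z1=92.0, z2=304.0, z3=503.0, z_max=1000.0)


@pytest.fixture
def simple_transects() -> list[TransectMeta]:
    out = []
    for station in ("A", "B"):
        for period in ("day", "night"):
            for depth in (100.0, 400.0, 700.0):
                out.append(
                    TransectMeta(
                        station=station,
                        deployment_id=f"{station}-{period}",
                        transect_depth_m=depth,
                        period=period,
                        duration_min=11.0,
                    )
                )
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
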