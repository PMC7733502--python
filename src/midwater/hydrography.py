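"""Mean hydrographic profiles and oxygen-defined habitat strata.

The water column is partitioned into four layers from the station-mean
oxygen profile: an upper layer (UL), an upper oxycline (UOC), the oxygen
minimum zone (OMZ) proper — the contiguous depth band where mean dissolved
oxygen falls below a threshold (default 60 µmol kg⁻¹) — and a lower
oxycline (LOC) extending to the bottom of the sampled range.  The OMZ
boundaries z2/z3 are the linear-interpolation crossing depths of the
threshold; the UL/UOC boundary z1 is either a configured constant or the
depth of the strongest thermal gradient.

Stratum membership is upper-inclusive: a depth exactly on a boundary
belongs to the layer whose *upper* (deeper) edge it closes, so z1 is still
UL, z2 is still UOC, and z3 is still OMZ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CtdCast

STRATA_NAMES = ("UL", "UOC", "OMZ", "LOC")

PROFILE_VARIABLES = ("temp_C", "sal_psu", "oxy_umol_kg", "chla_mg_m3")


@dataclass
class MeanProfile:
    """Mean ± SD of each CTD variable on a regular depth-bin grid.

    ``table`` is indexed by bin midpoint depth and has ``<var>_mean`` and
    ``<var>_sd`` columns plus ``<var>_n`` sample counts.  Bins with no data
    are simply absent from the index (never zero-filled).
    """

    bin_width_m: float
    table: pd.DataFrame

    @property
    def depth_m(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=float)

    def mean(self, variable: str) -> pd.Series:
        """Mean of ``variable`` vs depth, with empty bins dropped."""
        return self.table[f"{variable}_mean"].dropna()

    def sd(self, variable: str) -> pd.Series:
        return self.table[f"{variable}_sd"].dropna()

    def interp(self, variable: str, depth_m: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the mean profile at arbitrary depth(s)."""
        series = self.mean(variable)
        return np.interp(np.asarray(depth_m, dtype=float),
                         series.index.to_numpy(), series.to_numpy())


@dataclass
class DepthStrata:
    """The four oxygen-defined habitat layers partitioning [0, z_max].

    UL = [0, z1], UOC = (z1, z2], OMZ = (z2, z3], LOC = (z3, z_max].
    z2 and z3 are the threshold crossing depths of the mean oxygen profile.
    """

    z1: float
    z2: float
    z3: float
    z_max: float
    threshold_umol_kg: float = 60.0

    def __post_init__(self) -> None:
        if not (0 < self.z1 < self.z2 < self.z3 <= self.z_max):
            raise ValueError(
                f"strata boundaries must satisfy 0 < z1 < z2 < z3 <= z_max, got "
                f"({self.z1}, {self.z2}, {self.z3}, {self.z_max})"
            )

    @property
    def omz_mid_m(self) -> float:
        return 0.5 * (self.z2 + self.z3)

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {
            "UL": (0.0, self.z1),
            "UOC": (self.z1, self.z2),
            "OMZ": (self.z2, self.z3),
            "LOC": (self.z3, self.z_max),
        }

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"stratum": name, "upper_m": lo, "lower_m": hi}
            for name, (lo, hi) in self.bounds().items()
        ]
        df = pd.DataFrame(rows)
        df["threshold_umol_kg"] = self.threshold_umol_kg
        return df


def compute_mean_profile(
    casts: Sequence[CtdCast], bin_width_m: float = 5.0
) -> MeanProfile:
    """Pool all cast samples into regular depth bins and average.

    Samples are assigned to half-open bins [k·w, (k+1)·w) and reported at the
    bin midpoint; the SD uses the n−1 denominator (0 for single-sample bins).
    """
    if not casts:
        raise ValueError("compute_mean_profile requires at least one cast")
    if bin_width_m <= 0:
        raise ValueError("bin_width_m must be positive")
    frames = [
        pd.DataFrame(
            {
                "depth_m": c.depth_m,
                "temp_C": c.temp_C,
                "sal_psu": c.sal_psu,
                "oxy_umol_kg": c.oxy_umol_kg,
                "chla_mg_m3": c.chla_mg_m3,
            }
        )
        for c in casts
    ]
    pooled = pd.concat(frames, ignore_index=True)
    mid = np.floor(pooled["depth_m"] / bin_width_m) * bin_width_m + bin_width_m / 2
    pooled["bin_mid_m"] = mid
    out = {}
    grouped = pooled.groupby("bin_mid_m")
    for var in PROFILE_VARIABLES:
        agg = grouped[var].agg(["mean", "std", "count"])
        out[f"{var}_mean"] = agg["mean"]
        out[f"{var}_sd"] = agg["std"].where(agg["count"] > 1, 0.0)
        out[f"{var}_n"] = agg["count"]
    table = pd.DataFrame(out).sort_index()
    table.index.name = "depth_m"
    return MeanProfile(bin_width_m=bin_width_m, table=table)


def _crossing(d0: float, d1: float, o0: float, o1: float, thr: float) -> float:
    """Depth where a linear segment crosses the oxygen threshold."""
    return d0 + (o0 - thr) / (o0 - o1) * (d1 - d0)


def detect_omz(
    profile: MeanProfile,
    threshold_umol_kg: float = 60.0,
    z1: float = 92.0,
    z_max: float | None = None,
) -> DepthStrata | None:
    """Locate the OMZ on the mean oxygen profile and build the four strata.

    All contiguous depth regions with mean oxygen below the threshold are
    found; the one containing the global oxygen minimum is taken as the OMZ
    (a secondary shallow minimum is deliberately ignored).  z2/z3 come from
    linear interpolation between the grid points straddling the threshold.
    Returns None when oxygen never drops below the threshold.
    """
    oxy = profile.mean("oxy_umol_kg")
    if len(oxy) < 3:
        raise ValueError("oxygen must be defined on at least 3 grid points")
    depths = oxy.index.to_numpy(dtype=float)
    values = oxy.to_numpy(dtype=float)
    below = values < threshold_umol_kg
    if not below.any():
        return None
    imin = int(np.argmin(values))
    # walk outward from the global minimum to the edges of its region
    lo = imin
    while lo > 0 and below[lo - 1]:
        lo -= 1
    hi = imin
    while hi < len(values) - 1 and below[hi + 1]:
        hi += 1
    if lo > 0:
        z2 = _crossing(depths[lo - 1], depths[lo], values[lo - 1], values[lo],
                       threshold_umol_kg)
    else:
        z2 = depths[0]
    if hi < len(values) - 1:
        z3 = _crossing(depths[hi], depths[hi + 1], values[hi], values[hi + 1],
                       threshold_umol_kg)
    else:
        z3 = depths[-1]
    if z_max is None:
        # default to the deep edge of the last sampled bin
        z_max = float(depths[-1] + profile.bin_width_m / 2)
    return DepthStrata(
        z1=float(z1), z2=float(z2), z3=float(z3), z_max=float(z_max),
        threshold_umol_kg=float(threshold_umol_kg),
    )


def define_ul_boundary(
    profile: MeanProfile,
    method: str = "fixed",
    fixed_m: float = 92.0,
    search_max_m: float = 200.0,
) -> float:
    """Depth of the UL/UOC boundary z1.

    ``fixed`` returns the configured constant (the survey convention when the
    boundary is set from mean hydrographic conditions).  ``max-gradient``
    returns the depth of maximum |dT/dz| within the upper ``search_max_m``.
    """
    if method == "fixed":
        return float(fixed_m)
    if method != "max-gradient":
        raise ValueError(f"unknown UL boundary method {method!r}")
    temp = profile.mean("temp_C")
    shallow = temp[temp.index <= search_max_m]
    if len(shallow) < 3:
        raise ValueError("temperature must be defined near the surface")
    depths = shallow.index.to_numpy(dtype=float)
    grad = np.gradient(shallow.to_numpy(dtype=float), depths)
    if np.max(np.abs(grad)) < 1e-6:
        raise ValueError("no thermocline: temperature profile is isothermal")
    return float(depths[int(np.argmax(np.abs(grad)))])


def assign_stratum(depth_m: float, strata: DepthStrata) -> str:
    """Map a depth to its habitat stratum (upper-inclusive boundaries)."""
    if depth_m < 0:
        raise ValueError(f"depth must be non-negative, got {depth_m}")
    if depth_m > strata.z_max:
        raise ValueError(
            f"depth {depth_m} m exceeds the sampled range (z_max = {strata.z_max} m)"
        )
    if depth_m <= strata.z1:
        return "UL"
    if depth_m <= strata.z2:
        return "UOC"
    if depth_m <= strata.z3:
        return "OMZ"
    return "LOC"
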