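"""Counts → rates → volumetric abundances for timed video transects.

A towed camera samples an unknown water volume per minute.  Counting a
slow-swimming reference taxon (pelagic worms, genus *Poeobius*) on the video
while a co-deployed quantitative particle profiler measures the same taxon's
true concentration gives a calibration factor F (m³ imaged per minute of
towing).  With F in hand, a transect of duration t min samples V = F·t m³,
and a raw count n becomes a concentration n / V × 1000 ind / 1000 m³ — the
standard unit for midwater video surveys.

The calibration estimator here is a pooled ratio,

    F̂ = Σᵢ nᵢ / Σᵢ (tᵢ · cᵢ),

with nᵢ the reference count, tᵢ the duration and cᵢ the profiler
concentration (ind m⁻³) matched to transect i.  It equals the spec of
"(total count / total minutes) ÷ duration-weighted mean concentration", is
insensitive to how a tow is split into sub-transects, and tolerates
zero-count transects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AnnotationRecord, ParticleProfile, TransectMeta

TRANSECT_KEY = ["station", "deployment_id", "transect_depth_m", "period"]


@dataclass(frozen=True)
class CalibrationFactor:
    """Water volume imaged per minute of towing."""

    volume_per_minute_m3: float
    source: str = "configured"  # or "estimated"
    reference_taxon: str | None = None

    def __post_init__(self) -> None:
        if self.volume_per_minute_m3 <= 0:
            raise ValueError("volume_per_minute_m3 must be > 0")


def aggregate_counts(
    annotations: Iterable[AnnotationRecord],
    transects: Sequence[TransectMeta],
    taxa: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tally annotation events per taxon × transect, zero-filled.

    Absence of a taxon from a sampled transect is a true zero for the
    abundance math, so every (transect, taxon) combination appears in the
    output with count ≥ 0.  ``taxa`` fixes the analysis taxon list; by
    default it is the sorted set of taxa seen in the annotations.
    """
    ann = pd.DataFrame(
        [
            {
                "station": a.station,
                "deployment_id": a.deployment_id,
                "transect_depth_m": a.transect_depth_m,
                "period": a.period,
                "taxon": a.taxon,
            }
            for a in annotations
        ]
    )
    if taxa is None:
        taxa = sorted(ann["taxon"].unique()) if len(ann) else []
    meta = pd.DataFrame(
        [
            {
                "station": t.station,
                "deployment_id": t.deployment_id,
                "transect_depth_m": t.transect_depth_m,
                "period": t.period,
            }
            for t in transects
        ]
    )
    grid = meta.merge(pd.DataFrame({"taxon": list(taxa)}), how="cross")
    if len(ann):
        tally = (
            ann.groupby(TRANSECT_KEY + ["taxon"]).size().rename("count").reset_index()
        )
        out = grid.merge(tally, on=TRANSECT_KEY + ["taxon"], how="left")
        out["count"] = out["count"].fillna(0).astype(int)
    else:
        out = grid
        out["count"] = 0
    return out.sort_values(TRANSECT_KEY + ["taxon"], ignore_index=True)


def match_reference_concentration(
    profile: ParticleProfile | pd.DataFrame,
    depth_m: float,
    halfwidth_m: float = 25.0,
    column: str = "conc_per_m3",
) -> float:
    """Profiler concentration averaged over ``depth_m ± halfwidth_m``.

    Accepts either a ParticleProfile-like object (bin midpoints used) or a
    DataFrame with ``depth_m`` and a concentration column.  Returns NaN when
    no profiler bin falls inside the window (the transect then drops out of
    the calibration).
    """
    if isinstance(profile, pd.DataFrame):
        depths = profile["depth_m"].to_numpy(dtype=float)
        conc = profile[column].to_numpy(dtype=float)
    else:
        depths = profile.depth_mid_m
        conc = getattr(profile, column)
    inside = np.abs(depths - depth_m) <= halfwidth_m
    if not inside.any():
        return float("nan")
    return float(np.nanmean(conc[inside]))


def estimate_calibration(
    reference: pd.DataFrame,
    reference_taxon: str = "Poeobius",
) -> CalibrationFactor:
    """Estimate the volume-per-minute factor from a reference taxon.

    ``reference`` needs one row per transect with columns ``count``,
    ``duration_min`` and ``conc_per_m3`` (the profiler concentration matched
    to the transect depth).  Rows without a concentration match (NaN) or with
    non-positive concentration are excluded.

    Raises ValueError when every usable reference count is zero — the signal
    to fall back to a configured factor.
    """
    usable = reference.dropna(subset=["conc_per_m3"])
    usable = usable[usable["conc_per_m3"] > 0]
    if len(usable) == 0 or usable["count"].sum() <= 0:
        raise ValueError(
            f"cannot estimate calibration: no usable {reference_taxon} "
            "reference counts"
        )
    total_count = float(usable["count"].sum())
    weighted_conc_minutes = float(
        (usable["duration_min"] * usable["conc_per_m3"]).sum()
    )
    return CalibrationFactor(
        volume_per_minute_m3=total_count / weighted_conc_minutes,
        source="estimated",
        reference_taxon=reference_taxon,
    )


def to_concentration(
    counts: pd.DataFrame,
    transects: Sequence[TransectMeta],
    factor: CalibrationFactor,
) -> pd.DataFrame:
    """Convert zero-filled counts to rates and volumetric concentrations.

    Adds ``duration_min``, ``rate_per_min`` (= count / duration),
    ``sampled_volume_m3`` (= F × duration) and ``concentration_per_1000m3``
    (= count / volume × 1000).
    """
    meta = pd.DataFrame(
        [
            {
                "station": t.station,
                "deployment_id": t.deployment_id,
                "transect_depth_m": t.transect_depth_m,
                "period": t.period,
                "duration_min": t.duration_min,
            }
            for t in transects
        ]
    )
    out = counts.merge(meta, on=TRANSECT_KEY, how="left", validate="many_to_one")
    if out["duration_min"].isna().any():
        missing = out[out["duration_min"].isna()].iloc[0]
        raise ValueError(
            "count row references unknown transect "
            f"({missing['station']}, {missing['deployment_id']}, "
            f"{missing['transect_depth_m']}, {missing['period']})"
        )
    out["rate_per_min"] = out["count"] / out["duration_min"]
    out["sampled_volume_m3"] = factor.volume_per_minute_m3 * out["duration_min"]
    out["concentration_per_1000m3"] = out["count"] / out["sampled_volume_m3"] * 1000.0
    return out
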