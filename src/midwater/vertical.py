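"""Per-taxon vertical distributions, weighted mean depths and migration tests.

The weighted mean depth (WMD) of a taxon is the abundance-weighted mean of
its observation depths,

    WMD = Σᵢ aᵢ zᵢ / Σᵢ aᵢ,

with aᵢ the concentration at transect depth zᵢ.  Diel vertical migration is
flagged by a two-sided paired t-test on per-station (day − night) WMD
differences: each station that sampled both periods contributes one pair.
Taxa with a bimodal vertical distribution are first split at a configured
depth into shallow/deep groups so that a single WMD per group is meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TaxonVerticalProfile:
    """Day or night vertical abundance structure of one taxon.

    ``station_table`` is indexed by transect depth with one column per
    station; NaN marks depths a station did not sample (never imputed as
    zero), while sampled-but-empty transects carry a true 0.
    """

    taxon: str
    period: str
    station_table: pd.DataFrame

    @property
    def pooled(self) -> pd.Series:
        """Mean concentration per depth over the stations sampling it."""
        return self.station_table.mean(axis=1, skipna=True).dropna()

    @property
    def depths(self) -> np.ndarray:
        return self.station_table.index.to_numpy(dtype=float)


@dataclass(frozen=True)
class SplitRule:
    """Depth at which a bimodal taxon is cut into shallow and deep groups."""

    taxon: str
    split_depth_m: float
    shallow_label: str = "shallow"
    deep_label: str = "deep"


@dataclass
class DvmTestResult:
    """Outcome of the paired day/night WMD comparison for one taxon."""

    taxon: str
    n_pairs: int
    t_stat: float
    p_value: float
    significant: bool
    direction: int  # sign of mean (day − night) WMD; +1 = deeper by day
    mean_diff_m: float
    status: str = "ok"  # or "insufficient pairs"


def build_profiles(
    abundances: pd.DataFrame,
) -> dict[tuple[str, str], TaxonVerticalProfile]:
    """Pivot the abundance table into per-(taxon, period) station × depth grids.

    Expects the zero-filled output of :func:`midwater.abundance.to_concentration`.
    Duplicate deployments of one station at the same depth and period are
    averaged.  Pooled means later exclude stations that did not sample a
    depth, rather than imputing zeros.
    """
    profiles: dict[tuple[str, str], TaxonVerticalProfile] = {}
    for (taxon, period), grp in abundances.groupby(["taxon", "period"], sort=True):
        table = grp.pivot_table(
            values="concentration_per_1000m3",
            index="transect_depth_m",
            columns="station",
            aggfunc="mean",
        ).sort_index()
        profiles[(taxon, period)] = TaxonVerticalProfile(
            taxon=taxon, period=period, station_table=table
        )
    return profiles


def weighted_mean_depth(
    depths_m: Sequence[float], abundances: Sequence[float]
) -> float:
    """Abundance-weighted mean depth; NaN when total abundance is zero."""
    z = np.asarray(depths_m, dtype=float)
    a = np.asarray(abundances, dtype=float)
    if z.shape != a.shape:
        raise ValueError("depths and abundances must have equal length")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total == 0:
        return float("nan")
    return float((a * z).sum() / total)


def station_wmds(profile: TaxonVerticalProfile) -> pd.Series:
    """Per-station WMD; NaN where the taxon was absent at that station."""
    out = {}
    for station in profile.station_table.columns:
        col = profile.station_table[station].dropna()
        if len(col) == 0:
            out[station] = float("nan")
        else:
            out[station] = weighted_mean_depth(col.index.to_numpy(), col.to_numpy())
    return pd.Series(out, name=f"{profile.taxon}:{profile.period}")


def apply_split(
    profile: TaxonVerticalProfile, rule: SplitRule
) -> tuple[TaxonVerticalProfile, TaxonVerticalProfile]:
    """Cut a profile at the split depth into shallow (≤) and deep (>) groups.

    Group names suffix the taxon label.  The split depth must lie strictly
    inside the sampled depth range; a group left with no abundance simply
    yields NaN WMDs downstream (taxon absent in that group).
    """
    depths = profile.depths
    if not (depths.min() < rule.split_depth_m < depths.max()):
        raise ValueError(
            f"split depth {rule.split_depth_m} m is outside the sampled range "
            f"[{depths.min()}, {depths.max()}] m"
        )
    shallow_mask = profile.station_table.index <= rule.split_depth_m
    shallow = TaxonVerticalProfile(
        taxon=f"{profile.taxon}_{rule.shallow_label}",
        period=profile.period,
        station_table=profile.station_table.loc[shallow_mask],
    )
    deep = TaxonVerticalProfile(
        taxon=f"{profile.taxon}_{rule.deep_label}",
        period=profile.period,
        station_table=profile.station_table.loc[~shallow_mask],
    )
    return shallow, deep


def dvm_test(
    day_wmds: pd.Series,
    night_wmds: pd.Series,
    alpha: float = 0.05,
    min_pairs: int = 3,
    taxon: str = "",
) -> DvmTestResult:
    """Two-sided paired t-test of per-station day vs night WMDs.

    Pairs are stations with a defined WMD in both periods.  Fewer than
    ``min_pairs`` pairs yields status ``"insufficient pairs"`` and is never
    significant (low sample sizes cannot support a migration call).  A
    zero-variance set of differences degenerates to t = 0, p = 1 when all
    differences vanish, and to |t| = ∞, p = 0 for a constant nonzero shift.
    """
    paired = pd.concat({"day": day_wmds, "night": night_wmds}, axis=1).dropna()
    n = len(paired)
    if n < min_pairs:
        return DvmTestResult(
            taxon=taxon, n_pairs=n, t_stat=float("nan"), p_value=float("nan"),
            significant=False, direction=0, mean_diff_m=float("nan"),
            status="insufficient pairs",
        )
    diffs = (paired["day"] - paired["night"]).to_numpy(dtype=float)
    mean_diff = float(diffs.mean())
    if float(diffs.std(ddof=1)) == 0.0:
        if mean_diff == 0.0:
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat, p_value = math.copysign(math.inf, mean_diff), 0.0
    else:
        t_stat, p_value = stats.ttest_rel(paired["day"], paired["night"])
        t_stat, p_value = float(t_stat), float(p_value)
    return DvmTestResult(
        taxon=taxon,
        n_pairs=n,
        t_stat=t_stat,
        p_value=p_value,
        significant=bool(p_value < alpha),
        direction=int(np.sign(mean_diff)),
        mean_diff_m=mean_diff,
    )


def wmd_table(
    profiles: Mapping[tuple[str, str], TaxonVerticalProfile],
) -> pd.DataFrame:
    """Long table of per-station and pooled WMDs for every taxon × period."""
    rows = []
    for (taxon, period), profile in sorted(profiles.items()):
        per_station = station_wmds(profile)
        for station, wmd in per_station.items():
            col = profile.station_table[station].dropna()
            rows.append(
                {
                    "taxon": taxon,
                    "period": period,
                    "station": station,
                    "wmd_m": wmd,
                    "total_abundance": float(col.sum()) if len(col) else 0.0,
                }
            )
        pooled = profile.pooled
        rows.append(
            {
                "taxon": taxon,
                "period": period,
                "station": "POOLED",
                "wmd_m": weighted_mean_depth(pooled.index.to_numpy(), pooled.to_numpy())
                if len(pooled)
                else float("nan"),
                "total_abundance": float(pooled.sum()),
            }
        )
    return pd.DataFrame(rows)


def dvm_tests_table(
    profiles: Mapping[tuple[str, str], TaxonVerticalProfile],
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Run the paired day/night test for every taxon with both periods.

    Adds a Benjamini–Hochberg adjusted p-value column for transparency; the
    migration flag itself follows the per-taxon uncorrected rule.
    """
    taxa = sorted({taxon for taxon, _ in profiles})
    results: list[DvmTestResult] = []
    for taxon in taxa:
        day = profiles.get((taxon, "day"))
        night = profiles.get((taxon, "night"))
        if day is None or night is None:
            results.append(
                DvmTestResult(
                    taxon=taxon, n_pairs=0, t_stat=float("nan"),
                    p_value=float("nan"), significant=False, direction=0,
                    mean_diff_m=float("nan"), status="insufficient pairs",
                )
            )
            continue
        results.append(
            dvm_test(
                station_wmds(day), station_wmds(night),
                alpha=alpha, min_pairs=min_pairs, taxon=taxon,
            )
        )
    df = pd.DataFrame([vars(r) for r in results])
    df["p_adj_bh"] = float("nan")
    valid = df["p_value"].notna()
    if valid.any():
        df.loc[valid, "p_adj_bh"] = multipletests(
            df.loc[valid, "p_value"], method="fdr_bh"
        )[1]
    return df
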