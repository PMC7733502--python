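"""Five-way OMZ-relative distribution typing of taxa, with migration flag.

Each taxon's pooled vertical profile is compared against the four habitat
strata and assigned one of five distribution types:

    1  peak concentration inside the OMZ
    2  bimodal — peaks above *and* below the OMZ with a depleted OMZ trough
    3  peak above the OMZ (UL or UOC)
    4  peak below the OMZ (LOC)
    5  no obvious peak (no stratum clearly dominates)

The modifier ``M`` marks taxa whose day and night weighted mean depths
differ significantly (diel vertical migrators); it attaches independently of
the type.  Migrators are typed from their *daytime* profile, because
migration smears the night distribution toward the surface and the daytime
residence depth is what characterises the taxon's relation to the OMZ.

The type definitions are verbal in origin; they are operationalised here by
three explicit, configurable rules:

* peak stratum = the stratum with the highest mean concentration across the
  transect depths falling inside it (a concentration basis, so unequal
  stratum thickness does not bias the peak);
* evenness: if the peak stratum's share of the summed stratum means is below
  a threshold (default 0.40), no stratum dominates → Type 5;
* bimodality: flanking concentration maxima above z2 and below z3 whose OMZ
  trough is at most ``trough_ratio`` (default 0.25) of the smaller flanking
  peak → Type 2, checked before all other rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .hydrography import DepthStrata, STRATA_NAMES, assign_stratum
from .vertical import DvmTestResult, TaxonVerticalProfile

_PEAK_TO_TYPE = {"OMZ": 1, "UL": 3, "UOC": 3, "LOC": 4}


@dataclass
class DistributionTypeResult:
    """Type 1–5 assignment (or unclassified) plus migration flag and evidence."""

    taxon: str
    dist_type: int | None
    migratory: bool
    peak_stratum: str | None
    stratum_means: dict[str, float]
    stratum_shares: dict[str, float]
    bimodal: bool
    bimodality_score: float
    status: str = "ok"  # or "unclassified - low n"


def stratum_stats(
    pooled: pd.Series, strata: DepthStrata
) -> tuple[dict[str, float], dict[str, float]]:
    """Mean concentration and share per stratum from a pooled profile.

    ``pooled`` is indexed by transect depth.  Strata containing no sampled
    depth get NaN means and are excluded from the share normalisation; an
    all-zero profile yields all-zero shares.
    """
    means: dict[str, float] = {}
    for name in STRATA_NAMES:
        means[name] = float("nan")
    labels = [assign_stratum(float(d), strata) for d in pooled.index]
    grouped = pooled.groupby(pd.Series(labels, index=pooled.index)).mean()
    for name, value in grouped.items():
        means[name] = float(value)
    total = np.nansum([v for v in means.values() if not np.isnan(v)])
    shares = {
        name: (0.0 if np.isnan(v) or total == 0 else v / total)
        for name, v in means.items()
    }
    return means, shares


def detect_bimodality(
    pooled: pd.Series, strata: DepthStrata, trough_ratio: float = 0.25
) -> tuple[bool, float]:
    """Is the profile depleted inside the OMZ but peaked on both flanks?

    True iff the maxima above z2 and below z3 are both positive and the
    minimum concentration at OMZ depths is below ``trough_ratio`` times the
    smaller flanking maximum.  The score 1 − trough/smaller-peak approaches
    1 for a fully evacuated OMZ and 0 for a flat profile.
    """
    depths = pooled.index.to_numpy(dtype=float)
    above = pooled[depths <= strata.z2]
    below = pooled[depths > strata.z3]
    inside = pooled[(depths > strata.z2) & (depths <= strata.z3)]
    if len(above) == 0 or len(below) == 0 or len(inside) == 0:
        return False, 0.0
    peak_above = float(above.max())
    peak_below = float(below.max())
    smaller_peak = min(peak_above, peak_below)
    if smaller_peak <= 0:
        return False, 0.0
    trough = float(inside.min())
    score = max(0.0, 1.0 - trough / smaller_peak)
    return bool(trough < trough_ratio * smaller_peak), score


def classify_distribution_type(
    taxon: str,
    pooled: pd.Series,
    strata: DepthStrata,
    dvm: DvmTestResult | None = None,
    evenness_threshold: float = 0.40,
    trough_ratio: float = 0.25,
    total_observations: int | None = None,
    min_observations: int = 20,
) -> DistributionTypeResult:
    """Assign one distribution type to a taxon from its pooled profile.

    Decision order: low observation count → unclassified; bimodal → Type 2;
    no dominant stratum → Type 5; otherwise the peak stratum maps OMZ → 1,
    UL/UOC → 3, LOC → 4.  The migration flag comes solely from a significant
    DVM test result.
    """
    migratory = bool(dvm.significant) if dvm is not None else False
    means, shares = stratum_stats(pooled, strata)
    bimodal, score = detect_bimodality(pooled, strata, trough_ratio)
    if total_observations is not None and total_observations < min_observations:
        return DistributionTypeResult(
            taxon=taxon, dist_type=None, migratory=migratory,
            peak_stratum=None, stratum_means=means, stratum_shares=shares,
            bimodal=bimodal, bimodality_score=score,
            status="unclassified - low n",
        )
    if bimodal:
        dist_type: int | None = 2
        peak = None
    else:
        defined = {k: v for k, v in means.items() if not np.isnan(v)}
        if not defined or max(shares.values()) == 0:
            return DistributionTypeResult(
                taxon=taxon, dist_type=None, migratory=migratory,
                peak_stratum=None, stratum_means=means, stratum_shares=shares,
                bimodal=False, bimodality_score=score,
                status="unclassified - no abundance",
            )
        peak = max(defined, key=lambda k: defined[k])
        if shares[peak] < evenness_threshold:
            dist_type = 5
            peak = None
        else:
            dist_type = _PEAK_TO_TYPE[peak]
    return DistributionTypeResult(
        taxon=taxon, dist_type=dist_type, migratory=migratory,
        peak_stratum=peak, stratum_means=means, stratum_shares=shares,
        bimodal=bimodal, bimodality_score=score,
    )


def combined_pooled_profile(
    day: TaxonVerticalProfile | None, night: TaxonVerticalProfile | None
) -> pd.Series:
    """Mean of the day and night pooled profiles over the union of depths."""
    parts = [p.pooled for p in (day, night) if p is not None]
    if not parts:
        return pd.Series(dtype=float)
    return pd.concat(parts, axis=1).mean(axis=1, skipna=True).sort_index()


def classify_taxa(
    profiles: Mapping[tuple[str, str], TaxonVerticalProfile],
    strata: DepthStrata,
    dvm_results: Mapping[str, DvmTestResult] | None = None,
    counts_per_taxon: Mapping[str, int] | None = None,
    evenness_threshold: float = 0.40,
    trough_ratio: float = 0.25,
    min_observations: int = 20,
) -> pd.DataFrame:
    """Classify every taxon present in the profile set.

    Non-migrants are typed on the day+night combined pooled profile;
    taxa with a significant DVM test on their daytime profile (falling back
    to whichever period exists).
    """
    dvm_results = dvm_results or {}
    taxa = sorted({taxon for taxon, _ in profiles})
    rows = []
    for taxon in taxa:
        day = profiles.get((taxon, "day"))
        night = profiles.get((taxon, "night"))
        dvm = dvm_results.get(taxon)
        migratory = bool(dvm.significant) if dvm is not None else False
        if migratory and day is not None:
            pooled = day.pooled
        else:
            pooled = combined_pooled_profile(day, night)
        result = classify_distribution_type(
            taxon=taxon,
            pooled=pooled,
            strata=strata,
            dvm=dvm,
            evenness_threshold=evenness_threshold,
            trough_ratio=trough_ratio,
            total_observations=(
                counts_per_taxon.get(taxon) if counts_per_taxon else None
            ),
            min_observations=min_observations,
        )
        row = {
            "taxon": result.taxon,
            "dist_type": result.dist_type,
            "migratory": result.migratory,
            "label": (
                f"{result.dist_type}{'M' if result.migratory else ''}"
                if result.dist_type is not None
                else result.status
            ),
            "peak_stratum": result.peak_stratum,
            "bimodal": result.bimodal,
            "bimodality_score": result.bimodality_score,
            "status": result.status,
        }
        for name in STRATA_NAMES:
            row[f"mean_conc_{name}"] = result.stratum_means[name]
            row[f"share_{name}"] = result.stratum_shares[name]
        rows.append(row)
    return pd.DataFrame(rows)
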