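"""Readers and writers for the delimited-text tables of a towed-camera survey.

Four input tables drive the analysis, all comma-separated with a mandatory
header row, UTF-8, ``.`` decimal separator and no quoting of numerics:

``annotations.csv``
    One row per observed organism (VARS-style event log): station,
    deployment, target transect depth, day/night period, taxon label, and an
    ``in_transect`` flag distinguishing organisms seen during a timed
    transect from those seen while the camera was ascending or descending
    between transects.  Only in-transect observations enter the analysis.
``transects.csv``
    One row per timed horizontal tow at a target depth; duration and tow
    speed define the sampled volume once a volume-per-minute calibration
    factor is known.
``ctd.csv``
    Depth-gridded temperature, salinity, dissolved oxygen and
    chlorophyll-a per CTD cast.
``particles.csv``
    Depth-binned particle and copepod concentrations from an optical
    profiler (UVP-style export).

Depths are metres below the surface, positive downward.  Organisms are keyed
to the *target* depth of their transect; real tows wobble around the target,
but the target depth is the analysis coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PERIODS = ("day", "night")

#: column sets required in the four input files
ANNOTATION_COLUMNS = (
    "station", "deployment_id", "transect_depth_m", "period", "taxon", "in_transect",
)
TRANSECT_COLUMNS = (
    "station", "deployment_id", "transect_depth_m", "period", "duration_min",
)
CTD_COLUMNS = (
    "station", "cast_id", "depth_m", "temp_C", "sal_psu", "oxy_umol_kg", "chla_mg_m3",
)
PARTICLE_COLUMNS = (
    "station", "depth_bin_top_m", "depth_bin_bottom_m",
    "small_particles_per_L", "large_particles_per_L", "copepods_per_m3",
)

DEFAULT_TOW_SPEED_M_S = 0.51


class FormatError(ValueError):
    """A table violates the on-disk contract (missing column, bad value, ...)."""


@dataclass(frozen=True)
class AnnotationRecord:
    """A single observed organism tied to a transect and a taxon."""

    station: str
    deployment_id: str
    transect_depth_m: float
    period: str
    taxon: str
    in_transect: bool = True
    timestamp: str | None = None

    @property
    def transect_key(self) -> tuple[str, str, float, str]:
        return (self.station, self.deployment_id, self.transect_depth_m, self.period)


@dataclass(frozen=True)
class TransectMeta:
    """A timed horizontal tow at a target depth, defining a sampled volume."""

    station: str
    deployment_id: str
    transect_depth_m: float
    period: str
    duration_min: float
    tow_speed_m_s: float = DEFAULT_TOW_SPEED_M_S

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise FormatError(f"duration_min must be > 0, got {self.duration_min}")
        if self.tow_speed_m_s <= 0:
            raise FormatError(f"tow_speed_m_s must be > 0, got {self.tow_speed_m_s}")
        if self.transect_depth_m <= 0:
            raise FormatError(f"transect_depth_m must be > 0, got {self.transect_depth_m}")
        if self.period not in PERIODS:
            raise FormatError(f"period must be one of {PERIODS}, got {self.period!r}")

    @property
    def key(self) -> tuple[str, str, float, str]:
        return (self.station, self.deployment_id, self.transect_depth_m, self.period)


@dataclass
class CtdCast:
    """One CTD profile: strictly increasing depth grid plus sensor columns."""

    station: str
    cast_id: str
    depth_m: np.ndarray
    temp_C: np.ndarray
    sal_psu: np.ndarray
    oxy_umol_kg: np.ndarray
    chla_mg_m3: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.depth_m, kind="stable")
        for name in ("depth_m", "temp_C", "sal_psu", "oxy_umol_kg", "chla_mg_m3"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float)[order])
        if len(self.depth_m) != len(np.unique(self.depth_m)):
            raise FormatError(
                f"duplicate depths in cast ({self.station}, {self.cast_id})"
            )
        if np.nanmin(self.oxy_umol_kg) < 0:
            raise FormatError(f"negative oxygen in cast ({self.station}, {self.cast_id})")
        if np.nanmin(self.chla_mg_m3) < 0:
            raise FormatError(
                f"negative chlorophyll in cast ({self.station}, {self.cast_id})"
            )


@dataclass
class ParticleProfile:
    """Depth-binned particle/copepod concentrations for one station."""

    station: str
    depth_bin_top_m: np.ndarray
    depth_bin_bottom_m: np.ndarray
    small_particles_per_L: np.ndarray
    large_particles_per_L: np.ndarray
    copepods_per_m3: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.depth_bin_top_m, kind="stable")
        for name in (
            "depth_bin_top_m", "depth_bin_bottom_m", "small_particles_per_L",
            "large_particles_per_L", "copepods_per_m3",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float)[order])
        if np.any(self.depth_bin_bottom_m <= self.depth_bin_top_m):
            bad = int(np.argmax(self.depth_bin_bottom_m <= self.depth_bin_top_m))
            raise FormatError(
                f"bin bottom must exceed bin top (station {self.station}, bin {bad})"
            )
        # bins must not overlap once sorted by top depth
        if np.any(self.depth_bin_top_m[1:] < self.depth_bin_bottom_m[:-1] - 1e-9):
            raise FormatError(f"overlapping depth bins (station {self.station})")
        for name in ("small_particles_per_L", "large_particles_per_L", "copepods_per_m3"):
            vals = getattr(self, name)
            if np.nanmin(vals) < 0:
                bad = int(np.nanargmin(vals))
                raise FormatError(
                    f"negative {name} (station {self.station}, row {bad})"
                )

    @property
    def depth_mid_m(self) -> np.ndarray:
        return 0.5 * (self.depth_bin_top_m + self.depth_bin_bottom_m)


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    return df

def _check_numeric(df: pd.DataFrame, columns: Iterable[str], name: str) -> None:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header row plus 1-based numbering
            raise FormatError(
                f"{name}: non-numeric value {df.loc[bad[0], col]!r} in column "
                f"'{col}' at line {bad[0] + 2}"
            )
        df[col] = coerced


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "t", "yes"):
        return True
    if text in ("false", "0", "f", "no"):
        return False
    raise FormatError(f"unparseable boolean value {value!r}")


def read_transects(path: str | Path) -> list[TransectMeta]:
    """Read transect metadata; keys must be unique."""
    df = _read_table(path, TRANSECT_COLUMNS)
    _check_numeric(df, ["transect_depth_m", "duration_min"], Path(path).name)
    if "tow_speed_m_s" not in df.columns:
        df["tow_speed_m_s"] = DEFAULT_TOW_SPEED_M_S
    else:
        _check_numeric(df, ["tow_speed_m_s"], Path(path).name)
    transects = [
        TransectMeta(
            station=str(r.station),
            deployment_id=str(r.deployment_id),
            transect_depth_m=float(r.transect_depth_m),
            period=str(r.period).strip().lower(),
            duration_min=float(r.duration_min),
            tow_speed_m_s=float(r.tow_speed_m_s),
        )
        for r in df.itertuples()
    ]
    keys = [t.key for t in transects]
    if len(keys) != len(set(keys)):
        seen: set = set()
        dup = next(k for k in keys if k in seen or seen.add(k))
        raise FormatError(f"duplicate transect key {dup}")
    return transects


def read_annotations(
    path: str | Path, transects: Iterable[TransectMeta]
) -> list[AnnotationRecord]:
    """Read the annotation event log, keeping only analysable observations.

    Rows flagged ``in_transect = false`` (organisms seen between transects)
    and rows whose (station, deployment, depth, period) key matches no known
    transect are excluded; the exclusion counts are logged so that
    ``excluded + returned == total data rows``.
    """
    df = _read_table(path, ANNOTATION_COLUMNS)
    name = Path(path).name
    _check_numeric(df, ["transect_depth_m"], name)
    known = {t.key for t in transects}
    records: list[AnnotationRecord] = []
    n_out_of_transect = 0
    n_unmatched = 0
    for i, r in enumerate(df.itertuples()):
        period = str(r.period).strip().lower()
        if period not in PERIODS:
            raise FormatError(
                f"{name}: unparseable period {r.period!r} at line {i + 2}"
            )
        taxon = str(r.taxon).strip()
        if not taxon or taxon == "nan":
            raise FormatError(f"{name}: empty taxon at line {i + 2}")
        rec = AnnotationRecord(
            station=str(r.station),
            deployment_id=str(r.deployment_id),
            transect_depth_m=float(r.transect_depth_m),
            period=period,
            taxon=taxon,
            in_transect=_parse_bool(r.in_transect),
            timestamp=str(r.timestamp) if "timestamp" in df.columns else None,
        )
        if not rec.in_transect:
            n_out_of_transect += 1
            continue
        if rec.transect_key not in known:
            n_unmatched += 1
            continue
        records.append(rec)
    if n_out_of_transect or n_unmatched:
        logger.info(
            "read_annotations(%s): excluded %d between-transect and %d unmatched "
            "rows of %d (%d kept)",
            name, n_out_of_transect, n_unmatched, len(df), len(records),
        )
    return records


def read_ctd(path: str | Path) -> list[CtdCast]:
    """Read CTD casts grouped by (station, cast_id), depth-sorted."""
    df = _read_table(path, CTD_COLUMNS)
    _check_numeric(
        df, ["depth_m", "temp_C", "sal_psu", "oxy_umol_kg", "chla_mg_m3"],
        Path(path).name,
    )
    casts = []
    for (station, cast_id), grp in df.groupby(["station", "cast_id"], sort=True):
        casts.append(
            CtdCast(
                station=str(station),
                cast_id=str(cast_id),
                depth_m=grp["depth_m"].to_numpy(),
                temp_C=grp["temp_C"].to_numpy(),
                sal_psu=grp["sal_psu"].to_numpy(),
                oxy_umol_kg=grp["oxy_umol_kg"].to_numpy(),
                chla_mg_m3=grp["chla_mg_m3"].to_numpy(),
            )
        )
    return casts


def read_particles(path: str | Path) -> list[ParticleProfile]:
    """Read depth-binned particle/copepod profiles, one per station."""
    df = _read_table(path, PARTICLE_COLUMNS)
    _check_numeric(
        df,
        [
            "depth_bin_top_m", "depth_bin_bottom_m", "small_particles_per_L",
            "large_particles_per_L", "copepods_per_m3",
        ],
        Path(path).name,
    )
    profiles = []
    for station, grp in df.groupby("station", sort=True):
        profiles.append(
            ParticleProfile(
                station=str(station),
                depth_bin_top_m=grp["depth_bin_top_m"].to_numpy(),
                depth_bin_bottom_m=grp["depth_bin_bottom_m"].to_numpy(),
                small_particles_per_L=grp["small_particles_per_L"].to_numpy(),
                large_particles_per_L=grp["large_particles_per_L"].to_numpy(),
                copepods_per_m3=grp["copepods_per_m3"].to_numpy(),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# writers


def annotations_to_frame(records: Iterable[AnnotationRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def transects_to_frame(transects: Iterable[TransectMeta]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in transects])


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> dict[str, Path]:
    """Write each named result table to ``<out_dir>/<name>.csv``.

    Column order is whatever the table carries (result builders produce
    deterministic orders); floats are written with Python repr so a write →
    read round trip preserves values to full precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, encoding="utf-8")
        paths[name] = path
    return paths
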