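"""Synthetic survey generator: hydrography with an OMZ, particles, and taxa
with planted vertical structure.

The generator emulates the statistical structure of a tropical eastern-
boundary midwater survey so every pipeline stage can be tested by recovery
of known truth:

* smooth hydrographic profiles — warm (≈25 °C) surface layer over a
  logistic thermocline declining to ≈6 °C at 1000 m; a Gaussian oxygen
  deficit centred mid-water producing an oxygen minimum zone with a core
  around 35 µmol kg⁻¹; a subsurface chlorophyll maximum (~0.9 mg m⁻³ near
  50 m); particle maxima in the surface layer and a broader secondary bump
  inside the OMZ;
* a transect design of stations with paired day/night deployments (plus one
  day-only station) towing at fixed target depths from 50 to 1000 m for 11
  or 22 minutes;
* taxa whose depth distributions are truncated Gaussians (unimodal or
  two-mode mixtures) or uniform, optionally shifted shallower at night to
  plant diel vertical migration;
* a Poisson observation model: each transect's expected count is
  concentration × sampled volume, the canonical minimal model for counts
  from volume sampling (negative-binomial overdispersion available to
  stress the statistics).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AnnotationRecord, CtdCast, ParticleProfile, TransectMeta

DEFAULT_TRANSECT_DEPTHS_M = (
    50, 100, 150, 200, 250, 300, 350, 400, 450, 500, 600, 700, 800, 900, 1000,
)


@dataclass
class EnvironmentSpec:
    """Parameters of the synthetic hydrographic regime (units in names)."""

    surface_temp_C: float = 25.0
    deep_temp_C: float = 6.0
    thermocline_depth_m: float = 45.0
    thermocline_width_m: float = 25.0
    surface_oxy_umol_kg: float = 220.0
    omz_core_depth_m: float = 400.0
    omz_min_umol_kg: float = 35.0
    #: Gaussian sigma of the oxygen deficit; 180 m puts the 60 µmol kg⁻¹
    #: crossings of the default profile near 303 and 497 m
    omz_halfwidth_m: float = 180.0
    chla_max_depth_m: float = 50.0
    chla_max_mg_m3: float = 0.9
    chla_width_m: float = 20.0
    surface_sal_psu: float = 34.8
    sal_max_anomaly_psu: float = 1.5
    sal_max_depth_m: float = 60.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "temp_C": 0.3, "sal_psu": 0.05, "oxy_umol_kg": 5.0, "chla_mg_m3": 0.05,
        }
    )
    n_casts: int = 7
    depth_step_m: float = 5.0
    z_max_m: float = 1000.0

    def temp(self, z: np.ndarray) -> np.ndarray:
        span = self.surface_temp_C - self.deep_temp_C
        return self.deep_temp_C + span / (
            1.0 + np.exp((np.asarray(z, float) - self.thermocline_depth_m)
                         / self.thermocline_width_m)
        )

    def oxy(self, z: np.ndarray) -> np.ndarray:
        deficit = self.surface_oxy_umol_kg - self.omz_min_umol_kg
        out = self.surface_oxy_umol_kg - deficit * np.exp(
            -((np.asarray(z, float) - self.omz_core_depth_m) ** 2)
            / (2 * self.omz_halfwidth_m**2)
        )
        return np.clip(out, 0.0, None)

    def sal(self, z: np.ndarray) -> np.ndarray:
        return self.surface_sal_psu + self.sal_max_anomaly_psu * np.exp(
            -((np.asarray(z, float) - self.sal_max_depth_m) ** 2) / (2 * 50.0**2)
        )

    def chla(self, z: np.ndarray) -> np.ndarray:
        return 0.02 + self.chla_max_mg_m3 * np.exp(
            -((np.asarray(z, float) - self.chla_max_depth_m) ** 2)
            / (2 * self.chla_width_m**2)
        )

    def small_particles(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, float)
        # surface maximum decaying with depth plus a broad OMZ bump strong
        # enough to form a genuine intermediate maximum
        return 80.0 * np.exp(-z / 150.0) + 25.0 * np.exp(
            -((z - self.omz_core_depth_m) ** 2) / (2 * 100.0**2)
        )

    def large_particles(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, float)
        return 8.0 * np.exp(-z / 200.0) + 4.0 * np.exp(
            -((z - self.omz_core_depth_m) ** 2) / (2 * 100.0**2)
        )

    def copepods(self, z: np.ndarray) -> np.ndarray:
        return 2000.0 * np.exp(-np.asarray(z, float) / 250.0)


@dataclass
class TaxonSpec:
    """A planted taxon: depth distribution shape, abundance and migration."""

    name: str
    shape: str  # "gaussian" | "bimodal" | "uniform"
    day_mode_m: float | None = None
    sigma_m: float = 60.0
    second_mode_m: float | None = None
    second_sigma_m: float | None = None
    mode_weights: tuple[float, float] = (0.5, 0.5)
    #: positive values move the taxon shallower at night (classic DVM)
    night_shift_m: float = 0.0
    peak_conc_per_1000m3: float = 100.0
    planted_type: int | None = None
    planted_M: bool = False

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "bimodal", "uniform"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape in ("gaussian", "bimodal") and self.day_mode_m is None:
            raise ValueError(f"{self.name}: day_mode_m required for {self.shape}")
        if self.shape == "bimodal" and self.second_mode_m is None:
            raise ValueError(f"{self.name}: bimodal shape needs second_mode_m")
        if bool(self.night_shift_m) != bool(self.planted_M):
            raise ValueError(
                f"{self.name}: night_shift_m must be nonzero iff planted_M"
            )

    def concentration(self, depth_m: float | np.ndarray, period: str) -> np.ndarray:
        """True concentration (ind / 1000 m³) at depth for the given period."""
        z = np.asarray(depth_m, dtype=float)
        shift = self.night_shift_m if period == "night" else 0.0
        if self.shape == "uniform":
            return np.full_like(z, self.peak_conc_per_1000m3, dtype=float)
        mode1 = self.day_mode_m - shift
        g1 = np.exp(-((z - mode1) ** 2) / (2 * self.sigma_m**2))
        if self.shape == "gaussian":
            return self.peak_conc_per_1000m3 * g1
        sigma2 = self.second_sigma_m or self.sigma_m
        mode2 = self.second_mode_m - shift
        g2 = np.exp(-((z - mode2) ** 2) / (2 * sigma2**2))
        w1, w2 = self.mode_weights
        mix = w1 * g1 + w2 * g2
        return self.peak_conc_per_1000m3 * mix / max(w1, w2)


@dataclass
class DesignSpec:
    """Transect design: stations, target depths, durations, true calibration."""

    n_stations_paired: int = 6
    n_stations_day_only: int = 1
    transect_depths_m: tuple[float, ...] = DEFAULT_TRANSECT_DEPTHS_M
    duration_shallow_min: float = 11.0
    duration_deep_min: float = 22.0
    deep_from_m: float = 350.0
    #: the true volume imaged per minute of towing (what calibration recovers)
    volume_per_minute_m3: float = 15.0
    tow_speed_m_s: float = 0.51

    def stations(self) -> list[tuple[str, tuple[str, ...]]]:
        out = [
            (f"ST{i + 1}", ("day", "night")) for i in range(self.n_stations_paired)
        ]
        for j in range(self.n_stations_day_only):
            out.append((f"ST{self.n_stations_paired + j + 1}", ("day",)))
        return out

    def duration_min(self, depth_m: float) -> float:
        return (
            self.duration_deep_min
            if depth_m >= self.deep_from_m
            else self.duration_shallow_min
        )

    def transects(self) -> list[TransectMeta]:
        out = []
        for station, periods in self.stations():
            for period in periods:
                for depth in self.transect_depths_m:
                    out.append(
                        TransectMeta(
                            station=station,
                            deployment_id=f"{station}-{period}",
                            transect_depth_m=float(depth),
                            period=period,
                            duration_min=self.duration_min(depth),
                            tow_speed_m_s=self.tow_speed_m_s,
                        )
                    )
        return out


# ---------------------------------------------------------------------------
# environment


def generate_environment(
    spec: EnvironmentSpec, seed: int | np.random.Generator = 0
) -> tuple[list[CtdCast], list[ParticleProfile]]:
    """Draw noisy CTD casts and particle profiles around the spec's curves.

    One cast and one particle profile per station; independent Gaussian
    sensor noise per cast (oxygen/chlorophyll clipped at zero); particle
    counts get 5% relative noise.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = np.arange(
        spec.depth_step_m / 2, spec.z_max_m + spec.depth_step_m / 2, spec.depth_step_m
    )
    casts, particles = [], []
    for i in range(spec.n_casts):
        station = f"ST{i + 1}"
        casts.append(
            CtdCast(
                station=station,
                cast_id=f"C{i + 1}",
                depth_m=z.copy(),
                temp_C=spec.temp(z) + rng.normal(0, spec.noise_sd["temp_C"], z.size),
                sal_psu=spec.sal(z) + rng.normal(0, spec.noise_sd["sal_psu"], z.size),
                oxy_umol_kg=np.clip(
                    spec.oxy(z) + rng.normal(0, spec.noise_sd["oxy_umol_kg"], z.size),
                    0, None,
                ),
                chla_mg_m3=np.clip(
                    spec.chla(z) + rng.normal(0, spec.noise_sd["chla_mg_m3"], z.size),
                    0, None,
                ),
            )
        )
        top = np.arange(0.0, spec.z_max_m, 5.0)
        bottom = top + 5.0
        mid = top + 2.5
        rel = lambda n: np.clip(1 + rng.normal(0, 0.05, n), 0, None)  # noqa: E731
        particles.append(
            ParticleProfile(
                station=station,
                depth_bin_top_m=top,
                depth_bin_bottom_m=bottom,
                small_particles_per_L=spec.small_particles(mid) * rel(mid.size),
                large_particles_per_L=spec.large_particles(mid) * rel(mid.size),
                copepods_per_m3=spec.copepods(mid) * rel(mid.size),
            )
        )
    return casts, particles


# ---------------------------------------------------------------------------
# community


def expected_counts(
    taxa: Sequence[TaxonSpec], design: DesignSpec
) -> pd.DataFrame:
    """Expected (Poisson mean) count per transect × taxon.

    λ = concentration / 1000 × volume-per-minute × duration.
    """
    rows = []
    for t in design.transects():
        volume = design.volume_per_minute_m3 * t.duration_min
        for taxon in taxa:
            conc = float(taxon.concentration(t.transect_depth_m, t.period))
            rows.append(
                {
                    "station": t.station,
                    "deployment_id": t.deployment_id,
                    "transect_depth_m": t.transect_depth_m,
                    "period": t.period,
                    "taxon": taxon.name,
                    "lambda": conc / 1000.0 * volume,
                }
            )
    return pd.DataFrame(rows)


def simulate_transect_counts(
    taxa: Sequence[TaxonSpec],
    design: DesignSpec,
    seed: int | np.random.Generator = 0,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Draw per-transect counts (Poisson, or negative binomial when
    ``dispersion`` — the NB size parameter — is given)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    df = expected_counts(taxa, design)
    lam = df["lambda"].to_numpy()
    if dispersion is None:
        df["count"] = rng.poisson(lam)
    else:
        # NB as gamma-mixed Poisson: variance = λ + λ²/size
        mix = rng.gamma(shape=dispersion, scale=lam / dispersion)
        df["count"] = rng.poisson(np.where(lam > 0, mix, 0.0))
    return df.drop(columns=["lambda"])


def generate_community_counts(
    taxa: Sequence[TaxonSpec],
    design: DesignSpec,
    seed: int | np.random.Generator = 0,
    dispersion: float | None = None,
) -> tuple[list[AnnotationRecord], list[TransectMeta]]:
    """Simulate the survey as an annotation event log plus transect table."""
    counts = simulate_transect_counts(taxa, design, seed, dispersion)
    annotations = []
    for r in counts.itertuples():
        for _ in range(int(r.count)):
            annotations.append(
                AnnotationRecord(
                    station=r.station,
                    deployment_id=r.deployment_id,
                    transect_depth_m=r.transect_depth_m,
                    period=r.period,
                    taxon=r.taxon,
                    in_transect=True,
                )
            )
    return annotations, design.transects()


def generate_reference_taxon(
    design: DesignSpec,
    true_conc_per_m3: float | Callable[[np.ndarray], np.ndarray] = 0.5,
    seed: int | np.random.Generator = 0,
    profiler_rel_noise: float = 0.0,
) -> pd.DataFrame:
    """Simulate the calibration reference taxon seen by camera and profiler.

    Returns one row per transect with the camera ``count`` (Poisson around
    concentration × true volume), the ``duration_min``, and the profiler
    ``conc_per_m3`` (true concentration times optional relative noise) —
    exactly the table :func:`midwater.abundance.estimate_calibration` takes.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for t in design.transects():
        if callable(true_conc_per_m3):
            conc = float(true_conc_per_m3(np.asarray(t.transect_depth_m)))
        else:
            conc = float(true_conc_per_m3)
        volume = design.volume_per_minute_m3 * t.duration_min
        count = int(rng.poisson(conc * volume))
        measured = conc * max(0.0, 1.0 + rng.normal(0, profiler_rel_noise)) \
            if profiler_rel_noise > 0 else conc
        rows.append(
            {
                "station": t.station,
                "deployment_id": t.deployment_id,
                "transect_depth_m": t.transect_depth_m,
                "period": t.period,
                "duration_min": t.duration_min,
                "count": count,
                "conc_per_m3": measured,
            }
        )
    return pd.DataFrame(rows)


def simulate_wmd_pairs(
    n_stations: int,
    shift_m: float,
    between_station_sd_m: float,
    seed: int | np.random.Generator = 0,
    base_wmd_m: float = 400.0,
) -> tuple[pd.Series, pd.Series]:
    """Station-level day/night WMD pairs for migration-test calibration.

    Day WMDs are ``base + ε``, night WMDs ``base − shift + ε'`` with
    independent N(0, sd²) station noise; ``shift_m = 0`` gives the null of
    no diel migration.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    stations = [f"ST{i + 1}" for i in range(n_stations)]
    day = base_wmd_m + rng.normal(0, between_station_sd_m, n_stations)
    night = base_wmd_m - shift_m + rng.normal(0, between_station_sd_m, n_stations)
    return pd.Series(day, index=stations), pd.Series(night, index=stations)


# ---------------------------------------------------------------------------
# scenarios


def archetype_taxa() -> list[TaxonSpec]:
    """Five planted archetypes, one per distribution type.

    An OMZ-core resident, a bimodal OMZ-avoider, a shallow resident, a deep
    diel migrator (200 m shallower at night) and a taxon spread uniformly
    through the water column.
    """
    return [
        TaxonSpec(
            "Lilyopsis", "gaussian", day_mode_m=400, sigma_m=60,
            peak_conc_per_1000m3=150, planted_type=1,
        ),
        TaxonSpec(
            "Beroe", "bimodal", day_mode_m=120, sigma_m=50,
            second_mode_m=650, second_sigma_m=60,
            peak_conc_per_1000m3=150, planted_type=2,
        ),
        TaxonSpec(
            "Praya", "gaussian", day_mode_m=150, sigma_m=60,
            peak_conc_per_1000m3=150, planted_type=3,
        ),
        TaxonSpec(
            "Atolla", "gaussian", day_mode_m=750, sigma_m=70,
            night_shift_m=200, peak_conc_per_1000m3=150,
            planted_type=4, planted_M=True,
        ),
        TaxonSpec(
            "Chaetognatha", "uniform", peak_conc_per_1000m3=60, planted_type=5,
        ),
    ]


def typed_taxon_population(
    n_per_type: int = 50,
    seed: int | np.random.Generator = 0,
    peak_conc_per_1000m3: float = 320.0,
) -> list[TaxonSpec]:
    """A population of taxa with randomized parameters, n per planted type.

    Mode ranges are placed relative to the default environment's OMZ
    (crossings ≈ 303 / 497 m) so each draw genuinely belongs to its type.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    taxa: list[TaxonSpec] = []
    for k in range(n_per_type):
        taxa.append(TaxonSpec(
            f"T1_{k}", "gaussian",
            day_mode_m=rng.uniform(360, 440), sigma_m=rng.uniform(40, 70),
            peak_conc_per_1000m3=peak_conc_per_1000m3, planted_type=1,
        ))
        taxa.append(TaxonSpec(
            f"T2_{k}", "bimodal",
            day_mode_m=rng.uniform(80, 180), sigma_m=rng.uniform(40, 60),
            second_mode_m=rng.uniform(620, 800),
            second_sigma_m=rng.uniform(40, 60),
            peak_conc_per_1000m3=peak_conc_per_1000m3, planted_type=2,
        ))
        taxa.append(TaxonSpec(
            f"T3_{k}", "gaussian",
            day_mode_m=rng.uniform(100, 240), sigma_m=rng.uniform(40, 70),
            peak_conc_per_1000m3=peak_conc_per_1000m3, planted_type=3,
        ))
        taxa.append(TaxonSpec(
            f"T4_{k}", "gaussian",
            day_mode_m=rng.uniform(620, 850), sigma_m=rng.uniform(50, 80),
            peak_conc_per_1000m3=peak_conc_per_1000m3, planted_type=4,
        ))
        taxa.append(TaxonSpec(
            f"T5_{k}", "uniform",
            peak_conc_per_1000m3=peak_conc_per_1000m3, planted_type=5,
        ))
    return taxa


@dataclass
class Scenario:
    """A complete synthetic study: environment, design, taxa, seed."""

    environment: EnvironmentSpec = field(default_factory=EnvironmentSpec)
    design: DesignSpec = field(default_factory=DesignSpec)
    taxa: list[TaxonSpec] = field(default_factory=archetype_taxa)
    reference_conc_per_m3: float = 0.5
    seed: int = 0


def default_scenario(seed: int = 0) -> Scenario:
    return Scenario(seed=seed)


def scenario_from_dict(data: dict) -> Scenario:
    """Build a scenario from a (YAML-loaded) mapping of overrides."""
    env = EnvironmentSpec(**data.get("environment", {}))
    design = DesignSpec(**{
        **data.get("design", {}),
        **(
            {"transect_depths_m": tuple(data["design"]["transect_depths_m"])}
            if "transect_depths_m" in data.get("design", {})
            else {}
        ),
    })
    if "taxa" in data:
        taxa = [TaxonSpec(**t) for t in data["taxa"]]
    else:
        taxa = archetype_taxa()
    return Scenario(
        environment=env,
        design=design,
        taxa=taxa,
        reference_conc_per_m3=data.get("reference_conc_per_m3", 0.5),
        seed=int(data.get("seed", 0)),
    )


def write_scenario_inputs(scenario: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the four survey input tables plus truth tables.

    Produces ``annotations.csv``, ``transects.csv``, ``ctd.csv``,
    ``particles.csv``, a ``reference_conc.csv`` profiler table for the
    calibration reference taxon, and ``truth.csv`` recording every planted
    parameter.
    """
    from .io import annotations_to_frame, transects_to_frame

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    casts, particles = generate_environment(scenario.environment, rng)
    annotations, transects = generate_community_counts(
        scenario.taxa, scenario.design, rng
    )
    reference = generate_reference_taxon(
        scenario.design, scenario.reference_conc_per_m3, rng
    )
    # the reference taxon enters the event log like any other observation
    for r in reference.itertuples():
        for _ in range(int(r.count)):
            annotations.append(
                AnnotationRecord(
                    station=r.station, deployment_id=r.deployment_id,
                    transect_depth_m=r.transect_depth_m, period=r.period,
                    taxon="Poeobius", in_transect=True,
                )
            )

    paths: dict[str, Path] = {}

    ann = annotations_to_frame(annotations)
    paths["annotations"] = out_dir / "annotations.csv"
    ann.to_csv(paths["annotations"], index=False)

    paths["transects"] = out_dir / "transects.csv"
    transects_to_frame(transects).to_csv(paths["transects"], index=False)

    ctd = pd.concat(
        [
            pd.DataFrame(
                {
                    "station": c.station, "cast_id": c.cast_id,
                    "depth_m": c.depth_m, "temp_C": c.temp_C,
                    "sal_psu": c.sal_psu, "oxy_umol_kg": c.oxy_umol_kg,
                    "chla_mg_m3": c.chla_mg_m3,
                }
            )
            for c in casts
        ],
        ignore_index=True,
    )
    paths["ctd"] = out_dir / "ctd.csv"
    ctd.to_csv(paths["ctd"], index=False)

    part = pd.concat(
        [
            pd.DataFrame(
                {
                    "station": p.station,
                    "depth_bin_top_m": p.depth_bin_top_m,
                    "depth_bin_bottom_m": p.depth_bin_bottom_m,
                    "small_particles_per_L": p.small_particles_per_L,
                    "large_particles_per_L": p.large_particles_per_L,
                    "copepods_per_m3": p.copepods_per_m3,
                }
            )
            for p in particles
        ],
        ignore_index=True,
    )
    paths["particles"] = out_dir / "particles.csv"
    part.to_csv(paths["particles"], index=False)

    ref = reference.rename(columns={"transect_depth_m": "depth_m"})[
        ["station", "depth_m", "conc_per_m3"]
    ].drop_duplicates(["station", "depth_m"])
    paths["reference_conc"] = out_dir / "reference_conc.csv"
    ref.to_csv(paths["reference_conc"], index=False)

    truth_rows = [asdict(t) for t in scenario.taxa]
    truth = pd.DataFrame(truth_rows)
    truth["true_volume_per_minute_m3"] = scenario.design.volume_per_minute_m3
    paths["truth"] = out_dir / "truth.csv"
    truth.to_csv(paths["truth"], index=False)
    return paths
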