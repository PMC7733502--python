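"""End-to-end analysis: inputs → strata → abundances → WMD/DVM → types → PCA.

Stages run in dependency order; any failure aborts with an error naming the
stage.  Given the same configuration and seed the run is deterministic and
its numeric outputs are byte-identical across repeats; the written manifest
(config echo, package versions, seed) suffices to reproduce a run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import abundance as ab
from . import classify as cl
from . import hydrography as hy
from . import io
from . import ordination as ordn
from . import vertical as vt
from .config import RunConfig
from .vertical import SplitRule

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunResult:
    """All result tables plus the derived strata and calibration factor."""

    tables: dict[str, pd.DataFrame]
    strata: hy.DepthStrata
    factor: ab.CalibrationFactor
    paths: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    class _ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _ctx()


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Execute the full analysis described by ``config``."""
    problems = config.validate(require_inputs=True)
    if problems:
        raise PipelineError("config", "; ".join(problems))
    c = config.data
    tables: dict[str, pd.DataFrame] = {}

    with _stage("read"):
        transects = io.read_transects(c["inputs"]["transects"])
        annotations = io.read_annotations(c["inputs"]["annotations"], transects)
        casts = io.read_ctd(c["inputs"]["ctd"])
        particles = io.read_particles(c["inputs"]["particles"])

    with _stage("profile"):
        profile = hy.compute_mean_profile(casts, c["profile"]["bin_width_m"])
        tables["mean_profile"] = profile.table.reset_index()

    with _stage("strata"):
        z1 = hy.define_ul_boundary(
            profile, c["strata"]["ul_method"], c["strata"]["ul_fixed_m"]
        )
        strata = hy.detect_omz(
            profile,
            threshold_umol_kg=c["strata"]["threshold_umol_kg"],
            z1=z1,
            z_max=c["strata"]["z_max_m"],
        )
        if strata is None:
            raise PipelineError(
                "strata",
                "oxygen never falls below the threshold: no OMZ to delimit",
            )
        tables["strata"] = strata.as_frame()

    with _stage("counts"):
        counts = ab.aggregate_counts(annotations, transects)

    with _stage("calibration"):
        if c["calibration"]["mode"] == "estimated":
            ref_taxon = c["calibration"]["reference_taxon"]
            ref_conc = pd.read_csv(c["inputs"]["reference_conc"])
            ref_counts = counts[counts["taxon"] == ref_taxon].copy()
            if ref_counts.empty:
                raise PipelineError(
                    "calibration", f"reference taxon {ref_taxon!r} not in counts"
                )
            durations = {t.key: t.duration_min for t in transects}
            ref_counts["duration_min"] = [
                durations[(r.station, r.deployment_id, r.transect_depth_m, r.period)]
                for r in ref_counts.itertuples()
            ]
            half = c["calibration"]["depth_match_halfwidth_m"]
            ref_counts["conc_per_m3"] = [
                ab.match_reference_concentration(
                    ref_conc[ref_conc["station"] == r.station],
                    r.transect_depth_m,
                    half,
                )
                for r in ref_counts.itertuples()
            ]
            factor = ab.estimate_calibration(ref_counts, ref_taxon)
        else:
            factor = ab.CalibrationFactor(
                volume_per_minute_m3=c["calibration"]["volume_per_minute_m3"],
                source="configured",
            )

    with _stage("abundance"):
        abundances = ab.to_concentration(counts, transects, factor)
        tables["abundances"] = abundances

    with _stage("vertical"):
        profiles = vt.build_profiles(abundances)
        # resolve splits; split groups replace the parent for WMD/DVM
        split_groups: dict[str, list[str]] = {}
        dvm_profiles = dict(profiles)
        for taxon, depth in c["splits"].items():
            depth_m = strata.omz_mid_m if depth == "omz_mid" else float(depth)
            rule = SplitRule(taxon=taxon, split_depth_m=depth_m)
            members = []
            for period in ("day", "night"):
                prof = dvm_profiles.pop((taxon, period), None)
                if prof is None:
                    continue
                shallow, deep = vt.apply_split(prof, rule)
                dvm_profiles[(shallow.taxon, period)] = shallow
                dvm_profiles[(deep.taxon, period)] = deep
                members = [shallow.taxon, deep.taxon]
            if members:
                split_groups[taxon] = members
        tables["wmd"] = vt.wmd_table(dvm_profiles)
        dvm_table = vt.dvm_tests_table(
            dvm_profiles, alpha=c["dvm"]["alpha"], min_pairs=c["dvm"]["min_pairs"]
        )
        tables["dvm_tests"] = dvm_table

    with _stage("classification"):
        dvm_by_taxon = {
            r.taxon: vt.DvmTestResult(
                taxon=r.taxon, n_pairs=r.n_pairs, t_stat=r.t_stat,
                p_value=r.p_value, significant=bool(r.significant),
                direction=r.direction, mean_diff_m=r.mean_diff_m, status=r.status,
            )
            for r in dvm_table.itertuples()
        }
        # a split taxon is migratory if any of its depth groups is
        for taxon, members in split_groups.items():
            sub = [dvm_by_taxon[m] for m in members if m in dvm_by_taxon]
            if sub:
                best = min(
                    sub, key=lambda r: r.p_value if np.isfinite(r.p_value) else 2.0
                )
                dvm_by_taxon[taxon] = vt.DvmTestResult(
                    taxon=taxon, n_pairs=best.n_pairs, t_stat=best.t_stat,
                    p_value=best.p_value,
                    significant=any(r.significant for r in sub),
                    direction=best.direction, mean_diff_m=best.mean_diff_m,
                    status=best.status,
                )
        counts_per_taxon = counts.groupby("taxon")["count"].sum().to_dict()
        tables["types"] = cl.classify_taxa(
            profiles,
            strata,
            dvm_results=dvm_by_taxon,
            counts_per_taxon=counts_per_taxon,
            evenness_threshold=c["classify"]["evenness_threshold"],
            trough_ratio=c["classify"]["trough_ratio"],
            min_observations=c["classify"]["min_observations"],
        )

    with _stage("ordination"):
        for period in ("day", "night"):
            if not (abundances["period"] == period).any():
                continue
            matrix = ordn.build_sample_matrix(
                abundances, period, profile, particles, strata,
                particles_var=c["ordination"]["particles_var"],
            )
            stratum_labels = matrix.pop("stratum")
            norm, constant = ordn.minmax_normalize(matrix)
            if constant:
                logger.info("%s ordination: constant columns %s", period, constant)
            pca = ordn.run_pca(norm)
            scores = pca.scores.reset_index()
            scores.insert(2, "stratum", stratum_labels.to_numpy())
            tables[f"pca_scores_{period}"] = scores
            tables[f"pca_loadings_{period}"] = pca.loadings.reset_index(
                names="variable"
            )
            tables[f"pca_variance_{period}"] = pd.DataFrame(
                {
                    "component": pca.scores.columns,
                    "explained_variance": pca.explained_variance,
                    "explained_variance_ratio": pca.explained_variance_ratio,
                }
            )

    result = RunResult(tables=tables, strata=strata, factor=factor)
    if write:
        with _stage("write"):
            out_dir = Path(c["output_dir"])
            result.paths = io.write_results(tables, out_dir)
            manifest = {
                "config": c,
                "seed": c["seed"],
                "calibration_factor_m3_per_min": factor.volume_per_minute_m3,
                "calibration_source": factor.source,
                "versions": _versions(),
            }
            manifest_path = out_dir / "manifest.json"
            manifest_path.write_text(
                json.dumps(manifest, indent=2, default=str), encoding="utf-8"
            )
            result.paths["manifest"] = manifest_path
    return result


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("midwater", "numpy", "pandas", "scipy", "scikit-learn",
                "statsmodels"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
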