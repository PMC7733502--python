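"""Run configuration: defaults, YAML loading, validation.

A run is fully described by one mapping (usually a YAML file).  Unknown keys
are rejected, missing keys fall back to defaults, and CLI flags may override
individual values.  The same mapping is echoed into the run manifest so a
run can be reproduced exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

CONFIG_SCHEMA_VERSION = 1

DEFAULTS: dict[str, Any] = {
    "schema_version": CONFIG_SCHEMA_VERSION,
    "inputs": {
        "annotations": None,
        "transects": None,
        "ctd": None,
        "particles": None,
        "reference_conc": None,  # only needed for calibration.mode = estimated
    },
    "output_dir": "results",
    "seed": 0,
    "log_level": "INFO",
    "profile": {"bin_width_m": 5.0},
    "strata": {
        "threshold_umol_kg": 60.0,
        "ul_method": "fixed",        # or "max-gradient"
        "ul_fixed_m": 92.0,
        "z_max_m": 1000.0,
    },
    "calibration": {
        "mode": "configured",        # or "estimated"
        "volume_per_minute_m3": 15.0,
        "reference_taxon": "Poeobius",
        "depth_match_halfwidth_m": 25.0,
    },
    "dvm": {"alpha": 0.05, "min_pairs": 3},
    # taxon -> split depth in metres, or the string "omz_mid"
    "splits": {},
    "classify": {
        "evenness_threshold": 0.40,
        "trough_ratio": 0.25,
        "min_observations": 20,
    },
    "ordination": {"particles_var": "both", "biplot_figures": False},
}


class ConfigError(ValueError):
    """The run configuration is invalid."""


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in out:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(out[key], dict) and isinstance(value, Mapping):
            if key == "splits":
                out[key] = dict(value)
            else:
                out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Validated analysis configuration (defaults merged in)."""

    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_dict(cls, overrides: Mapping | None = None) -> "RunConfig":
        merged = _merge(DEFAULTS, dict(overrides or {}))
        # splits is free-form (taxon names), merge separately
        return cls(data=merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(loaded)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def validate(self, require_inputs: bool = True) -> list[str]:
        """Return a list of problems (empty = valid)."""
        problems: list[str] = []
        c = self.data
        if require_inputs:
            for name in ("annotations", "transects", "ctd", "particles"):
                path = c["inputs"][name]
                if path is None:
                    problems.append(f"inputs.{name} is not set")
                elif not Path(path).exists():
                    problems.append(f"inputs.{name}: file not found: {path}")
            if c["calibration"]["mode"] == "estimated":
                ref = c["inputs"]["reference_conc"]
                if ref is None or not Path(ref).exists():
                    problems.append(
                        "calibration.mode=estimated requires inputs.reference_conc"
                    )
        if c["calibration"]["mode"] not in ("configured", "estimated"):
            problems.append(f"unknown calibration.mode {c['calibration']['mode']!r}")
        if c["calibration"]["volume_per_minute_m3"] <= 0:
            problems.append("calibration.volume_per_minute_m3 must be > 0")
        if not 0 < c["dvm"]["alpha"] < 1:
            problems.append("dvm.alpha must be in (0, 1)")
        if c["dvm"]["min_pairs"] < 2:
            problems.append("dvm.min_pairs must be at least 2")
        if not 0 < c["classify"]["evenness_threshold"] <= 1:
            problems.append("classify.evenness_threshold must be in (0, 1]")
        if not 0 < c["classify"]["trough_ratio"] < 1:
            problems.append("classify.trough_ratio must be in (0, 1)")
        if c["strata"]["threshold_umol_kg"] <= 0:
            problems.append("strata.threshold_umol_kg must be > 0")
        if c["strata"]["ul_method"] not in ("fixed", "max-gradient"):
            problems.append(f"unknown strata.ul_method {c['strata']['ul_method']!r}")
        if c["profile"]["bin_width_m"] <= 0:
            problems.append("profile.bin_width_m must be > 0")
        if c["ordination"]["particles_var"] not in ("small", "large", "both"):
            problems.append(
                f"unknown ordination.particles_var {c['ordination']['particles_var']!r}"
            )
        for taxon, depth in c["splits"].items():
            if depth != "omz_mid" and not isinstance(depth, (int, float)):
                problems.append(
                    f"splits.{taxon} must be a depth in metres or 'omz_mid'"
                )
        return problems
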