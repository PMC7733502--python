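"""Community ordination: min-max normalisation and PCA with biplot output.

One sample is one transect (station × target depth) within one period.  The
sample matrix holds every analysis taxon's concentration plus four
environmental variables interpolated to the transect depth — temperature,
oxygen, chlorophyll-a and particle concentration.  All columns are min-max
normalised to [0, 1] (no further unit-variance scaling), centred, and
decomposed by PCA on the covariance matrix, separately for day and night.

Determinism: the eigendecomposition is exact (LAPACK full SVD, no
randomised solver) and component signs are fixed so that the
largest-magnitude entry of each loading vector is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .hydrography import DepthStrata, MeanProfile, assign_stratum
from .io import ParticleProfile

ENV_VARIABLES = ("temperature", "oxygen", "chlorophyll", "particles")


@dataclass
class PcaResult:
    """Scores, unit-norm loadings and explained variance of one ordination."""

    scores: pd.DataFrame        # samples × PC1..PCk
    loadings: pd.DataFrame      # variables × PC1..PCk, orthonormal columns
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    variables: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def mean_particle_concentration(
    profiles: Sequence[ParticleProfile],
    depth_m: float | np.ndarray,
    which: str = "both",
) -> np.ndarray:
    """Station-mean particle concentration (per L) interpolated to depth.

    ``which`` selects the profiler size class: "small" (64–256 µm), "large"
    (> 256 µm) or "both" (their sum, the default proxy for total particle
    load).
    """
    if which not in ("small", "large", "both"):
        raise ValueError(f"unknown particle class {which!r}")
    rows = []
    for p in profiles:
        conc = np.zeros_like(p.depth_mid_m)
        if which in ("small", "both"):
            conc = conc + p.small_particles_per_L
        if which in ("large", "both"):
            conc = conc + p.large_particles_per_L
        rows.append(pd.Series(conc, index=p.depth_mid_m))
    pooled = pd.concat(rows, axis=1).mean(axis=1).sort_index()
    return np.interp(
        np.asarray(depth_m, dtype=float),
        pooled.index.to_numpy(),
        pooled.to_numpy(),
    )


def build_sample_matrix(
    abundances: pd.DataFrame,
    period: str,
    profile: MeanProfile,
    particles: Sequence[ParticleProfile],
    strata: DepthStrata | None = None,
    particles_var: str = "both",
) -> pd.DataFrame:
    """Assemble the samples × (taxa + environment) matrix for one period.

    Rows are indexed by (station, transect_depth_m); taxon columns carry
    concentrations (ind / 1000 m³); environmental columns are interpolated
    from the mean hydrographic and particle profiles at the transect depth.
    A ``stratum`` label column is attached when strata are supplied (it is
    not part of the numeric matrix).
    """
    sub = abundances[abundances["period"] == period]
    if sub.empty:
        raise ValueError(f"no samples for period {period!r}")
    wide = sub.pivot_table(
        values="concentration_per_1000m3",
        index=["station", "transect_depth_m"],
        columns="taxon",
        aggfunc="mean",
    ).sort_index()
    depths = wide.index.get_level_values("transect_depth_m").to_numpy(dtype=float)
    wide["temperature"] = profile.interp("temp_C", depths)
    wide["oxygen"] = profile.interp("oxy_umol_kg", depths)
    wide["chlorophyll"] = profile.interp("chla_mg_m3", depths)
    wide["particles"] = mean_particle_concentration(particles, depths, particles_var)
    wide.columns.name = None
    if strata is not None:
        wide["stratum"] = [assign_stratum(d, strata) for d in depths]
    return wide


def minmax_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Scale each column to [0, 1]; constant columns map to 0 and are flagged."""
    numeric = matrix.select_dtypes(include=[np.number])
    lo = numeric.min(axis=0)
    hi = numeric.max(axis=0)
    span = hi - lo
    constant = span[span == 0].index.tolist()
    span = span.replace(0, 1.0)
    return (numeric - lo) / span, constant


def run_pca(matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of the column-centred normalised sample matrix.

    Uses the deterministic full SVD solver; sign convention: the
    largest-magnitude entry of each loading vector is made positive.
    """
    numeric = matrix.select_dtypes(include=[np.number])
    if numeric.shape[0] < 3:
        raise ValueError("PCA requires at least 3 samples")
    k = n_components or min(numeric.shape[0] - 1, numeric.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(numeric.to_numpy(dtype=float))
    loadings = pca.components_.T  # variables × components
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=numeric.index, columns=names),
        loadings=pd.DataFrame(loadings, index=numeric.columns, columns=names),
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        variables=list(numeric.columns),
    )


def biplot_coordinates(
    pca: PcaResult,
    env_variables: Sequence[str] = ENV_VARIABLES,
    scale: float = 1.0,
) -> pd.DataFrame:
    """PC1/PC2 biplot geometry: environment as arrows, taxa as points.

    Environmental variables are rendered as vectors from the origin
    (loading × scale); every other variable is a labelled point at its
    loading coordinates, matching the convention of drawing arrows only for
    the environment in a community biplot.
    """
    rows = []
    for var in pca.loadings.index:
        kind = "vector" if var in env_variables else "point"
        factor = scale if kind == "vector" else 1.0
        rows.append(
            {
                "variable": var,
                "kind": kind,
                "pc1": float(pca.loadings.loc[var, "PC1"]) * factor,
                "pc2": float(pca.loadings.loc[var, "PC2"]) * factor
                if "PC2" in pca.loadings.columns
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def plot_biplot(
    pca: PcaResult,
    path: str,
    env_variables: Sequence[str] = ENV_VARIABLES,
    scale: float = 1.0,
    title: str = "",
) -> None:
    """Render the PC1/PC2 biplot to an image file (matplotlib, Agg backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = biplot_coordinates(pca, env_variables, scale)
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(pca.scores["PC1"], pca.scores["PC2"], s=18, c="0.6", zorder=1)
    for _, row in coords.iterrows():
        if row["kind"] == "vector":
            ax.annotate(
                "", xy=(row["pc1"], row["pc2"]), xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color="tab:blue"),
            )
            ax.text(row["pc1"], row["pc2"], row["variable"], color="tab:blue")
        else:
            ax.text(row["pc1"], row["pc2"], row["variable"], fontsize=6, color="0.2")
    evr = pca.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
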