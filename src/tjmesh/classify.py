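"""Hierarchical classification of per-sample feature profiles.

Two analyses mirror the study design: a texture-only clustering of all
claudins (euclidean distance, average linkage, unit-variance column
scaling) and a combined texture + morphometry clustering of the
meshwork-forming claudins (ln transform, centering, unit-variance scaling,
correlation distance, average linkage). Per-ROI rows are aggregated to one
row per sample by the arithmetic mean over that sample's QC-passing ROIs.

The number of clusters is selected by maximizing the mean silhouette over a
candidate range (the study cut its dendrogram visually; an explicit
criterion replaces that for reproducibility).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .core import FeatureTable
from .meshseg import qc_filter
from .texture import DISTANCES_PX, FEATURE_NAMES

__all__ = [
    "TEXTURE_COLUMNS",
    "MORPHO_COLUMNS",
    "Dendrogram",
    "ClusterAssignment",
    "build_feature_matrix",
    "scale_features",
    "hcluster",
    "cut_and_score",
    "pca_scores",
]

TEXTURE_COLUMNS = tuple(
    f"{name}_d{d}" for d in DISTANCES_PX for name in FEATURE_NAMES
)
MORPHO_COLUMNS = (
    "pct_segmented_area",
    "n_branches",
    "avg_branch_len_nm",
    "max_branch_len_nm",
    "n_junctions",
    "n_triple",
    "n_quadruple",
    "n_meshes",
    "mean_mesh_area_nm2",
    "var_mesh_area_nm2",
)


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_labels: list
    metric: str
    linkage_method: str = "average"

    def cophenetic_matrix(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(cophenet(self.merges))


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # cluster id in [1..k] per leaf
    leaf_labels: list
    k: int
    silhouette_per_leaf: np.ndarray
    mean_silhouette: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.leaf_labels,
                "cluster": self.labels,
                "silhouette": self.silhouette_per_leaf,
            }
        )


def build_feature_matrix(table: FeatureTable, mode: str = "combined") -> FeatureTable:
    """Aggregate per-ROI rows to one feature row per sample.

    ``mode='texture'`` keeps the 12 texture columns; ``mode='combined'``
    additionally keeps the morphometry columns and applies the QC filter
    first. Samples whose every ROI fails QC are dropped with a warning.
    """
    if mode not in ("texture", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    df = table.data.copy()
    if df.empty:
        raise ValueError("feature table is empty")
    columns = list(TEXTURE_COLUMNS)
    if mode == "combined":
        columns += list(MORPHO_COLUMNS)
        keep = df.apply(lambda r: qc_filter(r)[0], axis=1)
        dropped = set(df.loc[~keep, "sample_id"]) - set(df.loc[keep, "sample_id"])
        if dropped:
            warnings.warn(
                f"samples dropped entirely by QC: {sorted(map(str, dropped))}"
            )
        df = df.loc[keep]
        if df.empty:
            raise ValueError("no rows left after QC")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    agg = df.groupby("sample_id", sort=True)[columns].mean().reset_index()
    return FeatureTable(agg, dict(table.provenance, aggregated=mode))


def scale_features(
    table: FeatureTable,
    ln_transform: bool = False,
    center: bool = True,
) -> FeatureTable:
    """Optional ln(x+1) per cell, then per-column centering and unit-variance scaling.

    ln(x+1) rather than ln(x) because morphometry counts can be zero.
    Constant columns are set to all-zero with a warning. Variance is the
    sample variance (ddof=1), matching the R ``scale`` convention used by
    the heatmap tools this pipeline mirrors.
    """
    df = table.data.copy()
    feats = [c for c in df.columns if c not in FeatureTable.KEY_COLUMNS]
    X = df[feats].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("NaN in feature matrix; impute or drop before scaling")
    if ln_transform:
        if np.any(X <= -1):
            raise ValueError("ln(x+1) transform requires all values > -1")
        X = np.log1p(X)
    if center:
        X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant columns set to zero: {[feats[i] for i in np.nonzero(constant)[0]]}"
        )
    sd_safe = np.where(constant, 1.0, sd)
    X = np.where(constant, 0.0, X / sd_safe)
    out = df.copy()
    out[feats] = X
    return FeatureTable(
        out, dict(table.provenance, scaled=f"ln={ln_transform},center={center}")
    )


def _row_matrix(table: FeatureTable) -> tuple[np.ndarray, list]:
    df = table.data
    feats = [c for c in df.columns if c not in FeatureTable.KEY_COLUMNS]
    labels = (
        df["sample_id"].tolist() if "sample_id" in df.columns else list(df.index)
    )
    return df[feats].to_numpy(dtype=np.float64), labels


def hcluster(
    table: FeatureTable, metric: str = "correlation", linkage_method: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of sample rows.

    ``metric`` is ``euclidean`` or ``correlation`` (1 - Pearson between
    rows). Average-linkage merge heights are non-decreasing, which is
    asserted on every run.
    """
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    X, labels = _row_matrix(table)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    if metric == "correlation":
        if X.shape[1] < 2:
            raise ValueError("correlation distance needs >= 2 columns")
        if np.any(X.std(axis=1) == 0):
            raise ValueError("correlation distance undefined for constant rows")
    Z = linkage(pdist(X, metric=metric), method=linkage_method)
    heights = Z[:, 2]
    if linkage_method == "average" and np.any(np.diff(heights) < -1e-10):
        raise AssertionError("average-linkage merge heights must be non-decreasing")
    return Dendrogram(Z, labels, metric, linkage_method)


def cut_and_score(
    dendrogram: Dendrogram, table: FeatureTable, k_range=range(2, 7)
) -> ClusterAssignment:
    """Cut at each k in range, score by mean silhouette, return the best cut.

    The silhouette uses the same metric as the clustering. Ties go to the
    smallest k.
    """
    X, labels = _row_matrix(table)
    n = X.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"each k must satisfy 2 <= k <= n-1 = {n - 1}")
    best: ClusterAssignment | None = None
    for k in ks:
        assign = fcluster(dendrogram.merges, t=k, criterion="maxclust")
        if len(np.unique(assign)) < 2:
            continue
        sil = silhouette_samples(X, assign, metric=dendrogram.metric)
        mean_sil = float(sil.mean())
        if best is None or mean_sil > best.mean_silhouette + 1e-12:
            best = ClusterAssignment(assign, labels, k, sil, mean_sil)
    if best is None:
        raise ValueError("no valid cut found in k_range")
    return best


def pca_scores(table: FeatureTable, n_components: int = 2):
    """Principal-component scores and explained-variance fractions.

    Expects an already-scaled table. Fractions are non-increasing and sum
    to <= 1.
    """
    X, labels = _row_matrix(table)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= min(n_rows-1, n_cols) = {max_comp}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    frame.insert(0, "sample_id", labels)
    return frame, pca.explained_variance_ratio_.copy()
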