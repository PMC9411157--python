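"""End-to-end per-ROI feature extraction and library classification.

`analyze_roi` runs the full single-ROI measurement chain (Gaussian
prefilter -> GLCM texture features; tubularity -> threshold -> skeleton and
mesh morphometry) and returns one flat feature row. `classify_library`
assembles rows from many images into the combined clustering analysis.
"""

from __future__ import annotations

import pandas as pd

from .classify import (
    ClusterAssignment,
    build_feature_matrix,
    cut_and_score,
    hcluster,
    scale_features,
)
from .core import FeatureTable, PixelImage, RoiSpec
from .io import crop_roi
from .meshseg import (
    DEFAULT_RADII_PX,
    DEFAULT_THRESHOLD,
    mesh_statistics,
    qc_filter,
    segment_meshwork,
    skeletonize_and_measure,
)
from .texture import haralick_selected, prefilter_gaussian

__all__ = ["analyze_roi", "classify_library"]


def analyze_roi(
    image: PixelImage,
    roi: RoiSpec | None = None,
    sample_id: str = "",
    roi_id: str = "roi0",
    radii_px=DEFAULT_RADII_PX,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict:
    """Texture + morphometry feature row for one ROI.

    Morphometry fields of an empty segmentation are zeroed (such rows are
    dropped by QC anyway since their segmented area is 0%). The QC verdict
    and reason are included in the row.
    """
    crop = crop_roi(image, roi) if roi is not None else image
    row: dict = {"sample_id": sample_id, "roi_id": roi_id}
    row.update(haralick_selected(prefilter_gaussian(crop)).as_row())
    mask = segment_meshwork(crop, radii_px=radii_px, threshold=threshold)
    if mask.empty:
        row.update(
            n_branches=0, avg_branch_len_nm=0.0, max_branch_len_nm=0.0,
            n_junctions=0, n_triple=0, n_quadruple=0,
        )
        row.update(
            n_meshes=0, mean_mesh_area_nm2=0.0, var_mesh_area_nm2=0.0,
            pct_segmented_area=0.0,
        )
    else:
        row.update(skeletonize_and_measure(mask).as_row())
        stats = mesh_statistics(mask)
        sr = stats.as_row()
        if stats.n_meshes == 0:  # undefined mean/var -> zero for the table
            sr["mean_mesh_area_nm2"] = 0.0
            sr["var_mesh_area_nm2"] = 0.0
        row.update(sr)
    keep, reason = qc_filter(row)
    row["qc_keep"] = keep
    row["qc_reason"] = reason
    return row


def classify_library(
    rows,
    mode: str = "combined",
    metric: str = "correlation",
    k_range=range(2, 7),
    ln_transform: bool = True,
) -> tuple[ClusterAssignment, FeatureTable]:
    """Cluster a library of per-ROI feature rows into meshwork classes.

    Aggregates rows per sample, applies the scaling appropriate to the
    analysis mode (combined: ln(x+1), centering, unit variance; texture:
    centering + unit variance), clusters with average linkage under
    ``metric`` and selects k by mean silhouette.
    """
    table = FeatureTable(pd.DataFrame(list(rows)))
    matrix = build_feature_matrix(table, mode=mode)
    scaled = scale_features(
        matrix, ln_transform=(ln_transform and mode == "combined")
    )
    dend = hcluster(scaled, metric=metric)
    return cut_and_score(dend, scaled, k_range), scaled
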