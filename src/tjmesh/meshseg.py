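"""Meshwork segmentation and morphometry.

The meshwork is segmented by multiscale curvilinear (tubularity) filtering,
a fixed threshold, and retention of the largest connected region. The mask
is then thinned to a skeleton whose branches and junctions are counted and
measured, and inverted to measure the enclosed mesh (polygon) sizes,
excluding background objects touching the ROI border. QC drops ROIs whose
segmented area fraction falls outside [10%, 90%] or whose skeleton has
fewer than 10 branches.

Tubularity is the oriented-flux response in its Gaussian-smoothed
Hessian-equivalent form: at each scale r the image is smoothed with a
Gaussian of sigma r, the 2x2 Hessian is assembled, and the response is the
negated smaller eigenvalue clamped at zero (bright ridges give a strongly
negative second derivative across the ridge), gamma-normalized by r^2 so
responses are comparable across scales; the final response is the maximum
over scales.

Conventions (fixed and recorded in output metadata): mask connectivity 8,
mesh/background connectivity 4; skeleton branch lengths count orthogonal
steps as 1 px and diagonal steps as sqrt(2) px and include the single step
joining a branch to each adjacent junction node; junction nodes are
8-connected clusters of skeleton pixels with >= 3 skeleton neighbours, and
their multiplicity is the number of incident branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from skimage.morphology import skeletonize

from .core import PixelImage

__all__ = [
    "DEFAULT_RADII_PX",
    "DEFAULT_THRESHOLD",
    "MeshworkMask",
    "SkeletonStats",
    "MeshStats",
    "tubularity",
    "segment",
    "skeletonize_and_measure",
    "mesh_statistics",
    "mesh_correspondence",
    "qc_filter",
    "segment_meshwork",
]

#: Tubularity scales; strand FWHM is ~3 px at 20 nm/px.
DEFAULT_RADII_PX = (2, 3, 4)

#: Frozen segmentation threshold applied to the tubularity response of
#: max-normalized images. Calibrated once as the Otsu threshold of the
#: response over a small default-noise synthetic calibration set
#: (see :func:`calibrate_threshold`) and then fixed.
DEFAULT_THRESHOLD = 0.074

_S8 = np.ones((3, 3), dtype=int)  # 8-connectivity structure
_S4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class MeshworkMask:
    """Binary segmentation aligned to the source ROI."""

    mask: np.ndarray
    pixel_size_nm: float
    threshold_used: float
    tubularity_scales_px: tuple = DEFAULT_RADII_PX
    empty: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            self.empty = True


@dataclass
class SkeletonStats:
    n_branches: int
    avg_branch_len_nm: float
    max_branch_len_nm: float
    n_junctions_total: int
    n_triple: int
    n_quadruple: int

    def as_row(self) -> dict[str, float]:
        return {
            "n_branches": self.n_branches,
            "avg_branch_len_nm": self.avg_branch_len_nm,
            "max_branch_len_nm": self.max_branch_len_nm,
            "n_junctions": self.n_junctions_total,
            "n_triple": self.n_triple,
            "n_quadruple": self.n_quadruple,
        }


@dataclass
class MeshStats:
    n_meshes: int
    mean_mesh_area_nm2: float  # NaN when n_meshes == 0
    var_mesh_area_nm2: float  # NaN when n_meshes == 0
    pct_segmented_area: float
    areas_nm2: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def as_row(self) -> dict[str, float]:
        return {
            "n_meshes": self.n_meshes,
            "mean_mesh_area_nm2": self.mean_mesh_area_nm2,
            "var_mesh_area_nm2": self.var_mesh_area_nm2,
            "pct_segmented_area": self.pct_segmented_area,
        }


# ---------------------------------------------------------------------------
# tubularity + threshold segmentation

def tubularity(image: PixelImage, radii_px=DEFAULT_RADII_PX) -> PixelImage:
    """Multiscale curvilinear response (max over scales).

    Raises if any radius reaches half the smaller ROI dimension (the
    smoothing support would no longer fit the ROI).
    """
    radii = tuple(radii_px)
    if len(radii) == 0 or any(r < 1 for r in radii):
        raise ValueError("radii_px must be non-empty with each radius >= 1")
    if max(radii) >= min(image.shape) / 2:
        raise ValueError("tubularity radius must be < half the ROI size")
    px = image.pixels
    best = np.zeros_like(px)
    for r in radii:
        # truncate=8: the truncated second-derivative kernel must sum to ~0
        # or flat regions pick up a spurious response proportional to their
        # intensity
        ixx = ndimage.gaussian_filter(px, r, order=(0, 2), mode="reflect",
                                      truncate=8.0)
        iyy = ndimage.gaussian_filter(px, r, order=(2, 0), mode="reflect",
                                      truncate=8.0)
        ixy = ndimage.gaussian_filter(px, r, order=(1, 1), mode="reflect",
                                      truncate=8.0)
        # smaller eigenvalue of [[ixx, ixy], [ixy, iyy]]
        half_tr = 0.5 * (ixx + iyy)
        disc = np.sqrt(0.25 * (ixx - iyy) ** 2 + ixy**2)
        lam_small = half_tr - disc
        resp = np.clip(-lam_small, 0.0, None) * r**2
        np.maximum(best, resp, out=best)
    return PixelImage(best, image.pixel_size_nm, image.channel_name)


def segment(response: PixelImage, threshold: float) -> MeshworkMask:
    """Fixed threshold then largest 8-connected component.

    An all-below-threshold response yields an empty-flagged mask rather than
    an exception so QC can drop the ROI. Ties between equally large
    components go to the one whose first pixel comes first in scan order.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    binary = response.pixels >= threshold
    if not binary.any():
        return MeshworkMask(
            np.zeros_like(binary), response.pixel_size_nm, threshold, empty=True
        )
    labels, n = ndimage.label(binary, structure=_S8)
    counts = np.bincount(labels.ravel())[1:]
    # ndimage labels components in scan order, so argmax's first-maximum
    # rule implements the declared tie-break
    keep = int(np.argmax(counts)) + 1
    return MeshworkMask(labels == keep, response.pixel_size_nm, threshold)


def segment_meshwork(
    image: PixelImage,
    radii_px=DEFAULT_RADII_PX,
    threshold: float = DEFAULT_THRESHOLD,
) -> MeshworkMask:
    """Full segmentation: max-normalize, tubularity filter, fixed threshold.

    Intensities are scaled to peak 1 before filtering so the frozen
    threshold is transferable across acquisitions with different intensity
    scales.
    """
    peak = image.pixels.max()
    norm = PixelImage(
        image.pixels / peak if peak > 0 else image.pixels,
        image.pixel_size_nm,
        image.channel_name,
    )
    resp = tubularity(norm, radii_px)
    out = segment(resp, threshold)
    out.tubularity_scales_px = tuple(radii_px)
    return out


def calibrate_threshold(responses) -> float:
    """Otsu threshold pooled over a calibration set of tubularity responses.

    Used once to derive :data:`DEFAULT_THRESHOLD`; kept for reproducibility.
    """
    from skimage.filters import threshold_otsu

    pooled = np.concatenate([np.asarray(r.pixels).ravel() for r in responses])
    return float(threshold_otsu(pooled))


# ---------------------------------------------------------------------------
# skeleton morphometry

_NEIGHBOUR_OFFSETS = [
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
]


def _branch_length_px(rows: np.ndarray, cols: np.ndarray) -> float:
    """Geodesic length of one 1-px-wide branch via its minimum spanning tree.

    Orthogonal steps weigh 1, diagonal steps sqrt(2). For a clean path the
    MST is the path itself; for the rare branch containing a cycle the
    closing step is not counted (documented limitation).
    """
    n = rows.size
    if n <= 1:
        return 0.0
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(rows, cols))}
    src, dst, wts = [], [], []
    for i, (r, c) in enumerate(zip(rows, cols)):
        for dr, dc in _NEIGHBOUR_OFFSETS:
            j = index.get((int(r) + dr, int(c) + dc))
            if j is not None and j > i:
                src.append(i)
                dst.append(j)
                wts.append(math.sqrt(2.0) if dr and dc else 1.0)
    graph = coo_matrix((wts, (src, dst)), shape=(n, n))
    return float(minimum_spanning_tree(graph).sum())


def skeletonize_and_measure(mask: MeshworkMask) -> SkeletonStats:
    """Thin the mask to a 1-px skeleton and measure its branch/junction graph."""
    if mask.empty or not mask.mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = skeletonize(mask.mask)
    nm = mask.pixel_size_nm
    # neighbour count within the skeleton
    degree = ndimage.convolve(skel.astype(int), _S8, mode="constant") - skel
    junction_px = skel & (degree >= 3)
    junc_labels, n_junctions = ndimage.label(junction_px, structure=_S8)
    branch_px = skel & ~junction_px
    br_labels, n_branches_raw = ndimage.label(branch_px, structure=_S8)

    lengths_px: list[float] = []
    incidence: dict[int, set[int]] = {j: set() for j in range(1, n_junctions + 1)}
    # pad label grids so neighbour lookups need no bound checks
    jpad = np.pad(junc_labels, 1)
    for b in range(1, n_branches_raw + 1):
        rr, cc = np.nonzero(br_labels == b)
        length = _branch_length_px(rr, cc)
        # one connecting step per adjacent junction node (min step weight)
        adjacent: dict[int, float] = {}
        for r, c in zip(rr, cc):
            for dr, dc in _NEIGHBOUR_OFFSETS:
                j = jpad[r + 1 + dr, c + 1 + dc]
                if j:
                    step = math.sqrt(2.0) if dr and dc else 1.0
                    adjacent[j] = min(adjacent.get(j, step), step)
        for j, step in adjacent.items():
            length += step
            incidence[j].add(b)
        lengths_px.append(length)

    if lengths_px:
        lengths_nm = np.asarray(lengths_px) * nm
        avg_len, max_len = float(lengths_nm.mean()), float(lengths_nm.max())
    else:
        avg_len = max_len = 0.0
    multiplicities = [len(v) for v in incidence.values()]
    return SkeletonStats(
        n_branches=n_branches_raw,
        avg_branch_len_nm=avg_len,
        max_branch_len_nm=max_len,
        n_junctions_total=n_junctions,
        n_triple=sum(1 for m in multiplicities if m == 3),
        n_quadruple=sum(1 for m in multiplicities if m == 4),
    )


# ---------------------------------------------------------------------------
# mesh (enclosed polygon) statistics

def mesh_statistics(mask: MeshworkMask) -> MeshStats:
    """Mesh sizes from the inverted mask, excluding border-touching objects.

    Meshes are 4-connected background components not touching the ROI
    border; areas are converted to nm^2 via the pixel size. Zero meshes is a
    valid result (mean/var reported as NaN). Variance is the population
    variance of the mesh areas.
    """
    grid = mask.mask
    nm2 = mask.pixel_size_nm**2
    pct = 100.0 * grid.sum() / grid.size
    labels, n = ndimage.label(~grid, structure=_S4)
    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.setdiff1d(np.arange(1, n + 1), border)
    areas = counts[keep].astype(np.float64) * nm2
    if areas.size:
        mean_a, var_a = float(areas.mean()), float(areas.var())
    else:
        mean_a = var_a = float("nan")
    return MeshStats(
        n_meshes=int(areas.size),
        mean_mesh_area_nm2=mean_a,
        var_mesh_area_nm2=var_a,
        pct_segmented_area=float(pct),
        areas_nm2=areas,
    )


def mesh_correspondence(
    truth: MeshworkMask, measured: MeshworkMask, min_area_nm2: float = 0.0
) -> tuple[int, int]:
    """One-to-one matching of measured meshes to ground-truth meshes.

    Returns ``(n_truth, n_matched)`` where ``n_truth`` counts ground-truth
    meshes with area >= ``min_area_nm2`` and ``n_matched`` counts those
    covered by exactly one measured mesh not shared with any other truth
    mesh. Equality means the segmentation neither merged nor split any mesh
    above the size floor.
    """

    def _labelled(mask: MeshworkMask):
        labels, n = ndimage.label(~mask.mask, structure=_S4)
        border = set(
            np.unique(
                np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
            )
        )
        return labels, [l for l in range(1, n + 1) if l not in border]

    nm2 = truth.pixel_size_nm**2
    t_lab, t_keep = _labelled(truth)
    m_lab, m_keep = _labelled(measured)
    m_keep_set = set(m_keep)
    large = [l for l in t_keep if (t_lab == l).sum() * nm2 >= min_area_nm2]
    used: set[int] = set()
    matched = 0
    for l in large:
        inside = (set(np.unique(m_lab[t_lab == l])) - {0}) & m_keep_set
        if len(inside) == 1 and not (inside & used):
            matched += 1
            used |= inside
    return len(large), matched


# ---------------------------------------------------------------------------
# QC

def qc_filter(row) -> tuple[bool, str]:
    """Keep rule: 10% <= segmented area <= 90% and >= 10 branches.

    Boundary values are kept ("less/more than" are strict exclusions). The
    reason string records which rule fired.
    """
    try:
        area = float(row["pct_segmented_area"])
        branches = float(row["n_branches"])
    except (KeyError, TypeError) as exc:
        raise KeyError(
            "row must provide pct_segmented_area and n_branches"
        ) from exc
    if area < 10.0:
        return False, "area<10%"
    if area > 90.0:
        return False, "area>90%"
    if branches < 10:
        return False, "branches<10"
    return True, "ok"
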