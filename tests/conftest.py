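"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive each quantity by the most direct
(slow) route — explicit pair enumeration for GLCM features, breadth-first
flood fill for mesh areas, the textbook O(n^3) agglomeration for average
linkage — so the pipeline implementations are checked against code that
shares none of their machinery.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from tjmesh.core import PixelImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(arr, pixel_size_nm=20.0):
    return PixelImage(np.asarray(arr, dtype=float), pixel_size_nm)


# ---------------------------------------------------------------------------
# GLCM / Haralick oracle: explicit enumeration of all ordered pixel pairs

# (dr, dc) = (d sin(theta), d cos(theta)), rows increasing downwards
_ANGLE_OFFSETS = {
    0.0: (0, 1),
    math.pi / 4: (1, 1),
    math.pi / 2: (1, 0),
    3 * math.pi / 4: (1, -1),
}


def glcm_oracle(levels: np.ndarray, distance: int, angle: float,
                n_levels: int) -> np.ndarray:
    """Symmetric normalized GLCM by brute-force pair enumeration."""
    dr, dc = _ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = levels.shape
    counts = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[levels[r, c], levels[r2, c2]] += 1
                counts[levels[r2, c2], levels[r, c]] += 1
    total = counts.sum()
    return counts / total if total else counts


def haralick_oracle(levels: np.ndarray, distance: int, angle: float,
                    n_levels: int) -> dict:
    """The three selected features computed directly from the definitions."""
    p = glcm_oracle(levels, distance, angle, n_levels)
    ng = n_levels
    f_sa = f_sv = f_var = 0.0
    p_sum = {}
    for i in range(ng):
        for j in range(ng):
            k = (i + 1) + (j + 1)
            p_sum[k] = p_sum.get(k, 0.0) + p[i, j]
    f_sa = sum(k * v for k, v in p_sum.items())
    f_sv = sum((k - f_sa) ** 2 * v for k, v in p_sum.items())
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    f_var = sum(((i + 1) - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    return {"sum_average": f_sa, "sum_variance": f_sv, "variance_sos": f_var}


# ---------------------------------------------------------------------------
# flood-fill oracle for mesh statistics

def mesh_oracle(mask: np.ndarray, pixel_size_nm: float):
    """Mesh areas by explicit BFS flood fill of the inverted mask (4-conn)."""
    h, w = mask.shape
    seen = np.array(mask, dtype=bool)  # treat mask pixels as visited
    areas = []
    for r0 in range(h):
        for c0 in range(w):
            if seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            pixels = []
            touches_border = False
            while stack:
                r, c = stack.pop()
                pixels.append((r, c))
                if r in (0, h - 1) or c in (0, w - 1):
                    touches_border = True
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            if not touches_border:
                areas.append(len(pixels) * pixel_size_nm**2)
    return areas


# ---------------------------------------------------------------------------
# O(n^3) average-linkage oracle

def average_linkage_oracle(dists: np.ndarray):
    """Textbook agglomeration on a full distance matrix.

    Returns the merge heights (sorted) and the cophenetic distance matrix;
    clusters merge at the unweighted mean of pairwise inter-cluster
    distances, smallest-index pair first on ties.
    """
    n = dists.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = np.mean(
                    [dists[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights), coph


# ---------------------------------------------------------------------------
# cluster purity

def label_purity(assigned_labels, true_labels) -> float:
    """Fraction of samples whose cluster's majority truth label matches theirs."""
    from collections import Counter

    assigned = np.asarray(assigned_labels)
    true = np.asarray(true_labels)
    correct = 0
    for c in np.unique(assigned):
        members = true[assigned == c]
        correct += Counter(members).most_common(1)[0][1]
    return correct / len(true)
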