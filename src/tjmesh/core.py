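"""Core domain types shared across the pipeline.

All coordinates are 0-based with x increasing rightwards (columns) and y
increasing downwards (rows). Rectangular ROIs are half-open:
``[origin, origin + size)``. Image intensities are promoted to
double-precision floats at load; explicit gray-level quantization is applied
later by the texture stage where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PixelImage", "RoiSpec", "FeatureTable"]


@dataclass
class PixelImage:
    """A 2D intensity grid with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        Non-negative, finite 2D intensity grid. Promoted to float64.
    pixel_size_nm : float
        Physical edge length of one pixel in nanometres. The study's
        conventions are 18.9 nm (STED acquisition) and 20 nm (texture
        analysis); both are simply stored here.
    channel_name : str
        Free-text channel label.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be >= 0")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest, default 200 x 200 px.

    ``origin_xy`` is the (x, y) pixel coordinate of the top-left corner,
    0-based; the ROI covers the half-open box
    ``[x, x + width) x [y, y + height)``.
    """

    origin_xy: tuple[int, int] = (0, 0)
    width_px: int = 200
    height_px: int = 200

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("ROI width and height must be >= 1")
        if self.origin_xy[0] < 0 or self.origin_xy[1] < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate_within(self, image: PixelImage) -> None:
        h, w = image.shape
        x, y = self.origin_xy
        if x + self.width_px > w or y + self.height_px > h:
            raise ValueError(
                f"ROI {self} exceeds image bounds {w}x{h} (width x height)"
            )


@dataclass
class FeatureTable:
    """Per-ROI feature rows keyed by (sample_id, roi_id) plus provenance.

    ``data`` is a pandas DataFrame; key columns ``sample_id``, ``roi_id`` and
    optionally ``group_label`` identify rows, the remaining columns are
    numeric features. ``provenance`` records config hash and seed so every
    output table can be traced to the run that produced it.
    """

    data: "object"  # pandas.DataFrame; typed loosely to keep core light
    provenance: dict = field(default_factory=dict)

    KEY_COLUMNS = ("sample_id", "roi_id", "group_label")

    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.KEY_COLUMNS]
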