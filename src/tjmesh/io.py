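"""Image / ROI / table / config I/O shared by all pipeline stages.

TIFF images are read and written with :mod:`tifffile`; feature and
physiology tables are CSV via pandas (values serialized with 12 significant
digits, so a write -> read round trip reproduces them to that precision);
ROIs, line coordinates and config echoes are JSON; run configuration is a
single YAML file whose SHA-256 hash is logged into every output table for
provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import FeatureTable, PixelImage, RoiSpec

__all__ = [
    "read_image",
    "write_image",
    "crop_roi",
    "read_feature_table",
    "write_feature_table",
    "read_rois",
    "write_rois",
    "load_config",
    "config_hash",
]

_MAX_CHANNELS = 4


def read_image(path, pixel_size_nm: float, channel_names=None) -> list[PixelImage]:
    """Read a single- or multi-channel TIFF as one :class:`PixelImage` per channel.

    Channel axes are recognised as a leading or trailing axis of length
    <= 4; anything with more than two spatial dimensions per channel is
    rejected. Integer data are promoted to float64.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not pixel_size_nm > 0:
        raise ValueError("pixel_size_nm must be > 0")
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        planes = [arr]
    elif arr.ndim == 3 and arr.shape[0] <= _MAX_CHANNELS:
        planes = [arr[c] for c in range(arr.shape[0])]
    elif arr.ndim == 3 and arr.shape[-1] <= _MAX_CHANNELS:
        planes = [arr[..., c] for c in range(arr.shape[-1])]
    else:
        raise ValueError(
            f"cannot interpret TIFF of shape {arr.shape}: more than 2 "
            "spatial dimensions per channel"
        )
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(len(planes))]
    return [
        PixelImage(p, pixel_size_nm=pixel_size_nm, channel_name=n)
        for p, n in zip(planes, channel_names)
    ]


def write_image(path, images) -> None:
    """Write one or more :class:`PixelImage` channels to a TIFF file.

    Integer-valued data are stored as uint16 when within range (bit-exact
    round trip); anything else is stored as float32.
    """
    if isinstance(images, PixelImage):
        images = [images]
    stack = np.stack([im.pixels for im in images])
    if np.all(stack == np.round(stack)) and stack.max(initial=0) <= np.iinfo(np.uint16).max:
        stack = stack.astype(np.uint16)
    else:
        stack = stack.astype(np.float32)
    tifffile.imwrite(path, stack[0] if len(images) == 1 else stack)


def crop_roi(image: PixelImage, roi: RoiSpec) -> PixelImage:
    """Extract the ROI crop; pixel size and channel name are preserved."""
    roi.validate_within(image)
    x, y = roi.origin_xy
    block = image.pixels[y : y + roi.height_px, x : x + roi.width_px]
    return PixelImage(block.copy(), image.pixel_size_nm, image.channel_name)


# ---------------------------------------------------------------------------
# tables

def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table to CSV with provenance as '#'-prefixed header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in sorted(table.provenance.items()):
            fh.write(f"# {key}: {value}\n")
        table.data.to_csv(fh, index=False, float_format="%.12g")


def read_feature_table(path, expect_columns=None) -> FeatureTable:
    """Read a CSV feature table; ``expect_columns`` enforces the column contract."""
    path = Path(path)
    provenance = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            provenance[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        data = pd.read_csv(fh)
    if expect_columns is not None:
        missing = [c for c in expect_columns if c not in data.columns]
        if missing:
            raise ValueError(f"CSV {path} is missing columns: {missing}")
    return FeatureTable(data=data, provenance=provenance)


# ---------------------------------------------------------------------------
# ROIs, polylines, config

def write_rois(rois, path) -> None:
    payload = [
        {"x": r.origin_xy[0], "y": r.origin_xy[1], "width": r.width_px, "height": r.height_px}
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_rois(path) -> list[RoiSpec]:
    payload = json.loads(Path(path).read_text())
    return [
        RoiSpec(origin_xy=(int(d["x"]), int(d["y"])), width_px=int(d["width"]),
                height_px=int(d["height"]))
        for d in payload
    ]


def load_config(path) -> dict:
    """Load a structured YAML config file (nested key/value sections)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping at top level")
    return cfg


def config_hash(cfg: dict) -> str:
    """Short, order-independent SHA-256 hash of a config mapping."""
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
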