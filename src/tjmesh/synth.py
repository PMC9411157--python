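"""Seeded synthetic STED-like data with known ground truth.

Every downstream stage of the pipeline is testable without real microscopy
or Ussing-chamber recordings via this module. It emulates:

* single-channel claudin meshwork images in the three morphology regimes
  the classification stage must separate — large polygonal meshes
  (class A, ~600 nm mean mesh diameter), much smaller meshes (class B,
  ~250 nm), and dense near-parallel strands (class C, ~150 nm spacing) —
  plus the non-meshwork phenotypes (uniform, punctae, clusters);
* two-channel co-expression patterns (intermix, integrate, induction,
  segregate, exclude) with per-channel ground-truth strand maps;
* noisy Gaussian line profiles for the strand-width (FWHM) stage;
* GHK forward-model dilution-potential datasets;
* emission lambda-stacks for spectral unmixing / FRET.

Strand centerlines are built from a seeded perturbed-grid tessellation
(classes A/B; the mean tessellation cell area equals the squared grid
spacing exactly) or jittered parallel sinusoids (class C), rendered as
Gaussian-cross-section tubes (sigma ``strand_sigma_nm``), blurred with a
Gaussian PSF (default sigma 21 nm, i.e. ~50 nm lateral FWHM resolution),
and corrupted with Poisson shot noise plus additive Gaussian read noise,
clipped at zero. A noiseless render of a straight strand therefore has an
exactly Gaussian cross-section with sigma
sqrt(strand_sigma^2 + psf_sigma^2).

Induction is generated identically to intermixing: the distinction between
the two co-expression patterns is biological (whether either claudin forms
strands alone), not geometric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi, cKDTree

from .coloc import FWHM_FACTOR, LineProfile
from .core import PixelImage
from .meshseg import MeshStats, MeshworkMask, SkeletonStats, mesh_statistics, \
    skeletonize_and_measure
from .physiol import FRET_PRESETS, DilutionExperiment, SpectralStack, \
    dilution_from_ratio

__all__ = [
    "ARCHETYPES",
    "TWO_CHANNEL_MODES",
    "SynthConfig",
    "TwoChannelTruth",
    "default_config",
    "make_meshwork",
    "make_two_channel",
    "make_line_profile",
    "make_dilution_dataset",
    "reference_spectra",
    "make_fret_spectrum",
]

ARCHETYPES = (
    "class_A_large_mesh",
    "class_B_small_mesh",
    "class_C_dense_parallel",
    "punctae",
    "uniform",
    "clusters",
)
TWO_CHANNEL_MODES = ("intermix", "integrate", "induction", "segregate", "exclude")

#: mean mesh diameter (A/B), strand spacing (C) or feature spacing (others), nm
_ARCHETYPE_SCALE_NM = {
    "class_A_large_mesh": 600.0,
    "class_B_small_mesh": 250.0,
    "class_C_dense_parallel": 150.0,
    "punctae": 400.0,
    "clusters": 600.0,
    "uniform": 400.0,
}

_SAMPLE_STEP_PX = 0.15  # centerline sampling step for rendering


@dataclass
class SynthConfig:
    """Generator parameters; defaults are the study's imaging conditions.

    ``mean_mesh_diameter_nm`` is the target mean mesh diameter for the
    polygonal classes and the strand spacing for class C. ``dispersion``
    (0..1) jitters the underlying point grid / strand paths.
    """

    archetype: str
    mean_mesh_diameter_nm: float
    dispersion: float = 0.35
    strand_sigma_nm: float = 25.0
    psf_sigma_nm: float = 21.0
    photon_scale: float = 50.0
    read_noise_sd: float = 2.0
    pixel_size_nm: float = 20.0
    image_size_px: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        for v in (self.mean_mesh_diameter_nm, self.strand_sigma_nm,
                  self.psf_sigma_nm, self.pixel_size_nm):
            if not v > 0:
                raise ValueError("all length scales must be > 0")
        if not self.photon_scale > 0:
            raise ValueError("photon_scale must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.image_size_px < 8:
            raise ValueError("image too small")


@dataclass
class TwoChannelTruth:
    """Ground truth of a two-channel co-expression render."""

    mode: str
    segment_length_nm: float | None
    mask_ch1: np.ndarray = field(repr=False)
    mask_ch2: np.ndarray = field(repr=False)


def default_config(archetype: str, seed: int = 0, **overrides) -> SynthConfig:
    """Study-condition defaults for one archetype."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    cfg = SynthConfig(
        archetype=archetype,
        mean_mesh_diameter_nm=_ARCHETYPE_SCALE_NM[archetype],
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# centerline geometry

def _grid_points(size_px: float, spacing_px: float, dispersion: float,
                 rng: np.random.Generator, pad_px: float) -> np.ndarray:
    """Perturbed square grid of tessellation seeds over a padded region."""
    lo, hi = -pad_px, size_px + pad_px
    coords = np.arange(lo + spacing_px / 2, hi, spacing_px)
    gx, gy = np.meshgrid(coords, coords)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    jitter = rng.uniform(-0.5, 0.5, pts.shape) * dispersion * spacing_px * 2
    return pts + jitter


def _voronoi_polylines(cfg: SynthConfig, rng: np.random.Generator):
    """Voronoi ridge segments of a perturbed-grid point process.

    The grid spacing s is chosen so the mean tessellation cell area s^2
    equals (pi/4) * mean_mesh_diameter^2; the expected cell area is exact
    by construction and reported in metadata.
    """
    px = cfg.pixel_size_nm
    d_px = cfg.mean_mesh_diameter_nm / px
    spacing = math.sqrt(math.pi / 4.0) * d_px
    pts = _grid_points(cfg.image_size_px, spacing, cfg.dispersion, rng,
                       pad_px=2 * spacing)
    vor = Voronoi(pts)
    polylines = []
    for (i, j) in vor.ridge_vertices:
        if i == -1 or j == -1:
            continue
        polylines.append(np.array([vor.vertices[i], vor.vertices[j]]))
    return polylines, spacing**2 * px**2


def _parallel_polylines(cfg: SynthConfig, rng: np.random.Generator):
    """Near-parallel jittered sinusoidal strands (class C)."""
    size = cfg.image_size_px
    spacing = cfg.mean_mesh_diameter_nm / cfg.pixel_size_nm
    amp = cfg.dispersion * spacing
    xs = np.arange(-2.0, size + 2.0, 0.5)
    polylines = []
    y0 = rng.uniform(0, spacing)
    while y0 < size:
        period = rng.uniform(8, 20) * spacing
        phase = rng.uniform(0, 2 * math.pi)
        ys = y0 + amp * np.sin(2 * math.pi * xs / period + phase)
        polylines.append(np.column_stack([xs, ys]))
        y0 += spacing
    return polylines


def _point_polylines(cfg: SynthConfig, rng: np.random.Generator,
                     clustered: bool):
    """Degenerate single-point 'polylines' for punctae / clusters."""
    size = cfg.image_size_px
    spacing = cfg.mean_mesh_diameter_nm / cfg.pixel_size_nm
    n = max(4, int((size / spacing) ** 2))
    if not clustered:
        pts = rng.uniform(0, size, (n, 2))
    else:
        n_clusters = max(3, n // 12)
        centers = rng.uniform(0, size, (n_clusters, 2))
        idx = rng.integers(0, n_clusters, n)
        pts = centers[idx] + rng.normal(0, 1.5 * spacing / 4, (n, 2))
    return [p[None, :] for p in pts]


def _polylines_for(cfg: SynthConfig, rng: np.random.Generator):
    """Centerline polylines + expected cell area (nm^2, NaN if undefined)."""
    if cfg.archetype in ("class_A_large_mesh", "class_B_small_mesh"):
        if cfg.mean_mesh_diameter_nm < 3 * cfg.pixel_size_nm:
            raise ValueError("mesh diameter < 3 pixels is unresolvable")
        if cfg.mean_mesh_diameter_nm >= cfg.image_size_px * cfg.pixel_size_nm:
            raise ValueError("image too small to contain a single mesh")
        return _voronoi_polylines(cfg, rng)
    if cfg.archetype == "class_C_dense_parallel":
        return _parallel_polylines(cfg, rng), float("nan")
    if cfg.archetype == "uniform":
        return [], float("nan")
    return _point_polylines(cfg, rng, clustered=cfg.archetype == "clusters"), \
        float("nan")


def _sample_polyline(poly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dense sample points along a polyline plus their arclengths (px)."""
    if poly.shape[0] == 1:
        return poly, np.zeros(1)
    segs = np.diff(poly, axis=0)
    seglen = np.hypot(segs[:, 0], segs[:, 1])
    total = seglen.sum()
    n = max(2, int(math.ceil(total / _SAMPLE_STEP_PX)) + 1)
    s = np.linspace(0.0, total, n)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    xs = np.interp(s, cum, poly[:, 0])
    ys = np.interp(s, cum, poly[:, 1])
    return np.column_stack([xs, ys]), s


def _in_bounds(pts: np.ndarray, size: int) -> np.ndarray:
    return (
        (pts[:, 0] >= 0) & (pts[:, 0] <= size - 1)
        & (pts[:, 1] >= 0) & (pts[:, 1] <= size - 1)
    )


def _rasterize(pts: np.ndarray, size: int) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    if pts.size:
        inb = _in_bounds(pts, size)
        cc = np.round(pts[inb, 0]).astype(int)
        rr = np.round(pts[inb, 1]).astype(int)
        mask[rr, cc] = True
    return mask


def _render_signal(pts: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Unit-peak noiseless signal: Gaussian tubes around the sample points."""
    size = cfg.image_size_px
    if pts.size == 0:
        return np.full((size, size), 0.3)
    sigma_px = cfg.strand_sigma_nm / cfg.pixel_size_nm
    tree = cKDTree(pts)
    gy, gx = np.mgrid[0:size, 0:size]
    d, _ = tree.query(np.column_stack([gx.ravel(), gy.ravel()]))
    base = np.exp(-(d**2) / (2 * sigma_px**2)).reshape(size, size)
    psf_px = cfg.psf_sigma_nm / cfg.pixel_size_nm
    return ndimage.gaussian_filter(base, psf_px, mode="constant", truncate=6.0)


def _apply_noise(signal: np.ndarray, cfg: SynthConfig,
                 rng: np.random.Generator | None) -> np.ndarray:
    expected = cfg.photon_scale * signal
    if rng is None:
        return expected
    noisy = rng.poisson(expected).astype(np.float64)
    if cfg.read_noise_sd > 0:
        noisy += rng.normal(0.0, cfg.read_noise_sd, signal.shape)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# public generators

def make_meshwork(cfg: SynthConfig, noiseless: bool = False):
    """Render one meshwork image with its ground truth.

    Returns ``(image, truth_mask, truth_skeleton, metadata)`` where
    ``truth_mask`` holds the 1-px rasterized centerlines, ``truth_skeleton``
    their branch/junction statistics, and ``metadata`` includes the
    tessellation's expected cell area and the ground-truth mesh statistics
    measured on the centerline complement.
    """
    rng = np.random.default_rng(cfg.seed)
    polylines, expected_area = _polylines_for(cfg, rng)
    sampled = [_sample_polyline(p)[0] for p in polylines]
    pts = np.concatenate(sampled) if sampled else np.empty((0, 2))
    pts = pts[_in_bounds(pts, cfg.image_size_px)] if pts.size else pts
    signal = _render_signal(pts, cfg)
    image = PixelImage(
        _apply_noise(signal, cfg, None if noiseless else rng),
        cfg.pixel_size_nm,
        cfg.archetype,
    )
    truth_mask = MeshworkMask(
        _rasterize(pts, cfg.image_size_px), cfg.pixel_size_nm,
        threshold_used=float("nan"),
    )
    if truth_mask.empty:
        truth_skel = SkeletonStats(0, 0.0, 0.0, 0, 0, 0)
        truth_mesh = MeshStats(0, float("nan"), float("nan"), 0.0)
    else:
        truth_skel = skeletonize_and_measure(truth_mask)
        truth_mesh = mesh_statistics(truth_mask)
    metadata = {
        "archetype": cfg.archetype,
        "seed": cfg.seed,
        "expected_cell_area_nm2": expected_area,
        "truth_mesh_stats": truth_mesh,
        "strand_fwhm_nm": FWHM_FACTOR
        * math.hypot(cfg.strand_sigma_nm, cfg.psf_sigma_nm),
    }
    return image, truth_mask, truth_skel, metadata


def make_two_channel(
    cfg: SynthConfig,
    mode: str,
    segment_length_nm: float = 500.0,
    noiseless: bool = False,
):
    """Render a two-channel co-expression pattern with ground truth.

    intermix / integrate / induction: both channels share the same strand
    centerlines (independent noise). segregate: every strand is partitioned
    into alternating single-channel stretches of ``segment_length_nm``.
    exclude: two spatially disjoint meshworks (left/right halves from
    independent tessellations).
    """
    if mode not in TWO_CHANNEL_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    size = cfg.image_size_px
    rng = np.random.default_rng(cfg.seed)
    strand_fwhm = FWHM_FACTOR * math.hypot(cfg.strand_sigma_nm, cfg.psf_sigma_nm)

    if mode == "exclude":
        polys1, _ = _polylines_for(cfg, rng)
        polys2, _ = _polylines_for(cfg, rng)
        gap = strand_fwhm / cfg.pixel_size_nm
        pts1 = np.concatenate([_sample_polyline(p)[0] for p in polys1])
        pts2 = np.concatenate([_sample_polyline(p)[0] for p in polys2])
        pts1 = pts1[pts1[:, 0] < size / 2 - gap]
        pts2 = pts2[pts2[:, 0] > size / 2 + gap]
    elif mode == "segregate":
        if segment_length_nm < strand_fwhm:
            raise ValueError(
                f"segment_length_nm must be >= the strand FWHM ({strand_fwhm:.0f} nm)"
            )
        seg_px = segment_length_nm / cfg.pixel_size_nm
        polylines, _ = _polylines_for(cfg, rng)
        parts1, parts2 = [], []
        for poly in polylines:
            pts, arclen = _sample_polyline(poly)
            phase = rng.uniform(0, 2 * seg_px)
            parity = (np.floor((arclen + phase) / seg_px) % 2).astype(int)
            parts1.append(pts[parity == 0])
            parts2.append(pts[parity == 1])
        pts1 = np.concatenate([p for p in parts1 if p.size] or [np.empty((0, 2))])
        pts2 = np.concatenate([p for p in parts2 if p.size] or [np.empty((0, 2))])
    else:  # intermix / integrate / induction share the geometry
        polylines, _ = _polylines_for(cfg, rng)
        pts1 = pts2 = np.concatenate([_sample_polyline(p)[0] for p in polylines])

    pts1 = pts1[_in_bounds(pts1, size)] if pts1.size else pts1
    pts2 = pts2[_in_bounds(pts2, size)] if pts2.size else pts2
    sig1 = _render_signal(pts1, cfg)
    sig2 = _render_signal(pts2, cfg)
    rng1 = np.random.default_rng(rng.integers(2**31))
    rng2 = np.random.default_rng(rng.integers(2**31))
    ch1 = PixelImage(_apply_noise(sig1, cfg, None if noiseless else rng1),
                     cfg.pixel_size_nm, "ch1")
    ch2 = PixelImage(_apply_noise(sig2, cfg, None if noiseless else rng2),
                     cfg.pixel_size_nm, "ch2")
    mask1 = _rasterize(pts1, size)
    mask2 = _rasterize(pts2, size)
    if mode in ("segregate", "exclude"):
        overlap = mask1 & mask2  # rounding collisions at segment boundaries
        mask1 &= ~overlap
        mask2 &= ~overlap
    truth = TwoChannelTruth(
        mode=mode,
        segment_length_nm=segment_length_nm if mode == "segregate" else None,
        mask_ch1=mask1,
        mask_ch2=mask2,
    )
    return ch1, ch2, truth


def make_line_profile(
    sigma_nm: float,
    amplitude: float = 100.0,
    offset: float = 10.0,
    noise_sd: float = 0.0,
    n_points: int = 31,
    spacing_nm: float = 10.0,
    seed: int = 0,
    center_nm: float | None = None,
) -> LineProfile:
    """Gaussian bump + offset + i.i.d. Gaussian noise on a regular grid."""
    if n_points < 7:
        raise ValueError("need >= 7 points")
    if not (sigma_nm > 0 and spacing_nm > 0):
        raise ValueError("sigma and spacing must be > 0")
    rng = np.random.default_rng(seed)
    x = np.arange(n_points, dtype=np.float64) * spacing_nm
    mu = float(x[-1]) / 2 if center_nm is None else center_nm
    y = amplitude * np.exp(-((x - mu) ** 2) / (2 * sigma_nm**2)) + offset
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_points)
    return LineProfile(x, y, ((0.0, 0.0), (0.0, 0.0)), width_px=1)


def make_dilution_dataset(
    r_true: float,
    ter_true: float,
    n: int = 1,
    noise_sd_mv: float = 0.5,
    seed: int = 0,
    temperature_k: float = 310.15,
    concentrations: tuple[float, float, float, float] | None = None,
) -> list[DilutionExperiment]:
    """Forward-model dilution-potential records with Gaussian voltage noise.

    ``concentrations`` is (cNa_api, cCl_api, cNa_baso, cCl_baso) in mM;
    default is the study's solution pair.
    """
    if not (r_true > 0 and ter_true > 0):
        raise ValueError("r_true and TER must be > 0")
    rng = np.random.default_rng(seed)
    kw = {}
    if concentrations is not None:
        kw = dict(zip(("c_na_api", "c_cl_api", "c_na_baso", "c_cl_baso"),
                      concentrations))
    base = DilutionExperiment(temperature_k=temperature_k,
                              ter_ohm_cm2=ter_true, **kw)
    v_model = dilution_from_ratio(r_true, base)
    out = []
    for _ in range(n):
        v = v_model + (rng.normal(0.0, noise_sd_mv) if noise_sd_mv > 0 else 0.0)
        out.append(replace(base, v_dil_mv=float(v)))
    return out


def reference_spectra(preset: str = "hek"):
    """Synthetic unit-peak donor/acceptor emission reference spectra.

    Gaussian-shaped stand-ins peaking at the preset's donor/acceptor
    readout wavelengths (not measured fluorophore spectra).
    """
    if preset not in FRET_PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    lam_d, lam_a = FRET_PRESETS[preset]
    wl = np.arange(430.0, 651.0, 2.0)
    s_d = np.exp(-((wl - lam_d) ** 2) / (2 * 32.0**2))
    s_a = np.exp(-((wl - lam_a) ** 2) / (2 * 27.0**2))
    return wl, s_d, s_a, lam_d, lam_a


def make_fret_spectrum(
    c_donor: float,
    c_sensitized: float,
    c_direct: float = 0.0,
    preset: str = "hek",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SpectralStack, float]:
    """Forward-simulated lambda-stack; returns (stack, true FRET ratio).

    The measured spectrum is c_donor * S_D + (c_sensitized + c_direct) * S_A
    plus optional Gaussian noise; the true ratio divides the sensitized
    acceptor emission at the acceptor readout by the donor emission at the
    donor readout.
    """
    if c_donor <= 0:
        raise ValueError("c_donor must be > 0")
    wl, s_d, s_a, lam_d, lam_a = reference_spectra(preset)
    measured = c_donor * s_d + (c_sensitized + c_direct) * s_a
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        measured = np.clip(measured + rng.normal(0, noise_sd, wl.size), 0, None)
    stack = SpectralStack(
        wl, measured, s_d, s_a, lambda_donor=lam_d, lambda_acceptor=lam_a,
        direct_acceptor_coef=c_direct,
    )
    true_ratio = (
        c_sensitized * float(np.interp(lam_a, wl, stack.s_acceptor))
        / (c_donor * float(np.interp(lam_d, wl, stack.s_donor)))
    )
    return stack, true_ratio
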