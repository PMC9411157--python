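"""Electrophysiology and spectral-FRET computations.

Dilution-potential permeametry: when NaCl on the apical side of an
epithelial monolayer is partially replaced by mannitol, the voltage across
the tight junction follows the Goldman-Hodgkin-Katz (GHK) equation for a
Na+/Cl- selective barrier,

    V = (RT/F) * ln[(r * cNa_baso + cCl_api) / (r * cNa_api + cCl_baso)],

with r = PNa/PCl the permeability ratio and V the apical-minus-basolateral
potential (so cations diluted apically give V > 0 for r > 1; the symmetric
solution pair used here, 140/128.8 mM vs 80.5/69.3 mM, makes r = 1 imply
V = 0 exactly). Absolute permeabilities follow the Kimizuka-Koketsu
partition of the trans-epithelial conductance G = 1/TER:

    PCl = G R T / (F^2 (r cNa + cCl)),   PNa = r PCl,

with the symmetric Ringer concentrations in mol/cm^3; permeabilities are
reported in 1e-6 cm/s. Tracer fluxes give the apparent permeability
Papp = (dC/dt * V_baso) / (A * C0) from an ordinary least-squares slope.

Spectral FRET: an emission lambda-stack is unmixed into donor and acceptor
reference spectra by linear least squares; the FRET ratio divides the
crosstalk-corrected acceptor emission at the acceptor readout wavelength by
the donor emission at the donor readout wavelength (instrument presets
468/532 nm and 478/530 nm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "R_GAS",
    "FARADAY",
    "DilutionExperiment",
    "PermeabilityResult",
    "FluxExperiment",
    "SpectralStack",
    "FRET_PRESETS",
    "dilution_from_ratio",
    "ratio_from_dilution",
    "estimate_ratio",
    "absolute_permeabilities",
    "papp_flux",
    "unmix_spectrum",
    "fret_ratio",
]

R_GAS = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol

#: Donor/acceptor readout wavelengths (nm) for the two instrument configs.
FRET_PRESETS = {"hek": (468.0, 532.0), "cos7": (478.0, 530.0)}


@dataclass
class DilutionExperiment:
    """One Ussing-chamber dilution-potential record.

    Concentrations in mM; the defaults are the study's Ringer
    (140 mM Na+ / 128.8 mM Cl- basolateral) and mannitol-modified apical
    solution (80.5 mM Na+ / 69.3 mM Cl-). ``v_dil_mv`` is apical minus
    basolateral.
    """

    c_na_api: float = 80.5
    c_cl_api: float = 69.3
    c_na_baso: float = 140.0
    c_cl_baso: float = 128.8
    v_dil_mv: float = 0.0
    ter_ohm_cm2: float = float("nan")
    temperature_k: float = 310.15

    def __post_init__(self) -> None:
        for c in (self.c_na_api, self.c_cl_api, self.c_na_baso, self.c_cl_baso):
            if not c > 0:
                raise ValueError("concentrations must be > 0")
        if not (270.0 < self.temperature_k < 320.0):
            raise ValueError("temperature must lie in (270, 320) K")
        if not (math.isnan(self.ter_ohm_cm2) or self.ter_ohm_cm2 > 0):
            raise ValueError("TER must be > 0")

    @property
    def rt_over_f_mv(self) -> float:
        return 1e3 * R_GAS * self.temperature_k / FARADAY


@dataclass
class PermeabilityResult:
    ratio: float  # PNa / PCl
    p_na: float  # 1e-6 cm/s
    p_cl: float  # 1e-6 cm/s


@dataclass
class FluxExperiment:
    """Tracer accumulation time course in the basolateral compartment."""

    times_min: np.ndarray
    c_baso_um: np.ndarray
    volume_baso_ml: float = 5.0
    area_cm2: float = 0.6
    c0_apical_um: float = 100.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=np.float64)
        self.c_baso_um = np.asarray(self.c_baso_um, dtype=np.float64)
        if self.times_min.size != self.c_baso_um.size:
            raise ValueError("times and concentrations must match in length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (self.c0_apical_um > 0 and self.area_cm2 > 0 and self.volume_baso_ml > 0):
            raise ValueError("C0, area and volume must be > 0")


@dataclass
class SpectralStack:
    """Emission lambda-stack plus unit-peak donor/acceptor reference spectra."""

    wavelength_nm: np.ndarray
    measured: np.ndarray
    s_donor: np.ndarray
    s_acceptor: np.ndarray
    lambda_donor: float = FRET_PRESETS["hek"][0]
    lambda_acceptor: float = FRET_PRESETS["hek"][1]
    direct_acceptor_coef: float = 0.0
    _refs_normalized: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=np.float64)
        self.measured = np.asarray(self.measured, dtype=np.float64)
        self.s_donor = np.asarray(self.s_donor, dtype=np.float64)
        self.s_acceptor = np.asarray(self.s_acceptor, dtype=np.float64)
        sizes = {a.size for a in (self.wavelength_nm, self.measured,
                                  self.s_donor, self.s_acceptor)}
        if len(sizes) != 1:
            raise ValueError("all spectra must share the wavelength grid")
        if np.any(self.s_donor < 0) or np.any(self.s_acceptor < 0):
            raise ValueError("reference spectra must be non-negative")
        for name in ("s_donor", "s_acceptor"):
            ref = getattr(self, name)
            peak = ref.max()
            if peak <= 0:
                raise ValueError(f"{name} is identically zero")
            setattr(self, name, ref / peak)
        self._refs_normalized = True


# ---------------------------------------------------------------------------
# GHK dilution potentials

def dilution_from_ratio(r: float, exp: DilutionExperiment) -> float:
    """Forward GHK dilution potential (mV) for permeability ratio r = PNa/PCl."""
    if not r > 0:
        raise ValueError("permeability ratio must be > 0")
    num = r * exp.c_na_baso + exp.c_cl_api
    den = r * exp.c_na_api + exp.c_cl_baso
    return exp.rt_over_f_mv * math.log(num / den)


def ratio_from_dilution(exp: DilutionExperiment) -> float:
    """Invert the GHK relation: r from a measured dilution potential.

    The potential must lie strictly between the two limiting potentials
    (RT/F) ln(cCl_api/cCl_baso) (r -> 0) and (RT/F) ln(cNa_baso/cNa_api)
    (r -> infinity); outside that interval the inversion has no positive
    solution.
    """
    ex = math.exp(exp.v_dil_mv / exp.rt_over_f_mv)
    num = ex * exp.c_cl_baso - exp.c_cl_api
    den = exp.c_na_baso - ex * exp.c_na_api
    if num <= 0 or den <= 0:
        lo = exp.rt_over_f_mv * math.log(exp.c_cl_api / exp.c_cl_baso)
        hi = exp.rt_over_f_mv * math.log(exp.c_na_baso / exp.c_na_api)
        raise ValueError(
            f"potential {exp.v_dil_mv:.3f} mV outside the admissible interval "
            f"({lo:.3f}, {hi:.3f}) mV"
        )
    return num / den


def estimate_ratio(experiments) -> float:
    """Least-squares estimate of r from repeated dilution-potential records.

    Minimizes the sum of squared deviations between measured potentials and
    the GHK forward model over log r; robust to records whose noisy
    potential falls outside the single-record inversion interval.
    """
    experiments = list(experiments)
    if not experiments:
        raise ValueError("need at least one experiment")

    def cost(log_r: float) -> float:
        rr = math.exp(log_r)
        return sum((dilution_from_ratio(rr, e) - e.v_dil_mv) ** 2 for e in experiments)

    res = optimize.minimize_scalar(cost, bounds=(math.log(1e-4), math.log(1e4)),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    return float(math.exp(res.x))


def absolute_permeabilities(
    r: float,
    ter_ohm_cm2: float,
    c_na_mm: float = 140.0,
    c_cl_mm: float = 128.8,
    temperature_k: float = 310.15,
    blank_ter_ohm_cm2: float = 0.0,
) -> PermeabilityResult:
    """Kimizuka-Koketsu absolute permeabilities from r and TER.

    Concentrations are the symmetric Ringer values (mM); activity
    coefficients are not applied. ``blank_ter_ohm_cm2`` optionally subtracts
    a cell-free blank resistance before converting to conductance.
    """
    if not r > 0:
        raise ValueError("permeability ratio must be > 0")
    ter = ter_ohm_cm2 - blank_ter_ohm_cm2
    if not ter > 0:
        raise ValueError("TER (after blank subtraction) must be > 0")
    g = 1.0 / ter  # S / cm^2
    c_na = c_na_mm * 1e-6  # mol / cm^3
    c_cl = c_cl_mm * 1e-6
    p_cl = g * R_GAS * temperature_k / (FARADAY**2 * (r * c_na + c_cl))  # cm/s
    return PermeabilityResult(ratio=r, p_na=r * p_cl * 1e6, p_cl=p_cl * 1e6)


def papp_flux(exp: FluxExperiment) -> float:
    """Apparent tracer permeability (1e-6 cm/s) from the accumulation slope.

    Papp = (dC/dt * V) / (A * C0) with the slope from ordinary least
    squares; a negative fitted slope is reported with a warning, not
    clamped.
    """
    if exp.times_min.size < 2:
        raise ValueError("need >= 2 samples for a slope")
    slope_per_min = float(np.polyfit(exp.times_min, exp.c_baso_um, 1)[0])
    if slope_per_min < 0:
        warnings.warn("negative accumulation slope; reporting as-is")
    slope_per_s = slope_per_min / 60.0
    papp_cm_s = slope_per_s * exp.volume_baso_ml / (exp.area_cm2 * exp.c0_apical_um)
    return papp_cm_s * 1e6


# ---------------------------------------------------------------------------
# spectral unmixing and FRET ratio

def unmix_spectrum(stack: SpectralStack) -> tuple[float, float, float]:
    """Linear unmixing of the measured spectrum into donor + acceptor references.

    Returns ``(c_donor, c_acceptor, residual_norm)`` from least squares;
    negative coefficients are clamped to zero with the other coefficient
    refitted (two-column non-negative least squares).
    """
    A = np.column_stack([stack.s_donor, stack.s_acceptor])
    # collinearity check
    norms = np.linalg.norm(A, axis=0)
    cosang = abs(float(A[:, 0] @ A[:, 1]) / (norms[0] * norms[1]))
    if cosang > 1 - 1e-10:
        raise ValueError("reference spectra are collinear; unmixing is ill-posed")
    coef, *_ = np.linalg.lstsq(A, stack.measured, rcond=None)
    if coef.min() < 0:
        j = int(np.argmin(coef))  # clamp the negative one, refit the other
        k = 1 - j
        coef = coef.copy()
        coef[j] = 0.0
        coef[k] = max(0.0, float(A[:, k] @ stack.measured) / float(A[:, k] @ A[:, k]))
    resid = float(np.linalg.norm(stack.measured - A @ coef))
    return float(coef[0]), float(coef[1]), resid


def fret_ratio(stack: SpectralStack) -> float:
    """Sensitized-acceptor / donor emission ratio after crosstalk correction.

    The acceptor coefficient from unmixing contains both sensitized
    emission and direct acceptor excitation; ``stack.direct_acceptor_coef``
    (from an acceptor-only control, default 0) is subtracted before the
    acceptor emission is evaluated at the acceptor readout wavelength and
    divided by the donor emission at the donor readout wavelength.
    """
    c_d, c_a, _ = unmix_spectrum(stack)
    donor_em = c_d * float(
        np.interp(stack.lambda_donor, stack.wavelength_nm, stack.s_donor)
    )
    if donor_em <= 0:
        raise ValueError("donor emission at the readout wavelength must be > 0")
    c_sens = c_a - stack.direct_acceptor_coef
    acceptor_em = c_sens * float(
        np.interp(stack.lambda_acceptor, stack.wavelength_nm, stack.s_acceptor)
    )
    return acceptor_em / donor_em
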