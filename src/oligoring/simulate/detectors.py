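"""Synthetic detector signals: chromatograms, MALS runs, SAXS curves,
standard-curve tables and noisy kinetic traces.

Every generator takes an integer seed and is bit-reproducible; noise is
additive Gaussian throughout (SAXS additionally carries a sigma column
combining a floor with a counting-statistics-like proportional term).
Signal models mirror the corresponding analysers so that noiseless
round trips are exact: these are fixtures for testing the analysis code,
not instrument emulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..kinetics import KineticTrace
from ..mals import (
    DEFAULT_DN_DC,
    DEFAULT_SOLVENT_RI,
    DEFAULT_WAVELENGTH_NM,
    MalsRun,
)
from ..saxs import SaxsCurve
from .assembly import SimState

__all__ = [
    "Chromatogram",
    "simulate_pi_trace",
    "simulate_trp_trace",
    "make_sec_chromatogram",
    "make_mals_run",
    "make_saxs_sphere",
    "make_standard_curve_data",
    "default_mals_angles",
]


@dataclass
class Chromatogram:
    """A gel-filtration elution profile on a uniform volume grid."""

    volume_ml: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.volume_ml.shape != self.signal.shape:
            raise ValueError("volume and signal lengths differ")


def simulate_pi_trace(
    state: SimState, noise_sd_um: float = 0.0, seed: int = 0
) -> KineticTrace:
    """Phosphate-release trace Pi(t) with additive Gaussian detector noise."""
    if noise_sd_um < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    signal = state.pi.copy()
    if noise_sd_um > 0:
        signal = signal + rng.normal(0.0, noise_sd_um, size=signal.shape)
    return KineticTrace(
        time_s=state.time_s.copy(),
        signal=signal,
        calibrated=True,
        mcrB_conc_um=state.total_monomer,
        mcrC_conc_um=state.total_mcrC,
        metadata={
            "generator": "simulate_pi_trace",
            "noise_sd_um": noise_sd_um,
            "seed": seed,
            "n_ring": state.params.n_ring,
            "k_cat": state.params.k_cat,
        },
    )


def simulate_trp_trace(
    state: SimState,
    enhancement: Optional[float] = None,
    baseline: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticTrace:
    """Tryptophan-fluorescence-like signal tied to nucleotide loading.

    signal(t) = baseline * (1 + enhancement * f(t)) with f the fraction of
    subunits carrying nucleotide (monomeric or oligomeric).  Whether the
    real signal reports binding, oligomerisation or both is genuinely
    unresolved; loading fraction is the stand-in adopted here.
    """
    if enhancement is None:
        enhancement = state.params.trp_enhancement
    if enhancement < 0:
        raise ValueError("enhancement must be non-negative")
    rng = np.random.default_rng(seed)
    signal = baseline * (1.0 + enhancement * state.loaded_fraction())
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return KineticTrace(
        time_s=state.time_s.copy(),
        signal=signal,
        calibrated=False,
        mcrB_conc_um=state.total_monomer,
        mcrC_conc_um=state.total_mcrC,
        metadata={
            "generator": "simulate_trp_trace",
            "enhancement": enhancement,
            "baseline": baseline,
            "seed": seed,
        },
    )


def make_sec_chromatogram(
    peaks: Sequence[tuple[float, float, float]],
    vo_ml: float = 8.4,
    vt_ml: float = 24.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 1200,
) -> Chromatogram:
    """Sum-of-Gaussians elution profile.

    ``peaks`` is a list of (Ve ml, height, width ml) with width the
    Gaussian sigma; every Ve must lie strictly between the void and total
    column volumes.
    """
    for ve, _, width in peaks:
        if not (vo_ml < ve < vt_ml):
            raise ValueError(f"peak at {ve} ml outside (Vo={vo_ml}, Vt={vt_ml})")
        if width <= 0:
            raise ValueError("peak width must be positive")
    rng = np.random.default_rng(seed)
    volume = np.linspace(0.0, vt_ml, n_points)
    signal = np.zeros_like(volume)
    for ve, height, width in peaks:
        signal += height * np.exp(-0.5 * ((volume - ve) / width) ** 2)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return Chromatogram(
        volume_ml=volume,
        signal=signal,
        metadata={
            "generator": "make_sec_chromatogram",
            "vo_ml": vo_ml,
            "vt_ml": vt_ml,
            "noise_sd": noise_sd,
            "seed": seed,
            "peaks": list(peaks),
        },
    )


def default_mals_angles(n: int = 18) -> np.ndarray:
    """Evenly spread detector angles (degrees), 18 by default."""
    return np.linspace(20.0, 160.0, n)


def make_mals_run(
    true_mass_kda: float,
    rg_nm: float = 0.0,
    peak: tuple[float, float, float] = (12.0, 1.0, 0.3),
    angles_deg: Optional[Sequence[float]] = None,
    dn_dc: float = DEFAULT_DN_DC,
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
    solvent_ri: float = DEFAULT_SOLVENT_RI,
    instrument_constant: float = 1.0,
    noise_frac: float = 0.0,
    seed: int = 0,
    n_slices: int = 60,
) -> MalsRun:
    """Per-slice RI + multi-angle scattering for a monodisperse peak.

    ``peak`` = (Ve ml, apex concentration mg/ml, sigma ml).  Per slice,
    excess RI = c * dn/dc and LS(theta) = K* c M P(theta) with the
    single-term form-factor expansion

        P(theta) = 1 - (16 pi^2 / 3 lambda^2) Rg^2 sin^2(theta/2),

    lambda being the in-medium wavelength, matching the Debye analyser's
    convention so noiseless round trips are exact.  ``noise_frac`` is the
    relative SD applied to both detectors.
    """
    if true_mass_kda <= 0:
        raise ValueError("true_mass must be positive")
    angles = (
        default_mals_angles()
        if angles_deg is None
        else np.asarray(angles_deg, dtype=float)
    )
    if angles.size < 3:
        raise ValueError("need >= 3 detector angles")
    rng = np.random.default_rng(seed)

    ve, apex_c, width = peak
    volume = np.linspace(ve - 3 * width, ve + 3 * width, n_slices)
    conc = apex_c * np.exp(-0.5 * ((volume - ve) / width) ** 2)

    lam_nm = wavelength_nm / solvent_ri
    p_theta = 1.0 - (16.0 * np.pi**2 / (3.0 * lam_nm**2)) * rg_nm**2 * np.sin(
        np.radians(angles) / 2.0
    ) ** 2
    if np.any(p_theta <= 0):
        raise ValueError("rg too large for the single-term form-factor expansion")

    excess_ri = conc * dn_dc
    ls = instrument_constant * conc[:, None] * true_mass_kda * p_theta[None, :]
    if noise_frac > 0:
        excess_ri = excess_ri * (1.0 + rng.normal(0.0, noise_frac, excess_ri.shape))
        ls = ls * (1.0 + rng.normal(0.0, noise_frac, ls.shape))
    return MalsRun(
        volume_ml=volume,
        excess_ri=excess_ri,
        ls_intensity=ls,
        angles_deg=angles,
        dn_dc=dn_dc,
        wavelength_nm=wavelength_nm,
        solvent_ri=solvent_ri,
        instrument_constant=instrument_constant,
        metadata={
            "generator": "make_mals_run",
            "true_mass_kda": true_mass_kda,
            "rg_nm": rg_nm,
            "noise_frac": noise_frac,
            "seed": seed,
        },
    )


def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Normalised sphere form factor [3 (sin x - x cos x)/x^3]^2, x = qR."""
    x = np.asarray(q, dtype=float) * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(
            x < 1e-6,
            1.0 - x**2 / 10.0,  # series expansion near 0
            3.0 * (np.sin(x) - x * np.cos(x)) / np.maximum(x, 1e-300) ** 3,
        )
    return amp**2


def make_saxs_sphere(
    radius_a: float,
    i0: float = 1.0,
    q_grid: Optional[np.ndarray] = None,
    noise_floor: float = 0.0,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> SaxsCurve:
    """Sphere scattering curve I(q) = i0 [3 (sin qR - qR cos qR)/(qR)^3]^2.

    The sigma column is max(noise_floor, noise_frac * I) per point; noise
    draws are Gaussian with that sigma.  Noiseless when both terms are 0.
    """
    if radius_a <= 0:
        raise ValueError("radius must be positive")
    if q_grid is None:
        q_grid = np.linspace(0.004, 0.5, 800)
    q = np.asarray(q_grid, dtype=float)
    if np.any(np.diff(q) <= 0) or np.any(q <= 0):
        raise ValueError("q grid must be positive and strictly increasing")
    rng = np.random.default_rng(seed)
    intensity = i0 * sphere_form_factor(q, radius_a)
    sigma = np.maximum(noise_floor, noise_frac * intensity)
    if noise_floor > 0 or noise_frac > 0:
        intensity = intensity + rng.normal(0.0, 1.0, size=q.shape) * sigma
        return SaxsCurve(q=q, intensity=intensity, sigma=sigma)
    return SaxsCurve(q=q, intensity=intensity, sigma=None)


def make_standard_curve_data(
    true_slope: float,
    true_intercept: float,
    levels_um: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """(concentration, response) table for a linear detector standard.

    Returns an (n, 2) array: response = slope * conc + intercept + noise.
    """
    levels = np.asarray(levels_um, dtype=float)
    if len(np.unique(levels)) < 2:
        raise ValueError("need >= 2 distinct concentration levels")
    rng = np.random.default_rng(seed)
    response = true_slope * levels + true_intercept
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=levels.shape)
    return np.column_stack([levels, response])
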