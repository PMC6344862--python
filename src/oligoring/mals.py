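"""Absolute molar mass from multi-angle light scattering and size from DLS.

SEC-MALS measures, for every elution slice, the excess differential
refractive index (giving concentration via dn/dc) and the scattered
intensity at many angles.  The Debye plot in the Zimm formulation,

    K* c / R(theta)  versus  sin^2(theta/2),

has intercept 1/M (absolute molar mass, no shape assumption) and a slope
that encodes the radius of gyration:

    slope / intercept = (16 pi^2 / 3 lambda^2) Rg^2,

with lambda the in-medium wavelength (vacuum wavelength / solvent
refractive index).  A co-mounted dynamic light-scattering detector yields
the translational diffusion coefficient, converted to a hydrodynamic
radius by the Stokes-Einstein relation r_h = kB T / (6 pi eta D).

The instrument constant K* maps raw detector counts onto the Rayleigh
ratio; here it is carried symmetrically between the synthetic-data
generator and the analyser, so absolute toluene-standard calibration is
out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

BOLTZMANN_J_PER_K = 1.380649e-23
DEFAULT_DN_DC = 0.186e-3  # RI increment per mg/ml of protein
DEFAULT_WAVELENGTH_NM = 658.0  # vacuum wavelength of the laser
DEFAULT_SOLVENT_RI = 1.33  # aqueous buffer
DEFAULT_VISCOSITY_PA_S = 9.3e-4  # 9.3e-3 Poise

__all__ = [
    "MalsRun",
    "MassProfile",
    "DlsResult",
    "slice_concentration",
    "debye_fit",
    "mass_profile",
    "weight_average_mass",
    "stokes_einstein",
    "fit_autocorrelation",
    "BOLTZMANN_J_PER_K",
    "DEFAULT_DN_DC",
    "DEFAULT_WAVELENGTH_NM",
    "DEFAULT_SOLVENT_RI",
    "DEFAULT_VISCOSITY_PA_S",
]


@dataclass
class MalsRun:
    """Per-slice MALS + RI records for one chromatographic run.

    ``ls_intensity[i, j]`` is the light-scattering signal of slice ``i`` at
    ``angles_deg[j]``; ``excess_ri[i]`` is the refractive-index detector
    reading of that slice.
    """

    volume_ml: np.ndarray
    excess_ri: np.ndarray
    ls_intensity: np.ndarray
    angles_deg: np.ndarray
    dn_dc: float = DEFAULT_DN_DC
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    solvent_ri: float = DEFAULT_SOLVENT_RI
    instrument_constant: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        self.excess_ri = np.asarray(self.excess_ri, dtype=float)
        self.ls_intensity = np.atleast_2d(np.asarray(self.ls_intensity, dtype=float))
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.size < 3:
            raise ValueError("MALS analysis requires >= 3 detector angles")
        if self.dn_dc <= 0:
            raise ValueError("dn/dc must be positive")
        if self.ls_intensity.shape != (self.volume_ml.size, self.angles_deg.size):
            raise ValueError("ls_intensity must be (n_slices, n_angles)")

    @property
    def n_slices(self) -> int:
        return self.volume_ml.size

    @property
    def wavelength_medium_nm(self) -> float:
        return self.wavelength_nm / self.solvent_ri


@dataclass(frozen=True)
class MassProfile:
    """Per-slice masses and concentrations over an elution region."""

    volume_ml: np.ndarray
    mass_kda: np.ndarray
    concentration_mg_ml: np.ndarray


@dataclass(frozen=True)
class DlsResult:
    diffusion_m2_s: float
    temperature_k: float
    viscosity_pa_s: float
    r_h_nm: float


def slice_concentration(excess_ri: float | np.ndarray, dn_dc: float = DEFAULT_DN_DC):
    """Concentration (mg/ml) from the excess refractive index, c = RI / (dn/dc)."""
    if dn_dc <= 0:
        raise ValueError("dn/dc must be positive")
    return np.asarray(excess_ri, dtype=float) / dn_dc


def debye_fit(run: MalsRun, slice_index: int) -> tuple[float, float]:
    """Mass (kDa) and Rg (nm) of one elution slice from the Debye plot.

    Ordinary least squares of K*c/R(theta) on sin^2(theta/2); the intercept
    gives 1/M and slope/intercept gives (16 pi^2/3 lambda^2) Rg^2.  When the
    fitted slope is non-positive (angle-independent scattering, particle
    small relative to the wavelength) Rg is reported as 0.
    """
    c = float(slice_concentration(run.excess_ri[slice_index], run.dn_dc))
    if c <= 0:
        raise ValueError(f"slice {slice_index}: non-positive concentration")
    r_theta = run.ls_intensity[slice_index]
    if np.any(r_theta <= 0):
        raise ValueError(f"slice {slice_index}: non-positive scattering signal")

    x = np.sin(np.radians(run.angles_deg) / 2.0) ** 2
    y = run.instrument_constant * c / r_theta
    slope, intercept = np.polyfit(x, y, 1)
    if intercept <= 0:
        raise ValueError(
            f"slice {slice_index}: non-positive Debye intercept, mass undefined"
        )
    mass_kda = 1.0 / intercept

    if slope <= 0 or slope < 1e-12 * intercept:  # angle-independent scattering
        return float(mass_kda), 0.0
    lam_nm = run.wavelength_medium_nm
    rg_sq_nm2 = (slope / intercept) * 3.0 * lam_nm**2 / (16.0 * math.pi**2)
    return float(mass_kda), float(math.sqrt(rg_sq_nm2))


def mass_profile(
    run: MalsRun,
    region: tuple[float, float] | None = None,
    concentration_floor_frac: float = 0.01,
) -> MassProfile:
    """Debye-fit every usable slice in ``region``.

    Slices with concentration below ``concentration_floor_frac`` of the apex
    concentration are excluded: the per-slice mass diverges as c -> 0.
    """
    conc = slice_concentration(run.excess_ri, run.dn_dc)
    apex = float(np.max(conc))
    if apex <= 0:
        raise ValueError("run contains no positive-concentration slice")
    keep = conc >= concentration_floor_frac * apex
    if region is not None:
        lo, hi = region
        keep &= (run.volume_ml >= lo) & (run.volume_ml <= hi)
    idx = np.nonzero(keep)[0]
    if idx.size < 3:
        raise ValueError("region overlaps fewer than 3 usable slices")
    masses = np.array([debye_fit(run, i)[0] for i in idx])
    return MassProfile(
        volume_ml=run.volume_ml[idx],
        mass_kda=masses,
        concentration_mg_ml=np.asarray(conc)[idx],
    )


def weight_average_mass(profile: MassProfile) -> float:
    """Concentration-weighted mean mass, sum(c_i M_i)/sum(c_i), in kDa."""
    c = profile.concentration_mg_ml
    return float(np.sum(c * profile.mass_kda) / np.sum(c))


def stokes_einstein(
    diffusion_m2_s: float,
    temperature_k: float = 298.15,
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S,
) -> float:
    """Hydrodynamic radius (nm) from a diffusion coefficient (m^2/s)."""
    if diffusion_m2_s <= 0 or temperature_k <= 0 or viscosity_pa_s <= 0:
        raise ValueError("diffusion, temperature and viscosity must be positive")
    r_m = BOLTZMANN_J_PER_K * temperature_k / (6.0 * math.pi * viscosity_pa_s * diffusion_m2_s)
    return r_m * 1e9


def fit_autocorrelation(
    tau_s: Sequence[float], g2: Sequence[float], q_per_m: float
) -> float:
    """Diffusion coefficient (m^2/s) from a DLS intensity autocorrelation.

    Fits the single-exponential Siegert form g2(tau) = 1 + beta
    exp(-2 D q^2 tau).  Multi-modal decays are out of scope; the fit is a
    first-order cumulant stand-in for the vendor analysis.
    """
    from scipy.optimize import curve_fit

    tau = np.asarray(tau_s, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    amp0 = float(g2[0] - 1.0)
    if amp0 <= 1e-12:
        raise ValueError("no dynamic signal: g2 does not decay from above 1")

    # seed the decay rate from the 1/e crossing of (g2-1)/beta
    target = 1.0 + amp0 / math.e
    below = np.nonzero(g2 <= target)[0]
    tau_e = tau[below[0]] if below.size else tau[-1]
    rate0 = 1.0 / max(tau_e, 1e-12)

    def model(t, beta, rate):
        return 1.0 + beta * np.exp(-rate * t)

    popt, _ = curve_fit(model, tau, g2, p0=[amp0, rate0], maxfev=20000)
    rate = abs(popt[1])
    return float(rate / (2.0 * q_per_m**2))
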