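"""Size-exclusion chromatography calibration and apparent-mass estimation.

A gel-filtration column is calibrated by running globular standards of known
molecular mass and recording their elution volumes.  The chromatographic
partition coefficient

    Kav = (Ve - Vo) / (Vt - Vo)

is, for well-behaved globular proteins, linear in the logarithm of molecular
mass.  Fitting a straight line through Kav versus log10(mass) gives a
standard curve that converts any elution volume into an *apparent* molecular
mass.  Apparent masses are shape-sensitive: elongated or ring-shaped
oligomers migrate anomalously, which is precisely why orthogonal
(light-scattering, SAXS) mass measurements matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ColumnConstants",
    "CalibrationStandard",
    "SecCalibration",
    "compute_kav",
    "fit_calibration",
    "apparent_mass",
    "find_peaks",
]


@dataclass(frozen=True)
class ColumnConstants:
    """Void volume Vo and total volume Vt of a gel-filtration column, in ml."""

    vo: float
    vt: float

    def __post_init__(self) -> None:
        if not (0 < self.vo < self.vt):
            raise ValueError(
                f"invalid column: need 0 < Vo < Vt, got Vo={self.vo}, Vt={self.vt}"
            )


@dataclass(frozen=True)
class CalibrationStandard:
    """A calibration protein: name, molecular mass (kDa), elution volume (ml)."""

    name: str
    mass_kda: float
    ve_ml: float

    def __post_init__(self) -> None:
        if self.mass_kda <= 0:
            raise ValueError(f"standard {self.name!r}: mass must be positive")


@dataclass(frozen=True)
class SecCalibration:
    """Fitted Kav-vs-log10(mass) line.

    ``slope`` is negative for a valid size-exclusion calibration (larger
    species elute earlier, hence smaller Kav).
    """

    slope: float
    intercept: float
    r_squared: float
    column: ColumnConstants
    standards: tuple[CalibrationStandard, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            warnings.warn(
                "calibration slope is non-negative; Kav should decrease with mass",
                stacklevel=2,
            )


def compute_kav(ve_ml: float, column: ColumnConstants) -> float:
    """Partition coefficient Kav = (Ve - Vo)/(Vt - Vo).

    Values outside [0, 1] are physically suspect (elution before the void
    or after the total volume) and trigger a warning, but are returned so
    that near-void oligomer peaks can still be extrapolated.
    """
    kav = (ve_ml - column.vo) / (column.vt - column.vo)
    if not (0.0 <= kav <= 1.0):
        warnings.warn(
            f"Kav={kav:.3f} outside [0, 1] for Ve={ve_ml} ml; extrapolating",
            stacklevel=2,
        )
    return kav


def fit_calibration(
    standards: Sequence[CalibrationStandard], column: ColumnConstants
) -> SecCalibration:
    """Ordinary least squares of Kav on log10(mass/kDa).

    Requires at least three standards with distinct masses.
    """
    if len(standards) < 3:
        raise ValueError("need >= 3 calibration standards")
    masses = np.array([s.mass_kda for s in standards], dtype=float)
    if len(np.unique(masses)) < 3:
        raise ValueError("calibration standards must have >= 3 distinct masses")
    log_mass = np.log10(masses)
    kav = np.array([compute_kav(s.ve_ml, column) for s in standards])

    slope, intercept = np.polyfit(log_mass, kav, 1)
    fitted = slope * log_mass + intercept
    ss_res = float(np.sum((kav - fitted) ** 2))
    ss_tot = float(np.sum((kav - kav.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return SecCalibration(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        column=column,
        standards=tuple(standards),
    )


def apparent_mass(ve_ml: float, cal: SecCalibration) -> float:
    """Invert the calibration line at an elution volume; returns kDa."""
    if cal.slope == 0:
        raise ValueError("degenerate calibration: slope is zero")
    kav = compute_kav(ve_ml, cal.column)
    log_mass = (kav - cal.intercept) / cal.slope
    return float(10.0**log_mass)


def find_peaks(
    volume_ml: np.ndarray,
    signal: np.ndarray,
    min_height: float = 0.0,
    min_separation_ml: float = 0.2,
) -> list[tuple[float, float]]:
    """Locate chromatogram peaks as (Ve, height) pairs.

    Local maxima above ``min_height`` separated by at least
    ``min_separation_ml`` are kept; the apex position is refined by a
    three-point parabolic interpolation so Ve does not quantise to the
    volume grid.
    """
    from scipy.signal import find_peaks as _scipy_find_peaks

    volume_ml = np.asarray(volume_ml, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if volume_ml.ndim != 1 or volume_ml.shape != signal.shape:
        raise ValueError("volume and signal must be 1-D arrays of equal length")
    steps = np.diff(volume_ml)
    if len(steps) and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
        raise ValueError("find_peaks requires a uniform volume grid")
    dv = steps[0] if len(steps) else 0.0
    distance = max(1, int(round(min_separation_ml / dv))) if dv > 0 else 1

    idx, props = _scipy_find_peaks(signal, height=min_height, distance=distance)
    out: list[tuple[float, float]] = []
    for i in idx:
        ve, height = volume_ml[i], signal[i]
        if 0 < i < len(signal) - 1:
            y0, y1, y2 = signal[i - 1], signal[i], signal[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                delta = 0.5 * (y0 - y2) / denom
                if abs(delta) <= 1:
                    ve = volume_ml[i] + delta * dv
                    height = y1 - 0.25 * (y0 - y2) * delta
        out.append((float(ve), float(height)))
    return out
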