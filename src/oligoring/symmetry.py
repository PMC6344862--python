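"""Rotational-symmetry analysis of 2D ring-particle images.

Class averages of a ring-shaped oligomer viewed down its symmetry axis
carry the subunit count in their angular frequency content: resampling the
image on polar coordinates about the ring centre and taking the angular
Fourier power, summed over an annular band covering the ring wall, gives a
rotational power spectrum with a dominant peak at the n-fold order
(hexamer -> 6, heptamer -> 7).  Powers are normalised by the order-0
(rotationally symmetric) component, which makes the spectrum invariant to
global intensity scaling; only relative peak structure is interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "RingImage",
    "RotationalSpectrum",
    "estimate_center",
    "rotational_power_spectrum",
    "detect_symmetry_order",
]

DEFAULT_RADIAL_BAND_A = (12.5, 47.5)  # pore radius .. outer radius of a ~95 A ring


@dataclass
class RingImage:
    """A single 2D particle image with physical pixel size."""

    data: np.ndarray
    pixel_size_a: float = 1.33
    center: Optional[tuple[float, float]] = None  # (x, y) in pixels
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("image must be a 2D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")
        if self.pixel_size_a <= 0:
            raise ValueError("pixel size must be positive")


@dataclass(frozen=True)
class RotationalSpectrum:
    """Angular Fourier power per order n = 0..n_max, order-0 normalised."""

    power: np.ndarray  # raw power per order
    normalized: np.ndarray  # power / power[0]
    radial_band_a: tuple[float, float]
    n_max: int


def _radial_profile_sharpness(
    img: np.ndarray, cx: float, cy: float, r_max: float
) -> float:
    """Variance of the circular-average profile about a candidate centre.

    A well-centred ring has a sharply peaked radial mean profile; any
    decentre smears the annulus across radii and lowers the variance.
    """
    radii = np.arange(1.0, r_max)
    n_ang = 180
    theta = np.linspace(0.0, 2.0 * np.pi, n_ang, endpoint=False)
    xs = cx + radii[:, None] * np.cos(theta)[None, :]
    ys = cy + radii[:, None] * np.sin(theta)[None, :]
    samples = map_coordinates(img, [ys.ravel(), xs.ravel()], order=1, mode="constant")
    profile = samples.reshape(len(radii), n_ang).mean(axis=1)
    return float(np.var(profile))


def estimate_center(image: RingImage, refine_step: float = 0.25) -> tuple[float, float]:
    """Ring centre (x, y) in pixels: intensity centroid + sharpness refinement.

    The centroid of the (min-subtracted) intensity seeds a grid search over
    +/- 2 pixels that maximises the sharpness of the circular-average
    radial profile.
    """
    img = image.data
    if np.ptp(img) == 0:
        raise ValueError("cannot locate centre of a constant image")
    ny, nx = img.shape
    w = img - img.min()
    total = w.sum()
    ys, xs = np.mgrid[0:ny, 0:nx]
    cx0 = float((w * xs).sum() / total)
    cy0 = float((w * ys).sum() / total)

    r_max = min(cx0, cy0, nx - 1 - cx0, ny - 1 - cy0)
    if r_max < 3:
        return cx0, cy0
    offsets = np.arange(-2.0, 2.0 + 1e-9, refine_step)
    best = (cx0, cy0)
    best_score = -np.inf
    for dx in offsets:
        for dy in offsets:
            score = _radial_profile_sharpness(img, cx0 + dx, cy0 + dy, r_max)
            if score > best_score:
                best_score = score
                best = (cx0 + dx, cy0 + dy)
    return best


def rotational_power_spectrum(
    image: RingImage,
    center: Optional[tuple[float, float]] = None,
    radial_band_a: tuple[float, float] = DEFAULT_RADIAL_BAND_A,
    n_max: int = 12,
    n_angles: int = 256,
) -> RotationalSpectrum:
    """Angular Fourier power of the image over an annular band.

    The image is resampled bilinearly on polar coordinates (``n_angles``
    equispaced angles per 1-pixel radial step across the band); the power
    |F_n|^2 of each ring is summed over radii and normalised by order 0.
    """
    if n_angles < 4 * n_max:
        raise ValueError("n_angles must be >= 4 * n_max for unaliased orders")
    img = image.data
    ny, nx = img.shape
    if center is None:
        center = image.center if image.center is not None else estimate_center(image)
    cx, cy = center

    r_lo = radial_band_a[0] / image.pixel_size_a
    r_hi = radial_band_a[1] / image.pixel_size_a
    if not (0 <= r_lo < r_hi):
        raise ValueError("invalid radial band")
    lim = min(cx, cy, nx - 1 - cx, ny - 1 - cy)
    if r_hi > lim:
        raise ValueError(
            f"radial band (<= {r_hi:.1f} px) extends outside the image (limit {lim:.1f} px)"
        )

    radii = np.arange(max(r_lo, 1.0), r_hi + 1e-9, 1.0)
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    xs = cx + radii[:, None] * np.cos(theta)[None, :]
    ys = cy + radii[:, None] * np.sin(theta)[None, :]
    rings = map_coordinates(img, [ys.ravel(), xs.ravel()], order=1, mode="constant")
    rings = rings.reshape(len(radii), n_angles)

    coeffs = np.fft.rfft(rings, axis=1) / n_angles
    power_per_radius = np.abs(coeffs[:, : n_max + 1]) ** 2
    # weight by radius: each ring represents an annulus of circumference 2 pi r
    power = (power_per_radius * radii[:, None]).sum(axis=0)
    if power[0] <= 0:
        raise ValueError("order-0 power is non-positive: empty radial band")
    return RotationalSpectrum(
        power=power,
        normalized=power / power[0],
        radial_band_a=tuple(radial_band_a),
        n_max=n_max,
    )


def detect_symmetry_order(
    spectrum: RotationalSpectrum,
    candidates: Sequence[int] = tuple(range(2, 13)),
    prominence: float = 3.0,
    min_power: float = 1e-3,
) -> Optional[int]:
    """Symmetry order from the spectrum, or None when no clear peak exists.

    The winning candidate must carry at least ``min_power`` of the order-0
    power (a rotationally uniform ring has essentially none at any order)
    and exceed ``prominence`` times the median power of the other
    candidates; the winner's harmonics (2n, 3n, ...) are excluded from that
    denominator since a genuine n-fold ring also powers them.  Fuzzy or
    asymmetric particles fail these tests and return None rather than a
    guess.
    """
    cands = [c for c in candidates if 1 <= c <= spectrum.n_max]
    if not cands:
        raise ValueError("no candidate orders within the spectrum range")
    p = spectrum.normalized
    best = max(cands, key=lambda c: p[c])
    if p[best] < min_power:
        return None
    others = [p[c] for c in cands if c != best and c % best != 0]
    if not others:
        return best
    floor = float(np.median(others))
    if floor <= 0:
        return best
    return best if p[best] >= prominence * floor else None
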