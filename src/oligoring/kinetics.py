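"""Lag-phase analysis of phosphate-release time courses.

A product-release trace from an enzyme that must assemble before it can
turn over shows a lag followed by a linear steady state.  Fitting a
straight line to the steady-state phase gives:

    * steady-state rate        = slope (uM Pi / s)
    * relaxation (lag) time    = X-axis intercept of that line (s)
    * apparent initiation rate = 1 / relaxation time (1/s)
    * per-enzyme rate          = slope / [enzyme] (uM Pi / uM enzyme / s)

The mechanistic signature that complete assembly precedes hydrolysis is a
concentration series in which the per-enzyme steady-state rate is constant
while the initiation rate rises with concentration (mass action makes
assembly faster at higher concentration; the hydrolysing unit itself is
unchanged).  ``analyze_series`` tests exactly that.

Raw detector signals (plate-reader absorbance, coumarin-labelled
phosphate-sensor fluorescence) are converted to uM phosphate through a
linear standard curve whose linear range is found by a lack-of-fit test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "KineticTrace",
    "LagFit",
    "SeriesResult",
    "ExpFitResult",
    "fit_standard_curve",
    "calibrate_trace",
    "lag_fit",
    "analyze_series",
    "fit_single_exponential",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear detector response to phosphate concentration."""

    slope: float  # signal per uM Pi
    intercept: float
    linear_range: tuple[float, float]  # uM
    residual_sd: float
    n_levels_used: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be positive")


@dataclass
class KineticTrace:
    """A product-release (or fluorescence) time course."""

    time_s: np.ndarray
    signal: np.ndarray
    calibrated: bool = False
    mcrB_conc_um: float = float("nan")
    mcrC_conc_um: float = float("nan")
    gtp_conc_mm: float = float("nan")
    metadata: dict = field(default_factory=dict)
    out_of_range: Optional[np.ndarray] = None  # mask set by calibrate_trace

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.shape != self.signal.shape:
            raise ValueError("time and signal lengths differ")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class LagFit:
    """Straight-line analysis of the steady-state phase."""

    steady_state_rate: float  # uM Pi / s
    relaxation_time: float  # s (0 if the line passes left of the origin)
    initiation_rate: float  # 1/s; inf when relaxation_time == 0
    per_enzyme_rate: float  # uM Pi / uM enzyme / s (nan without [enzyme])
    fit_window: tuple[float, float]  # (t_start, t_end), s
    slope_se: float
    intercept: float


@dataclass(frozen=True)
class SeriesResult:
    concentrations_um: tuple[float, ...]
    fits: tuple[LagFit, ...]
    per_enzyme_rate_cv: float
    initiation_strictly_increasing: bool


@dataclass(frozen=True)
class ExpFitResult:
    amplitude: float
    rate: float
    baseline: float
    residual_sd: float
    runs_z: float
    runs_p: float
    identifiable: bool


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """slope, intercept, slope standard error."""
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    if n > 2:
        sxx = np.sum((x - x.mean()) ** 2)
        se = math.sqrt(np.sum(resid**2) / (n - 2) / sxx) if sxx > 0 else float("nan")
    else:
        se = 0.0
    return float(slope), float(intercept), se


def fit_standard_curve(
    conc_um: Sequence[float],
    response: Sequence[float],
    alpha: float = 0.01,
) -> StandardCurve:
    """Fit a phosphate standard curve and trim the linear range.

    Replicate-free implementation of the usual procedure: fit all levels,
    then iteratively drop the top concentration while a lack-of-fit
    F-statistic (quadratic vs linear model) is significant at ``alpha`` —
    saturating detectors bend downward at high phosphate.
    """
    conc = np.asarray(conc_um, dtype=float)
    resp = np.asarray(response, dtype=float)
    order = np.argsort(conc)
    conc, resp = conc[order], resp[order]
    if len(np.unique(conc)) < 3:
        raise ValueError("insufficient levels: need >= 3 distinct concentrations")

    def lack_of_fit_p(x, y) -> float:
        # F-test: does a quadratic term significantly improve on the line?
        if len(x) < 4:
            return 1.0
        lin = np.polyval(np.polyfit(x, y, 1), x)
        quad = np.polyval(np.polyfit(x, y, 2), x)
        rss_lin = float(np.sum((y - lin) ** 2))
        rss_quad = float(np.sum((y - quad) ** 2))
        df2 = len(x) - 3
        if rss_quad <= 0 or df2 <= 0:
            return 0.0 if rss_lin > rss_quad * (1 + 1e-9) else 1.0
        f = (rss_lin - rss_quad) / (rss_quad / df2)
        return float(stats.f.sf(f, 1, df2))

    hi = len(conc)
    while hi > 3 and lack_of_fit_p(conc[:hi], resp[:hi]) < alpha:
        hi -= 1
    x, y = conc[:hi], resp[:hi]
    slope, intercept, _ = _ols_line(x, y)
    resid = y - (slope * x + intercept)
    sd = float(np.sqrt(np.sum(resid**2) / max(len(x) - 2, 1)))
    return StandardCurve(
        slope=slope,
        intercept=intercept,
        linear_range=(float(x.min()), float(x.max())),
        residual_sd=sd,
        n_levels_used=hi,
    )


def calibrate_trace(raw: KineticTrace, curve: StandardCurve) -> KineticTrace:
    """Convert a raw detector trace to uM phosphate via the standard curve.

    Points that map outside the curve's linear range are flagged in the
    ``out_of_range`` mask, not discarded — the caller decides.
    """
    pi_um = (raw.signal - curve.intercept) / curve.slope
    lo, hi = curve.linear_range
    mask = (pi_um < lo - 1e-12) | (pi_um > hi + 1e-12)
    out = KineticTrace(
        time_s=raw.time_s.copy(),
        signal=pi_um,
        calibrated=True,
        mcrB_conc_um=raw.mcrB_conc_um,
        mcrC_conc_um=raw.mcrC_conc_um,
        gtp_conc_mm=raw.gtp_conc_mm,
        metadata=dict(raw.metadata),
    )
    out.out_of_range = mask
    return out


def _steady_state_window(
    t: np.ndarray, y: np.ndarray, tail_fraction: float, slope_tolerance: float
) -> int:
    """Index where the steady-state window starts.

    The terminal slope is estimated on the final ``tail_fraction`` of
    points; the window is then extended backwards while the local slope
    (5-point central fit) stays within ``slope_tolerance`` of it.
    """
    n = len(t)
    start = int(math.floor(n * (1.0 - tail_fraction)))
    start = min(max(start, 0), n - 3)
    term_slope = np.polyfit(t[start:], y[start:], 1)[0]
    if term_slope <= 0:
        raise ValueError("no steady state detected: terminal slope <= 0")

    half = 2  # 5-point local window
    i = start
    while i > 0:
        j = i - 1
        lo, hi = max(j - half, 0), min(j + half + 1, n)
        local = np.polyfit(t[lo:hi], y[lo:hi], 1)[0]
        if abs(local - term_slope) > slope_tolerance * abs(term_slope):
            break
        i = j
    return i


def lag_fit(
    trace: KineticTrace,
    tail_fraction: float = 0.4,
    slope_tolerance: float = 0.05,
) -> LagFit:
    """Straight-line fit of the steady-state phase of a phosphate trace.

    The fitted line y = m t + b yields steady_state_rate = m and
    relaxation_time = -b/m (its X-axis intercept).  Burst-like traces with
    a negative intercept clamp the relaxation time to 0 with a warning.
    """
    if len(trace.time_s) < 20:
        raise ValueError("lag_fit needs >= 20 points")
    if not trace.calibrated:
        warnings.warn("trace is not flagged as calibrated; rates are in signal units",
                      stacklevel=2)
    t, y = trace.time_s, trace.signal
    i0 = _steady_state_window(t, y, tail_fraction, slope_tolerance)
    slope, intercept, se = _ols_line(t[i0:], y[i0:])
    if slope <= 0:
        raise ValueError("no steady state detected: fitted slope <= 0")

    x_intercept = -intercept / slope
    if abs(x_intercept) < 1e-12 * (t[-1] - t[0]):  # numerically through origin
        x_intercept = 0.0
    if x_intercept < 0:
        warnings.warn(
            "negative X-intercept (burst-like trace); relaxation time clamped to 0",
            stacklevel=2,
        )
        x_intercept = 0.0
    initiation = float("inf") if x_intercept == 0 else 1.0 / x_intercept
    per_enzyme = (
        slope / trace.mcrB_conc_um
        if trace.mcrB_conc_um and not math.isnan(trace.mcrB_conc_um)
        else float("nan")
    )
    return LagFit(
        steady_state_rate=slope,
        relaxation_time=float(x_intercept),
        initiation_rate=float(initiation),
        per_enzyme_rate=float(per_enzyme),
        fit_window=(float(t[i0]), float(t[-1])),
        slope_se=se,
        intercept=intercept,
    )


def analyze_series(
    traces: Sequence[KineticTrace],
    ratio_check: Optional[float] = 4.0,
    **lag_kwargs,
) -> SeriesResult:
    """Lag analysis of a concentration ladder at fixed subunit ratio.

    Requires >= 3 distinct enzyme concentrations.  Reports the coefficient
    of variation of the per-enzyme steady-state rate (should be small when
    the hydrolysing unit is the same at every concentration) and whether
    the initiation rate increases strictly with concentration (Spearman
    rho exactly 1 — exact rank agreement, appropriate for short series).
    """
    concs = [tr.mcrB_conc_um for tr in traces]
    if len(set(concs)) < 3:
        raise ValueError("analyze_series needs >= 3 distinct concentrations")
    if ratio_check is not None:
        for tr in traces:
            if tr.mcrC_conc_um and not math.isnan(tr.mcrC_conc_um) and tr.mcrC_conc_um > 0:
                ratio = tr.mcrB_conc_um / tr.mcrC_conc_um
                if abs(ratio - ratio_check) > 1e-6 * ratio_check:
                    raise ValueError(
                        f"subunit ratio {ratio:g} differs from required {ratio_check:g}"
                    )

    order = np.argsort(concs)
    fits = [lag_fit(traces[i], **lag_kwargs) for i in order]
    sorted_concs = [concs[i] for i in order]

    rates = np.array([f.per_enzyme_rate for f in fits])
    cv = float(np.std(rates, ddof=1) / np.mean(rates))
    init = [f.initiation_rate for f in fits]
    increasing = all(b > a for a, b in zip(init, init[1:]))
    return SeriesResult(
        concentrations_um=tuple(sorted_concs),
        fits=tuple(fits),
        per_enzyme_rate_cv=cv,
        initiation_strictly_increasing=increasing,
    )


def _runs_test(residuals: np.ndarray) -> tuple[float, float]:
    """Wald-Wolfowitz runs test on residual signs; returns (z, p)."""
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    if n_pos == 0 or n_neg == 0:
        return float("-inf"), 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n_pos + n_neg
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 0.0, 1.0
    z = (runs - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def fit_single_exponential(trace: KineticTrace) -> ExpFitResult:
    """Fit baseline + A (1 - exp(-k t)) and diagnose misfit.

    A multi-step process (sequential assembly) produces sigmoid signals
    whose residuals against a single exponential are serially correlated;
    the Wald-Wolfowitz runs test on residual signs flags that structure.
    A near-constant trace is reported as unidentifiable.
    """
    from scipy.optimize import curve_fit

    if len(trace.time_s) < 10:
        raise ValueError("fit_single_exponential needs >= 10 points")
    t, y = trace.time_s, trace.signal
    span = float(y.max() - y.min())
    scale = max(abs(float(y.mean())), 1.0)
    if span < 1e-9 * scale:
        return ExpFitResult(0.0, float("nan"), float(y.mean()), 0.0, 0.0, 1.0, False)

    def model(tt, a, k, b):
        return b + a * (1.0 - np.exp(-k * tt))

    k0 = 1.0 / max(float(t[-1]) / 5.0, 1e-9)
    try:
        popt, _ = curve_fit(
            model, t, y, p0=[span, k0, float(y[0])], maxfev=20000
        )
    except RuntimeError:
        return ExpFitResult(float("nan"), float("nan"), float("nan"),
                            float("inf"), float("-inf"), 0.0, False)
    resid = y - model(t, *popt)
    z, p = _runs_test(resid)
    sd = float(np.std(resid, ddof=min(3, len(resid) - 1)))
    return ExpFitResult(
        amplitude=float(popt[0]),
        rate=float(popt[1]),
        baseline=float(popt[2]),
        residual_sd=sd,
        runs_z=z,
        runs_p=p,
        identifiable=True,
    )
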