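"""Curve rescue steps and derivative/baseline estimation.

These operations prepare suboptimal experimental curves for fitting
(trimming, median smoothing, binning) and extract the quantities used to
initialize the nonlinear fit: linear baselines from 10 K end stretches,
the S/Z orientation of the curve, and an initial melting-temperature
estimate from the extremum of a Savitzky–Golay derivative.

Windows are specified in kelvin (the natural unit of the instrument) and
converted internally to odd point counts via the median temperature step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt, savgol_filter

from .curves import MIN_POINTS, CurveError, MeltingCurve

#: Length of the end stretches used for baseline estimation, K.
BASELINE_STRETCH_K = 10.0

#: A curve is "flat" (no transition) when the variance of its residual
#: around a single straight line does not exceed this multiple of the
#: noise variance.  Pure noise gives a ratio of ~1 (±2/√n); any genuine
#: transition inflates it far past 2.
FLAT_VARIANCE_RATIO = 2.0


@dataclass
class CurveShape:
    """Orientation and initial estimates extracted from a raw curve.

    ``kind`` is "S" when the signal rises through the transition and "Z"
    when it falls; slopes/intercepts are least-squares lines on the first
    and last 10 K stretches; ``tm_initial`` is the temperature of the
    derivative extremum between the stretches.
    """

    kind: str  # "S" or "Z"
    k_N: float
    b_N: float
    k_U: float
    b_U: float
    tm_initial: float
    no_transition: bool = False


def window_points(window_k: float, median_step: float, minimum: int = 3) -> int:
    """Convert a kelvin window to an odd point count (≥ ``minimum``)."""
    if median_step <= 0:
        raise CurveError("nonpositive temperature step")
    n = int(round(window_k / median_step))
    if n % 2 == 0:
        n += 1
    if n < minimum:
        raise CurveError(
            f"window of {window_k} K spans only {n} points (minimum {minimum})"
        )
    return n


def trim(curve: MeltingCurve, t_low: float, t_high: float) -> MeltingCurve:
    """Keep only points with temperature in [t_low, t_high] (kelvin)."""
    if t_low >= t_high:
        raise CurveError("t_low must be below t_high")
    mask = (curve.temperature >= t_low) & (curve.temperature <= t_high)
    if mask.sum() < MIN_POINTS:
        raise CurveError(f"{curve.sample_id}: over-trimmed (<{MIN_POINTS} points remain)")
    return curve.replace_data(
        curve.temperature[mask], curve.signal[mask], f"trim to [{t_low}, {t_high}] K"
    )


def smooth_median(curve: MeltingCurve, window_k: float = 2.0) -> MeltingCurve:
    """Median-filter the signal with a window of ``window_k`` kelvin."""
    n = window_points(window_k, curve.median_step)
    if n >= len(curve):
        raise CurveError(f"{curve.sample_id}: median window exceeds curve length")
    smoothed = medfilt(curve.signal, kernel_size=n)
    # medfilt zero-pads the ends; keep original edge values instead
    half = n // 2
    smoothed[:half] = curve.signal[:half]
    smoothed[-half:] = curve.signal[-half:]
    return curve.replace_data(
        curve.temperature, smoothed, f"median filter window {window_k} K ({n} pts)"
    )


def bin_curve(curve: MeltingCurve, bin_width: float) -> MeltingCurve:
    """Average points into bins of ``bin_width`` kelvin (noise suppression).

    Each bin is represented by its mean temperature and mean signal; empty
    bins are dropped.  Requires the bin width to be at least twice the
    median step and at least 20 resulting bins.
    """
    step = curve.median_step
    if bin_width < 2 * step:
        raise CurveError("bin width must be at least twice the median step")
    edges = np.arange(curve.t_min, curve.t_max + bin_width, bin_width)
    idx = np.digitize(curve.temperature, edges) - 1
    t_out, s_out = [], []
    for b in np.unique(idx):
        m = idx == b
        t_out.append(curve.temperature[m].mean())
        s_out.append(curve.signal[m].mean())
    if len(t_out) < MIN_POINTS:
        raise CurveError(f"{curve.sample_id}: fewer than {MIN_POINTS} bins")
    return curve.replace_data(
        np.array(t_out), np.array(s_out), f"binned at {bin_width} K"
    )


def savgol_derivative(
    curve: MeltingCurve, window_k: float = 10.0, polyorder: int = 4
) -> np.ndarray:
    """First derivative of the signal (units/K) via a Savitzky–Golay
    filter with a 4th-order polynomial and a 10 K window by default.

    Exact for polynomial signals up to the filter order.
    """
    step = curve.median_step
    n = window_points(window_k, step, minimum=polyorder + 1 + (polyorder % 2))
    if n <= polyorder:
        raise CurveError("window must span more points than the polynomial order")
    if n > len(curve):
        raise CurveError(f"{curve.sample_id}: too few points for a {window_k} K window")
    return savgol_filter(curve.signal, n, polyorder, deriv=1, delta=step)


def _line_fit(T: np.ndarray, S: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(T, S, 1)
    return float(slope), float(intercept)


def looks_flat(T: np.ndarray, S: np.ndarray, ratio: float = FLAT_VARIANCE_RATIO) -> bool:
    """True when a single straight line explains the signal down to the
    noise floor (no transition present).

    The residual variance around the best line is compared with the noise
    variance estimated from first differences of the signal (a difference
    of two noisy points has variance 2σ²; 1.4826·MAD estimates σ
    robustly, immune to the transition's own contribution).
    """
    line = np.polyval(np.polyfit(T, S, 1), T)
    rms_resid = float(np.sqrt(np.mean((S - line) ** 2)))
    d1 = np.diff(S)
    sigma = 1.4826 * float(np.median(np.abs(d1 - np.median(d1)))) / np.sqrt(2.0)
    # floor keeps exact lines (zero noise, float-level residual) flat
    floor = 1e-9 * max(float(np.max(np.abs(S))), 1e-300)
    return rms_resid**2 <= ratio * sigma**2 + floor**2


def estimate_shape_and_baselines(
    curve: MeltingCurve,
    stretch_k: float = BASELINE_STRETCH_K,
    savgol_window_k: float = 10.0,
    savgol_polyorder: int = 4,
) -> CurveShape:
    """Estimate baselines, curve orientation and an initial T_m.

    Least-squares lines are fitted to the first and last ``stretch_k``
    kelvin of the curve.  The curve is S-shaped when the end line
    evaluated at the scan midpoint exceeds the start line (signal rises
    with temperature), Z-shaped otherwise.  The initial T_m is the global
    extremum (maximum for S, minimum for Z) of the Savitzky–Golay
    derivative restricted to strictly between the two stretches; ties go
    to the lower temperature.  Curves that a single straight line already
    explains down to the noise floor (see :func:`looks_flat`) are flagged
    ``no_transition`` with the scan midpoint as a placeholder T_m.
    """
    span = curve.t_max - curve.t_min
    if span < 3 * stretch_k:
        raise CurveError(
            f"{curve.sample_id}: scan too short for baseline estimation "
            f"(need ≥ {3 * stretch_k:.0f} K, have {span:.1f} K)"
        )
    T, S = curve.temperature, curve.signal
    pre = T <= curve.t_min + stretch_k
    post = T >= curve.t_max - stretch_k
    k_pre, b_pre = _line_fit(T[pre], S[pre])
    k_post, b_post = _line_fit(T[post], S[post])

    mid = 0.5 * (curve.t_min + curve.t_max)
    # Orientation from the two end lines evaluated at their own stretch
    # centers (robust when the transition overlaps an end stretch, where
    # the stretch line extrapolates wildly to the scan midpoint).
    c_pre = float(T[pre].mean())
    c_post = float(T[post].mean())
    s_shaped = (k_post * c_post + b_post) > (k_pre * c_pre + b_pre)

    deriv = savgol_derivative(curve, savgol_window_k, savgol_polyorder)
    interior = (~pre) & (~post)
    d_int = deriv[interior]
    t_int = T[interior]
    if d_int.size == 0:
        raise CurveError(f"{curve.sample_id}: no interior points between baseline stretches")

    signed = d_int if s_shaped else -d_int
    # ties broken toward lower temperature: argmax returns the first index
    tm_initial = float(t_int[int(np.argmax(signed))])

    # No-transition gate: a curve with no transition is one a single
    # straight line explains down to the noise floor.  The noise scale
    # comes from first differences of the signal (a difference of two
    # noisy points has variance 2σ²; 1.4826·MAD estimates σ robustly).
    no_transition = looks_flat(T, S)
    if no_transition:
        tm_initial = mid

    return CurveShape(
        kind="S" if s_shaped else "Z",
        k_N=k_pre,
        b_N=b_pre,
        k_U=k_post,
        b_U=b_post,
        tm_initial=tm_initial,
        no_transition=no_transition,
    )
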