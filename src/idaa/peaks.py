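"""Peak detection and quantification on electropherogram channels.

The processing chain expected by the rest of the toolkit is:

1. :func:`smooth_trace` — Savitzky–Golay polynomial smoothing;
2. :func:`estimate_baseline` — morphological-opening baseline, subtracted and
   clipped at zero by the caller;
3. :func:`detect_peaks` — local-maximum peak picking with height and
   separation thresholds, valley/threshold boundary assignment, trapezoidal
   area integration and sub-scan apex refinement.

Areas are the quantification currency downstream: allele fractions and
cutting efficiencies are ratios of peak areas, so boundaries and integration
are defined here once and reused everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps

from .errors import ParameterError

#: Raw fluorescence at or above which a detector is considered saturated.
SATURATION_THRESHOLD = 32000

DEFAULT_BASELINE_WINDOW = 151
DEFAULT_SMOOTH_WINDOW = 9
DEFAULT_SMOOTH_ORDER = 3
DEFAULT_MIN_HEIGHT = 50.0
DEFAULT_MIN_SEPARATION = 10


@dataclass(frozen=True)
class Peak:
    """A detected signal peak.

    ``apex_scan`` is the integer scan index of the maximum; ``apex`` is the
    sub-scan apex position estimated by local Gaussian interpolation, which
    is what sizing should use.  ``area`` is the trapezoidal integral of the
    (baseline-corrected) signal over ``[left_scan, right_scan]``.
    """

    apex_scan: int
    apex_height: float
    left_scan: int
    right_scan: int
    area: float
    saturated: bool = False
    apex: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.apex is None:
            object.__setattr__(self, "apex", float(self.apex_scan))
        if not (self.left_scan <= self.apex_scan <= self.right_scan):
            raise ParameterError("peak boundaries do not bracket the apex")


def estimate_baseline(intensities, window: int = DEFAULT_BASELINE_WINDOW) -> np.ndarray:
    """Morphological-opening baseline: rolling minimum then rolling maximum.

    The opening never exceeds the input, erases features narrower than
    *window* scans (peaks), and follows broad drift.  *window* must be odd
    and at least 3.
    """
    x = np.asarray(intensities, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ParameterError("baseline window must be odd and >= 3")
    if window > x.size:
        raise ParameterError("baseline window larger than signal")
    eroded = ndimage.minimum_filter1d(x, size=window, mode="nearest")
    return ndimage.maximum_filter1d(eroded, size=window, mode="nearest")


def smooth_trace(intensities, window: int = DEFAULT_SMOOTH_WINDOW,
                 order: int = DEFAULT_SMOOTH_ORDER) -> np.ndarray:
    """Savitzky–Golay smoothing; exact on polynomials up to degree *order*."""
    x = np.asarray(intensities, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ParameterError("smoothing window must be odd and positive")
    if order >= window:
        raise ParameterError("polynomial order must be smaller than the window")
    if window == 1 or x.size == 0:
        return x.copy()
    if window > x.size:
        raise ParameterError("smoothing window larger than signal")
    return sps.savgol_filter(x, window_length=window, polyorder=order)


def integrate_region(intensities, left: int, right: int) -> float:
    """Trapezoidal integral of the signal over the closed interval [left, right]."""
    x = np.asarray(intensities, dtype=float)
    if not (0 <= left < right < x.size):
        raise ParameterError(f"integration bounds [{left}, {right}] outside signal")
    return float(np.trapezoid(x[left : right + 1]))


def _refine_apex(y: np.ndarray, idx: int) -> float:
    """Sub-scan apex by 3-point Gaussian (log-parabolic) interpolation.

    Exact for samples of a Gaussian; falls back to the integer index when the
    neighbourhood is flat, clipped, or non-positive.
    """
    if idx <= 0 or idx >= y.size - 1:
        return float(idx)
    a, b, c = y[idx - 1], y[idx], y[idx + 1]
    if not (a > 0 and b > 0 and c > 0 and b >= a and b >= c):
        return float(idx)
    la, lb, lc = np.log(a), np.log(b), np.log(c)
    denom = la - 2.0 * lb + lc
    if denom >= -1e-12:  # flat or inverted curvature
        return float(idx)
    delta = 0.5 * (la - lc) / denom
    if not np.isfinite(delta) or abs(delta) > 1.0:
        return float(idx)
    return float(idx + delta)


def _walk_boundary(y: np.ndarray, apex: int, cutoff: float, step: int) -> int:
    """Walk downhill from the apex until the signal rises again (valley) or
    drops below *cutoff*, whichever happens closer to the apex."""
    j = apex
    last = y.size - 1
    while 0 < j < last or (step < 0 and j > 0) or (step > 0 and j < last):
        nxt = j + step
        if nxt < 0 or nxt > last:
            break
        if y[j] < cutoff:
            break
        if y[nxt] > y[j]:  # j is the valley
            break
        j = nxt
    return j


def detect_peaks(intensities, min_height: float = DEFAULT_MIN_HEIGHT,
                 min_separation: int = DEFAULT_MIN_SEPARATION,
                 raw=None,
                 saturation_threshold: float = SATURATION_THRESHOLD,
                 refine_on=None) -> list[Peak]:
    """Find peaks in a baseline-corrected signal.

    Local maxima with height >= *min_height* at least *min_separation* scans
    apart (the higher of a conflicting pair wins).  Boundaries sit at the
    nearest flanking local minimum, or where the signal falls below
    ``max(1% of apex, min_height / 2)``, whichever is closer to the apex.
    Plateau-topped (clipped) peaks are supported; their apex is the plateau
    midpoint.

    *raw* — the uncorrected signal, used only for the saturation flag.
    *refine_on* — signal used for sub-scan apex interpolation (defaults to
    the detection signal); pass the unsmoothed corrected signal to avoid
    filter-induced shape bias.
    """
    y = np.asarray(intensities, dtype=float)
    if min_height <= 0:
        raise ParameterError("min_height must be positive")
    if y.size == 0:
        return []
    idxs, props = sps.find_peaks(y, height=min_height, distance=max(1, int(min_separation)),
                                 plateau_size=(1, None))
    raw_y = None if raw is None else np.asarray(raw, dtype=float)
    refine_y = y if refine_on is None else np.asarray(refine_on, dtype=float)

    out: list[Peak] = []
    for k, idx in enumerate(idxs):
        le, re = int(props["left_edges"][k]), int(props["right_edges"][k])
        apex_idx = int(idx)
        height = float(y[apex_idx])
        cutoff = max(0.01 * height, min_height / 2.0)
        left = _walk_boundary(y, le, cutoff, -1)
        right = _walk_boundary(y, re, cutoff, +1)
        if left == right:
            continue  # degenerate single-scan spike
        if re > le:
            apex_pos = (le + re) / 2.0  # clipped/flat top: midpoint
            apex_idx = int(round(apex_pos))
        else:
            apex_pos = _refine_apex(refine_y, apex_idx)
        area = float(np.trapezoid(np.clip(y[left : right + 1], 0.0, None)))
        if area <= 0:
            continue
        sat_src = raw_y if raw_y is not None else y
        saturated = bool(np.max(sat_src[le : re + 1]) >= saturation_threshold)
        out.append(Peak(apex_scan=apex_idx, apex_height=height, left_scan=left,
                        right_scan=right, area=area, saturated=saturated, apex=apex_pos))
    out.sort(key=lambda p: p.apex_scan)
    return out


def correct_channel(intensities, baseline_window: int = DEFAULT_BASELINE_WINDOW,
                    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
                    smooth_order: int = DEFAULT_SMOOTH_ORDER) -> tuple[np.ndarray, np.ndarray]:
    """Standard conditioning: smooth, subtract an opening baseline, clip at zero.

    Returns ``(corrected_smoothed, corrected_unsmoothed)``; the second array
    preserves the raw peak shape (same baseline subtracted) for sub-scan apex
    interpolation.
    """
    x = np.asarray(intensities, dtype=float)
    smoothed = smooth_trace(x, smooth_window, smooth_order)
    base = estimate_baseline(smoothed, baseline_window)
    return np.clip(smoothed - base, 0.0, None), np.clip(x - base, 0.0, None)
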