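"""Size-standard matching and scan-to-basepair calibration.

Fragment analysis sizes unknown peaks against an in-lane ladder of fragments
of known length (e.g. the LIZ-labelled GeneScan 500/600 sets).  Two steps:

1. :func:`match_ladder` assigns every ladder fragment size to one detected
   ladder-channel peak, order-preservingly, minimising the residual sum of
   squares of a straight-line fit of scan on size over all admissible
   assignments — robust against spurious extra peaks.
2. :func:`fit_calibration` fits a monotone scan→bp mapping through the
   matched points.  The default is the Local Southern method: fragment
   mobility follows the reciprocal law ``L = c/(m - m0) + L0`` locally, so
   for each query two overlapping three-point hyperbolae are fitted through
   the flanking ladder points and their predictions averaged.

:func:`size_peaks` then annotates sample peaks with fractional sizes in bp.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import LadderFailureError, ParameterError
from .peaks import Peak

#: Max number of candidate subsets enumerated exactly in match_ladder before
#: switching to iterative refinement.
_MAX_ENUMERATION = 250_000


@dataclass(frozen=True)
class SizeStandard:
    """A named ladder: strictly increasing fragment sizes in bp (>= 4 of them)."""

    name: str
    fragment_sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.fragment_sizes)
        object.__setattr__(self, "fragment_sizes", sizes)
        if len(sizes) < 4:
            raise ParameterError("a size standard needs at least 4 fragments")
        if any(s <= 0 for s in sizes) or any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ParameterError("fragment sizes must be positive and strictly increasing")

    def __len__(self) -> int:
        return len(self.fragment_sizes)


def _load_builtin(name: str) -> SizeStandard:
    ref = importlib.resources.files("idaa.data") / f"{name.lower()}.tsv"
    with ref.open() as fh:
        return _parse_standard_tsv(fh, name.upper())


def _parse_standard_tsv(fh, name: str) -> SizeStandard:
    lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or lines[0].split("\t")[0].lower() != "size_bp":
        raise ParameterError("size-standard TSV must have a 'size_bp' header")
    return SizeStandard(name, tuple(float(ln.split("\t")[0]) for ln in lines[1:]))


def load_standard(spec: str) -> SizeStandard:
    """Resolve a standard by built-in name (``LIZ500``/``LIZ600``) or TSV path."""
    if spec.upper() in ("LIZ500", "LIZ600"):
        return _load_builtin(spec)
    with open(spec) as fh:
        return _parse_standard_tsv(fh, spec)


def _linear_rss(sizes: np.ndarray, scans: np.ndarray) -> float:
    """RSS of the least-squares line scan = a + b * size."""
    x = sizes - sizes.mean()
    y = scans - scans.mean()
    sxx = float(x @ x)
    if sxx == 0.0:
        return float(y @ y)
    return max(0.0, float(y @ y - (x @ y) ** 2 / sxx))


def _assignment_rss(sizes: np.ndarray, scans: np.ndarray, combos: np.ndarray) -> np.ndarray:
    """Vectorised linear-fit RSS for many candidate subsets (rows of scan values)."""
    y = scans[combos]
    x = sizes - sizes.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = float(x @ x)
    sxy = yc @ x
    return np.maximum(0.0, (yc * yc).sum(axis=1) - sxy**2 / sxx)


def _dp_assign(sizes: np.ndarray, scans: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Order-preserving injective assignment minimising squared deviation from
    per-fragment predicted scans (classic sequence-alignment DP)."""
    k, n = len(sizes), len(scans)
    cost = (scans[None, :] - predicted[:, None]) ** 2
    INF = math.inf
    dp = np.full((k + 1, n + 1), INF)
    dp[0, :] = 0.0
    choice = np.zeros((k + 1, n + 1), dtype=bool)
    for i in range(1, k + 1):
        for j in range(1, n + 1):
            skip = dp[i, j - 1]
            take = dp[i - 1, j - 1] + cost[i - 1, j - 1]
            if take <= skip:
                dp[i, j] = take
                choice[i, j] = True
            else:
                dp[i, j] = skip
    # backtrack
    idx = np.empty(k, dtype=int)
    j = n
    for i in range(k, 0, -1):
        while not choice[i, j]:
            j -= 1
        idx[i - 1] = j - 1
        j -= 1
    return idx


def match_ladder(peaks: list[Peak], standard: SizeStandard,
                 max_rss: float | None = None) -> list[tuple[float, float]]:
    """Assign every ladder fragment to a detected peak apex.

    Returns ``(scan, size_bp)`` pairs sorted by size.  The assignment is the
    order-preserving injective one minimising the linear-fit RSS of scan on
    size; for modest numbers of spurious candidates this optimum is found by
    exhaustive enumeration, otherwise by iterated dynamic-programming
    refinement against the current line fit.

    Raises :class:`LadderFailureError` when there are fewer candidate peaks
    than fragments, or when *max_rss* is set and the optimum exceeds it.
    """
    sizes = np.asarray(standard.fragment_sizes, dtype=float)
    scans = np.asarray(sorted(p.apex for p in peaks), dtype=float)
    k, n = len(sizes), len(scans)
    if n < k:
        raise LadderFailureError(
            f"{n} candidate peaks for the {k}-fragment standard {standard.name}"
        )
    if math.comb(n, k) <= _MAX_ENUMERATION:
        combos = np.array(list(combinations(range(n), k)), dtype=int)
        rss = _assignment_rss(sizes, scans, combos)
        best = int(np.argmin(rss))
        chosen, best_rss = combos[best], float(rss[best])
    else:
        # start from evenly spread candidates, iterate line fit <-> DP assignment
        idx = np.round(np.linspace(0, n - 1, k)).astype(int)
        for _ in range(50):
            b, a = np.polyfit(sizes, scans[idx], 1)
            new = _dp_assign(sizes, scans, a + b * sizes)
            if np.array_equal(new, idx):
                break
            idx = new
        chosen, best_rss = idx, _linear_rss(sizes, scans[idx])
    if max_rss is not None and best_rss > max_rss:
        raise LadderFailureError(
            f"ladder fit RSS {best_rss:.1f} exceeds ceiling {max_rss:.1f}"
        )
    return [(float(scans[j]), float(s)) for j, s in zip(chosen, sizes)]


def _fit_hyperbola(m: np.ndarray, L: np.ndarray):
    """Fit L = c/(scan - m0) + L0 exactly through three points.

    The relation is linear in (L0, m0, e = c - L0*m0):
    ``L*m = L0*m + m0*L + e``.  Returns an evaluator, or None when the three
    points are collinear/degenerate (caller falls back to a quadratic).
    """
    A = np.column_stack([m, L, np.ones(3)])
    try:
        a, b, e = np.linalg.solve(A, m * L)
    except np.linalg.LinAlgError:
        return None
    c = e + a * b
    if not np.isfinite(c) or min(m) < b < max(m):  # pole inside the bracket
        return None

    def ev(q: float) -> float:
        return a + c / (q - b)

    # collinear points make the system singular; floating point can return a
    # spurious finite solution, so verify the fit reproduces its own knots
    if any(abs(ev(mi) - Li) > 1e-6 * max(abs(L).max(), 1.0) for mi, Li in zip(m, L)):
        return None
    return ev


def _local_fit_eval(m: np.ndarray, L: np.ndarray, q: float) -> float:
    ev = _fit_hyperbola(m, L)
    if ev is not None:
        val = ev(q)
        if np.isfinite(val):
            return val
    return float(np.polyval(np.polyfit(m, L, 2), q))  # collinear fallback


@dataclass
class Calibration:
    """A fitted monotone scan→bp mapping.

    ``points`` are the matched ladder anchors; ``residuals`` are per-point
    leave-one-out refit errors in bp; ``calibrated_range`` is the scan span
    of the anchors — sizes outside it are extrapolations.
    """

    scans: np.ndarray
    sizes: np.ndarray
    method: str = "local_southern"
    residuals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scans = np.asarray(self.scans, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if np.any(np.diff(self.scans) <= 0) or np.any(np.diff(self.sizes) <= 0):
            raise ParameterError("calibration points must be strictly increasing in scan and size")
        if self.method not in ("local_southern", "spline"):
            raise ParameterError(f"unknown sizing method {self.method!r}")
        if self.method == "spline":
            self._pchip = PchipInterpolator(self.scans, self.sizes, extrapolate=True)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.scans.tolist(), self.sizes.tolist()))

    @property
    def calibrated_range(self) -> tuple[float, float]:
        return float(self.scans[0]), float(self.scans[-1])

    def _eval_local_southern(self, q: float) -> float:
        m, L, n = self.scans, self.sizes, len(self.scans)
        j = int(np.searchsorted(m, q, side="right")) - 1
        lo_ok = 1 <= j <= n - 2  # triple (j-1, j, j+1)
        hi_ok = 0 <= j <= n - 3  # triple (j, j+1, j+2)
        vals = []
        if lo_ok:
            vals.append(_local_fit_eval(m[j - 1 : j + 2], L[j - 1 : j + 2], q))
        if hi_ok:
            vals.append(_local_fit_eval(m[j : j + 3], L[j : j + 3], q))
        if not vals:  # outside the anchors: nearest end triple
            tri = slice(0, 3) if j < 1 else slice(n - 3, n)
            vals.append(_local_fit_eval(m[tri], L[tri], q))
        return float(np.mean(vals))

    def __call__(self, scan):
        if self.method == "spline":
            out = self._pchip(scan)
            return float(out) if np.isscalar(scan) else np.asarray(out)
        if np.isscalar(scan):
            return self._eval_local_southern(float(scan))
        return np.array([self._eval_local_southern(float(s)) for s in np.asarray(scan)])

    def contains(self, scan: float) -> bool:
        lo, hi = self.calibrated_range
        return lo <= scan <= hi


def fit_calibration(matched: list[tuple[float, float]],
                    method: str = "local_southern") -> Calibration:
    """Fit a calibration through matched ``(scan, size)`` pairs (>= 4, increasing).

    Leave-one-out residuals are computed by refitting without each anchor and
    predicting its size; they populate the ladder QC block of reports.
    """
    if len(matched) < 4:
        raise ParameterError("calibration requires at least 4 matched ladder points")
    pairs = sorted(matched, key=lambda t: t[1])
    scans = np.array([p[0] for p in pairs], dtype=float)
    sizes = np.array([p[1] for p in pairs], dtype=float)
    cal = Calibration(scans, sizes, method=method)
    resid = np.empty(len(pairs))
    for i in range(len(pairs)):
        sub = Calibration(np.delete(scans, i), np.delete(sizes, i), method=method)
        resid[i] = sub(scans[i]) - sizes[i]
    cal.residuals = resid
    return cal


@dataclass(frozen=True)
class SizedPeak:
    """A peak annotated with its fractional size in bp."""

    peak: Peak
    size_bp: float
    extrapolated: bool = False


def size_peaks(calibration: Calibration, peaks: list[Peak]) -> list[SizedPeak]:
    """Annotate each peak with the size at its (sub-scan) apex position."""
    return [
        SizedPeak(peak=p, size_bp=float(calibration(p.apex)),
                  extrapolated=not calibration.contains(p.apex))
        for p in peaks
    ]
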