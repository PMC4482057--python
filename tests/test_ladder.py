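"""Ladder matching and scan-to-bp calibration (Local Southern and spline)."""

from itertools import combinations

import numpy as np
import pytest

from idaa.errors import LadderFailureError, ParameterError
from idaa.ladder import (Calibration, SizeStandard, fit_calibration, load_standard, match_ladder,
                         size_peaks)
from tests.conftest import make_peak

M0, C = 10000.0, 2.0e5


def southern_scan(size):
    """Generating migration law: scan = m0 - c / size."""
    return M0 - C / np.asarray(size, dtype=float)


def southern_points(sizes):
    return [(float(southern_scan(s)), float(s)) for s in sizes]


def brute_force_match(scans, sizes):
    """Oracle: enumerate all order-preserving assignments, pick min linear RSS."""
    best, best_rss = None, np.inf
    scans = np.sort(np.asarray(scans, dtype=float))
    for combo in combinations(range(len(scans)), len(sizes)):
        y = scans[list(combo)]
        rss = np.sum((y - np.polyval(np.polyfit(sizes, y, 1), sizes)) ** 2)
        if rss < best_rss:
            best, best_rss = combo, rss
    return [float(scans[j]) for j in best]


class TestMatchLadder:
    def test_perfect_affine_case(self):
        std = SizeStandard("t", (50, 100, 200, 400, 500))
        peaks = [make_peak(1000 + 4 * s) for s in std.fragment_sizes]
        matched = match_ladder(peaks, std)
        assert [s for _, s in matched] == list(std.fragment_sizes)
        assert [m for m, _ in matched] == [1000 + 4 * s for s in std.fragment_sizes]

    def test_spurious_peak_skipped(self):
        std = SizeStandard("t", (50, 100, 200, 400, 500))
        scans = [1000 + 4 * s for s in std.fragment_sizes]
        peaks = [make_peak(s) for s in scans + [1150.0]]  # spike between first two
        matched = match_ladder(peaks, std)
        assert [m for m, _ in matched] == scans

    def test_too_few_candidates_is_a_ladder_failure(self):
        std = SizeStandard("t", (50, 100, 200, 400, 500))
        with pytest.raises(LadderFailureError):
            match_ladder([make_peak(s) for s in (100, 200, 300)], std)

    def test_rss_ceiling_enforced(self):
        std = SizeStandard("t", (50, 100, 200, 400))
        peaks = [make_peak(s) for s in (500, 600, 5000, 5100)]
        with pytest.raises(LadderFailureError):
            match_ladder(peaks, std, max_rss=10.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_exhaustive_search(self, seed):
        """Up to 9 candidates: the assignment equals brute-force enumeration."""
        rng = np.random.default_rng(seed)
        sizes = np.sort(rng.choice(np.arange(50, 600, 10), size=6, replace=False)).astype(float)
        true_scans = 800 + 7.5 * sizes + rng.normal(0, 4, size=6)
        n_spur = rng.integers(0, 4)
        spurious = rng.uniform(true_scans.min(), true_scans.max(), size=n_spur)
        cands = np.concatenate([true_scans, spurious])
        got = [m for m, _ in match_ladder([make_peak(s) for s in cands], SizeStandard("t", tuple(sizes)))]
        assert got == brute_force_match(cands, sizes)


class TestLocalSouthern:
    def test_recovers_generating_law_exactly(self):
        cal = fit_calibration(southern_points([50, 100, 200, 400]))
        assert cal(8000.0) == pytest.approx(100.0, abs=1e-9)

    def test_knots_are_interpolated(self):
        sizes = [50, 100, 200, 400, 500]
        cal = fit_calibration(southern_points(sizes))
        for s in sizes:
            assert cal(float(southern_scan(s))) == pytest.approx(s, abs=1e-6)

    def test_midway_query_matches_closed_form_inverse(self):
        cal = fit_calibration(southern_points([50, 100, 200, 400]))
        q = float(southern_scan(100) + southern_scan(200)) / 2
        assert cal(q) == pytest.approx(C / (M0 - q), abs=1e-9)

    def test_loo_residuals_track_scan_noise(self):
        """1-scan Gaussian jitter on the anchors: leave-one-out refit errors
        stay below 1 bp wherever the migration curve is steep (fragments
        <= 250 bp under this law, where a basepair spans >= ~6 scans) and
        bounded by a few bp at the flat top of the range where one scan spans
        more basepairs and the leave-one-out gap is wide."""
        m0, c = 12000.0, 4.0e5
        rng = np.random.default_rng(11)
        sizes = load_standard("LIZ500").fragment_sizes
        pts = [(float(m0 - c / s + rng.normal(0, 1)), float(s)) for s in sizes]
        cal = fit_calibration(pts)
        resid = np.abs(cal.residuals)
        steep = np.array([s <= 250 for s in sizes])
        assert np.all(resid[steep] < 1.0)
        assert np.all(resid < 4.0)

    def test_strictly_increasing_over_calibrated_range(self):
        for method in ("local_southern", "spline"):
            cal = fit_calibration(southern_points(load_standard("LIZ500").fragment_sizes),
                                  method=method)
            lo, hi = cal.calibrated_range
            grid = cal(np.linspace(lo, hi, 1500))
            assert np.all(np.diff(grid) > 0), method

    def test_spline_interpolates_knots(self):
        sizes = [50, 100, 200, 400]
        cal = fit_calibration(southern_points(sizes), method="spline")
        for s in sizes:
            assert cal(float(southern_scan(s))) == pytest.approx(s, abs=1e-9)

    def test_collinear_points_fall_back_gracefully(self):
        pts = [(1000.0 + 10 * s, float(s)) for s in (50, 100, 200, 400)]
        cal = fit_calibration(pts)
        assert cal(2500.0) == pytest.approx(150.0, abs=1e-6)

    def test_non_monotone_input_rejected(self):
        with pytest.raises(ParameterError):
            Calibration(np.array([1.0, 3.0, 2.0, 4.0]), np.array([50.0, 100.0, 200.0, 400.0]))

    def test_needs_four_points(self):
        with pytest.raises(ParameterError):
            fit_calibration(southern_points([50, 100, 200]))


class TestSizePeaks:
    def test_ladder_peaks_get_nominal_sizes(self):
        sizes = [50, 100, 200, 400, 500]
        cal = fit_calibration(southern_points(sizes))
        peaks = [make_peak(float(southern_scan(s))) for s in sizes]
        sized = size_peaks(cal, peaks)
        assert [sp.size_bp for sp in sized] == pytest.approx(sizes, abs=1e-6)
        assert not any(sp.extrapolated for sp in sized)

    def test_outside_range_flagged_extrapolated(self):
        cal = fit_calibration(southern_points([50, 100, 200, 400]))
        sized = size_peaks(cal, [make_peak(southern_scan(30)), make_peak(southern_scan(450))])
        assert all(sp.extrapolated for sp in sized)

    def test_empty_input(self):
        cal = fit_calibration(southern_points([50, 100, 200, 400]))
        assert size_peaks(cal, []) == []


class TestStandards:
    def test_builtins_load(self):
        liz500, liz600 = load_standard("LIZ500"), load_standard("LIZ600")
        assert len(liz500) == 16 and liz500.fragment_sizes[0] == 35.0
        assert len(liz600) == 36 and liz600.fragment_sizes[-1] == 600.0

    def test_user_tsv(self, tmp_path):
        p = tmp_path / "std.tsv"
        p.write_text("size_bp\n50\n120\n250\n400\n")
        std = load_standard(str(p))
        assert std.fragment_sizes == (50.0, 120.0, 250.0, 400.0)

    def test_tsv_header_required(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("50\n120\n250\n400\n")
        with pytest.raises(ParameterError):
            load_standard(str(p))

    def test_standard_invariants(self):
        with pytest.raises(ParameterError):
            SizeStandard("x", (50, 100, 200))  # too few
        with pytest.raises(ParameterError):
            SizeStandard("x", (50, 100, 100, 200))  # not strictly increasing
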