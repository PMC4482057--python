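"""Shared fixtures: synthetic signals, sized-peak builders and simulated runs."""

from __future__ import annotations

import numpy as np
import pytest

from idaa.ladder import SizedPeak
from idaa.peaks import Peak


def gaussian_signal(length: int, apexes, heights, sigma: float = 5.0) -> np.ndarray:
    """Sum of Gaussians on a zero baseline."""
    x = np.arange(length, dtype=float)
    y = np.zeros(length)
    for mu, h in zip(np.atleast_1d(apexes), np.atleast_1d(heights)):
        y += h * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))
    return y


def make_peak(apex: float, area: float = 100.0, height: float = 500.0) -> Peak:
    a = int(round(apex))
    return Peak(apex_scan=a, apex_height=height, left_scan=a - 10, right_scan=a + 10,
                area=area, apex=float(apex))


def make_sized(size_bp: float, area: float, height: float = 500.0,
               extrapolated: bool = False) -> SizedPeak:
    return SizedPeak(peak=make_peak(apex=size_bp * 10.0, area=area, height=height),
                     size_bp=size_bp, extrapolated=extrapolated)


@pytest.fixture
def gauss():
    return gaussian_signal


@pytest.fixture
def sized_peak():
    return make_sized


@pytest.fixture
def peak():
    return make_peak
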