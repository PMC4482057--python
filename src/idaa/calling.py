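"""Indel allele calling, cutting efficiency and clone genotyping.

Sized sample-channel peaks are converted to integer indel calls relative to
the wild-type amplicon size: ``indel = round(size - wt_size)`` with ties
rounded away from zero.  Peak areas carry the quantification — the fraction
of each allele is its share of total retained peak area, and the cutting
efficiency is the summed fraction of all non-wild-type alleles (peak area
relative to total peak area).

An indel disrupts the reading frame iff its size is not a multiple of 3;
clone genotypes are classified from the filtered allele set (wild type,
mono-allelic, mixed, or all alleles frame-disrupted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .errors import ReferenceSizeError, UndefinedResultError
from .ladder import SizedPeak

DEFAULT_WINDOW_BP = 150.0
DEFAULT_CLUSTER_TOL_BP = 0.5
DEFAULT_MIN_FRACTION = 0.005
DEFAULT_MIN_ALLELE_FRACTION = 0.15
DEFAULT_MAX_ALLELES = 4
#: A control trace must concentrate at least this area share in one peak.
DOMINANT_CONTROL_FRACTION = 0.8


class ReferenceSource(str, Enum):
    CONTROL_TRACE = "control_trace"
    EXPECTED_DESIGN = "expected_design"
    FIXED = "fixed"


class GenotypeClass(str, Enum):
    WILD_TYPE = "wild_type"
    MONO_ALLELIC = "mono_allelic"
    MULTI_ALLELIC_MIXED = "multi_allelic_mixed"
    ALL_ALLELES_DISRUPTED = "all_alleles_disrupted"


def classify_frame(indel_bp: int) -> bool:
    """True iff the indel disrupts the reading frame (size not a multiple of 3)."""
    return indel_bp != 0 and indel_bp % 3 != 0


@dataclass(frozen=True)
class AlleleCall:
    """One called allele: signed indel size, observed mean size, area fraction."""

    indel_bp: int
    mean_size_bp: float
    fraction: float
    frameshift: bool = None  # type: ignore[assignment]
    n_peaks_merged: int = 1
    fraction_raw: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.frameshift is None:
            object.__setattr__(self, "frameshift", classify_frame(self.indel_bp))
        if self.fraction_raw is None:
            object.__setattr__(self, "fraction_raw", self.fraction)


@dataclass
class IndelProfile:
    """Per-sample allele calls plus cutting efficiency and QC flags."""

    sample_name: str
    wt_size_bp: float
    wt_size_source: ReferenceSource
    alleles: list[AlleleCall] = field(default_factory=list)
    cutting_efficiency: float | None = None
    qc_flags: set[str] = field(default_factory=set)
    peaks: list[SizedPeak] = field(default_factory=list)
    calibration: object | None = None  # ladder QC (a ladder.Calibration) when sizing succeeded

    def allele(self, indel_bp: int) -> AlleleCall | None:
        for a in self.alleles:
            if a.indel_bp == indel_bp:
                return a
        return None


@dataclass(frozen=True)
class CloneGenotype:
    allele_count: int
    classification: GenotypeClass
    frame_disrupted_fraction: float
    warnings: tuple[str, ...] = ()


def _round_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (+0.5 -> +1, -0.5 -> -1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def reference_size(control, mode: ReferenceSource | str) -> tuple[float, ReferenceSource]:
    """Establish the wild-type amplicon size and record where it came from.

    *control* is either a number (expected/fixed size) or a collection of
    :class:`SizedPeak` from a wild-type control trace, whose dominant peak
    must hold at least 80% of total peak area.
    """
    mode = ReferenceSource(mode)
    if mode in (ReferenceSource.EXPECTED_DESIGN, ReferenceSource.FIXED):
        return float(control), mode
    peaks: list[SizedPeak] = list(control)
    if not peaks:
        raise ReferenceSizeError("control trace has no sized peaks; pass --expected-size")
    total = sum(p.peak.area for p in peaks)
    top = max(peaks, key=lambda p: p.peak.area)
    if top.peak.area < DOMINANT_CONTROL_FRACTION * total:
        raise ReferenceSizeError(
            f"control trace ambiguous: dominant peak holds "
            f"{top.peak.area / total:.0%} of area (< {DOMINANT_CONTROL_FRACTION:.0%}); "
            "pass --expected-size explicitly"
        )
    return float(top.size_bp), ReferenceSource.CONTROL_TRACE


def call_alleles(sized: list[SizedPeak], wt_size_bp: float,
                 window_bp: float = DEFAULT_WINDOW_BP,
                 min_fraction: float = DEFAULT_MIN_FRACTION,
                 cluster_tol_bp: float = DEFAULT_CLUSTER_TOL_BP) -> list[AlleleCall]:
    """Convert sized peaks into integer indel allele calls with area fractions.

    Peaks within *window_bp* of the wild-type size are kept; each maps to the
    integer offset ``round(size - wt)`` (ties away from zero), and peaks
    within *cluster_tol_bp* of the same integer are merged (areas summed,
    sizes area-weighted).  Fractions are areas over total retained area;
    alleles below *min_fraction* are dropped and the rest renormalised
    (original shares kept in ``fraction_raw``).
    """
    if wt_size_bp <= 0:
        raise ReferenceSizeError("wild-type size must be positive")
    kept = [p for p in sized if abs(p.size_bp - wt_size_bp) <= window_bp]
    if not kept:
        return []
    groups: dict[int, list[SizedPeak]] = {}
    for p in kept:
        groups.setdefault(_round_away(p.size_bp - wt_size_bp), []).append(p)

    total = sum(p.peak.area for p in kept)
    calls = []
    for indel, members in sorted(groups.items()):
        area = sum(p.peak.area for p in members)
        mean_size = sum(p.size_bp * p.peak.area for p in members) / area
        calls.append(AlleleCall(indel_bp=indel, mean_size_bp=mean_size,
                                fraction=area / total, n_peaks_merged=len(members),
                                fraction_raw=area / total))
    retained = [c for c in calls if c.fraction >= min_fraction]
    if not retained:
        return []
    norm = sum(c.fraction for c in retained)
    return [AlleleCall(indel_bp=c.indel_bp, mean_size_bp=c.mean_size_bp,
                       fraction=c.fraction / norm, n_peaks_merged=c.n_peaks_merged,
                       fraction_raw=c.fraction_raw)
            for c in retained]


def cutting_efficiency(alleles: list[AlleleCall]) -> float:
    """Summed area fraction of all non-wild-type alleles (1 - wild-type fraction)."""
    if not alleles:
        raise UndefinedResultError("cutting efficiency undefined for an empty allele set")
    return float(sum(a.fraction for a in alleles if a.indel_bp != 0))


def genotype_clone(profile: IndelProfile,
                   max_alleles: int = DEFAULT_MAX_ALLELES,
                   min_allele_fraction: float = DEFAULT_MIN_ALLELE_FRACTION) -> CloneGenotype:
    """Classify a single-cell clone from its allele calls.

    Alleles with fraction >= *min_allele_fraction* count.  A clone is
    ``wild_type`` when only the 0 allele remains, ``all_alleles_disrupted``
    when no wild-type allele is present and every counted allele shifts the
    reading frame, ``mono_allelic`` for a single non-disrupting non-zero
    allele, otherwise ``multi_allelic_mixed``.  More counted alleles than
    *max_alleles* raises a warning flag (possible clone impurity), not an
    error.
    """
    counted = [a for a in profile.alleles if a.fraction >= min_allele_fraction]
    if not counted:
        raise UndefinedResultError(f"no alleles above fraction {min_allele_fraction} to genotype")
    warns = ()
    if len(counted) > max_alleles:
        warns = (f"{len(counted)} alleles exceed max_alleles={max_alleles}: possible clone impurity",)
    frame_frac = sum(a.fraction for a in counted if a.frameshift) / sum(a.fraction for a in counted)
    has_wt = any(a.indel_bp == 0 for a in counted)
    if has_wt and len(counted) == 1:
        cls = GenotypeClass.WILD_TYPE
    elif not has_wt and all(a.frameshift for a in counted):
        cls = GenotypeClass.ALL_ALLELES_DISRUPTED
    elif len(counted) == 1:
        cls = GenotypeClass.MONO_ALLELIC
    else:
        cls = GenotypeClass.MULTI_ALLELIC_MIXED
    return CloneGenotype(allele_count=len(counted), classification=cls,
                         frame_disrupted_fraction=frame_frac, warnings=warns)
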