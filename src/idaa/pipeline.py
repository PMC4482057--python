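"""End-to-end analysis: trace file in, indel profile out.

``analyze_sample`` chains the stages: read the ABIF container, condition
each channel (smooth, subtract an opening baseline), detect peaks, match
the ladder channel against the size standard, fit the scan→bp calibration,
size the sample-channel peaks, and call indel alleles against the wild-type
reference size.  ``analyze_batch`` maps the same pipeline over a manifest
of samples and summarises clone genotypes and the batch-wide indel-size
distribution.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import calling, peaks as pk
from .abif import Trace, read_abif
from .calling import IndelProfile, ReferenceSource, genotype_clone, reference_size
from .errors import ConfigError, IdaaError, LadderFailureError, UndefinedResultError
from .ladder import Calibration, SizedPeak, fit_calibration, load_standard, match_ladder, size_peaks

log = logging.getLogger("idaa")


@dataclass
class RunConfig:
    """All pipeline thresholds and channel/reference selection in one place."""

    # channel selection: dye-name fragment, or explicit index override
    sample_dye: str = "FAM"
    ladder_dye: str = "LIZ"
    sample_channel: int | None = None
    ladder_channel: int | None = None
    # size standard and sizing method
    standard: str = "LIZ500"
    method: str = "local_southern"
    max_ladder_rss: float | None = None
    drop_below_bp: float | None = None  # optionally drop small ladder fragments from the fit
    # signal conditioning / peak detection
    baseline_window: int = pk.DEFAULT_BASELINE_WINDOW
    smooth_window: int = pk.DEFAULT_SMOOTH_WINDOW
    smooth_order: int = pk.DEFAULT_SMOOTH_ORDER
    min_height: float = pk.DEFAULT_MIN_HEIGHT
    min_separation: int = pk.DEFAULT_MIN_SEPARATION
    saturation_threshold: float = pk.SATURATION_THRESHOLD
    # allele calling
    window_bp: float = calling.DEFAULT_WINDOW_BP
    cluster_tol_bp: float = calling.DEFAULT_CLUSTER_TOL_BP
    min_fraction: float = calling.DEFAULT_MIN_FRACTION
    min_allele_fraction: float = calling.DEFAULT_MIN_ALLELE_FRACTION
    max_alleles: int = calling.DEFAULT_MAX_ALLELES
    # wild-type reference: exactly one of these for analyze
    control_path: str | None = None
    expected_size: float | None = None

    def validate(self) -> None:
        for name, lo in (("min_height", 0), ("min_fraction", 0), ("window_bp", 0)):
            if getattr(self, name) <= lo:
                raise ConfigError(f"{name} must be > {lo}")
        if self.control_path is not None and self.expected_size is not None:
            raise ConfigError("give either a control trace or an expected size, not both")


def detect_channel_peaks(trace: Trace, channel_index: int, config: RunConfig) -> list[pk.Peak]:
    """Condition one channel and detect its peaks (saturation from the raw signal)."""
    raw = trace.channels[channel_index].intensities
    corrected, _unsmoothed = pk.correct_channel(
        raw, config.baseline_window, config.smooth_window, config.smooth_order)
    return pk.detect_peaks(corrected, min_height=config.min_height,
                           min_separation=config.min_separation, raw=raw,
                           saturation_threshold=config.saturation_threshold)


def _channel_index(trace: Trace, explicit: int | None, dye: str) -> int:
    if explicit is not None:
        if not (0 <= explicit < len(trace.channels)):
            raise ConfigError(f"channel index {explicit} out of range")
        return explicit
    return trace.channel_by_dye(dye)


def calibrate_trace(trace: Trace, config: RunConfig) -> Calibration:
    """Detect ladder peaks, match them to the standard, and fit the calibration."""
    std = load_standard(config.standard)
    if config.drop_below_bp is not None:
        kept = tuple(s for s in std.fragment_sizes if s >= config.drop_below_bp)
        std = replace(std, fragment_sizes=kept)
    idx = _channel_index(trace, config.ladder_channel, config.ladder_dye)
    ladder_peaks = detect_channel_peaks(trace, idx, config)
    matched = match_ladder(ladder_peaks, std, max_rss=config.max_ladder_rss)
    return fit_calibration(matched, method=config.method)


def sized_sample_peaks(trace: Trace, config: RunConfig,
                       calibration: Calibration) -> list[SizedPeak]:
    idx = _channel_index(trace, config.sample_channel, config.sample_dye)
    return size_peaks(calibration, detect_channel_peaks(trace, idx, config))


def _resolve_reference(config: RunConfig) -> tuple[float, ReferenceSource] | None:
    if config.expected_size is not None:
        return reference_size(config.expected_size, ReferenceSource.EXPECTED_DESIGN)
    if config.control_path is not None:
        control = read_abif(config.control_path)
        cal = calibrate_trace(control, config)
        sized = sized_sample_peaks(control, config, cal)
        return reference_size(sized, ReferenceSource.CONTROL_TRACE)
    return None


def analyze_trace(trace: Trace, config: RunConfig, wt_size_bp: float,
                  wt_source: ReferenceSource) -> IndelProfile:
    """Run calibration, sizing and allele calling on an in-memory trace."""
    profile = IndelProfile(sample_name=trace.sample_name, wt_size_bp=wt_size_bp,
                           wt_size_source=wt_source)
    try:
        cal = calibrate_trace(trace, config)
    except LadderFailureError as exc:
        log.warning("%s: ladder failure: %s", trace.sample_name, exc)
        profile.qc_flags.add("ladder_fail")
        return profile
    profile.calibration = cal
    sized = sized_sample_peaks(trace, config, cal)
    profile.peaks = sized
    alleles = calling.call_alleles(sized, wt_size_bp, window_bp=config.window_bp,
                                   min_fraction=config.min_fraction,
                                   cluster_tol_bp=config.cluster_tol_bp)
    profile.alleles = alleles
    if not alleles:
        profile.qc_flags.add("no_peaks")
    else:
        profile.cutting_efficiency = calling.cutting_efficiency(alleles)
    in_window = [p for p in sized if abs(p.size_bp - wt_size_bp) <= config.window_bp]
    if any(p.peak.saturated for p in in_window):
        profile.qc_flags.add("saturated_peak")
    if any(p.extrapolated for p in in_window):
        profile.qc_flags.add("extrapolated")
    return profile


def analyze_sample(config: RunConfig, sample_path,
                   wt_override: tuple[float, ReferenceSource] | None = None) -> IndelProfile:
    """Analyze one ABIF file; the wild-type reference comes from the config
    (control trace or expected size) unless *wt_override* is given."""
    config.validate()
    ref = wt_override or _resolve_reference(config)
    if ref is None:
        raise ConfigError("no wild-type reference: set a control trace or an expected size")
    trace = read_abif(sample_path)
    if not trace.sample_name:
        trace.sample_name = Path(str(sample_path)).stem
    return analyze_trace(trace, config, ref[0], ref[1])


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and list(df.columns) == []:
        raise ConfigError("manifest is empty")
    missing = {"sample", "path"} - set(df.columns)
    if missing:
        raise ConfigError(f"manifest lacks required columns: {sorted(missing)}")
    return df


def analyze_batch(config: RunConfig, manifest_path) -> tuple[list[IndelProfile], pd.DataFrame,
                                                             dict[str, str]]:
    """Analyze every sample in a manifest TSV (columns: sample, path, and
    optional per-row control / expected_size overrides).

    Returns the profiles, a per-clone summary table (genotype classification
    and indel histogram counts), and a map of per-row errors; rows that fail
    do not stop the batch.
    """
    config.validate()
    df = read_manifest(manifest_path)
    base_ref = _resolve_reference(config)
    profiles: list[IndelProfile] = []
    errors: dict[str, str] = {}
    rows = []
    for rec in df.itertuples(index=False):
        name = str(rec.sample)
        try:
            ref = base_ref
            if getattr(rec, "expected_size", None) and not pd.isna(rec.expected_size):
                ref = reference_size(float(rec.expected_size), ReferenceSource.EXPECTED_DESIGN)
            elif getattr(rec, "control", None) and not pd.isna(rec.control):
                sub = replace(config, control_path=str(rec.control), expected_size=None)
                ref = _resolve_reference(sub)
            prof = analyze_sample(config, rec.path, wt_override=ref)
            prof.sample_name = name
        except (IdaaError, OSError) as exc:
            errors[name] = str(exc)
            log.error("%s: %s", name, exc)
            continue
        profiles.append(prof)
        try:
            geno = genotype_clone(prof, max_alleles=config.max_alleles,
                                  min_allele_fraction=config.min_allele_fraction)
            cls, n_alleles = geno.classification.value, geno.allele_count
        except UndefinedResultError:
            cls, n_alleles = "unclassified", 0
        rows.append({
            "sample": name,
            "wt_size_bp": round(prof.wt_size_bp, 2),
            "n_alleles": n_alleles,
            "classification": cls,
            "cutting_efficiency": (None if prof.cutting_efficiency is None
                                   else round(prof.cutting_efficiency, 4)),
            "indels": ",".join(str(a.indel_bp) for a in prof.alleles),
            "qc_flags": ";".join(sorted(prof.qc_flags)),
        })
    summary = pd.DataFrame(rows, columns=["sample", "wt_size_bp", "n_alleles", "classification",
                                          "cutting_efficiency", "indels", "qc_flags"])
    return profiles, summary, errors


def indel_histogram(profiles: list[IndelProfile],
                    min_allele_fraction: float = calling.DEFAULT_MIN_ALLELE_FRACTION) -> Counter:
    """Batch-wide histogram of called indel sizes (alleles above the clone threshold)."""
    counts: Counter = Counter()
    for prof in profiles:
        for a in prof.alleles:
            if a.fraction >= min_allele_fraction:
                counts[a.indel_bp] += 1
    return counts
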