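"""Synthetic electropherogram generation for pipeline validation.

A simulated run is a two-channel trace: a ladder channel with one Gaussian
per size-standard fragment, and a sample channel with one Gaussian per
allele of the amplicon pool.  Fragments migrate under the reciprocal
(Southern) law ``scan(L) = m0 - c / L`` by default — the same local model
the sizing method assumes, which makes noiseless recovery exact — with a
monotone polynomial alternative for robustness checks.

Allele peak height is ``amplitude * fraction`` (equal widths, so area is
proportional to fraction, which is the quantity the pipeline reads back);
the detector is modelled as a 16-bit ADC, so signal is quantised to
integers and clipped at the signed 16-bit ceiling, saturating very tall
peaks the way a real detector does.  Optional PCR stutter adds a -1 bp
satellite carrying ``stutter_rate`` times the parent area.  All noise is
drawn from a seeded generator: the same spec and seed give byte-identical
traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .abif import INT16_MAX, INT16_MIN, Channel, Trace
from .errors import SimulationSpecError
from .ladder import SizeStandard, load_standard

DEFAULT_SCAN_COUNT = 12000
DEFAULT_M0 = 12000.0
DEFAULT_C = 4.0e5
DEFAULT_PEAK_SIGMA = 4.0
DEFAULT_AMPLITUDE = 50000.0
DEFAULT_LADDER_AMPLITUDE = 1000.0
DEFAULT_NOISE_SD = 10.0


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated fragment-analysis run.

    ``migration`` is ``(m0, c)`` for the Southern law, or polynomial
    coefficients (highest power first, length != 2) evaluated at L when
    ``migration_model == "polynomial"``.
    """

    wt_size_bp: int
    alleles: dict[int, float]
    standard: SizeStandard = None  # type: ignore[assignment]
    migration: tuple[float, ...] = (DEFAULT_M0, DEFAULT_C)
    migration_model: str = "southern"
    peak_sigma_scan: float = DEFAULT_PEAK_SIGMA
    amplitude: float = DEFAULT_AMPLITUDE
    ladder_amplitude: float = DEFAULT_LADDER_AMPLITUDE
    noise_sd: float = DEFAULT_NOISE_SD
    baseline_drift: float = 0.0
    stutter_rate: float = 0.0
    seed: int = 0
    scan_count: int = DEFAULT_SCAN_COUNT
    sample_name: str = "sim"
    sample_dye: str = "6-FAM"
    ladder_dye: str = "LIZ"

    def __post_init__(self) -> None:
        if self.standard is None:
            object.__setattr__(self, "standard", load_standard("LIZ500"))
        if abs(sum(self.alleles.values()) - 1.0) > 1e-9:
            raise SimulationSpecError("allele fractions must sum to 1")
        if any(f <= 0 for f in self.alleles.values()):
            raise SimulationSpecError("allele fractions must be positive")
        if not (0.0 <= self.stutter_rate < 1.0):
            raise SimulationSpecError("stutter_rate must be in [0, 1)")
        if self.migration_model not in ("southern", "polynomial"):
            raise SimulationSpecError(f"unknown migration model {self.migration_model!r}")

    def scan_of_size(self, size_bp) -> np.ndarray:
        """Scan coordinate at which a fragment of the given size appears."""
        L = np.asarray(size_bp, dtype=float)
        if self.migration_model == "southern":
            m0, c = self.migration
            return m0 - c / L
        return np.polyval(self.migration, L)

    def sizes_simulated(self) -> list[float]:
        out = [float(s) for s in self.standard.fragment_sizes]
        for indel in self.alleles:
            out.append(float(self.wt_size_bp + indel))
            if self.stutter_rate > 0:
                out.append(float(self.wt_size_bp + indel - 1))
        return out

    def validate_geometry(self) -> None:
        # channels are independent: a sample allele may share a size with a
        # ladder fragment, so monotonicity is checked over unique sizes
        sizes = np.unique(np.array(self.sizes_simulated()))
        scans = self.scan_of_size(sizes)
        if np.any(np.diff(scans) <= 0):
            raise SimulationSpecError("migration model is not strictly increasing "
                                      "over the simulated sizes")
        margin = 4.0 * self.peak_sigma_scan
        if scans.min() < margin or scans.max() > self.scan_count - 1 - margin:
            raise SimulationSpecError(
                f"simulated scans span [{scans.min():.0f}, {scans.max():.0f}], outside "
                f"the trace of {self.scan_count} scans (margin {margin:.0f})")


def _render(scan_count: int, centers, heights, sigma: float) -> np.ndarray:
    x = np.arange(scan_count, dtype=float)
    y = np.zeros(scan_count)
    for mu, h in zip(centers, heights):
        lo = max(0, int(mu - 6 * sigma))
        hi = min(scan_count, int(mu + 6 * sigma) + 1)
        y[lo:hi] += h * np.exp(-((x[lo:hi] - mu) ** 2) / (2.0 * sigma**2))
    return y


def simulate_trace(spec: SimulationSpec, scan_count: int | None = None) -> Trace:
    """Render a :class:`SimulationSpec` into a two-channel :class:`~idaa.abif.Trace`."""
    if scan_count is not None:
        spec = replace(spec, scan_count=scan_count)
    spec.validate_geometry()
    rng = np.random.default_rng(spec.seed)
    n = spec.scan_count

    lad_centers = spec.scan_of_size(np.array(spec.standard.fragment_sizes))
    ladder = _render(n, lad_centers, [spec.ladder_amplitude] * len(lad_centers),
                     spec.peak_sigma_scan)

    centers, heights = [], []
    for indel, frac in sorted(spec.alleles.items()):
        size = spec.wt_size_bp + indel
        h = spec.amplitude * frac
        centers.append(float(spec.scan_of_size(size)))
        heights.append(h)
        if spec.stutter_rate > 0:
            centers.append(float(spec.scan_of_size(size - 1)))
            heights.append(h * spec.stutter_rate)
    sample = _render(n, centers, heights, spec.peak_sigma_scan)

    drift = spec.baseline_drift * np.arange(n, dtype=float)
    channels = []
    for dye, clean in ((spec.sample_dye, sample), (spec.ladder_dye, ladder)):
        y = clean + drift
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=n)
        y = np.clip(np.round(y), INT16_MIN, INT16_MAX).astype(np.int32)
        channels.append(Channel(dye, y))
    return Trace(sample_name=spec.sample_name, channels=channels)


def simulate_clone_panel(base: SimulationSpec, genotypes: list[dict[int, float]],
                         seed: int | None = None) -> list[tuple[str, Trace]]:
    """One trace per clone genotype, with stable names and per-clone seeds."""
    seed0 = base.seed if seed is None else seed
    width = max(3, len(str(len(genotypes))))
    out = []
    for i, alleles in enumerate(genotypes):
        name = f"clone{i + 1:0{width}d}"
        spec = replace(base, alleles=dict(alleles), seed=seed0 + i, sample_name=name)
        out.append((name, simulate_trace(spec)))
    return out


def load_spec(path) -> SimulationSpec:
    """Load a YAML simulation spec; keys mirror :class:`SimulationSpec` fields.

    ``standard`` may be a built-in name, a TSV path, or an explicit list of
    fragment sizes; ``alleles`` maps signed indel size to fraction.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "alleles" not in raw or "wt_size_bp" not in raw:
        raise SimulationSpecError("spec file must define wt_size_bp and alleles")
    raw["alleles"] = {int(k): float(v) for k, v in dict(raw["alleles"]).items()}
    std = raw.get("standard")
    if isinstance(std, str):
        raw["standard"] = load_standard(std)
    elif isinstance(std, (list, tuple)):
        raw["standard"] = SizeStandard("custom", tuple(float(s) for s in std))
    if "migration" in raw:
        raw["migration"] = tuple(float(v) for v in raw["migration"])
    known = set(SimulationSpec.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SimulationSpecError(f"unknown spec keys: {sorted(unknown)}")
    return SimulationSpec(**raw)
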