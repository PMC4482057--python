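"""Seeded simulation benchmarks of pipeline performance.

These routines measure what the toolkit claims: the smallest indel it can
resolve from wild type, its sensitivity to low-fraction alleles, and exact
integer calling across a wide indel size range.  They are driven entirely by
the simulator, so every number they report is recomputed from synthetic
traces at run time; both the test suite and ``scripts/acceptance.py`` call
them.

Amplicon sizes are chosen per benchmark to match the experimental regime
being emulated (see docs/methods.md): 180 bp for pool quantification and
resolution, 120 bp for the low-frequency sensitivity regime where the
wild-type and ±1 bp peaks are baseline-resolved.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .calling import ReferenceSource
from .pipeline import RunConfig, analyze_trace
from .sim import SimulationSpec, simulate_trace

RESOLUTION_WT_BP = 180
SENSITIVITY_WT_BP = 120


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _analyze(spec: SimulationSpec, config: RunConfig):
    return analyze_trace(simulate_trace(spec), config, float(spec.wt_size_bp),
                         ReferenceSource.EXPECTED_DESIGN)


def mutant_called_correctly(spec: SimulationSpec, config: RunConfig, indel: int) -> bool:
    """True when the dominant non-wild-type call equals the true indel and the
    wild-type allele is also recovered."""
    prof = _analyze(spec, config)
    non_wt = [a for a in prof.alleles if a.indel_bp != 0]
    if not non_wt or prof.allele(0) is None:
        return False
    return max(non_wt, key=lambda a: a.fraction).indel_bp == indel


def resolution_benchmark(seed: int = 0, n_replicates: int = 50,
                         magnitudes=(1, 2, 3, 4, 5), mutant_fraction: float = 0.30,
                         wt_size_bp: int = RESOLUTION_WT_BP, min_success: float = 0.95,
                         config: RunConfig | None = None) -> dict:
    """Smallest indel magnitude resolved from wild type at default noise.

    For each magnitude and each sign, *n_replicates* seeded traces carrying
    wild type plus one mutant allele at *mutant_fraction* are simulated and
    run through the full pipeline; a magnitude counts as resolved when both
    signs are called correctly in at least *min_success* of replicates.
    Returns the per-condition success rates and the smallest resolved
    magnitude (None if no magnitude qualifies).
    """
    config = config or RunConfig(expected_size=wt_size_bp)
    rng = np.random.default_rng(seed)
    rates: dict[int, dict[int, float]] = {}
    for mag in magnitudes:
        rates[mag] = {}
        for sign in (+1, -1):
            indel = sign * mag
            ok = 0
            for _ in range(n_replicates):
                spec = SimulationSpec(
                    wt_size_bp=wt_size_bp,
                    alleles={0: 1.0 - mutant_fraction, indel: mutant_fraction},
                    seed=_derive_seed(rng))
                ok += mutant_called_correctly(spec, config, indel)
            rates[mag][sign] = ok / n_replicates
    resolved = [m for m in magnitudes if min(rates[m].values()) >= min_success]
    return {
        "smallest_resolved_bp": min(resolved) if resolved else None,
        "rates": rates,
        "n_replicates": n_replicates,
        "n_runs": len(magnitudes) * 2 * n_replicates,
    }


def sensitivity_benchmark(seed: int = 0, n_replicates: int = 50, indel: int = 1,
                          mutant_fraction: float = 0.01,
                          wt_size_bp: int = SENSITIVITY_WT_BP,
                          config: RunConfig | None = None) -> dict:
    """Detection rate of a low-fraction mutant allele (default: 1% +1 bp)."""
    config = config or RunConfig(expected_size=wt_size_bp)
    rng = np.random.default_rng(seed)
    detected = 0
    for _ in range(n_replicates):
        spec = SimulationSpec(
            wt_size_bp=wt_size_bp,
            alleles={0: 1.0 - mutant_fraction, indel: mutant_fraction},
            seed=_derive_seed(rng))
        prof = _analyze(spec, config)
        a = prof.allele(indel)
        detected += a is not None and a.fraction >= config.min_fraction
    return {"detection_rate": detected / n_replicates, "n_replicates": n_replicates}


def size_range_benchmark(seed: int = 0, indel_min: int = -80, indel_max: int = 35,
                         wt_size_bp: int = RESOLUTION_WT_BP,
                         config: RunConfig | None = None) -> dict:
    """Exact integer calling of single-allele clones across an indel size span."""
    config = config or RunConfig(expected_size=wt_size_bp)
    rng = np.random.default_rng(seed)
    wrong = []
    indels = [i for i in range(indel_min, indel_max + 1) if i != 0]
    for indel in indels:
        spec = SimulationSpec(wt_size_bp=wt_size_bp, alleles={indel: 1.0},
                              seed=_derive_seed(rng))
        prof = _analyze(spec, config)
        calls = [a.indel_bp for a in prof.alleles]
        if calls != [indel]:
            wrong.append((indel, calls))
    return {"n_clones": len(indels), "n_exact": len(indels) - len(wrong), "wrong": wrong}
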