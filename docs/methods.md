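# Methods

## Signal model and processing chain

A fragment-analysis run records one fluorescence intensity per scan per dye
channel.  `idaa` conditions each channel in three steps: Savitzky–Golay
smoothing (window 9, order 3 — exact on locally cubic peak shapes, noise
s.d. roughly halved), a morphological-opening baseline (rolling minimum
then rolling maximum, window 151 scans — wide enough that amplicon peaks,
a few scans across, are erased while drift survives), subtraction and
clipping at zero.  Peaks are local maxima of the conditioned signal with
height ≥ `min_height` (default 50 FU) separated by ≥ `min_separation`
scans (default 10); boundaries sit at the nearest flanking valley or where
the signal falls below max(1% of apex, `min_height`/2), whichever is
closer; areas are trapezoidal integrals over the boundary interval.
Because two peaks sharing a valley split their overlap there, adjacent
(±1 bp) alleles exchange a small amount of tail area — see Limitations.

The integer apex index is supplemented by a sub-scan apex from three-point
log-parabolic interpolation, exact for Gaussian peak shapes and measured at
≤ 2×10⁻⁴ scans error on synthetic peaks.  Sizing uses this refined apex;
without it, integer quantization alone (≈0.04 bp at a typical 12 scans/bp)
would dominate the size error budget.  Clipped (saturated) peaks have a
flat top; their apex is the plateau midpoint and they carry a `saturated`
flag (raw signal ≥ 32000 FU).

## Ladder matching and Local Southern sizing

Ladder-channel peaks are assigned to the standard's fragment table
(built-in LIZ500/LIZ600 tables from manufacturer documentation, or a user
TSV) by the order-preserving injective assignment minimising the residual
sum of squares of a straight-line fit of scan on size.  The optimum is
found by exact vectorised enumeration whenever the number of admissible
subsets is ≤ 250 000 (all realistic ladders with a handful of spurious
peaks); beyond that, an iterated scheme alternates a line fit with an
order-preserving dynamic-programming reassignment.  The RSS ceiling that
declares a ladder failure is off by default: under the reciprocal
migration law the correct assignment's linear RSS is dominated by
curvature, so no scale-free default exists; it is exposed as
`max_ladder_rss`.  A failed ladder flags the sample `ladder_fail` and
leaves it unsized.

Sizing is Local Southern: fragment mobility locally follows
L = c/(m − m₀) + L₀.  For a query scan the two flanking matched points on
each side define two overlapping triples; a hyperbola of that family is
fitted exactly through each (the relation is linear in (L₀, m₀, c − L₀m₀))
and the two predictions are averaged, falling back to the single available
triple within one triple of either end of the ladder.  Three collinear
points make the system singular; the fit self-verifies against its knots
and falls back to an exact quadratic.  A monotone cubic (PCHIP) spline is
available as an alternative (`--method spline`).  Per-point leave-one-out
residuals populate the ladder QC block of the JSON report.  Sizes for
peaks outside the anchored scan range are flagged `extrapolated`.

Precision scales with the local steepness of the migration curve: with
1-scan jitter on the anchors, leave-one-out errors are sub-bp below
~250 bp (≥ ~6 scans/bp under the default law) and grow to a few bp at the
flat top of the range.  Indel calls are differences of sizes under one
calibration, so using a same-run wild-type control as the reference
(preferred over the designed size) cancels systematic mobility offsets.

## Allele calling and genotyping

Peaks within `window_bp` (default 150) of the wild-type size are kept;
each maps to the integer offset round(size − wt), ties away from zero, and
peaks sharing an integer merge (areas summed, sizes area-weighted;
`cluster_tol_bp` 0.5 is the rounding half-width — smaller values do not
split off-grid peaks into separate calls).  Fractions are areas over total
retained area; alleles under `min_fraction` (0.005) are dropped and the
rest renormalised, with pre-renormalisation shares kept as `fraction_raw`.
Cutting efficiency is the non-wild-type fraction sum.  Clone genotyping
counts alleles ≥ `min_allele_fraction` (0.15): wild type (only the 0
allele), all-alleles-disrupted (no 0 allele and every counted allele
frameshift — including a single frameshift allele), mono-allelic (a single
in-frame non-zero allele), otherwise mixed; more than `max_alleles` (4)
counted alleles raises an impurity warning, not an error.

## The simulator

The simulator emulates the data the pipeline consumes: a ladder channel
with one Gaussian per standard fragment (height `ladder_amplitude`,
default 1000 FU) and a sample channel with one Gaussian per allele, under
the same reciprocal migration law the sizing model assumes (defaults
m₀ = 12000, c = 4×10⁵, making noiseless recovery exact and leaving all
fragments below the scan asymptote; `scan_count` 12000 accommodates the
whole LIZ500 range with margin).  A monotone polynomial law exercises
robustness against model mismatch.  Allele peak height is
`amplitude × fraction` (default amplitude 50000 FU); widths are equal
(σ = 4 scans), so area is proportional to fraction, which is the quantity
the pipeline reads back.  The detector is a 16-bit ADC: signal is
quantised to integers and clipped at 32767, so near-pure alleles saturate
realistically (flat-topped peak, `saturated` flag) at the cost of some
truncated area.  White Gaussian noise (s.d. 10 FU), linear baseline drift
and an optional −1 bp stutter satellite (rate 0 by default; realistic
rates for non-repeat amplicons are not established) complete the model.
All randomness flows from one seed; identical specs give byte-identical
ABIF files.

What it does **not** emulate: dye-mobility shifts between channels,
spectral pull-up, electrokinetic injection bias, heteroscedastic shot
noise, peak tailing, or primer artefacts.  Passing the simulation suites
therefore demonstrates the correctness of the computational chain under a
faithful geometric model of CE migration, not robustness to every
instrument artefact.

### Benchmark amplicon sizes

`wt_size_bp` is a per-experiment quantity.  Under the default law the
scan-space spacing of 1 bp is c/L² ≈ 12 scans at 180 bp and ≈ 28 scans at
120 bp, against a peak σ of 4 scans.  The benchmarks use:

* **180 bp** for pool quantification and the resolution benchmark — ±1 bp
  peaks separated by ~3σ, the regime of a mid-range amplicon on a real
  instrument;
* **120 bp** for the 1%-sensitivity benchmark — the wild-type peak's tail
  is negligible at ±1 bp, so a 1% satellite stands clear of it, matching
  the visibly separated low-frequency ±1 bp peaks of a low-efficiency
  nuclease assay;
* **240 bp** for the stutter characterization — there a −1 bp satellite
  (6.9 scans away) rides the parent shoulder and is *not* separately
  called at 5% stutter.  On smaller amplicons the same satellite resolves
  and would be reported as a −1 bp allele: stutter tolerance is a function
  of amplicon size, and the characterization test pins the stated point of
  that trade-off.

## Numerical and policy choices

* Rounding ties away from zero keeps insertions and deletions symmetric.
* Negative conditioned signal is clipped to zero before integration so
  areas (hence fractions) are non-negative.
* The morphological baseline sits at the lower noise envelope, lifting the
  conditioned signal by roughly one noise s.d.; thresholds are interpreted
  on that conditioned scale.
* Channel selection is by dye-name substring ("FAM", "LIZ") with explicit
  index overrides, since instruments differ in which DATA tag carries
  which dye.
* ABIF writing always emits version 101, big-endian, directory after
  payload, channels as 16-bit shorts — the subset fragment-analysis
  readers expect; unknown tags round-trip as opaque metadata.
* Off-target candidates use full-protospacer Hamming distance plus exact
  IUPAC PAM adjacency.  Seed-window-weighted tools will rank sites
  differently; this scan is deliberately the transparent, enumerable
  definition, validated against brute force.

## Known limitations

* Valley-split integration biases fractions of directly adjacent alleles
  toward each other by ~1–2 percentage points at 3σ spacing (the worked
  example's +1 allele reads 0.306 for a simulated 0.32); well-separated
  alleles recover to 10⁻³.  Gaussian mixture deconvolution would remove
  this but is out of scope.
* Detector saturation truncates area: near-pure alleles against a tiny
  ladder are quantified slightly below their true share.
* Indel identity (which bases were inserted/deleted) is outside what
  fragment sizing can provide; that requires sequencing.
* Alleles with equal amplicon size but different sequence are one peak.
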