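# idaa — Indel Detection by Amplicon Analysis

`idaa` is the computational readout for a fast, sequencing-free assay of
nuclease-induced genome editing (CRISPR/Cas9, ZFNs, TALENs).  The edited
locus is PCR-amplified with a tri-primer scheme — a target forward primer
carrying a universal 5' extension, a 6-FAM-labelled universal primer
binding that extension, and a target reverse primer — and the labelled
amplicons are sized by capillary-electrophoresis fragment analysis against
an in-lane size standard.  Error-prone repair of the nuclease cut (NHEJ)
leaves insertions and deletions, so each editing allele appears as a peak
displaced from the wild-type amplicon position by its signed indel size, at
single-basepair resolution.

The package is for groups running editing experiments who want indel
spectra, cutting efficiencies and clone genotypes straight from `.fsa`
trace files (or who want to prototype the analysis without an instrument,
using the built-in simulator).

## What it computes

For a sample channel with detected peaks sized at $L_i$ bp (area $A_i$)
against the wild-type amplicon size $L_{wt}$:

* **Sizing** — ladder peaks are matched to the standard's fragment table by
  the order-preserving assignment minimising the linear-fit RSS of scan on
  size, then sizes come from the **Local Southern** method: fragment length
  and migration follow $L = c/(m - m_0) + L_0$ locally, fitted through
  overlapping triples of flanking ladder points and averaged.
* **Indel calls** — $\Delta_i = \operatorname{round}(L_i - L_{wt})$ (ties
  away from zero); peaks rounding to the same integer merge, areas summed.
* **Allele fractions** — $f_i = A_i / \sum_j A_j$ over retained peaks;
  alleles below `min_fraction` are dropped and fractions renormalised.
* **Cutting efficiency** — $E = \sum_{\Delta_i \neq 0} f_i = 1 - f_0$,
  peak area relative to total peak area.
* **Frameshift** — an allele disrupts the reading frame iff
  $\Delta \not\equiv 0 \pmod 3$; clones are classified as wild type,
  mono-allelic, mixed, or all-alleles-disrupted.
* **Assay design** — expected labelled wild-type size
  $(\text{amplicon end} - \text{start}) + |\text{extension}|$, and
  protospacer off-target candidates by full-length Hamming distance with an
  IUPAC PAM match on both strands.

## Worked example

Simulate a wild-type control and an edited pool (wild type at 54%, a −13 bp
deletion at 14%, a +1 bp insertion at 32%, on a 180 bp amplicon with a
LIZ500-style ladder), then analyse the pool against the control:

```
$ cat pool.yaml
wt_size_bp: 180
alleles: {-13: 0.14, 0: 0.54, 1: 0.32}
seed: 7
$ cat wt.yaml
wt_size_bp: 180
alleles: {0: 1.0}
seed: 3
$ idaa simulate --spec pool.yaml --out mix.fsa
$ idaa simulate --spec wt.yaml   --out wt.fsa
$ idaa analyze mix.fsa --control wt.fsa --out rep
sim	180.09	control_trace	-13	167.0	0.1402	True	1	0.4459
sim	180.09	control_trace	0	180.01	0.5541	False	1	0.4459
sim	180.09	control_trace	1	180.99	0.3057	True	1	0.4459
```

One row per called allele: the wild-type reference (180.09 bp, sized from
the control trace), the signed indel, the observed mean size, the area
fraction, the frameshift flag, and the cutting efficiency 0.4459 — the
non-wild-type area share, recovering the simulated 46% within the expected
peak-overlap tolerance.  `rep.tsv` holds the same table; `rep.json` adds
per-peak detail and ladder QC (leave-one-out residuals per fragment).

Other entry points: `idaa batch` (manifest of clones → per-clone genotypes
and an indel-size histogram), `idaa design` (tri-primer amplicon size
prediction from a FASTA reference), `idaa offtarget` (BED6 of candidate
sites), all with `--help`.

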