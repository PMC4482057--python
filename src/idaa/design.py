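"""Tri-primer assay design and off-target candidate enumeration.

The labelling strategy amplifies a target with three primers: a forward
target primer carrying a universal 5' extension, a 6-FAM-labelled universal
primer matching that extension, and a reverse target primer.  The labelled
wild-type product is therefore the genomic amplicon plus the extension, so
its expected size is ``(amplicon_end - amplicon_start) + len(extension)``.

Off-target candidates for a nuclease protospacer are enumerated by exact
Hamming distance over the full protospacer with an IUPAC PAM pattern
immediately 3' of the site, on both strands; no position weighting and no
bulges are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from .errors import DesignError, SequenceValidationError

#: The universal 6-FAM-labelled forward primer target sequence (21 nt, 52% GC)
#: prepended to the target-specific forward primer.
UNIVERSAL_EXTENSION = "AGCTGACCGGCAGCAAAATTG"

_ACGT = set("ACGT")


def _validate_seq(seq: str, what: str) -> str:
    s = str(seq).upper()
    if not s:
        raise SequenceValidationError(f"{what} is empty")
    bad = set(s) - _ACGT
    if bad:
        raise SequenceValidationError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return s


def primer_stats(seq: str) -> tuple[int, float]:
    """Length and G+C percentage of a primer (fractional percent; round for display)."""
    s = _validate_seq(seq, "primer")
    gc = 100.0 * (s.count("G") + s.count("C")) / len(s)
    return len(s), gc


def locate_amplicon(reference: str, fwd: str, rev: str) -> tuple[int, int]:
    """Locate the amplicon of a primer pair on a reference (0-based half-open).

    The forward primer must occur exactly once on the forward strand and the
    reverse complement of the reverse primer exactly once downstream of it.
    """
    ref = str(reference).upper()
    f = _validate_seq(fwd, "forward primer")
    r = _validate_seq(rev, "reverse primer")
    rrc = reverse_complement(r)

    def _find_unique(pattern: str, label: str) -> int:
        hits = []
        pos = ref.find(pattern)
        while pos != -1:
            hits.append(pos)
            pos = ref.find(pattern, pos + 1)
        if len(hits) != 1:
            raise DesignError(f"{label} matches the reference {len(hits)} times (need exactly 1)")
        return hits[0]

    start = _find_unique(f, "forward primer")
    r_start = _find_unique(rrc, "reverse primer (reverse complement)")
    end = r_start + len(rrc)
    if r_start < start + len(f):
        raise DesignError("reverse primer site lies upstream of (or overlaps) the forward primer")
    return start, end


@dataclass(frozen=True)
class AssayDesign:
    """A validated tri-primer assay on a reference locus."""

    reference_id: str
    fwd_primer: str
    rev_primer: str
    amplicon_start: int
    amplicon_end: int
    extension: str = UNIVERSAL_EXTENSION

    @property
    def expected_size_bp(self) -> int:
        return (self.amplicon_end - self.amplicon_start) + len(self.extension)


def design_assay(reference_id: str, reference: str, fwd: str, rev: str,
                 extension: str | None = None) -> AssayDesign:
    """Validate primers against the reference and build an :class:`AssayDesign`."""
    ext = UNIVERSAL_EXTENSION if extension is None else (
        _validate_seq(extension, "extension") if extension else ""
    )
    start, end = locate_amplicon(reference, fwd, rev)
    return AssayDesign(reference_id=reference_id, fwd_primer=str(fwd).upper(),
                       rev_primer=str(rev).upper(), amplicon_start=start,
                       amplicon_end=end, extension=ext)


def expected_wt_size(design: AssayDesign) -> int:
    """Expected labelled wild-type amplicon size in bp."""
    return design.expected_size_bp


@dataclass(frozen=True)
class OffTargetHit:
    """A PAM-adjacent near-match to the protospacer (forward-strand coordinates)."""

    contig: str
    start: int
    end: int
    strand: str
    mismatches: int
    site_sequence: str
    pam_sequence: str
    on_target: bool = False


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    """Encode bases as small ints; anything ambiguous becomes 4 (mismatches all)."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


def _pam_mask(enc: np.ndarray, seq: str, pam: str) -> np.ndarray:
    """Boolean mask over positions i: seq[i : i+len(pam)] matches the IUPAC pam."""
    n, k = len(enc), len(pam)
    ok = np.ones(max(0, n - k + 1), dtype=bool)
    for j, code in enumerate(pam):
        allowed = ambiguous_dna_values.get(code.upper())
        if allowed is None:
            raise SequenceValidationError(f"PAM contains non-IUPAC code {code!r}")
        col = enc[j : n - k + 1 + j]
        ok &= np.isin(col, [_BASE_CODE[b] for b in allowed])
    return ok


def _scan_strand(enc: np.ndarray, seq: str, proto: np.ndarray, pam: str,
                 max_mm: int) -> list[tuple[int, int]]:
    """All (window_start, mismatches) with PAM immediately 3' of the window."""
    L, P = len(proto), len(pam)
    n = len(enc)
    if n < L + P:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)[: n - L - P + 1]
    mm = (windows != proto[None, :]).sum(axis=1)
    pam_ok = _pam_mask(enc, seq, pam)[L : n - P + 1]
    hits = np.nonzero((mm <= max_mm) & pam_ok)[0]
    return [(int(i), int(mm[i])) for i in hits]


def find_off_targets(genome: dict[str, str], protospacer: str, pam: str = "NGG",
                     max_mm: int = 4,
                     on_target: tuple[str, int, str] | None = None) -> list[OffTargetHit]:
    """Enumerate PAM-adjacent near-matches to a protospacer on both strands.

    *genome* maps contig names to sequences; a hit is any window of
    protospacer length whose Hamming distance to the protospacer is at most
    *max_mm* with the IUPAC *pam* immediately 3'.  Ambiguous genome bases
    count as mismatches.  Reverse-strand hits are reported in forward-strand
    coordinates (0-based half-open, protospacer only).  *on_target* may name
    ``(contig, start, strand)`` of the design locus to label it in the output.
    """
    proto = _validate_seq(protospacer, "protospacer")
    if not (15 <= len(proto) <= 30):
        raise SequenceValidationError("protospacer length must be 15-30 nt")
    penc = _encode(proto)
    L, P = len(proto), len(pam)
    hits: list[OffTargetHit] = []
    for contig, seq in genome.items():
        s = str(seq).upper()
        enc = _encode(s)
        for start, mm in _scan_strand(enc, s, penc, pam, max_mm):
            hits.append(OffTargetHit(
                contig=contig, start=start, end=start + L, strand="+", mismatches=mm,
                site_sequence=s[start : start + L],
                pam_sequence=s[start + L : start + L + P],
                on_target=on_target == (contig, start, "+")))
        rc = reverse_complement(s)
        renc = _encode(rc)
        for rstart, mm in _scan_strand(renc, rc, penc, pam, max_mm):
            # forward-strand projection of the protospacer window
            start = len(s) - (rstart + L)
            hits.append(OffTargetHit(
                contig=contig, start=start, end=start + L, strand="-", mismatches=mm,
                site_sequence=rc[rstart : rstart + L],
                pam_sequence=rc[rstart + L : rstart + L + P],
                on_target=on_target == (contig, start, "-")))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def hits_to_bed(hits: list[OffTargetHit]) -> str:
    """Render hits as BED6 (name = mismatch count, score = 0)."""
    lines = [f"{h.contig}\t{h.start}\t{h.end}\t"
             f"{'on_target' if h.on_target else f'mm{h.mismatches}'}\t0\t{h.strand}"
             for h in hits]
    return "\n".join(lines) + ("\n" if lines else "")
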