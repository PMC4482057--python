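"""Tri-primer assay design and off-target enumeration against brute-force oracles."""

import numpy as np
import pytest
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from idaa.design import (UNIVERSAL_EXTENSION, design_assay, expected_wt_size, find_off_targets,
                         hits_to_bed, locate_amplicon, primer_stats)
from idaa.errors import DesignError, SequenceValidationError


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPrimerStats:
    def test_universal_fam_primer(self):
        length, gc = primer_stats(UNIVERSAL_EXTENSION)
        assert length == 21
        assert round(gc) == 52

    def test_all_gc(self):
        assert primer_stats("GGCC") == (4, 100.0)

    def test_empty_rejected(self):
        with pytest.raises(SequenceValidationError):
            primer_stats("")

    def test_non_acgt_rejected(self):
        with pytest.raises(SequenceValidationError):
            primer_stats("ACGN")


def build_reference(seed=0, fwd_at=100, rev_end=320, fwd_len=20, rev_len=20, n=400):
    ref = list(random_seq(n, seed))
    fwd = random_seq(fwd_len, seed + 1000)
    rev = random_seq(rev_len, seed + 2000)
    ref[fwd_at : fwd_at + fwd_len] = fwd
    ref[rev_end - rev_len : rev_end] = reverse_complement(rev)
    return "".join(ref), fwd, rev


class TestLocateAmplicon:
    def test_constructed_placement(self):
        ref, fwd, rev = build_reference()
        assert locate_amplicon(ref, fwd, rev) == (100, 320)

    def test_duplicate_primer_site_rejected(self):
        ref, fwd, rev = build_reference()
        with pytest.raises(DesignError, match="2 times"):
            locate_amplicon(ref + fwd, fwd, rev)

    def test_missing_primer_rejected(self):
        ref, fwd, rev = build_reference()
        with pytest.raises(DesignError, match="0 times"):
            locate_amplicon(ref, "A" * 25, rev)

    def test_wrong_orientation_rejected(self):
        ref, fwd, rev = build_reference()
        # swap: the rev-complement site now sits upstream of the fwd site
        with pytest.raises(DesignError):
            locate_amplicon(ref, reverse_complement(rev), reverse_complement(fwd))


class TestExpectedSize:
    def test_universal_extension_adds_21(self):
        ref, fwd, rev = build_reference()
        d = design_assay("locus", ref, fwd, rev)
        assert d.extension == UNIVERSAL_EXTENSION
        assert expected_wt_size(d) == (320 - 100) + 21 == 241

    def test_empty_extension(self):
        ref, fwd, rev = build_reference()
        d = design_assay("locus", ref, fwd, rev, extension="")
        assert expected_wt_size(d) == 220

    def test_invariant_under_reference_padding(self):
        ref, fwd, rev = build_reference()
        padded = random_seq(150, 9) + ref + random_seq(150, 10)
        d0 = design_assay("a", ref, fwd, rev)
        d1 = design_assay("a", padded, fwd, rev)
        assert expected_wt_size(d0) == expected_wt_size(d1)
        assert d1.amplicon_start == d0.amplicon_start + 150


# ---------------------------------------------------------------------------
# off-target scan vs an independent position-by-position Hamming oracle


def _pam_ok(site: str, pam: str) -> bool:
    return len(site) == len(pam) and all(
        b in ambiguous_dna_values[p] for b, p in zip(site, pam))


def brute_force_offtargets(genome, proto, pam, max_mm):
    hits = set()
    L, P = len(proto), len(pam)
    for contig, seq in genome.items():
        for strand in "+-":
            s = seq.upper() if strand == "+" else reverse_complement(seq.upper())
            for i in range(len(s) - L - P + 1):
                win, pm = s[i : i + L], s[i + L : i + L + P]
                mm = sum(a != b or a not in "ACGT" for a, b in zip(win, proto))
                if mm <= max_mm and _pam_ok(pm, pam):
                    start = i if strand == "+" else len(s) - (i + L)
                    hits.add((contig, start, strand, mm))
    return hits


def plant(seq, pos, site):
    return seq[:pos] + site + seq[pos + len(site) :]


PROTO = "GACGCATAAAGATGAGACGC"


class TestFindOffTargets:
    def test_exact_embedded_site(self):
        genome = {"c1": random_seq(200, 1)[:90] + PROTO + "AGG" + random_seq(100, 2)}
        hits = find_off_targets(genome, PROTO, max_mm=0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.mismatches) == (90, 110, "+", 0)
        assert h.pam_sequence == "AGG"

    def test_planted_two_mismatch_site_needs_max_mm_2(self):
        site = PROTO[:5] + "T" + PROTO[6:12] + "C" + PROTO[13:]
        assert site != PROTO
        genome = {"c1": plant(random_seq(500, 3), 200, site + "TGG")}
        assert not find_off_targets(genome, PROTO, max_mm=1)
        hits = find_off_targets(genome, PROTO, max_mm=2)
        assert [(h.start, h.mismatches) for h in hits] == [(200, 2)]

    def test_reverse_strand_projection(self):
        fwd_site = PROTO + "CGG"
        genome = {"c1": plant(random_seq(400, 4), 150, reverse_complement(fwd_site))}
        hits = find_off_targets(genome, PROTO, max_mm=0)
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "-"
        # forward-strand projection: the protospacer occupies the last 20 of the
        # 23-bp reverse-complemented insert starting at 150
        assert (h.start, h.end) == (153, 173)
        assert genome["c1"][h.start : h.end] == reverse_complement(PROTO)

    def test_ambiguous_bases_count_as_mismatches(self):
        genome = {"c1": plant(random_seq(300, 5), 100, "N" + PROTO[1:] + "AGG")}
        assert not find_off_targets(genome, PROTO, max_mm=0)
        hits = find_off_targets(genome, PROTO, max_mm=1)
        assert any(h.start == 100 and h.mismatches == 1 for h in hits)

    def test_protospacer_validation(self):
        with pytest.raises(SequenceValidationError):
            find_off_targets({"c": "ACGT" * 50}, "ACGTN" + "ACGT" * 4)
        with pytest.raises(SequenceValidationError):
            find_off_targets({"c": "ACGT" * 50}, "ACGT")  # too short

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_on_random_genomes(self, seed):
        rng = np.random.default_rng(seed + 50)
        genome = {"chrA": random_seq(30_000, seed), "chrB": random_seq(10_000, seed + 7)}
        # plant sites at known mismatch counts on both strands
        for k, (contig, pos) in enumerate([("chrA", 4000), ("chrA", 12_000), ("chrB", 3000)]):
            site = list(PROTO)
            for j in rng.choice(len(site), size=k + 1, replace=False):
                site[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[site[j]]
            insert = "".join(site) + "TGG"
            if k % 2:
                insert = reverse_complement(insert)
            genome[contig] = plant(genome[contig], pos, insert)
        for max_mm in (0, 2, 4):
            got = {(h.contig, h.start, h.strand, h.mismatches)
                   for h in find_off_targets(genome, PROTO, max_mm=max_mm)}
            assert got == brute_force_offtargets(genome, PROTO, "NGG", max_mm)

    def test_hit_count_monotone_in_max_mm(self):
        genome = {"c": random_seq(40_000, 17)}
        counts = [len(find_off_targets(genome, PROTO, max_mm=m)) for m in range(6)]
        assert counts == sorted(counts)

    def test_on_target_labelled_in_bed(self):
        genome = {"c1": plant(random_seq(300, 6), 100, PROTO + "AGG")}
        hits = find_off_targets(genome, PROTO, max_mm=0, on_target=("c1", 100, "+"))
        assert hits[0].on_target
        bed = hits_to_bed(hits)
        assert bed.splitlines()[0] == "c1\t100\t120\ton_target\t0\t+"
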