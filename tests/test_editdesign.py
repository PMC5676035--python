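"""Allele-discriminating guides, off-target scanning, donor design."""

import numpy as np
import pytest

from bsaqtl.editdesign import (GuideCandidate, design_block_replacement,
                               design_point_oligo, enumerate_guides,
                               offtarget_scan, revcomp)
from bsaqtl.fixtures import load_fixture


def _random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(seq, idx, base):
    return seq[:idx] + base + seq[idx + 1:]


class TestGuideEnumeration:
    def test_pam_snp_makes_guide_allele_specific(self):
        # NGG in parent A broken to NGA in parent B at the same site
        seq_a = _random_seq(60, seed=1)
        i = 30
        seq_a = seq_a[:i] + "TGG" + seq_a[i + 3:]
        seq_b = _mutate(seq_a, i + 2, "A")
        guides = enumerate_guides("chr", seq_a, seq_b, target_parent="A",
                                  require_allele_specific=True)
        plus = [g for g in guides if g.strand == "+"
                and g.start == i - 20 + 1]
        assert plus and plus[0].allele_specific and plus[0].pam_broken_in_other

    def test_snp_outside_seed_rejected(self):
        # parents differing only 12 nt from the PAM: not discriminating
        seq_a = ("A" * 10) + "C" * 20 + "TGG" + ("A" * 10)
        snp_idx = 10 + 20 - 12  # protospacer position 9, outside the 8-nt seed
        seq_b = _mutate(seq_a, snp_idx, "G")
        guides = enumerate_guides("chr", seq_a, seq_b, target_parent="A",
                                  require_allele_specific=True)
        assert all(g.start != 11 or g.strand != "+" for g in guides)

    def test_snp_in_seed_accepted(self):
        seq_a = ("A" * 10) + "C" * 20 + "TGG" + ("A" * 10)
        snp_idx = 10 + 20 - 4  # within the PAM-proximal 8 nt
        seq_b = _mutate(seq_a, snp_idx, "G")
        guides = enumerate_guides("chr", seq_a, seq_b, target_parent="A",
                                  require_allele_specific=True)
        mine = [g for g in guides if g.strand == "+" and g.start == 11]
        assert mine and mine[0].discriminating_snps == (snp_idx + 1,)

    def test_identical_parents_no_specific_guides(self):
        seq = _random_seq(200, seed=2)
        assert enumerate_guides("chr", seq, seq,
                                require_allele_specific=True) == []

    def test_all_candidates_without_filter(self):
        seq = _random_seq(200, seed=3)
        guides = enumerate_guides("chr", seq, seq, require_allele_specific=False)
        assert guides
        for g in guides:
            assert len(g.protospacer) == 20 and g.pam[1:] == "GG"

    def test_short_region_rejected(self):
        with pytest.raises(ValueError, match="23"):
            enumerate_guides("chr", "ACGTACGTACGT", "ACGTACGTACGT")

    def test_every_specific_guide_has_discriminating_snp_or_broken_pam(self):
        seq_a = _random_seq(2000, seed=4)
        rng = np.random.default_rng(5)
        seq_b = seq_a
        for idx in rng.choice(2000, size=20, replace=False):
            seq_b = _mutate(seq_b, int(idx),
                            {"A": "C", "C": "A", "G": "T", "T": "G"}[seq_b[idx]])
        for g in enumerate_guides("chr", seq_a, seq_b,
                                  require_allele_specific=True):
            assert g.discriminating_snps or g.pam_broken_in_other


def naive_offtarget_scan(guide, genome, max_mismatches=3):
    """Independent quadratic reference scan (pure python)."""
    hits = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        for strand in ("+", "-"):
            s = seq if strand == "+" else revcomp(seq)
            for i in range(len(s) - 22):
                window = s[i:i + 20]
                if s[i + 21:i + 23] != "GG":
                    continue
                mism = sum(a != b for a, b in zip(window, guide))
                if mism <= max_mismatches:
                    pos = i + 1 if strand == "+" else len(s) - (i + 20) + 1
                    hits.append((chrom, pos, strand, mism))
    return sorted(hits)


class TestOffTargetScan:
    def test_on_target_only_genome_gives_no_hits(self):
        guide = "ACGTACGTACGTACGTACGT"
        genome = {"chr": "TTTT" + guide + "AGG" + "TTTT"}
        hits = offtarget_scan(guide, genome, exclude=("chr", 5, "+"))
        assert hits == []

    def test_planted_two_mismatch_duplicate_found(self):
        guide = "ACGTACGTACGTACGTACGT"
        dup = _mutate(_mutate(guide, 3, "A"), 14, "T")
        genome = {"chr": guide + "AGG" + "T" * 30 + dup + "CGG" + "TT"}
        hits = offtarget_scan(guide, genome, exclude=("chr", 1, "+"))
        assert len(hits) == 1 and hits[0].mismatches == 2

    def test_invalid_pam_excludes_perfect_match(self):
        guide = "ACGTACGTACGTACGTACGT"
        genome = {"chr": guide + "AGA" + "TTTT"}  # NGA, not NGG
        assert offtarget_scan(guide, genome) == []

    def test_equals_naive_scan_on_random_genome(self):
        guide = _random_seq(20, seed=7)
        genome = {"chrA": _random_seq(5_000, seed=8),
                  "chrB": _random_seq(5_000, seed=9)}
        got = sorted((h.chrom, h.pos, h.strand, h.mismatches)
                     for h in offtarget_scan(guide, genome))
        assert got == naive_offtarget_scan(guide, genome)

    def test_reverse_complement_genome_flips_strands(self):
        guide = _random_seq(20, seed=10)
        genome = {"chr": _random_seq(3_000, seed=11)}
        fwd = offtarget_scan(guide, genome)
        rc = offtarget_scan(guide, {"chr": revcomp(genome["chr"])})
        L = len(genome["chr"])
        flipped = sorted((h.chrom, L - (h.pos + 20) + 2,
                          "+" if h.strand == "-" else "-", h.mismatches)
                         for h in rc)
        assert flipped == sorted((h.chrom, h.pos, h.strand, h.mismatches)
                                 for h in fwd)


class TestDonorDesign:
    def test_point_oligo_geometry(self):
        seq = _random_seq(200, seed=12)
        donor = design_point_oligo(seq, locus=100, desired_base="T", arm=35)
        assert len(donor.sequence) == 71
        assert donor.sequence[35] == "T"
        assert donor.sequence[:35] == seq[64:99]
        assert donor.sequence[36:] == seq[100:135]

    def test_zero_arm_is_single_base(self):
        donor = design_point_oligo("ACGT", locus=2, desired_base="G", arm=0)
        assert donor.sequence == "G"

    def test_insufficient_flank_reports_shortfall(self):
        with pytest.raises(ValueError, match="short by"):
            design_point_oligo("ACGTACGT", locus=2, desired_base="T", arm=35)

    def test_reconstructs_printed_tor1_donor(self):
        # recipient = superior allele (E216, G at the edited base); the
        # designed oligo must equal the published 71-nt donor
        donor_seq = load_fixture("tor1_donor")
        recipient = donor_seq[:35] + "G" + donor_seq[36:]
        donor = design_point_oligo(recipient, locus=36, desired_base="T")
        assert donor.sequence == donor_seq

    def test_oligo_differs_from_recipient_only_at_edit(self):
        seq = _random_seq(300, seed=13)
        locus = 150
        desired = "A" if seq[locus - 1] != "A" else "C"
        donor = design_point_oligo(seq, locus=locus, desired_base=desired)
        window = seq[locus - 36:locus + 35]
        diffs = [i for i, (x, y) in enumerate(zip(window, donor.sequence))
                 if x != y]
        assert diffs == [35]


def _flanking_guides(chrom, start, end):
    g = "ACGTACGTACGTACGTACGT"
    def mk(cut):
        return GuideCandidate(chrom, "+", g, "AGG", cut - 16, cut,
                              (cut,), False, True)
    return mk(start - 50), mk(end + 50)


class TestBlockReplacement:
    def test_table2_block7_length(self):
        blocks = load_fixture("table2_blocks")
        b7 = blocks[blocks["block"] == 7].iloc[0]
        plan = design_block_replacement(
            (b7["chrom"], int(b7["start"]), int(b7["end"])),
            _random_seq(120_000, seed=14),
            _flanking_guides(b7["chrom"], int(b7["start"]), int(b7["end"])),
            arm_range=(500, 800))
        assert plan.block_length == 6_399
        assert round(plan.block_length / 1000, 1) == 6.4

    def test_single_base_block_zero_arms(self):
        plan = design_block_replacement(
            ("chr", 5, 5), "ACGTACGTAC", _flanking_guides("chr", 5, 5),
            arm_range=(0, 0))
        assert plan.donor.sequence == "A" and plan.block_length == 1

    def test_blocks_tile_span(self):
        blocks = load_fixture("table2_blocks")
        starts = blocks["start"].to_numpy()
        ends = blocks["end"].to_numpy()
        assert ends.max() - starts.min() + 1 == 50_130
        # consecutive coordinate-bearing blocks overlap by ~20 bp except
        # across the uncoordinated gap (blocks 3-4)
        order = np.argsort(starts)
        gaps = starts[order][1:] - ends[order][:-1]
        assert (gaps <= 1).sum() == len(gaps) - 1

    def test_arm_lengths_within_range(self):
        plan = design_block_replacement(
            ("chr", 2_000, 3_000), _random_seq(6_000, seed=15),
            _flanking_guides("chr", 2_000, 3_000), arm_range=(500, 800))
        assert 500 <= plan.donor.arm_left <= 800
        assert 500 <= plan.donor.arm_right <= 800
        assert len(plan.donor.sequence) == plan.block_length + \
            plan.donor.arm_left + plan.donor.arm_right

    def test_non_flanking_guides_rejected(self):
        g1, g2 = _flanking_guides("chr", 5_000, 6_000)
        with pytest.raises(ValueError, match="flank"):
            design_block_replacement(("chr", 100, 8_000),
                                     _random_seq(10_000, seed=16), (g1, g2))
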