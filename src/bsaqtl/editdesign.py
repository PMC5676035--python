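"""CRISPR/Cas9 allele-swap design between two parent haplotypes.

Proving a candidate allele causative requires swapping it between the
parents.  This module plans such swaps with SpCas9 (NGG PAM):

* **Allele-discriminating guides** — candidate protospacers are kept
  when a natural parent-differentiating SNP falls in the PAM or in the
  8-nt seed immediately 5' of it, the region dominating target
  discrimination, so the guide cuts one parent's allele but not (or far
  less efficiently) the other's.  A SNP that breaks the NGG outright in
  the non-target parent is the strongest discriminator and is flagged.
* **Off-target scan** — every genomic 20-mer on either strand within 3
  mismatches of the guide and followed by a valid NGG is reported.
* **Donor molecules** — a 71-bp single-base-edit oligo (35-bp homology
  arms) for point mutations, or a block-replacement donor carrying the
  donor parent's sequence over a gene block with 500-800 bp homology
  arms, cut in by a pair of guides flanking the block.

Coordinates are 1-based inclusive; block length = end - start + 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "GuideCandidate", "OffTargetHit", "DonorMolecule", "EditPlan",
    "enumerate_guides", "offtarget_scan", "design_point_oligo",
    "design_block_replacement",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

SEED_LENGTH = 8  # PAM-proximal nucleotides scored for allele discrimination


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GuideCandidate:
    """One candidate protospacer on a parent haplotype.

    ``cut_pos`` is the genomic coordinate of the base 5' of the blunt
    cut, i.e. position 17 of the protospacer (3 bp upstream of the PAM).
    ``discriminating_snps`` are genomic positions inside the PAM or the
    8-nt seed where the parents differ; ``pam_broken_in_other`` marks
    the strong case where the other parent's sequence is no valid NGG.
    """

    chrom: str
    strand: str
    protospacer: str
    pam: str
    start: int  # genomic coordinate of protospacer 5' end on its strand's template
    cut_pos: int
    discriminating_snps: tuple[int, ...]
    pam_broken_in_other: bool
    allele_specific: bool

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if not (len(self.pam) == 3 and self.pam[1:] == "GG"):
            raise ValueError(f"PAM {self.pam!r} is not NGG")
        if self.allele_specific != bool(self.discriminating_snps):
            raise ValueError("allele_specific must track discriminating_snps")


@dataclass(frozen=True)
class OffTargetHit:
    """A genomic near-match of a guide followed by a valid NGG."""

    chrom: str
    pos: int  # 1-based genomic start of the matched 20-mer (plus-strand coords)
    strand: str
    mismatches: int

    def __post_init__(self) -> None:
        if self.mismatches > 3:
            raise ValueError("off-target hits are reported only up to 3 mismatches")


@dataclass(frozen=True)
class DonorMolecule:
    """A repair template: single-base-edit oligo or block-replacement donor."""

    kind: str  # "point_oligo" | "block"
    sequence: str
    arm_left: int
    arm_right: int
    edit_chrom: str
    edit_start: int
    edit_end: int

    def __post_init__(self) -> None:
        if self.kind not in ("point_oligo", "block"):
            raise ValueError(f"unknown donor kind {self.kind!r}")
        if self.kind == "point_oligo" and len(self.sequence) != self.arm_left + 1 + self.arm_right:
            raise ValueError("point oligo length must be arm_left + 1 + arm_right")


@dataclass(frozen=True)
class EditPlan:
    """A complete allele-swap plan: guides, cut sites, and donor."""

    chrom: str
    start: int
    end: int
    block_length: int
    cut_sites: tuple[int, ...]
    guides: tuple[GuideCandidate, ...]
    donor: DonorMolecule

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _parent_diff_positions(seq_a: str, seq_b: str, region_start: int) -> np.ndarray:
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    return np.flatnonzero(a != b) + region_start


def enumerate_guides(chrom: str, seq_a: str, seq_b: str,
                     target_parent: str = "A",
                     require_allele_specific: bool = True,
                     region_start: int = 1) -> list[GuideCandidate]:
    """Enumerate NGG-adjacent 20-mers on both strands of the targeted parent.

    ``seq_a`` and ``seq_b`` are aligned equal-coordinate haplotypes over
    the region (SNP-only differences; indels unsupported);
    ``region_start`` is the genomic coordinate of their first base.
    With ``require_allele_specific`` only candidates whose PAM or seed
    covers a parent-differing position — or whose PAM is intact in the
    target parent but broken in the other — are returned.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("parent haplotypes must have equal length over the region")
    if len(seq_a) < 23:
        raise ValueError("region shorter than 23 nt cannot contain a guide")
    target = seq_a if target_parent == "A" else seq_b
    other = seq_b if target_parent == "A" else seq_a
    diff_pos = set(_parent_diff_positions(seq_a, seq_b, region_start))

    candidates: list[GuideCandidate] = []
    for strand in ("+", "-"):
        t = target if strand == "+" else revcomp(target)
        o = other if strand == "+" else revcomp(other)
        L = len(t)
        for i in range(20, L - 2):
            pam = t[i:i + 3]
            if pam[1:] != "GG":
                continue
            proto = t[i - 20:i]
            # genomic coordinates of seed (protospacer pos 13..20) and PAM
            if strand == "+":
                seed_g = range(region_start + i - SEED_LENGTH, region_start + i)
                pam_g = range(region_start + i, region_start + i + 3)
                start_g = region_start + (i - 20)
                cut_g = region_start + i - 4  # base 17 of the protospacer
            else:
                # index j on the reverse strand maps to plus coordinate
                # region_start + L - 1 - j
                seed_g = range(region_start + L - 1 - (i - 1),
                               region_start + L - 1 - (i - SEED_LENGTH - 1))
                pam_g = range(region_start + L - 1 - (i + 2),
                              region_start + L - 1 - (i - 1))
                start_g = region_start + L - 1 - (i - 20)
                cut_g = region_start + L - 1 - (i - 4)
            disc = tuple(sorted(p for p in (*seed_g, *pam_g) if p in diff_pos))
            pam_broken = o[i + 1:i + 3] != "GG"
            keep = bool(disc) or pam_broken
            if require_allele_specific and not keep:
                continue
            candidates.append(GuideCandidate(
                chrom=chrom, strand=strand, protospacer=proto, pam=pam,
                start=start_g, cut_pos=cut_g,
                discriminating_snps=disc,
                pam_broken_in_other=pam_broken,
                allele_specific=bool(disc)))
    return candidates


def _scan_strand(guide: np.ndarray, genome: np.ndarray, max_mismatches: int) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch counts and NGG validity for every 20-mer start (one strand)."""
    L = genome.size
    n_windows = L - 22  # 20-mer + 3-nt PAM must fit
    if n_windows <= 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=bool)
    mism = np.zeros(n_windows, dtype=np.int16)
    for j in range(20):
        mism += genome[j:j + n_windows] != guide[j]
    g = ord("G")
    pam_ok = (genome[21:21 + n_windows] == g) & (genome[22:22 + n_windows] == g)
    return mism, pam_ok


def offtarget_scan(guide: GuideCandidate | str,
                   genome: dict[str, str],
                   max_mismatches: int = 3,
                   exclude: tuple[str, int, str] | None = None) -> list[OffTargetHit]:
    """Scan a genome for near-matches of a guide followed by a valid NGG.

    Reports every 20-mer on either strand with Hamming distance <=
    ``max_mismatches`` from the guide whose 3' neighbourhood is NGG.
    ``exclude`` (chrom, pos, strand) removes the on-target site; when a
    :class:`GuideCandidate` is passed, its own site is excluded
    automatically.  Positions are 1-based plus-strand coordinates of the
    matched 20-mer's first base.
    """
    if isinstance(guide, GuideCandidate):
        seq = guide.protospacer
        if exclude is None:
            plus_pos = (guide.start if guide.strand == "+"
                        else guide.start - 19)
            exclude = (guide.chrom, plus_pos, guide.strand)
    else:
        seq = guide
    if len(seq) != 20:
        raise ValueError("guide must be 20 nt")
    g = np.frombuffer(seq.upper().encode(), dtype=np.uint8)

    hits: list[OffTargetHit] = []
    for chrom, chrom_seq in genome.items():
        fwd = np.frombuffer(chrom_seq.upper().encode(), dtype=np.uint8)
        L = fwd.size
        mism, pam_ok = _scan_strand(g, fwd, max_mismatches)
        for i in np.flatnonzero((mism <= max_mismatches) & pam_ok):
            hit = OffTargetHit(chrom, int(i) + 1, "+", int(mism[i]))
            if exclude != (chrom, hit.pos, "+"):
                hits.append(hit)
        rev = np.frombuffer(revcomp(chrom_seq.upper()).encode(), dtype=np.uint8)
        mism, pam_ok = _scan_strand(g, rev, max_mismatches)
        for i in np.flatnonzero((mism <= max_mismatches) & pam_ok):
            # start i on the reverse strand: plus-strand start of the 20-mer
            plus_start = L - (int(i) + 20) + 1
            hit = OffTargetHit(chrom, plus_start, "-", int(mism[i]))
            if exclude != (chrom, hit.pos, "-"):
                hits.append(hit)
    hits.sort(key=lambda h: (h.chrom, h.pos, h.strand))
    return hits


def design_point_oligo(recipient_seq: str, locus: int, desired_base: str,
                       arm: int = 35, chrom: str = "",
                       region_start: int = 1) -> DonorMolecule:
    """Single-base-edit donor oligo: left arm + edited base + right arm.

    ``locus`` is the genomic coordinate of the edited base;
    ``recipient_seq`` is the recipient haplotype starting at
    ``region_start``.  The default 35-bp arms give the standard 71-nt
    oligo with the edit central.
    """
    if arm < 0:
        raise ValueError("arm length must be >= 0")
    i = locus - region_start  # 0-based index of edited base
    if i < 0 or i >= len(recipient_seq):
        raise ValueError(f"locus {locus} outside the supplied sequence")
    if i - arm < 0 or i + arm >= len(recipient_seq):
        short = max(arm - i, i + arm - len(recipient_seq) + 1)
        raise ValueError(
            f"insufficient flank for {arm}-bp arms at {chrom or 'seq'}:{locus} "
            f"(short by {short} bp)")
    seq = (recipient_seq[i - arm:i] + desired_base.upper()
           + recipient_seq[i + 1:i + arm + 1])
    return DonorMolecule("point_oligo", seq, arm, arm, chrom, locus, locus)


def design_block_replacement(block: tuple[str, int, int], donor_seq: str,
                             guides: tuple[GuideCandidate, GuideCandidate],
                             arm_range: tuple[int, int] = (500, 800),
                             region_start: int = 1) -> EditPlan:
    """Plan a 2xgRNA block replacement.

    ``block`` = (chrom, start, end), 1-based inclusive; ``donor_seq`` is
    the donor parent's sequence starting at ``region_start`` and must
    cover the block plus homology arms.  The two guides must cut on
    opposite sides of the block (one upstream of its first base, one
    downstream of its last).  Arms take the largest length within
    ``arm_range`` available in ``donor_seq``.
    """
    chrom, start, end = block
    if start > end:
        raise ValueError("block start must be <= end")
    arm_min, arm_max = arm_range
    cut_positions = sorted(g.cut_pos for g in guides)
    if not (cut_positions[0] <= start and cut_positions[1] >= end):
        raise ValueError(
            f"guides cut at {cut_positions}, which does not flank "
            f"block {chrom}:{start}-{end}")

    i0 = start - region_start
    i1 = end - region_start
    if i0 < 0 or i1 >= len(donor_seq):
        raise ValueError("donor sequence does not cover the block")
    arm_left = min(arm_max, i0)
    arm_right = min(arm_max, len(donor_seq) - 1 - i1)
    if arm_min > 0 and (arm_left < arm_min or arm_right < arm_min):
        raise ValueError(
            f"donor sequence leaves arms of {arm_left}/{arm_right} bp, "
            f"below the {arm_min}-bp minimum")
    seq = donor_seq[i0 - arm_left:i1 + 1 + arm_right]
    donor = DonorMolecule("block", seq, arm_left, arm_right, chrom, start, end)
    return EditPlan(chrom=chrom, start=start, end=end,
                    block_length=end - start + 1,
                    cut_sites=tuple(cut_positions), guides=tuple(guides),
                    donor=donor)
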