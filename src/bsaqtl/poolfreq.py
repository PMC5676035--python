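"""Pool allele counts, SNP filters, and the variant-frequency track.

The linkage signal of a pooled-segregant experiment lives in per-site
read counts for the two parental alleles.  This module applies the two
standard pre-mapping filters — minimum coverage (default 20x) and
removal of sites where the two parents carry the same nucleotide (such
sites are parent-vs-reference SNPs, not cross markers) — and computes
the SNP variant frequency f_A = reads(A) / total reads per site.

Pools are serialized as VCF with per-sample AD (allelic depth) fields;
REF is the parent-A allele and ALT the parent-B allele, and the two
parents are carried as haploid GT-only samples so a reader can recover
parent-of-origin without a sidecar table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PoolCounts", "FilterReport", "filter_sites", "variant_frequency",
    "write_pool_vcf", "read_pool_vcf", "track_to_tsv", "track_from_tsv",
]


@dataclass(frozen=True)
class PoolCounts:
    """Read counts at one biallelic site in one pool.

    ``count_a`` supports the parent-A allele, ``count_b`` the parent-B
    allele; position is 1-based.
    """

    chrom: str
    pos: int
    count_a: int
    count_b: int

    def __post_init__(self) -> None:
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError(f"negative read count at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        return self.count_a + self.count_b


@dataclass
class FilterReport:
    """Bookkeeping for :func:`filter_sites`."""

    n_input: int = 0
    n_low_coverage: int = 0
    n_parents_identical: int = 0

    @property
    def n_passed(self) -> int:
        return self.n_input - self.n_low_coverage - self.n_parents_identical


def filter_sites(sites: list[PoolCounts], min_coverage: int = 20,
                 parent_alleles: dict[tuple[str, int], tuple[str, str]] | None = None,
                 ) -> tuple[list[PoolCounts], FilterReport]:
    """Apply the coverage and parent-identity filters.

    Retains sites with depth >= ``min_coverage`` whose two parents carry
    distinct alleles.  ``parent_alleles`` maps (chrom, pos) to the
    (parentA, parentB) nucleotides; when omitted, all sites are assumed
    parent-differentiating (as for simulated pools, where the marker map
    guarantees it).  Sites where the parents agree are dropped and
    counted, not treated as errors.
    """
    report = FilterReport(n_input=len(sites))
    kept: list[PoolCounts] = []
    for site in sites:
        if parent_alleles is not None:
            a, b = parent_alleles.get((site.chrom, site.pos), ("A", "B"))
            if a == b:
                report.n_parents_identical += 1
                continue
        if site.depth < min_coverage:
            report.n_low_coverage += 1
            continue
        kept.append(site)
    return kept, report


def variant_frequency(sites: list[PoolCounts]) -> pd.DataFrame:
    """SNP variant-frequency track: f_A = count_a / depth per site.

    Returns a DataFrame with columns chrom, pos, depth, f_a, sorted by
    (chrom, pos) in input chromosome order.  Zero-depth sites are an
    error: they should have been removed by :func:`filter_sites`.
    """
    for s in sites:
        if s.depth == 0:
            raise ValueError(f"zero-depth site {s.chrom}:{s.pos} in frequency track")
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "depth": [s.depth for s in sites],
            "count_a": [s.count_a for s in sites],
        }
    )
    df["f_a"] = df["count_a"] / df["depth"]
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(df["chrom"]))}
    df = df.sort_values(["chrom", "pos"],
                        key=lambda s: s.map(chrom_order) if s.name == "chrom" else s)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# VCF serialization

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bsaqtl
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples with data">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
"""


def write_pool_vcf(path: str | Path,
                   pools: dict[str, list[PoolCounts]],
                   alleles: dict[tuple[str, int], tuple[str, str]] | None = None,
                   contig_lengths: dict[str, int] | None = None) -> None:
    """Write one VCF with a haploid GT sample per parent and an AD sample per pool.

    All pools must cover the same sites.  REF = parent-A allele, ALT =
    parent-B allele (default A/G when ``alleles`` is omitted), so
    sample ``parentA`` is GT ``0`` and ``parentB`` is GT ``1`` at every
    record.
    """
    pool_names = list(pools)
    sites = pools[pool_names[0]]
    keys = [(s.chrom, s.pos) for s in sites]
    for name in pool_names[1:]:
        if [(s.chrom, s.pos) for s in pools[name]] != keys:
            raise ValueError(f"pool {name!r} covers different sites")

    lines = [_VCF_HEADER]
    if contig_lengths:
        for chrom, length in contig_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>\n")
    else:
        for chrom in dict.fromkeys(s.chrom for s in sites):
            lines.append(f"##contig=<ID={chrom}>\n")
    samples = "\t".join(["parentA", "parentB"] + pool_names)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + samples + "\n")

    for i, (chrom, pos) in enumerate(keys):
        ref, alt = (alleles or {}).get((chrom, pos), ("A", "G"))
        fields = [chrom, str(pos), ".", ref, alt, ".", "PASS",
                  f"NS={len(pool_names) + 2}", "GT:AD", "0:.", "1:."]
        for name in pool_names:
            s = pools[name][i]
            fields.append(f".:{s.count_a},{s.count_b}")
        lines.append("\t".join(fields) + "\n")
    Path(path).write_text("".join(lines))


def read_pool_vcf(path: str | Path, pool_sample: str,
                  parent_a_sample: str = "parentA",
                  parent_b_sample: str = "parentB",
                  ) -> tuple[list[PoolCounts], int]:
    """Read one pool's allele counts from a VCF with AD fields.

    REF/ALT are assigned to parent A or B from the haploid genotypes of
    the two parent sample columns.  Multiallelic records are skipped and
    counted (second return value).  A record without AD for the pool
    sample is an error naming the record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    for needed in (pool_sample, parent_a_sample, parent_b_sample):
        if needed not in samples:
            raise ValueError(f"sample {needed!r} not in VCF ({samples})")
    i_pool = samples.index(pool_sample)
    i_pa = samples.index(parent_a_sample)
    i_pb = samples.index(parent_b_sample)

    counts: list[PoolCounts] = []
    n_multiallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        ad = rec.format("AD")
        if ad is None or np.any(np.asarray(ad[i_pool]) < 0):
            raise ValueError(f"record {rec.CHROM}:{rec.POS} lacks AD for {pool_sample!r}")
        ref_reads, alt_reads = (int(x) for x in ad[i_pool][:2])
        # haploid GT: allele index of each parent (0=REF, 1=ALT)
        gt_a, gt_b = rec.genotypes[i_pa][0], rec.genotypes[i_pb][0]
        if {gt_a, gt_b} != {0, 1}:
            raise ValueError(
                f"record {rec.CHROM}:{rec.POS}: parent genotypes {gt_a}/{gt_b} "
                "do not assign REF and ALT to distinct parents")
        if gt_a == 0:
            count_a, count_b = ref_reads, alt_reads
        else:
            count_a, count_b = alt_reads, ref_reads
        counts.append(PoolCounts(rec.CHROM, rec.POS, count_a, count_b))
    return counts, n_multiallelic


def track_to_tsv(track: pd.DataFrame, path: str | Path,
                 header_comment: str | None = None) -> None:
    """Write a frequency or linkage track as TSV, optionally with a # header."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        track.to_csv(fh, sep="\t", index=False)


def track_from_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def counts_from_track(track: pd.DataFrame) -> list[PoolCounts]:
    """Rebuild PoolCounts from a frequency track (needs count_a or f_a+depth)."""
    out = []
    for row in track.itertuples(index=False):
        count_a = int(getattr(row, "count_a", round(row.f_a * row.depth)))
        out.append(PoolCounts(row.chrom, int(row.pos), count_a,
                              int(row.depth) - count_a))
    return out
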