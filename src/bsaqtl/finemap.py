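"""Fine mapping of a QTL by marker genotyping of individual segregants.

After the pooled scan localizes a QTL to tens of kilobases, selected
marker SNPs spaced 5-15 kb apart are scored in each superior segregant
individually (experimentally by allele-specific PCR; here read off
simulated haplotypes).  At each marker the count k of parent-A calls
among n genotyped segregants is tested with the exact two-sided binomial
against 0.5; the marker of minimum P-value pins the causative region,
and the refined interval is the contiguous run of significant markers
containing it.

Missing genotype calls (failed PCRs) reduce n rather than being imputed,
keeping the per-marker test exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bsaqtl.cross import GenomeMap, Segregant
from bsaqtl.linkage import QtlCall, binom_two_sided

__all__ = [
    "MarkerGenotypes", "FineMapResult", "score_markers",
    "design_marker_grid", "simulate_marker_calls",
    "markers_to_tsv", "markers_from_tsv",
]

MISSING = "NA"


@dataclass(frozen=True)
class MarkerGenotypes:
    """Per-segregant parental-origin calls at one marker SNP.

    ``calls`` holds one symbol per segregant: "A", "B", or "NA" for a
    failed genotyping.
    """

    marker_id: str
    chrom: str
    pos: int
    calls: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.calls) - {"A", "B", MISSING}
        if bad:
            raise ValueError(f"marker {self.marker_id}: invalid calls {bad}")

    @property
    def k(self) -> int:
        return sum(c == "A" for c in self.calls)

    @property
    def n(self) -> int:
        return sum(c != MISSING for c in self.calls)


@dataclass(frozen=True)
class FineMapResult:
    """Per-marker statistics plus the refined interval.

    ``table`` columns: marker_id, chrom, pos, k, n, f (k/n), p.  Markers
    with n = 0 appear with NaN frequency and P and are listed in
    ``unusable``.  ``best_marker`` is the usable marker of minimum P
    (ties -> leftmost); ``interval`` spans the maximal run of markers
    with P < alpha containing it (None when the best marker itself is
    not significant).
    """

    table: pd.DataFrame
    best_marker: str | None
    interval: tuple[int, int] | None
    unusable: tuple[str, ...]
    alpha: float


def score_markers(genotypes: list[MarkerGenotypes], alpha: float = 0.05) -> FineMapResult:
    """Exact binomial scoring of fine-mapping markers.

    Markers must be sorted by position (within one chromosome).  Each
    usable marker gets P = binom_two_sided(k, n, 0.5) with k the
    parent-A calls among the n non-missing genotypes.
    """
    if not genotypes:
        raise ValueError("no markers to score")
    positions = [m.pos for m in genotypes]
    if positions != sorted(positions):
        raise ValueError("markers must be sorted by position")

    rows, unusable = [], []
    for m in genotypes:
        if m.n == 0:
            unusable.append(m.marker_id)
            rows.append((m.marker_id, m.chrom, m.pos, m.k, m.n, np.nan, np.nan))
        else:
            rows.append((m.marker_id, m.chrom, m.pos, m.k, m.n,
                         m.k / m.n, binom_two_sided(m.k, m.n, 0.5)))
    table = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "k", "n", "f", "p"])

    usable = table.dropna(subset=["p"])
    if usable.empty:
        return FineMapResult(table, None, None, tuple(unusable), alpha)
    best_row = usable.loc[usable["p"].idxmin()]  # idxmin is leftmost on ties
    best = str(best_row["marker_id"])

    interval = None
    if best_row["p"] < alpha:
        sig = (table["p"] < alpha).to_numpy()
        i = int(table.index[table["marker_id"] == best][0])
        lo = hi = i
        while lo > 0 and sig[lo - 1]:
            lo -= 1
        while hi < len(table) - 1 and sig[hi + 1]:
            hi += 1
        interval = (int(table.iloc[lo]["pos"]), int(table.iloc[hi]["pos"]))
    return FineMapResult(table, best, interval, tuple(unusable), alpha)


def design_marker_grid(qtl: QtlCall, gmap: GenomeMap,
                       spacing_min: int = 5_000,
                       spacing_max: int = 15_000) -> list[tuple[str, int]]:
    """Choose marker SNPs covering a QTL with gaps in [spacing_min, spacing_max].

    Greedy left-to-right walk over the QTL's SNPs: start from the first
    SNP in the interval, and from each chosen marker take the furthest
    SNP within ``spacing_max``; if the only options are nearer than
    ``spacing_min`` the nearest available SNP is taken so coverage never
    stalls.  The last feasible SNP of the interval is always included.
    Returns (chrom, pos) pairs.
    """
    positions = gmap.snp_positions[qtl.chrom]
    inside = positions[(positions >= qtl.start) & (positions <= qtl.end)]
    if inside.size == 0:
        raise ValueError(f"QTL {qtl.chrom}:{qtl.start}-{qtl.end} contains no SNPs")
    if inside.size == 1:
        return [(qtl.chrom, int(inside[0]))]

    last = int(inside[-1])
    chosen = [int(inside[0])]
    while chosen[-1] != last:
        current = chosen[-1]
        if spacing_min <= last - current <= spacing_max:
            chosen.append(last)
            continue
        ahead = inside[inside > current]
        window = ahead[(ahead - current >= spacing_min)
                       & (ahead - current <= spacing_max)]
        # prefer the furthest in-window SNP that still leaves room for a
        # final gap >= spacing_min, so the last marker never crowds in
        ok = window[last - window >= spacing_min]
        if ok.size:
            nxt = int(ok[-1])
        elif window.size:
            nxt = int(window[-1])
        else:
            under = ahead[ahead - current <= spacing_max]
            # dense region without a compliant gap: take the furthest SNP
            # under spacing_max; sparse region: jump to the next SNP beyond
            nxt = int(under[-1]) if under.size else int(ahead[0])
        chosen.append(nxt)
    return [(qtl.chrom, p) for p in chosen]


def simulate_marker_calls(segregants: list[Segregant],
                          markers: list[tuple[str, int]], gmap: GenomeMap,
                          missing_rate: float = 0.0,
                          seed: int | np.random.Generator = 0) -> list[MarkerGenotypes]:
    """Read marker calls off segregant haplotypes, with genotyping dropout.

    A synthetic stand-in for allele-specific PCR: every call is the true
    parental origin, independently masked to "NA" with ``missing_rate``.
    """
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for chrom, pos in markers:
        idx = gmap.snp_index(chrom, pos)
        calls = []
        for seg in segregants:
            if missing_rate > 0 and rng.random() < missing_rate:
                calls.append(MISSING)
            else:
                calls.append(seg.origin(chrom, idx))
        out.append(MarkerGenotypes(f"{chrom}:{pos}", chrom, pos, tuple(calls)))
    return out


def markers_to_tsv(genotypes: list[MarkerGenotypes], path) -> None:
    """Rows = markers, columns = segregants, cells A/B/NA."""
    n_seg = len(genotypes[0].calls)
    header = ["marker_id", "chrom", "pos"] + [f"seg{i + 1}" for i in range(n_seg)]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for m in genotypes:
            fh.write("\t".join([m.marker_id, m.chrom, str(m.pos), *m.calls]) + "\n")


def markers_from_tsv(path) -> list[MarkerGenotypes]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        calls = tuple(row.iloc[3:].fillna(MISSING))
        out.append(MarkerGenotypes(row["marker_id"], row["chrom"],
                                   int(row["pos"]), calls))
    return out
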