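"""Residue-level comparison of candidate-gene alleles across a strain panel.

Once a QTL narrows to a handful of candidate genes, the parents' protein
sequences are compared position by position and each parental residue is
checked against a panel of sequenced strains: a residue found in neither
parent's relatives nor any other strain is a prime causative candidate
(for the Fas2 alpha subunit of yeast fatty acid synthetase this scan
singles out positions 1136 and 1624 of the superior parent's allele).

Panels mirror a published residue table: rows are strains, columns are
protein positions (1-based), cells hold one-letter residues, '*' for a
nonsense (stop) codon, and blank/'X' for undetermined — undetermined
cells never count as occurrences of a residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq

__all__ = [
    "ResiduePanel", "AlleleDiff", "diff_parent_alleles", "uniqueness_scan",
    "translate_and_diff",
]

_MISSING = {"", "X"}


@dataclass(frozen=True)
class ResiduePanel:
    """Residues of one protein at selected positions across strains.

    ``rows`` maps strain name to one symbol per entry of ``positions``
    ('' for a blank cell).  ``parent_a`` and ``parent_b`` name the two
    parent rows.
    """

    gene: str
    positions: tuple[int, ...]
    rows: dict[str, tuple[str, ...]]
    parent_a: str
    parent_b: str

    def __post_init__(self) -> None:
        for parent in (self.parent_a, self.parent_b):
            if parent not in self.rows:
                raise ValueError(f"parent row {parent!r} missing from panel")
        for strain, symbols in self.rows.items():
            if len(symbols) != len(self.positions):
                raise ValueError(
                    f"strain {strain!r}: {len(symbols)} symbols for "
                    f"{len(self.positions)} positions")

    @property
    def other_strains(self) -> list[str]:
        return [s for s in self.rows if s not in (self.parent_a, self.parent_b)]


@dataclass(frozen=True)
class AlleleDiff:
    """Positions where the two parental proteins differ.

    ``diffs`` holds (position, residue_A, residue_B, kind) with kind
    "nonsense" when either residue is '*', else "missense".
    ``unevaluable`` lists positions where a parent residue is
    undetermined.  ``synonymous`` counts nucleotide-only differences
    (populated by :func:`translate_and_diff`).
    """

    gene: str
    diffs: tuple[tuple[int, str, str, str], ...]
    unevaluable: tuple[int, ...] = ()
    synonymous: int = 0

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(d[0] for d in self.diffs)

    @property
    def n_nonsense(self) -> int:
        return sum(d[3] == "nonsense" for d in self.diffs)


def diff_parent_alleles(panel: ResiduePanel) -> AlleleDiff:
    """List every panel position where the parents' residues differ."""
    row_a = panel.rows[panel.parent_a]
    row_b = panel.rows[panel.parent_b]
    diffs, unevaluable = [], []
    for pos, a, b in zip(panel.positions, row_a, row_b):
        if a in _MISSING or b in _MISSING:
            unevaluable.append(pos)
            continue
        if a != b:
            kind = "nonsense" if "*" in (a, b) else "missense"
            diffs.append((pos, a, b, kind))
    return AlleleDiff(panel.gene, tuple(diffs), tuple(unevaluable))


def uniqueness_scan(panel: ResiduePanel, parent: str = "A") -> set[int]:
    """Positions where the chosen parent's residue occurs in no other strain.

    "Other" means every panel row except the two parents.  Undetermined
    cells are missing data, not evidence of occurrence.
    """
    if parent not in ("A", "B"):
        raise ValueError("parent must be 'A' or 'B'")
    parent_row = panel.rows[panel.parent_a if parent == "A" else panel.parent_b]
    unique: set[int] = set()
    for i, pos in enumerate(panel.positions):
        residue = parent_row[i]
        if residue in _MISSING:
            continue
        seen = any(panel.rows[s][i] == residue for s in panel.other_strains
                   if panel.rows[s][i] not in _MISSING)
        if not seen:
            unique.add(pos)
    return unique


def translate_and_diff(cds_a: str, cds_b: str, gene: str = "") -> AlleleDiff:
    """Translate two aligned in-frame coding sequences and diff the proteins.

    Sequences must be equal length and a multiple of 3 (SNP-only
    alignment).  Translation continues through internal stops ('*') so
    downstream codons are still reported.  Codons that differ in
    nucleotide but not residue are counted as synonymous.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError(f"coding sequences differ in length: {len(cds_a)} vs {len(cds_b)}")
    if len(cds_a) % 3:
        raise ValueError(f"coding length {len(cds_a)} is not a multiple of 3")
    prot_a = str(Seq(cds_a).translate())
    prot_b = str(Seq(cds_b).translate())
    diffs, synonymous = [], 0
    for i, (ra, rb) in enumerate(zip(prot_a, prot_b)):
        codon_a, codon_b = cds_a[3 * i:3 * i + 3], cds_b[3 * i:3 * i + 3]
        if ra != rb:
            kind = "nonsense" if "*" in (ra, rb) else "missense"
            diffs.append((i + 1, ra, rb, kind))
        elif codon_a != codon_b:
            synonymous += 1
    return AlleleDiff(gene, tuple(diffs), (), synonymous)


def panel_from_tsv(path: str | Path, gene: str, parent_a: str,
                   parent_b: str) -> ResiduePanel:
    """Load a residue panel from TSV (column 1 = strain, then one column
    per position; header row holds the positions)."""
    lines = Path(path).read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    positions = tuple(int(p) for p in header[1:])
    rows: dict[str, tuple[str, ...]] = {}
    for line in lines[1:]:
        cells = line.split("\t")
        rows[cells[0]] = tuple(c.strip() for c in cells[1:])
    return ResiduePanel(gene, positions, rows, parent_a, parent_b)
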