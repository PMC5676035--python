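"""Packaged worked-example data for the BTC.1D x ER18 cross.

Three small fixtures ship with the package:

``table1``
    Residue panels for Tor1 (8 positions) and Fas2 (5 positions) across
    the two parents, the S288c reference, and 38 other sequenced
    *S. cerevisiae* strains.
``table2_blocks``
    Coordinates of the eight coordinate-bearing ChrXVI gene blocks used
    for bulk replacement of the chromosome-XVI QTL (blocks 3 and 4 of
    the original ten carry no published coordinates).
``tor1_donor``
    The 71-nt single-base-edit donor oligo for the TOR1 E216* swap.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from bsaqtl.alleles import ResiduePanel, panel_from_tsv

__all__ = ["load_fixture"]

PARENT_A = "BTC.1D"
PARENT_B = "ER18"


def _data_path(name: str):
    return resources.files("bsaqtl") / "data" / name


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``"table1"`` -> dict of gene -> :class:`~bsaqtl.alleles.ResiduePanel`
    (keys "TOR1", "FAS2"); ``"table2_blocks"`` -> DataFrame with columns
    block, strain, chrom, start, end; ``"tor1_donor"`` -> the 71-nt
    donor sequence as a string.
    """
    if name == "table1":
        return {
            "TOR1": panel_from_tsv(_data_path("table1_tor1.tsv"),
                                   "TOR1", PARENT_A, PARENT_B),
            "FAS2": panel_from_tsv(_data_path("table1_fas2.tsv"),
                                   "FAS2", PARENT_A, PARENT_B),
        }
    if name == "table2_blocks":
        with resources.as_file(_data_path("table2_blocks.tsv")) as path:
            return pd.read_csv(path, sep="\t")
    if name == "tor1_donor":
        return _data_path("tor1_donor.txt").read_text().strip()
    raise KeyError(f"unknown fixture {name!r}")
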