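"""Shared genotype codes and the bin-marker genotype matrix container.

A recombinant inbred line (RIL) genome is a mosaic of the two parental
haplotypes, so every locus carries one of two parental origins.  The
package encodes origins as small integers throughout:

====  =======  =================================
code  letter   meaning
====  =======  =================================
0     ``A``    first parent (e.g. Bay-0) allele
1     ``B``    second parent (e.g. Sha) allele
-1    ``NA``   missing / unassignable
====  =======  =================================
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

A = 0
B = 1
MISSING = -1

_CODE_TO_CHAR = {A: "A", B: "B", MISSING: "NA"}
_CHAR_TO_CODE = {"A": A, "B": B, "NA": MISSING, "": MISSING}

MARKER_COLUMNS = ["name", "chrom", "start_bp", "end_bp", "midpoint_mb", "n_snps"]


def chrom_label(chrom: str | int) -> str:
    """Normalise a chromosome name for marker naming ("Chr1" -> "1")."""
    s = str(chrom)
    m = re.fullmatch(r"(?:chr)?_?(\w+)", s, flags=re.IGNORECASE)
    return m.group(1) if m else s


def codes_to_letters(codes: pd.DataFrame) -> pd.DataFrame:
    return codes.replace(_CODE_TO_CHAR)


def letters_to_codes(letters: pd.DataFrame) -> pd.DataFrame:
    out = letters.fillna("NA").astype(str).apply(lambda col: col.map(_CHAR_TO_CODE))
    return out.astype(np.int8)


@dataclass
class GenotypeMatrix:
    """Lines x bin-markers parental-origin matrix with physical anchors.

    Parameters
    ----------
    codes
        DataFrame indexed by line name, one column per marker, int8 values
        in {0 (A), 1 (B), -1 (missing)}.  Column order is physical order
        within and across chromosomes.
    markers
        Marker sheet with columns ``name, chrom, start_bp, end_bp,
        midpoint_mb, n_snps`` in the same order as ``codes`` columns.
    support
        Optional per-cell evidence: ``(n_calls_A, n_calls_B)`` integer
        arrays of the same shape as ``codes``.
    """

    codes: pd.DataFrame
    markers: pd.DataFrame
    support: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.codes.columns) != list(self.markers["name"]):
            raise ValueError("codes columns must match markers['name'] in order")

    @property
    def lines(self) -> list[str]:
        return list(self.codes.index)

    @property
    def n_lines(self) -> int:
        return len(self.codes)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_markers(self, chrom: str) -> pd.DataFrame:
        return self.markers[self.markers["chrom"] == chrom]

    def chrom_codes(self, chrom: str) -> pd.DataFrame:
        names = self.chrom_markers(chrom)["name"]
        return self.codes[list(names)]

    def subset_markers(self, names: list[str]) -> "GenotypeMatrix":
        """Restrict to a subset of markers, keeping physical order."""
        keep = self.markers[self.markers["name"].isin(set(names))].reset_index(drop=True)
        sub_support = None
        if self.support is not None:
            idx = [list(self.codes.columns).index(n) for n in keep["name"]]
            sub_support = (self.support[0][:, idx], self.support[1][:, idx])
        return GenotypeMatrix(self.codes[list(keep["name"])], keep, sub_support)

    def subset_lines(self, lines: list[str]) -> "GenotypeMatrix":
        keep = [ln for ln in self.codes.index if ln in set(lines)]
        sub_support = None
        if self.support is not None:
            pos = [self.lines.index(ln) for ln in keep]
            sub_support = (self.support[0][pos], self.support[1][pos])
        return GenotypeMatrix(self.codes.loc[keep], self.markers, sub_support)

    # -- persistence ---------------------------------------------------

    def to_csv(self, codes_path, markers_path=None) -> None:
        """Write codes as a lines x markers CSV of A/B/NA, plus a marker sheet."""
        codes_to_letters(self.codes).to_csv(codes_path, index_label="line")
        if markers_path is not None:
            self.markers.to_csv(markers_path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, codes_path, markers_path) -> "GenotypeMatrix":
        letters = pd.read_csv(codes_path, index_col="line")
        markers = pd.read_csv(markers_path, sep="\t", dtype={"chrom": str})
        return cls(letters_to_codes(letters), markers)


def read_legacy_map(path) -> pd.DataFrame:
    """Read a legacy marker map TSV.

    Expected columns: ``marker, chrom, pos_bp, cM`` followed by one column
    per line holding A/B/NA genotypes.  Returns the frame with genotype
    columns recoded to int8.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["marker", "chrom", "pos_bp", "cM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"legacy map missing columns: {missing}")
    line_cols = [c for c in df.columns if c not in required]
    if not line_cols:
        raise ValueError("legacy map has no per-line genotype columns")
    df[line_cols] = letters_to_codes(df[line_cols])
    return df.sort_values(["chrom", "pos_bp"]).reset_index(drop=True)


def write_legacy_map(df: pd.DataFrame, path) -> None:
    out = df.copy()
    line_cols = [c for c in df.columns if c not in ("marker", "chrom", "pos_bp", "cM")]
    out[line_cols] = codes_to_letters(out[line_cols])
    out.to_csv(path, sep="\t", index=False)
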