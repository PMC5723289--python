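"""Population statistics on the bin-marker matrix.

Covers the descriptive genetics of a RIL population: per-marker allele
frequencies with an exact segregation-distortion test, crossover counting
from genotype-block transitions, and detection of introgressions that a
sparse legacy map could not see.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .core import A, B, MISSING, GenotypeMatrix


def exact_binomial_p(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided exact binomial p-value against p=0.5, vectorised.

    For the symmetric null the two-sided p-value is twice the smaller tail
    (capped at 1), which matches the minlike convention of
    ``scipy.stats.binomtest`` exactly at p=0.5.
    """
    k = np.asarray(k, dtype=int)
    n = np.asarray(n, dtype=int)
    lo = np.minimum(k, n - k)
    with np.errstate(invalid="ignore"):
        p = 2.0 * binom.cdf(lo, n, 0.5)
        # when k is exactly n/2 both tails overlap at the centre point
        p = np.where(2 * lo == n, 1.0, np.minimum(p, 1.0))
    return np.where(n > 0, p, np.nan)


def segregation_distortion(matrix: GenotypeMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Test every marker for departure from the expected 1:1 segregation.

    Percentages are reported over all lines (the convention used for
    published allele-frequency figures) while the exact binomial test uses
    the non-missing counts.  Significance is Bonferroni-corrected at the
    family level: p < alpha / M with M the total marker count.  Markers
    with no informative call get an undefined p-value and are flagged.
    """
    codes = matrix.codes.to_numpy()
    n_lines = matrix.n_lines
    n_a = (codes == A).sum(axis=0)
    n_b = (codes == B).sum(axis=0)
    n_missing = (codes == MISSING).sum(axis=0)
    n_called = n_a + n_b
    p = exact_binomial_p(n_a, n_called)
    M = len(matrix.markers)
    table = matrix.markers[["name", "chrom", "midpoint_mb"]].copy()
    table["n_A"] = n_a
    table["n_B"] = n_b
    table["n_missing"] = n_missing
    table["pct_A"] = 100.0 * n_a / n_lines
    table["pct_B"] = 100.0 * n_b / n_lines
    table["p_value"] = p
    table["significant"] = p < (alpha / M)
    table["undefined"] = n_called == 0
    return table


@dataclass
class CrossoverCounts:
    per_line_chrom: pd.DataFrame  # line, chrom, n_crossovers

    @property
    def total(self) -> int:
        return int(self.per_line_chrom["n_crossovers"].sum())

    def per_chromosome(self) -> pd.Series:
        return self.per_line_chrom.groupby("chrom", sort=False)["n_crossovers"].sum()

    def per_line(self) -> pd.Series:
        return self.per_line_chrom.groupby("line", sort=False)["n_crossovers"].sum()


def count_crossovers(matrix: GenotypeMatrix, break_on_missing: bool = False) -> CrossoverCounts:
    """Count genotype-block transitions per line and chromosome.

    A breakpoint is a change between consecutive non-missing genotypes
    along the physically ordered markers.  By default missing cells are
    skipped without terminating a block (a conservative count);
    ``break_on_missing`` instead discards transitions spanning a gap.
    """
    rows = []
    for chrom in matrix.chromosomes:
        X = matrix.chrom_codes(chrom).to_numpy()
        for li, line in enumerate(matrix.lines):
            row = X[li]
            obs = row[row != MISSING]
            if break_on_missing:
                # count changes only between directly adjacent non-missing cells
                adj = (row[:-1] != MISSING) & (row[1:] != MISSING)
                n = int(((row[:-1] != row[1:]) & adj).sum())
            else:
                n = int((obs[:-1] != obs[1:]).sum()) if obs.size > 1 else 0
            rows.append({"line": line, "chrom": chrom, "n_crossovers": n})
    return CrossoverCounts(pd.DataFrame(rows))


def detect_introgressions(
    matrix: GenotypeMatrix,
    legacy_map: pd.DataFrame,
    min_size_bp: int = 200_000,
) -> pd.DataFrame:
    """Find introgressions invisible to a sparse legacy marker map.

    For each line and each pair of physically consecutive legacy markers at
    which the line carries the same genotype ``g``, every maximal run of
    bins with the opposite genotype strictly inside the span is reported
    when the run spans at least ``min_size_bp`` (default 200 kbp, i.e. two
    bins) — a double recombination event the legacy map cannot detect.
    Spans whose legacy flanks disagree (ordinary recombinant spans) are
    not searched.

    ``legacy_map`` follows the legacy TSV schema (marker, chrom, pos_bp,
    cM, one int8 genotype column per line).
    """
    meta_cols = {"marker", "chrom", "pos_bp", "cM"}
    line_cols = [c for c in legacy_map.columns if c not in meta_cols]
    if not line_cols:
        raise ValueError("legacy map carries no per-line genotype columns")
    shared_lines = [ln for ln in matrix.lines if ln in line_cols]

    records = []
    for chrom in matrix.chromosomes:
        leg = legacy_map[legacy_map["chrom"] == chrom].sort_values("pos_bp")
        if len(leg) < 2:
            continue
        bins_meta = matrix.chrom_markers(chrom).reset_index(drop=True)
        starts = bins_meta["start_bp"].to_numpy()
        ends = bins_meta["end_bp"].to_numpy()
        mids = (bins_meta["midpoint_mb"].to_numpy() * 1e6).astype(float)
        codes = matrix.chrom_codes(chrom).to_numpy()
        leg_pos = leg["pos_bp"].to_numpy()
        for line in shared_lines:
            li = matrix.lines.index(line)
            leg_geno = leg[line].to_numpy()
            row = codes[li]
            for j in range(len(leg) - 1):
                g1, g2 = leg_geno[j], leg_geno[j + 1]
                if g1 == MISSING or g1 != g2:
                    continue
                g = g1
                inside = np.flatnonzero((mids > leg_pos[j]) & (mids < leg_pos[j + 1]))
                if inside.size == 0:
                    continue
                opp = row[inside] == (1 - g)
                # maximal runs of the opposite genotype
                k = 0
                while k < inside.size:
                    if not opp[k]:
                        k += 1
                        continue
                    k2 = k
                    while k2 + 1 < inside.size and opp[k2 + 1] and inside[k2 + 1] == inside[k2] + 1:
                        k2 += 1
                    start = int(starts[inside[k]])
                    end = int(ends[inside[k2]])
                    size = end - start
                    if size >= min_size_bp:
                        records.append(
                            {
                                "line": line,
                                "chrom": chrom,
                                "start_bp": start,
                                "end_bp": end,
                                "size_bp": size,
                                "genotype": "B" if g == A else "A",
                                "left_marker": leg.iloc[j]["marker"],
                                "right_marker": leg.iloc[j + 1]["marker"],
                            }
                        )
                    k = k2 + 1
    return pd.DataFrame(
        records,
        columns=[
            "line",
            "chrom",
            "start_bp",
            "end_bp",
            "size_bp",
            "genotype",
            "left_marker",
            "right_marker",
        ],
    )


def global_allele_balance(matrix: GenotypeMatrix) -> dict:
    """Pooled allele percentages over all determinate cells."""
    codes = matrix.codes.to_numpy()
    n_a = int((codes == A).sum())
    n_b = int((codes == B).sum())
    tot = n_a + n_b
    return {
        "pct_A": 100.0 * n_a / tot if tot else float("nan"),
        "pct_B": 100.0 * n_b / tot if tot else float("nan"),
        "n_called": tot,
    }
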