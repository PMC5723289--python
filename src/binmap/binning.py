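"""100-kbp bin-marker scoring from per-SNP parental-origin calls.

Individual RNA-seq SNP calls are noisy and unevenly spaced; collapsing
them into fixed-width physical bins averages out miscalls and yields a
regular grid of markers anchored on the genome.  Each line x bin genotype
is the majority vote of the origin calls inside the bin; ties and empty
bins are resolved afterwards from the flanking genotype blocks.

Bin coordinates are 0-based half-open windows; a 1-based SNP position
``p`` falls in bin ``[s, e)`` iff ``s < p <= e``.  Marker names follow
the ``RSM_<chrom>_<midpoint Mbp, 2 decimals>`` convention (RSM_1_0.05 is
the marker at 0.05 Mbp on chromosome 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import A, B, MISSING, GenotypeMatrix, chrom_label


def define_bins(
    chrom_lengths: dict[str, int],
    bin_size: int = 100_000,
    snp_positions: pd.DataFrame | None = None,
    min_snps: int = 2,
) -> pd.DataFrame:
    """Tile each chromosome with fixed-size bins and name the markers.

    The last window of a chromosome may be short and keeps its true
    midpoint in the name.  When ``snp_positions`` (columns chrom, pos_bp)
    is given, per-bin population-level SNP counts are attached and bins
    with fewer than ``min_snps`` SNPs are dropped — a bin needs at least
    two SNPs to be a trustworthy marker.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        mids = (starts + ends) / 2.0
        label = chrom_label(chrom)
        for i, (s, e, m) in enumerate(zip(starts, ends, mids)):
            rows.append(
                {
                    "name": f"RSM_{label}_{m / 1e6:.2f}",
                    "chrom": str(chrom),
                    "start_bp": int(s),
                    "end_bp": int(e),
                    "midpoint_mb": m / 1e6,
                    "n_snps": 0,
                }
            )
    bins = pd.DataFrame(rows)
    if snp_positions is not None:
        counts = np.zeros(len(bins), dtype=int)
        for chrom, sub in snp_positions.groupby("chrom"):
            mask = bins["chrom"] == str(chrom)
            if not mask.any():
                continue
            starts = bins.loc[mask, "start_bp"].to_numpy()
            ends = bins.loc[mask, "end_bp"].to_numpy()
            pos0 = sub["pos_bp"].to_numpy() - 1
            idx = np.searchsorted(starts, pos0, side="right") - 1
            ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
            counts[np.flatnonzero(mask)] = np.bincount(idx[ok], minlength=len(starts))
        bins["n_snps"] = counts
        bins = bins[bins["n_snps"] >= min_snps].reset_index(drop=True)
    return bins


def score_bins(snps: pd.DataFrame, bins: pd.DataFrame) -> GenotypeMatrix:
    """Majority-vote bin genotypes from the SNP origin table.

    ``snps`` is the long table (line, chrom, pos_bp, origin).  Per line and
    bin, A wins if A-calls outnumber B-calls and vice versa; zero
    informative calls or an exact tie leave the cell missing (pending
    transition resolution).  Per-cell support counts are retained.
    The result is invariant to the input row order.
    """
    lines = sorted(snps["line"].unique())
    n_l, n_m = len(lines), len(bins)
    line_idx = {ln: i for i, ln in enumerate(lines)}
    n_a = np.zeros((n_l, n_m), dtype=np.int32)
    n_b = np.zeros((n_l, n_m), dtype=np.int32)

    informative = snps[snps["origin"] != MISSING]
    for chrom, sub in informative.groupby("chrom"):
        mask = (bins["chrom"] == str(chrom)).to_numpy()
        if not mask.any():
            continue
        col_offset = np.flatnonzero(mask)
        starts = bins.loc[mask, "start_bp"].to_numpy()
        ends = bins.loc[mask, "end_bp"].to_numpy()
        pos0 = sub["pos_bp"].to_numpy() - 1  # to 0-based
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        rows = sub["line"].map(line_idx).to_numpy()[ok]
        cols = col_offset[idx[ok]]
        orig = sub["origin"].to_numpy()[ok]
        np.add.at(n_a, (rows[orig == A], cols[orig == A]), 1)
        np.add.at(n_b, (rows[orig == B], cols[orig == B]), 1)

    codes = np.full((n_l, n_m), MISSING, dtype=np.int8)
    codes[n_a > n_b] = A
    codes[n_b > n_a] = B
    frame = pd.DataFrame(codes, index=pd.Index(lines, name="line"), columns=list(bins["name"]))
    return GenotypeMatrix(frame, bins.reset_index(drop=True), support=(n_a, n_b))


def resolve_transitions(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, dict]:
    """Assign undetermined bins from the flanking genotype blocks.

    For each line and chromosome, every missing/tied bin with determinate
    neighbours on both sides takes the shared neighbour genotype when the
    neighbours agree; at a true transition (neighbours disagree) it takes
    the genotype of the physically closer determinate neighbour (midpoint
    distance), and stays missing on an exact distance tie.  Terminal runs
    copy the single available neighbour.  Determinate cells are never
    changed.

    Returns the resolved matrix and a report with the fraction of cells
    that were already unambiguous.
    """
    codes = matrix.codes.to_numpy().copy()
    markers = matrix.markers
    n_cells = codes.size
    n_determinate_before = int((codes != MISSING).sum())

    for chrom in matrix.chromosomes:
        cols = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        mids = markers["midpoint_mb"].to_numpy()[cols]
        block = codes[:, cols]
        for li in range(block.shape[0]):
            row = block[li]
            det = np.flatnonzero(row != MISSING)
            if det.size == 0:
                continue
            miss = np.flatnonzero(row == MISSING)
            if miss.size == 0:
                continue
            right_rank = np.searchsorted(det, miss)
            for m, rr in zip(miss, right_rank):
                left = det[rr - 1] if rr > 0 else None
                right = det[rr] if rr < det.size else None
                if left is None:
                    row[m] = row[right]
                elif right is None:
                    row[m] = row[left]
                elif row[left] == row[right]:
                    row[m] = row[left]
                else:
                    dl = mids[m] - mids[left]
                    dr = mids[right] - mids[m]
                    if np.isclose(dl, dr, rtol=1e-9, atol=1e-12):
                        pass  # equidistant conflicting flanks: stays missing
                    elif dl < dr:
                        row[m] = row[left]
                    else:
                        row[m] = row[right]
        codes[:, cols] = block

    resolved = GenotypeMatrix(
        pd.DataFrame(codes, index=matrix.codes.index, columns=matrix.codes.columns),
        matrix.markers,
        support=matrix.support,
    )
    report = {
        "n_cells": n_cells,
        "fraction_unambiguous_before": n_determinate_before / n_cells if n_cells else float("nan"),
        "n_resolved": int((codes != MISSING).sum()) - n_determinate_before,
    }
    return resolved, report


def bin_quality(matrix: GenotypeMatrix, min_match: float = 0.8) -> dict:
    """QC of the scored matrix via adjacent-marker agreement.

    For every physically adjacent marker pair on a chromosome, computes the
    fraction of lines (non-missing at both) with matching genotypes and
    the Pearson correlation of the +/-1-coded genotypes; pairs below
    ``min_match`` are flagged.  Also reports the percentage of determinate
    cells and the percentage of bins determinate in every line (the two
    readings of "unambiguously assigned").
    """
    rows = []
    for chrom in matrix.chromosomes:
        sub = matrix.chrom_markers(chrom)
        names = list(sub["name"])
        if len(names) < 2:
            continue
        X = matrix.codes[names].to_numpy()
        for j in range(len(names) - 1):
            a, b = X[:, j], X[:, j + 1]
            ok = (a != MISSING) & (b != MISSING)
            n = int(ok.sum())
            if n >= 2:
                match = float((a[ok] == b[ok]).mean())
                ca = 2.0 * a[ok] - 1.0
                cb = 2.0 * b[ok] - 1.0
                if ca.std() > 0 and cb.std() > 0:
                    corr = float(np.corrcoef(ca, cb)[0, 1])
                else:
                    corr = float("nan")
            else:
                match, corr = float("nan"), float("nan")
            rows.append(
                {
                    "chrom": chrom,
                    "marker1": names[j],
                    "marker2": names[j + 1],
                    "n": n,
                    "match_fraction": match,
                    "correlation": corr,
                    "flagged": bool(n >= 2 and match < min_match),
                }
            )
    codes = matrix.codes.to_numpy()
    determinate = codes != MISSING
    return {
        "adjacent_pairs": pd.DataFrame(rows),
        "pct_cells_determinate": 100.0 * determinate.mean() if codes.size else float("nan"),
        "pct_bins_fully_determinate": 100.0 * determinate.all(axis=0).mean() if codes.size else float("nan"),
    }
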