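"""Quantitative comparison of QTL scans across marker densities.

The value of a dense bin map is measured against a sparser map of the
same population three ways: per-map summary statistics, classification of
per-trait-per-chromosome LOD peaks (new / lost / higher / lower /
unchanged), and the change in LOD-drop confidence-interval width for QTLs
significant in both maps.  Comparisons assume both scans were run on the
same lines; :func:`intersect_lines` enforces the common-line restriction
before map estimation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .linkage import GeneticMap, map_summary
from .popgen import global_allele_balance


def intersect_lines(matrices: list[GenotypeMatrix]) -> list[GenotypeMatrix]:
    """Restrict every matrix to the lines shared by all of them."""
    shared = set(matrices[0].lines)
    for m in matrices[1:]:
        shared &= set(m.lines)
    if not shared:
        raise ValueError("no lines shared across matrices")
    return [m.subset_lines(sorted(shared)) for m in matrices]


def thin_matrix(matrix: GenotypeMatrix, n_markers: int) -> GenotypeMatrix:
    """Evenly thin a matrix to ~``n_markers`` markers by physical position.

    Marker allocation is proportional to each chromosome's physical span
    (minimum two per chromosome) — emulating a legacy low-density map of
    the same population.
    """
    spans = {
        c: matrix.chrom_markers(c)["midpoint_mb"].max() - matrix.chrom_markers(c)["midpoint_mb"].min()
        for c in matrix.chromosomes
    }
    total = sum(spans.values())
    keep: list[str] = []
    for chrom in matrix.chromosomes:
        sub = matrix.chrom_markers(chrom)
        k = max(2, round(n_markers * spans[chrom] / total))
        idx = np.unique(np.linspace(0, len(sub) - 1, min(k, len(sub))).round().astype(int))
        keep.extend(sub["name"].iloc[idx])
    return matrix.subset_markers(keep)


def compare_lod(
    peaks1: pd.DataFrame,
    peaks2: pd.DataFrame,
    sig_lod: float = 3.0,
    delta: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Classify per-trait-per-chromosome peaks between two maps.

    Classes: ``new`` (significant in map2 only), ``lost`` (map1 only),
    ``higher``/``lower`` (significant in both with ``|dLOD| >= delta``,
    inclusive boundary), else ``unchanged``.  Pairs present in only one
    peak set are excluded.  Where both scans report CI widths the width
    change is classified as reduced/increased/equal.

    Returns the per-pair table and a summary dict with counts,
    percentages and average |dLOD| under both conditionings (pairs
    significant in map1; pairs significant in map2).
    """
    keys = ["trait", "chrom"]
    merged = peaks1.merge(peaks2, on=keys, suffixes=("_1", "_2"), how="inner")
    sig1 = merged["lod_1"] > sig_lod
    sig2 = merged["lod_2"] > sig_lod
    dlod = merged["lod_2"] - merged["lod_1"]
    cls = np.full(len(merged), "unchanged", dtype=object)
    cls[(~sig1) & sig2] = "new"
    cls[sig1 & (~sig2)] = "lost"
    both = sig1 & sig2
    cls[both & (dlod >= delta)] = "higher"
    cls[both & (dlod <= -delta)] = "lower"
    merged["delta_lod"] = dlod
    merged["class"] = cls
    if "width_mb_1" in merged and "width_mb_2" in merged:
        dw = merged["width_mb_1"] - merged["width_mb_2"]
        ci_cls = np.where(dw > 0, "reduced", np.where(dw < 0, "increased", "equal"))
        merged["ci_class"] = np.where(both & dw.notna(), ci_cls, "")

    n_pairs = len(merged)
    counts = {c: int((cls == c).sum()) for c in ("new", "lost", "higher", "lower", "unchanged")}
    n_sig1 = int(sig1.sum())
    summary = {
        "n_pairs": n_pairs,
        "n_significant_map1": n_sig1,
        "n_significant_map2": int(sig2.sum()),
        **{f"n_{c}": v for c, v in counts.items()},
        # percentages follow the published convention: relative to the
        # significant QTLs of the reference (map1) for new/higher/lower
        "pct_new": 100.0 * counts["new"] / n_sig1 if n_sig1 else float("nan"),
        "pct_higher": 100.0 * counts["higher"] / n_sig1 if n_sig1 else float("nan"),
        "pct_lower": 100.0 * counts["lower"] / n_sig1 if n_sig1 else float("nan"),
        "avg_abs_dlod_sig_map1": float(dlod[sig1].abs().mean()) if n_sig1 else float("nan"),
        "avg_abs_dlod_sig_map2": float(dlod[sig2].abs().mean()) if sig2.any() else float("nan"),
    }
    return merged, summary


def compare_ci(qtls1: pd.DataFrame, qtls2: pd.DataFrame, sig_lod: float = 3.0) -> tuple[pd.DataFrame, dict]:
    """Compare CI widths of QTLs significant in both maps.

    Inputs are peak tables with ``width_mb`` columns (as produced by
    :func:`binmap.qtl.scan_traits`).  Reports per-QTL ``width1 - width2``
    and the counts/percentage with a reduced width in map2.
    """
    keys = ["trait", "chrom"]
    merged = qtls1.merge(qtls2, on=keys, suffixes=("_1", "_2"), how="inner")
    both = (
        (merged["lod_1"] > sig_lod)
        & (merged["lod_2"] > sig_lod)
        & merged["width_mb_1"].notna()
        & merged["width_mb_2"].notna()
    )
    shared = merged[both].copy()
    shared["width_change_mb"] = shared["width_mb_1"] - shared["width_mb_2"]
    n = len(shared)
    n_red = int((shared["width_change_mb"] > 0).sum())
    n_inc = int((shared["width_change_mb"] < 0).sum())
    summary = {
        "n_shared_significant": n,
        "n_reduced": n_red,
        "n_increased": n_inc,
        "n_equal": n - n_red - n_inc,
        "pct_reduced": 100.0 * n_red / n if n else float("nan"),
        "median_width_map1_mb": float(shared["width_mb_1"].median()) if n else float("nan"),
        "median_width_map2_mb": float(shared["width_mb_2"].median()) if n else float("nan"),
    }
    return shared, summary


def map_stats_table(entries: list[tuple[str, GeneticMap, GenotypeMatrix]]) -> pd.DataFrame:
    """Per-map summary statistics for maps of the same population.

    Each entry is ``(label, map, matrix)``; rows report marker count,
    total length, average spacing, maximum gap, crossover count,
    percentage of genotyped cells and the pooled allele percentages.
    """
    rows = []
    for label, gmap, matrix in entries:
        ms = map_summary(gmap, matrix)
        balance = global_allele_balance(matrix)
        codes = matrix.codes.to_numpy()
        rows.append(
            {
                "map": label,
                "n_markers": ms.totals["n_markers"],
                "length_cm": ms.totals["length_cm"],
                "avg_spacing_cm": ms.totals["avg_spacing_cm"],
                "max_gap_cm": ms.totals["max_gap_cm"],
                "n_crossovers": ms.totals["n_crossovers"],
                "pct_genotyped": 100.0 * (codes != -1).mean(),
                "pct_allele_A": balance["pct_A"],
                "pct_allele_B": balance["pct_B"],
            }
        )
    return pd.DataFrame(rows)
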