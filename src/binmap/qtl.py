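"""Single-QTL genome scans on the bin map.

The scan follows the classical interval-mapping workflow for an inbred
two-genotype population: smooth the observed marker genotypes into
conditional genotype probabilities with the same hidden-chain model the
map was estimated under, regress each trait on the probability of
carrying the B allele at every evaluation position (Haley-Knott
regression), and summarise each chromosome by its LOD peak,

    LOD = (n/2) * log10(RSS0 / RSS1),

with RSS0 from the intercept-only model.  Genome-wide significance comes
from a seeded permutation null of whole phenotype vectors; QTL location
uncertainty from LOD-1 support intervals converted to physical
coordinates through the chromosome's genetic-to-physical linear fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .linkage import GeneticMap, emission_likelihoods, forward_backward
from .mapfunc import haldane_r, kosambi_r, ril_observed


@dataclass
class GenoProbGrid:
    """Posterior P(genotype = B) per line at each evaluation position."""

    positions: pd.DataFrame  # chrom, cm, physical_mb, is_marker, name
    prob_b: np.ndarray  # n_lines x n_positions
    lines: list[str]

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.positions["chrom"] == chrom).to_numpy())


@dataclass
class LodCurve:
    """LOD at every evaluation position for one trait."""

    positions: pd.DataFrame
    lod: np.ndarray
    trait: str
    n_lines: int

    def chrom_slice(self, chrom: str) -> tuple[pd.DataFrame, np.ndarray]:
        mask = (self.positions["chrom"] == chrom).to_numpy()
        return self.positions[mask].reset_index(drop=True), self.lod[mask]


def genotype_probabilities(
    matrix: GenotypeMatrix,
    gmap: GeneticMap,
    step_cm: float = 0.0,
    error_prob: float | None = None,
) -> GenoProbGrid:
    """Hidden-state posteriors at markers (plus an optional cM grid).

    ``step_cm = 0`` evaluates at markers only; otherwise pseudo-positions
    are inserted every ``step_cm`` between adjacent markers and treated as
    markers with missing observations.  Physical coordinates of
    pseudo-positions are interpolated linearly between flanking markers.
    """
    if error_prob is None:
        error_prob = gmap.error_prob
    inv = kosambi_r if gmap.map_function == "kosambi" else haldane_r

    pos_frames = []
    probs = []
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_table(chrom).reset_index(drop=True)
        marker_cm = sub["cm"].to_numpy()
        marker_mb = sub["physical_mb"].to_numpy()
        eval_cm = [marker_cm[0]]
        is_marker = [True]
        for j in range(len(marker_cm) - 1):
            lo, hi = marker_cm[j], marker_cm[j + 1]
            if step_cm > 0 and hi - lo > step_cm:
                inner = np.arange(lo + step_cm, hi - 1e-9, step_cm)
                eval_cm.extend(inner)
                is_marker.extend([False] * len(inner))
            eval_cm.append(hi)
            is_marker.append(True)
        eval_cm = np.asarray(eval_cm)
        is_marker = np.asarray(is_marker)

        X = matrix.chrom_codes(chrom).to_numpy()
        m_eval = len(eval_cm)
        Xa = np.full((X.shape[0], m_eval), MISSING, dtype=np.int8)
        Xa[:, is_marker] = X
        E = emission_likelihoods(Xa, error_prob)
        R = ril_observed(inv(np.diff(eval_cm)))
        alpha, beta = forward_backward(E, R)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        probs.append(gamma[:, :, 1].T)  # P(state = B), n_lines x m_eval

        names = np.where(is_marker, sub["marker"].to_numpy()[np.cumsum(is_marker) - 1], "")
        mb = np.interp(eval_cm, marker_cm, marker_mb)
        pos_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "cm": eval_cm,
                    "physical_mb": mb,
                    "is_marker": is_marker,
                    "name": names,
                }
            )
        )
    positions = pd.concat(pos_frames, ignore_index=True)
    return GenoProbGrid(positions=positions, prob_b=np.hstack(probs), lines=matrix.lines)


def _lod_from_corr(rho2: np.ndarray, n: int) -> np.ndarray:
    # single-regressor identity: RSS1 = RSS0 * (1 - rho^2)
    return -(n / 2.0) * np.log10(np.clip(1.0 - rho2, 1e-300, None))


def scan_single_qtl(probs: GenoProbGrid, trait: pd.Series, name: str | None = None) -> LodCurve:
    """Haley-Knott regression of one trait on P(B) at every position.

    Lines with missing trait values are dropped; needs at least three
    informative lines.  A zero-variance trait yields an all-zero curve
    with a warning.
    """
    name = name if name is not None else (trait.name or "trait")
    y = trait.reindex(probs.lines).to_numpy(dtype=float)
    keep = ~np.isnan(y)
    if keep.sum() < 3:
        raise ValueError("need at least three lines with trait values")
    y = y[keep]
    P = probs.prob_b[keep]
    n = len(y)
    yc = y - y.mean()
    y_ss = yc @ yc
    if y_ss == 0:
        warnings.warn(f"trait {name!r} has zero variance; LOD curve is all zero", stacklevel=2)
        return LodCurve(probs.positions, np.zeros(P.shape[1]), name, n)
    Pc = P - P.mean(axis=0)
    p_ss = (Pc * Pc).sum(axis=0)
    cov = yc @ Pc
    with np.errstate(divide="ignore", invalid="ignore"):
        rho2 = np.where(p_ss > 0, cov**2 / (p_ss * y_ss), 0.0)
    return LodCurve(probs.positions, _lod_from_corr(rho2, n), name, n)


def find_peaks(curve: LodCurve, sig_lod: float = 3.0) -> pd.DataFrame:
    """Per-chromosome LOD peak calls for one trait."""
    rows = []
    for chrom in dict.fromkeys(curve.positions["chrom"]):
        pos, lod = curve.chrom_slice(chrom)
        k = int(np.argmax(lod))
        rows.append(
            {
                "trait": curve.trait,
                "chrom": chrom,
                "peak_cm": float(pos["cm"].iloc[k]),
                "peak_mb": float(pos["physical_mb"].iloc[k]),
                "lod": float(lod[k]),
                "significant": bool(lod[k] > sig_lod),
            }
        )
    return pd.DataFrame(rows)


def permutation_threshold(
    probs: GenoProbGrid,
    trait: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide significance threshold from phenotype permutations.

    Shuffles the whole phenotype vector (preserving its distribution)
    ``n_perm`` times, records each genome-wide maximum LOD, and returns
    the empirical ``1 - alpha`` quantile (linear/type-7 interpolation).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    y = trait.reindex(probs.lines).to_numpy(dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    P = probs.prob_b[keep]
    n = len(y)
    rng = np.random.default_rng(seed)
    Y = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)  # n_perm x n
    Yc = Y - Y.mean(axis=1, keepdims=True)
    y_ss = (Yc * Yc).sum(axis=1)
    if np.all(y_ss == 0):
        return 0.0
    Pc = P - P.mean(axis=0)
    p_ss = (Pc * Pc).sum(axis=0)
    cov = Yc @ Pc  # n_perm x n_positions
    with np.errstate(divide="ignore", invalid="ignore"):
        rho2 = np.where(p_ss > 0, cov**2 / np.outer(y_ss, p_ss), 0.0)
    maxima = _lod_from_corr(rho2.max(axis=1), n)
    return float(np.quantile(maxima, 1.0 - alpha))


def lod_support_interval(
    curve: LodCurve,
    chrom: str,
    drop: float = 1.0,
    fit: tuple[float, float] | None = None,
    extend_to_flanking: bool = True,
) -> dict:
    """LOD-drop support interval around the chromosome peak.

    The interval spans the outermost evaluated positions with
    ``LOD >= peak - drop``; with ``extend_to_flanking`` it is widened to
    the next evaluated position on each side (one-sided at chromosome
    ends).  ``fit = (slope_mb_per_cm, intercept_mb)`` converts the cM
    endpoints to physical Mbp; without a fit the positions' interpolated
    physical coordinates are used instead.
    """
    pos, lod = curve.chrom_slice(chrom)
    if len(pos) == 0:
        raise ValueError(f"no positions on chromosome {chrom!r}")
    k = int(np.argmax(lod))
    peak_lod = float(lod[k])
    sel = np.flatnonzero(lod >= peak_lod - drop)
    lo, hi = int(sel.min()), int(sel.max())
    if extend_to_flanking:
        lo = max(lo - 1, 0)
        hi = min(hi + 1, len(pos) - 1)
    cm_lo, cm_hi = float(pos["cm"].iloc[lo]), float(pos["cm"].iloc[hi])
    if fit is not None:
        slope, intercept = fit
        mb_lo = intercept + slope * cm_lo
        mb_hi = intercept + slope * cm_hi
    else:
        mb_lo = float(pos["physical_mb"].iloc[lo])
        mb_hi = float(pos["physical_mb"].iloc[hi])
    mb_lo, mb_hi = sorted((mb_lo, mb_hi))
    return {
        "chrom": chrom,
        "peak_cm": float(pos["cm"].iloc[k]),
        "peak_mb": float(pos["physical_mb"].iloc[k]),
        "peak_lod": peak_lod,
        "cm_lo": cm_lo,
        "cm_hi": cm_hi,
        "mb_lo": float(mb_lo),
        "mb_hi": float(mb_hi),
        "width_mb": float(mb_hi - mb_lo),
    }


def scan_traits(
    probs: GenoProbGrid,
    phenotypes: pd.DataFrame,
    sig_lod: float = 3.0,
    lod_drop: float = 1.0,
    fits: dict | None = None,
) -> pd.DataFrame:
    """Scan every trait and collect peaks with LOD-drop intervals.

    ``fits`` maps chromosome to the genetic-to-physical fit (as produced
    by :func:`binmap.linkage.map_summary`); when given, support-interval
    endpoints are converted through it.  Intervals are reported for
    significant peaks only.
    """
    frames = []
    for trait in phenotypes.columns:
        curve = scan_single_qtl(probs, phenotypes[trait], name=trait)
        peaks = find_peaks(curve, sig_lod=sig_lod)
        ci_cols = {c: [] for c in ("cm_lo", "cm_hi", "mb_lo", "mb_hi", "width_mb")}
        for _, row in peaks.iterrows():
            if row["significant"]:
                fit3 = fits.get(row["chrom"]) if fits else None
                fit = fit3[:2] if fit3 is not None else None
                ci = lod_support_interval(curve, row["chrom"], drop=lod_drop, fit=fit)
                for c in ci_cols:
                    ci_cols[c].append(ci[c])
            else:
                for c in ci_cols:
                    ci_cols[c].append(np.nan)
        for c, vals in ci_cols.items():
            peaks[c] = vals
        frames.append(peaks)
    return pd.concat(frames, ignore_index=True)
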