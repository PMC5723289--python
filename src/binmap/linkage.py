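"""Genetic map estimation for selfed RIL populations.

Marker order is taken from the physical positions (the markers are bins
anchored on the genome sequence); what is estimated is the genetic
distance between adjacent markers.  Each chromosome is modelled as a
hidden two-state Markov chain per line — hidden parental origin with
stationary distribution (1/2, 1/2), switch probability ``R_j`` between
adjacent markers, and a symmetric genotyping-error emission (observed
code equals the hidden state with probability ``1 - error_prob``; missing
observations are uninformative).  The interval fractions ``R_j`` are
fitted by EM (forward-backward expected transition counts), corrected to
meiotic fractions ``r_j = R_j / (2(1 - R_j))`` and converted to
centimorgans with the Kosambi (default) or Haldane map function.

With ``error_prob = 0`` and complete data the EM fixed point is reached in
one step and equals the directly counted adjacent-pair recombinant
fraction, which is the property the estimator is validated against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .mapfunc import haldane_cm, kosambi_cm, kosambi_r, haldane_r, ril_meiotic, ril_observed
from .popgen import count_crossovers

R_CAP = 0.4999  # keeps the meiotic fraction < 0.5 and map distances finite


@dataclass
class GeneticMap:
    """Ordered markers with genetic and physical positions per chromosome."""

    table: pd.DataFrame  # marker, chrom, physical_mb, cm
    map_function: str = "kosambi"
    error_prob: float = 0.0
    converged: dict = field(default_factory=dict)
    n_iter: dict = field(default_factory=dict)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def chrom_length_cm(self, chrom: str) -> float:
        cm = self.chrom_table(chrom)["cm"]
        return float(cm.iloc[-1] - cm.iloc[0]) if len(cm) else 0.0

    @property
    def total_length_cm(self) -> float:
        return float(sum(self.chrom_length_cm(c) for c in self.chromosomes))

    def intervals(self, chrom: str) -> pd.DataFrame:
        """Per adjacent-marker interval: d (cM), meiotic r, observed R."""
        d = np.diff(self.chrom_table(chrom)["cm"].to_numpy())
        inv = kosambi_r if self.map_function == "kosambi" else haldane_r
        r = inv(d)
        return pd.DataFrame({"d_cm": d, "r": r, "R": ril_observed(r)})

    def genetic_to_physical_fit(self, chrom: str) -> tuple[float, float, float]:
        """Least-squares fit physical_mb = a + b * cM; returns (b, a, r2)."""
        sub = self.chrom_table(chrom)
        x = sub["cm"].to_numpy()
        y = sub["physical_mb"].to_numpy()
        if len(x) < 2 or np.ptp(x) == 0:
            return float("nan"), float("nan"), float("nan")
        b, a = np.polyfit(x, y, 1)
        resid = y - (a + b * x)
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else float("nan")
        return float(b), float(a), float(r2)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, map_function: str = "kosambi") -> "GeneticMap":
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(table=table, map_function=map_function)


@dataclass
class PairwiseLinkage:
    """Symmetric marker x marker matrices of R-hat and linkage LOD."""

    rf: pd.DataFrame
    lod: pd.DataFrame
    n: pd.DataFrame


def pairwise_rf(matrix: GenotypeMatrix, cap: tuple[float, float] = (1e-6, 0.5)) -> PairwiseLinkage:
    """Two-point recombination fractions and linkage LODs for all pairs.

    For each marker pair, over the lines non-missing at both: R-hat is the
    recombinant fraction (capped to ``cap``) and
    ``LOD = x*log10(2R) + (n-x)*log10(2(1-R))`` for ``x`` recombinants of
    ``n``.  Pairs with fewer than two informative lines are NaN.  Used as
    the marker-order diagnostic; it performs no reordering.
    """
    names = list(matrix.codes.columns)
    if len(names) < 2:
        raise ValueError("need at least two markers")
    X = matrix.codes.to_numpy().astype(float)
    V = (X != MISSING).astype(float)
    S = np.where(X == MISSING, 0.0, 2.0 * X - 1.0)  # +1 = B, -1 = A, 0 = missing
    n = V.T @ V
    agree = S.T @ S  # matches minus mismatches among co-observed lines
    x = (n - agree) / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(n > 0, x / n, np.nan)
    Rc = np.clip(R, cap[0], cap[1])
    with np.errstate(invalid="ignore"):
        lod = x * np.log10(2.0 * Rc) + (n - x) * np.log10(2.0 * (1.0 - Rc))
    bad = n < 2
    Rc = np.where(bad, np.nan, Rc)
    lod = np.where(bad, np.nan, lod)
    np.fill_diagonal(Rc, 0.0)
    idx = pd.Index(names)
    return PairwiseLinkage(
        rf=pd.DataFrame(Rc, index=idx, columns=idx),
        lod=pd.DataFrame(lod, index=idx, columns=idx),
        n=pd.DataFrame(n.astype(int), index=idx, columns=idx),
    )


def _adjacent_complete_case_R(X: np.ndarray) -> np.ndarray:
    """Initial interval estimates from directly counted adjacent pairs."""
    left, right = X[:, :-1], X[:, 1:]
    ok = (left != MISSING) & (right != MISSING)
    n = ok.sum(axis=0)
    x = ((left != right) & ok).sum(axis=0)
    with np.errstate(invalid="ignore"):
        R = np.where(n > 0, x / np.maximum(n, 1), 0.01)
    return np.clip(R, 1e-6, R_CAP)


def emission_likelihoods(X: np.ndarray, error_prob: float) -> np.ndarray:
    """Per line x marker x hidden-state emission likelihoods.

    Observed codes match the hidden state with probability
    ``1 - error_prob``; missing observations emit likelihood 1.
    """
    n_lines, m = X.shape
    E = np.ones((n_lines, m, 2))
    obs = X != MISSING
    for s in (0, 1):
        E[:, :, s] = np.where(obs, np.where(X == s, 1.0 - error_prob, error_prob), 1.0)
    return E


def forward_backward(E: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward/backward passes of the two-state symmetric chain.

    ``E`` is (n_lines, m, 2); ``R`` the m-1 switch probabilities.  Returns
    per-position alpha and beta arrays of shape (m, n_lines, 2), each
    normalised per line and position; the state posterior is proportional
    to ``alpha * beta``.
    """
    n_lines, m, _ = E.shape
    alpha = np.empty((m, n_lines, 2))
    a = 0.5 * E[:, 0, :]
    alpha[0] = a / a.sum(axis=1, keepdims=True)
    for j in range(m - 1):
        r = R[j]
        prev = alpha[j]
        a0 = prev[:, 0] * (1 - r) + prev[:, 1] * r
        a1 = prev[:, 0] * r + prev[:, 1] * (1 - r)
        a = np.stack([a0, a1], axis=1) * E[:, j + 1, :]
        alpha[j + 1] = a / a.sum(axis=1, keepdims=True)
    beta = np.empty((m, n_lines, 2))
    beta[m - 1] = 1.0
    for j in range(m - 2, -1, -1):
        r = R[j]
        nxt = beta[j + 1] * E[:, j + 1, :]
        b0 = nxt[:, 0] * (1 - r) + nxt[:, 1] * r
        b1 = nxt[:, 0] * r + nxt[:, 1] * (1 - r)
        b = np.stack([b0, b1], axis=1)
        beta[j] = b / b.sum(axis=1, keepdims=True)
    return alpha, beta


def _em_chromosome(
    X: np.ndarray, error_prob: float, tol: float, max_iter: int
) -> tuple[np.ndarray, bool, int]:
    """EM for one chromosome; returns (R per interval, converged, n_iter)."""
    n_lines, m = X.shape
    if m < 2:
        return np.zeros(0), True, 0
    E = emission_likelihoods(X, error_prob)

    R = _adjacent_complete_case_R(X)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        alpha, beta = forward_backward(E, R)
        # expected recombinant transitions per interval
        R_new = np.empty_like(R)
        for j in range(m - 1):
            r = R[j]
            right = beta[j + 1] * E[:, j + 1, :]
            num_same = alpha[j][:, 0] * (1 - r) * right[:, 0] + alpha[j][:, 1] * (1 - r) * right[:, 1]
            num_diff = alpha[j][:, 0] * r * right[:, 1] + alpha[j][:, 1] * r * right[:, 0]
            R_new[j] = (num_diff / (num_same + num_diff)).mean()
        R_new = np.clip(R_new, 0.0, R_CAP)
        if np.max(np.abs(R_new - R)) < tol:
            R = R_new
            converged = True
            break
        R = R_new
    return R, converged, it


def estimate_map(
    matrix: GenotypeMatrix,
    error_prob: float = 1e-4,
    map_function: str = "kosambi",
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> GeneticMap:
    """Multipoint EM estimation of the genetic map.

    Per chromosome the adjacent-interval observed fractions ``R_j`` are
    fitted by EM under the hidden-chain model described in the module
    docstring, then RIL-corrected and converted to cM; positions are the
    cumulative distances with the first marker at 0.  Non-convergence
    within ``max_iter`` returns the last iterate with a warning and a
    False flag in ``converged``.
    """
    if map_function not in ("kosambi", "haldane"):
        raise ValueError(f"unknown map function {map_function!r}")
    to_cm = kosambi_cm if map_function == "kosambi" else haldane_cm
    rows = []
    converged_flags: dict = {}
    iters: dict = {}
    for chrom in matrix.chromosomes:
        sub = matrix.chrom_markers(chrom)
        X = matrix.chrom_codes(chrom).to_numpy()
        R, ok, it = _em_chromosome(X, error_prob, tol, max_iter)
        converged_flags[chrom] = ok
        iters[chrom] = it
        if not ok:
            warnings.warn(f"EM did not converge on chromosome {chrom} after {it} iterations", stacklevel=2)
        d = to_cm(ril_meiotic(R)) if len(R) else np.zeros(0)
        cm = np.concatenate([[0.0], np.cumsum(d)])
        for (_, mk), pos in zip(sub.iterrows(), cm):
            rows.append(
                {"marker": mk["name"], "chrom": chrom, "physical_mb": mk["midpoint_mb"], "cm": pos}
            )
    return GeneticMap(
        table=pd.DataFrame(rows),
        map_function=map_function,
        error_prob=error_prob,
        converged=converged_flags,
        n_iter=iters,
    )


@dataclass
class MapSummary:
    per_chrom: pd.DataFrame
    totals: dict
    fits: dict  # chrom -> (slope_mb_per_cm, intercept_mb, r2)


def map_summary(gmap: GeneticMap, matrix: GenotypeMatrix) -> MapSummary:
    """Map characteristics table: lengths, spacing, gaps, crossovers, rates.

    The recombination rate is reported two ways per chromosome: the span
    ratio (physical span in kbp over map length in cM) and 1000x the slope
    of the genetic-to-physical least-squares fit.  The genome-wide rate in
    the totals row is the mean of the per-chromosome span ratios; the
    genome-wide average spacing is total length over total interval count.
    """
    xo = count_crossovers(matrix).per_chromosome()
    rows = []
    fits = {}
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_table(chrom)
        m = len(sub)
        length = gmap.chrom_length_cm(chrom)
        gaps = np.diff(sub["cm"].to_numpy())
        span_mb = float(sub["physical_mb"].max() - sub["physical_mb"].min())
        slope, intercept, r2 = gmap.genetic_to_physical_fit(chrom)
        fits[chrom] = (slope, intercept, r2)
        rows.append(
            {
                "chrom": chrom,
                "n_markers": m,
                "length_cm": length,
                "avg_spacing_cm": length / (m - 1) if m > 1 else float("nan"),
                "max_gap_cm": float(gaps.max()) if len(gaps) else float("nan"),
                "n_crossovers": int(xo.get(chrom, 0)),
                "rate_kbp_per_cm": 1000.0 * span_mb / length if length > 0 else float("nan"),
                "fit_rate_kbp_per_cm": 1000.0 * slope,
                "fit_r2": r2,
            }
        )
    per_chrom = pd.DataFrame(rows)
    n_intervals = int((per_chrom["n_markers"] - 1).clip(lower=0).sum())
    totals = {
        "n_markers": int(per_chrom["n_markers"].sum()),
        "length_cm": float(per_chrom["length_cm"].sum()),
        "avg_spacing_cm": float(per_chrom["length_cm"].sum() / n_intervals) if n_intervals else float("nan"),
        "max_gap_cm": float(per_chrom["max_gap_cm"].max()),
        "n_crossovers": int(per_chrom["n_crossovers"].sum()),
        "rate_kbp_per_cm": float(per_chrom["rate_kbp_per_cm"].mean()),
    }
    return MapSummary(per_chrom=per_chrom, totals=totals, fits=fits)


def export_rqtl_csvr(matrix: GenotypeMatrix, gmap: GeneticMap, phenotypes: pd.DataFrame, path) -> None:
    """Export genotypes + map (+ phenotypes) in the R/qtl "csvr" layout.

    One row per phenotype (name, two blanks, values) then one row per
    marker (name, chromosome, cM, A/B/- genotypes), individuals as
    columns — convenient for cross-validating the map or scans in R/qtl.
    """
    lines = matrix.lines
    with open(path, "w") as fh:
        ph = phenotypes.reindex(lines)
        for trait in ph.columns:
            vals = ",".join("" if pd.isna(v) else repr(float(v)) for v in ph[trait])
            fh.write(f"{trait},,,{vals}\n")
        code_map = {0: "A", 1: "B", MISSING: "-"}
        pos = gmap.table.set_index("marker")
        for name in matrix.codes.columns:
            chrom = pos.loc[name, "chrom"]
            cm = pos.loc[name, "cm"]
            genos = ",".join(code_map[int(v)] for v in matrix.codes[name])
            fh.write(f"{name},{chrom},{cm:.6f},{genos}\n")
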