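import itertools

import numpy as np
import pandas as pd
import pytest

import binmap as bm
from binmap.core import A, B, MISSING
from binmap.linkage import GeneticMap
from binmap.mapfunc import kosambi_r, ril_observed
from binmap.qtl import LodCurve
from tests.conftest import make_matrix


def chain_map(cm_positions, chrom="1", kbp_per_cm=250.0):
    rows = [
        {
            "marker": f"RSM_{chrom}_{(0.05 + 0.1 * j):.2f}",
            "chrom": chrom,
            "physical_mb": 0.05 + 0.1 * j,
            "cm": c,
        }
        for j, c in enumerate(cm_positions)
    ]
    return GeneticMap(pd.DataFrame(rows))


def enumerate_posterior(obs, R, error_prob):
    """Exhaustive-path posterior P(state=B) for a short hidden chain."""
    m = len(obs)
    post = np.zeros(m)
    total = 0.0
    for path in itertools.product((0, 1), repeat=m):
        p = 0.5
        for j in range(m - 1):
            p *= R[j] if path[j] != path[j + 1] else 1 - R[j]
        for j in range(m):
            if obs[j] != MISSING:
                p *= (1 - error_prob) if obs[j] == path[j] else error_prob
        total += p
        for j in range(m):
            if path[j] == 1:
                post[j] += p
    return post / total


class TestGenotypeProbabilities:
    def test_observed_markers_are_certain_without_error(self):
        codes = np.array([[A, B, B], [B, A, A]], dtype=np.int8)
        mat = make_matrix(codes)
        gmap = chain_map([0.0, 5.0, 10.0])
        probs = bm.genotype_probabilities(mat, gmap, error_prob=0.0)
        assert np.allclose(probs.prob_b, codes.astype(float))

    @pytest.mark.parametrize(
        "obs,cm,eps",
        [
            ([A, MISSING, A], [0.0, 5.56, 11.12], 0.0),  # flanks A at R ~ 0.1 each
            ([A, MISSING, B], [0.0, 5.0, 10.0], 0.0),
            ([A, B, MISSING, B], [0.0, 3.0, 9.0, 14.0], 0.01),
            ([B, MISSING, MISSING, A], [0.0, 2.0, 7.0, 20.0], 0.02),
        ],
    )
    def test_posterior_matches_exhaustive_enumeration(self, obs, cm, eps):
        mat = make_matrix(np.array([obs], dtype=np.int8))
        gmap = chain_map(cm)
        probs = bm.genotype_probabilities(mat, gmap, error_prob=eps)
        R = ril_observed(kosambi_r(np.diff(cm)))
        oracle = enumerate_posterior(obs, R, eps)
        assert np.allclose(probs.prob_b[0], oracle, atol=1e-10)

    def test_symmetric_flanks_give_half(self):
        mat = make_matrix(np.array([[A, MISSING, B]], dtype=np.int8))
        gmap = chain_map([0.0, 5.0, 10.0])
        probs = bm.genotype_probabilities(mat, gmap, error_prob=0.0)
        assert probs.prob_b[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_pseudo_position_grid(self):
        mat = make_matrix(np.array([[A, B]], dtype=np.int8))
        gmap = chain_map([0.0, 10.0])
        probs = bm.genotype_probabilities(mat, gmap, step_cm=2.0, error_prob=0.0)
        pos = probs.positions
        assert pos["is_marker"].sum() == 2
        assert len(pos) == 6  # markers at 0,10 plus pseudo at 2,4,6,8
        # posterior rises monotonically from the A flank to the B flank
        assert np.all(np.diff(probs.prob_b[0]) > 0)
        # physical interpolation between the flanking markers
        assert pos["physical_mb"].iloc[1] == pytest.approx(0.05 + 0.1 * 0.2)


class TestScanSingleQtl:
    def test_lod_formula_value(self):
        # construct data with a known RSS ratio via the correlation identity:
        # rho^2 = 0.5  <=>  RSS0/RSS1 = 2, so LOD = (n/2) log10 2
        rng = np.random.default_rng(1)
        n = 100
        g = rng.integers(0, 2, n).astype(float)
        resid = rng.normal(size=n)
        resid -= np.polyval(np.polyfit(g, resid, 1), g)  # orthogonal to g
        g_c = g - g.mean()
        y = g_c / np.linalg.norm(g_c) + resid / np.linalg.norm(resid)  # rho^2 = 1/2
        probs = bm.GenoProbGrid(
            positions=pd.DataFrame(
                {"chrom": ["1"], "cm": [0.0], "physical_mb": [0.05], "is_marker": [True], "name": ["m"]}
            ),
            prob_b=g[:, None],
            lines=[f"l{i}" for i in range(n)],
        )
        curve = bm.scan_single_qtl(probs, pd.Series(y, index=probs.lines))
        assert curve.lod[0] == pytest.approx(50 * np.log10(2), abs=1e-8)

    def test_equals_direct_marker_regression_on_complete_data(self, small_genome):
        """Haley-Knott at fully observed markers reduces to single-marker regression."""
        config = bm.SimConfig(n_lines=80, seed=37, qtls=[("t", "1", 2_050_000, 0.3)])
        truth = bm.simulate_ril_genotypes(small_genome, config)
        pheno, _ = bm.simulate_phenotypes(truth, config)
        mat = truth.to_matrix()
        gmap = bm.estimate_map(mat, error_prob=0.0)
        probs = bm.genotype_probabilities(mat, gmap, error_prob=0.0)
        curve = bm.scan_single_qtl(probs, pheno["t"])

        y = pheno["t"].to_numpy()
        n = len(y)
        rss0 = ((y - y.mean()) ** 2).sum()
        X = mat.codes.to_numpy().astype(float)
        for j in range(X.shape[1]):
            beta = np.polyfit(X[:, j], y, 1) if np.ptp(X[:, j]) > 0 else (0.0, y.mean())
            rss1 = ((y - np.polyval(beta, X[:, j])) ** 2).sum()
            lod_direct = (n / 2) * np.log10(rss0 / rss1)
            assert curve.lod[j] == pytest.approx(lod_direct, abs=1e-8)

    def test_zero_variance_trait_warns(self):
        probs = bm.GenoProbGrid(
            positions=pd.DataFrame(
                {"chrom": ["1"], "cm": [0.0], "physical_mb": [0.05], "is_marker": [True], "name": ["m"]}
            ),
            prob_b=np.array([[0.0], [1.0], [0.0]]),
            lines=["a", "b", "c"],
        )
        with pytest.warns(UserWarning):
            curve = bm.scan_single_qtl(probs, pd.Series([1.0, 1.0, 1.0], index=["a", "b", "c"]))
        assert np.all(curve.lod == 0)

    def test_needs_three_lines(self):
        probs = bm.GenoProbGrid(
            positions=pd.DataFrame(
                {"chrom": ["1"], "cm": [0.0], "physical_mb": [0.05], "is_marker": [True], "name": ["m"]}
            ),
            prob_b=np.array([[0.0], [1.0], [0.5]]),
            lines=["a", "b", "c"],
        )
        with pytest.raises(ValueError):
            bm.scan_single_qtl(probs, pd.Series([1.0, 2.0, np.nan], index=["a", "b", "c"]))


def _population_probs(seed=41, n_lines=60):
    genome = bm.SimGenome((bm.SimChromosome("1", 5_000_000, 20.0, 2_500_000, 0),))
    config = bm.SimConfig(n_lines=n_lines, seed=seed)
    truth = bm.simulate_ril_genotypes(genome, config)
    mat = truth.to_matrix()
    gmap = bm.estimate_map(mat, error_prob=0.0)
    return bm.genotype_probabilities(mat, gmap, error_prob=0.0)


class TestPermutationThreshold:
    def test_alpha_one_is_minimum(self):
        probs = _population_probs()
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=60), index=probs.lines)
        tmin = bm.permutation_threshold(probs, y, n_perm=50, alpha=1.0, seed=9)
        t95 = bm.permutation_threshold(probs, y, n_perm=50, alpha=0.05, seed=9)
        assert tmin <= t95

    def test_constant_trait_threshold_zero(self):
        probs = _population_probs()
        y = pd.Series(np.ones(60), index=probs.lines)
        assert bm.permutation_threshold(probs, y, n_perm=20, seed=1) == 0.0

    def test_seeded_determinism(self):
        probs = _population_probs()
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(size=60), index=probs.lines)
        t1 = bm.permutation_threshold(probs, y, n_perm=100, seed=4)
        t2 = bm.permutation_threshold(probs, y, n_perm=100, seed=4)
        assert t1 == t2


class TestLodSupportInterval:
    @staticmethod
    def curve_from(cm, lod, chrom="1"):
        positions = pd.DataFrame(
            {
                "chrom": chrom,
                "cm": cm,
                "physical_mb": np.asarray(cm) * 0.25,
                "is_marker": True,
                "name": [f"m{j}" for j in range(len(cm))],
            }
        )
        return LodCurve(positions, np.asarray(lod, dtype=float), "t", 100)

    def test_flat_curve_spans_chromosome(self):
        curve = self.curve_from([0, 5, 10, 15], [4.0, 4.0, 4.0, 4.0])
        ci = bm.lod_support_interval(curve, "1")
        assert ci["cm_lo"] == 0 and ci["cm_hi"] == 15

    def test_triangular_curve_halfwidth(self):
        # slope 0.5 LOD/cM: LOD-1 crossing 2 cM either side of the peak
        cm = np.arange(0, 21.0)
        lod = 5.0 - 0.5 * np.abs(cm - 10.0)
        curve = self.curve_from(cm, lod)
        ci = bm.lod_support_interval(curve, "1", drop=1.0, extend_to_flanking=False)
        assert ci["cm_lo"] == pytest.approx(8.0)
        assert ci["cm_hi"] == pytest.approx(12.0)
        extended = bm.lod_support_interval(curve, "1", drop=1.0)
        assert extended["cm_lo"] == pytest.approx(7.0)
        assert extended["cm_hi"] == pytest.approx(13.0)

    def test_linear_physical_conversion(self):
        cm = np.arange(0, 31.0)
        lod = 5.0 - 0.5 * np.abs(cm - 15.0)
        curve = self.curve_from(cm, lod)
        ci = bm.lod_support_interval(curve, "1", drop=2.5, fit=(0.25, 0.0), extend_to_flanking=False)
        assert (ci["cm_lo"], ci["cm_hi"]) == (10.0, 20.0)
        assert ci["mb_lo"] == pytest.approx(2.5)
        assert ci["mb_hi"] == pytest.approx(5.0)
        assert ci["width_mb"] == pytest.approx(2.5)

    def test_peak_at_chromosome_end_one_sided(self):
        cm = np.arange(0, 11.0)
        lod = 5.0 - 0.5 * cm
        curve = self.curve_from(cm, lod)
        ci = bm.lod_support_interval(curve, "1", drop=1.0)
        assert ci["cm_lo"] == 0.0
        assert ci["peak_cm"] == 0.0


def test_scan_traits_reports_intervals_for_significant_peaks(small_genome):
    config = bm.SimConfig(n_lines=120, seed=43, qtls=[("t", "1", 2_050_000, 0.4)], n_null_traits=1)
    truth = bm.simulate_ril_genotypes(small_genome, config)
    pheno, _ = bm.simulate_phenotypes(truth, config)
    mat = truth.to_matrix()
    gmap = bm.estimate_map(mat, error_prob=0.0)
    ms = bm.map_summary(gmap, mat)
    probs = bm.genotype_probabilities(mat, gmap, error_prob=0.0)
    peaks = bm.scan_traits(probs, pheno, fits=ms.fits)
    hit = peaks[(peaks["trait"] == "t") & (peaks["chrom"] == "1")].iloc[0]
    assert hit["significant"]
    assert hit["width_mb"] > 0
    # interval covers the causal position up to the bin resolution (0.1 Mbp)
    assert hit["mb_lo"] - 0.1 <= 2.05 <= hit["mb_hi"] + 0.1
    assert abs(hit["peak_mb"] - 2.05) < 1.5
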