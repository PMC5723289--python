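"""Why marker density matters: QTL interval widths on a dense vs sparse map.

Scans the same simulated traits on the full 100-kbp bin map and on a
69-marker thinning of the same population, then compares LOD scores and
LOD-1 confidence-interval widths between the two maps.
"""

import numpy as np

import binmap as bm

genome = bm.default_genome()
config = bm.SimConfig(n_lines=160, seed=33)
truth = bm.simulate_ril_genotypes(genome, config)

rng = np.random.default_rng(33)
config.qtls = [
    (f"trait{k:02d}", c.name, int(rng.uniform(0.1, 0.9) * c.length_bp), 0.30)
    for k in range(12)
    for c in [genome.chromosomes[rng.integers(0, 5)]]
]
pheno, _ = bm.simulate_phenotypes(truth, config)

dense = truth.to_matrix()
sparse = bm.thin_matrix(dense, 69)
gd = bm.estimate_map(dense, error_prob=0.0)
gs = bm.estimate_map(sparse, error_prob=0.0)
pd_ = bm.genotype_probabilities(dense, gd)
ps_ = bm.genotype_probabilities(sparse, gs)

peaks_dense = bm.scan_traits(pd_, pheno)
peaks_sparse = bm.scan_traits(ps_, pheno)

pairs, lod_summary = bm.compare_lod(peaks_sparse, peaks_dense)
shared, ci_summary = bm.compare_ci(peaks_sparse, peaks_dense)

table = bm.map_stats_table([("sparse (69)", gs, sparse), ("dense (bins)", gd, dense)])
print(table.round(2).to_string(index=False))
print(f"\nhigher-LOD QTLs on the dense map: {lod_summary['n_higher']}"
      f" of {lod_summary['n_significant_map1']} significant sparse-map QTLs")
print(f"CI width reduced on the dense map for {ci_summary['pct_reduced']:.0f}% "
      f"of {ci_summary['n_shared_significant']} shared QTLs")
print(f"median LOD-1 width: sparse {ci_summary['median_width_map1_mb']:.2f} Mbp "
      f"-> dense {ci_summary['median_width_map2_mb']:.2f} Mbp")
# The dense map cannot create recombination events, but it places the
# existing ones precisely, which is what shrinks the support intervals.
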