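"""Estimate a genetic map from a bin genotype matrix and summarise it.

The map estimator fits adjacent-interval recombination fractions by
multipoint EM under a hidden two-state chain with a genotyping-error
emission, corrects them for repeated selfing and converts to cM with the
Kosambi map function.
"""

import binmap as bm

genome = bm.default_genome()  # 5 chromosomes, 252.65 kbp/cM
config = bm.SimConfig(n_lines=160, seed=11)
truth = bm.simulate_ril_genotypes(genome, config)
matrix = truth.to_matrix()

gmap = bm.estimate_map(matrix, error_prob=0.0, map_function="kosambi")
summary = bm.map_summary(gmap, matrix)

cols = ["chrom", "n_markers", "length_cm", "avg_spacing_cm", "max_gap_cm", "n_crossovers", "rate_kbp_per_cm"]
print(summary.per_chrom[cols].round(2).to_string(index=False))
t = summary.totals
print(f"\ntotal: {t['n_markers']} markers, {t['length_cm']:.2f} cM, "
      f"average spacing {t['avg_spacing_cm']:.2f} cM, {t['n_crossovers']} crossovers, "
      f"{t['rate_kbp_per_cm']:.1f} kbp/cM")
true_total = sum(c.genetic_length_cm for c in genome.chromosomes)
print(f"simulated true total length: {true_total:.2f} cM")
# The per-chromosome genetic-to-physical fits (summary.fits) give the
# slope in Mbp/cM used to place QTL support intervals on the genome.
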