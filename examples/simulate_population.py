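"""Simulate a small RIL population and inspect its recombination structure.

A selfed RIL genome is a mosaic of the two parental haplotypes; the
simulator draws each line as a two-state Markov chain along a 100-kbp bin
grid, with switch probabilities from the Kosambi map function and the
selfed-RIL correction R = 2r/(1+2r).
"""

import binmap as bm

genome = bm.SimGenome(
    (
        bm.SimChromosome("1", 10_000_000, 40.0, 5_000_000, 1_000_000),
        bm.SimChromosome("2", 6_000_000, 24.0, 3_000_000, 800_000),
    )
)
config = bm.SimConfig(n_lines=100, seed=7)
truth = bm.simulate_ril_genotypes(genome, config)

counts = truth.crossover_counts()
print(f"{config.n_lines} lines on {len(genome.chromosomes)} chromosomes "
      f"({truth.genotypes.shape[1]} bin loci)")
print(f"total crossovers: {len(truth.crossovers)}")
print(f"mean crossovers per line: {counts.groupby('line')['n_crossovers'].sum().mean():.2f}")
balance = (truth.genotypes.to_numpy() == bm.A).mean()
print(f"pooled parent-A allele fraction: {balance:.3f}  (expected ~0.5, no distortion)")
# Each line carries on average 2 crossovers per Morgan of map length --
# the extra factor of ~2 over a single meiosis comes from repeated selfing.
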