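# Methods

## Population model

All estimators assume a fully selfed bi-parental RIL population: each
line is homozygous at every locus for one of the two parental haplotypes,
so a genome is a two-state mosaic along each chromosome. Two
recombination-fraction conventions are kept strictly separate. The
per-meiosis fraction between two loci is `r`; repeated selfing
accumulates recombination until fixation, so the fraction of recombinant
*lines* observed in the final population is the Haldane-Waddington
equilibrium `R = 2r/(1+2r)`. Map distances use the Kosambi function
`d = 25 ln((1+2r)/(1-2r))` cM by default (partial crossover
interference); Haldane is available. `R` is capped at 0.4999 throughout
so that `r < 0.5` and distances stay finite.

## Simulator

`simulate_ril_genotypes` draws each line directly at the midpoints of the
100-kbp bin grid as a Markov chain with switch probability `R_j` per
interval, `r_j` from the inverse Kosambi of the interval's map distance.
This is exactly the stationary model the map estimator assumes, which is
deliberate: the estimators, not the breeding history, are under test.
Generation-by-generation meiosis, crossover interference and residual
heterozygosity are not modelled; lines are treated as fully fixed (the
residual heterozygosity of a real F6 panel, unstated in most study
designs, is assumed 0). True crossover positions are drawn uniformly
within the interval where the state switches and recorded exactly.

The default genome has five chromosomes of 30.4/19.7/23.5/18.6/27.0 Mbp
with genetic lengths derived from a uniform 252.65 kbp/cM — the scale of
the *A. thaliana* Bay-0 x Sha population this design emulates — and
centromere windows of ±1.5 Mbp around approximate *A. thaliana*
centromere positions.

SNP sites are placed uniformly at a mean density of 24 per 100 kbp
(configurable) and thinned to 10% inside centromere windows, emulating
the transcriptome-derived SNP deserts of centromeric regions. Each
RIL x SNP call equals the line's true genotype at the *bin* containing
the SNP, flipped with probability `error_prob` and dropped with
probability `dropout_prob`; parent replicates are emitted noiseless.
What this noise model does **not** capture: read-depth-dependent error,
allele-specific expression bias, alignment artefacts, and
expression-level variation between lines. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
noise model, not robustness to every artefact of real RNA-seq data.

Segregation distortion is implemented as viability selection by rejection
resampling at one locus (a line carrying the disfavoured allele is
regenerated with probability `(1-s)/s` for survival ratio `s`); linked
markers inherit the distortion through linkage, as in real data.

Phenotypes are additive: `trait = sum_i a_i * 1[g_i = B] + e`, with
`a_i` scaled against the empirical indicator variance so each QTL
explains its stated fraction of a unit total variance, and Gaussian noise
filling the remainder.

## Genotyping and binning

The parental consistency filter requires at least `min_replicates`
(default 2; the replicate quorum is a free parameter since published
pipelines rarely state one) homozygous calls per parent, within-parent
agreement, and different alleles between parents; indels and
multi-allelic records are dropped. Heterozygous RIL calls are coded
missing — under the two-class model they are most likely technical. VCF
coordinates are 1-based; bins are 0-based half-open windows, so a 1-based
position `p` belongs to bin `[s, e)` iff `s < p <= e`. Marker positions
are window midpoints; short terminal windows keep their true midpoint in
the marker name (2-decimal Mbp).

Bin scoring is a per-line majority vote; a determinate call needs only
one informative SNP (configurable). Transition resolution operationalises
"round to the closest genotypic score": a missing or tied bin takes the
shared genotype of its flanking determinate bins when they agree, the
physically closer flank's genotype when they disagree, and stays missing
on an exact distance tie (tolerance 1e-9 relative, so floating-point
noise cannot break symmetric cases). Terminal runs copy the single
available flank. Determinate cells are never altered.

## Map estimation

Marker order is fixed by physical position — bin markers are anchored on
the genome, so no de-novo ordering is attempted; `pairwise_rf` provides
the two-point R-hat/LOD matrices as an order diagnostic only. Per
chromosome, interval fractions `R_j` are fitted by EM on a hidden
two-state chain per line: stationary distribution (1/2, 1/2), transition
probability `R_j`, and a symmetric emission in which the observed code
matches the hidden state with probability `1 - error_prob` (default
1e-4, the customary value for this kind of multipoint estimator;
missing cells emit likelihood 1). The E-step is scaled forward-backward;
the M-step sets `R_j` to the mean expected transition count.
Initialisation uses complete-case adjacent-pair estimates capped to
[1e-6, 0.4999]; convergence when `max_j |dR_j| < 1e-6` (default) or
10,000 iterations, returning the last iterate with a warning otherwise.
With `error_prob = 0` and complete data the first M-step already equals
the directly counted recombinant fractions — the fixed point the tests
pin down. Zero-recombination regions (e.g. inversion-suppressed
segments) appear naturally as zero-length intervals.

Map summaries report the recombination rate both as the physical span
over map length per chromosome and as 1000x the slope of the
least-squares genetic-to-physical fit; the genome-wide figure is the mean
of per-chromosome span ratios, and the genome-wide average spacing is
total length over total interval count. These conventions do not coincide
exactly and are reported side by side rather than forced to agree.

## QTL scanning

Genotype probabilities are posteriors of the same hidden chain used for
map estimation, evaluated at markers (default) or on an inserted cM grid
with physical coordinates interpolated between flanking markers.
Scanning is Haley-Knott regression of the trait on P(B) — with two
genotype classes and smoothed probabilities this is a deterministic,
numerically exact surrogate for maximum-likelihood interval mapping at
RIL heritabilities, and on complete data it reduces to single-marker
regression exactly. LOD values are computed through the single-regressor
identity `RSS1 = RSS0 (1 - rho^2)`, clipping `1 - rho^2` at 1e-300.

Permutation thresholds shuffle whole phenotype vectors (preserving the
trait distribution), record genome-wide maximum LODs, and take the
empirical `1 - alpha` quantile with linear (type-7) interpolation.
Significance calls use a configurable stringent cutoff (default
LOD > 3) alongside the permutation threshold; both are reported.

LOD-drop support intervals span the outermost evaluated positions within
`drop` (default 1) of the peak and are widened to the next evaluated
position on each side (one-sided at chromosome ends). Two physical
conversions are available: the chromosome's genetic-to-physical
least-squares line (the convention of legacy-map workflows, used in the
map-comparison analyses) and the evaluation positions' own physical
anchors. For physically anchored bin markers the anchored conversion is
preferred and is what the validation suite uses for coverage: the fitted
line inherits the random-walk error of the cumulative cM positions
(~1 Mbp mid-chromosome at n = 160), which is larger than a typical
dense-map interval and degrades coverage for no benefit when exact
anchors exist.

Map comparisons classify shared trait x chromosome peaks as new, lost,
higher, lower or unchanged with an inclusive |dLOD| >= 0.5 boundary;
percentages are quoted against the reference map's significant-QTL count,
and mean |dLOD| is emitted under both conditionings (significant in
map1; significant in map2) because the published convention is ambiguous.
Comparisons are run on the intersection of lines (`intersect_lines`).

## Distortion testing

The segregation test is the exact two-sided binomial against 1:1 on the
non-missing counts, vectorised as twice the smaller tail (exact for the
symmetric null and identical to `scipy.stats.binomtest`), with
Bonferroni correction over all markers. Allele percentages are reported
over all lines — the convention of published allele-frequency figures —
while the test uses informative counts; both appear in the output.
Exactness matters at n = 160 and removes continuity-correction choices;
the discreteness of the exact test makes the Bonferroni screen
conservative, which the null-simulation check reflects. Missing cells do
not terminate genotype blocks when counting crossovers (conservative);
a strict break-on-missing variant is available by flag.

## Validation scale

The test suite validates against simulated truth at the sizes a desk
machine handles comfortably: oracle equivalences on small constructed
chains; parameter recovery on twenty 200-line full-genome populations
(chromosome lengths within 10% on the seed average, crossovers exact);
the distortion screen's family-wise error over 200 null populations of
160 lines; permutation calibration over 100 nested replicates of 1000
permutations each (false-positive rate within [2%, 8%] of nominal 5%);
and the resolution property — median LOD-1 physical width strictly
smaller on the full bin map than on a 69-marker thinning, with >= 80%
true-QTL coverage — over 50 planted-QTL traits at 30% explained variance.
The acceptance script runs the same pipeline once at full study scale
(160 lines, ~28k SNP sites through the VCF round trip) in about a minute.

## Known limitations

- No crossover interference in the simulator beyond what the Kosambi
  function absorbs; no residual heterozygosity; no read-level noise.
- No de-novo marker ordering or grouping; the pipeline trusts the
  physical anchors.
- Single-QTL scans only; no multiple-QTL or composite interval mapping.
- The transition-resolution rule is a local nearest-neighbour heuristic;
  genuinely ambiguous mid-transition bins stay missing by design.
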