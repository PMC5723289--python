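"""Seeded simulator for selfed RIL populations and their RNA-seq-style SNP calls.

The generator produces everything the downstream pipeline consumes — noisy
per-sample SNP calls (as VCFs), a legacy low-density marker map, phenotype
tables — together with a :class:`TruthSet` recording the true genotypes,
crossover positions and planted QTL effects for parameter-recovery checks.

Model
-----
Genotypes are simulated directly at the midpoints of fixed 100-kbp bins as
a two-state Markov chain per line and chromosome: the probability of a
parental-origin switch between adjacent loci is the observed RIL
recombination fraction ``R = 2r/(1+2r)`` with ``r`` obtained from the
inter-locus map distance through the inverse Kosambi function.  This is
the Haldane-Waddington equilibrium of repeated selfing and is exactly the
process the multipoint map estimator assumes; breeding history
(generation-by-generation meiosis, residual heterozygosity, crossover
interference) is deliberately not modelled.

SNP placement emulates expression-weighted marker density: positions are
drawn uniformly at a configurable mean density and thinned to ~10% inside
centromere windows, reproducing the centromeric SNP deserts of
transcriptome-derived variant calls.  Each RIL call equals the line's true
local genotype, flipped with probability ``error_prob`` and dropped with
probability ``dropout_prob``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import A, B, GenotypeMatrix, chrom_label
from .mapfunc import kosambi_r, ril_observed

CENTROMERE_SNP_RETENTION = 0.10

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimChromosome:
    name: str
    length_bp: int
    genetic_length_cm: float
    centromere_center_bp: int
    centromere_halfwidth_bp: int

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError("chromosome length must be positive")
        if self.genetic_length_cm < 0:
            raise ValueError("genetic length must be non-negative")
        lo = self.centromere_center_bp - self.centromere_halfwidth_bp
        hi = self.centromere_center_bp + self.centromere_halfwidth_bp
        if lo < 0 or hi > self.length_bp:
            raise ValueError("centromere interval must lie inside the chromosome")


@dataclass(frozen=True)
class SimGenome:
    chromosomes: tuple[SimChromosome, ...]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom(self, name: str) -> SimChromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def total_length_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)


def default_genome(kbp_per_cm: float = 252.65) -> SimGenome:
    """Five-chromosome genome emulating A. thaliana Bay-0 x Sha.

    Physical lengths 30.4/19.7/23.5/18.6/27.0 Mbp; genetic lengths derived
    from a uniform genome-wide recombination rate (default 252.65 kbp/cM).
    Centromere windows approximate the A. thaliana centromere positions.
    """
    sizes_mb = [30.4, 19.7, 23.5, 18.6, 27.0]
    cen_mb = [15.1, 3.6, 13.8, 4.0, 11.2]
    chroms = []
    for i, (size, cen) in enumerate(zip(sizes_mb, cen_mb), start=1):
        length = int(size * 1e6)
        chroms.append(
            SimChromosome(
                name=str(i),
                length_bp=length,
                genetic_length_cm=length / (kbp_per_cm * 1000.0),
                centromere_center_bp=int(cen * 1e6),
                centromere_halfwidth_bp=1_500_000,
            )
        )
    return SimGenome(tuple(chroms))


@dataclass
class SimConfig:
    """Population and noise-model parameters for one simulated study."""

    n_lines: int = 160
    error_prob: float = 0.0
    dropout_prob: float = 0.0
    snps_per_100kbp: float = 24.0
    bin_size_bp: int = 100_000
    distortion_locus: tuple[str, int, float] | None = None  # (chrom, pos_bp, survival_ratio)
    qtls: list[tuple[str, str, int, float]] = field(default_factory=list)  # (trait, chrom, pos_bp, var_fraction)
    n_null_traits: int = 0
    n_parent_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_prob < 0.5:
            raise ValueError("error_prob must lie in [0, 0.5)")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if self.n_lines <= 0:
            raise ValueError("n_lines must be positive")
        for _, _, _, frac in self.qtls:
            if not 0 < frac < 1:
                raise ValueError("QTL variance fractions must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "distortion_locus" in raw and raw["distortion_locus"] is not None:
            c, p, s = raw["distortion_locus"]
            raw["distortion_locus"] = (str(c), int(p), float(s))
        if "qtls" in raw:
            raw["qtls"] = [(str(t), str(c), int(p), float(f)) for t, c, p, f in raw["qtls"]]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "n_lines": self.n_lines,
            "error_prob": self.error_prob,
            "dropout_prob": self.dropout_prob,
            "snps_per_100kbp": self.snps_per_100kbp,
            "bin_size_bp": self.bin_size_bp,
            "distortion_locus": list(self.distortion_locus) if self.distortion_locus else None,
            "qtls": [list(q) for q in self.qtls],
            "n_null_traits": self.n_null_traits,
            "n_parent_replicates": self.n_parent_replicates,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TruthSet:
    """Ground truth of one simulated population.

    ``genotypes``: lines x loci int8 codes at the bin-midpoint grid, with
    marker-style column names; ``loci``: the grid (name, chrom, start_bp,
    end_bp, midpoint_bp); ``crossovers``: one row per true crossover
    (line, chrom, pos_bp, sorted); ``qtl_truth``: planted QTLs, filled in
    by :func:`simulate_phenotypes`.
    """

    genotypes: pd.DataFrame
    loci: pd.DataFrame
    crossovers: pd.DataFrame
    qtl_truth: pd.DataFrame | None = None

    @property
    def lines(self) -> list[str]:
        return list(self.genotypes.index)

    def locus_index(self, chrom: str, pos_bp: int) -> str:
        """Name of the grid locus whose bin contains ``pos_bp``."""
        sub = self.loci[self.loci["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"no loci on chromosome {chrom!r}")
        hit = sub[(sub["start_bp"] < pos_bp) & (sub["end_bp"] >= pos_bp)]
        if hit.empty:
            raise ValueError(f"position {pos_bp} outside chromosome {chrom!r}")
        return hit.iloc[0]["name"]

    def genotype_at(self, chrom: str, pos_bp: int) -> pd.Series:
        """True genotype codes of every line at the bin containing ``pos_bp``."""
        return self.genotypes[self.locus_index(chrom, pos_bp)]

    def to_matrix(self) -> GenotypeMatrix:
        """View the truth as a noiseless, fully observed GenotypeMatrix."""
        markers = self.loci.rename(columns={"midpoint_bp": "midpoint_mb"}).copy()
        markers["midpoint_mb"] = markers["midpoint_mb"] / 1e6
        markers["n_snps"] = 0
        markers = markers[["name", "chrom", "start_bp", "end_bp", "midpoint_mb", "n_snps"]]
        return GenotypeMatrix(self.genotypes.copy(), markers)

    def crossover_counts(self) -> pd.DataFrame:
        """Per line/chromosome true crossover counts (zeros included)."""
        chroms = list(dict.fromkeys(self.loci["chrom"]))
        idx = pd.MultiIndex.from_product([self.lines, chroms], names=["line", "chrom"])
        counts = self.crossovers.groupby(["line", "chrom"]).size()
        return counts.reindex(idx, fill_value=0).rename("n_crossovers").reset_index()


def bin_midpoint_grid(genome: SimGenome, bin_size_bp: int = 100_000) -> pd.DataFrame:
    """Locus grid at the midpoints of a fixed-size bin tiling of each chromosome."""
    rows = []
    for c in genome.chromosomes:
        starts = np.arange(0, c.length_bp, bin_size_bp)
        ends = np.minimum(starts + bin_size_bp, c.length_bp)
        mids = (starts + ends) / 2.0
        label = chrom_label(c.name)
        for s, e, m in zip(starts, ends, mids):
            rows.append(
                {
                    "name": f"RSM_{label}_{m / 1e6:.2f}",
                    "chrom": c.name,
                    "start_bp": int(s),
                    "end_bp": int(e),
                    "midpoint_bp": m,
                }
            )
    if not rows:
        raise ValueError("genome produced an empty locus grid")
    return pd.DataFrame(rows)


def _interval_switch_probs(chrom: SimChromosome, mids_bp: np.ndarray) -> np.ndarray:
    """Observed RIL switch probability R for each adjacent midpoint interval."""
    cm_per_bp = chrom.genetic_length_cm / chrom.length_bp
    d_cm = np.diff(mids_bp) * cm_per_bp
    r = kosambi_r(d_cm)
    return np.where(r > 0, ril_observed(np.maximum(r, 0.0)), 0.0)


def _simulate_chrom_states(rng, n_lines, mids_bp, R):
    """States (n_lines x n_loci) and flip indicators (n_lines x n_loci-1)."""
    init = rng.random(n_lines) < 0.5
    flips = rng.random((n_lines, len(R))) < R[None, :]
    states = np.empty((n_lines, len(mids_bp)), dtype=np.int8)
    states[:, 0] = init
    if len(R):
        states[:, 1:] = (init[:, None] + np.cumsum(flips, axis=1)) % 2
    return states, flips


def simulate_ril_genotypes(genome: SimGenome, config: SimConfig) -> TruthSet:
    """Simulate true RIL genotypes on the bin-midpoint grid.

    Returns a :class:`TruthSet` with exact crossover positions (uniform
    within the interval where the parental origin switches).  If
    ``config.distortion_locus`` is set, lines are rejection-resampled on
    that chromosome so the expected allele-B fraction at the locus equals
    the survival ratio — linked markers inherit the distortion through
    linkage, as viability selection would produce.
    """
    rng = np.random.default_rng(config.seed)
    grid = bin_midpoint_grid(genome, config.bin_size_bp)
    n = config.n_lines
    lines = [f"RIL_{i + 1:03d}" for i in range(n)]

    geno_blocks = []
    xo_rows = []
    for c in genome.chromosomes:
        sub = grid[grid["chrom"] == c.name]
        if sub.empty:
            raise ValueError(f"no loci on chromosome {c.name}")
        mids = sub["midpoint_bp"].to_numpy()
        R = _interval_switch_probs(c, mids)
        states, flips = _simulate_chrom_states(rng, n, mids, R)

        if config.distortion_locus and config.distortion_locus[0] == c.name:
            _, pos, survival = config.distortion_locus
            li = int(np.searchsorted(sub["start_bp"].to_numpy(), pos, side="right") - 1)
            li = max(0, min(li, len(mids) - 1))
            # viability selection: line survives with genotype-dependent probability
            p_keep_b = min(1.0, survival / (1.0 - survival))
            p_keep_a = min(1.0, (1.0 - survival) / survival)
            pending = np.arange(n)
            while pending.size:
                g = states[pending, li]
                keep_prob = np.where(g == B, p_keep_b, p_keep_a)
                rejected = pending[rng.random(pending.size) >= keep_prob]
                if rejected.size == 0:
                    break
                new_states, new_flips = _simulate_chrom_states(rng, rejected.size, mids, R)
                states[rejected] = new_states
                flips[rejected] = new_flips
                pending = rejected

        geno_blocks.append(states)
        li_idx, int_idx = np.nonzero(flips)
        if li_idx.size:
            pos = mids[int_idx] + rng.random(li_idx.size) * (mids[int_idx + 1] - mids[int_idx])
            for ln, p in zip(li_idx, pos):
                xo_rows.append({"line": lines[ln], "chrom": c.name, "pos_bp": float(p)})

    genotypes = pd.DataFrame(
        np.hstack(geno_blocks), index=pd.Index(lines, name="line"), columns=list(grid["name"])
    ).astype(np.int8)
    crossovers = (
        pd.DataFrame(xo_rows, columns=["line", "chrom", "pos_bp"])
        .sort_values(["line", "chrom", "pos_bp"])
        .reset_index(drop=True)
    )
    return TruthSet(genotypes=genotypes, loci=grid, crossovers=crossovers)


def draw_snp_sites(genome: SimGenome, config: SimConfig, rng=None) -> pd.DataFrame:
    """Draw SNP positions and parental alleles along the genome.

    Density is uniform at ``snps_per_100kbp`` outside centromere windows
    and thinned to 10% inside them.  Returns (chrom, pos_bp 1-based, ref,
    alt) with ref carrying the parent-A allele and alt the parent-B allele.
    """
    if config.snps_per_100kbp <= 0:
        raise ValueError("snps_per_100kbp must be positive")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    rows = []
    for c in genome.chromosomes:
        mean_count = config.snps_per_100kbp * c.length_bp / 100_000.0
        count = rng.poisson(mean_count)
        pos = rng.integers(1, c.length_bp + 1, size=count)
        in_cen = (
            np.abs(pos - c.centromere_center_bp) <= c.centromere_halfwidth_bp
            if c.centromere_halfwidth_bp > 0
            else np.zeros(count, dtype=bool)
        )
        keep = ~in_cen | (rng.random(count) < CENTROMERE_SNP_RETENTION)
        pos = np.unique(pos[keep])
        ref_i = rng.integers(0, 4, size=pos.size)
        alt_i = (ref_i + rng.integers(1, 4, size=pos.size)) % 4
        for p, ri, ai in zip(pos, ref_i, alt_i):
            rows.append({"chrom": c.name, "pos_bp": int(p), "ref": _BASES[ri], "alt": _BASES[ai]})
    if not rows:
        raise ValueError("no SNP sites drawn anywhere in the genome")
    return pd.DataFrame(rows)


def simulate_snp_calls(
    truth: TruthSet, genome: SimGenome, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate noisy per-line SNP origin calls.

    Each RIL x SNP call equals the line's true genotype at the bin
    containing the SNP, flipped with probability ``error_prob``; calls are
    then dropped with probability ``dropout_prob`` (no record emitted).

    Returns ``(calls, sites)`` where ``calls`` is a long table
    (line, chrom, pos_bp, origin int8) of the surviving calls and
    ``sites`` the SNP site sheet from :func:`draw_snp_sites`.
    """
    rng = np.random.default_rng(config.seed + 1)
    sites = draw_snp_sites(genome, config, rng)
    frames = []
    for c in genome.chromosomes:
        sub_sites = sites[sites["chrom"] == c.name]
        if sub_sites.empty:
            continue
        loci = truth.loci[truth.loci["chrom"] == c.name]
        starts = loci["start_bp"].to_numpy()
        bin_idx = np.searchsorted(starts, sub_sites["pos_bp"].to_numpy(), side="right") - 1
        locus_names = loci["name"].to_numpy()[bin_idx]
        true_codes = truth.genotypes[list(locus_names)].to_numpy()  # lines x snps

        flip = rng.random(true_codes.shape) < config.error_prob
        obs = np.where(flip, 1 - true_codes, true_codes).astype(np.int8)
        drop = rng.random(true_codes.shape) < config.dropout_prob
        li, si = np.nonzero(~drop)
        frames.append(
            pd.DataFrame(
                {
                    "line": np.asarray(truth.lines)[li],
                    "chrom": c.name,
                    "pos_bp": sub_sites["pos_bp"].to_numpy()[si],
                    "origin": obs[li, si],
                }
            )
        )
    calls = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["line", "chrom", "pos_bp", "origin"]
    )
    calls = calls.sort_values(["line", "chrom", "pos_bp"]).reset_index(drop=True)
    return calls, sites


def write_population_vcfs(
    calls: pd.DataFrame,
    sites: pd.DataFrame,
    genome: SimGenome,
    out_dir,
    n_parent_replicates: int = 2,
    parent_a: str = "parentA",
    parent_b: str = "parentB",
) -> dict[str, Path]:
    """Write one VCF 4.2 per simulated sample (parent replicates + RILs).

    Parent replicates are noiseless: every site is homozygous reference in
    parent-A replicates and homozygous alternate in parent-B replicates.
    RIL files contain only the line's surviving calls, coded 0/0 when the
    call matches the parent-A allele and 1/1 otherwise.
    """
    import pysam

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sites = sites.sort_values(["chrom", "pos_bp"]).reset_index(drop=True)

    def _write(sample: str, sub: pd.DataFrame) -> Path:
        header = pysam.VariantHeader()
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        for c in genome.chromosomes:
            header.contigs.add(c.name, length=c.length_bp)
        header.add_sample(sample)
        path = out_dir / f"{sample}.vcf"
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for row in sub.itertuples(index=False):
                rec = vf.new_record(
                    contig=row.chrom,
                    start=row.pos_bp - 1,
                    stop=row.pos_bp,
                    alleles=(row.ref, row.alt),
                )
                gt = (0, 0) if row.origin == A else (1, 1)
                rec.samples[sample]["GT"] = gt
                rec.samples[sample].phased = False
                vf.write(rec)
        return path

    paths: dict[str, Path] = {}
    parent_sites = sites.copy()
    for rep in range(1, n_parent_replicates + 1):
        sample = f"{parent_a}_{rep}"
        paths[sample] = _write(sample, parent_sites.assign(origin=A))
        sample = f"{parent_b}_{rep}"
        paths[sample] = _write(sample, parent_sites.assign(origin=B))

    keyed = calls.merge(sites, on=["chrom", "pos_bp"], how="left")
    for line, sub in keyed.groupby("line", sort=True):
        paths[str(line)] = _write(str(line), sub.sort_values(["chrom", "pos_bp"]))
    return paths


def simulate_phenotypes(
    truth: TruthSet, config: SimConfig, rng=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate additive trait values from planted QTLs.

    Each trait is the sum of its QTL indicator effects plus Gaussian noise,
    scaled so each QTL explains its stated fraction of the trait variance
    (fractions computed against the empirical indicator variance, total
    variance 1).  ``config.n_null_traits`` extra pure-noise traits are
    appended.  Returns ``(phenotypes, qtl_truth)``; the QTL truth is also
    stored on the TruthSet.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    by_trait: dict[str, list] = {}
    for trait, chrom, pos, frac in config.qtls:
        by_trait.setdefault(trait, []).append((chrom, pos, frac))

    n = len(truth.lines)
    pheno = {}
    truth_rows = []
    for trait, qtls in by_trait.items():
        total_frac = sum(f for _, _, f in qtls)
        if total_frac >= 1:
            raise ValueError(f"trait {trait!r}: QTL variance fractions sum to >= 1")
        values = np.zeros(n)
        for chrom, pos, frac in qtls:
            g = (truth.genotype_at(chrom, pos).to_numpy() == B).astype(float)
            sd_g = g.std()
            if sd_g == 0:
                raise ValueError(f"trait {trait!r}: QTL locus {chrom}:{pos} is monomorphic")
            effect = np.sqrt(frac) / sd_g
            values += effect * g
            truth_rows.append(
                {
                    "trait": trait,
                    "chrom": chrom,
                    "pos_bp": pos,
                    "locus": truth.locus_index(chrom, pos),
                    "var_fraction": frac,
                    "effect": effect,
                }
            )
        noise_sd = np.sqrt(1.0 - total_frac)
        values = values + rng.normal(0.0, noise_sd, size=n)
        pheno[trait] = values
    for k in range(1, config.n_null_traits + 1):
        pheno[f"null_{k:03d}"] = rng.normal(0.0, 1.0, size=n)

    phenotypes = pd.DataFrame(pheno, index=pd.Index(truth.lines, name="line"))
    qtl_truth = pd.DataFrame(
        truth_rows, columns=["trait", "chrom", "pos_bp", "locus", "var_fraction", "effect"]
    )
    truth.qtl_truth = qtl_truth
    return phenotypes, qtl_truth


def legacy_map_from_truth(
    truth: TruthSet, genome: SimGenome, n_markers: int = 69
) -> pd.DataFrame:
    """Thin the truth grid to a low-density 'legacy' marker map.

    Markers are spread evenly along each chromosome (allocation
    proportional to physical length, minimum two per chromosome) with
    noiseless genotypes taken from the truth — emulating the PCR-marker
    maps that high-density maps are compared against.  Returns the legacy
    map TSV schema: marker, chrom, pos_bp, cM, one column per line.
    """
    rows = []
    total = genome.total_length_bp
    for c in genome.chromosomes:
        loci = truth.loci[truth.loci["chrom"] == c.name].reset_index(drop=True)
        k = max(2, round(n_markers * c.length_bp / total))
        pick = np.unique(np.linspace(0, len(loci) - 1, k).round().astype(int))
        cm_per_bp = c.genetic_length_cm / c.length_bp
        for i in pick:
            locus = loci.iloc[i]
            row = {
                "marker": f"LEG_{chrom_label(c.name)}_{locus['midpoint_bp'] / 1e6:.2f}",
                "chrom": c.name,
                "pos_bp": int(locus["midpoint_bp"]),
                "cM": locus["midpoint_bp"] * cm_per_bp,
            }
            geno = truth.genotypes[locus["name"]]
            row.update({ln: int(v) for ln, v in geno.items()})
            rows.append(row)
    return pd.DataFrame(rows)
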