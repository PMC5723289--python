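"""VCF ingestion, parental SNP-set derivation and parental-origin coding.

The genotyping strategy for a bi-parental RIL population needs only the
SNPs that reliably distinguish the two parents.  Per-sample VCFs are
merged into one long call table; sites are retained when the parental
replicates are internally consistent and the two parents carry different
alleles; each RIL call at a retained site is then coded by the parent
whose allele it matches.

Coordinates are 1-based VCF positions throughout this module; conversion
to 0-based half-open windows happens only in :mod:`binmap.binning`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import A, B, MISSING

# cyvcf2 gt_types codes
_HOM_REF, _HET, _UNKNOWN, _HOM_ALT = 0, 1, 2, 3


@dataclass
class ParentalSnpSet:
    """Retained parent-discriminating SNPs with provenance counts."""

    table: pd.DataFrame  # chrom, pos_bp, allele_a, allele_b
    n_raw_sites: int
    n_retained: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ParentalSnpSet":
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(table=table, n_raw_sites=-1, n_retained=len(table))


def read_variant_calls(vcf_paths) -> pd.DataFrame:
    """Merge per-sample VCFs into one long call table.

    Returns columns ``sample, chrom, pos_bp, ref, alt, allele`` where
    ``allele`` is the called allele for homozygous genotypes and NaN for
    heterozygous or uncalled genotypes (RILs are modelled as fixed, so
    only homozygous calls are informative).  Multi-allelic records keep a
    comma-joined alt.  Fails on unparseable files or duplicate sample
    names across files.
    """
    frames = []
    seen_samples: set[str] = set()
    for path in vcf_paths:
        try:
            vcf = VCF(str(path))
        except Exception as exc:  # cyvcf2 raises bare OSError on bad files
            raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
        samples = list(vcf.samples)
        dup = seen_samples.intersection(samples)
        if dup:
            raise ValueError(f"duplicate sample name(s) {sorted(dup)} in {path}")
        seen_samples.update(samples)
        rows = []
        for v in vcf:
            alts = v.ALT or []
            alt = ",".join(alts)
            gt_types = v.gt_types
            for si, sample in enumerate(samples):
                gt = gt_types[si]
                if gt == _HOM_REF:
                    allele = v.REF
                elif gt == _HOM_ALT:
                    allele = alts[0] if len(alts) == 1 else np.nan
                else:  # het or uncalled: uninformative for a fixed line
                    allele = np.nan
                rows.append((sample, v.CHROM, v.POS, v.REF, alt, allele))
        vcf.close()
        frames.append(
            pd.DataFrame(rows, columns=["sample", "chrom", "pos_bp", "ref", "alt", "allele"])
        )
    if not frames:
        return pd.DataFrame(columns=["sample", "chrom", "pos_bp", "ref", "alt", "allele"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos_bp", "sample"]).reset_index(drop=True)


def _is_simple_snp(ref: pd.Series, alt: pd.Series) -> pd.Series:
    bases = {"A", "C", "G", "T"}
    return ref.isin(bases) & alt.isin(bases)


def derive_parental_snps(
    calls: pd.DataFrame,
    parent_a_samples: list[str],
    parent_b_samples: list[str],
    min_replicates: int = 2,
) -> ParentalSnpSet:
    """Apply the parental consistency filter.

    A site is retained iff each parent has at least ``min_replicates``
    homozygous calls, all replicates of a parent agree on one allele, and
    the two parental alleles differ.  Indels and multi-allelic records are
    dropped.  Returns the retained set with raw/retained provenance
    counts; an empty set (with a warning) if nothing survives.
    """
    if min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")
    n_raw = calls.groupby(["chrom", "pos_bp"]).ngroups if len(calls) else 0

    snp_calls = calls[_is_simple_snp(calls["ref"], calls["alt"]) & calls["allele"].notna()]

    def _consensus(samples: list[str], out_col: str) -> pd.DataFrame:
        sub = snp_calls[snp_calls["sample"].isin(samples)]
        grp = sub.groupby(["chrom", "pos_bp"])["allele"].agg(["nunique", "count", "first"])
        ok = grp[(grp["nunique"] == 1) & (grp["count"] >= min_replicates)]
        return ok["first"].rename(out_col).reset_index()

    cons_a = _consensus(parent_a_samples, "allele_a")
    cons_b = _consensus(parent_b_samples, "allele_b")
    merged = cons_a.merge(cons_b, on=["chrom", "pos_bp"])
    merged = merged[merged["allele_a"] != merged["allele_b"]].reset_index(drop=True)
    if merged.empty:
        import warnings

        warnings.warn("parental consistency filter retained no SNPs", stacklevel=2)
    table = merged.sort_values(["chrom", "pos_bp"]).reset_index(drop=True)
    return ParentalSnpSet(table=table, n_raw_sites=n_raw, n_retained=len(table))


def genotype_snp_calls(
    calls: pd.DataFrame,
    parents: ParentalSnpSet,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Assign each RIL call at a retained site a parental origin.

    ``samples`` restricts the call table to the RIL samples (pass the
    non-parent sample names); by default every sample in ``calls`` is
    genotyped.  Origin is A when the called allele equals the parent-A
    allele, B for the parent-B allele, and missing for heterozygous,
    uncalled or third-allele calls.

    Returns the long SNP genotype table (line, chrom, pos_bp, origin int8)
    covering every retained site x sample combination present in ``calls``.
    """
    if parents.table.empty:
        raise ValueError("parental SNP set is empty")
    sub = calls if samples is None else calls[calls["sample"].isin(samples)]
    merged = sub.merge(parents.table, on=["chrom", "pos_bp"], how="inner")
    origin = np.full(len(merged), MISSING, dtype=np.int8)
    origin[(merged["allele"] == merged["allele_a"]).to_numpy()] = A
    origin[(merged["allele"] == merged["allele_b"]).to_numpy()] = B
    out = pd.DataFrame(
        {
            "line": merged["sample"],
            "chrom": merged["chrom"],
            "pos_bp": merged["pos_bp"],
            "origin": origin,
        }
    )
    return out.sort_values(["line", "chrom", "pos_bp"]).reset_index(drop=True)


def write_snp_table(table: pd.DataFrame, path) -> None:
    """Write a SNP genotype table as TSV (origin coded A/B/NA)."""
    out = table.copy()
    out["origin"] = out["origin"].map({A: "A", B: "B", MISSING: "NA"})
    out.to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    table["origin"] = table["origin"].map({"A": A, "B": B, "NA": MISSING}).astype(np.int8)
    return table
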