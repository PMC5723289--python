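import numpy as np
import pandas as pd
import pytest

import binmap as bm
from binmap.core import A, B, MISSING

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1,length=1000000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
)


def write_vcf(path, sample, records):
    body = "".join(
        f"1\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t{gt}\n" for pos, ref, alt, gt in records
    )
    path.write_text(VCF_HEADER.format(sample=sample) + body)
    return path


def calls_table(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos_bp", "ref", "alt", "allele"])


def test_empty_vcf_body(tmp_path):
    p = write_vcf(tmp_path / "s.vcf", "s1", [])
    table = bm.read_variant_calls([p])
    assert len(table) == 0


def test_merge_shares_variant_rows(tmp_path):
    p1 = write_vcf(tmp_path / "a.vcf", "s1", [(100, "A", "C", "0/0")])
    p2 = write_vcf(tmp_path / "b.vcf", "s2", [(100, "A", "C", "1/1")])
    table = bm.read_variant_calls([p1, p2])
    assert len(table) == 2
    assert set(table["sample"]) == {"s1", "s2"}
    assert table["pos_bp"].nunique() == 1
    by = table.set_index("sample")["allele"]
    assert by["s1"] == "A" and by["s2"] == "C"


def test_het_and_missing_are_uninformative(tmp_path):
    p = write_vcf(tmp_path / "s.vcf", "s1", [(10, "A", "G", "0/1"), (20, "A", "G", "./.")])
    table = bm.read_variant_calls([p])
    assert table["allele"].isna().all()


def test_duplicate_sample_rejected(tmp_path):
    p1 = write_vcf(tmp_path / "a.vcf", "s1", [(100, "A", "C", "0/0")])
    p2 = write_vcf(tmp_path / "b.vcf", "s1", [(200, "A", "C", "0/0")])
    with pytest.raises(ValueError, match="duplicate sample"):
        bm.read_variant_calls([p1, p2])


def test_malformed_vcf_rejected(tmp_path):
    bad = tmp_path / "bad.vcf"
    bad.write_text("this is not a vcf\n")
    with pytest.raises(ValueError, match="bad.vcf"):
        bm.read_variant_calls([bad])


def test_simulator_roundtrip(tmp_path, noiseless_population, small_genome):
    truth, calls, sites, _ = noiseless_population
    paths = bm.write_population_vcfs(calls, sites, small_genome, tmp_path)
    line = truth.lines[0]
    table = bm.read_variant_calls([paths[line]])
    keyed = sites.set_index(["chrom", "pos_bp"])
    expected = calls[calls["line"] == line]
    got = table.set_index(["chrom", "pos_bp"])
    assert len(got) == len(expected)
    for row in expected.itertuples(index=False):
        site = keyed.loc[(row.chrom, row.pos_bp)]
        want = site["ref"] if row.origin == A else site["alt"]
        assert got.loc[(row.chrom, row.pos_bp), "allele"] == want


class TestDeriveParentalSnps:
    def test_concordant_site_retained(self):
        calls = calls_table(
            [
                ("pa1", "1", 100, "A", "C", "A"),
                ("pa2", "1", 100, "A", "C", "A"),
                ("pb1", "1", 100, "A", "C", "C"),
                ("pb2", "1", 100, "A", "C", "C"),
            ]
        )
        out = bm.derive_parental_snps(calls, ["pa1", "pa2"], ["pb1", "pb2"])
        assert out.n_retained == 1
        rec = out.table.iloc[0]
        assert rec["allele_a"] == "A" and rec["allele_b"] == "C"

    def test_discordant_replicates_dropped(self):
        calls = calls_table(
            [
                ("pa1", "1", 100, "A", "C", "A"),
                ("pa2", "1", 100, "A", "C", "C"),
                ("pb1", "1", 100, "A", "C", "C"),
                ("pb2", "1", 100, "A", "C", "C"),
            ]
        )
        with pytest.warns(UserWarning):
            out = bm.derive_parental_snps(calls, ["pa1", "pa2"], ["pb1", "pb2"])
        assert out.n_retained == 0

    def test_ril_only_variant_dropped(self):
        calls = calls_table([("ril1", "1", 100, "A", "C", "C")])
        with pytest.warns(UserWarning):
            out = bm.derive_parental_snps(calls, ["pa1"], ["pb1"], min_replicates=1)
        assert out.n_retained == 0

    def test_same_allele_in_both_parents_dropped(self):
        calls = calls_table(
            [("pa1", "1", 100, "A", "C", "C"), ("pb1", "1", 100, "A", "C", "C")]
        )
        with pytest.warns(UserWarning):
            out = bm.derive_parental_snps(calls, ["pa1"], ["pb1"], min_replicates=1)
        assert out.n_retained == 0

    def test_indel_and_multiallelic_dropped(self):
        calls = calls_table(
            [
                ("pa1", "1", 100, "AT", "A", "AT"),
                ("pb1", "1", 100, "AT", "A", "A"),
                ("pa1", "1", 200, "A", "C,G", "A"),
                ("pb1", "1", 200, "A", "C,G", np.nan),
            ]
        )
        with pytest.warns(UserWarning):
            out = bm.derive_parental_snps(calls, ["pa1"], ["pb1"], min_replicates=1)
        assert out.n_retained == 0

    def test_replicate_quorum(self):
        calls = calls_table(
            [
                ("pa1", "1", 100, "A", "C", "A"),
                ("pb1", "1", 100, "A", "C", "C"),
                ("pb2", "1", 100, "A", "C", "C"),
            ]
        )
        with pytest.warns(UserWarning):
            assert bm.derive_parental_snps(calls, ["pa1", "pa2"], ["pb1", "pb2"]).n_retained == 0
        assert (
            bm.derive_parental_snps(calls, ["pa1"], ["pb1", "pb2"], min_replicates=1).n_retained == 1
        )


class TestGenotypeSnpCalls:
    parents = bm.ParentalSnpSet(
        table=pd.DataFrame(
            {"chrom": ["1", "1"], "pos_bp": [100, 200], "allele_a": ["A", "G"], "allele_b": ["C", "T"]}
        ),
        n_raw_sites=2,
        n_retained=2,
    )

    def test_origin_coding(self):
        calls = calls_table(
            [
                ("r1", "1", 100, "A", "C", "C"),   # parent-B allele
                ("r1", "1", 200, "G", "T", "G"),   # parent-A allele
                ("r2", "1", 100, "A", "C", np.nan),  # het/uncalled
                ("r2", "1", 200, "G", "T", "A"),   # third allele
                ("r2", "1", 300, "A", "C", "C"),   # site not in parental set
            ]
        )
        out = bm.genotype_snp_calls(calls, self.parents)
        keyed = out.set_index(["line", "pos_bp"])["origin"]
        assert keyed.loc[("r1", 100)] == B
        assert keyed.loc[("r1", 200)] == A
        assert keyed.loc[("r2", 100)] == MISSING
        assert keyed.loc[("r2", 200)] == MISSING
        assert ("r2", 300) not in keyed.index
        assert len(out) == 4  # only retained sites survive

    def test_empty_parent_set_rejected(self):
        empty = bm.ParentalSnpSet(pd.DataFrame(columns=["chrom", "pos_bp", "allele_a", "allele_b"]), 0, 0)
        with pytest.raises(ValueError):
            bm.genotype_snp_calls(calls_table([]), empty)


def test_noiseless_pipeline_recovers_truth(tmp_path, noiseless_population, small_genome):
    """VCF write -> read -> parental filter -> origin coding reproduces the truth exactly."""
    truth, calls, sites, _ = noiseless_population
    lines = truth.lines[:8]
    sub_calls = calls[calls["line"].isin(lines)]
    paths = bm.write_population_vcfs(sub_calls, sites, small_genome, tmp_path)
    raw = bm.read_variant_calls(list(paths.values()))
    parents = bm.derive_parental_snps(raw, ["parentA_1", "parentA_2"], ["parentB_1", "parentB_2"])
    assert parents.n_retained == len(sites)
    snps = bm.genotype_snp_calls(raw, parents, samples=lines)
    merged = snps.merge(sub_calls, on=["line", "chrom", "pos_bp"], suffixes=("", "_sim"))
    assert len(merged) == len(sub_calls)
    assert (merged["origin"] == merged["origin_sim"]).all()


def test_snp_table_tsv_roundtrip(tmp_path, noiseless_population):
    _, calls, _, _ = noiseless_population
    sub = calls.head(1000)
    path = tmp_path / "snps.tsv"
    bm.write_snp_table(sub, path)
    back = bm.read_snp_table(path)
    pd.testing.assert_frame_equal(sub.reset_index(drop=True), back)
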