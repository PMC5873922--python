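"""Panel I/O: VCF coding and round-trips, masking, site filters, GFF
classification, GRM text, phenotype tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from inbredpanel import (
    MISSING,
    GenotypeMatrix,
    PanelError,
    PhenotypeTable,
    SiteFilterSpec,
    apply_site_filters,
    classify_sites,
    mask_low_confidence,
    read_grm_text,
    read_phenotypes,
    read_vcf,
    write_grm_text,
    write_phenotypes,
    write_vcf,
)
from conftest import make_gm


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def test_vcf_genotype_coding_table(tmp_path):
    """Reference-counted codes map to GTs 1/1, 0/1, 0/0, ./. and back."""
    gm = make_gm([[0], [1], [2], [MISSING]])
    path = tmp_path / "a.vcf"
    write_vcf(gm, path)
    gts = [l.split("\t")[9:] for l in path.read_text().splitlines()
           if not l.startswith("#")][0]
    assert gts == ["1/1", "0/1", "0/0", "./."]
    back = read_vcf(path)
    assert np.array_equal(back.genotypes, gm.genotypes)


def test_heterozygote_code_policy_invariant(tmp_path):
    gm = make_gm([[1], [1]])
    assert np.array_equal(gm.with_policy("minor").genotypes, gm.genotypes)


def test_empty_matrix_header_only_vcf(tmp_path):
    gm = make_gm(np.zeros((3, 0), dtype=np.int8))
    path = tmp_path / "empty.vcf"
    write_vcf(gm, path)
    body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert body == []


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**32 - 1))
def test_vcf_roundtrip_genotype_exact(tmp_path_factory, seed):
    """write(read) is the identity on genotype codes for random fixtures."""
    rng = np.random.default_rng(seed)
    codes = rng.choice([-1, 0, 1, 2], size=(rng.integers(1, 6), rng.integers(1, 9)))
    gm = make_gm(codes)
    path = tmp_path_factory.mktemp("rt") / "rt.vcf"
    write_vcf(gm, path)
    back = read_vcf(path)
    assert np.array_equal(back.genotypes, gm.genotypes)
    assert back.line_ids == gm.line_ids
    assert back.sites["pos"].tolist() == gm.sites["pos"].tolist()


def test_malformed_vcf_raises_with_location(tmp_path):
    path = tmp_path / "bad.vcf"
    path.write_text("this is not a vcf\n")
    with pytest.raises(PanelError):
        read_vcf(path)


def test_unknown_policy_rejected(tmp_path):
    gm = make_gm([[0], [2]])
    path = tmp_path / "p.vcf"
    write_vcf(gm, path)
    with pytest.raises(PanelError, match="policy"):
        read_vcf(path, counted_allele_policy="major")


# ----------------------------------------------------------------------
# Allele-policy flips
# ----------------------------------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_policy_flip_involution_and_maf_invariance(seed):
    rng = np.random.default_rng(seed)
    codes = rng.choice([-1, 0, 1, 2], size=(6, 12))
    gm = make_gm(codes)
    flipped = gm.with_policy("minor")
    back = flipped.with_policy("reference")
    assert np.array_equal(back.genotypes, gm.genotypes)
    np.testing.assert_allclose(
        np.nan_to_num(flipped.maf(), nan=-1), np.nan_to_num(gm.maf(), nan=-1)
    )
    # minor-counted frequency never exceeds 1/2
    p = flipped.counted_allele_freq()
    assert np.all(p[np.isfinite(p)] <= 0.5 + 1e-12)


# ----------------------------------------------------------------------
# Masking
# ----------------------------------------------------------------------

def test_mask_low_confidence_full_probability_noop():
    gm = make_gm([[0, 1], [2, 1]], gt_probs=np.ones((2, 2)))
    out = mask_low_confidence(gm, 0.99)
    assert np.array_equal(out.genotypes, gm.genotypes)


def test_mask_low_confidence_strict_inequality():
    gm = make_gm([[0, 1], [2, 1]], gt_probs=[[0.98, 0.99], [1.0, 0.995]])
    out = mask_low_confidence(gm, 0.99)
    assert out.genotypes[0, 0] == MISSING
    assert (out.genotypes != MISSING).sum() == 3


def test_mask_low_confidence_counts_engineered(tmp_path):
    """Exactly the engineered sub-threshold calls become MISSING."""
    rng = np.random.default_rng(1)
    codes = rng.choice([0, 1, 2], size=(5, 10))
    probs = np.ones((5, 10))
    low = [(0, 1), (1, 3), (2, 2), (3, 9), (4, 0), (0, 7), (2, 5)]
    for i, j in low:
        probs[i, j] = 0.9
    gm = make_gm(codes, gt_probs=probs)
    out = mask_low_confidence(gm, 0.99)
    assert (out.genotypes == MISSING).sum() == 7
    assert {(i, j) for i, j in zip(*np.where(out.genotypes == MISSING))} == set(low)


def test_mask_without_confidence_is_noop():
    gm = make_gm([[0, 1]])
    out = mask_low_confidence(gm, 0.99)
    assert np.array_equal(out.genotypes, gm.genotypes)


def test_gq_converted_to_probability(tmp_path):
    """GQ 20 reads back as probability 0.99; GQ 13 (< 99%) masks."""
    path = tmp_path / "gq.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT:GQ\t0/0:20\t0/1:13\n"
    )
    gm = read_vcf(path)
    np.testing.assert_allclose(gm.gt_probs[0, 0], 1 - 10 ** (-2.0), rtol=1e-9)
    out = mask_low_confidence(gm, 0.99)
    assert out.genotypes[0, 0] != MISSING
    assert out.genotypes[1, 0] == MISSING


# ----------------------------------------------------------------------
# Site filters
# ----------------------------------------------------------------------

def test_filters_remove_monomorphic_and_depth_boundary():
    gm = make_gm(
        [[2, 2], [2, 0]],
        depths=[[30.0, 61.0], [30.0, 61.0]],
    )
    out, report = apply_site_filters(gm, SiteFilterSpec(call_rate_min=0.0))
    # site 1 monomorphic (MAF 0), site 2 depth 61 > 60
    assert out.n_sites == 0
    assert report.removed_depth == 1
    assert report.removed_maf == 1


def test_filters_inclusive_boundaries():
    """Depth exactly 5 or 60 and MAF exactly 0.05 survive."""
    codes = np.ones((20, 2), dtype=np.int8) * 2
    codes[0, :] = 0  # MAF = 1/20 = 0.05
    gm = make_gm(codes, depths=np.tile([5.0, 60.0], (20, 1)))
    out, report = apply_site_filters(gm)
    assert out.n_sites == 2


def test_filter_report_engineered_composition():
    """20 sites: 5 fail depth, 2 fail call rate, 3 fail MAF -> 10 survive."""
    rng = np.random.default_rng(0)
    n_lines, n_sites = 10, 20
    codes = rng.choice([0, 2], size=(n_lines, n_sites)).astype(np.int8)
    codes[: n_lines // 2, :] = 0
    codes[n_lines // 2:, :] = 2  # every site MAF 0.5, full call rate
    depths = np.full((n_lines, n_sites), 30.0)
    depths[:, :5] = 100.0                      # 5 fail depth
    codes[:7, 5:7] = MISSING                   # 2 fail call rate (30%)
    codes[1:, 7:10] = 2
    codes[0, 7:10] = 2                         # 3 monomorphic -> fail MAF
    gm = make_gm(codes, depths=depths)
    out, report = apply_site_filters(gm)
    assert (report.removed_depth, report.removed_call_rate, report.removed_maf) == (5, 2, 3)
    assert out.n_sites == 10
    assert report.total_removed == report.n_input - report.n_output


def test_filtering_idempotent(sim_panel_small):
    gm = sim_panel_small.gm
    once, r1 = apply_site_filters(gm)
    twice, r2 = apply_site_filters(once)
    assert np.array_equal(once.genotypes, twice.genotypes)
    assert r2.total_removed == 0


def test_empty_matrix_filter_report_zeros():
    gm = make_gm(np.zeros((2, 0), dtype=np.int8))
    out, report = apply_site_filters(gm)
    assert out.n_sites == 0 and report.total_removed == 0


def test_multiallelic_flagged_and_filtered(tmp_path):
    path = tmp_path / "ma.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "chr1\t100\t.\tA\tC,G\t.\tPASS\t.\tGT\t0/1\t1/2\n"
        "chr1\t200\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\t1/1\n"
    )
    gm = read_vcf(path)
    assert gm.sites["biallelic"].tolist() == [False, True]
    out, report = apply_site_filters(gm, SiteFilterSpec(maf_min=0.0, call_rate_min=0.0))
    assert out.n_sites == 1 and report.removed_not_biallelic == 1


# ----------------------------------------------------------------------
# GFF classification
# ----------------------------------------------------------------------

def test_classify_sites_toy_gff(toy_gff):
    # exon A: 100-200, 400-500; gene A: 100-500; exon B: 1000-1100; gene B: 1000-1400
    positions = [50, 100, 150, 250, 399, 400, 500, 600, 1050, 1200]
    expected = [
        "intergenic", "exonic", "exonic", "intronic", "intronic",
        "exonic", "exonic", "intergenic", "exonic", "intronic",
    ]
    gm = make_gm(np.zeros((2, 10), dtype=np.int8), positions=positions)
    assert classify_sites(gm, toy_gff).tolist() == expected


def test_classify_unknown_contig_intergenic(toy_gff):
    gm = make_gm(np.zeros((2, 3), dtype=np.int8), chrom="chrX")
    assert set(classify_sites(gm, toy_gff)) == {"intergenic"}


# ----------------------------------------------------------------------
# GRM text
# ----------------------------------------------------------------------

def test_grm_text_identity(tmp_path):
    path = tmp_path / "i.txt"
    path.write_text("1 0\n0 1\n")
    mat, ids = read_grm_text(path)
    np.testing.assert_array_equal(mat, np.eye(2))
    assert ids == ["L1", "L2"]


def test_grm_text_roundtrip_random(tmp_path):
    rng = np.random.default_rng(3)
    x = rng.standard_normal((5, 5))
    x = (x + x.T) / 2
    path = tmp_path / "g.txt"
    write_grm_text(x, path, ids=[f"s{i}" for i in range(5)])
    mat, ids = read_grm_text(path)
    np.testing.assert_allclose(mat, x, rtol=5e-12, atol=1e-15)
    assert ids == [f"s{i}" for i in range(5)]


@pytest.mark.parametrize(
    "content", ["1 2 3\n4 5 6\n", "1 2\n2.1 1\n"],
    ids=["non_square", "asymmetric"],
)
def test_grm_text_format_errors(tmp_path, content):
    path = tmp_path / "bad.txt"
    path.write_text(content)
    with pytest.raises(PanelError):
        read_grm_text(path)


# ----------------------------------------------------------------------
# Phenotypes
# ----------------------------------------------------------------------

def test_phenotype_roundtrip_and_unmatched(tmp_path):
    df = pd.DataFrame(
        {"line": ["L1", "L1", "L9"], "rep": [1, 2, 1],
         "focal": [1.0, 1.1, 0.9], "divisor": [0.5, 0.4, 0.6]}
    )
    table = PhenotypeTable(df)
    path = tmp_path / "p.tsv"
    write_phenotypes(table, path)
    back = read_phenotypes(path)
    assert back.traits == ["focal", "divisor"]
    gm = make_gm([[0], [2]], line_ids=["L1", "L2"])
    assert back.unmatched_lines(gm) == ["L9"]


def test_phenotype_duplicate_replicate_rejected():
    df = pd.DataFrame({"line": ["L1", "L1"], "rep": [1, 1], "t": [1.0, 2.0]})
    with pytest.raises(PanelError, match="duplicate"):
        PhenotypeTable(df)
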