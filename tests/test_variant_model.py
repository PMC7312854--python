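"""Coordinate mapping, HGVS parsing, and consequence classification."""

import pytest

from brcakit.variant_model import (
    ConsistencyError,
    Consequence,
    CoordinateError,
    HgvsParseError,
    build_variant,
    classify_consequence,
    map_c_to_g,
    map_g_to_c,
    read_variant_table,
    read_vcf,
    revcomp,
    write_vcf,
)

# The four published g./c. anchor pairs that pin the transcript models.
ANCHOR_PAIRS = [
    ("BRCA1", "c.4957G>T", 41222974, "C", "A"),
    ("BRCA1", "c.3707A>G", 41243841, "T", "C"),
    ("BRCA2", "c.6131G>T", 32914623, "G", "T"),
    ("BRCA2", "c.2350A>G", 32910842, "A", "G"),
]


@pytest.mark.parametrize("gene,hgvs_c,g_pos,g_ref,g_alt", ANCHOR_PAIRS)
def test_anchor_pairs_map_both_ways(models, gene, hgvs_c, g_pos, g_ref, g_alt):
    tm = models[gene]
    assert map_c_to_g(tm, hgvs_c) == (g_pos, g_ref, g_alt)
    assert map_g_to_c(tm, g_pos, g_ref, g_alt) == hgvs_c


def test_round_trip_on_every_coding_position(models):
    """c->g->c is the identity across the entire CDS of both genes."""
    for gene in ("BRCA1", "BRCA2"):
        tm = models[gene]
        assert tm.cds_length in (5592, 10257)
        for c in range(1, tm.cds_length + 1):
            hgvs = f"c.{c}A>G"
            g, ref, alt = map_c_to_g(tm, hgvs)
            assert map_g_to_c(tm, g, ref, alt) == hgvs


def test_minus_strand_complements_alleles(models):
    tm = models["BRCA1"]
    assert tm.strand == "-"
    for c in (1, 100, 2500, tm.cds_length):
        _, ref, alt = map_c_to_g(tm, f"c.{c}A>C")
        assert (ref, alt) == ("T", "G")
    tm2 = models["BRCA2"]
    _, ref, alt = map_c_to_g(tm2, "c.100A>C")
    assert (ref, alt) == ("A", "C")


def test_exonic_g_positions_are_unique(models):
    """Every CDS position maps to exactly one genomic position."""
    for gene in ("BRCA1", "BRCA2"):
        tm = models[gene]
        gs = {tm.c_to_g(c) for c in range(1, tm.cds_length + 1)}
        assert len(gs) == tm.cds_length


@pytest.mark.parametrize("gene,bad_c", [
    ("BRCA1", "c.5593A>G"),   # beyond the CDS
    ("BRCA2", "c.10258A>G"),
    ("BRCA1", "c.0A>G"),
])
def test_out_of_range_c_raises(models, gene, bad_c):
    with pytest.raises((CoordinateError, HgvsParseError)):
        map_c_to_g(models[gene], bad_c)


def test_intronic_g_raises(models):
    tm = models["BRCA1"]
    with pytest.raises(CoordinateError):
        map_g_to_c(tm, 41223256, "A", "G")  # one base past an exon boundary


@pytest.mark.parametrize("bad", ["c.123", "c.12X>Y", "p.V1653L", "", "c.4957G>G"])
def test_malformed_hgvs_raises(models, bad):
    with pytest.raises(HgvsParseError):
        map_c_to_g(models["BRCA1"], bad)


@pytest.mark.parametrize("gene,hgvs_c,hgvs_p,cons,last_exon", [
    ("BRCA1", "c.4957G>T", "p.V1653L", Consequence.MISSENSE, False),
    ("BRCA1", "c.4957G>T", "p.Val1653Leu", Consequence.MISSENSE, False),
    ("BRCA2", "c.10219del", "p.N3407fs", Consequence.FRAMESHIFT, True),
    ("BRCA2", "c.3067_3072del", "p.N1023_I1024del", Consequence.INFRAME_INDEL, False),
    ("BRCA1", "c.68-1G>A", None, Consequence.CANONICAL_SPLICE, False),
    ("BRCA1", "c.81-2A>G", None, Consequence.CANONICAL_SPLICE, False),
    ("BRCA1", None, "p.Q356*", Consequence.NONSENSE, False),
    ("BRCA2", None, "p.K3326*", Consequence.NONSENSE, True),  # last-exon stop
    ("BRCA1", "c.4308T>C", "p.S1436=", Consequence.SYNONYMOUS, False),
    ("BRCA2", None, "p.T582P", Consequence.MISSENSE, False),
    ("BRCA2", "c.100del", None, Consequence.FRAMESHIFT, False),
    ("BRCA2", "c.100_105del", None, Consequence.INFRAME_INDEL, False),
    ("BRCA2", "c.100A>G", None, Consequence.OTHER, False),
])
def test_classify_consequence(models, gene, hgvs_c, hgvs_p, cons, last_exon):
    assert classify_consequence(hgvs_c, hgvs_p, models[gene]) == (cons, last_exon)


def test_consequence_is_deterministic(models):
    tm = models["BRCA2"]
    results = {classify_consequence("c.10219del", "p.N3407fs", tm) for _ in range(5)}
    assert len(results) == 1


def test_contradictory_c_p_pair_raises(models):
    with pytest.raises(ConsistencyError):
        classify_consequence("c.68-1G>A", "p.V23L", models["BRCA1"])


def test_build_variant_key_is_normalized(models):
    v = build_variant("BRCA1", "4957G>T", "p.V1653L", None, models)
    assert v.key == "BRCA1:c.4957G>T"
    assert v.chrom == "17" and v.g_pos == 41222974


def test_read_fixture_variant_table(models, fixture):
    keys = {v.key for v in fixture.variants}
    assert len(fixture.variants) == 15
    assert "BRCA1:c.4957G>T" in keys
    assert "BRCA2:c.10219del" in keys


def test_vcf_round_trip(tmp_path, models):
    variants = [
        build_variant("BRCA1", "c.4957G>T", "p.V1653L", "rs80357261", models),
        build_variant("BRCA2", "c.6131G>T", "p.G2044V", "rs56191579", models),
        build_variant("BRCA2", "c.2350A>G", "p.M784V", None, models),
    ]
    path = tmp_path / "test.vcf"
    write_vcf(path, variants)
    back, skipped = read_vcf(path, models)
    assert not skipped
    assert [v.key for v in back] == [v.key for v in sorted(variants, key=lambda x: x.sort_key)]
    assert all(v.hgvs_p for v in back)


def test_vcf_reader_skips_foreign_chromosomes(tmp_path, models):
    text = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=17,length=81195210>\n"
        "##contig=<ID=5,length=180915260>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "17\t41222974\t.\tC\tA\t.\t.\t.\n"
        "5\t1000\t.\tA\tG\t.\t.\t.\n"
    )
    path = tmp_path / "mixed.vcf"
    path.write_text(text)
    variants, skipped = read_vcf(path, models)
    assert [v.key for v in variants] == ["BRCA1:c.4957G>T"]
    assert len(skipped) == 1
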