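"""Whole-genome alignment, variant scanning/classification, coding
effects, ts/tv counting, pairwise differences and identity."""

import re

import numpy as np
import pytest

from plastovar.alignment import (
    RearrangementError,
    align_plastomes,
    annotate_coding_effect,
    classify_variant,
    compute_pairwise_identity,
    count_ts_tv,
    mark_ir_mirrors,
    pairwise_differences,
    scan_variants,
    variants_to_frame,
    write_minimal_vcf,
)
from plastovar.synthetic import CohortConfig, GenusConfig, PlantCounts, simulate_plastomes
from plastovar.types import GeneFeature, PlastomeRecord, VariantSite

from tests.conftest import random_seq


# ---------------------------------------------------------------------------
# alignment


def test_identical_genomes_align_without_gaps(rng):
    s = random_seq(rng, 5000)
    aln = align_plastomes([PlastomeRecord(id="a", sequence=s), PlastomeRecord(id="b", sequence=s)], "a")
    assert aln.n_columns == 5000
    assert "-" not in aln.rows["b"]
    assert scan_variants(aln) == []


def test_single_70bp_deletion_yields_one_gap_run(rng):
    s = random_seq(rng, 5000)
    deleted = s[:2000] + s[2070:]
    aln = align_plastomes(
        [PlastomeRecord(id="a", sequence=s), PlastomeRecord(id="b", sequence=deleted)], "a"
    )
    runs = re.findall(r"-+", aln.rows["b"])
    assert [len(r) for r in runs] == [70]
    sites = scan_variants(aln)
    assert len(sites) == 1
    assert sites[0].var_class == "InDel"
    assert sites[0].indel_length == 70


def test_degapped_rows_reproduce_inputs(focal_scan, focal):
    aln, _sites, _regions = focal_scan
    genomes, _ref, _truth = focal
    for g in genomes:
        assert aln.rows[g.id].replace("-", "") == g.sequence


def test_rearranged_genome_rejected(rng):
    s = random_seq(rng, 6000)
    swapped = s[3000:] + s[:3000]
    with pytest.raises((RearrangementError, ValueError)):
        align_plastomes(
            [PlastomeRecord(id="a", sequence=s), PlastomeRecord(id="b", sequence=swapped)], "a"
        )


# ---------------------------------------------------------------------------
# scanning vs truth


def test_scan_recovers_planted_truth_exactly(focal_scan, focal):
    """Precision = recall = 1 against the generator's truth tables,
    for positions, classes and every individual's allele string."""
    _aln, sites, _regions = focal_scan
    _genomes, _ref, truth = focal
    tv = truth.variants[truth.variants.genus == "Alnus"]
    got = sorted((s.ref_position, s.var_class) for s in sites)
    assert got == sorted(zip(tv.position, tv.var_class))
    by_pos = {s.ref_position: s for s in sites}
    for _, row in tv.iterrows():
        site = by_pos[row.position]
        carriers = set(row.carriers.split(","))
        for ind, allele in site.alleles.items():
            if ind == "Alnus_ref":
                continue
            assert allele == (row.alt_allele if ind in carriers else row.ref_allele)


def test_scan_coordinates_slice_reference(focal_scan):
    aln, sites, _ = focal_scan
    ref_seq = aln.reference_sequence()
    for s in sites:
        if s.var_class == "SNP":
            ref_allele = ref_seq[s.ref_position]
            assert ref_allele in s.distinct_alleles


def test_scan_class_partition(focal_scan):
    _aln, sites, _ = focal_scan
    counts = {"SNP": 0, "InDel": 0, "homopolymer": 0}
    for s in sites:
        counts[s.var_class] += 1
    assert sum(counts.values()) == len(sites)
    assert counts == {"SNP": 16, "InDel": 5, "homopolymer": 13}


def test_scan_matches_bruteforce_columns_oracle():
    """On equal-length (SNP-only) cohorts the scanner must equal an
    exhaustive column-by-column comparison."""
    cfg = CohortConfig(
        seed=31, genome_length=20_000,
        genera=[GenusConfig("Alnus", 0.0, [("Taymyr", 4), ("Omoloy", 1), ("Kolyma", 2)],
                            PlantCounts(indels=0, homopolymer_diffs=0, shared_indels=0,
                                        shared_homopolymer_diffs=0))],
    )
    genomes, _ = simulate_plastomes(cfg)
    aln = align_plastomes([g for g in genomes if g.taxon == "Alnus"], "Alnus_ref")
    sites = scan_variants(aln)
    inds = [g for g in genomes if g.role == "individual"]
    brute = [
        i
        for i in range(len(inds[0].sequence))
        if len({g.sequence[i] for g in inds}) > 1
    ]
    assert [s.ref_position for s in sites] == brute


# ---------------------------------------------------------------------------
# classification rules


@pytest.mark.parametrize(
    "alleles, context, expected",
    [
        ({"a": "A", "b": "A", "c": "G"}, "", ("SNP", "transition")),
        ({"a": "A", "b": "A", "c": "T"}, "", ("SNP", "transversion")),
        ({"a": "C", "b": "T"}, "", ("SNP", "transition")),
        ({"a": "A", "b": "C", "c": "G"}, "", ("SNP", "multiallelic")),
        # TTTT vs TTTTT inside a poly-T run (minimal anchored form)
        ({"a": "G", "b": "GT"}, "ACGTACG|G|TTTTACGAT", ("homopolymer", "none")),
        # gap with mixed bases and no qualifying run
        ({"a": "G", "b": "GACT"}, "ACGTACG|G|CCATTGCA", ("InDel", "none")),
        ({"a": "GACTG", "b": "G"}, "ACGTACG|GACTG|CATTGCA", ("InDel", "none")),
        ({"a": "A", "b": "N"}, "", ("ambiguous", "none")),
    ],
)
def test_classify_variant_rule_order(alleles, context, expected):
    assert classify_variant(alleles, context) == expected


def test_classify_needs_two_alleles():
    with pytest.raises(ValueError):
        classify_variant({"a": "A", "b": "A"})


# ---------------------------------------------------------------------------
# coding effects


def _toy_genome_with_cds(cds: str, strand="+"):
    lead, tail = "GGGGGCCCCC", "AAAAATTTTT"
    from plastovar._dna import revcomp

    body = cds if strand == "+" else revcomp(cds)
    seq = lead + body + tail
    feat = GeneFeature(name="toy", start=len(lead), end=len(lead) + len(cds), strand=strand, kind="CDS")
    return seq, [feat]


def test_synonymous_third_position():
    seq, feats = _toy_genome_with_cds("ATGGCTTGA")  # Met-Ala-Stop
    pos = 10 + 5  # third base of GCT
    site = VariantSite(ref_position=pos, var_class="SNP", alleles={"x": "T", "y": "C"})
    eff = annotate_coding_effect(site, feats, seq)
    assert eff.synonymous and eff.ref_aa == "A" and eff.alt_aa == "A"


def test_nonsynonymous_pro_to_ala():
    seq, feats = _toy_genome_with_cds("ATGCCTTGA")  # Met-Pro-Stop
    pos = 10 + 3  # first base of CCT -> GCT
    site = VariantSite(ref_position=pos, var_class="SNP", alleles={"x": "C", "y": "G"})
    eff = annotate_coding_effect(site, feats, seq)
    assert not eff.synonymous
    assert (eff.ref_aa, eff.alt_aa) == ("P", "A")
    assert (eff.ref_property, eff.alt_property) == ("hydrophilic", "hydrophilic")


def test_hand_translated_asn_to_thr():
    seq, feats = _toy_genome_with_cds("ATGAATTGA")  # Met-Asn-Stop
    pos = 10 + 4  # AAT -> ACT at codon 2, position 2
    site = VariantSite(ref_position=pos, var_class="SNP", alleles={"x": "A", "y": "C"})
    eff = annotate_coding_effect(site, feats, seq)
    assert (eff.ref_aa, eff.alt_aa) == ("N", "T")
    assert eff.codon_index == 1


def test_reverse_strand_codon():
    seq, feats = _toy_genome_with_cds("ATGAATTGA", strand="-")
    # genome carries revcomp(CDS); codon 2 pos 2 (the Asn A->C change)
    # sits at genome position lead + len - 1 - 4
    pos = 10 + 9 - 1 - 4
    site = VariantSite(ref_position=pos, var_class="SNP", alleles={"x": "T", "y": "G"})
    eff = annotate_coding_effect(site, feats, seq)
    assert (eff.ref_aa, eff.alt_aa) == ("N", "T")


def test_noncoding_site_returns_none():
    seq, feats = _toy_genome_with_cds("ATGAATTGA")
    site = VariantSite(ref_position=2, var_class="SNP", alleles={"x": "G", "y": "T"})
    assert annotate_coding_effect(site, feats, seq) is None


# ---------------------------------------------------------------------------
# counting, differences, identity


def test_ts_tv_counts(focal_scan, focal):
    _aln, sites, _ = focal_scan
    assert count_ts_tv(sites) == {"transitions": 8, "transversions": 8, "multiallelic": 0}
    assert count_ts_tv([]) == {"transitions": 0, "transversions": 0, "multiallelic": 0}


def test_pairwise_differences_toy_oracle():
    sites = [
        VariantSite(0, "SNP", {"x": "A", "y": "G", "z": "A"}),
        VariantSite(10, "SNP", {"x": "C", "y": "C", "z": "T"}),
        VariantSite(20, "InDel", {"x": "ATTT", "y": "A", "z": "A"}, indel_length=3),
        VariantSite(30, "homopolymer", {"x": "C", "y": "CA", "z": "C"}),
    ]
    mat = pairwise_differences(sites)
    # hand count (homopolymer excluded): x-y: sites 0,20; x-z: 10,20; y-z: 0,10
    assert mat.loc["x", "y"] == 2
    assert mat.loc["x", "z"] == 2
    assert mat.loc["y", "z"] == 2
    assert (np.diag(mat.values) == 0).all()
    assert (mat.values == mat.values.T).all()


def test_pairwise_differences_identical_pair(focal_scan):
    _aln, sites, _ = focal_scan
    mat = pairwise_differences(sites)
    assert mat.loc["Alnus_ref", "Alnus_ref"] == 0


def test_pairwise_identity_examples(rng):
    s = random_seq(rng, 2000)
    assert compute_pairwise_identity(s, s) == 1.0
    assert compute_pairwise_identity(s, s[:1000]) <= 0.5
    # hand-computable toy: ACGT vs AGGT -> 1 mismatch over 4 columns
    assert compute_pairwise_identity("ACGT", "AGGT") == pytest.approx(0.75)
    # gap columns count in the denominator: ACGT vs ACG -> 3/4
    assert compute_pairwise_identity("ACGT", "ACG") == pytest.approx(0.75)
    with pytest.raises(ValueError):
        compute_pairwise_identity("", "ACGT")


def test_ir_mirror_cross_reference():
    bounds = {"IRb": (100, 200), "IRa": (300, 400)}
    s1 = VariantSite(150, "SNP", {"x": "A", "y": "G"}, snp_subtype="transition")
    s2 = VariantSite(349, "SNP", {"x": "T", "y": "C"}, snp_subtype="transition")  # mirror of 150
    sites = [s1, s2]
    mark_ir_mirrors(sites, bounds)
    assert s1.ir_mirror_of == 349 and s2.ir_mirror_of == 150
    assert count_ts_tv(sites)["transitions"] == 1  # counted once


def test_variant_frame_and_vcf_export(tmp_path, focal_scan):
    aln, sites, _ = focal_scan
    df = variants_to_frame(sites)
    assert len(df) == len(sites)
    assert (df.position == [s.ref_position + 1 for s in sorted(sites, key=lambda x: x.ref_position)]).all()
    path = tmp_path / "v.vcf"
    write_minimal_vcf(sites, aln.ref_id, aln.reference_sequence(), path)
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == len(sites)
    for line in lines:
        fields = line.split("\t")
        pos, ref_allele = int(fields[1]), fields[3]
        assert aln.reference_sequence()[pos - 1: pos - 1 + len(ref_allele)] == ref_allele
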