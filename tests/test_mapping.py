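"""Seed-and-extend mapping, duplicate marking, coverage, abundance
arithmetic, damage profiling and provenance ranking."""

import numpy as np
import pandas as pd
import pytest

from plastovar._dna import revcomp
from plastovar.datasets import sediment_read_counts
from plastovar.mapping import (
    MODERN_PRESET,
    coverage_stats,
    damage_profile,
    dedup_counts,
    map_reads,
    mark_duplicates,
    provenance_scores,
    relative_abundance,
)
from plastovar.synthetic import CohortConfig, DamageConfig, SampleConfig, simulate_plastomes, simulate_reads
from plastovar.types import Read

from tests.conftest import random_seq


def _r(rid, seq, q=40):
    return Read(id=rid, sequence=seq, qualities=chr(q + 33) * len(seq))


@pytest.fixture(scope="module")
def ref(request):
    rng = np.random.default_rng(2718)
    return random_seq(rng, 8000)


# ---------------------------------------------------------------------------
# mapping


def test_exact_substring_maps_at_source(ref):
    a = map_reads([_r("x", ref[500:560])], "ref", ref)[0]
    assert (a.start, a.end, a.strand, a.mismatches) == (500, 560, "+", 0)
    assert a.cigar == "60="


def test_reverse_strand_read_maps(ref):
    a = map_reads([_r("x", revcomp(ref[500:560]))], "ref", ref)[0]
    assert (a.start, a.end, a.strand) == (500, 560, "-")


def test_origin_wrapping_read_maps_end_to_end(ref):
    frag = ref[-30:] + ref[:30]
    a = map_reads([_r("x", frag)], "ref", ref)[0]
    assert a.start == len(ref) - 30
    assert a.end - a.start == 60


def test_mismatch_threshold_rejects(ref):
    frag = list(ref[1000:1060])
    for i in range(0, 30, 5):  # 6 mismatches = 10%, clustered so seeds remain
        frag[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[i]]
    read = _r("x", "".join(frag))
    assert map_reads([read], "ref", ref, max_mismatch_frac=0.05) == []
    assert len(map_reads([read], "ref", ref, **MODERN_PRESET)) == 1


def test_read_spanning_reference_deletion(ref):
    # 120 nt read matching a donor with a 5 bp deletion relative to the
    # reference: one 5 bp gap (4.2% gap bases, within the 5% budget)
    frag = ref[2000:2060] + ref[2065:2125]
    a = map_reads([_r("x", frag)], "ref", ref)[0]
    assert a.gap_bases == 5
    assert "5D" in a.cigar
    assert (a.start, a.end) == (2000, 2125)


def test_empty_reference_rejected():
    with pytest.raises(ValueError):
        map_reads([_r("x", "ACGT" * 20)], "ref", "")


# ---------------------------------------------------------------------------
# duplicates


def test_identical_coordinates_marked(ref):
    reads = [_r("a", ref[100:160], 30), _r("b", ref[100:160], 40)]
    alns = mark_duplicates(map_reads(reads, "ref", ref))
    kept = [a for a in alns if not a.duplicate]
    assert len(kept) == 1
    assert kept[0].read_id == "b"  # highest quality sum wins
    assert dedup_counts(alns) == (1, 2)


def test_different_end_not_duplicate(ref):
    alns = mark_duplicates(map_reads([_r("a", ref[100:160]), _r("b", ref[100:170])], "ref", ref))
    assert dedup_counts(alns) == (2, 2)


def test_dedup_idempotent_and_order_invariant(cohort):
    genomes, _ = cohort
    g = next(x for x in genomes if x.id == "Alnus_ref")
    samp = SampleConfig("s", {"Alnus": 1.0}, n_reads=2000, damage=DamageConfig(0, 0, 0.3))
    reads, _ = simulate_reads([g], samp, seed=12)
    alns = map_reads(reads, g.id, g.sequence)
    once = mark_duplicates(alns)
    twice = mark_duplicates(once)
    key = lambda a: (a.read_id, a.duplicate)
    assert sorted(map(key, once)) == sorted(map(key, twice))
    rev = mark_duplicates(list(reversed(alns)))
    assert sorted(map(key, once)) == sorted(map(key, rev))


def test_duplication_rate_recovered(cohort):
    from plastovar.synthetic import duplicate_reads

    genomes, _ = cohort
    g = next(x for x in genomes if x.id == "Alnus_ref")
    samp = SampleConfig("s", {"Alnus": 1.0}, n_reads=1500, damage=DamageConfig(0, 0, 0.3))
    reads, _ = simulate_reads([g], samp, seed=13)
    dup = duplicate_reads(reads, 0.3, seed=14)
    alns = mark_duplicates(map_reads(dup, g.id, g.sequence))
    kept, total = dedup_counts(alns)
    # geometric resampling at rate r inflates totals by 1/(1-r)
    ratio = kept / total
    p = 0.7
    assert abs(ratio - p) <= 3 * np.sqrt(p * (1 - p) / total)


# ---------------------------------------------------------------------------
# coverage


def test_breadth_single_read(ref):
    alns = mark_duplicates(map_reads([_r("x", ref[0:800])], "ref", ref))
    _, breadth = coverage_stats(alns, len(ref))
    assert breadth == pytest.approx(10.0)


def test_breadth_full_tiling(ref):
    reads = [_r(f"t{i}", ref[i: i + 100]) for i in range(0, len(ref) - 99, 50)]
    reads.append(_r("tail", ref[-100:] + ref[:20]))
    alns = mark_duplicates(map_reads(reads, "ref", ref))
    _, breadth = coverage_stats(alns, len(ref))
    assert breadth == pytest.approx(100.0)


def test_breadth_matches_position_set_oracle(ref, rng):
    starts = rng.integers(0, len(ref) - 60, size=1000)
    reads = [_r(f"r{i}", ref[s: s + 60]) for i, s in enumerate(starts)]
    alns = mark_duplicates(map_reads(reads, "ref", ref))
    depth, breadth = coverage_stats(alns, len(ref))
    covered = set()
    for a in alns:
        if not a.duplicate:
            covered.update(range(a.start, a.end))
    assert breadth == pytest.approx(100 * len(covered) / len(ref))
    assert int((depth > 0).sum()) == len(covered)


# ---------------------------------------------------------------------------
# relative abundance


def test_relative_abundance_published_counts():
    counts = pd.DataFrame(
        [
            dict(sample="6700 cal yr BP", method="capture", taxon="Alnus", read_count=1072),
            dict(sample="6700 cal yr BP", method="capture", taxon="Betula", read_count=37),
            dict(sample="6700 cal yr BP", method="capture", taxon="Salix", read_count=1164),
        ]
    )
    out = relative_abundance(counts).set_index("taxon")
    assert out.loc["Alnus", "relative_pct"] == 47.16
    assert out.loc["Betula", "relative_pct"] == 1.63
    assert out.loc["Salix", "relative_pct"] == 51.21


@pytest.mark.parametrize(
    "counts, expected",
    [((10, 0, 0), (100.0, 0.0, 0.0)), ((1, 1, 1), (33.33, 33.33, 33.33))],
)
def test_relative_abundance_edge_cases(counts, expected):
    df = pd.DataFrame(
        [dict(sample="s", method="m", taxon=t, read_count=c) for t, c in zip("ABC", counts)]
    )
    out = relative_abundance(df)
    assert tuple(out.relative_pct) == expected


def test_all_zero_sample_flagged():
    df = pd.DataFrame([dict(sample="s", method="m", taxon=t, read_count=0) for t in "ABC"])
    out = relative_abundance(df)
    assert out.undefined.all()
    assert out.relative_pct.isna().all()


def test_bundled_table_recomputes_to_published_percentages():
    """Recomputing relative percentages from the bundled post-dedup
    counts reproduces the published column to 2 decimals, and each
    recomputed (sample, method) row set sums to 100 within rounding."""
    df = sediment_read_counts().rename(columns={"total": "read_count"})
    out = relative_abundance(df[["sample", "method", "taxon", "read_count"]])
    merged = out.merge(df, on=["sample", "method", "taxon"], suffixes=("_calc", "_pub"))
    assert (merged.relative_pct_calc == merged.relative_pct_pub).all()
    sums = out.groupby(["sample", "method"]).relative_pct.sum()
    assert ((sums - 100).abs() <= 0.02).all()  # per-entry rounding to 2 dp


# ---------------------------------------------------------------------------
# damage


def test_damage_free_terminal_rates_near_baseline(cohort):
    genomes, _ = cohort
    g = next(x for x in genomes if x.id == "Alnus_ref")
    samp = SampleConfig("s", {"Alnus": 1.0}, n_reads=4000, damage=DamageConfig(0, 0, 0.3))
    reads, _ = simulate_reads([g], samp, seed=21, baseline_error=0.002)
    prof = damage_profile(mark_duplicates(map_reads(reads, g.id, g.sequence)), g.sequence)
    # a baseline error is C->T in 1/3 of cases
    null_rate = prof.baseline / 3
    se = np.sqrt(max(null_rate, 1e-4) / 900)
    assert prof.ct5[0] <= null_rate + 4 * se
    assert prof.ga3[0] <= null_rate + 4 * se


def test_damage_recovery_generative(cohort):
    genomes, _ = cohort
    g = next(x for x in genomes if x.id == "Alnus_ref")
    samp = SampleConfig("s", {"Alnus": 1.0}, n_reads=12_000, damage=DamageConfig(0.3, 0.3, 0.2))
    reads, _ = simulate_reads([g], samp, seed=22, baseline_error=0.001)
    prof = damage_profile(mark_duplicates(map_reads(reads, g.id, g.sequence, **MODERN_PRESET)), g.sequence)
    expected = 0.3 * np.exp(-0.2 * np.arange(prof.window))
    assert abs(prof.ct5[0] - 0.3) <= 0.02
    assert abs(prof.ga3[0] - 0.3) <= 0.02
    assert np.all(np.abs(prof.ct5[:10] - expected[:10]) <= 0.03)


def test_damage_profile_strand_mirror(cohort):
    """Reverse-complementing the input data swaps the roles of the two
    ends; the profile is computed in sequencing orientation so the
    curves must stay put."""
    genomes, _ = cohort
    g = next(x for x in genomes if x.id == "Alnus_ref")
    samp = SampleConfig("s", {"Alnus": 1.0}, n_reads=6000, damage=DamageConfig(0.3, 0.0, 0.2))
    reads, _ = simulate_reads([g], samp, seed=23, baseline_error=0.0)
    alns = mark_duplicates(map_reads(reads, g.id, g.sequence, **MODERN_PRESET))
    prof = damage_profile(alns, g.sequence)
    # only 5' C->T was simulated: it must appear on ct5 and not on ga3,
    # regardless of which genomic strand each fragment came from
    assert prof.ct5[0] > 0.25
    assert prof.ga3[0] < 0.02
    strands = {a.strand for a in alns}
    assert strands == {"+", "-"}


def test_damage_profile_requires_alignments():
    with pytest.raises(ValueError):
        damage_profile([], "ACGT")


# ---------------------------------------------------------------------------
# provenance


def test_provenance_ranks_true_source_first(focal, cohort):
    genomes, _ = cohort
    alnus, ref, _truth = focal
    donor = next(g for g in alnus if g.id == "A01")
    samp = SampleConfig("s", {"Alnus": 1.0}, n_reads=1200, damage=DamageConfig(0, 0, 0.3))
    reads, _ = simulate_reads([donor], samp, seed=31, baseline_error=0.0)
    candidates = [(g.id, g.sequence) for g in alnus if g.role == "individual"]
    scores = provenance_scores(reads, candidates)
    assert scores[0].genome_id == "A01"
    for s in scores:
        assert s.identical_bases <= s.covered_bases


def test_provenance_tied_for_identical_candidates(ref):
    reads = [_r(f"r{i}", ref[i * 40: i * 40 + 60]) for i in range(30)]
    scores = provenance_scores(reads, [("c1", ref), ("c2", ref)])
    assert scores[0].identical_bases == scores[1].identical_bases
    with pytest.raises(ValueError):
        provenance_scores(reads, [("c1", ref)])


def test_provenance_zero_mapped(ref, rng):
    other = random_seq(rng, 3000)
    reads = [_r("r", other[100:160])]
    scores = provenance_scores(reads, [("c1", ref), ("c2", ref[::-1])])
    assert all(s.aligned_reads == 0 and s.identical_bases == 0 for s in scores)
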