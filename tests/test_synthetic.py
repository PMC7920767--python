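"""Generator invariants: determinism, quadripartite structure, planted
variant recoverability, read mixture statistics, capture filtering."""

import numpy as np
import pandas as pd
import pytest

from plastovar._dna import revcomp
from plastovar.synthetic import (
    BaitConfig,
    CohortConfig,
    DamageConfig,
    GenusConfig,
    PlantCounts,
    SampleConfig,
    conservation_track,
    duplicate_reads,
    make_bait_genome,
    read_truth,
    simulate_capture,
    simulate_plastomes,
    simulate_reads,
    write_truth,
)


def snp_only_config(seed=3):
    return CohortConfig(
        seed=seed,
        genome_length=20_000,
        genera=[
            GenusConfig(
                "Alnus",
                0.0,
                [("Taymyr", 4), ("Omoloy", 1), ("Kolyma", 2)],
                PlantCounts(indels=0, homopolymer_diffs=0, shared_indels=0, shared_homopolymer_diffs=0),
            )
        ],
    )


def test_zero_variants_yields_identical_individuals():
    cfg = CohortConfig(
        seed=5,
        genome_length=20_000,
        genera=[GenusConfig("Alnus", 0.0, [("Taymyr", 3)], PlantCounts(0, 0, 0, 0, 0, 0, 0, 0))],
    )
    genomes, truth = simulate_plastomes(cfg)
    seqs = {g.sequence for g in genomes if g.role == "individual"}
    assert len(seqs) == 1
    assert truth.variants.empty


def test_seed_determinism_byte_identical(tmp_path):
    out_a, out_b = tmp_path / "a", tmp_path / "b"
    for out in (out_a, out_b):
        genomes, truth = simulate_plastomes(CohortConfig(seed=7, genome_length=20_000))
        with open(out.with_suffix(".fasta"), "w") as fh:
            for g in genomes:
                fh.write(f">{g.id}\n{g.sequence}\n")
        out.mkdir()
        write_truth(truth, out)
    assert out_a.with_suffix(".fasta").read_bytes() == out_b.with_suffix(".fasta").read_bytes()
    for name in ("variants", "markers"):
        assert (out_a / f"truth_{name}.tsv").read_bytes() == (out_b / f"truth_{name}.tsv").read_bytes()


def test_ir_mirror_invariant():
    cfg = CohortConfig(seed=9, genome_length=20_000)
    genomes, _ = simulate_plastomes(cfg)
    rl = cfg.resolved_region_lengths()
    b0 = rl["LSC"]
    b1 = b0 + rl["IRb"]
    a0 = b1 + rl["SSC"]
    for g in genomes:
        if g.role == "reference":
            assert g.sequence[a0:] == revcomp(g.sequence[b0:b1]), g.id


def test_column_scan_oracle_recovers_planted_snps():
    """Exhaustive alignment-free column comparison of the emitted genomes
    recovers exactly the planted SNP positions and subtypes."""
    genomes, truth = simulate_plastomes(snp_only_config())
    inds = [g for g in genomes if g.role == "individual"]
    L = len(inds[0].sequence)
    assert all(len(g.sequence) == L for g in inds)
    found = []
    for i in range(L):
        col = {g.sequence[i] for g in inds}
        if len(col) > 1:
            found.append(i)
    tv = truth.variants
    assert sorted(found) == sorted(tv.position)
    assert (tv.var_class == "SNP").all()
    assert (tv.subtype == "transition").sum() == 8
    assert (tv.subtype == "transversion").sum() == 8
    # subtypes verified against the emitted alleles themselves
    purines = set("AG")
    for _, r in tv.iterrows():
        is_ts = ({r.ref_allele, r.alt_allele} <= purines) or ({r.ref_allele, r.alt_allele} <= set("CT"))
        assert is_ts == (r.subtype == "transition")


def test_read_mixture_binomial_bounds():
    genomes, _ = simulate_plastomes(CohortConfig(seed=2, genome_length=20_000))
    props = {"Alnus": 0.5, "Betula": 0.3, "Salix": 0.2}
    n = 10_000
    seeds = (123, 124, 125)
    totals = {t: 0 for t in props}
    for seed in seeds:
        samp = SampleConfig("s", props, n_reads=n, damage=DamageConfig(0, 0, 0.3))
        reads, tr = simulate_reads(genomes, samp, seed=seed)
        assert len(reads) == n  # conservation: all reads emitted before capture
        assert len(tr) == n
        for taxon in props:
            totals[taxon] += int((tr.taxon == taxon).sum())
    big_n = n * len(seeds)
    for taxon, p in props.items():
        sd = np.sqrt(big_n * p * (1 - p))
        assert abs(totals[taxon] - big_n * p) <= 3 * sd


def test_fragment_length_mean_recovered():
    genomes, _ = simulate_plastomes(CohortConfig(seed=2, genome_length=20_000))
    samp = SampleConfig("s", {"Alnus": 1.0}, n_reads=4000, fragment_length_mean=60,
                        fragment_length_sd=10, damage=DamageConfig(0, 0, 0.3))
    reads, tr = simulate_reads(genomes, samp, seed=321)
    # truncation at 30 skews the mean upward slightly; 2 SE of the
    # empirical SD around the true (truncated-normal) mean ~ 60.1
    se = tr.length.std() / np.sqrt(len(tr))
    assert abs(tr.length.mean() - 60) <= 2 * se + 0.2


def test_zero_damage_gives_baseline_terminal_rate():
    genomes, _ = simulate_plastomes(CohortConfig(seed=2, genome_length=20_000))
    ref = next(g for g in genomes if g.id == "Alnus_ref")
    samp = SampleConfig("s", {"Alnus": 1.0}, n_reads=3000, damage=DamageConfig(0, 0, 0.3))
    reads, tr = simulate_reads([ref], samp, seed=11, baseline_error=0.003)
    s2 = ref.sequence * 2
    n_c = n_t = 0
    for r, (_, row) in zip(reads, tr.iterrows()):
        frag = s2[row.start: row.start + row.length]
        if row.strand == "-":
            frag = revcomp(frag)
        if frag[0] == "C":
            n_c += 1
            n_t += r.sequence[0] == "T"
    rate = n_t / n_c
    # baseline errors hit C->T a third of the time
    expected = 0.003 / 3
    assert rate <= expected + 3 * np.sqrt(expected / n_c)


def test_simulate_reads_input_validation():
    genomes, _ = simulate_plastomes(CohortConfig(seed=2, genome_length=20_000))
    samp = SampleConfig("s", {"Alnus": 1.0}, n_reads=0)
    with pytest.raises(ValueError):
        simulate_reads(genomes, samp, seed=1)
    with pytest.raises(ValueError):
        simulate_reads([], SampleConfig("s", {"Alnus": 1.0}, n_reads=10), seed=1)
    with pytest.raises(ValueError):
        SampleConfig("s", {"Alnus": 0.6, "Betula": 0.3})  # proportions must sum to 1


class TestCapture:
    def _setup(self, bait_cfg, seed=4):
        genomes, truth = simulate_plastomes(CohortConfig(seed=seed, genome_length=20_000, bait=bait_cfg))
        ref = next(g for g in genomes if g.id == "Alnus_ref")
        samp = SampleConfig("s", {"Alnus": 1.0}, n_reads=4000, damage=DamageConfig(0, 0, 0.3))
        reads, tr = simulate_reads([ref], samp, seed=77)
        return genomes, ref, reads, tr

    def test_identical_bait_retains_at_conserved_rate(self):
        bait_cfg = BaitConfig(bait_taxon_divergence=0.0, p_retain_conserved=0.8, p_retain_diverged=0.0)
        genomes, ref, reads, tr = self._setup(bait_cfg)
        kept, log = simulate_capture(reads, tr, genomes, ref.sequence, bait_cfg, seed=5)
        n = len(reads)
        rate = len(kept) / n
        assert log.conserved.all()
        assert abs(rate - 0.8) <= 3 * np.sqrt(0.8 * 0.2 / n)
        assert all(r.method == "capture" for r in kept)

    def test_fully_diverged_genus_zero_survivors(self):
        bait_cfg = BaitConfig(bait_taxon_divergence=0.35, conserved_fraction=0.0,
                              p_retain_conserved=0.9, p_retain_diverged=0.0)
        genomes, ref, reads, tr = self._setup(bait_cfg)
        bait = make_bait_genome(ref.sequence, bait_cfg, seed=9)
        kept, log = simulate_capture(reads, tr, genomes, bait, bait_cfg, seed=5)
        assert kept == []
        assert not log.conserved.any()

    def test_mixed_conservation_rates_within_binomial_bounds(self):
        bait_cfg = BaitConfig(bait_taxon_divergence=0.35, conserved_fraction=0.5,
                              p_retain_conserved=0.9, p_retain_diverged=0.1)
        genomes, ref, reads, tr = self._setup(bait_cfg)
        bait = make_bait_genome(ref.sequence, bait_cfg, seed=9)
        kept, log = simulate_capture(reads, tr, genomes, bait, bait_cfg, seed=5)
        for conserved, p in ((True, 0.9), (False, 0.1)):
            sub = log[log.conserved == conserved]
            n = len(sub)
            rate = sub.retained.mean()
            assert abs(rate - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_missing_bait_rejected(self):
        bait_cfg = BaitConfig()
        genomes, ref, reads, tr = self._setup(bait_cfg)
        with pytest.raises(ValueError):
            simulate_capture(reads, tr, genomes, "", bait_cfg, seed=5)


def test_conservation_track_windows(rng):
    from tests.conftest import random_seq

    g = random_seq(rng, 1000)
    bait = g[:500] + random_seq(rng, 500)
    track = conservation_track(g, bait, window=100)
    assert (track[:5] == 1.0).all()
    assert (track[5:] < 0.9).all()


def test_duplicate_reads_rate():
    genomes, _ = simulate_plastomes(CohortConfig(seed=2, genome_length=20_000))
    samp = SampleConfig("s", {"Alnus": 1.0}, n_reads=2000, damage=DamageConfig(0, 0, 0.3))
    reads, _ = simulate_reads(genomes, samp, seed=8)
    dups = duplicate_reads(reads, rate=0.3, seed=9)
    extra = len(dups) - len(reads)
    # geometric resampling: expected extras = n * rate / (1 - rate)
    exp = len(reads) * 0.3 / 0.7
    assert abs(extra - exp) <= 3 * np.sqrt(exp)


def test_truth_tables_round_trip(tmp_path):
    genomes, truth = simulate_plastomes(CohortConfig(seed=7, genome_length=20_000))
    samp = SampleConfig("s", {"Alnus": 1.0}, n_reads=1000, damage=DamageConfig(0, 0, 0.3))
    _, truth.reads = simulate_reads(genomes, samp, seed=3)
    write_truth(truth, tmp_path)
    back = read_truth(tmp_path)
    pd.testing.assert_frame_equal(truth.variants, back.variants)
    pd.testing.assert_frame_equal(truth.reads, back.reads)
    assert len(back.reads) == 1000


def test_empty_truth_table_round_trips_header_only(tmp_path):
    cfg = CohortConfig(
        seed=5, genome_length=20_000,
        genera=[GenusConfig("Alnus", 0.0, [("Taymyr", 2)], None)],
    )
    _, truth = simulate_plastomes(cfg)
    write_truth(truth, tmp_path)
    text = (tmp_path / "truth_variants.tsv").read_text().strip().splitlines()
    assert len(text) == 1  # header only
    back = read_truth(tmp_path)
    assert back.variants.empty
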