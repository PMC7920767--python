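"""End-to-end orchestration: simulate -> variants -> network -> markers
-> trim -> classify -> map -> stats -> tally -> confirm.

Every stage writes its artifacts under ``outdir`` as it completes, so a
failed run preserves partial output; a manifest records inputs,
parameters, seed and versions.  All randomness flows from the single
config seed (stage-specific streams are derived deterministically), so
re-running a config reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import align_plastomes, scan_variants, variants_to_frame, write_minimal_vcf
from .io import ensure_dir, read_fasta, read_fastq, write_fasta, write_fastq, write_gff3
from .markers import markers_to_frame, screen_region_diagnostic
from .mapping import (
    ANCIENT_PRESET,
    MODERN_PRESET,
    ReferenceIndex,
    coverage_stats,
    damage_profile,
    map_reads,
    mark_duplicates,
    relative_abundance,
)
from .network import (
    build_tcs_network,
    collapse_haplotypes,
    connection_limit,
    export_network,
    haplotype_distances,
)
from .reads import build_kmer_index, classify_reads, extract_genus_reads, trim_reads
from .synthetic import (
    BaitConfig,
    CohortConfig,
    make_bait_genome,
    simulate_capture,
    simulate_plastomes,
    simulate_reads,
    write_truth,
)
from .tracking import confirm_markers, evaluate_sites, evaluations_to_frame, tally_alleles

STAGES = (
    "simulate",
    "variants",
    "network",
    "markers",
    "trim",
    "classify",
    "map",
    "stats",
    "tally",
    "confirm",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "plastovar_out"
    seed: int = 0
    core_region: str = "Taymyr"
    focal_genus: str = "Alnus"
    simulate: bool = True
    genome_length: int = 20_000
    n_reads_per_sample: int = 2_000
    genomes_path: str | None = None  # external modern genomes (FASTA)
    reads_path: str | None = None  # external ancient reads (FASTQ)
    trim: dict = field(default_factory=lambda: dict(window=4, avg_q=15.0, end_q=3, min_len=40))
    classify: dict = field(default_factory=lambda: dict(k=31, min_hits=2))
    map_preset: str = "ancient"
    network: dict = field(default_factory=lambda: dict(alpha=0.95, include_indels=False))
    capture: bool = True

    KNOWN_KEYS = None  # filled below

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig, through: str = "confirm") -> dict:
    """Run stages in order up to ``through``; returns the report bundle."""
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    outdir = ensure_dir(config.outdir)
    bundle: dict = {"config": config, "outdir": outdir}
    manifest = {
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()},
        "stages": [],
    }
    last = STAGES.index(through)
    for stage in STAGES[: last + 1]:
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, bundle)
        except Exception as exc:  # noqa: BLE001 - abort with the failing stage named
            raise PipelineError(stage, exc) from exc
        manifest["stages"].append({"name": stage, "seconds": round(time.time() - t0, 3)})
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    if through == "confirm":
        make_report(bundle)
    return bundle


# --------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig, b: dict) -> None:
    out = b["outdir"]
    if cfg.simulate:
        cc = CohortConfig(seed=cfg.seed, genome_length=cfg.genome_length)
        for s in cc.samples:
            s.n_reads = cfg.n_reads_per_sample
            s.local_region = cfg.core_region
        genomes, truth = simulate_plastomes(cc)
        reads = []
        truth_reads = []
        for i, samp in enumerate(cc.samples):
            rr, tt = simulate_reads(genomes, samp, seed=cfg.seed * 1009 + 17 * i + 1,
                                    baseline_error=cc.baseline_error)
            reads.extend(rr)
            truth_reads.append(tt)
        truth.reads = pd.concat(truth_reads, ignore_index=True)
        if cfg.capture:
            rl = cc.resolved_region_lengths()
            bounds, pos = {}, 0
            for name in ("LSC", "IRb", "SSC", "IRa"):
                bounds[name] = (pos, pos + rl[name])
                pos += rl[name]
            bait = make_bait_genome(
                next(g for g in genomes if g.id == f"{cfg.focal_genus}_ref").sequence,
                cc.bait, seed=cfg.seed * 2003 + 5, bounds=bounds,
            )
            cap, log = simulate_capture(reads, truth.reads, genomes, bait, cc.bait,
                                        seed=cfg.seed * 3001 + 7)
            truth.capture = log
            cap_truth = truth.reads[truth.reads.read_id.isin({r.id for r in cap})].copy()
            cap_truth["method"] = "capture"
            truth.reads = pd.concat([truth.reads, cap_truth], ignore_index=True)
            reads = reads + cap
        truth.proportions = pd.DataFrame(
            [
                dict(sample=s.age_label, method=m, taxon=t, proportion=p, n_reads=s.n_reads)
                for s in cc.samples
                for m in (("shotgun", "capture") if cfg.capture else ("shotgun",))
                for t, p in sorted(s.taxon_proportions.items())
            ]
        )
        b["cohort_config"] = cc
        b["genomes"], b["truth"], b["reads"] = genomes, truth, reads
        write_fasta(genomes, os.path.join(out, "genomes.fasta"))
        write_gff3(genomes[0].features, f"{cfg.focal_genus}_ref", os.path.join(out, "features.gff3"))
        write_truth(truth, out)
        for method in sorted({r.method for r in reads}):
            write_fastq([r for r in reads if r.method == method],
                        os.path.join(out, f"reads_{method}.fastq"))
    else:
        if not cfg.genomes_path:
            raise ValueError("simulate disabled but no genomes_path given")
        b["genomes"] = read_fasta(cfg.genomes_path)
        b["truth"] = None
        if cfg.reads_path:
            b["reads"] = read_fastq(cfg.reads_path)
        else:
            raise ValueError("classify/map stages enabled but no reads_path given")


def _focal(b, cfg):
    return [g for g in b["genomes"] if g.taxon == cfg.focal_genus or not g.taxon]


def _stage_variants(cfg: PipelineConfig, b: dict) -> None:
    genomes = _focal(b, cfg)
    ref = next((g for g in genomes if g.role == "reference"), genomes[0])
    aln = align_plastomes(genomes, ref.id)
    sites = scan_variants(aln)
    b["alignment"], b["sites"], b["ref"] = aln, sites, ref
    b["regions"] = {g.id: g.region_label for g in genomes if g.role == "individual" and g.region_label}
    out = b["outdir"]
    aln.write_fasta(os.path.join(out, "alignment.fasta"))
    variants_to_frame(sites).to_csv(os.path.join(out, "variants.tsv"), sep="\t", index=False)
    write_minimal_vcf(sites, ref.id, ref.sequence, os.path.join(out, "variants.vcf"))


def _stage_network(cfg: PipelineConfig, b: dict) -> None:
    haps = collapse_haplotypes(
        b["sites"], b["regions"],
        include_indels=bool(cfg.network.get("include_indels", False)),
        exclude={b["ref"].id},
    )
    dist = haplotype_distances(haps)
    limit = connection_limit(b["alignment"].n_columns, float(cfg.network.get("alpha", 0.95)))
    net = build_tcs_network(haps, dist, limit, float(cfg.network.get("alpha", 0.95)))
    b["haplotypes"], b["network"] = haps, net
    out = b["outdir"]
    pd.DataFrame(
        [dict(haplotype=h.id, members=",".join(h.members), regions=",".join(h.regions)) for h in haps]
    ).to_csv(os.path.join(out, "haplotypes.tsv"), sep="\t", index=False)
    for fmt in ("tsv", "gml", "nexus"):
        export_network(net, os.path.join(out, f"network.{fmt}"), fmt)


def _stage_markers(cfg: PipelineConfig, b: dict) -> None:
    calls = screen_region_diagnostic(b["sites"], b["regions"])
    b["markers"] = calls
    markers_to_frame(calls).to_csv(os.path.join(b["outdir"], "markers.tsv"), sep="\t", index=False)


def _stage_trim(cfg: PipelineConfig, b: dict) -> None:
    trimmed, stats = trim_reads(b["reads"], **cfg.trim)
    b["reads"] = trimmed
    b["trim_stats"] = stats
    with open(os.path.join(b["outdir"], "trim_stats.json"), "w") as fh:
        json.dump(dataclasses.asdict(stats), fh, indent=2)


def _stage_classify(cfg: PipelineConfig, b: dict) -> None:
    idx = build_kmer_index(
        [(g.id, g.taxon or g.id, g.sequence) for g in b["genomes"]],
        k=int(cfg.classify.get("k", 31)),
    )
    asg = classify_reads(b["reads"], idx, min_hits=int(cfg.classify.get("min_hits", 2)))
    b["kmer_index"], b["assignments"] = idx, asg
    asg.to_csv(os.path.join(b["outdir"], "assignments.tsv"), sep="\t", index=False)


def _stage_map(cfg: PipelineConfig, b: dict) -> None:
    preset = ANCIENT_PRESET if cfg.map_preset == "ancient" else MODERN_PRESET
    taxa = sorted({g.taxon for g in b["genomes"] if g.taxon})
    alignments: dict[str, list] = {}
    for taxon in taxa:
        ref = next(g for g in b["genomes"] if g.taxon == taxon and g.role == "reference")
        sub = extract_genus_reads(b["reads"], b["assignments"], taxon) if taxon in set(b["assignments"].genus) else []
        if not sub:
            alignments[taxon] = []
            continue
        idx = ReferenceIndex(ref.id, ref.sequence)
        alns = map_reads(sub, ref.id, ref.sequence, index=idx, **preset)
        # duplicates are a within-library artifact: mark per (sample, method)
        marked = []
        for key in sorted({(a.sample, a.method) for a in alns}):
            group = [a for a in alns if (a.sample, a.method) == key]
            marked.extend(mark_duplicates(group))
        alignments[taxon] = marked
    b["alignments_by_taxon"] = alignments


def _stage_stats(cfg: PipelineConfig, b: dict) -> None:
    rows = []
    damage = None
    for taxon, alns in sorted(b["alignments_by_taxon"].items()):
        ref = next(g for g in b["genomes"] if g.taxon == taxon and g.role == "reference")
        for key in sorted({(a.sample, a.method) for a in alns}) if alns else []:
            group = [a for a in alns if (a.sample, a.method) == key]
            kept = [a for a in group if not a.duplicate]
            _depth, breadth = coverage_stats(group, len(ref.sequence))
            rows.append(
                dict(sample=key[0], method=key[1], taxon=taxon,
                     read_count=len(kept), read_count_with_duplicates=len(group),
                     breadth_pct=round(breadth, 2))
            )
        if taxon == cfg.focal_genus and alns:
            damage = damage_profile(alns, ref.sequence)
    # complete missing (sample, method, taxon) combinations with zeros
    if rows:
        df = pd.DataFrame(rows)
        samples = sorted({r.sample for r in b["reads"]})
        methods = sorted({r.method for r in b["reads"]})
        taxa = sorted(b["alignments_by_taxon"])
        full = pd.MultiIndex.from_product([samples, methods, taxa], names=["sample", "method", "taxon"])
        df = (
            df.set_index(["sample", "method", "taxon"]).reindex(full, fill_value=0).reset_index()
        )
        abundance = relative_abundance(df.rename(columns={}), taxa=tuple(taxa))
    else:
        abundance = pd.DataFrame()
    b["abundance"] = abundance
    b["damage"] = damage
    out = b["outdir"]
    abundance.to_csv(os.path.join(out, "abundance.tsv"), sep="\t", index=False)
    if damage is not None:
        pd.DataFrame(
            dict(offset=np.arange(1, damage.window + 1), ct5=damage.ct5.round(5), ga3=damage.ga3.round(5))
        ).to_csv(os.path.join(out, "damage.tsv"), sep="\t", index=False)


def _stage_tally(cfg: PipelineConfig, b: dict) -> None:
    alns = b["alignments_by_taxon"].get(cfg.focal_genus, [])
    tallies = tally_alleles(alns, b["sites"], b["ref"].sequence, ref_id=b["ref"].id)
    evals, summary = evaluate_sites(tallies, b["sites"], b["regions"])
    b["tallies"], b["evaluations"], b["site_summary"] = tallies, evals, summary
    out = b["outdir"]
    evaluations_to_frame(evals, b["regions"]).to_csv(os.path.join(out, "site_evaluations.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "site_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def _stage_confirm(cfg: PipelineConfig, b: dict) -> None:
    updated = confirm_markers(b["markers"], b["evaluations"], cfg.core_region)
    b["markers_confirmed"] = updated
    markers_to_frame(updated).to_csv(os.path.join(b["outdir"], "markers_confirmed.tsv"), sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "variants": _stage_variants,
    "network": _stage_network,
    "markers": _stage_markers,
    "trim": _stage_trim,
    "classify": _stage_classify,
    "map": _stage_map,
    "stats": _stage_stats,
    "tally": _stage_tally,
    "confirm": _stage_confirm,
}


def make_report(bundle: dict) -> str:
    """Human-readable markdown summary of the bundle; missing members
    are listed as absent rather than fatal."""
    lines = ["# plastovar run summary", ""]
    net = bundle.get("network")
    lines.append("## Haplotype network")
    if net is not None:
        n_obs = len(net.observed_nodes())
        n_int = net.graph.number_of_nodes() - n_obs
        lines += [
            f"- observed haplotypes: {n_obs}; inferred intermediates: {n_int}",
            f"- components: {len(net.components)}; connection limit: {net.limit} steps (alpha={net.alpha})",
            "",
        ]
    else:
        lines += ["- absent", ""]
    lines.append("## Abundance")
    ab = bundle.get("abundance")
    if ab is not None and len(ab):
        lines.append(ab.to_string(index=False))
        lines.append("")
    else:
        lines += ["- absent", ""]
    lines.append("## Marker status")
    mk = bundle.get("markers_confirmed")
    if mk:
        from collections import Counter

        for (region, status), n in sorted(Counter((m.target_region, m.status) for m in mk).items()):
            lines.append(f"- {region}: {status} x{n}")
        lines.append("")
    else:
        lines += ["- absent", ""]
    lines.append("## Damage")
    dmg = bundle.get("damage")
    if dmg is not None:
        lines.append(
            "- 5' C->T offsets 1-5: " + ", ".join(f"{v:.3f}" for v in dmg.ct5[:5])
        )
        lines.append(
            "- 3' G->A offsets 1-5: " + ", ".join(f"{v:.3f}" for v in dmg.ga3[:5])
        )
        lines.append(f"- baseline mismatch rate: {dmg.baseline:.5f}")
    else:
        lines.append("- absent")
    text = "\n".join(lines) + "\n"
    outdir = bundle.get("outdir")
    if outdir:
        with open(os.path.join(outdir, "report.md"), "w") as fh:
            fh.write(text)
    return text
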