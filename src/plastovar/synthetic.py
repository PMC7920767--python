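"""Synthetic plastome cohorts, ancient read sets, and truth tables.

The generator emulates the study system this package analyses: a small
panel of near-identical quadripartite plastomes (~150-165 kb) sampled
from three Siberian regions, carrying a handful of planted SNP / InDel /
homopolymer differences; a three-genus mixture of short (30-120 bp)
ancient fragments with terminal C->T / G->A deamination; and a
hybridization-capture filter that retains fragments from regions
conserved with a bait plastome.

All genomes of a cohort share one coordinate frame: genus ancestors are
derived from a common base sequence by substitutions only, and the only
length changes are the planted within-genus InDels.  This keeps every
planted variant recoverable by an alignment-free column scan and lets
the capture filter score conservation on ancestor coordinates.

Every random draw flows from ``CohortConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dna import revcomp
from .types import GeneFeature, PlastomeRecord, Read

BASES = np.array(list("ACGT"))

# transition partner per base
_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

_MAX_PLANT_RETRIES = 200


@dataclass
class DamageConfig:
    """Terminal deamination model: offset i (1-based from the read end)
    is hit with probability p_max * exp(-decay * (i - 1))."""

    p5_max: float = 0.3
    p3_max: float = 0.3
    decay: float = 0.3

    def __post_init__(self):
        for p in (self.p5_max, self.p3_max):
            if not 0.0 <= p <= 1.0:
                raise ValueError("damage probabilities must lie in [0,1]")


@dataclass
class SampleConfig:
    """One sediment-core sample: an age label, a genus mixture and the
    fragment/damage model for its reads."""

    age_label: str
    taxon_proportions: dict[str, float]
    n_reads: int = 5000
    fragment_length_mean: float = 60.0
    fragment_length_sd: float = 15.0
    fragment_length_min: int = 30
    damage: DamageConfig = field(default_factory=DamageConfig)
    method: str = "shotgun"
    #: sedaDNA is predominantly of local origin: when set, fragments of a
    #: taxon are drawn from that region's individuals (if it has any)
    local_region: str | None = None

    def __post_init__(self):
        total = sum(self.taxon_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxon proportions sum to {total}, expected 1")


@dataclass
class BaitConfig:
    """Capture model: the bait plastome diverges from the cohort's base
    ancestor over a configurable fraction of the genome; fragments whose
    source window is conserved with the bait are preferentially kept."""

    bait_taxon_divergence: float = 0.35
    conserved_fraction: float = 0.45
    window: int = 100
    identity_threshold: float = 0.90
    p_retain_conserved: float = 0.90
    p_retain_diverged: float = 0.02


@dataclass
class PlantCounts:
    """Planted variant budget for one genus, split shared-vs-private.

    ``region_shared`` variants are carried by every individual of one
    region (the regions are cycled); ``private`` variants by a single
    individual.  Defaults mirror an alder-like panel: 16 SNPs (8
    transitions / 8 transversions, 13 of them region-shared), 5 InDels
    and 13 homopolymer-run length differences.
    """

    snp_transitions: int = 8
    snp_transversions: int = 8
    indels: int = 5
    homopolymer_diffs: int = 13
    shared_snp_transitions: int = 7
    shared_snp_transversions: int = 6
    shared_indels: int = 2
    shared_homopolymer_diffs: int = 4
    indel_lengths: tuple[int, ...] = (2, 3, 4, 5, 8, 12)


@dataclass
class GenusConfig:
    name: str
    divergence: float = 0.0  # substitution fraction vs the base ancestor
    regions: list[tuple[str, int]] = field(default_factory=list)  # (region label, n individuals)
    variants: PlantCounts | None = None


def _default_genera() -> list[GenusConfig]:
    return [
        GenusConfig(
            "Alnus",
            0.0,
            [("Taymyr", 4), ("Omoloy", 1), ("Kolyma", 2)],
            PlantCounts(),
        ),
        GenusConfig("Betula", 0.20, [("Taymyr", 1)], None),
        GenusConfig("Salix", 0.25, [("Omoloy", 1)], None),
    ]


def _default_samples() -> list[SampleConfig]:
    # four core depths, oldest to youngest, with an alder-to-willow shift
    mixes = [
        ("6700 cal yr BP", {"Alnus": 0.47, "Betula": 0.02, "Salix": 0.51}),
        ("5400 cal yr BP", {"Alnus": 0.42, "Betula": 0.02, "Salix": 0.56}),
        ("1900 cal yr BP", {"Alnus": 0.07, "Betula": 0.05, "Salix": 0.88}),
        ("60 cal yr BP", {"Alnus": 0.01, "Betula": 0.04, "Salix": 0.95}),
    ]
    return [SampleConfig(age, mix) for age, mix in mixes]


@dataclass
class CohortConfig:
    seed: int = 0
    genome_length: int = 160_000
    region_lengths: dict[str, int] | None = None  # LSC/IRb/SSC/IRa
    genera: list[GenusConfig] = field(default_factory=_default_genera)
    samples: list[SampleConfig] = field(default_factory=_default_samples)
    bait: BaitConfig = field(default_factory=BaitConfig)
    gene_density: float = 0.5  # features per kb
    plant_in_ir: bool = False
    baseline_error: float = 0.001
    duplication_rate: float = 0.0

    def resolved_region_lengths(self) -> dict[str, int]:
        if self.region_lengths is not None:
            rl = dict(self.region_lengths)
        else:
            # proportions of a typical 160 kb quadripartite plastome
            lsc = int(round(self.genome_length * 0.5625))
            ir = int(round(self.genome_length * 0.1625))
            rl = {"LSC": lsc, "IRb": ir, "SSC": self.genome_length - lsc - 2 * ir, "IRa": ir}
        if rl["IRa"] != rl["IRb"]:
            raise ValueError("IRa and IRb must have equal length")
        if sum(rl.values()) != self.genome_length:
            raise ValueError("region lengths must sum to genome_length")
        return rl


@dataclass
class TruthTables:
    """Ground truth for everything the generator emitted (TSV-backed)."""

    variants: pd.DataFrame
    markers: pd.DataFrame
    reads: pd.DataFrame
    proportions: pd.DataFrame
    capture: pd.DataFrame
    params: pd.DataFrame

    TABLE_NAMES = ("variants", "markers", "reads", "proportions", "capture", "params")


def _empty_truth() -> TruthTables:
    return TruthTables(
        variants=pd.DataFrame(
            columns=["genus", "position", "var_class", "subtype", "ref_allele", "alt_allele", "carriers", "pattern", "target_region"]
        ),
        markers=pd.DataFrame(columns=["genus", "position", "var_class", "target_region", "allele", "n_target", "n_other", "support_class"]),
        reads=pd.DataFrame(columns=["read_id", "sample", "method", "taxon", "genome_id", "start", "length", "strand"]),
        proportions=pd.DataFrame(columns=["sample", "method", "taxon", "proportion", "n_reads"]),
        capture=pd.DataFrame(columns=["read_id", "conserved", "retained"]),
        params=pd.DataFrame(columns=["key", "value"]),
    )


# ---------------------------------------------------------------------------
# genome simulation


def _random_quadripartite(rng: np.random.Generator, config: CohortConfig) -> tuple[str, dict[str, tuple[int, int]]]:
    rl = config.resolved_region_lengths()
    n_free = rl["LSC"] + rl["IRb"] + rl["SSC"]
    core = "".join(BASES[rng.integers(0, 4, size=n_free)])
    lsc = core[: rl["LSC"]]
    irb = core[rl["LSC"]: rl["LSC"] + rl["IRb"]]
    ssc = core[rl["LSC"] + rl["IRb"]:]
    seq = lsc + irb + ssc + revcomp(irb)
    bounds = {}
    pos = 0
    for name in ("LSC", "IRb", "SSC", "IRa"):
        bounds[name] = (pos, pos + rl[name])
        pos += rl[name]
    return seq, bounds


def _mirror_ira(seq: str, bounds: dict[str, tuple[int, int]]) -> str:
    ib0, ib1 = bounds["IRb"]
    ia0, ia1 = bounds["IRa"]
    return seq[:ia0] + revcomp(seq[ib0:ib1]) + seq[ia1:]


#: cross-genus substitution rates relative to the LSC rate; plastomes
#: show a strong conservation gradient (IRs nearly identical across
#: genera, SSC intermediate, LSC most diverged)
REGION_DIVERGENCE_SCALE = {"LSC": 1.0, "SSC": 0.6, "IRb": 0.05}


def _diverge(seq: str, bounds, fraction: float, rng: np.random.Generator) -> str:
    """Substitution-only divergence with the plastome conservation
    gradient (``fraction`` = LSC rate); IRa re-mirrored afterwards."""
    if fraction <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for region, scale in REGION_DIVERGENCE_SCALE.items():
        lo, hi = bounds[region]
        n = int(round(fraction * scale * (hi - lo)))
        if n == 0:
            continue
        pos = lo + rng.choice(hi - lo, size=n, replace=False)
        for p in pos:
            cur = arr[p].decode()
            alts = [b for b in "ACGT" if b != cur]
            arr[p] = alts[rng.integers(0, 3)]
    out = arr.tobytes().decode()
    return _mirror_ira(out, bounds)


def _place_genes(rng: np.random.Generator, config: CohortConfig, length: int) -> list[GeneFeature]:
    n = max(1, int(round(config.gene_density * length / 1000)))
    feats: list[GeneFeature] = []
    taken: list[tuple[int, int]] = []
    tries = 0
    while len(feats) < n and tries < 50 * n:
        tries += 1
        glen = 3 * int(rng.integers(100, 400))  # 300..1197 bp CDS
        start = int(rng.integers(0, length - glen))
        if any(start < e + 50 and s - 50 < start + glen for s, e in taken):
            continue
        strand = "+" if rng.integers(0, 2) else "-"
        feats.append(GeneFeature(name=f"gene{len(feats) + 1:03d}", start=start, end=start + glen, strand=strand, kind="CDS"))
        taken.append((start, start + glen))
    feats.sort(key=lambda f: f.start)
    return feats


def _single_copy_intervals(bounds) -> list[tuple[int, int]]:
    return [bounds["LSC"], bounds["SSC"]]


def _find_runs(seq: str, min_len: int = 4) -> list[tuple[int, int, str]]:
    """(start, length, base) of mononucleotide runs >= min_len."""
    runs = []
    i = 0
    L = len(seq)
    while i < L:
        j = i
        while j + 1 < L and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= min_len:
            runs.append((i, j - i + 1, seq[i]))
        i = j + 1
    return runs


@dataclass
class _Plant:
    position: int  # anchor convention: SNP -> site itself; indel/homopolymer -> left anchor base
    var_class: str
    subtype: str
    ref_allele: str
    alt_allele: str
    carriers: tuple[str, ...]
    pattern: str  # region-shared | private
    target_region: str

    @property
    def footprint(self) -> tuple[int, int]:
        span = max(len(self.ref_allele), len(self.alt_allele))
        return (self.position - 15, self.position + span + 15)


def _overlaps(iv: tuple[int, int], occupied: list[tuple[int, int]]) -> bool:
    return any(iv[0] < e and s < iv[1] for s, e in occupied)


def _carrier_sets(gcfg: GenusConfig, rng: np.random.Generator):
    """Yield (carriers, pattern, region) assignments, cycling the regions
    for region-shared plants."""
    individuals = []
    by_region: dict[str, list[str]] = {}
    for region, count in gcfg.regions:
        ids = [f"{gcfg.name[0]}{len(individuals) + k + 1:02d}" for k in range(count)]
        by_region[region] = ids
        individuals.extend(ids)
    region_cycle = [r for r, _ in gcfg.regions]

    def shared(idx: int):
        region = region_cycle[idx % len(region_cycle)]
        return tuple(by_region[region]), "region-shared", region

    def private(idx: int):
        ind = individuals[int(rng.integers(0, len(individuals)))]
        region = next(r for r, ids in by_region.items() for i in ids if i == ind)
        return (ind,), "private", region

    return individuals, by_region, shared, private


def _plan_plants(gcfg: GenusConfig, ancestor: str, bounds, rng: np.random.Generator,
                 plant_in_ir: bool, features: list[GeneFeature] | None = None) -> list[_Plant]:
    counts = gcfg.variants
    if counts is None:
        return []
    intervals = _single_copy_intervals(bounds)
    if plant_in_ir:
        intervals = intervals + [bounds["IRb"]]
    _, _, shared, private = _carrier_sets(gcfg, rng)
    gene_ivs = [(f.start, f.end) for f in features or []]

    plants: list[_Plant] = []
    occupied: list[tuple[int, int]] = []
    shared_idx = 0

    def assign(is_shared):
        nonlocal shared_idx
        if is_shared:
            out = shared(shared_idx)
            shared_idx += 1
            return out
        return private(0)

    def pick_pos(span: int, avoid_genes: bool = False) -> int | None:
        for _ in range(_MAX_PLANT_RETRIES):
            lo, hi = intervals[int(rng.integers(0, len(intervals)))]
            p = int(rng.integers(lo + 20, hi - span - 20))
            if _overlaps((p - 15, p + span + 15), occupied):
                continue
            if avoid_genes and _overlaps((p, p + span + 1), gene_ivs):
                continue
            return p
        return None

    def plant_snp(subtype: str, is_shared: bool):
        p = pick_pos(1)
        if p is None:
            raise RuntimeError("could not place SNP: region too crowded")
        ref = ancestor[p]
        alt = _TS[ref] if subtype == "transition" else _TV[ref][int(rng.integers(0, 2))]
        carriers, pattern, region = assign(is_shared)
        plants.append(_Plant(p, "SNP", subtype, ref, alt, carriers, pattern, region))
        occupied.append((p - 15, p + 16))

    def plant_indel(is_shared: bool):
        lengths = counts.indel_lengths
        for _ in range(_MAX_PLANT_RETRIES):
            L = int(lengths[int(rng.integers(0, len(lengths)))])
            p = pick_pos(L + 2, avoid_genes=True)
            if p is None:
                continue
            is_del = bool(rng.integers(0, 2))
            anchor = ancestor[p]
            if is_del:
                seg = ancestor[p + 1: p + 1 + L]
                # unambiguous leftmost placement & not a pure homopolymer change
                if len(set(seg)) < 2 or ancestor[p] == ancestor[p + L]:
                    continue
                if any(r[0] <= p + 1 + L and p + 1 <= r[0] + r[1] for r in _find_runs(ancestor[p - 10: p + L + 11])):
                    pass  # runs near the event are fine as long as seg is mixed-base
                ref_allele, alt_allele = anchor + seg, anchor
            else:
                seg = "".join(BASES[np.asarray(rng.integers(0, 4, size=L))])
                if len(set(seg)) < 2 or seg[-1] == anchor or seg[0] == ancestor[p + 1]:
                    continue
                ref_allele, alt_allele = anchor, anchor + seg
            carriers, pattern, region = assign(is_shared)
            plants.append(_Plant(p, "InDel", "none", ref_allele, alt_allele, carriers, pattern, region))
            occupied.append((p - 15, p + L + 16))
            return
        raise RuntimeError("could not place InDel after bounded retries")

    def plant_homopolymer(is_shared: bool):
        for _ in range(_MAX_PLANT_RETRIES):
            lo, hi = intervals[int(rng.integers(0, len(intervals)))]
            window = ancestor[lo + 20: hi - 20]
            runs = _find_runs(window, 4)
            if not runs:
                continue
            start, rlen, base = runs[int(rng.integers(0, len(runs)))]
            start += lo + 20
            if _overlaps((start - 15, start + rlen + 15), occupied):
                continue
            if _overlaps((start - 1, start + rlen + 3), gene_ivs):
                continue
            delta = int(rng.integers(1, 3)) * (1 if rng.integers(0, 2) else -1)
            if rlen + delta < 4:
                delta = abs(delta)
            p = start - 1  # left anchor base just before the run
            if ancestor[p] == base:
                continue
            # minimal VCF-style alleles: anchor plus the length difference
            if delta > 0:
                ref_allele = ancestor[p]
                alt_allele = ancestor[p] + base * delta
            else:
                ref_allele = ancestor[p] + base * (-delta)
                alt_allele = ancestor[p]
            carriers, pattern, region = assign(is_shared)
            plants.append(_Plant(p, "homopolymer", "none", ref_allele, alt_allele, carriers, pattern, region))
            occupied.append((p - 15, p + rlen + abs(delta) + 16))
            return
        raise RuntimeError("could not place homopolymer variant after bounded retries")

    jobs = (
        [("snp_ts", True)] * counts.shared_snp_transitions
        + [("snp_ts", False)] * (counts.snp_transitions - counts.shared_snp_transitions)
        + [("snp_tv", True)] * counts.shared_snp_transversions
        + [("snp_tv", False)] * (counts.snp_transversions - counts.shared_snp_transversions)
        + [("indel", True)] * counts.shared_indels
        + [("indel", False)] * (counts.indels - counts.shared_indels)
        + [("homopolymer", True)] * counts.shared_homopolymer_diffs
        + [("homopolymer", False)] * (counts.homopolymer_diffs - counts.shared_homopolymer_diffs)
    )
    for kind, is_shared in jobs:
        if kind == "snp_ts":
            plant_snp("transition", is_shared)
        elif kind == "snp_tv":
            plant_snp("transversion", is_shared)
        elif kind == "indel":
            plant_indel(is_shared)
        else:
            plant_homopolymer(is_shared)
    plants.sort(key=lambda p: p.position)
    return plants


def _apply_plants(ancestor: str, plants: list[_Plant], individual: str) -> str:
    """Build one individual's genome by applying its alt alleles."""
    edits = [p for p in plants if individual in p.carriers]
    edits.sort(key=lambda p: p.position, reverse=True)
    seq = ancestor
    for p in edits:
        if p.var_class == "SNP":
            seq = seq[: p.position] + p.alt_allele + seq[p.position + 1:]
        else:
            end = p.position + len(p.ref_allele)
            seq = seq[: p.position] + p.alt_allele + seq[end:]
    return seq


def simulate_plastomes(config: CohortConfig) -> tuple[list[PlastomeRecord], TruthTables]:
    """Emit per-genus ancestors (role=reference) and per-individual
    genomes carrying the planted variants, plus the truth tables."""
    rng = np.random.default_rng(config.seed)
    base, bounds = _random_quadripartite(rng, config)
    features = _place_genes(rng, config, config.genome_length)

    genomes: list[PlastomeRecord] = []
    var_rows = []
    marker_rows = []
    for gcfg in config.genera:
        anc = _diverge(base, bounds, gcfg.divergence, rng)
        # keep planted InDels clear of genes: mask CDS intervals from planting
        plants = _plan_plants_avoiding_genes(gcfg, anc, bounds, rng, config.plant_in_ir, features)
        genomes.append(PlastomeRecord(id=f"{gcfg.name}_ref", sequence=anc, taxon=gcfg.name, role="reference", features=list(features)))
        individuals, by_region, _, _ = _carrier_sets(gcfg, rng)
        region_of = {i: r for r, ids in by_region.items() for i in ids}
        for ind in individuals:
            genomes.append(
                PlastomeRecord(
                    id=ind,
                    sequence=_apply_plants(anc, plants, ind),
                    taxon=gcfg.name,
                    region_label=region_of[ind],
                    role="individual",
                    features=list(features),
                )
            )
        for p in plants:
            var_rows.append(
                dict(genus=gcfg.name, position=p.position, var_class=p.var_class, subtype=p.subtype,
                     ref_allele=p.ref_allele, alt_allele=p.alt_allele, carriers=",".join(p.carriers),
                     pattern=p.pattern, target_region=p.target_region)
            )
        marker_rows.extend(_truth_markers(gcfg, plants, by_region))

    truth = _empty_truth()
    if var_rows:
        truth.variants = pd.DataFrame(var_rows)
    if marker_rows:
        truth.markers = pd.DataFrame(marker_rows)
    truth.params = pd.DataFrame(
        [{"key": "seed", "value": config.seed}, {"key": "genome_length", "value": config.genome_length}]
    )
    return genomes, truth


def _plan_plants_avoiding_genes(gcfg, anc, bounds, rng, plant_in_ir, features):
    """Plan plants with length-changing events kept out of gene features."""
    plants = _plan_plants(gcfg, anc, bounds, rng, plant_in_ir, features)
    for p in plants:
        if p.var_class == "SNP":
            continue
        span = (p.position, p.position + len(p.ref_allele))
        if any(f.start < span[1] and span[0] < f.end for f in features):
            raise RuntimeError("planted InDel splits a gene feature")
    return plants


def _truth_markers(gcfg: GenusConfig, plants: list[_Plant], by_region) -> list[dict]:
    """Apply the diagnostic-marker rule exhaustively to the truth matrix."""
    rows = []
    n_total = sum(len(v) for v in by_region.values())
    for p in plants:
        for region, ids in by_region.items():
            carriers = set(p.carriers)
            if carriers == set(ids):
                rows.append(
                    dict(genus=gcfg.name, position=p.position, var_class=p.var_class,
                         target_region=region, allele=p.alt_allele, n_target=len(ids),
                         n_other=n_total - len(ids),
                         support_class="robust" if len(ids) >= 2 else "singleton-region")
                )
    return rows


# ---------------------------------------------------------------------------
# read simulation


def _circular_slice(seq: str, start: int, length: int) -> str:
    L = len(seq)
    start %= L
    if start + length <= L:
        return seq[start: start + length]
    return seq[start:] + seq[: (start + length) % L]


def simulate_reads(
    genomes: list[PlastomeRecord],
    sample: SampleConfig,
    seed: int,
    baseline_error: float = 0.001,
) -> tuple[list[Read], pd.DataFrame]:
    """Draw ancient fragments from the configured genus mixture.

    Returns the reads and a per-read truth table (taxon, source genome,
    start, length, strand).  Positions are uniform on the circle and
    fragments may wrap the origin.
    """
    if not genomes:
        raise ValueError("empty genome set")
    if sample.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    taxa = sorted(sample.taxon_proportions)
    probs = np.array([sample.taxon_proportions[t] for t in taxa])
    pool: dict[str, list[PlastomeRecord]] = {}
    for t in taxa:
        inds = [g for g in genomes if g.taxon == t and g.role == "individual"]
        if sample.local_region is not None:
            local = [g for g in inds if g.region_label == sample.local_region]
            inds = local or inds
        pool[t] = inds or [g for g in genomes if g.taxon == t]
        if not pool[t]:
            raise ValueError(f"no genome supplied for taxon {t}")

    reads: list[Read] = []
    rows = []
    taxon_draws = rng.choice(len(taxa), size=sample.n_reads, p=probs)
    for i, ti in enumerate(taxon_draws):
        taxon = taxa[int(ti)]
        src = pool[taxon][int(rng.integers(0, len(pool[taxon])))]
        L = len(src.sequence)
        length = int(np.clip(round(rng.normal(sample.fragment_length_mean, sample.fragment_length_sd)),
                             sample.fragment_length_min, max(sample.fragment_length_min, L - 1)))
        start = int(rng.integers(0, L))
        strand = "+" if rng.integers(0, 2) else "-"
        frag = _circular_slice(src.sequence, start, length)
        if strand == "-":
            frag = revcomp(frag)
        frag = _apply_damage(frag, sample.damage, rng)
        frag = _apply_errors(frag, baseline_error, rng)
        quals = (rng.integers(33, 41, size=length) + 33).astype(np.uint8).tobytes().decode("ascii")
        rid = f"{sample.age_label.replace(' ', '_')}:{i}"
        reads.append(Read(id=rid, sequence=frag, qualities=quals, sample=sample.age_label, method=sample.method))
        rows.append(dict(read_id=rid, sample=sample.age_label, method=sample.method, taxon=taxon,
                         genome_id=src.id, start=start, length=length, strand=strand))
    return reads, pd.DataFrame(rows)


def _apply_damage(frag: str, dmg: DamageConfig, rng: np.random.Generator) -> str:
    n = len(frag)
    arr = list(frag)
    if dmg.p5_max > 0:
        for i in range(n):
            p = dmg.p5_max * np.exp(-dmg.decay * i)
            if p < 1e-4:
                break
            if arr[i] == "C" and rng.random() < p:
                arr[i] = "T"
    if dmg.p3_max > 0:
        for j in range(n):
            p = dmg.p3_max * np.exp(-dmg.decay * j)
            if p < 1e-4:
                break
            i = n - 1 - j
            if arr[i] == "G" and rng.random() < p:
                arr[i] = "A"
    return "".join(arr)


def _apply_errors(frag: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return frag
    n = len(frag)
    k = rng.binomial(n, rate)
    if k == 0:
        return frag
    arr = list(frag)
    for p in rng.choice(n, size=k, replace=False):
        cur = arr[p]
        alts = [b for b in "ACGT" if b != cur]
        arr[p] = alts[int(rng.integers(0, 3))]
    return "".join(arr)


def duplicate_reads(reads: list[Read], rate: float, seed: int) -> list[Read]:
    """PCR duplication as resampling of emitted fragments: each read is
    re-emitted once with probability ``rate`` (id suffixed ``/dupN``)."""
    rng = np.random.default_rng(seed)
    out = []
    for r in reads:
        out.append(r)
        k = 0
        while rng.random() < rate:
            k += 1
            out.append(dataclasses.replace(r, id=f"{r.id}/dup{k}"))
    return out


# ---------------------------------------------------------------------------
# capture simulation


def make_bait_genome(base_ancestor: str, bait: BaitConfig, seed: int, bounds=None) -> str:
    """Bait plastome for the capture model.

    With ``bounds`` (the quadripartite region map) the bait is a
    fourth, larch-like taxon: diverged from the base ancestor at
    ``bait_taxon_divergence`` in the LSC with the usual conservation
    gradient (IRs nearly identical) — so only the conserved regions of
    the cohort genera hybridise, whichever genus a fragment came from.
    Without ``bounds`` a simpler synthetic layout is produced: conserved
    over the first ``conserved_fraction`` of the genome, uniformly
    diverged elsewhere (convenient for controlled tests).
    """
    rng = np.random.default_rng(seed)
    if bounds is not None:
        return _diverge(base_ancestor, bounds, bait.bait_taxon_divergence, rng)
    L = len(base_ancestor)
    cut = int(L * bait.conserved_fraction)
    arr = list(base_ancestor)
    n_sub = int(round(bait.bait_taxon_divergence * (L - cut)))
    if n_sub:
        for p in rng.choice(np.arange(cut, L), size=n_sub, replace=False):
            cur = arr[p]
            alts = [b for b in "ACGT" if b != cur]
            arr[p] = alts[int(rng.integers(0, 3))]
    return "".join(arr)


def conservation_track(genome: str, bait: str, window: int) -> np.ndarray:
    """Per-window identity between a (coordinate-compatible) genome and
    the bait; both circular, compared column-wise."""
    L = min(len(genome), len(bait))
    n_win = L // window
    a = np.frombuffer(genome[: n_win * window].encode(), dtype="S1")
    b = np.frombuffer(bait[: n_win * window].encode(), dtype="S1")
    eq = (a == b).reshape(n_win, window)
    return eq.mean(axis=1)


def simulate_capture(
    reads: list[Read],
    read_truth: pd.DataFrame,
    genomes: list[PlastomeRecord],
    bait_genome: str,
    bait: BaitConfig,
    seed: int,
) -> tuple[list[Read], pd.DataFrame]:
    """Retain reads whose source window is conserved with the bait.

    Conservation is looked up on the genus-reference coordinate frame
    (planted InDel shifts of a few bp are negligible against the window
    size).  Returns the retained reads (method=capture) and a retention
    log keyed by read id.
    """
    if not bait_genome:
        raise ValueError("bait genome missing")
    rng = np.random.default_rng(seed)
    ref_by_taxon = {g.taxon: g for g in genomes if g.role == "reference"}
    tracks = {t: conservation_track(g.sequence, bait_genome, bait.window) for t, g in ref_by_taxon.items()}
    truth_by_id = read_truth.set_index("read_id")

    kept: list[Read] = []
    log = []
    for r in reads:
        row = truth_by_id.loc[r.id]
        taxon = row["taxon"]
        track = tracks[taxon]
        widx = int((int(row["start"]) + int(row["length"]) // 2) // bait.window) % len(track)
        conserved = bool(track[widx] >= bait.identity_threshold)
        p = bait.p_retain_conserved if conserved else bait.p_retain_diverged
        retained = bool(rng.random() < p)
        log.append(dict(read_id=r.id, conserved=conserved, retained=retained))
        if retained:
            kept.append(dataclasses.replace(r, method="capture"))
    return kept, pd.DataFrame(log)


# ---------------------------------------------------------------------------
# truth table IO


def write_truth(truth: TruthTables, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    for name in TruthTables.TABLE_NAMES:
        getattr(truth, name).to_csv(os.path.join(str(outdir), f"truth_{name}.tsv"), sep="\t", index=False)


def read_truth(outdir) -> TruthTables:
    import os

    kw = {}
    empty = _empty_truth()
    for name in TruthTables.TABLE_NAMES:
        path = os.path.join(str(outdir), f"truth_{name}.tsv")
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            df = getattr(empty, name)
        kw[name] = df
    return TruthTables(**kw)
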