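"""Quality trimming and genus-level k-mer LCA classification of ancient
reads.

Trimming follows the classic sliding-window rule used for degraded
short reads: clip terminal bases below a floor quality, then cut at the
first 4-base window whose mean quality drops under 15, and drop reads
shorter than 40 nt.

Classification uses canonical k-mers (k=31) against a labeled plastome
database with a two-level taxonomy (root -> genus): a read is assigned
to the genus holding a strict majority of its matching k-mers (with at
least ``min_hits`` of them); any tie or conflict collapses to the root,
i.e. the read stays unclassified at genus level.  The classifier is
exact-match by design — deaminated positions simply contribute no hits;
mismatch tolerance is the mapper's job downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._dna import canonical_kmer, phred_values
from .types import Read


@dataclass
class TrimStats:
    total: int = 0
    kept: int = 0
    dropped_short: int = 0
    malformed: int = 0


def trim_reads(
    reads: list[Read],
    window: int = 4,
    avg_q: float = 15.0,
    end_q: int = 3,
    min_len: int = 40,
) -> tuple[list[Read], TrimStats]:
    """Sliding-window quality trim; returns surviving reads and counts."""
    stats = TrimStats()
    out: list[Read] = []
    for r in reads:
        stats.total += 1
        if len(r.sequence) != len(r.qualities):
            stats.malformed += 1
            continue
        quals = phred_values(r.qualities)
        seq = r.sequence
        # leading/trailing bases below the floor quality
        lo = 0
        while lo < len(quals) and quals[lo] < end_q:
            lo += 1
        hi = len(quals)
        while hi > lo and quals[hi - 1] < end_q:
            hi -= 1
        seq, quals = seq[lo:hi], quals[lo:hi]
        # 5'->3' scan: cut at the first window with mean quality < avg_q
        cut = len(seq)
        for i in range(0, max(0, len(quals) - window + 1)):
            if sum(quals[i: i + window]) / window < avg_q:
                cut = i
                break
        seq, quals = seq[:cut], quals[:cut]
        if len(seq) < min_len:
            stats.dropped_short += 1
            continue
        stats.kept += 1
        out.append(
            Read(
                id=r.id,
                sequence=seq,
                qualities="".join(chr(q + 33) for q in quals),
                sample=r.sample,
                method=r.method,
            )
        )
    return out, stats


@dataclass
class KmerIndex:
    """Canonical k-mer -> genus-id-set index over labeled plastomes."""

    k: int
    kmer_genera: dict[str, frozenset[str]]
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)

    def lookup(self, kmer: str) -> frozenset[str] | None:
        return self.kmer_genera.get(canonical_kmer(kmer))


def build_kmer_index(
    genomes: list[tuple[str, str, str]], k: int = 31, circular: bool = True
) -> KmerIndex:
    """Index (genome_id, genus, sequence) triples.

    Circular genomes contribute the k-1 origin-wrapping k-mers too, so a
    linear genome of length L yields L-k+1 k-mers and a circular one L.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical-form ties)")
    seen_ids = set()
    table: dict[str, set[str]] = {}
    manifest = []
    for gid, genus, seq in genomes:
        if gid in seen_ids:
            raise ValueError(f"duplicate genome id {gid}")
        seen_ids.add(gid)
        s = seq + (seq[: k - 1] if circular else "")
        n = 0
        for i in range(len(s) - k + 1):
            km = s[i: i + k]
            if "N" in km:
                continue
            table.setdefault(canonical_kmer(km), set()).add(genus)
            n += 1
        manifest.append(dict(genome_id=gid, genus=genus, length=len(seq), kmers=n))
    return KmerIndex(
        k=k,
        kmer_genera={km: frozenset(gs) for km, gs in table.items()},
        manifest=pd.DataFrame(manifest),
    )


def classify_read(read: Read | str, index: KmerIndex, min_hits: int = 2) -> tuple[str, dict[str, int]]:
    """Assign a read to a genus, or 'unclassified'.

    Counts k-mer hits per genus (a k-mer shared by several genera counts
    for each — its LCA is the root, so it can never give one genus a
    majority by itself).  The winning genus needs a strict majority of
    hit k-mers and at least ``min_hits``.
    """
    seq = read.sequence if isinstance(read, Read) else read
    k = index.k
    if len(seq) < k:
        return "unclassified", {}
    hits: Counter = Counter()
    total = 0
    for i in range(len(seq) - k + 1):
        genera = index.lookup(seq[i: i + k])
        if genera is None:
            continue
        total += 1
        if len(genera) == 1:
            hits[next(iter(genera))] += 1
    if not hits:
        return "unclassified", {}
    best, best_n = max(sorted(hits.items()), key=lambda kv: kv[1])
    if best_n < min_hits or best_n * 2 <= total:
        return "unclassified", dict(hits)
    return best, dict(hits)


def classify_reads(reads: list[Read], index: KmerIndex, min_hits: int = 2) -> pd.DataFrame:
    """Per-read assignment table: read_id, genus, hit counts."""
    rows = []
    for r in reads:
        genus, hits = classify_read(r, index, min_hits)
        rows.append(
            dict(
                read_id=r.id,
                sample=r.sample,
                method=r.method,
                genus=genus,
                hits=sum(hits.values()),
                top_hits=max(hits.values()) if hits else 0,
            )
        )
    return pd.DataFrame(rows, columns=["read_id", "sample", "method", "genus", "hits", "top_hits"])


def extract_genus_reads(reads: list[Read], assignments: pd.DataFrame, genus: str) -> list[Read]:
    """Subset of ``reads`` assigned to ``genus``, input order preserved."""
    known = set(assignments["genus"])
    if genus not in known:
        raise ValueError(f"unknown genus {genus!r}; assigned genera: {sorted(known)}")
    wanted = set(assignments.loc[assignments["genus"] == genus, "read_id"])
    return [r for r in reads if r.id in wanted]


def genus_classifiability(
    index: KmerIndex,
    genomes: list[tuple[str, str, str]],
    read_length: int = 60,
    min_hits: int = 2,
) -> dict[str, float]:
    """Per-genus fraction of genome windows a read can be assigned from.

    Conserved regions (the IRs above all) are shared across genera and
    collapse to the taxonomy root, so raw classified counts under-count
    taxa whose genomes the database covers densely.  Tiling each genus's
    genomes into damage-free pseudo-reads of the observed length and
    classifying them against the same index measures that per-genus
    sensitivity — using nothing but the database itself.
    """
    per_genus: dict[str, list[float]] = {}
    for _gid, genus, seq in genomes:
        s = seq + seq[: read_length]
        total = hit = 0
        for start in range(0, len(seq), max(1, read_length // 2)):
            frag = s[start: start + read_length]
            total += 1
            hit += classify_read(frag, index, min_hits)[0] == genus
        per_genus.setdefault(genus, []).append(hit / total if total else 0.0)
    return {g: float(sum(v) / len(v)) for g, v in per_genus.items()}


def estimate_taxon_proportions(
    assignments: pd.DataFrame,
    classifiability: dict[str, float],
) -> dict[str, float]:
    """Sensitivity-corrected mixture proportions from assignment counts:
    p_t proportional to n_t / s_t over the genera in ``classifiability``."""
    counts = assignments[assignments.genus != "unclassified"].genus.value_counts()
    raw = {g: counts.get(g, 0) / s if s > 0 else 0.0 for g, s in classifiability.items()}
    total = sum(raw.values())
    if total == 0:
        return {g: float("nan") for g in classifiability}
    return {g: v / total for g, v in raw.items()}
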