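"""Read mapping to draft plastomes and downstream per-sample statistics.

The mapper is a deterministic seed-and-extend aligner tuned for short
degraded fragments on a small circular reference: exact k-mer seeds
(word length 24) on either strand vote for diagonals, candidate
windows are aligned end-to-end with edlib, and the best placement wins
by fewest edits with ties broken by leftmost reference position, then
forward strand.  Two presets mirror the two use cases: strict ancient
mapping (5% mismatches, 5% gap bases) and permissive modern-scaffold
mapping (20% mismatches, 10% gap bases).

The reference is linearised with wrap padding so origin-spanning
fragments align end-to-end; output coordinates are folded back onto
[0, L).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import edlib
import numpy as np
import pandas as pd

from ._dna import phred_values, revcomp
from .types import DamageProfile, ProvenanceScore, Read, ReadAlignment

_CIG_RE = re.compile(r"(\d+)([=XIDM])")

#: mapping presets: (max_mismatch_frac, max_gap_frac, max_gap)
ANCIENT_PRESET = dict(max_mismatch_frac=0.05, max_gap_frac=0.05, max_gap=50)
MODERN_PRESET = dict(max_mismatch_frac=0.20, max_gap_frac=0.10, max_gap=50)


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG_RE.findall(cigar)]


def cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, gap_bases, longest_gap_run)."""
    m = x = g = longest = 0
    for n, op in parse_cigar(cigar):
        if op == "=":
            m += n
        elif op == "X":
            x += n
        elif op in "ID":
            g += n
            longest = max(longest, n)
    return m, x, g, longest


class ReferenceIndex:
    """Exact k-mer seed index over a wrap-padded circular reference."""

    def __init__(self, ref_id: str, sequence: str, word: int = 24, wrap_pad: int = 200, max_hits: int = 64):
        self.ref_id = ref_id
        self.length = len(sequence)
        self.word = word
        self.padded = sequence + sequence[: min(wrap_pad, self.length)]
        self.seeds: dict[str, list[int]] = {}
        for i in range(len(self.padded) - word + 1):
            km = self.padded[i: i + word]
            lst = self.seeds.get(km)
            if lst is None:
                self.seeds[km] = [i]
            elif len(lst) < max_hits:
                lst.append(i)


def map_reads(
    reads: list[Read],
    ref_id: str,
    ref_seq: str,
    word: int = 24,
    max_mismatch_frac: float = 0.05,
    max_gap: int = 50,
    max_gap_frac: float = 0.05,
    index: ReferenceIndex | None = None,
) -> list[ReadAlignment]:
    """Map reads to one circular reference; unmappable reads are dropped."""
    if not ref_seq:
        raise ValueError("empty reference")
    idx = index or ReferenceIndex(ref_id, ref_seq, word)
    out = []
    for r in reads:
        aln = _map_one(r, idx, max_mismatch_frac, max_gap, max_gap_frac)
        if aln is not None:
            out.append(aln)
    return out


def _seed_positions(n: int, word: int) -> list[int]:
    if n < word:
        return []
    stride = max(1, (n - word) // 6) if n > word else 1
    pos = list(range(0, n - word + 1, stride))
    if pos[-1] != n - word:
        pos.append(n - word)
    return pos


def _map_one(read: Read, idx: ReferenceIndex, max_mm: float, max_gap: int, max_gap_frac: float):
    n = len(read.sequence)
    if n < idx.word:
        return None
    candidates = []  # (edits, start, strand_rank, payload)
    for strand in ("+", "-"):
        seq = read.sequence if strand == "+" else revcomp(read.sequence)
        quals = read.qualities if strand == "+" else read.qualities[::-1]
        diagonals: dict[int, int] = {}
        for qp in _seed_positions(n, idx.word):
            for rp in idx.seeds.get(seq[qp: qp + idx.word], ()):
                d = rp - qp
                diagonals[d] = diagonals.get(d, 0) + 1
        if not diagonals:
            continue
        # strongest diagonals first; deterministic tie-break on position
        ranked = sorted(diagonals.items(), key=lambda kv: (-kv[1], kv[0]))[:4]
        for d, _votes in ranked:
            lo = max(0, d - max_gap)
            hi = min(len(idx.padded), d + n + max_gap)
            window = idx.padded[lo:hi]
            res = edlib.align(seq, window, mode="HW", task="path")
            if res["editDistance"] < 0:
                continue
            loc = res["locations"][0]
            start = lo + loc[0]
            end = lo + loc[1] + 1
            start, end, cigar = _patch_terminal_insertions(
                res["cigar"], start, end, seq, idx.padded
            )
            matches, mism, gaps, longest = cigar_stats(cigar)
            if mism > max_mm * n or gaps > max_gap_frac * n or longest > max_gap:
                continue
            edits = mism + gaps
            candidates.append((edits, start % idx.length, 0 if strand == "+" else 1,
                               (start, end, strand, cigar, mism, gaps, seq, quals)))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[:3])
    start, end, strand, cigar, mism, gaps, seq, quals = candidates[0][3]
    fold = start % idx.length
    span = end - start
    return ReadAlignment(
        read_id=read.id,
        ref_id=idx.ref_id,
        start=fold,
        end=fold + span,
        strand=strand,
        cigar=cigar,
        mismatches=mism,
        gap_bases=gaps,
        read_seq=seq,
        read_quals=quals,
        sample=read.sample,
        method=read.method,
    )


def _compress_cigar(ops: list[tuple[int, str]]) -> str:
    out = []
    for n, op in ops:
        if n <= 0:
            continue
        if out and out[-1][1] == op:
            out[-1][0] += n
        else:
            out.append([n, op])
    return "".join(f"{n}{op}" for n, op in out)


def _patch_terminal_insertions(cigar: str, start: int, end: int, seq: str, padded: str):
    """Re-express insertions at the read termini as aligned columns.

    An infix aligner can tie a terminal substitution (e.g. a deaminated
    first base) against an insertion of the same cost; for damage
    profiling the substitution representation is the meaningful one, so
    terminal I runs are pulled back onto the reference."""
    ops = parse_cigar(cigar)
    if ops and ops[0][1] == "I" and start - ops[0][0] >= 0:
        k = ops[0][0]
        cols = [(1, "=" if seq[i] == padded[start - k + i] else "X") for i in range(k)]
        ops = cols + ops[1:]
        start -= k
    if ops and ops[-1][1] == "I" and end + ops[-1][0] <= len(padded):
        k = ops[-1][0]
        qoff = len(seq) - k
        cols = [(1, "=" if seq[qoff + i] == padded[end + i] else "X") for i in range(k)]
        ops = ops[:-1] + cols
        end += k
    start, end, ops = _canonicalise_terminal_gaps(ops, start, end, seq, padded)
    return start, end, _compress_cigar(ops)


_TERMINAL_GAP_WINDOW = 10


def _block_cost(ops: list[tuple[int, str]]) -> int:
    return sum(n for n, op in ops if op in "XID")


def _cols(seq_part: str, ref_part: str) -> list[tuple[int, str]]:
    return [(1, "=" if a == b else "X") for a, b in zip(seq_part, ref_part)]


def _canonicalise_terminal_gaps(ops: list[tuple[int, str]], start: int, end: int, seq: str, padded: str):
    """Prefer the substitution form over cost-tied near-terminal gaps.

    Patterns like ``1=1D`` (leading) or ``1I1=`` (trailing) can tie with
    plain mismatch columns for a deaminated terminal base; the aligned
    form is the meaningful one for damage statistics, so gap runs within
    10 columns of either read end are re-expressed as columns whenever
    that does not raise the edit cost."""
    for _ in range(3):
        ops = [(n, op) for n, op in ops if n > 0]
        changed = False
        # leading (k M)(d gap) with small k, or nothing changed
        if len(ops) >= 2 and ops[0][1] in "=X" and ops[1][1] in "ID" and ops[0][0] <= _TERMINAL_GAP_WINDOW:
            k, (d, gop) = ops[0][0], ops[1]
            if gop == "D":
                new_start = start + d
                cols = _cols(seq[:k], padded[new_start: new_start + k])
            else:
                new_start = start - d
                if new_start < 0:
                    cols = None
                else:
                    cols = _cols(seq[: k + d], padded[new_start: new_start + k + d])
            if cols is not None and _block_cost(cols) <= _block_cost(ops[:2]):
                ops = cols + ops[2:]
                start = new_start
                changed = True
        if len(ops) >= 2 and ops[-1][1] in "=X" and ops[-2][1] in "ID" and ops[-1][0] <= _TERMINAL_GAP_WINDOW:
            k, (d, gop) = ops[-1][0], ops[-2]
            if gop == "D":
                new_end = end - d
                cols = _cols(seq[len(seq) - k:], padded[new_end - k: new_end])
                width = k
            else:
                new_end = end + d
                width = k + d
                cols = (
                    _cols(seq[len(seq) - width:], padded[new_end - width: new_end])
                    if new_end <= len(padded)
                    else None
                )
            if cols is not None and _block_cost(cols) <= _block_cost(ops[-2:]):
                ops = ops[:-2] + cols
                end = new_end
                changed = True
        if not changed:
            break
    return start, end, ops


# ---------------------------------------------------------------------------
# duplicates, coverage, abundance


def mark_duplicates(alignments: list[ReadAlignment]) -> list[ReadAlignment]:
    """Coordinate-based single-end duplicate marking.

    Alignments sharing (ref, start, end, strand) form one group; the
    member with the highest base-quality sum is kept, the rest are
    flagged.  Idempotent and invariant to input order.
    """
    groups: dict[tuple, list[ReadAlignment]] = {}
    for a in alignments:
        groups.setdefault((a.ref_id, a.start, a.end, a.strand), []).append(a)
    out = []
    for key in sorted(groups):
        members = groups[key]
        best = max(members, key=lambda a: (sum(phred_values(a.read_quals)), a.read_id))
        for a in members:
            out.append(replace(a, duplicate=a is not best))
    return out


def dedup_counts(alignments: list[ReadAlignment]) -> tuple[int, int]:
    """(kept, total) — printed as 'kept (total)' in reports."""
    total = len(alignments)
    kept = sum(1 for a in alignments if not a.duplicate)
    return kept, total


def _ref_intervals(a: ReadAlignment):
    """Reference intervals consumed by an alignment (insertions skip)."""
    pos = a.start
    for n, op in parse_cigar(a.cigar):
        if op in "=XM":
            yield pos, pos + n
            pos += n
        elif op == "D":
            pos += n
        # 'I' consumes read only


def coverage_stats(alignments: list[ReadAlignment], ref_length: int, include_duplicates: bool = False):
    """Per-position depth (origin-folded) and breadth of coverage (%)."""
    depth = np.zeros(ref_length, dtype=np.int32)
    for a in alignments:
        if a.duplicate and not include_duplicates:
            continue
        for s, e in _ref_intervals(a):
            if e <= ref_length:
                depth[s:e] += 1
            else:
                depth[s:ref_length] += 1
                depth[: e - ref_length] += 1
    breadth_pct = 100.0 * float((depth > 0).sum()) / ref_length
    return depth, breadth_pct


def relative_abundance(counts: pd.DataFrame, taxa: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-(sample, method) relative percentages over the taxon set.

    ``counts`` needs columns sample, method, taxon, read_count.  The
    relative percentage of a taxon is 100 x its reads over the summed
    reads of all taxa in that sample/method; rows of an all-zero sample
    are flagged undefined rather than divided by zero.  ``relative_pct``
    is rounded to 2 decimals, matching report conventions.
    """
    df = counts.copy()
    if taxa is None:
        taxa = tuple(sorted(df["taxon"].unique()))
    missing = [t for t in taxa if t not in set(df["taxon"])]
    for t in missing:
        raise ValueError(f"taxon {t} absent from counts (zero rows are required)")
    df = df[df["taxon"].isin(taxa)].copy()
    totals = df.groupby(["sample", "method"])["read_count"].transform("sum")
    df["relative_pct"] = np.where(totals > 0, 100.0 * df["read_count"] / totals, np.nan)
    df["relative_pct"] = df["relative_pct"].round(2)
    df["undefined"] = totals == 0
    return df


# ---------------------------------------------------------------------------
# damage profiling


def _aligned_pairs(a: ReadAlignment, ref_seq: str) -> list[tuple[str, str]]:
    """(ref_base, read_base) per aligned column in read-sequencing
    orientation (5' of the sequenced fragment first)."""
    pairs = []
    rpos, qpos = a.start, 0
    L = len(ref_seq)
    for n, op in parse_cigar(a.cigar):
        if op in "=XM":
            for i in range(n):
                pairs.append((ref_seq[(rpos + i) % L], a.read_seq[qpos + i]))
            rpos += n
            qpos += n
        elif op == "D":
            rpos += n
        elif op == "I":
            qpos += n
    if a.strand == "-":
        comp = str.maketrans("ACGTN", "TGCAN")
        pairs = [(r.translate(comp), q.translate(comp)) for r, q in reversed(pairs)]
    return pairs


def damage_profile(alignments: list[ReadAlignment], ref_seq: str, window: int = 25) -> DamageProfile:
    """Empirical terminal misincorporation frequencies.

    For each offset from the sequenced 5' end: frequency of read T at
    reference-C positions; symmetrically G->A from the 3' end.  The
    baseline is the overall mismatch rate at interior offsets (more
    than ``window`` bases from both ends).
    """
    use = [a for a in alignments if not a.duplicate]
    if not use:
        raise ValueError("no alignments to profile")
    c_tot = np.zeros(window, dtype=np.int64)
    ct = np.zeros(window, dtype=np.int64)
    g_tot = np.zeros(window, dtype=np.int64)
    ga = np.zeros(window, dtype=np.int64)
    interior_cols = 0
    interior_mm = 0
    for a in use:
        pairs = _aligned_pairs(a, ref_seq)
        n = len(pairs)
        for i, (rb, qb) in enumerate(pairs):
            if i < window and rb == "C":
                c_tot[i] += 1
                ct[i] += qb == "T"
            j = n - 1 - i
            if j < window and rb == "G":
                g_tot[j] += 1
                ga[j] += qb == "A"
            if i >= window and n - 1 - i >= window:
                interior_cols += 1
                interior_mm += rb != qb
    with np.errstate(invalid="ignore", divide="ignore"):
        ct5 = np.where(c_tot > 0, ct / np.maximum(c_tot, 1), 0.0)
        ga3 = np.where(g_tot > 0, ga / np.maximum(g_tot, 1), 0.0)
    baseline = interior_mm / interior_cols if interior_cols else 0.0
    return DamageProfile(ct5=ct5, ga3=ga3, baseline=baseline, window=window)


# ---------------------------------------------------------------------------
# provenance


def provenance_scores(
    reads: list[Read],
    candidates: list[tuple[str, str]],
    **map_kwargs,
) -> list[ProvenanceScore]:
    """Map the full read set independently against each candidate genome
    (identical parameters) and count identical aligned bases.

    Returns scores sorted best-first by identical bases (then id)."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidate genomes")
    scores = []
    for gid, seq in candidates:
        alns = map_reads(reads, gid, seq, **map_kwargs)
        identical = covered = 0
        for a in alns:
            m, x, _g, _ = cigar_stats(a.cigar)
            identical += m
            covered += m + x
        scores.append(ProvenanceScore(genome_id=gid, aligned_reads=len(alns),
                                      identical_bases=identical, covered_bases=covered))
    return sorted(scores, key=lambda s: (-s.identical_bases, s.genome_id))


def provenance_to_frame(scores: list[ProvenanceScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(genome_id=s.genome_id, aligned_reads=s.aligned_reads,
                 identical_bases=s.identical_bases, covered_bases=s.covered_bases,
                 identity=round(s.identity, 6))
            for s in scores
        ]
    )
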