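"""Tracking modern variant positions through ancient sediment reads.

Only sites already discovered among the modern plastome panel are
evaluated: for each such site, the bases of deduplicated reads that
fully span it are tallied per (sample, method), the majority ancient
allele is matched against every modern individual, and region-level
matches confirm or refute the region-diagnostic markers.  Alleles that
could be terminal deamination artifacts (C->T / G->A within 10 bp of a
read end) are flagged, not silently dropped; a strict mode excludes
them from majority calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .mapping import parse_cigar
from .types import MarkerCall, ReadAlignment, VariantSite

DAMAGE_END_WINDOW = 10


@dataclass
class AlleleTally:
    """Per-site ancient allele counts, keyed by (sample, method)."""

    ref_position: int
    var_class: str
    counts: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    damage_support: dict[str, list[bool]] = field(default_factory=dict)

    @property
    def covered(self) -> bool:
        return any(sum(c.values()) > 0 for c in self.counts.values())

    def merged_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.counts.values():
            for allele, n in c.items():
                out[allele] = out.get(allele, 0) + n
        return out

    def damage_suspect(self, allele: str) -> bool:
        flags = self.damage_support.get(allele, [])
        return bool(flags) and sum(flags) * 2 >= len(flags)


@dataclass
class SiteEvaluation:
    ref_position: int
    var_class: str
    modern_alleles: dict[str, str]
    ancient_allele: str | None  # majority over merged samples; None if uncovered
    per_sample: dict[tuple[str, str], str | None]
    match_individuals: list[str]
    match_regions: list[str]
    classification: str  # matches_one_region | matches_multiple | conflict | uncovered


def _spanning_allele(
    a: ReadAlignment, start: int, end: int, ref_length: int, slack: int = 0,
    capture_insertions: bool = False,
) -> str | None:
    """Read allele over reference span [start, end), or None if the read
    does not fully span it (plus ``slack`` anchor bases on each side).

    ``capture_insertions`` additionally collects read bases inserted
    after any reference position inside the span (including its right
    boundary) — required for InDel/homopolymer events whose extra bases
    consume no reference."""
    for off in (0, ref_length):  # origin-wrapped alignments keep end > L
        s, e = start + off, end + off
        if a.start <= s - slack and a.end >= e + slack:
            start, end = s, e
            break
    else:
        return None
    rpos, qpos = a.start, 0
    allele = []
    for n, op in parse_cigar(a.cigar):
        if op in "=XM":
            for i in range(n):
                if start <= rpos + i < end:
                    allele.append(a.read_seq[qpos + i])
            rpos += n
            qpos += n
        elif op == "D":
            rpos += n
        elif op == "I":
            if capture_insertions and start < rpos <= end:
                allele.append(a.read_seq[qpos: qpos + n])
            qpos += n
        if rpos > end and op in "=XMD":
            break
    return "".join(a for a in allele)


def _damage_explicable(a: ReadAlignment, ref_base: str, read_base: str, site_pos: int, ref_length: int) -> bool:
    """Could this mismatch be terminal deamination on the sequenced strand?"""
    pos = site_pos if a.start <= site_pos else site_pos + ref_length
    # column offset within the aligned reference span
    off_left = pos - a.start
    off_right = (a.end - 1) - pos
    if a.strand == "+":
        d5, d3 = off_left, off_right
        rb, qb = ref_base, read_base
    else:
        d5, d3 = off_right, off_left
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        rb, qb = comp.get(ref_base, "N"), comp.get(read_base, "N")
    if rb == "C" and qb == "T" and d5 < DAMAGE_END_WINDOW:
        return True
    if rb == "G" and qb == "A" and d3 < DAMAGE_END_WINDOW:
        return True
    return False


def _detect_reference_row(sites: list[VariantSite], ref_seq: str) -> str | None:
    """Find the individual whose alleles always equal the reference
    sequence (i.e. the alignment's reference row, if it was included)."""
    ids = set.intersection(*(set(s.alleles) for s in sites)) if sites else set()
    for gid in sorted(ids):
        if all(s.alleles[gid] == ref_seq[s.ref_position: s.ref_position + len(s.alleles[gid])] for s in sites):
            return gid
    return None


def tally_alleles(
    alignments: list[ReadAlignment],
    sites: list[VariantSite],
    ref_seq: str,
    min_span: int = 1,
    ref_id: str | None = None,
) -> list[AlleleTally]:
    """Tally ancient read bases at every modern variant site.

    Alignments must be deduplicated and on the same reference frame as
    the sites.  SNP sites count single bases of fully spanning reads;
    InDel sites require the read to span the whole event plus one
    anchor base each side.  Homopolymer sites are tallied as run
    lengths over the whole reference run and re-expressed in the same
    minimal anchored form the variant scanner uses, so ancient and
    modern alleles are directly comparable.
    """
    L = len(ref_seq)
    if ref_id is None and sites:
        ref_id = _detect_reference_row(sites, ref_seq)
    tallies = []
    for site in sorted(sites, key=lambda s: s.ref_position):
        p = site.ref_position
        if p >= L:
            raise ValueError(f"site {p} outside reference")
        run_base = ""
        run_len = 0
        if site.var_class == "SNP":
            span = (p, p + 1)
            slack = 0
        elif site.var_class == "homopolymer":
            tails = [a[1:] for a in site.distinct_alleles if len(a) > 1]
            run_base = tails[0][0] if tails else ref_seq[(p + 1) % L]
            while ref_seq[(p + 1 + run_len) % L] == run_base:
                run_len += 1
            span = (p, p + 1 + run_len)
            slack = 1
        else:
            # InDel: the event's reference span = its longest allele that
            # matches the reference sequence at this position
            ref_len = (
                len(site.alleles[ref_id])
                if ref_id is not None and ref_id in site.alleles
                else max((len(a) for a in site.distinct_alleles if ref_seq[p: p + len(a)] == a), default=1)
            )
            span = (p, p + ref_len)
            slack = 1
        ref_extra = len(site.alleles[ref_id]) - 1 if ref_id is not None and ref_id in site.alleles else 0
        tally = AlleleTally(ref_position=p, var_class=site.var_class)
        for a in alignments:
            if a.duplicate:
                continue
            allele = _spanning_allele(a, span[0], span[1], L, slack,
                                      capture_insertions=site.var_class != "SNP")
            if allele is None:
                continue
            if site.var_class == "homopolymer" and allele and set(allele[1:]) <= {run_base}:
                # re-anchor the observed run length into minimal form
                extra = ref_extra + (len(allele) - 1) - run_len
                if extra >= 0:
                    allele = allele[0] + run_base * extra
            key = (a.sample, a.method)
            tally.counts.setdefault(key, {})
            tally.counts[key][allele] = tally.counts[key].get(allele, 0) + 1
            if site.var_class == "SNP" and len(allele) == 1:
                suspect = _damage_explicable(a, ref_seq[p], allele, p, L)
                tally.damage_support.setdefault(allele, []).append(suspect)
        if sum(tally.merged_counts().values()) < min_span:
            tally.counts = {}
            tally.damage_support = {}
        tallies.append(tally)
    return tallies


def _majority(counts: dict[str, int], exclude: set[str] = frozenset()) -> str | None:
    """Unique majority allele, or None on a tie / empty tally."""
    usable = {a: n for a, n in counts.items() if a not in exclude and n > 0}
    if not usable:
        return None
    best = max(usable.values())
    winners = [a for a, n in usable.items() if n == best]
    return winners[0] if len(winners) == 1 else None


def evaluate_sites(
    tallies: list[AlleleTally],
    sites: list[VariantSite],
    region_labels: dict[str, str],
    strict_damage: bool = False,
) -> tuple[list[SiteEvaluation], dict]:
    """Match each site's majority ancient allele against the modern
    panel; summarise covered counts, per-region matches and conflicts.

    ``strict_damage`` removes damage-suspect alleles before the
    majority call.  Ties are reported as conflict rather than resolved.
    """
    by_pos = {s.ref_position: s for s in sites}
    evaluations = []
    summary = {"n_sites": len(tallies), "covered": 0, "conflicts": 0, "region_matches": {}}
    for tally in tallies:
        site = by_pos[tally.ref_position]
        modern = {i: a for i, a in site.alleles.items() if i in region_labels}
        per_sample = {}
        for key, counts in sorted(tally.counts.items()):
            excl = {a for a in counts if tally.damage_suspect(a)} if strict_damage else set()
            per_sample[key] = _majority(counts, excl)
        merged = tally.merged_counts()
        excl = {a for a in merged if tally.damage_suspect(a)} if strict_damage else set()
        ancient = _majority(merged, excl)
        if not tally.covered:
            cls = "uncovered"
            match_inds: list[str] = []
        elif ancient is None:
            cls = "conflict"
            match_inds = []
        else:
            match_inds = sorted(i for i, a in modern.items() if a == ancient)
            regions = sorted({region_labels[i] for i in match_inds})
            if len(regions) == 1:
                cls = "matches_one_region"
            elif regions:
                cls = "matches_multiple"
            else:
                cls = "conflict"  # ancient allele absent from the modern panel
        match_regions = sorted({region_labels[i] for i in match_inds})
        evaluations.append(
            SiteEvaluation(
                ref_position=tally.ref_position,
                var_class=tally.var_class,
                modern_alleles=modern,
                ancient_allele=ancient,
                per_sample=per_sample,
                match_individuals=match_inds,
                match_regions=match_regions,
                classification=cls,
            )
        )
        if cls != "uncovered":
            summary["covered"] += 1
        if cls == "conflict":
            summary["conflicts"] += 1
        for reg in match_regions:
            summary["region_matches"][reg] = summary["region_matches"].get(reg, 0) + 1
    return evaluations, summary


def confirm_markers(
    markers: list[MarkerCall],
    evaluations: list[SiteEvaluation],
    core_region: str,
) -> list[MarkerCall]:
    """Confirm or refute diagnostic markers against the sediment core.

    The core sits in ``core_region``: a marker for that region is
    confirmed when every covered evaluation at its site shows the
    marker allele, and refuted when the local core lacks it.  A marker
    for a *different* region is confirmed (as correctly absent) when
    the local core lacks its allele, and refuted when the core shows it.
    """
    if not core_region:
        raise ValueError("core location region label missing")
    by_pos = {e.ref_position: e for e in evaluations}
    out = []
    for m in markers:
        ev = by_pos.get(m.ref_position)
        status = "uncovered"
        if ev is not None and ev.classification != "uncovered":
            local_has_allele = ev.ancient_allele == m.allele
            if m.target_region == core_region:
                status = "confirmed_by_ancient" if local_has_allele else "refuted_by_ancient"
            else:
                status = "confirmed_by_ancient" if not local_has_allele else "refuted_by_ancient"
        out.append(
            MarkerCall(
                ref_position=m.ref_position,
                var_class=m.var_class,
                target_region=m.target_region,
                allele=m.allele,
                n_target=m.n_target,
                n_other=m.n_other,
                support_class=m.support_class,
                status=status,
            )
        )
    return out


def evaluations_to_frame(evaluations: list[SiteEvaluation], region_labels: dict[str, str]) -> pd.DataFrame:
    """Figure-style matrix: rows = sites, columns = modern individuals
    then ancient (sample, method) majority alleles."""
    inds = sorted(region_labels)
    samples = sorted({k for e in evaluations for k in e.per_sample})
    rows = []
    for e in sorted(evaluations, key=lambda x: x.ref_position):
        row = dict(position=e.ref_position + 1, var_class=e.var_class, classification=e.classification)
        for i in inds:
            row[f"{i} ({region_labels[i]})"] = e.modern_alleles.get(i, ".")
        for key in samples:
            allele = e.per_sample.get(key)
            row[f"{key[0]} [{key[1]}]"] = allele if allele is not None else "."
        rows.append(row)
    return pd.DataFrame(rows)
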