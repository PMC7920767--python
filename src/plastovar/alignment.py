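"""Whole-genome alignment of near-identical collinear plastomes and
variant-column scanning.

The aligner assumes the genomes are collinear (no rearrangements): it
chains unique shared k-mer anchors (k=24) that occur in the same order
in every genome, aligns the short inter-anchor segments with edlib, and
left-normalises all gap runs so InDels are reported at their leftmost
placement with a VCF-style anchor base.  Columns with two or more
distinct alleles become :class:`~plastovar.types.VariantSite` records,
classified as SNP (transition/transversion/multiallelic), InDel, or
homopolymer-run length difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._dna import is_transition, revcomp
from .types import CodingEffect, GeneFeature, PlastomeRecord, VariantSite

ANCHOR_K = 24
MIN_IDENTITY_FLOOR = 0.80

# amino-acid property classes (fixed lookup used in all reports)
AA_PROPERTY = {
    **{aa: "acidic" for aa in "DE"},
    **{aa: "basic" for aa in "RKH"},
    **{aa: "aromatic" for aa in "FWY"},
    **{aa: "hydrophobic" for aa in "LVIMC"},
    **{aa: "hydrophilic" for aa in "AGPSTNQ"},
    "*": "none",
    "X": "none",
}


class RearrangementError(RuntimeError):
    """Anchors are not collinear across genomes (suspected rearrangement)."""


@dataclass
class WholeGenomeAlignment:
    """A reference-anchored multiple alignment.

    ``rows`` are gapped sequences of equal length; degapping a row
    reproduces the input genome exactly.  ``col_to_ref`` maps each
    column to a 0-based reference position, or -1 for columns that are
    insertions relative to the reference.
    """

    ref_id: str
    ids: list[str]
    rows: dict[str, str]
    col_to_ref: np.ndarray
    genomes: dict[str, PlastomeRecord] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.col_to_ref)

    def reference_sequence(self) -> str:
        return self.rows[self.ref_id].replace("-", "")

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gid in self.ids:
                fh.write(f">{gid}\n{self.rows[gid]}\n")


# ---------------------------------------------------------------------------
# pairwise alignment machinery


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i: i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _longest_increasing_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """LIS on the second coordinate of (ref_pos, seq_pos) pairs sorted by
    the first; O(n log n)."""
    import bisect

    tails: list[int] = []
    tail_idx: list[int] = []
    prev = [-1] * len(pairs)
    for i, (_r, s) in enumerate(pairs):
        j = bisect.bisect_left(tails, s)
        if j == len(tails):
            tails.append(s)
            tail_idx.append(i)
        else:
            tails[j] = s
            tail_idx[j] = i
        prev[i] = tail_idx[j - 1] if j else -1
    chain = []
    i = tail_idx[-1] if tail_idx else -1
    while i != -1:
        chain.append(pairs[i])
        i = prev[i]
    return chain[::-1]


def _edlib_blocks(a: str, b: str) -> list[tuple[str, str, str]]:
    """Global alignment of a (ref segment) vs b, as (op, ref_seg, seq_seg)
    blocks with op in {M, I, D}; I = extra bases in b, D = bases only in a."""
    if not a and not b:
        return []
    if not a:
        return [("I", "", b)]
    if not b:
        return [("D", a, "")]
    res = edlib.align(b, a, mode="NW", task="path")
    blocks: list[tuple[str, str, str]] = []
    ia = ib = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            blocks.append(("M", a[ia: ia + n], b[ib: ib + n]))
            ia += n
            ib += n
        elif ch == "I":  # consumes query (b)
            blocks.append(("I", "", b[ib: ib + n]))
            ib += n
        elif ch == "D":  # consumes target (a)
            blocks.append(("D", a[ia: ia + n], ""))
            ia += n
    return blocks


def _merge_blocks(blocks: list[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
    out: list[tuple[str, str, str]] = []
    for op, ra, sa in blocks:
        if not ra and not sa:
            continue
        if out and out[-1][0] == op:
            prev = out.pop()
            out.append((op, prev[1] + ra, prev[2] + sa))
        else:
            out.append((op, ra, sa))
    return out


def _left_normalise_rows(ref_row: list[str], seq_row: list[str]) -> None:
    """Shift every gap run as far left as score-equivalence allows (the
    VCF left-alignment convention), in place.

    Moving a gap run ``[i, j)`` in row A one column left is score
    preserving iff the opposite row's characters at ``i-1`` and ``j-1``
    are equal bases; the degapped sequences are unchanged by any shift.
    """
    for row, other in ((ref_row, seq_row), (seq_row, ref_row)):
        n = len(row)
        i = 0
        while i < n:
            if row[i] != "-":
                i += 1
                continue
            j = i
            while j < n and row[j] == "-":
                j += 1
            a, b = i, j  # current gap-run bounds
            while a > 0 and row[a - 1] != "-" and other[a - 1] != "-" and other[a - 1] == other[b - 1]:
                row[b - 1] = row[a - 1]
                row[a - 1] = "-"
                a -= 1
                b -= 1
            i = j


def _pairwise_rows(ref: str, seq: str, k: int = ANCHOR_K) -> tuple[str, str]:
    """Anchor-chained, left-normalised global alignment of ``seq``
    against ``ref``; returns the two gapped rows."""
    ref_pos = _unique_kmer_positions(ref, k)
    seq_pos = _unique_kmer_positions(seq, k)
    shared = sorted(
        (rp, seq_pos[km]) for km, rp in ref_pos.items() if km in seq_pos
    )
    if shared:
        chain = _longest_increasing_chain(shared)
        if len(chain) < 0.5 * len(shared):
            raise RearrangementError(
                f"only {len(chain)}/{len(shared)} shared anchors are collinear"
            )
        # keep non-overlapping anchors
        anchors = []
        last_r = last_s = -k
        for r, s in chain:
            if r >= last_r + k and s >= last_s + k:
                anchors.append((r, s))
                last_r, last_s = r, s
    else:
        anchors = []

    ref_row: list[str] = []
    seq_row: list[str] = []
    pr = ps = 0
    for r, s in anchors + [(len(ref), len(seq))]:
        for op, ra, sa in _edlib_blocks(ref[pr:r], seq[ps:s]):
            width = max(len(ra), len(sa))
            ref_row.extend(ra if ra else "-" * width)
            seq_row.extend(sa if sa else "-" * width)
        if r < len(ref):
            ref_row.extend(ref[r: r + k])
            seq_row.extend(seq[s: s + k])
        pr, ps = r + k, s + k
    _left_normalise_rows(ref_row, seq_row)
    return "".join(ref_row), "".join(seq_row)


def align_plastomes(
    genomes: list[PlastomeRecord], reference_id: str | None = None, k: int = ANCHOR_K
) -> WholeGenomeAlignment:
    """Align collinear same-genus plastomes against a chosen reference.

    Raises :class:`RearrangementError` when anchor chains are not
    collinear, and ``ValueError`` when pairwise identity falls below the
    floor this aligner is meant for (near-identical genomes).
    """
    if not genomes:
        raise ValueError("no genomes to align")
    by_id = {g.id: g for g in genomes}
    if len(by_id) != len(genomes):
        raise ValueError("duplicate genome ids")
    ref_id = reference_id or genomes[0].id
    ref = by_id[ref_id].sequence
    Lref = len(ref)

    # per-genome: base at each ref position ('-' if deleted) and
    # insertions keyed by the ref position they follow (-1 = before start)
    subs: dict[str, list[str]] = {}
    inss: dict[str, dict[int, str]] = {}
    for gid, rec in by_id.items():
        if gid == ref_id:
            subs[gid] = list(ref)
            inss[gid] = {}
            continue
        rrow, srow = _pairwise_rows(ref, rec.sequence, k)
        ident = sum(a == b for a, b in zip(rrow, srow)) / len(rrow)
        if ident < MIN_IDENTITY_FLOOR:
            raise ValueError(f"{gid}: identity {ident:.2f} below floor; not near-identical")
        sub = []
        ins: dict[int, str] = {}
        rpos = -1
        for rc, sc in zip(rrow, srow):
            if rc != "-":
                rpos += 1
                sub.append(sc)
            else:
                ins[rpos] = ins.get(rpos, "") + sc
        subs[gid] = sub
        inss[gid] = ins

    ids = [ref_id] + sorted(gid for gid in by_id if gid != ref_id)
    # build MSA columns: substitution column per ref position, then any
    # insertion columns (identical inserted strings share columns)
    out_rows = {gid: [] for gid in ids}
    col_to_ref: list[int] = []

    def emit_insertions(rpos: int) -> None:
        strings = sorted({inss[g].get(rpos, "") for g in ids if inss[g].get(rpos, "")})
        for s in strings:
            for gid in ids:
                mine = inss[gid].get(rpos, "")
                out_rows[gid].append(s if mine == s else "-" * len(s))
            col_to_ref.extend([-1] * len(s))

    emit_insertions(-1)
    for rpos in range(Lref):
        for gid in ids:
            out_rows[gid].append(subs[gid][rpos])
        col_to_ref.append(rpos)
        emit_insertions(rpos)

    rows = {gid: "".join(out_rows[gid]) for gid in ids}
    return WholeGenomeAlignment(
        ref_id=ref_id,
        ids=ids,
        rows=rows,
        col_to_ref=np.asarray(col_to_ref, dtype=np.int64),
        genomes=dict(by_id),
    )


# ---------------------------------------------------------------------------
# variant scanning and classification


def _context(ref: str, start: int, end: int, flank: int = 10) -> str:
    return ref[max(0, start - flank): start] + "|" + ref[start:end] + "|" + ref[end: end + flank]


def classify_variant(alleles: dict[str, str], context: str = "") -> tuple[str, str]:
    """Classify an extracted allele set; returns (class, snp_subtype).

    Rule order: (1) a pure length difference of one base X lying inside
    a mononucleotide run of X of length >= 4 in at least one allele's
    context => homopolymer; (2) any length difference / gap => InDel;
    (3) single-base substitution => SNP (transition / transversion /
    multiallelic).  Non-ACGT alleles flag the site ambiguous.
    """
    distinct = sorted(set(alleles.values()))
    if len(distinct) < 2:
        raise ValueError("not a variant: fewer than 2 distinct alleles")
    if any(set(a) - set("ACGT") for a in distinct):
        return "ambiguous", "none"
    lengths = {len(a) for a in distinct}
    if len(lengths) > 1:
        left, _, right = context.partition("|")[0], None, context.rpartition("|")[2]
        if _is_homopolymer_event(distinct, left, right):
            return "homopolymer", "none"
        return "InDel", "none"
    if lengths == {1}:
        if len(distinct) > 2:
            return "SNP", "multiallelic"
        a, b = distinct
        return "SNP", "transition" if is_transition(a, b) else "transversion"
    # equal-length multi-base alleles: treat as a clustered substitution block
    return "SNP", "multiallelic"


def _is_homopolymer_event(distinct: list[str], left_flank: str, right_flank: str) -> bool:
    """True when alleles share an anchor and differ only in the length of
    a single-base run that reaches >= 4 in some allele's context."""
    anchors = {a[0] for a in distinct}
    if len(anchors) != 1:
        return False
    tails = [a[1:] for a in distinct]
    bases = {t[0] for t in tails if t}
    if len(bases) != 1:
        return False
    x = bases.pop()
    if any(set(t) != {x} for t in tails if t):
        return False
    lf = 0
    for c in reversed(left_flank):
        if c == x:
            lf += 1
        else:
            break
    rf = 0
    for c in right_flank:
        if c == x:
            rf += 1
        else:
            break
    longest = max(len(t) for t in tails)
    return lf + longest + rf >= 4


def scan_variants(aln: WholeGenomeAlignment) -> list[VariantSite]:
    """Scan every alignment column; merge adjacent gap columns into one
    InDel event; classify and sort by reference position."""
    ids = aln.ids
    rows = {g: aln.rows[g] for g in ids}
    ncol = aln.n_columns
    col_to_ref = aln.col_to_ref
    ref_seq = aln.reference_sequence()

    sites: list[VariantSite] = []
    # pass 1: find maximal runs of columns containing any gap
    gap_mask = np.zeros(ncol, dtype=bool)
    arrs = {g: np.frombuffer(rows[g].encode(), dtype="S1") for g in ids}
    for g in ids:
        gap_mask |= arrs[g] == b"-"

    c = 0
    while c < ncol:
        if gap_mask[c]:
            d = c
            while d < ncol and gap_mask[d]:
                d += 1
            site = _gap_run_site(aln, ids, rows, col_to_ref, ref_seq, c, d)
            if site is not None:
                sites.append(site)
            c = d
            continue
        col = {g: rows[g][c] for g in ids}
        if len(set(col.values())) > 1:
            rpos = int(col_to_ref[c])
            ctx = _context(ref_seq, rpos, rpos + 1)
            var_class, subtype = classify_variant(col, ctx)
            sites.append(
                VariantSite(
                    ref_position=rpos,
                    var_class="SNP" if var_class == "ambiguous" else var_class,
                    alleles=col,
                    snp_subtype=subtype,
                    context=ctx,
                    ambiguous=var_class == "ambiguous",
                )
            )
        c += 1
    sites.sort(key=lambda s: s.ref_position)
    return sites


def _gap_run_site(aln, ids, rows, col_to_ref, ref_seq, c, d) -> VariantSite | None:
    """Build one InDel/homopolymer VariantSite from gap-run columns [c, d)."""
    # anchor = last reference position before the run
    before = col_to_ref[:c]
    anchor_ref = int(before[before >= 0][-1]) if (before >= 0).any() else -1
    run_refs = [int(r) for r in col_to_ref[c:d] if r >= 0]
    end_ref = (max(run_refs) + 1) if run_refs else anchor_ref + 1
    if anchor_ref < 0:
        return None  # event at the very start of the alignment; no anchor base
    alleles = {}
    for g in ids:
        seg = rows[g][c:d].replace("-", "")
        alleles[g] = ref_seq[anchor_ref] + seg
    if len(set(alleles.values())) < 2:
        return None
    ctx = _context(ref_seq, anchor_ref + 1, end_ref)
    var_class, subtype = classify_variant(alleles, ctx)
    max_len = max(len(a) for a in alleles.values())
    min_len = min(len(a) for a in alleles.values())
    return VariantSite(
        ref_position=anchor_ref,
        var_class="InDel" if var_class == "ambiguous" else var_class,
        alleles=alleles,
        snp_subtype=subtype,
        indel_length=max_len - min_len,
        context=ctx,
        ambiguous=var_class == "ambiguous",
    )


def mark_ir_mirrors(sites: list[VariantSite], ir_bounds: dict[str, tuple[int, int]]) -> None:
    """Cross-reference variant sites duplicated across the two IR copies.

    A site at IRb offset o mirrors IRa position (IRa_end - 1 - o); both
    copies stay listed, each pointing at the other, so downstream counts
    can keep one per physical position.
    """
    b0, b1 = ir_bounds["IRb"]
    a0, a1 = ir_bounds["IRa"]
    by_pos = {s.ref_position: s for s in sites}
    for s in sites:
        if b0 <= s.ref_position < b1:
            mirror = a1 - 1 - (s.ref_position - b0)
            if mirror in by_pos:
                s.ir_mirror_of = mirror
                by_pos[mirror].ir_mirror_of = s.ref_position


def annotate_coding_effect(
    site: VariantSite, features: list[GeneFeature], ref_seq: str
) -> CodingEffect | None:
    """Recompute the affected codon per allele (bacterial/plastid code,
    table 11), strand-aware.  Non-SNP and noncoding sites return None."""
    from Bio.Seq import Seq

    if site.var_class != "SNP":
        return None
    pos = site.ref_position
    feat = next((f for f in features if f.kind == "CDS" and f.start <= pos < f.end), None)
    if feat is None:
        return None
    ref_base = ref_seq[pos]
    alts = [a for a in sorted(site.distinct_alleles) if a != ref_base]
    if not alts:
        return None
    alt_base = alts[0]
    if set(ref_base + alt_base) - set("ACGT"):
        return CodingEffect(feat.name, -1, "X", "X", False, "none", "none", indeterminate=True)

    if feat.strand == "+":
        offset = pos - feat.start
    else:
        offset = feat.end - 1 - pos
    codon_index = offset // 3
    within = offset % 3

    def codon_for(base: str) -> str:
        s = ref_seq[: pos] + base + ref_seq[pos + 1:]
        cds = s[feat.start: feat.end]
        if feat.strand == "-":
            cds = revcomp(cds)
        return cds[codon_index * 3: codon_index * 3 + 3]

    table = feat.codon_table
    ref_aa = str(Seq(codon_for(ref_base)).translate(table=table))
    alt_aa = str(Seq(codon_for(alt_base)).translate(table=table))
    return CodingEffect(
        gene=feat.name,
        codon_index=codon_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=ref_aa == alt_aa,
        ref_property=AA_PROPERTY.get(ref_aa, "none"),
        alt_property=AA_PROPERTY.get(alt_aa, "none"),
    )


def count_ts_tv(sites: list[VariantSite]) -> dict[str, int]:
    """Transition/transversion counts over SNP sites (multiallelic and
    ambiguous reported separately; IR mirrors counted once)."""
    out = {"transitions": 0, "transversions": 0, "multiallelic": 0}
    for s in sites:
        if s.var_class != "SNP" or s.ambiguous:
            continue
        if s.ir_mirror_of is not None and s.ir_mirror_of < s.ref_position:
            continue
        if s.snp_subtype == "transition":
            out["transitions"] += 1
        elif s.snp_subtype == "transversion":
            out["transversions"] += 1
        else:
            out["multiallelic"] += 1
    return out


def pairwise_differences(
    sites: list[VariantSite], include_classes: frozenset = frozenset({"SNP", "InDel"})
) -> pd.DataFrame:
    """Symmetric individual-by-individual difference counts; each InDel
    counts once regardless of length; homopolymer sites excluded by
    default."""
    ids = sorted({g for s in sites for g in s.alleles})
    mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for s in sites:
        if s.var_class not in include_classes or s.ambiguous:
            continue
        if s.ir_mirror_of is not None and s.ir_mirror_of < s.ref_position:
            continue
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if a in s.alleles and b in s.alleles and s.alleles[a] != s.alleles[b]:
                    mat.loc[a, b] += 1
                    mat.loc[b, a] += 1
    return mat


def compute_pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: identical columns / total alignment
    columns, gap columns included in the denominator."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            cols += int(num)
            num = ""
    return (cols - res["editDistance"]) / cols


def variants_to_frame(sites: list[VariantSite]) -> pd.DataFrame:
    """Flat TSV-ready table (1-based positions) with one allele column
    per individual."""
    ids = sorted({g for s in sites for g in s.alleles})
    rows = []
    for s in sites:
        row = dict(
            position=s.ref_position + 1,
            var_class=s.var_class,
            subtype=s.snp_subtype,
            indel_length=s.indel_length,
            ambiguous=s.ambiguous,
            ir_mirror=("" if s.ir_mirror_of is None else s.ir_mirror_of + 1),
        )
        for g in ids:
            row[g] = s.alleles.get(g, "")
        rows.append(row)
    return pd.DataFrame(rows)


def write_minimal_vcf(sites: list[VariantSite], ref_id: str, ref_seq: str, path) -> None:
    """Minimal VCF with one pseudo-sample column per individual."""
    ids = sorted({g for s in sites for g in s.alleles})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref_id},length={len(ref_seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        for s in sorted(sites, key=lambda x: x.ref_position):
            if s.var_class == "SNP":
                pos = s.ref_position + 1
                ref_allele = ref_seq[s.ref_position]
            else:
                pos = s.ref_position + 1
                ref_allele = s.alleles.get(ref_id) or sorted(s.distinct_alleles, key=len)[-1]
            alts = sorted(a for a in s.distinct_alleles if a != ref_allele)
            if not alts:
                continue
            idx = {ref_allele: 0, **{a: i + 1 for i, a in enumerate(alts)}}
            gts = "\t".join(str(idx.get(s.alleles.get(g, ref_allele), ".")) for g in ids)
            info = f"TYPE={s.var_class};SUBTYPE={s.snp_subtype}"
            fh.write(f"{ref_id}\t{pos}\t.\t{ref_allele}\t{','.join(alts)}\t.\tPASS\t{info}\tGT\t{gts}\n")
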