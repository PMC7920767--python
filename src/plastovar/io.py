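"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; GFF3 and the TSV truth tables are
simple enough to emit directly.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import GeneFeature, PlastomeRecord, Read


def write_fasta(records: Iterable[PlastomeRecord], path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"taxon={r.taxon} region={r.region_label} role={r.role}")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path, taxon: str = "", region: str = "") -> list[PlastomeRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        out.append(
            PlastomeRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                taxon=meta.get("taxon", taxon),
                region_label=meta.get("region", region),
                role=meta.get("role", "individual"),
            )
        )
    return out


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")


def read_fastq(path, sample: str = "", method: str = "shotgun") -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(id=rec.id, sequence=str(rec.seq).upper(), qualities=quals, sample=sample, method=method))
    return reads


def write_gff3(features: Sequence[GeneFeature], seqid: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            ftype = "CDS" if f.kind == "CDS" else f.kind
            fh.write(
                f"{seqid}\tplastovar\t{ftype}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.name};codon_table={f.codon_table}\n"
            )


def read_gff3(path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, _src, ftype, start, end, _score, strand, _frame, attrs = line.rstrip("\n").split("\t")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            feats.append(
                GeneFeature(
                    name=attr.get("ID", f"{ftype}_{start}"),
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    kind=ftype,
                    codon_table=int(attr.get("codon_table", 11)),
                )
            )
    return feats


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
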