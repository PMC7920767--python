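"""Domain containers used across the pipeline.

Coordinates are 0-based half-open internally; user-facing reports print
1-based positions.  Plastomes are circular; all records store a fixed
linearisation (origin at the LSC start).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

VALID_ALPHABET = frozenset("ACGTN")


@dataclass
class GeneFeature:
    """An annotated feature on a linearised plastome."""

    name: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"
    kind: str = "CDS"  # CDS | tRNA | rRNA | noncoding
    codon_table: int = 11
    partial: bool = False

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature interval {self.start}..{self.end}")
        if self.kind == "CDS" and not self.partial and (self.end - self.start) % 3:
            raise ValueError(f"CDS {self.name} length not divisible by 3")


@dataclass
class PlastomeRecord:
    """One circular plastome with its sampling-region label."""

    id: str
    sequence: str
    region_label: str = ""
    features: list[GeneFeature] = field(default_factory=list)
    role: str = "individual"  # individual | reference | draft
    taxon: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        if set(self.sequence) - VALID_ALPHABET:
            raise ValueError(f"{self.id}: alphabet outside ACGTN")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(f"{self.id}: feature {f.name} beyond sequence end")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CodingEffect:
    gene: str
    codon_index: int  # 0-based codon number within the CDS
    ref_aa: str
    alt_aa: str
    synonymous: bool
    ref_property: str
    alt_property: str
    indeterminate: bool = False


@dataclass
class VariantSite:
    """One variable locus in a whole-genome alignment.

    ``ref_position`` is 0-based internally (the position of the left
    anchor base for InDel/homopolymer events); reports add 1.
    InDel alleles include the left anchor base, VCF style.
    """

    ref_position: int
    var_class: str  # SNP | InDel | homopolymer
    alleles: dict[str, str]  # individual id -> allele string
    snp_subtype: str = "none"  # transition | transversion | multiallelic | none
    indel_length: int = 0
    context: str = ""
    coding: Optional[CodingEffect] = None
    ambiguous: bool = False
    ir_mirror_of: Optional[int] = None  # physical duplicate in the other IR copy

    @property
    def distinct_alleles(self) -> set[str]:
        return set(self.alleles.values())


@dataclass
class Haplotype:
    id: str
    alleles: tuple
    members: list[str]
    regions: list[str]


@dataclass
class Read:
    id: str
    sequence: str
    qualities: str  # Phred+33
    sample: str = ""
    method: str = "shotgun"  # shotgun | capture

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadAlignment:
    """A gapped placement of a read on a linearised circular reference.

    ``start``/``end`` are reference coordinates; ``end`` may exceed the
    reference length for origin-wrapping reads (fold modulo length when
    computing per-position statistics).  ``cigar`` uses =/X/I/D ops with
    I consuming read bases and D consuming reference bases.
    """

    read_id: str
    ref_id: str
    start: int
    end: int
    strand: str  # + | -
    cigar: str
    mismatches: int
    gap_bases: int
    read_seq: str  # oriented as aligned (reverse-complemented for '-')
    read_quals: str
    duplicate: bool = False
    sample: str = ""
    method: str = "shotgun"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("alignment end must exceed start")


@dataclass
class DamageProfile:
    ct5: np.ndarray  # offset 1..window C->T frequency from the 5' end
    ga3: np.ndarray  # offset 1..window G->A frequency from the 3' end
    baseline: float
    window: int = 25


@dataclass
class MarkerCall:
    ref_position: int
    var_class: str
    target_region: str
    allele: str
    n_target: int
    n_other: int
    support_class: str  # robust | singleton-region
    status: str = "candidate"  # candidate|confirmed_by_ancient|refuted_by_ancient|uncovered|absent_locally


@dataclass
class ProvenanceScore:
    genome_id: str
    aligned_reads: int
    identical_bases: int
    covered_bases: int

    @property
    def identity(self) -> float:
        return self.identical_bases / self.covered_bases if self.covered_bases else 0.0
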