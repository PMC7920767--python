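"""Small sequence helpers shared across modules.

Only plain ACGTN strings are handled; anything else is the caller's bug.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T."""
    pair = {a, b}
    return pair <= PURINES or pair <= PYRIMIDINES


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def phred_string(quals) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


def phred_values(qual_string: str) -> list[int]:
    return [ord(c) - 33 for c in qual_string]


def homopolymer_run_length(seq: str, pos: int) -> int:
    """Length of the maximal mononucleotide run covering ``pos``."""
    base = seq[pos]
    i = pos
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos
    while j + 1 < len(seq) and seq[j + 1] == base:
        j += 1
    return j - i + 1
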