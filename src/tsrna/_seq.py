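"""Small DNA-string helpers shared across modules.

All sequences are handled in DNA space ({A,C,G,T}); uracil appears only in
user-facing tables, where T is printed as U.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= DNA_ALPHABET


def as_rna(seq: str) -> str:
    """Display form: T shown as U."""
    return seq.replace("T", "U")
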