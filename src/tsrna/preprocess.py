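"""Adapter trimming, length filtering and read collapsing.

The 3' adapter is located by an exact match of its first 6 nt — no
mismatches — and everything from the adapter onward is cut off.  Reads in
which that 6-mer never occurs are discarded: with ~35 nt inserts and 42
sequencing cycles every genuine insert is followed by adapter sequence, so a
missing adapter signals a failed ligation or an over-long insert.  Surviving
inserts are length-filtered and collapsed to unique sequences with counts
("redundant" reads = total occurrences, "unique" = distinct sequences).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "CollapsedRead",
    "TrimCounters",
    "trim_adapter",
    "trim_library",
    "collapse_reads",
    "read_sequences",
    "write_collapsed_fasta",
]

ADAPTER_SEED_LEN = 6  # number of adapter nt used for matching, always


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct trimmed sequence with the number of redundant reads it represents."""

    sequence: str
    count: int


@dataclass
class TrimCounters:
    total_in: int = 0
    no_adapter_discarded: int = 0
    length_discarded: int = 0
    kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total_in": self.total_in,
            "no_adapter_discarded": self.no_adapter_discarded,
            "length_discarded": self.length_discarded,
            "kept": self.kept,
        }


def _adapter_seed(adapter: str) -> str:
    if len(adapter) < ADAPTER_SEED_LEN:
        raise ValueError(
            f"adapter must be at least {ADAPTER_SEED_LEN} nt (got {len(adapter)})"
        )
    return adapter[:ADAPTER_SEED_LEN].upper()


def trim_adapter(sequence: str, adapter: str) -> str | None:
    """Return the insert 5' of the leftmost adapter-6-mer, or None to discard.

    Only the first 6 adapter nt are ever used for matching, exactly.  N in
    the read matches nothing.  The leftmost occurrence wins when several
    occur, treating the earliest possible ligation junction as real.
    """
    seed = _adapter_seed(adapter)
    if not sequence:
        return None
    pos = sequence.upper().find(seed)
    if pos < 0:
        return None
    return sequence[:pos]


def trim_library(
    reads: Iterable[str],
    adapter: str,
    min_len: int = 16,
    max_len: int = 45,
) -> tuple[list[str], TrimCounters]:
    """Trim every read; keep inserts with min_len <= length <= max_len.

    Counters always reconcile: total_in = kept + no_adapter + length_discarded.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    _adapter_seed(adapter)  # validate once up front
    counters = TrimCounters()
    kept: list[str] = []
    for read in reads:
        counters.total_in += 1
        insert = trim_adapter(read, adapter)
        if insert is None:
            counters.no_adapter_discarded += 1
        elif not (min_len <= len(insert) <= max_len):
            counters.length_discarded += 1
        else:
            kept.append(insert)
            counters.kept += 1
    return kept, counters


def collapse_reads(sequences: Iterable[str]) -> list[CollapsedRead]:
    """Collapse trimmed sequences to unique records with redundant counts.

    The sum of counts equals the number of input sequences.  Output order is
    deterministic: by decreasing count, then lexicographically.
    """
    tally = Counter(sequences)
    return [
        CollapsedRead(seq, n)
        for seq, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def read_sequences(path) -> Iterator[str]:
    """Yield raw read sequences from a FASTA or FASTQ file (format sniffed)."""
    from Bio import SeqIO

    with open(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        fmt = "fastq" if first == "@" else "fasta"
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq).upper()


def write_collapsed_fasta(collapsed: Sequence[CollapsedRead], path) -> dict[str, str]:
    """Write collapsed reads as FASTA with 'seq<k>_x<count>' headers.

    Returns the {read_id: sequence} mapping used downstream by the matcher.
    """
    ids: dict[str, str] = {}
    with open(path, "w") as fh:
        for k, rec in enumerate(collapsed, start=1):
            rid = f"seq{k}_x{rec.count}"
            ids[rid] = rec.sequence
            fh.write(f">{rid}\n{rec.sequence}\n")
    return ids
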