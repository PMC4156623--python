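"""Exact, gapless, zero-mismatch multi-pattern matching of reads on references.

Collapsed reads are placed on reference sequence sets (the genome on both
strands, mature tRNAs sense-strand only) reporting *every* occurrence.  The
search is a single pass of an Aho–Corasick automaton over each reference, so
total work is O(reference length + hits) regardless of how many query
sequences are indexed.  A brute-force sliding-window oracle with the same
contract is provided for testing.

Coordinates are 0-based half-open internally; exporters convert to 1-based
inclusive.  On the '-' strand the reverse complement of the reference slice
equals the query.  A reverse-complement-palindromic query matching at one
locus is reported twice, once per strand: the contract is
"every occurrence on every requested strand", with no deduplication.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

from ._seq import DNA_ALPHABET, reverse_complement

__all__ = ["Hit", "MatchIndex", "build_index", "match_all", "naive_match_oracle", "hits_to_table"]


@dataclass(frozen=True, order=True)
class Hit:
    """One exact placement of a query on a reference."""

    query_id: str
    ref_id: str
    start: int  # 0-based
    end: int    # exclusive
    strand: str  # '+' or '-'


class MatchIndex:
    """Aho–Corasick automaton over a set of distinct DNA query sequences."""

    def __init__(self, queries: Mapping[str, str]):
        if not queries:
            raise ValueError("empty query set")
        seen: dict[str, str] = {}
        for qid, seq in queries.items():
            if not seq or not set(seq) <= DNA_ALPHABET:
                raise ValueError(f"query {qid!r} contains non-ACGT symbols or is empty")
            if seq in seen:
                raise ValueError(f"duplicate query sequence: {qid!r} repeats {seen[seq]!r}")
            seen[seq] = qid
        self.queries = dict(queries)
        self._build(list(queries.items()))

    def __len__(self) -> int:
        return len(self.queries)

    def _build(self, items: list[tuple[str, str]]) -> None:
        # goto[node] maps base -> node; out[node] lists (query_id, length)
        goto: list[dict[str, int]] = [{}]
        out: list[list[tuple[str, int]]] = [[]]
        for qid, seq in items:
            node = 0
            for base in seq:
                nxt = goto[node].get(base)
                if nxt is None:
                    goto.append({})
                    out.append([])
                    nxt = len(goto) - 1
                    goto[node][base] = nxt
                node = nxt
            out[node].append((qid, len(seq)))
        fail = [0] * len(goto)
        queue: deque[int] = deque(goto[0].values())
        while queue:
            node = queue.popleft()
            for base, child in goto[node].items():
                queue.append(child)
                f = fail[node]
                while f and base not in goto[f]:
                    f = fail[f]
                fail[child] = goto[f].get(base, 0) if goto[f].get(base, 0) != child else 0
                out[child].extend(out[fail[child]])
        self._goto, self._fail, self._out = goto, fail, out

    def scan(self, text: str) -> Iterator[tuple[str, int, int]]:
        """Yield (query_id, start, end) for every occurrence in text."""
        goto, fail, out = self._goto, self._fail, self._out
        node = 0
        for i, base in enumerate(text):
            while node and base not in goto[node]:
                node = fail[node]
            node = goto[node].get(base, 0)
            for qid, qlen in out[node]:
                yield qid, i - qlen + 1, i + 1


def build_index(queries: Mapping[str, str]) -> MatchIndex:
    """Build a reusable match index from {query_id: sequence}.

    Sequences must be distinct (collapsed reads are, by construction) and
    strictly over {A,C,G,T}; violations raise ``ValueError`` naming the id.
    """
    return MatchIndex(queries)


def _normalise_refs(references) -> list[tuple[str, str]]:
    if isinstance(references, Mapping):
        refs = list(references.items())
    else:
        refs = list(references)
    if not refs:
        raise ValueError("empty reference set")
    return refs


def match_all(index: MatchIndex, references, strands: str = "both") -> list[Hit]:
    """Enumerate every occurrence of every indexed query in every reference.

    Parameters
    ----------
    references : mapping or iterable of (ref_id, sequence)
    strands : 'sense_only' or 'both'
        'both' also reports occurrences on the reverse strand, where the
        reverse complement of the reference slice equals the query.
    """
    if strands not in ("sense_only", "both"):
        raise ValueError(f"unknown strands mode {strands!r}")
    hits: list[Hit] = []
    for ref_id, seq in _normalise_refs(references):
        for qid, s, e in index.scan(seq):
            hits.append(Hit(qid, ref_id, s, e, "+"))
        if strands == "both":
            L = len(seq)
            for qid, s, e in index.scan(reverse_complement(seq)):
                hits.append(Hit(qid, ref_id, L - e, L - s, "-"))
    return hits


def naive_match_oracle(queries: Mapping[str, str], references, strands: str = "both") -> list[Hit]:
    """Brute-force sliding-window matcher; set-equal to :func:`match_all`.

    Intended for small inputs only (test oracle): O(n*m) per query/reference.
    """
    hits: list[Hit] = []
    for ref_id, seq in _normalise_refs(references):
        L = len(seq)
        for qid, q in queries.items():
            m = len(q)
            rc = reverse_complement(q)
            for s in range(L - m + 1):
                window = seq[s : s + m]
                if window == q:
                    hits.append(Hit(qid, ref_id, s, s + m, "+"))
                if strands == "both" and window == rc:
                    hits.append(Hit(qid, ref_id, s, s + m, "-"))
    return hits


def hits_to_table(hits: Sequence[Hit], counts: Mapping[str, int] | None = None):
    """Hits as a DataFrame with 1-based inclusive coordinates for export."""
    import pandas as pd

    rows = [
        {
            "read": h.query_id,
            "ref": h.ref_id,
            "start1": h.start + 1,
            "end1": h.end,
            "strand": h.strand,
            "count": counts.get(h.query_id, 1) if counts else 1,
        }
        for h in hits
    ]
    df = pd.DataFrame(rows, columns=["read", "ref", "start1", "end1", "strand", "count"])
    return df.sort_values(["ref", "start1", "end1", "strand", "read"], kind="mergesort").reset_index(drop=True)
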