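"""Classify tRNA-mapped reads by end anchoring, fragment type and cleavage context.

A read placed on a mature tRNA is *anchored* if one of its ends coincides
exactly (0 nt tolerance) with a mature end: start 0 → five_prime, end =
|mature| → three_prime, both → full_length, neither → internal.  For an
end-anchored read the cleavage site is the mature coordinate of the
nucleotide 5' of the cut that released the fragment:

* a five_prime read covering [0, L) was released by a cut after its last
  nucleotide → position L - 1;
* a three_prime read starting at s was released by a cut before its first
  nucleotide → position s - 1.

The cut's structural context is the pairing state of that nucleotide in the
dot-bracket structure: '.' → loop_or_bulge, '(' or ')' → paired.  (An
optional "symmetric" variant also checks the 3' neighbour and calls
loop_or_bulge if either side is unpaired; the default is the stricter
single-position rule.)  Fragment types follow the structural rule first —
an end-anchored read cut inside the anticodon loop is a tRNA half
regardless of its length — with tsRNA length windows (default 16–23 nt)
applied only to the remaining end-anchored reads.

The non-templated CCA is part of the mature 3' end: a three_prime read must
include it, because the mature reference carries it by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import MatureTRNA
from .matcher import Hit

__all__ = [
    "ANCHOR_CLASSES",
    "anchor_class",
    "cleavage_site",
    "structural_context",
    "fragment_type",
    "classify_hits",
    "per_trna_profile",
    "end_preference_summary",
    "bulge_cleavage_fraction",
    "cleavage_summary",
]

ANCHOR_CLASSES = ("five_prime", "internal", "three_prime", "full_length")
DEFAULT_TSRNA_WINDOW = (16, 23)


def anchor_class(start: int, end: int, mature_length: int) -> str:
    """Anchor label from an exact-offset rule (0 nt tolerance at both ends)."""
    at5, at3 = start == 0, end == mature_length
    if at5 and at3:
        return "full_length"
    if at5:
        return "five_prime"
    if at3:
        return "three_prime"
    return "internal"


def cleavage_site(start: int, end: int, mature_length: int) -> int | None:
    """Mature coordinate of the nucleotide 5' of the releasing cut.

    Defined only for end-anchored reads; internal and full-length reads
    return None (undefined-signal — the caller filters).
    """
    anchor = anchor_class(start, end, mature_length)
    if anchor == "five_prime":
        return end - 1
    if anchor == "three_prime":
        return start - 1
    return None


def structural_context(position: int, structure: str, symmetric: bool = False) -> str:
    """Pairing state at a cut position: 'loop_or_bulge' or 'paired'."""
    if not 0 <= position < len(structure):
        raise ValueError(f"position {position} outside structure of length {len(structure)}")
    if structure[position] == ".":
        return "loop_or_bulge"
    if symmetric and position + 1 < len(structure) and structure[position + 1] == ".":
        return "loop_or_bulge"
    return "paired"


def fragment_type(
    anchor: str,
    cleavage_position: int | None,
    loop_span: tuple[int, int],
    length: int,
    tsrna_window: tuple[int, int] = DEFAULT_TSRNA_WINDOW,
) -> str:
    """Fragment-type label; the structural (loop-span) rule beats length windows."""
    if anchor == "full_length":
        return "full"
    if anchor == "internal":
        return "internal"
    lo_span, hi_span = loop_span
    in_loop = cleavage_position is not None and lo_span <= cleavage_position < hi_span
    if anchor == "five_prime":
        if in_loop:
            return "five_half"
        return "tsRNA_5p" if tsrna_window[0] <= length <= tsrna_window[1] else "other_end"
    if in_loop:
        return "three_half"
    return "tsRNA_3p" if tsrna_window[0] <= length <= tsrna_window[1] else "other_end"


def classify_hits(
    trna_hits: Iterable[Hit],
    matures: Mapping[str, MatureTRNA],
    counts: Mapping[str, int],
    sequences: Mapping[str, str] | None = None,
    tsrna_window: tuple[int, int] = DEFAULT_TSRNA_WINDOW,
    symmetric_context: bool = False,
) -> pd.DataFrame:
    """One FragmentAnnotation row per (sequence, tRNA, placement).

    Columns: read, sequence, count, trna, isoacceptor, start, end, length,
    anchor, fragment_type, cleavage_position (empty for internal/full),
    cleavage_context (NA for internal/full), n_placements (across the whole
    mature set, for weighted summaries).
    """
    hits = list(trna_hits)
    placements: dict[str, int] = {}
    for h in hits:
        if h.strand != "+":
            raise ValueError("mature-tRNA hits must be sense-strand")
        placements[h.query_id] = placements.get(h.query_id, 0) + 1
    rows = []
    for h in hits:
        m = matures[h.ref_id]
        L = len(m.sequence)
        anchor = anchor_class(h.start, h.end, L)
        cut = cleavage_site(h.start, h.end, L)
        if cut is None:
            context = "NA"
        else:
            context = structural_context(cut, m.structure, symmetric_context)
        ftype = fragment_type(anchor, cut, m.anticodon_loop_span, h.end - h.start, tsrna_window)
        rows.append({
            "read": h.query_id,
            "sequence": sequences.get(h.query_id, "") if sequences else "",
            "count": int(counts.get(h.query_id, 1)),
            "trna": h.ref_id,
            "isoacceptor": m.isoacceptor,
            "start": h.start,
            "end": h.end,
            "length": h.end - h.start,
            "anchor": anchor,
            "fragment_type": ftype,
            "cleavage_position": "" if cut is None else cut,
            "cleavage_context": context,
            "n_placements": placements[h.query_id],
        })
    df = pd.DataFrame(rows, columns=[
        "read", "sequence", "count", "trna", "isoacceptor", "start", "end",
        "length", "anchor", "fragment_type", "cleavage_position",
        "cleavage_context", "n_placements",
    ])
    return df.sort_values(["trna", "start", "end", "read"], kind="mergesort").reset_index(drop=True)


def per_trna_profile(annotations: pd.DataFrame, mature_length: int):
    """Coverage vector, size histogram and top sequence for one tRNA.

    coverage[i] = sum of counts of reads covering mature position i, so
    sum(coverage) = sum(count * length).  The top sequence is the
    max-count read; ties break to the lexicographically smallest sequence.
    """
    coverage = np.zeros(mature_length, dtype=float)
    hist: dict[int, int] = {}
    top_seq, top_count = "", -1
    for row in annotations.itertuples():
        coverage[row.start:row.end] += row.count
        hist[row.length] = hist.get(row.length, 0) + row.count
        key = row.sequence or row.read
        if row.count > top_count or (row.count == top_count and key < top_seq):
            top_seq, top_count = key, row.count
    return coverage, dict(sorted(hist.items())), top_seq


def end_preference_summary(annotations: pd.DataFrame) -> dict:
    """Redundant-count totals per anchor group and the dominant group."""
    totals = {a: 0 for a in ("five_prime", "internal", "three_prime")}
    for row in annotations.itertuples():
        if row.anchor == "full_length":
            continue
        totals[row.anchor] += row.count
    best = max(totals.values()) if totals else 0
    winners = [a for a, v in totals.items() if v == best and best > 0]
    dominant = winners[0] if len(winners) == 1 else "none"
    ratio = totals["five_prime"] / totals["three_prime"] if totals["three_prime"] else float("inf")
    return {"totals": totals, "dominant": dominant, "five_to_three_ratio": ratio}


def bulge_cleavage_fraction(annotations: pd.DataFrame, weighted: bool = True) -> float | None:
    """Percent of end-anchored cleavage events falling at an unpaired position.

    Count-weighted by default; ``weighted=False`` counts each (sequence,
    placement) once.  None when no end-anchored reads are in scope.
    """
    scope = annotations[annotations["anchor"].isin(["five_prime", "three_prime"])]
    if not len(scope):
        return None
    w = scope["count"] if weighted else pd.Series(1, index=scope.index)
    loop = w[scope["cleavage_context"] == "loop_or_bulge"].sum()
    return 100.0 * float(loop) / float(w.sum())


def cleavage_summary(annotations: pd.DataFrame) -> dict:
    """Library-level cleavage behaviour (JSON-ready)."""
    scope = annotations[annotations["anchor"].isin(["five_prime", "three_prime"])]
    hists: dict[str, dict[int, int]] = {}
    for anchor in ("five_prime", "internal", "three_prime", "full_length"):
        sub = annotations[annotations["anchor"] == anchor]
        hists[anchor] = {
            int(k): int(v) for k, v in sub.groupby("length")["count"].sum().items()
        }
    pref = end_preference_summary(annotations)
    return {
        "n_end_anchored": int(scope["count"].sum()) if len(scope) else 0,
        "bulge_fraction_weighted_pct": bulge_cleavage_fraction(annotations, weighted=True),
        "bulge_fraction_unique_pct": bulge_cleavage_fraction(annotations, weighted=False),
        "size_histograms": hists,
        "end_preference": pref,
    }
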