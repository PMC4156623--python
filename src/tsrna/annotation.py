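"""Assign genome-mapped reads to feature categories and count them.

Reads are labelled by ≥1 bp overlap between any of their genomic placements
and user-supplied feature intervals (GFF3/BED).  rRNA, tRNA and other-ncRNA
overlap is sense-strand (fragments of a transcript exist in sense
orientation); repeat and gene overlap is strand-blind (repeat families have
no meaningful strand for sRNA origin).  Two labelling modes are offered:

* non_exclusive — a read carries every category it overlaps;
* hierarchical — a read gets the single highest-priority category, in the
  order rRNA > tRNA > repeat > gene > other_ncRNA > unannotated, so category
  counts partition the mapped reads exactly.

Because a single sequence can map to many loci (tRNA gene copies, repeat
families), per-reference abundances are placement-weighted: each placement
receives count / n_placements, conserving the library total.  Hyperabundant
single sequences (rRNA degradation products that dominate a library) can be
flagged and masked out of global statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .matcher import Hit

__all__ = [
    "Feature",
    "FeatureSet",
    "read_gff3",
    "read_bed",
    "CATEGORY_PRIORITY",
    "annotate_reads",
    "weighted_trna_counts",
    "rrna_exclusion_mask",
    "hyperabundant_flags",
]

CATEGORY_PRIORITY = ["rRNA", "tRNA", "repeat", "gene", "other_ncRNA"]
STRAND_AWARE = {"rRNA": True, "tRNA": True, "other_ncRNA": True, "repeat": False, "gene": False}


@dataclass(frozen=True)
class Feature:
    feature_id: str
    seq_id: str
    start: int   # 0-based
    end: int     # exclusive
    strand: str


@dataclass
class FeatureSet:
    category: str
    features: list[Feature]

    def __post_init__(self):
        if self.category not in CATEGORY_PRIORITY:
            raise ValueError(f"unknown feature category {self.category!r}")


def read_gff3(path, category: str) -> FeatureSet:
    """Read a 9-column GFF3 file (1-based inclusive) into a FeatureSet."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: not a 9-column GFF3 line")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            fid = attrs.get("ID", f"{parts[2]}_{lineno}")
            feats.append(
                Feature(fid, parts[0], int(parts[3]) - 1, int(parts[4]), parts[6])
            )
    return FeatureSet(category, feats)


def read_bed(path, category: str) -> FeatureSet:
    """Read BED (0-based half-open; name and strand columns optional)."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[3] if len(parts) > 3 else f"{category}_{lineno}"
            strand = parts[5] if len(parts) > 5 else "."
            feats.append(Feature(name, parts[0], int(parts[1]), int(parts[2]), strand))
    return FeatureSet(category, feats)


def _build_trees(
    feature_sets: Sequence[FeatureSet], sequence_ids: set[str] | None
) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {}
    for fs in feature_sets:
        per_seq = trees.setdefault(fs.category, {})
        for f in fs.features:
            if sequence_ids is not None and f.seq_id not in sequence_ids:
                raise ValueError(
                    f"feature {f.feature_id} references unknown sequence {f.seq_id!r}"
                )
            per_seq.setdefault(f.seq_id, IntervalTree()).addi(f.start, f.end, f)
    return trees


def annotate_reads(
    genome_hits: Iterable[Hit],
    counts: Mapping[str, int],
    feature_sets: Sequence[FeatureSet],
    mode: str = "hierarchical",
    sequence_ids: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label genome-mapped reads by overlapping feature categories.

    Returns ``(per_read, category_counts)``.  ``per_read`` has one row per
    mapped read: its categories (comma-joined in non_exclusive mode, single
    label in hierarchical mode) and its redundant count.  ``category_counts``
    reports, per category, redundant and unique counts plus two published
    framings of "percent": of all genome-mapped reads and of reads that
    overlap at least one feature.
    """
    if mode not in ("non_exclusive", "hierarchical"):
        raise ValueError(f"unknown annotation mode {mode!r}")
    trees = _build_trees(feature_sets, sequence_ids)
    present = {fs.category for fs in feature_sets}

    per_read_cats: dict[str, set[str]] = {}
    for h in genome_hits:
        cats = per_read_cats.setdefault(h.query_id, set())
        for category, per_seq in trees.items():
            tree = per_seq.get(h.ref_id)
            if tree is None:
                continue
            for iv in tree.overlap(h.start, h.end):
                if STRAND_AWARE[category] and iv.data.strand in "+-" and iv.data.strand != h.strand:
                    continue
                cats.add(category)
                break

    rows = []
    for rid in sorted(per_read_cats):
        cats = per_read_cats[rid]
        if mode == "hierarchical":
            label = next((c for c in CATEGORY_PRIORITY if c in cats), "unannotated")
            labels = [label]
        else:
            labels = sorted(cats, key=CATEGORY_PRIORITY.index) or ["unannotated"]
        rows.append({
            "read": rid,
            "categories": ",".join(labels),
            "count": int(counts.get(rid, 1)),
        })
    per_read = pd.DataFrame(rows, columns=["read", "categories", "count"])

    total_mapped = int(per_read["count"].sum()) if len(per_read) else 0
    annotated = per_read[per_read["categories"] != "unannotated"] if len(per_read) else per_read
    total_annotated = int(annotated["count"].sum()) if len(per_read) else 0
    cat_rows = []
    for category in CATEGORY_PRIORITY + ["unannotated"]:
        if category != "unannotated" and category not in present:
            cat_rows.append({
                "category": category, "redundant": pd.NA, "unique": pd.NA,
                "pct_of_mapped": pd.NA, "pct_of_annotated": pd.NA,
            })
            continue
        if len(per_read):
            sel = per_read[per_read["categories"].str.split(",").apply(lambda ls: category in ls)]
        else:
            sel = per_read
        red = int(sel["count"].sum()) if len(sel) else 0
        cat_rows.append({
            "category": category,
            "redundant": red,
            "unique": len(sel),
            "pct_of_mapped": 100.0 * red / total_mapped if total_mapped else 0.0,
            "pct_of_annotated": (
                100.0 * red / total_annotated if (total_annotated and category != "unannotated") else 0.0
            ),
        })
    category_counts = pd.DataFrame(cat_rows)
    return per_read, category_counts


def weighted_trna_counts(
    trna_hits: Iterable[Hit], counts: Mapping[str, int]
) -> pd.DataFrame:
    """Placement-weighted abundance per mature tRNA reference.

    Each placement of a sequence contributes count / n_placements, where
    n_placements is the sequence's total number of placements across the
    whole mature set, so the summed weighted abundance equals the summed
    redundant count of every placed sequence (to 1e-6).
    """
    hits = list(trna_hits)
    placements: dict[str, int] = {}
    for h in hits:
        placements[h.query_id] = placements.get(h.query_id, 0) + 1
    per_ref: dict[str, float] = {}
    uniq: dict[str, int] = {}
    for h in hits:
        w = counts.get(h.query_id, 1) / placements[h.query_id]
        per_ref[h.ref_id] = per_ref.get(h.ref_id, 0.0) + w
        uniq[h.ref_id] = uniq.get(h.ref_id, 0) + 1
    df = pd.DataFrame(
        {
            "trna": sorted(per_ref),
            "weighted_count": [per_ref[k] for k in sorted(per_ref)],
            "n_placements": [uniq[k] for k in sorted(per_ref)],
        }
    )
    return df


def rrna_exclusion_mask(
    per_read: pd.DataFrame, policy: str = "all_rrna", k: int = 1
) -> set[str]:
    """Read ids to drop from global statistics because they are rRNA.

    ``all_rrna`` masks every rRNA-labelled read (the headline size-class
    figures exclude all rRNA); ``top_k_rrna`` masks only the k most
    abundant rRNA-labelled sequences (the narrower exclusion of single
    hyperabundant degradation products, k = 1 per library).
    """
    if policy not in ("all_rrna", "top_k_rrna"):
        raise ValueError(f"unknown rRNA exclusion policy {policy!r}")
    if not len(per_read):
        return set()
    is_rrna = per_read["categories"].str.split(",").apply(lambda ls: "rRNA" in ls)
    rrna = per_read[is_rrna]
    if policy == "all_rrna":
        return set(rrna["read"])
    top = rrna.sort_values(["count", "read"], ascending=[False, True]).head(k)
    return set(top["read"])


def hyperabundant_flags(
    counts: Mapping[str, int], threshold: float
) -> list[str]:
    """Sequences whose count exceeds threshold x library redundant total."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    total = sum(counts.values())
    return sorted(k for k, c in counts.items() if c > threshold * total)
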