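"""Fragment typing: anchors, cleavage sites, structural context, summaries."""

import numpy as np
import pandas as pd
import pytest

from tsrna.classify import (
    anchor_class,
    bulge_cleavage_fraction,
    classify_hits,
    cleavage_site,
    cleavage_summary,
    end_preference_summary,
    fragment_type,
    per_trna_profile,
    structural_context,
)
from tsrna.matcher import Hit


@pytest.mark.parametrize(
    "start,end,anchor",
    [(0, 34, "five_prime"), (40, 75, "three_prime"), (0, 75, "full_length"), (5, 40, "internal")],
)
def test_anchor_is_exact_offset_rule(start, end, anchor):
    assert anchor_class(start, end, 75) == anchor


def test_cleavage_site_convention():
    assert cleavage_site(0, 34, 75) == 33     # 3'-terminal nt of a 5' fragment
    assert cleavage_site(40, 75, 75) == 39    # nt immediately 5' of a 3' fragment
    assert cleavage_site(0, 75, 75) is None   # full-length: undefined
    assert cleavage_site(5, 40, 75) is None   # internal: undefined


def test_structural_context_lookup():
    assert structural_context(3, "((...))") == "loop_or_bulge"
    assert structural_context(1, "((...))") == "paired"
    # symmetric option also accepts an unpaired 3' neighbour
    assert structural_context(1, "((...))", symmetric=True) == "loop_or_bulge"
    assert structural_context(0, "((...))", symmetric=True) == "paired"
    with pytest.raises(ValueError, match="outside"):
        structural_context(7, "((...))")


def test_fragment_type_structural_rule_beats_length_window():
    span = (31, 38)
    assert fragment_type("five_prime", 35, span, 36) == "five_half"
    assert fragment_type("three_prime", 53, span, 20) == "tsRNA_3p"
    assert fragment_type("internal", None, span, 25) == "internal"
    assert fragment_type("full_length", None, span, 74) == "full"
    # a 20 nt five-prime read cut inside the loop is still a half
    assert fragment_type("five_prime", 33, span, 20) == "five_half"
    # end-anchored, outside loop and outside the window -> other_end
    assert fragment_type("five_prime", 29, span, 30) == "other_end"


def _mature(name="chr1.trna1"):
    from tsrna.catalog import MatureTRNA

    seq = "G" * 28 + "AAAGTCAAAA" + "C" * 33 + "CCA"
    struct = "(" * 28 + "." * 10 + ")" * 28 + "....." + "..."
    return MatureTRNA(name, "AspGTC", seq, struct, (28, 38))


def test_classify_hits_rows_and_na_fields():
    m = _mature()
    L = len(m.sequence)
    hits = [
        Hit("a_x3", m.name, 0, 34, "+"),
        Hit("b_x1", m.name, 10, 40, "+"),
        Hit("c_x2", m.name, 0, L, "+"),
    ]
    df = classify_hits(hits, {m.name: m}, {"a_x3": 3, "b_x1": 1, "c_x2": 2})
    by_read = df.set_index("read")
    assert by_read.loc["a_x3", "anchor"] == "five_prime"
    assert by_read.loc["a_x3", "cleavage_position"] == 33
    assert by_read.loc["a_x3", "fragment_type"] == "five_half"
    assert by_read.loc["b_x1", "anchor"] == "internal"
    assert by_read.loc["b_x1", "cleavage_context"] == "NA"
    assert by_read.loc["c_x2", "anchor"] == "full_length"
    assert by_read.loc["c_x2", "fragment_type"] == "full"


def test_antisense_trna_hit_is_rejected():
    m = _mature()
    with pytest.raises(ValueError, match="sense"):
        classify_hits([Hit("a", m.name, 0, 20, "-")], {m.name: m}, {"a": 1})


def test_anchor_partition_is_exhaustive(bundle, library, adapter):
    from tsrna.matcher import build_index, match_all
    from tsrna.preprocess import collapse_reads, trim_library

    kept, _ = trim_library((s for _, s in library.reads), adapter)
    collapsed = collapse_reads(kept)
    queries = {f"s{i}_x{c.count}": c.sequence for i, c in enumerate(collapsed)}
    counts = {rid: int(rid.rsplit("_x", 1)[1]) for rid in queries}
    matures = {m.name: m for m in bundle.matures}
    hits = match_all(build_index(queries), {n: m.sequence for n, m in matures.items()}, "sense_only")
    df = classify_hits(hits, matures, counts, sequences=queries)
    assert len(df) == len(hits)
    assert set(df.anchor) <= {"five_prime", "internal", "three_prime", "full_length"}
    per_anchor = df.groupby("anchor")["count"].sum().sum()
    assert per_anchor == df["count"].sum()


def test_profile_coverage_of_single_read():
    df = pd.DataFrame([{"start": 0, "end": 20, "count": 3, "length": 20, "sequence": "A" * 20, "read": "r"}])
    coverage, hist, top = per_trna_profile(df, 75)
    assert coverage[:20].tolist() == [3.0] * 20
    assert coverage[20:].sum() == 0
    assert hist == {20: 3}
    assert top == "A" * 20


def test_profile_conservation_identity():
    rng = np.random.default_rng(1)
    rows = []
    for i in range(40):
        s = int(rng.integers(0, 50))
        e = s + int(rng.integers(16, 25))
        rows.append({"start": s, "end": e, "count": int(rng.integers(1, 9)),
                     "length": e - s, "sequence": f"S{i}", "read": f"r{i}"})
    df = pd.DataFrame(rows)
    coverage, hist, _ = per_trna_profile(df, 80)
    assert coverage.sum() == (df["count"] * df["length"]).sum()
    assert sum(hist.values()) == df["count"].sum()


def test_empty_profile():
    coverage, hist, top = per_trna_profile(pd.DataFrame(columns=["start", "end", "count", "length", "sequence", "read"]), 74)
    assert coverage.sum() == 0 and hist == {} and top == ""


def test_profile_top_sequence_tie_breaks_lexicographically():
    df = pd.DataFrame([
        {"start": 0, "end": 4, "count": 5, "length": 4, "sequence": "TTTT", "read": "a"},
        {"start": 0, "end": 4, "count": 5, "length": 4, "sequence": "AAAA", "read": "b"},
    ])
    assert per_trna_profile(df, 10)[2] == "AAAA"


def test_end_preference_dominant_and_ties():
    def df_of(totals):
        return pd.DataFrame([
            {"anchor": a, "count": c, "cleavage_context": "NA"}
            for a, c in totals.items()
        ])

    assert end_preference_summary(df_of({"five_prime": 100, "internal": 10, "three_prime": 20}))["dominant"] == "five_prime"
    assert end_preference_summary(df_of({"internal": 10}))["dominant"] == "internal"
    assert end_preference_summary(df_of({"five_prime": 5, "three_prime": 5}))["dominant"] == "none"


def test_simulated_three_prime_biased_library_is_three_dominant(bundle, adapter):
    from tsrna.matcher import build_index, match_all
    from tsrna.preprocess import collapse_reads, trim_library
    from tsrna.synthetic import FragmentModel, simulate_library

    model = FragmentModel(class_mixture={"three_tsRNA": 0.8, "five_half": 0.2})
    lib = simulate_library(bundle, model, 600, adapter, seed=17)
    kept, _ = trim_library((s for _, s in lib.reads), adapter)
    collapsed = collapse_reads(kept)
    queries = {f"s{i}_x{c.count}": c.sequence for i, c in enumerate(collapsed)}
    counts = {rid: int(rid.rsplit("_x", 1)[1]) for rid in queries}
    matures = {m.name: m for m in bundle.matures}
    hits = match_all(build_index(queries), {n: m.sequence for n, m in matures.items()}, "sense_only")
    df = classify_hits(hits, matures, counts, sequences=queries)
    assert end_preference_summary(df)["dominant"] == "three_prime"


def test_bulge_fraction_by_hand():
    df = pd.DataFrame([
        {"anchor": "five_prime", "count": 1, "cleavage_context": "loop_or_bulge"},
        {"anchor": "five_prime", "count": 1, "cleavage_context": "loop_or_bulge"},
        {"anchor": "three_prime", "count": 1, "cleavage_context": "loop_or_bulge"},
        {"anchor": "three_prime", "count": 1, "cleavage_context": "paired"},
        {"anchor": "internal", "count": 99, "cleavage_context": "NA"},
    ])
    assert bulge_cleavage_fraction(df) == pytest.approx(75.0)


def test_bulge_fraction_empty_scope_is_na():
    df = pd.DataFrame([{"anchor": "internal", "count": 1, "cleavage_context": "NA"}])
    assert bulge_cleavage_fraction(df) is None


def test_doubling_counts_leaves_percentages_unchanged():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(30):
        anchor = rng.choice(["five_prime", "three_prime", "internal"])
        ctx = "NA" if anchor == "internal" else rng.choice(["loop_or_bulge", "paired"])
        rows.append({"anchor": anchor, "count": int(rng.integers(1, 20)),
                     "cleavage_context": ctx, "length": 20})
    df = pd.DataFrame(rows)
    doubled = df.assign(count=df["count"] * 2)
    assert bulge_cleavage_fraction(df) == pytest.approx(bulge_cleavage_fraction(doubled))
    a, b = cleavage_summary(df), cleavage_summary(doubled)
    assert a["bulge_fraction_weighted_pct"] == pytest.approx(b["bulge_fraction_weighted_pct"])
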