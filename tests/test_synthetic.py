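"""Simulator contracts: structures, reference files, and truth-table guarantees."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tsrna._seq import reverse_complement
from tsrna.synthetic import (
    ArmLengths,
    FragmentModel,
    ReferenceConfig,
    TRNAGeneSpec,
    build_reference_set,
    build_trna_gene,
    simulate_library,
    write_feature_gff3,
)

WOBBLE_OK = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def pair_map(structure: str) -> dict[int, int]:
    """Independent bracket-pairing scan (stack)."""
    stack, pairs = [], {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    assert not stack, "unbalanced structure"
    return pairs


def spec(**kw):
    defaults = dict(id="t", isotype="Asp", anticodon="GTC")
    defaults.update(kw)
    return TRNAGeneSpec(**defaults)


def test_same_spec_and_seed_reproduce_identical_gene():
    a = build_trna_gene(spec(), seed=7)
    b = build_trna_gene(spec(), seed=7)
    assert (a.sequence, a.structure) == (b.sequence, b.structure)


@given(
    st.integers(2, 9), st.integers(2, 6), st.integers(3, 10),
    st.integers(2, 7), st.integers(3, 9), st.integers(0, 6),
    st.integers(2, 7), st.integers(3, 9), st.integers(0, 2**31 - 1),
)
def test_structures_are_balanced_and_complementary(acc, ds, dl, acs, acl, vl, ts, tl, seed):
    arms = ArmLengths(acc, ds, dl, acs, acl, vl, ts, tl)
    g = build_trna_gene(spec(arms=arms), seed=seed)
    assert len(g.sequence) == len(g.structure) == arms.gene_length()
    pairs = pair_map(g.structure)
    for i, j in pairs.items():
        assert (g.sequence[i], g.sequence[j]) in WOBBLE_OK


def test_acceptor_stem_brackets_flank_the_gene_body():
    g = build_trna_gene(spec(arms=ArmLengths(acceptor_stem=4)), seed=3)
    assert g.structure[:4] == "(((("
    assert g.structure[-4:] == "))))"
    pairs = pair_map(g.structure)  # independent scan: the two flanks pair up
    n = len(g.structure)
    assert all(pairs[i] == n - 1 - i for i in range(4))


def test_degenerate_arm_lengths_are_rejected():
    with pytest.raises(ValueError, match="stem"):
        ArmLengths(acceptor_stem=1).validate()
    with pytest.raises(ValueError, match="loop"):
        ArmLengths(d_loop=2).validate()


def test_intron_must_lie_strictly_inside_the_gene_body():
    with pytest.raises(ValueError, match="intron"):
        spec(intron=(0, 10))
    g = build_trna_gene(spec(intron=(40, 12)), seed=1)
    assert len(g.sequence) == ArmLengths().gene_length() + 12
    pair_map(g.structure)  # still balanced: intron columns are unpaired


def test_anticodon_sits_inside_the_anticodon_loop():
    g = build_trna_gene(spec(anticodon="GTC"), seed=2)
    lo, hi = g.anticodon_loop_span
    assert g.sequence[g.anticodon_index:g.anticodon_index + 3] == "GTC"
    assert lo <= g.anticodon_index and g.anticodon_index + 3 <= hi


# ---------------------------------------------------------------------------
# reference set

def test_prediction_file_has_one_row_per_trna(bundle, tmp_path):
    from tsrna.catalog import write_trnascan_table

    write_trnascan_table(bundle.trna_genes, tmp_path / "t.tab")
    rows = [
        line for line in (tmp_path / "t.tab").read_text().splitlines()
        if line and not line.startswith(("Sequence", "Name", "--"))
    ]
    assert len(rows) == len(bundle.trna_genes) == 6


def test_embedded_genes_match_genome_slice(bundle):
    chrom = bundle.genome.sequences["chr1"]
    for g in bundle.trna_genes:
        sl = chrom[g.begin - 1:g.end]
        expected = sl if g.strand == "+" else reverse_complement(sl)
        assert expected == g.gene_sequence
    assert any(g.strand == "-" for g in bundle.trna_genes)


def test_zero_repeats_give_header_only_gff(tmp_path):
    b = build_reference_set(ReferenceConfig(genome_length=15_000, n_repeat=0), seed=4)
    write_feature_gff3(b.genome, "repeat", tmp_path / "r.gff3")
    assert (tmp_path / "r.gff3").read_text() == "##gff-version 3\n"


def test_overfull_genome_is_rejected():
    with pytest.raises(ValueError, match="genome_length"):
        build_reference_set(ReferenceConfig(genome_length=2_000, n_trna=10, n_rrna=4), seed=1)


# ---------------------------------------------------------------------------
# library simulation

def test_degenerate_mixture_yields_only_five_halves(bundle, adapter):
    model = FragmentModel(class_mixture={"five_half": 1.0})
    lib = simulate_library(bundle, model, n_reads=200, adapter=adapter, seed=9)
    assert len(lib.truth) == 200
    matures = {m.name: m for m in bundle.matures}
    for t in lib.truth.itertuples():
        assert t.intended_class == "five_half"
        lo, hi = matures[t.source_feature_id].anticodon_loop_span
        assert lo <= int(t.cleavage_position) < hi
        assert t.insert == matures[t.source_feature_id].sequence[: int(t.cleavage_position) + 1]


def test_same_seed_reproduces_identical_library(bundle, adapter, tmp_path):
    a = simulate_library(bundle, FragmentModel(), 150, adapter, seed=21)
    b = simulate_library(bundle, FragmentModel(), 150, adapter, seed=21)
    a.write_reads_fasta(tmp_path / "a.fasta")
    b.write_reads_fasta(tmp_path / "b.fasta")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
    assert a.truth.equals(b.truth)


def test_loop_cleavage_prob_one_puts_every_cut_at_an_unpaired_position(bundle, adapter):
    model = FragmentModel(loop_cleavage_prob=1.0)
    lib = simulate_library(bundle, model, 400, adapter, seed=2)
    matures = {m.name: m for m in bundle.matures}
    cut_rows = lib.truth[lib.truth.cleavage_context != ""]
    assert len(cut_rows) > 0
    for t in cut_rows.itertuples():
        assert t.cleavage_context == "loop"
        assert matures[t.source_feature_id].structure[int(t.cleavage_position)] == "."


def test_half_inserts_are_end_exact(bundle, adapter):
    model = FragmentModel(class_mixture={"five_half": 0.5, "three_half": 0.5})
    lib = simulate_library(bundle, model, 300, adapter, seed=6)
    matures = {m.name: m for m in bundle.matures}
    for t in lib.truth.itertuples():
        m = matures[t.source_feature_id]
        if t.intended_class == "five_half":
            assert m.sequence.startswith(t.insert)
        else:
            assert m.sequence.endswith(t.insert) and t.insert.endswith("CCA")


def test_every_trna_insert_exact_matches_its_source_mature(bundle, library):
    matures = {m.name: m for m in bundle.matures}
    trna = library.truth[library.truth.source_feature_id.str.contains("trna")]
    assert len(trna) > 0
    for t in trna.itertuples():
        assert t.insert in matures[t.source_feature_id].sequence


def test_class_counts_stay_within_multinomial_bounds_over_20_seeds(bundle, adapter):
    model = FragmentModel()
    n = 400
    probs = model.class_mixture
    for seed in range(20):
        lib = simulate_library(bundle, model, n, adapter, seed=seed)
        counts = lib.truth.intended_class.value_counts()
        for cls, p in probs.items():
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts.get(cls, 0) - n * p) <= 4 * sigma, (seed, cls)


def test_raw_reads_keep_at_least_six_adapter_nt(library, adapter):
    for (rid, raw), t in zip(library.reads, library.truth.itertuples()):
        assert raw.startswith(t.insert)
        tail = raw[len(t.insert):]
        assert tail.startswith(adapter[:6])


def test_short_adapter_and_bad_mixture_are_rejected(bundle):
    with pytest.raises(ValueError, match="adapter"):
        simulate_library(bundle, FragmentModel(), 10, "TCGTA", seed=0)
    with pytest.raises(ValueError, match="sums"):
        FragmentModel(class_mixture={"five_half": 0.5}).validate()
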