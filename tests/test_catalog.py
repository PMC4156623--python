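"""tRNA prediction parsing and maturation (intron out, CCA on, structure along)."""

import pytest

from tsrna._seq import reverse_complement
from tsrna.catalog import (
    TRNAGene,
    build_catalog,
    catalog_summary,
    mature_sequence,
    parse_trnascan,
    write_structure_file,
    write_trnascan_table,
)
from tsrna.synthetic import ArmLengths, TRNAGeneSpec, build_trna_gene


def gene_from_built(built, name="chr1.trna1", begin=101, strand="+"):
    end = begin + len(built.sequence) - 1
    if built.spec.intron is None:
        ib = ie = 0
    else:
        s, length = built.spec.intron
        if strand == "+":
            ib, ie = begin + s, begin + s + length - 1
        else:
            ib, ie = end - s, end - s - length + 1
    return TRNAGene(
        name=name, seq_id="chr1", begin=begin, end=end, strand=strand,
        isotype=built.spec.isotype, anticodon=built.spec.anticodon,
        intron_begin=ib, intron_end=ie, score=60.0,
        gene_sequence=built.sequence, gene_structure=built.structure,
    )


def test_intron_free_gene_matures_to_length_plus_three_ending_cca():
    built = build_trna_gene(TRNAGeneSpec("t", "Asp", "GTC"), seed=1)
    m = mature_sequence(gene_from_built(built))
    assert len(m.sequence) == len(built.sequence) + 3
    assert m.sequence.endswith("CCA")
    assert m.structure.endswith("...")


def test_ninety_nt_gene_with_18nt_intron_matures_to_75():
    # arms giving a 72 nt body + 18 nt intron = 90 nt gene
    arms = ArmLengths(d_loop=9)
    assert arms.gene_length() == 72
    built = build_trna_gene(TRNAGeneSpec("t", "Glu", "CTC", arms=arms, intron=(40, 18)), seed=2)
    assert len(built.sequence) == 90
    m = mature_sequence(gene_from_built(built))
    assert len(m.sequence) == 90 - 18 + 3 == 75


def test_mature_structure_is_gene_structure_with_intron_columns_deleted():
    built = build_trna_gene(TRNAGeneSpec("t", "His", "GTG", intron=(40, 12)), seed=3)
    m = mature_sequence(gene_from_built(built))
    s, length = built.spec.intron
    expected = built.structure[:s] + built.structure[s + length:] + "..."
    assert m.structure == expected


def test_intron_breaking_bracket_balance_is_an_error():
    built = build_trna_gene(TRNAGeneSpec("t", "Asp", "GTC"), seed=4)
    # claim an intron overlapping a paired stem column on one side only
    bad = gene_from_built(built)
    bad = TRNAGene(**{**bad.__dict__, "intron_begin": bad.begin + 1, "intron_end": bad.begin + 10})
    with pytest.raises(ValueError, match="balance|inside"):
        mature_sequence(bad)


def test_anticodon_loop_span_comes_from_the_structure(bundle):
    for g, m in zip(bundle.trna_genes, bundle.matures):
        lo, hi = m.anticodon_loop_span
        assert set(m.structure[lo:hi]) == {"."}
        assert g.anticodon in m.sequence[lo:hi]


def test_roundtrip_through_tabular_and_structure_files(bundle, tmp_path):
    write_trnascan_table(bundle.trna_genes, tmp_path / "t.tab")
    write_structure_file(bundle.trna_genes, tmp_path / "t.struct")
    parsed = parse_trnascan(tmp_path / "t.tab", tmp_path / "t.struct")
    assert len(parsed) == len(bundle.trna_genes)
    for orig, back in zip(bundle.trna_genes, parsed):
        for field in ("name", "begin", "end", "strand", "isotype", "anticodon",
                      "intron_begin", "intron_end", "gene_sequence", "gene_structure"):
            assert getattr(orig, field) == getattr(back, field), field


def test_minus_strand_rows_are_normalised_and_match_genome_revcomp(bundle, tmp_path):
    write_trnascan_table(bundle.trna_genes, tmp_path / "t.tab")
    write_structure_file(bundle.trna_genes, tmp_path / "t.struct")
    parsed = parse_trnascan(tmp_path / "t.tab", tmp_path / "t.struct")
    minus = [g for g in parsed if g.strand == "-"]
    assert minus, "fixture should contain minus-strand genes"
    chrom = bundle.genome.sequences["chr1"]
    for g in minus:
        assert g.begin < g.end
        assert reverse_complement(chrom[g.begin - 1:g.end]) == g.gene_sequence


def test_intron_sentinel_zero_zero_means_no_intron(bundle, tmp_path):
    write_trnascan_table(bundle.trna_genes, tmp_path / "t.tab")
    write_structure_file(bundle.trna_genes, tmp_path / "t.struct")
    for g in parse_trnascan(tmp_path / "t.tab", tmp_path / "t.struct"):
        if g.intron_begin == 0:
            assert g.local_intron() is None


def test_unparsable_coordinates_raise_with_line_number(tmp_path):
    (tmp_path / "bad.tab").write_text("chr1\t1\tXX\t50\tAsp\tGTC\t0\t0\t60.0\n")
    (tmp_path / "bad.struct").write_text(">chr1.trna1\nACGT\n....\n")
    with pytest.raises(ValueError, match="bad.tab:1"):
        parse_trnascan(tmp_path / "bad.tab", tmp_path / "bad.struct")


def test_missing_structure_record_raises(tmp_path):
    (tmp_path / "t.tab").write_text("chr1\t1\t10\t80\tAsp\tGTC\t0\t0\t60.0\n")
    (tmp_path / "t.struct").write_text("")
    with pytest.raises(ValueError, match="missing structure"):
        parse_trnascan(tmp_path / "t.tab", tmp_path / "t.struct")


def test_catalog_summary_counts_gene_copies():
    b1 = build_trna_gene(TRNAGeneSpec("a", "Asp", "GTC"), seed=1)
    b2 = build_trna_gene(TRNAGeneSpec("b", "Asp", "GTC"), seed=2)
    b3 = build_trna_gene(TRNAGeneSpec("c", "Glu", "CTC"), seed=3)
    matures = build_catalog([
        gene_from_built(b1, "chr1.trna1"),
        gene_from_built(b2, "chr1.trna2", begin=500),
        gene_from_built(b3, "chr1.trna3", begin=900),
    ])
    table = catalog_summary(matures)
    assert dict(zip(table.isoacceptor, table.gene_copies)) == {"AspGTC": 2, "GluCTC": 1}
    assert table.gene_copies.sum() == 3


def test_empty_catalog_summary_is_empty():
    assert catalog_summary([]).empty


def test_identical_mature_sequences_are_flagged_not_merged():
    b = build_trna_gene(TRNAGeneSpec("a", "Asp", "GTC"), seed=5)
    matures = build_catalog([
        gene_from_built(b, "chr1.trna1"),
        gene_from_built(b, "chr1.trna2", begin=700),
    ])
    assert len(matures) == 2
    assert matures[0].duplicate_of is None
    assert matures[1].duplicate_of == "chr1.trna1"


def test_every_mature_structure_is_balanced_and_colinear(bundle):
    for m in bundle.matures:
        assert len(m.sequence) == len(m.structure)
        depth = 0
        for ch in m.structure:
            depth += {"(": 1, ")": -1, ".": 0}[ch]
            assert depth >= 0
        assert depth == 0
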