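"""tRNA gene catalog: parse tRNAscan-SE-style predictions and build mature references.

A predicted tRNA gene becomes a mature reference by (i) excising the intron
the predictor labelled, (ii) appending the non-templated 3' CCA, and
(iii) carrying the dot-bracket secondary structure along positionally.  The
structure is never re-folded: intron columns are deleted from the structure
string and the CCA positions are appended as unpaired ('.').  Mature
references are what sRNA reads are mapped against with zero mismatches —
fragments of the processed transcript match the mature sequence exactly even
where they span the intron junction or the CCA, which the genome does not
contain.

Coordinate dialect: the tabular file is 1-based inclusive and encodes the
minus strand as begin > end; parsing normalises to begin < end plus an
explicit strand.  Intron fields of 0/0 mean "no intron".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TRNAGene",
    "MatureTRNA",
    "parse_trnascan",
    "mature_sequence",
    "build_catalog",
    "catalog_summary",
    "write_trnascan_table",
    "write_structure_file",
    "write_mature_fasta",
    "write_structure_sidecar",
]


@dataclass(frozen=True)
class TRNAGene:
    """One tRNAscan-SE prediction, coordinates normalised to begin < end."""

    name: str
    seq_id: str
    begin: int           # 1-based inclusive, genomic
    end: int
    strand: str
    isotype: str         # 3-letter amino-acid code
    anticodon: str       # DNA-space 3-mer
    intron_begin: int    # 1-based genomic, 0 = none
    intron_end: int
    score: float
    gene_sequence: str   # 5'->3' on the gene strand, intron included
    gene_structure: str  # dot-bracket aligned to gene_sequence

    def __post_init__(self):
        if (self.intron_begin == 0) != (self.intron_end == 0):
            raise ValueError(f"{self.name}: intron fields must both be 0 or both set")
        if len(self.gene_sequence) != len(self.gene_structure):
            raise ValueError(f"{self.name}: structure length != sequence length")

    def local_intron(self) -> tuple[int, int] | None:
        """Intron as (0-based start in gene coordinates, length), or None."""
        if self.intron_begin == 0:
            return None
        length = abs(self.intron_end - self.intron_begin) + 1
        if self.strand == "+":
            start = self.intron_begin - self.begin
        else:
            start = self.end - max(self.intron_begin, self.intron_end)
        return start, length


@dataclass
class MatureTRNA:
    """Intron-excised, CCA-appended tRNA reference with aligned structure."""

    name: str
    isoacceptor: str                  # isotype + anticodon, e.g. AspGTC
    sequence: str                     # ends with CCA
    structure: str                    # dot-bracket, CCA positions are '.'
    anticodon_loop_span: tuple[int, int]  # 0-based half-open, mature coords
    duplicate_of: str | None = None   # another catalog entry with identical sequence

    def __post_init__(self):
        if not self.sequence.endswith("CCA"):
            raise ValueError(f"{self.name}: mature sequence must end with CCA")
        if len(self.sequence) != len(self.structure):
            raise ValueError(f"{self.name}: structure/sequence length mismatch")
        _check_balanced(self.structure, self.name)
        lo, hi = self.anticodon_loop_span
        if not (0 <= lo < hi <= len(self.sequence)):
            raise ValueError(f"{self.name}: anticodon_loop_span out of bounds")


def _check_balanced(structure: str, name: str = "") -> None:
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"{name}: unbalanced dot-bracket structure")
        elif ch != ".":
            raise ValueError(f"{name}: illegal structure character {ch!r}")
    if depth != 0:
        raise ValueError(f"{name}: unbalanced dot-bracket structure")


# ---------------------------------------------------------------------------
# parsing

_TABLE_COLUMNS = 9  # name, trna#, begin, end, type, anticodon, intron begin/end, score


def parse_trnascan(table_path, structure_path) -> list[TRNAGene]:
    """Parse a tRNAscan-SE tabular file plus its structure file.

    The structure file holds one record per gene: a '>name' line, the gene
    sequence (intron included) and its dot-bracket line.  Every table row
    must have a structure record; coordinates that fail to parse raise with
    the offending line number.
    """
    structures = _read_structure_file(structure_path)
    genes: list[TRNAGene] = []
    with open(table_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("Sequence", "Name", "--")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < _TABLE_COLUMNS:
                raise ValueError(f"{table_path}:{lineno}: expected {_TABLE_COLUMNS} columns")
            seq_id, trna_num = parts[0].strip(), parts[1].strip()
            try:
                begin, end = int(parts[2]), int(parts[3])
                ib, ie = int(parts[6]), int(parts[7])
                score = float(parts[8])
            except ValueError as exc:
                raise ValueError(f"{table_path}:{lineno}: unparsable coordinates ({exc})") from None
            strand = "+"
            if begin > end:
                strand = "-"
                begin, end = end, begin
            name = f"{seq_id}.trna{trna_num}"
            if name not in structures:
                raise ValueError(f"missing structure record for {name}")
            seq, struct = structures[name]
            genes.append(
                TRNAGene(
                    name=name, seq_id=seq_id, begin=begin, end=end, strand=strand,
                    isotype=parts[4].strip(), anticodon=parts[5].strip().upper().replace("U", "T"),
                    intron_begin=ib, intron_end=ie, score=score,
                    gene_sequence=seq, gene_structure=struct,
                )
            )
    return genes


def _read_structure_file(path) -> dict[str, tuple[str, str]]:
    records: dict[str, tuple[str, str]] = {}
    name, lines = None, []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records[name] = _finish_structure_record(name, lines)
                name, lines = line[1:].strip(), []
            elif line.strip():
                lines.append(line.strip())
    if name is not None:
        records[name] = _finish_structure_record(name, lines)
    return records


def _finish_structure_record(name: str, lines: list[str]) -> tuple[str, str]:
    if len(lines) != 2:
        raise ValueError(f"structure record {name}: expected sequence and structure lines")
    seq, struct = lines[0].upper(), lines[1]
    if len(seq) != len(struct):
        raise ValueError(f"structure record {name}: sequence/structure length mismatch")
    return seq, struct


# ---------------------------------------------------------------------------
# maturation

def mature_sequence(gene: TRNAGene) -> MatureTRNA:
    """Excise the labelled intron, append CCA, and locate the anticodon loop.

    |mature| = |gene| - intron_length + 3.  The mature structure is the gene
    structure with intron columns deleted and '...' appended for the CCA; a
    deletion that breaks bracket balance is a malformed input and raises.
    """
    seq, struct = gene.gene_sequence, gene.gene_structure
    intron = gene.local_intron()
    if intron is not None:
        s, length = intron
        if not (0 < s and s + length < len(seq)):
            raise ValueError(f"{gene.name}: intron not strictly inside the gene body")
        seq = seq[:s] + seq[s + length:]
        struct = struct[:s] + struct[s + length:]
    try:
        _check_balanced(struct, gene.name)
    except ValueError:
        raise ValueError(f"{gene.name}: intron removal breaks structure balance") from None
    mature_seq = seq + "CCA"
    mature_struct = struct + "..."
    span = _anticodon_loop_span(mature_seq, mature_struct, gene.anticodon, gene.name)
    return MatureTRNA(
        name=gene.name,
        isoacceptor=gene.isotype + gene.anticodon,
        sequence=mature_seq,
        structure=mature_struct,
        anticodon_loop_span=span,
    )


def _anticodon_loop_span(seq: str, struct: str, anticodon: str, name: str) -> tuple[int, int]:
    """The maximal unpaired run containing the anticodon triplet.

    Among unpaired runs whose sequence contains the anticodon, the run whose
    centre is nearest the middle of the molecule wins (the anticodon loop is
    the central loop of the cloverleaf; a chance occurrence of the same
    3-mer in the D- or T-loop is farther from the centre).
    """
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(struct):
        if struct[i] == ".":
            j = i
            while j < len(struct) and struct[j] == ".":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    mid = len(seq) / 2
    candidates = [
        (lo, hi) for lo, hi in runs
        if hi - lo >= 3 and anticodon in seq[lo:hi]
    ]
    if not candidates:
        raise ValueError(f"{name}: anticodon {anticodon} not found in any unpaired loop")
    return min(candidates, key=lambda r: abs((r[0] + r[1]) / 2 - mid))


def build_catalog(genes: Iterable[TRNAGene]) -> list[MatureTRNA]:
    """Mature every gene and flag identical mature sequences from gene copies.

    Duplicates stay in the catalog as separate references (copy number is
    itself of interest); multi-mapping between them is handled downstream by
    placement-weighted counting.
    """
    matures = [mature_sequence(g) for g in genes]
    first_by_seq: dict[str, str] = {}
    for m in matures:
        if m.sequence in first_by_seq:
            m.duplicate_of = first_by_seq[m.sequence]
        else:
            first_by_seq[m.sequence] = m.name
    return matures


def catalog_summary(matures: Sequence[MatureTRNA]) -> pd.DataFrame:
    """Per-isoacceptor gene-copy counts; copies sum to the catalog size."""
    if not matures:
        return pd.DataFrame(columns=["isoacceptor", "gene_copies"])
    counts = pd.Series([m.isoacceptor for m in matures]).value_counts().sort_index()
    return pd.DataFrame({"isoacceptor": counts.index, "gene_copies": counts.values})


# ---------------------------------------------------------------------------
# writers

def write_trnascan_table(genes: Sequence[TRNAGene], path) -> None:
    """Write the tabular dialect (1-based; minus strand as begin > end)."""
    with open(path, "w") as fh:
        fh.write("Sequence\t\ttRNA\tBounds\t\ttRNA\tAnti\tIntron Bounds\tCove\n")
        fh.write("Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n")
        fh.write("--------\t------\t-----\t----\t----\t-----\t-----\t----\t-----\n")
        for g in genes:
            num = g.name.rsplit("trna", 1)[-1]
            b, e = (g.begin, g.end) if g.strand == "+" else (g.end, g.begin)
            ib, ie = g.intron_begin, g.intron_end
            fh.write(f"{g.seq_id}\t{num}\t{b}\t{e}\t{g.isotype}\t{g.anticodon}\t{ib}\t{ie}\t{g.score:.1f}\n")


def write_structure_file(genes: Sequence[TRNAGene], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.name}\n{g.gene_sequence}\n{g.gene_structure}\n")


def write_mature_fasta(matures: Sequence[MatureTRNA], path) -> None:
    with open(path, "w") as fh:
        for m in matures:
            fh.write(f">{m.name}|{m.isoacceptor}\n{m.sequence}\n")


def write_structure_sidecar(matures: Sequence[MatureTRNA], path) -> None:
    rows = [
        {
            "name": m.name,
            "isoacceptor": m.isoacceptor,
            "structure": m.structure,
            "loop_start1": m.anticodon_loop_span[0] + 1,
            "loop_end1": m.anticodon_loop_span[1],
            "duplicate_of": m.duplicate_of or "",
        }
        for m in matures
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
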