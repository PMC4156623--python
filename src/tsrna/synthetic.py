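"""Synthetic references and sRNA libraries with per-read ground truth.

Every downstream stage of the pipeline is exercised against libraries whose
origin is known exactly: cloverleaf tRNA genes with known dot-bracket
structures are embedded in a toy genome together with rRNA, repeat and
protein-coding gene intervals; reads are then drawn as

* tRNA halves — fragments running from a mature end to a cut in (or, with
  probability 1 - loop_cleavage_prob, just beside) the anticodon loop,
* tsRNAs — shorter end-anchored fragments cut in the D- or T-arm,
* internal tRNA fragments touching neither end,
* repeat-derived reads with a tunable 5'-uracil bias,
* an rRNA degradation background, optionally dominated by one
  hyperabundant sequence,

each ligated to a 3' adapter as sequenced.  The truth table records, per
read, the source feature, the intended class and (for end-anchored tRNA
fragments) the cut position and its structural context.

Cut convention, shared with the classifier: a cut sits between nucleotides
and is recorded as the mature-coordinate index of the nucleotide 5' of the
cut.  Sequences are DNA-space ({A,C,G,T}); there is no sequencing-error
model by default — a nonzero substitution rate deliberately breaks the
zero-mismatch recovery guarantee and is off unless asked for.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import reverse_complement
from .catalog import TRNAGene, MatureTRNA, build_catalog

__all__ = [
    "ArmLengths",
    "TRNAGeneSpec",
    "BuiltGene",
    "Feature",
    "SyntheticGenome",
    "ReferenceConfig",
    "ReferenceBundle",
    "FragmentModel",
    "SimulatedLibrary",
    "build_trna_gene",
    "build_reference_set",
    "simulate_library",
    "write_genome_fasta",
    "write_feature_gff3",
]

_BASES = np.array(list("ACGT"))
_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}

# (isotype, anticodon) pool for generated genes; includes the isoacceptors
# most productive of tRNA fragments in diatom libraries.
ISOACCEPTOR_POOL = [
    ("Asp", "GTC"), ("Glu", "CTC"), ("Glu", "TTC"), ("His", "GTG"),
    ("Gly", "GCC"), ("Lys", "CTT"), ("Pro", "AGG"), ("Ala", "AGC"),
    ("Val", "CAC"), ("Leu", "CAA"),
]


@dataclass(frozen=True)
class ArmLengths:
    """Stem/loop sizes of the cloverleaf, in nt.

    Defaults give the canonical compact tRNA: 7 bp acceptor stem, 4 bp D
    stem with 8 nt loop, 5 bp anticodon stem with 7 nt loop, 4 nt variable
    loop, 5 bp T stem with 7 nt loop — a 71 nt gene body, 74 nt mature.
    """

    acceptor_stem: int = 7
    d_stem: int = 4
    d_loop: int = 8
    anticodon_stem: int = 5
    anticodon_loop: int = 7
    variable_loop: int = 4
    t_stem: int = 5
    t_loop: int = 7

    def validate(self) -> None:
        stems = (self.acceptor_stem, self.d_stem, self.anticodon_stem, self.t_stem)
        loops = (self.d_loop, self.anticodon_loop, self.t_loop, self.variable_loop)
        if min(stems) < 2:
            raise ValueError("degenerate arm lengths: every stem needs >= 2 bp")
        if min(self.d_loop, self.anticodon_loop, self.t_loop) < 3:
            raise ValueError("degenerate arm lengths: every loop needs >= 3 nt")
        if self.variable_loop < 0:
            raise ValueError("variable loop length must be >= 0")

    def gene_length(self) -> int:
        return (
            2 * self.acceptor_stem + 2 + 2 * self.d_stem + self.d_loop + 1
            + 2 * self.anticodon_stem + self.anticodon_loop + self.variable_loop
            + 2 * self.t_stem + self.t_loop
        )


@dataclass(frozen=True)
class TRNAGeneSpec:
    """Blueprint for one synthetic tRNA gene."""

    id: str
    isotype: str
    anticodon: str
    arms: ArmLengths = ArmLengths()
    intron: tuple[int, int] | None = None  # (0-based start in intronless gene, length)

    def __post_init__(self):
        if len(self.anticodon) != 3 or not set(self.anticodon) <= set("ACGT"):
            raise ValueError(f"{self.id}: anticodon must be a 3-mer over ACGT")
        self.arms.validate()
        if self.intron is not None:
            s, length = self.intron
            if length < 1 or not (0 < s < self.arms.gene_length()):
                raise ValueError(f"{self.id}: intron must lie strictly inside the gene body")


@dataclass(frozen=True)
class BuiltGene:
    """A realised gene: sequence + structure, with the mature-view bookkeeping."""

    spec: TRNAGeneSpec
    sequence: str                    # with intron, if any
    structure: str                   # dot-bracket aligned to sequence
    anticodon_loop_span: tuple[int, int]  # mature (intronless) coordinates
    anticodon_index: int             # mature coordinate of anticodon first nt


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n else ""


def build_trna_gene(spec: TRNAGeneSpec, seed: int) -> BuiltGene:
    """Generate one cloverleaf tRNA gene deterministically from (spec, seed).

    Stems are Watson–Crick paired by construction (satisfying the WC-or-G·U
    pairing contract); loop identities are random except the anticodon,
    which sits centred in the anticodon loop.  The structure is emitted in
    dot-bracket notation, balanced, with intron columns unpaired so that
    positional intron excision preserves balance.  No thermodynamic folding
    is involved: the structure must be known exactly for truth labelling.
    """
    a = spec.arms
    rng = np.random.default_rng(seed)
    acc5 = _random_seq(rng, a.acceptor_stem)
    spacer1 = _random_seq(rng, 2)
    d5 = _random_seq(rng, a.d_stem)
    dloop = _random_seq(rng, a.d_loop)
    spacer2 = _random_seq(rng, 1)
    ac5 = _random_seq(rng, a.anticodon_stem)
    off = (a.anticodon_loop - 3) // 2
    acloop = (
        _random_seq(rng, off) + spec.anticodon
        + _random_seq(rng, a.anticodon_loop - 3 - off)
    )
    varloop = _random_seq(rng, a.variable_loop)
    t5 = _random_seq(rng, a.t_stem)
    tloop = _random_seq(rng, a.t_loop)

    def rc(s: str) -> str:
        return "".join(_WC[b] for b in reversed(s))

    seq = (
        acc5 + spacer1 + d5 + dloop + rc(d5) + spacer2
        + ac5 + acloop + rc(ac5) + varloop + t5 + tloop + rc(t5) + rc(acc5)
    )
    struct = (
        "(" * a.acceptor_stem + ".." + "(" * a.d_stem + "." * a.d_loop + ")" * a.d_stem + "."
        + "(" * a.anticodon_stem + "." * a.anticodon_loop + ")" * a.anticodon_stem
        + "." * a.variable_loop
        + "(" * a.t_stem + "." * a.t_loop + ")" * a.t_stem + ")" * a.acceptor_stem
    )
    loop_start = a.acceptor_stem + 2 + 2 * a.d_stem + a.d_loop + 1 + a.anticodon_stem
    span = (loop_start, loop_start + a.anticodon_loop)
    anticodon_index = loop_start + off
    if spec.intron is not None:
        s, length = spec.intron
        intron_seq = _random_seq(rng, length)
        seq = seq[:s] + intron_seq + seq[s:]
        struct = struct[:s] + "." * length + struct[s:]
    return BuiltGene(spec, seq, struct, span, anticodon_index)


# ---------------------------------------------------------------------------
# reference set

@dataclass(frozen=True)
class Feature:
    feature_id: str
    category: str        # tRNA | rRNA | repeat | gene
    seq_id: str
    start: int           # 0-based
    end: int             # exclusive
    strand: str


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    features: list[Feature]


@dataclass(frozen=True)
class ReferenceConfig:
    """Counts and sizes of the toy genome's features."""

    genome_length: int = 30_000
    n_trna: int = 6
    n_rrna: int = 2
    n_repeat: int = 3
    n_gene: int = 4
    rrna_length: int = 600
    repeat_length: int = 200
    gene_length: int = 400
    intron_prob: float = 0.4
    intron_length_range: tuple[int, int] = (11, 20)
    chrom: str = "chr1"
    min_gap: int = 20


@dataclass
class ReferenceBundle:
    """Everything build_reference_set knows: genome, genes, and mature views."""

    genome: SyntheticGenome
    built_genes: list[BuiltGene]
    trna_genes: list[TRNAGene]        # catalog-module view of the same genes
    matures: list[MatureTRNA]

    def features_by_category(self, category: str) -> list[Feature]:
        return [f for f in self.genome.features if f.category == category]


def build_reference_set(config: ReferenceConfig, seed: int) -> ReferenceBundle:
    """Build a toy genome with embedded tRNA/rRNA/repeat/gene features.

    Features are placed non-overlapping on a single chromosome with random
    gaps; strands are random.  Embedded tRNA gene sequences match the
    genome slice at their coordinates (reverse-complemented on the minus
    strand) — the invariant the tabular writers and parsers round-trip.
    Raises if the requested features cannot fit the genome length.
    """
    rng = np.random.default_rng(seed)
    built: list[BuiltGene] = []
    for i in range(config.n_trna):
        iso, anti = ISOACCEPTOR_POOL[int(rng.integers(len(ISOACCEPTOR_POOL)))]
        arms = ArmLengths()
        intron = None
        if rng.random() < config.intron_prob:
            length = int(rng.integers(*config.intron_length_range, endpoint=True))
            # canonical intron position: immediately 3' of the anticodon
            loop_start = arms.acceptor_stem + 2 + 2 * arms.d_stem + arms.d_loop + 1 + arms.anticodon_stem
            intron = (loop_start + (arms.anticodon_loop - 3) // 2 + 3, length)
        spec = TRNAGeneSpec(id=f"trna{i + 1}", isotype=iso, anticodon=anti, arms=arms, intron=intron)
        built.append(build_trna_gene(spec, seed=int(rng.integers(2**31))))

    pieces: list[tuple[str, str, str]] = []  # (category, feature_id, sequence on + strand of genome)
    strands: dict[str, str] = {}
    for i, bg in enumerate(built):
        strand = "+" if rng.random() < 0.5 else "-"
        strands[bg.spec.id] = strand
        emb = bg.sequence if strand == "+" else reverse_complement(bg.sequence)
        pieces.append(("tRNA", bg.spec.id, emb))
    for i in range(config.n_rrna):
        pieces.append(("rRNA", f"rrna{i + 1}", _random_seq(rng, config.rrna_length)))
        strands[f"rrna{i + 1}"] = "+" if rng.random() < 0.5 else "-"
    for i in range(config.n_repeat):
        pieces.append(("repeat", f"repeat{i + 1}", _random_seq(rng, config.repeat_length)))
        strands[f"repeat{i + 1}"] = "+"
    for i in range(config.n_gene):
        pieces.append(("gene", f"gene{i + 1}", _random_seq(rng, config.gene_length)))
        strands[f"gene{i + 1}"] = "+" if rng.random() < 0.5 else "-"

    order = rng.permutation(len(pieces))
    pieces = [pieces[i] for i in order]
    total = sum(len(p[2]) for p in pieces)
    slack = config.genome_length - total - config.min_gap * (len(pieces) + 1)
    if slack < 0:
        raise ValueError(
            f"requested features need more than genome_length={config.genome_length} nt"
        )
    extra = rng.multinomial(slack, np.full(len(pieces) + 1, 1 / (len(pieces) + 1)))
    gaps = [config.min_gap + int(e) for e in extra]

    chunks: list[str] = []
    features: list[Feature] = []
    pos = 0
    for (category, fid, emb), gap in zip(pieces, gaps[:-1]):
        chunks.append(_random_seq(rng, gap))
        pos += gap
        features.append(Feature(fid, category, config.chrom, pos, pos + len(emb), strands[fid]))
        chunks.append(emb)
        pos += len(emb)
    chunks.append(_random_seq(rng, gaps[-1]))
    genome_seq = "".join(chunks)
    genome = SyntheticGenome({config.chrom: genome_seq}, features)

    feature_by_id = {f.feature_id: f for f in features}
    trna_genes: list[TRNAGene] = []
    for num, bg in enumerate(built, start=1):
        f = feature_by_id[bg.spec.id]
        intron = bg.spec.intron
        if intron is None:
            ib = ie = 0
        else:
            s, length = intron
            if f.strand == "+":
                ib, ie = f.start + s + 1, f.start + s + length
            else:
                ib, ie = f.end - s, f.end - s - length + 1
        trna_genes.append(
            TRNAGene(
                name=f"{config.chrom}.trna{num}", seq_id=config.chrom,
                begin=f.start + 1, end=f.end, strand=f.strand,
                isotype=bg.spec.isotype, anticodon=bg.spec.anticodon,
                intron_begin=ib, intron_end=ie, score=float(np.round(50 + 50 * rng.random(), 1)),
                gene_sequence=bg.sequence, gene_structure=bg.structure,
            )
        )
    matures = build_catalog(trna_genes)
    return ReferenceBundle(genome, built, trna_genes, matures)


# ---------------------------------------------------------------------------
# library simulation

FRAGMENT_CLASSES = (
    "five_half", "three_half", "five_tsRNA", "three_tsRNA",
    "internal", "repeat_read", "rrna_background",
)


@dataclass
class FragmentModel:
    """Composition of the simulated library.

    The default mixture emulates a diatom-like small-RNA population: a mixed
    25–35 nt band dominated by tRNA fragments, a repeat-derived component
    with a 5'-uracil bias, and an rRNA degradation background.  Cuts are
    placed at unpaired positions with probability ``loop_cleavage_prob``
    (default 1.0: every cut in a loop, the canonical picture) and otherwise
    at a paired stem position flanking the same region.
    """

    class_mixture: dict[str, float] = field(default_factory=lambda: {
        "five_half": 0.25, "three_half": 0.05, "five_tsRNA": 0.10,
        "three_tsRNA": 0.20, "internal": 0.10, "repeat_read": 0.10,
        "rrna_background": 0.20,
    })
    loop_cleavage_prob: float = 1.0
    length_ranges: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "five_tsRNA": (16, 23), "three_tsRNA": (16, 23),
        "internal": (16, 30), "repeat_read": (26, 30),
        "rrna_background": (16, 35),
    })
    hyperabundant_rrna: tuple[str, int] | None = None
    trna_zipf_exponent: float = 1.0    # source-tRNA weight ~ 1/rank^a; 0 = uniform
    u_start_prob: float = 0.8          # 5'-T probability for repeat reads
    substitution_rate: float = 0.0     # breaks 0-mismatch recovery by design
    read_length: int | None = 42       # sequencing cycles; None = insert + full adapter

    def validate(self) -> None:
        unknown = set(self.class_mixture) - set(FRAGMENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown fragment classes: {sorted(unknown)}")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mixture sums to {total}, not 1")
        if any(p < 0 for p in self.class_mixture.values()):
            raise ValueError("class_mixture probabilities must be >= 0")
        for name, (lo, hi) in self.length_ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"length range for {name} must be positive and ordered")
        if not 0 <= self.loop_cleavage_prob <= 1:
            raise ValueError("loop_cleavage_prob must be in [0, 1]")


@dataclass
class SimulatedLibrary:
    reads: list[tuple[str, str]]   # (read_id, raw sequence with adapter)
    truth: pd.DataFrame
    adapter: str

    def write_reads_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f">{rid}\n{seq}\n")

    def write_truth_tsv(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _feature_sense_seq(genome: SyntheticGenome, f: Feature) -> str:
    s = genome.sequences[f.seq_id][f.start:f.end]
    return s if f.strand == "+" else reverse_complement(s)


def _pick_cut(rng, loop_positions, paired_positions, loop_prob) -> tuple[int, str]:
    use_loop = rng.random() < loop_prob
    if use_loop and loop_positions:
        return int(rng.choice(loop_positions)), "loop"
    if paired_positions:
        return int(rng.choice(paired_positions)), "paired"
    return int(rng.choice(loop_positions)), "loop"


def simulate_library(
    bundle: ReferenceBundle,
    model: FragmentModel,
    n_reads: int,
    adapter: str,
    seed: int,
) -> SimulatedLibrary:
    """Draw an adapter-ligated sRNA library with a per-read truth table.

    Per-read classes are a multinomial draw from ``model.class_mixture``.
    tRNA-derived inserts are exact substrings of their source mature tRNA;
    five/three halves start at mature position 0 / end at the final CCA
    position, respectively, with the cut in (or, at 1 - loop_cleavage_prob,
    beside) the anticodon loop.  The raw read is insert + adapter,
    right-truncated to ``model.read_length`` but never into the first 6
    adapter nt (the trimming rule's seed must survive).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt for the trimming rule")
    model.validate()
    rng = np.random.default_rng(seed)
    classes = [c for c in FRAGMENT_CLASSES if model.class_mixture.get(c, 0) > 0]
    probs = np.array([model.class_mixture[c] for c in classes])
    probs = probs / probs.sum()
    needs = {"five_half", "three_half", "five_tsRNA", "three_tsRNA", "internal"}
    if needs & set(classes) and not bundle.matures:
        raise ValueError("model draws tRNA fragments but the bundle has no tRNAs")
    if "repeat_read" in classes and not bundle.features_by_category("repeat"):
        raise ValueError("model draws repeat reads but the bundle has no repeats")
    if "rrna_background" in classes and not bundle.features_by_category("rRNA"):
        raise ValueError("model draws rRNA background but the bundle has no rRNAs")

    drawn = rng.choice(len(classes), size=n_reads, p=probs)
    # tRNA-fragment production is strongly non-uniform across tRNA types in
    # real libraries: weight source genes by a Zipf law over catalog order
    if bundle.matures:
        ranks = np.arange(1, len(bundle.matures) + 1, dtype=float)
        trna_w = ranks ** -model.trna_zipf_exponent
        trna_w /= trna_w.sum()
    repeats = bundle.features_by_category("repeat")
    rrnas = bundle.features_by_category("rRNA")
    hyper_left = model.hyperabundant_rrna[1] if model.hyperabundant_rrna else 0
    seed6 = adapter[:6].upper()
    if model.hyperabundant_rrna and (model.hyperabundant_rrna[0] + seed6).find(seed6) != len(model.hyperabundant_rrna[0]):
        raise ValueError("hyperabundant sequence would be truncated by the adapter 6-mer seed")

    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    for i, ci in enumerate(drawn):
        cls = classes[ci]
        rid = f"read{i + 1:06d}"
        # redraw inserts in which the adapter's 6-mer seed occurs before the
        # ligation junction (inside the insert, or spanning the junction):
        # the leftmost-occurrence trimming rule would truncate them, so the
        # junction must be the leftmost occurrence for the truth to hold
        for _attempt in range(50):
            cut = context = None
            source = ""
            if cls in needs:
                m = bundle.matures[int(rng.choice(len(bundle.matures), p=trna_w))]
                source = m.name
                insert, cut, context = _draw_trna_insert(rng, m, cls, model)
            elif cls == "repeat_read":
                f = repeats[int(rng.integers(len(repeats)))]
                source = f.feature_id
                insert = _draw_repeat_read(rng, bundle.genome, f, model)
            else:  # rrna_background
                f = rrnas[int(rng.integers(len(rrnas)))]
                source = f.feature_id
                if hyper_left > 0:
                    insert = model.hyperabundant_rrna[0]
                    break
                lo, hi = model.length_ranges["rrna_background"]
                seq = _feature_sense_seq(bundle.genome, f)
                length = int(rng.integers(lo, min(hi, len(seq)) + 1))
                s = int(rng.integers(0, len(seq) - length + 1))
                insert = seq[s:s + length]
            if (insert + seed6).find(seed6) == len(insert):
                break
        if cls == "rrna_background" and hyper_left > 0:
            hyper_left -= 1
        if model.substitution_rate > 0:
            insert = _mutate(rng, insert, model.substitution_rate)
        raw = insert + adapter
        if model.read_length is not None:
            raw = raw[: max(model.read_length, len(insert) + 6)]
        reads.append((rid, raw))
        truth_rows.append({
            "read_id": rid,
            "source_feature_id": source,
            "intended_class": cls,
            "cleavage_position": "" if cut is None else cut,
            "cleavage_context": "" if context is None else context,
            "insert": insert,
        })
    truth = pd.DataFrame(truth_rows)
    return SimulatedLibrary(reads, truth, adapter)


def _draw_trna_insert(rng, m: MatureTRNA, cls: str, model: FragmentModel):
    """Insert + (cut, context) for one tRNA-derived read class."""
    L = len(m.sequence)
    struct = m.structure
    lo_span, hi_span = m.anticodon_loop_span
    if cls in ("five_half", "three_half"):
        loop_pos = [p for p in range(lo_span, hi_span) if struct[p] == "."]
        flank = [lo_span - 2, lo_span - 1, hi_span, hi_span + 1]
        paired_pos = [p for p in flank if 0 <= p < L and struct[p] in "()"]
        cut, ctx = _pick_cut(rng, loop_pos, paired_pos, model.loop_cleavage_prob)
        insert = m.sequence[: cut + 1] if cls == "five_half" else m.sequence[cut + 1:]
        return insert, cut, ctx
    if cls in ("five_tsRNA", "three_tsRNA"):
        lo, hi = model.length_ranges[cls]
        if cls == "five_tsRNA":
            cand = [length - 1 for length in range(lo, hi + 1) if length < L]
        else:
            cand = [L - length - 1 for length in range(lo, hi + 1) if length < L]
        loop_pos = [c for c in cand if struct[c] == "."]
        paired_pos = [c for c in cand if struct[c] in "()"]
        cut, ctx = _pick_cut(rng, loop_pos, paired_pos, model.loop_cleavage_prob)
        insert = m.sequence[: cut + 1] if cls == "five_tsRNA" else m.sequence[cut + 1:]
        return insert, cut, ctx
    # internal: touch neither end, no recorded cut
    lo, hi = model.length_ranges["internal"]
    length = int(rng.integers(lo, min(hi, L - 2) + 1))
    s = int(rng.integers(1, L - length))
    return m.sequence[s:s + length], None, None


def _draw_repeat_read(rng, genome: SyntheticGenome, f: Feature, model: FragmentModel) -> str:
    lo, hi = model.length_ranges["repeat_read"]
    seq = genome.sequences[f.seq_id][f.start:f.end]
    length = int(rng.integers(lo, min(hi, len(seq)) + 1))
    starts = np.arange(len(seq) - length + 1)
    if rng.random() < model.u_start_prob:
        t_starts = [s for s in starts if seq[s] == "T"]
        if t_starts:
            return seq[(s := int(rng.choice(t_starts))):s + length]
    non_t = [s for s in starts if seq[s] != "T"] or list(starts)
    s = int(rng.choice(non_t))
    return seq[s:s + length]


def _mutate(rng, seq: str, rate: float) -> str:
    out = list(seq)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = str(rng.choice([x for x in "ACGT" if x != b]))
    return "".join(out)


# ---------------------------------------------------------------------------
# file writers

def write_genome_fasta(genome: SyntheticGenome, path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_feature_gff3(genome: SyntheticGenome, category: str, path) -> None:
    """GFF3 (1-based inclusive) for one feature category; header-only if empty."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in genome.features:
            if f.category != category:
                continue
            fh.write(
                f"{f.seq_id}\ttsrna_sim\t{f.category}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.feature_id}\n"
            )
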