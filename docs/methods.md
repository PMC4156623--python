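# Methods

## The problem

Small-RNA sequencing libraries from many eukaryotes — diatoms prominently
among them — are dominated not by canonical miRNAs/siRNAs but by fragments
of structural RNAs: rRNA degradation products, repeat-derived reads, and
above all tRNA-derived small RNAs. The latter fall into two classes defined
by where the parent tRNA was cleaved: **tRNA halves** (~30–40 nt), released
by a cut in the anticodon loop and running from a mature end to the cut, and
shorter **tsRNAs** (~16–23 nt), released by a cut in the D- or T-arm. Because
tRNAs fold into hairpins, these fragments are routinely mistaken for miRNAs
by prediction tools, so any sRNA survey needs to identify and characterise
them explicitly.

`tsrna` implements that characterisation as a reusable pipeline and — because
the defining property of the method is exactness (0-mismatch placement,
exact end anchoring) — validates every stage against a simulator whose
per-read ground truth is known.

## Pipeline model

1. **Adapter trimming.** The 3′ adapter is located by an exact match of its
   first 6 nt only; the insert is everything 5′ of the leftmost occurrence;
   reads without the 6-mer are discarded. Inserts are kept at 16–45 nt
   (configurable; the trimming rule itself fixes only the 6-mer).
2. **Collapsing.** Identical inserts become one record with a redundant
   count ("redundant" = read occurrences, "unique" = distinct sequences).
   Every later percentage is redundant-count-weighted unless suffixed
   `_unique`.
3. **Exact mapping.** An Aho–Corasick automaton over the collapsed
   sequences is streamed across each reference once, reporting *every*
   occurrence with no mismatches or gaps: the genome on both strands,
   mature tRNAs sense-only (fragments of a processed transcript exist only
   in sense orientation). Coordinates are 0-based half-open internally,
   1-based inclusive in exported tables. Reverse-complement-palindromic
   matches are reported once per strand, deliberately: the contract is
   "every occurrence on every requested strand", which a brute-force oracle
   can verify verbatim.
4. **Mature tRNA catalog.** tRNAscan-SE-style predictions (tabular +
   structure records) are normalised (minus strand encoded as begin > end),
   introns excised *positionally* from both sequence and dot-bracket
   structure (no refolding — the structure is a prediction-time annotation
   and must follow the sequence edit mechanically), and the non-templated
   CCA appended as three unpaired positions. Identical mature sequences
   from distinct gene copies stay as separate references, flagged, because
   copy number is itself reported; multi-mapping between them is resolved
   by weighted counting. The anticodon loop is located structurally: the
   unpaired run containing the anticodon whose centre is nearest the middle
   of the molecule (robust to arm-length variation; a chance anticodon
   3-mer in the D/T loop is off-centre).
5. **Annotation.** Genome-mapped reads are labelled by ≥1 bp overlap with
   rRNA / repeat / gene / other-ncRNA intervals and genomic tRNA loci.
   rRNA, tRNA and other-ncRNA overlap is sense-strand; repeats and genes
   are strand-blind. Two modes: non-exclusive (all overlapping categories)
   and hierarchical (rRNA > tRNA > repeat > gene > other_ncRNA >
   unannotated — an ordering the data themselves cannot fix, so both modes
   are emitted). Two percent denominators are reported side by side
   (of genome-mapped; of feature-annotated) because published per-feature
   fractions use both framings. tRNA membership is additionally determined
   by mapping to the mature references — CCA- and junction-spanning
   fragments never map to the genome, so locus overlap alone undercounts.
6. **Weighted counts.** A sequence placed k times across the mature set
   contributes count/k per placement; summed weighted abundance equals the
   summed count of placed sequences (asserted to 1e-6).
7. **Fragment classification.** Anchor by exact offsets (start = 0 →
   five_prime; end = |mature| → three_prime; both → full_length; else
   internal; tolerance 0 nt, a ±k option exists but defaults off). For
   end-anchored reads the cleavage site is the mature index of the
   nucleotide 5′ of the cut (five_prime read of length L → L−1;
   three_prime read starting at s → s−1); its context is the dot-bracket
   state at that single position ('.' → loop_or_bulge, else paired); a
   "symmetric" option also accepts an unpaired 3′ neighbour, to quantify
   sensitivity to the convention, which the data do not pin down. Typing
   puts the structural rule first: an end-anchored cut inside the anticodon
   loop is a half regardless of length; remaining end-anchored reads are
   tsRNAs if 16–23 nt, else `other_end`; length windows are reported, never
   override structure.
8. **Statistics.** Size-class distributions over genome-matched reads with
   rRNA excluded (all-rRNA by default; a top-k policy masks only the k most
   abundant rRNA sequences, k = 1, for the narrower
   hyperabundant-degradation-product exclusion), 5′-nucleotide composition
   per length (T printed as U), per-isoacceptor weighted abundance (summed
   over gene copies; absent → 0), and cross-sample Pearson correlation with
   p from the t-transform t = r·√((n−2)/(1−r²)), two-sided, df = n−2
   (|r| = 1 → p = 0); a seeded permutation p and a log10(x+1) transform are
   options, raw + t-transform the defaults (minimal assumptions).

## The simulator

`tsrna.synthetic` generates the full study scaffold:

* **Cloverleaf tRNA genes** from a fixed canonical template (7 bp acceptor
  stem; 4+8 D arm; 5+7 anticodon arm with the anticodon centred; 4 nt
  variable loop; 5+7 T arm; 71 nt body, 74 nt mature) with random loop
  identities and Watson–Crick-paired stems — no thermodynamic folding, so
  the dot-bracket truth is exact by construction. Optional introns
  (canonically just 3′ of the anticodon) are inserted as unpaired columns,
  so positional excision preserves bracket balance. The template carries no
  discriminator base: the gene body ends with the acceptor stem and CCA is
  added at maturation.
* **A toy genome** (default 30 kb, single chromosome) embedding the tRNA
  genes (either strand; reverse-complemented as placed), rRNA, repeat and
  gene intervals with random gaps, plus writers for FASTA, GFF3 and the
  tRNAscan-style tabular/structure files the catalog parser consumes.
* **Libraries** drawn per read from a class mixture (default: five_half
  0.25, three_half 0.05, five_tsRNA 0.10, three_tsRNA 0.20, internal 0.10,
  repeat_read 0.10, rrna_background 0.20 — a diatom-like population with a
  mixed 25–35 nt band dominated by tRNA fragments). Cuts fall between
  nucleotides; the recorded position is the nucleotide 5′ of the cut, the
  same convention the classifier uses. `loop_cleavage_prob` (default 1.0,
  the canonical all-loop picture) sends each cut to an unpaired position in
  the class's region — the anticodon loop for halves, the D/T-arm windows
  for tsRNAs — and with the complementary probability to a paired stem
  position flanking that region, for *all* end-anchored classes, so the
  realised loop fraction tracks the parameter. Source tRNAs are drawn with
  Zipf(1) weights over the catalog (real libraries are dominated by a few
  isoacceptors; exponent 0 restores uniform). Repeat reads start on a T
  with probability 0.8 (the repeat-derived 5′-U bias); rRNA background is
  uniform fragments of rRNA intervals, optionally preceded by a fixed
  hyperabundant sequence repeated a set number of times. Raw reads are
  insert + adapter, truncated to 42 cycles but never into the first 6
  adapter nt.

Truth records carry cleavage fields only for end-anchored tRNA classes:
internal fragments are not produced by a single annotated end-cut, and the
classifier likewise leaves their cleavage fields undefined.

One deliberate idealisation: an insert in which the adapter's 6-mer seed
occurs at or before the ligation junction is redrawn (re-picking the source),
so the leftmost-occurrence trimming rule recovers every insert exactly.
Real libraries contain such reads (~0.7% at 6 nt seeds) and lose them to
truncation; the simulator excludes this artifact class so that end-anchoring
recovery can be asserted exactly rather than approximately.

What the simulator does **not** emulate: sequencing errors and quality
scores (a substitution-rate parameter exists, default 0, and by design
breaks 0-mismatch recovery), chemical modifications that block reverse
transcription, ligation biases, isoacceptor-specific cleavage preferences,
and genome-scale repeat families. Passing tests therefore demonstrate the
pipeline's correctness on exact-substring data, not robustness to
base-calling noise — on real data the 0-mismatch contract itself already
discards erroneous reads, as in the original protocol.

## Validation and problem sizes

The suite validates the matcher against a brute-force sliding-window oracle
on 200 randomised instances (queries ≤ 40 nt, references up to 5 kb, both
strands), checks count conservation at every stage, and runs a 5,000-read
end-to-end recovery study (mixture five_half 0.4 / three_tsRNA 0.3 /
internal 0.2 / rRNA 0.1, loop_cleavage_prob 0.9, 6 tRNA genes in 30 kb):
anchor recovery is exact, the recovered loop-cleavage fraction sits within
3 percentage points of 90, and recovered anchor-group proportions stay
within 4σ multinomial bounds. Composition recovery is measured at the
anchor-group level (5′ / 3′ / internal) rather than per fragment type,
because with loop_cleavage_prob < 1 a stem-cut half is — correctly — typed
`other_end` by the structural rule, so per-type proportions intentionally
differ from the mixture while the anchor composition does not. These sizes
keep the full suite in the tens of seconds while leaving all binomial
tolerances far wider than sampling noise (σ ≈ 0.5 pp at n ≈ 3,500
end-anchored events).

## Numerical and degenerate-input choices

* Ties for a profile's top sequence break to the lexicographically smallest.
* The mixture must sum to 1 within 1e-9; weighted-count conservation is
  asserted at 1e-6 (float accumulation over thousands of terms).
* Empty scopes return explicit undefined signals: bulge fraction → None,
  correlation with n < 3 or zero variance → `CorrelationUndefined`.
* `r` is clamped to [−1, 1] after the product-moment division to guard
  against 1 + 1e-16 artifacts before the t-transform.
* Hierarchical category counts partition genome-mapped reads exactly and
  are asserted as such; categories whose interval file was not supplied are
  reported NA, not 0 — "no annotation available" and "nothing annotated"
  are different statements.

## Known limitations

* The matcher is a pure-Python automaton: linear-time, ample for desk-scale
  and test workloads, but not engineered for hundred-million-read libraries.
* Structure input is required; tRNAs whose predictor emitted no structure
  cannot enter cleavage-context analysis.
* The anticodon-loop locator assumes a cloverleaf-like central loop; exotic
  permuted or armless tRNAs would need explicit spans.
* Whether published loop-cleavage percentages are redundant-count-weighted
  or per unique sequence is not derivable from the outputs alone; both are
  emitted (`bulge_fraction_weighted_pct`, `bulge_fraction_unique_pct`).
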