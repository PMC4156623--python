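"""Stage-wise pipeline: simulate → trim → catalog → map → annotate → classify → report.

Each stage reads its inputs from, and writes its outputs into, one run
directory, so stages can be run individually from the CLI or chained by
:func:`run_pipeline`.  Given the same config and seed the whole run is
deterministic: every table is written in a fixed sort order and the JSON
manifest carries no timestamps, so repeated runs are byte-identical.

Config schema (YAML or dict)::

    simulate:                 # either this ...
      n_reads: 5000
      reference: {genome_length: 30000, n_trna: 6, ...}   # ReferenceConfig fields
      model: {class_mixture: {...}, loop_cleavage_prob: 1.0, ...}
    inputs:                   # ... or this
      reads: reads.fasta      # FASTA or FASTQ, adapter still attached
      genome: genome.fasta
      trnascan_table: trnascan.tab
      trnascan_structure: trnascan.struct
      features: {rRNA: rrna.gff3, repeat: repeat.gff3, gene: genes.gff3}
    params:
      adapter: TCGTATGCCGTCTTCTGCTTG
      min_len: 16
      max_len: 45
      annotation_mode: hierarchical      # or non_exclusive
      rrna_exclusion: all_rrna           # or top_k_rrna
      rrna_top_k: 1
      tsrna_window: [16, 23]
      symmetric_context: false
      plots: false
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from . import annotation as ann
from . import catalog as cat
from . import classify as cls
from . import preprocess as pre
from . import report as rep
from . import synthetic as syn
from .matcher import Hit, build_index, match_all, hits_to_table

__all__ = ["DEFAULT_PARAMS", "run_pipeline", "load_config"] + [
    f"stage_{s}" for s in ("simulate", "trim", "catalog", "map", "annotate", "classify", "report")
]

log = logging.getLogger("tsrna")

DEFAULT_PARAMS = {
    "adapter": "TCGTATGCCGTCTTCTGCTTG",  # Illumina small-RNA 3' adapter
    "min_len": 16,
    "max_len": 45,
    "annotation_mode": "hierarchical",
    "rrna_exclusion": "all_rrna",
    "rrna_top_k": 1,
    "tsrna_window": [16, 23],
    "symmetric_context": False,
    "plots": False,
}


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _params(config: Mapping) -> dict:
    p = dict(DEFAULT_PARAMS)
    p.update(config.get("params") or {})
    return p


def _inputs(config: Mapping, outdir: Path) -> dict:
    """Resolve stage input paths: simulated files in outdir, or user files."""
    if "simulate" in config:
        return {
            "reads": outdir / "simulated_reads.fasta",
            "genome": outdir / "genome.fasta",
            "trnascan_table": outdir / "trnascan.tab",
            "trnascan_structure": outdir / "trnascan.struct",
            "features": {
                "rRNA": outdir / "rrna.gff3",
                "repeat": outdir / "repeat.gff3",
                "gene": outdir / "genes.gff3",
            },
        }
    inp = dict(config.get("inputs") or {})
    for key in ("reads", "genome", "trnascan_table", "trnascan_structure"):
        if key not in inp:
            raise FileNotFoundError(f"pipeline stage inputs: missing required input {key!r}")
    inp["features"] = {k: Path(v) for k, v in (inp.get("features") or {}).items()}
    return inp


def _timed(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %-9s done in %.2fs", name, time.perf_counter() - t0)
            return out
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


@_timed("simulate")
def stage_simulate(config: Mapping, seed: int, outdir: Path) -> None:
    """Build the synthetic reference set and library; write all input files."""
    sim = config["simulate"]
    ref_cfg = syn.ReferenceConfig(**(sim.get("reference") or {}))
    model_kw = dict(sim.get("model") or {})
    if "length_ranges" in model_kw:
        model_kw["length_ranges"] = {
            k: tuple(v) for k, v in model_kw["length_ranges"].items()
        }
    if model_kw.get("hyperabundant_rrna"):
        model_kw["hyperabundant_rrna"] = tuple(model_kw["hyperabundant_rrna"])
    model = syn.FragmentModel(**model_kw)
    # reference_seed pins the reference set so several libraries (samples)
    # can be drawn from the same genome and tRNA catalog
    bundle = syn.build_reference_set(ref_cfg, seed=int(sim.get("reference_seed", seed)))
    if sim.get("hyperabundant_fraction"):
        # carve a hyperabundant sequence out of the first rRNA feature
        frac = float(sim["hyperabundant_fraction"])
        rr = bundle.features_by_category("rRNA")[0]
        seq = syn._feature_sense_seq(bundle.genome, rr)[100:130]
        model.hyperabundant_rrna = (seq, int(frac * int(sim.get("n_reads", 1000))))
    lib = syn.simulate_library(
        bundle, model, n_reads=int(sim.get("n_reads", 1000)),
        adapter=_params(config)["adapter"], seed=seed + 1,
    )
    syn.write_genome_fasta(bundle.genome, outdir / "genome.fasta")
    cat.write_trnascan_table(bundle.trna_genes, outdir / "trnascan.tab")
    cat.write_structure_file(bundle.trna_genes, outdir / "trnascan.struct")
    syn.write_feature_gff3(bundle.genome, "rRNA", outdir / "rrna.gff3")
    syn.write_feature_gff3(bundle.genome, "repeat", outdir / "repeat.gff3")
    syn.write_feature_gff3(bundle.genome, "gene", outdir / "genes.gff3")
    lib.write_reads_fasta(outdir / "simulated_reads.fasta")
    lib.write_truth_tsv(outdir / "truth.tsv")


@_timed("trim")
def stage_trim(config: Mapping, outdir: Path) -> None:
    """Adapter-trim, length-filter and collapse the raw reads."""
    p = _params(config)
    inp = _inputs(config, outdir)
    reads = pre.read_sequences(inp["reads"])
    kept, counters = pre.trim_library(reads, p["adapter"], p["min_len"], p["max_len"])
    collapsed = pre.collapse_reads(kept)
    pre.write_collapsed_fasta(collapsed, outdir / "collapsed.fasta")
    with open(outdir / "trim_counters.json", "w") as fh:
        json.dump(counters.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


@_timed("catalog")
def stage_catalog(config: Mapping, outdir: Path) -> None:
    """Parse tRNA predictions and emit the mature reference catalog."""
    inp = _inputs(config, outdir)
    genes = cat.parse_trnascan(inp["trnascan_table"], inp["trnascan_structure"])
    matures = cat.build_catalog(genes)
    cat.write_mature_fasta(matures, outdir / "mature_trnas.fasta")
    cat.write_structure_sidecar(matures, outdir / "mature_structures.tsv")
    cat.catalog_summary(matures).to_csv(outdir / "catalog_summary.tsv", sep="\t", index=False)


def _load_collapsed(outdir: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(outdir / "collapsed.fasta", "fasta")}


def _counts_from_ids(seqs: Mapping[str, str]) -> dict[str, int]:
    return {rid: int(rid.rsplit("_x", 1)[1]) for rid in seqs}


def load_matures(outdir: Path) -> dict[str, cat.MatureTRNA]:
    """Reload the mature catalog written by stage_catalog."""
    from Bio import SeqIO

    side = pd.read_csv(outdir / "mature_structures.tsv", sep="\t", keep_default_na=False)
    seqs = {
        rec.id.split("|")[0]: str(rec.seq)
        for rec in SeqIO.parse(outdir / "mature_trnas.fasta", "fasta")
    }
    matures = {}
    for row in side.itertuples():
        matures[row.name] = cat.MatureTRNA(
            name=row.name, isoacceptor=row.isoacceptor, sequence=seqs[row.name],
            structure=row.structure,
            anticodon_loop_span=(int(row.loop_start1) - 1, int(row.loop_end1)),
            duplicate_of=row.duplicate_of or None,
        )
    return matures


def _read_hits(path) -> list[Hit]:
    df = pd.read_csv(path, sep="\t")
    return [
        Hit(r.read, r.ref, int(r.start1) - 1, int(r.end1), r.strand)
        for r in df.itertuples()
    ]


@_timed("map")
def stage_map(config: Mapping, outdir: Path) -> None:
    """Exact 0-mismatch mapping: genome (both strands) and mature tRNAs (sense)."""
    from Bio import SeqIO

    inp = _inputs(config, outdir)
    seqs = _load_collapsed(outdir)
    counts = _counts_from_ids(seqs)
    index = build_index(seqs) if seqs else None
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(inp["genome"], "fasta")}
    matures = load_matures(outdir)
    genome_hits = match_all(index, genome, strands="both") if index else []
    trna_hits = (
        match_all(index, {m.name: m.sequence for m in matures.values()}, strands="sense_only")
        if index else []
    )
    hits_to_table(genome_hits, counts).to_csv(outdir / "genome_hits.tsv", sep="\t", index=False)
    hits_to_table(trna_hits, counts).to_csv(outdir / "trna_hits.tsv", sep="\t", index=False)


@_timed("annotate")
def stage_annotate(config: Mapping, outdir: Path) -> None:
    """Feature-category annotation and redundant/unique/weighted counting."""
    p = _params(config)
    inp = _inputs(config, outdir)
    seqs = _load_collapsed(outdir)
    counts = _counts_from_ids(seqs)
    genome_hits = _read_hits(outdir / "genome_hits.tsv")
    trna_hits = _read_hits(outdir / "trna_hits.tsv")

    feature_sets = []
    for category, path in inp["features"].items():
        if path is not None and Path(path).exists():
            feature_sets.append(ann.read_gff3(path, category))
    # tRNA annotation comes from mapping to mature references, but the
    # genomic tRNA loci are also included so locus overlap is reported
    genes = cat.parse_trnascan(inp["trnascan_table"], inp["trnascan_structure"])
    feature_sets.append(ann.FeatureSet("tRNA", [
        ann.Feature(g.name, g.seq_id, g.begin - 1, g.end, g.strand) for g in genes
    ]))

    per_read, category_counts = ann.annotate_reads(
        genome_hits, counts, feature_sets, mode=p["annotation_mode"]
    )
    # reads matching a mature tRNA, whether or not their genome placement
    # overlaps the locus (CCA- and junction-spanning fragments do not)
    mature_mapped = {h.query_id for h in trna_hits}
    per_read["maps_mature_trna"] = per_read["read"].isin(mature_mapped)
    per_read.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    category_counts.to_csv(outdir / "category_counts.tsv", sep="\t", index=False, na_rep="NA")
    ann.weighted_trna_counts(trna_hits, counts).to_csv(
        outdir / "weighted_trna_counts.tsv", sep="\t", index=False
    )


@_timed("classify")
def stage_classify(config: Mapping, outdir: Path) -> None:
    """Fragment classification against the mature catalog, with summaries."""
    p = _params(config)
    seqs = _load_collapsed(outdir)
    counts = _counts_from_ids(seqs)
    trna_hits = _read_hits(outdir / "trna_hits.tsv")
    matures = load_matures(outdir)
    annotations = cls.classify_hits(
        trna_hits, matures, counts, sequences=seqs,
        tsrna_window=tuple(p["tsrna_window"]), symmetric_context=p["symmetric_context"],
    )
    annotations.to_csv(outdir / "fragment_annotations.tsv", sep="\t", index=False)
    with open(outdir / "cleavage_summary.json", "w") as fh:
        json.dump(cls.cleavage_summary(annotations), fh, indent=2, sort_keys=True)
        fh.write("\n")
    profiles = outdir / "profiles"
    profiles.mkdir(exist_ok=True)
    for name, m in sorted(matures.items()):
        sub = annotations[annotations["trna"] == name]
        coverage, hist, top = cls.per_trna_profile(sub, len(m.sequence))
        pd.DataFrame({
            "position": range(len(coverage)),
            "coverage": coverage,
            "structure": list(m.structure),
        }).to_csv(profiles / f"{name}.coverage.tsv", sep="\t", index=False)
        with open(profiles / f"{name}.summary.json", "w") as fh:
            json.dump(
                {"size_histogram": hist, "top_sequence": top}, fh, indent=2, sort_keys=True
            )
            fh.write("\n")
        if p["plots"]:
            rep.plot_trna_profile(coverage, m.structure, name, profiles / f"{name}.png")


@_timed("report")
def stage_report(config: Mapping, outdir: Path) -> None:
    """Library-level distributions, bias and isoacceptor abundance tables."""
    p = _params(config)
    seqs = _load_collapsed(outdir)
    counts = _counts_from_ids(seqs)
    per_read = pd.read_csv(outdir / "annotation.tsv", sep="\t") if (outdir / "annotation.tsv").exists() else pd.DataFrame(columns=["read", "categories", "count"])
    # global distributions are over genome-matched reads only
    mapped = set(per_read["read"]) if len(per_read) else set()
    reads = {rid: (seq, counts[rid]) for rid, seq in seqs.items() if rid in mapped}
    mask = ann.rrna_exclusion_mask(per_read, policy=p["rrna_exclusion"], k=p["rrna_top_k"])
    dist = rep.size_class_distribution(reads, mask, scope="global_excl_rRNA")
    dist.to_csv(outdir / "size_distribution.tsv", sep="\t", index=False)
    rep.five_prime_bias(reads, mask).to_csv(outdir / "five_prime_bias.tsv", sep="\t", index=False)
    matures = load_matures(outdir)
    weighted = pd.read_csv(outdir / "weighted_trna_counts.tsv", sep="\t")
    abundance = rep.trna_type_abundance({"sample": weighted}, list(matures.values()))
    abundance.to_csv(outdir / "isoacceptor_abundance.tsv", sep="\t", index=False)
    if p["plots"]:
        rep.plot_size_distribution(dist, outdir / "size_distribution.png")


STAGES = {
    "trim": stage_trim,
    "catalog": stage_catalog,
    "map": stage_map,
    "annotate": stage_annotate,
    "classify": stage_classify,
    "report": stage_report,
}


def _display_path(path: Path, outdir: Path) -> str:
    """Input paths inside the run dir are recorded relative to it, so that
    identical runs in different directories produce identical manifests."""
    try:
        return str(path.resolve().relative_to(outdir.resolve()))
    except ValueError:
        return str(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping, seed: int, outdir) -> dict:
    """Run every stage in order and write a manifest; returns the manifest.

    Deterministic: identical config + seed produce byte-identical outputs.
    Missing inputs fail fast with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    if "simulate" in config:
        stage_simulate(config, seed, outdir)
    inp = _inputs(config, outdir)
    for name, stage in STAGES.items():
        try:
            stage(config, outdir)
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"pipeline stage {name!r}: {exc}") from exc
    input_files = [inp["reads"], inp["genome"], inp["trnascan_table"], inp["trnascan_structure"]]
    input_files += [p for p in inp["features"].values() if p is not None and Path(p).exists()]
    manifest = {
        "tool": "tsrna",
        "version": __version__,
        "seed": seed,
        "params": _params(config),
        "inputs": {_display_path(Path(p), outdir): _sha256(Path(p)) for p in input_files},
        "outputs": sorted(
            str(p.relative_to(outdir))
            for p in outdir.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
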