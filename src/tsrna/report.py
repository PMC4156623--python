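"""Library-level statistics: size classes, 5' nucleotide bias, isoacceptor abundance.

All proportions are redundant-count-weighted unless a table is explicitly
suffixed "_unique".  T is printed as U in user-facing composition tables;
sequences stay in DNA space internally.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .catalog import MatureTRNA

__all__ = [
    "size_class_distribution",
    "five_prime_bias",
    "trna_type_abundance",
    "cross_sample_correlation",
    "CorrelationUndefined",
    "plot_size_distribution",
    "plot_trna_profile",
]


class CorrelationUndefined(ValueError):
    """Raised when a correlation is not defined (n < 3 or zero variance)."""


def size_class_distribution(
    reads: Mapping[str, tuple[str, int]],
    mask: set[str] | None = None,
    scope: str = "global_excl_rRNA",
) -> pd.DataFrame:
    """Redundant counts and proportions per insert length, after masking.

    ``reads`` maps read_id -> (sequence, count); ``mask`` is a set of read
    ids to exclude (typically from rrna_exclusion_mask).  Proportions sum
    to 1 over the lengths present.
    """
    mask = mask or set()
    tally: dict[int, int] = {}
    for rid, (seq, count) in reads.items():
        if rid in mask:
            continue
        tally[len(seq)] = tally.get(len(seq), 0) + count
    total = sum(tally.values())
    rows = [
        {"length": n, "count": c, "proportion": c / total if total else 0.0, "scope": scope}
        for n, c in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["length", "count", "proportion", "scope"])


def five_prime_bias(
    reads: Mapping[str, tuple[str, int]], mask: set[str] | None = None
) -> pd.DataFrame:
    """Count-weighted 5'-most nucleotide composition per read length.

    Per-length proportions of A/C/G/U sum to 1 (T reported as U).
    """
    mask = mask or set()
    per_len: dict[int, dict[str, int]] = {}
    for rid, (seq, count) in reads.items():
        if rid in mask or not seq:
            continue
        comp = per_len.setdefault(len(seq), {"A": 0, "C": 0, "G": 0, "U": 0})
        base = seq[0].replace("T", "U")
        if base in comp:
            comp[base] += count
    rows = []
    for n in sorted(per_len):
        comp = per_len[n]
        total = sum(comp.values())
        row = {"length": n, "n_reads": total}
        for base in "ACGU":
            row[base] = comp[base] / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows, columns=["length", "n_reads", "A", "C", "G", "U"])


def trna_type_abundance(
    weighted_tables: Mapping[str, pd.DataFrame],
    matures: Sequence[MatureTRNA],
) -> pd.DataFrame:
    """Weighted abundance summed over gene copies of each isoacceptor.

    ``weighted_tables`` maps sample name -> weighted_trna_counts output.
    One row per isoacceptor present in any sample; an isoacceptor absent
    from a sample is 0, not missing.
    """
    iso_of = {m.name: m.isoacceptor for m in matures}
    samples = sorted(weighted_tables)
    per_iso: dict[str, dict[str, float]] = {}
    for sample in samples:
        table = weighted_tables[sample]
        for row in table.itertuples():
            iso = iso_of.get(row.trna, row.trna)
            per_iso.setdefault(iso, {})[sample] = per_iso.setdefault(iso, {}).get(sample, 0.0) + row.weighted_count
    rows = []
    for iso in sorted(per_iso):
        r = {"isoacceptor": iso}
        for sample in samples:
            r[sample] = per_iso[iso].get(sample, 0.0)
        rows.append(r)
    return pd.DataFrame(rows, columns=["isoacceptor"] + samples)


def cross_sample_correlation(
    x: Sequence[float],
    y: Sequence[float],
    log_transform: bool = False,
    permutation: int | None = None,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Pearson correlation with a two-sided p-value, returned as (r, p, n).

    r is the product-moment coefficient; the p-value comes from the
    t-transform t = r sqrt((n-2) / (1-r^2)) against a t distribution with
    n-2 degrees of freedom (|r| = 1 gives p = 0 by convention).  With
    ``permutation`` set, the p-value is instead the seeded permutation
    fraction of |r*| >= |r|.  An optional log10(x+1) transform is offered
    because raw abundances are heavy-tailed; the default is raw.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise CorrelationUndefined(f"need >= 3 shared points, got {n}")
    if log_transform:
        x, y = np.log10(x + 1), np.log10(y + 1)
    xd, yd = x - x.mean(), y - y.mean()
    denom = np.sqrt((xd ** 2).sum() * (yd ** 2).sum())
    if denom == 0:
        raise CorrelationUndefined("zero variance in one of the inputs")
    r = float((xd * yd).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if permutation is not None:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutation):
            yp = rng.permutation(y)
            yd2 = yp - yp.mean()
            rp = (xd * yd2).sum() / np.sqrt((xd ** 2).sum() * (yd2 ** 2).sum())
            if abs(rp) >= abs(r) - 1e-12:
                hits += 1
        return r, (hits + 1) / (permutation + 1), n
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sstats.t.sf(abs(t), df=n - 2))
    return r, p, n


# ---------------------------------------------------------------------------
# convenience plots (tables are the contract; plots are optional output)

def plot_size_distribution(dist: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(dist["length"], dist["proportion"], color="#4878a8")
    ax.set_xlabel("insert length (nt)")
    ax.set_ylabel("proportion of reads")
    scopes = dist["scope"].unique()
    ax.set_title(scopes[0] if len(scopes) else "")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trna_profile(coverage, structure: str, name: str, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.fill_between(range(len(coverage)), coverage, step="mid", color="#a84848")
    ax.set_xlabel("mature tRNA position (dot-bracket below)")
    ax.set_ylabel("read coverage")
    ax.set_title(name)
    ax.set_xticks(range(0, len(structure), 10))
    ax.text(0, -0.28, structure, transform=ax.get_xaxis_transform(),
            family="monospace", fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
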