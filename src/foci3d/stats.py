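"""Group summaries, exact Fisher tests and volume distributions.

The bespoke statistics of the pipeline (cluster positivity, nuclear
fractions, volume CDFs, the exact 2x2 Fisher test used for cluster-positive
proportions) are implemented here; omnibus group comparisons (ANOVA /
Kruskal-Wallis with multiple-comparison correction) are standard procedures
and are delegated to scipy/statsmodels behind a thin reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "cluster_positive_fraction",
    "fisher_exact_2x2",
    "volume_cdf",
    "group_compare",
    "summarize_group",
]

#: Cluster volume cut-off marked on CDF plots, um^3.
CLUSTER_CUTOFF_UM3 = 0.6


@dataclass
class GroupSummary:
    """Per-group aggregate over one channel's cell records."""

    label: str
    channel: str
    n_cells: int
    cluster_positive_fraction: float
    nuclear_fraction_median: float
    nuclear_fraction_q1: float
    nuclear_fraction_q3: float
    volumes_um3: np.ndarray  # per-object volumes, for CDFs


def cluster_positive_fraction(cells: pd.DataFrame, channel: str | None = None) -> float:
    """Fraction of cells carrying a nuclear cluster in the channel."""
    sub = cells if channel is None else cells[cells["channel"] == channel]
    if not len(sub):
        raise ValueError("no cell records for the requested channel")
    return float(sub["has_nuclear_cluster"].mean())


def _hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> Fraction:
    return Fraction(comb(r1, a) * comb(r2, c1 - a), comb(r1 + r2, c1))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact test by the probability-mass convention.

    Sums hypergeometric probabilities of all margin-fixed tables no more
    probable than the observed one (the convention of the usual statistical
    software for 2x2 tables).  Exact rational arithmetic for totals up to
    10 000; larger tables delegate to scipy.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integer counts")
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if n == 0:
        raise ValueError("all-zero table")
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    if n > 10_000:
        return float(sps.fisher_exact(t, alternative="two-sided")[1])
    observed = _hypergeom_pmf(int(t[0, 0]), r1, r2, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p = Fraction(0)
    for a in range(lo, hi + 1):
        pa = _hypergeom_pmf(a, r1, r2, c1)
        if pa <= observed:
            p += pa
    return float(min(p, Fraction(1)))


def volume_cdf(volumes) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF of object volumes.

    Returns ``(sorted values, fraction <= value)``; plotting code marks the
    0.6 um^3 cluster cut-off on top of the curve.
    """
    v = np.sort(np.asarray(volumes, dtype=float))
    if v.size == 0:
        raise ValueError("empty volume list")
    frac = np.arange(1, v.size + 1) / v.size
    return v, frac


def summarize_group(
    label: str,
    cells: pd.DataFrame,
    objects: pd.DataFrame,
    channel: str,
) -> GroupSummary:
    """Aggregate one group's cell and object tables for one channel."""
    sub = cells[cells["channel"] == channel]
    if not len(sub):
        raise ValueError(f"no cells for channel {channel!r}")
    nf = sub["nuclear_fraction"].dropna().to_numpy()
    q1, med, q3 = (
        np.percentile(nf, [25, 50, 75]) if nf.size else (np.nan, np.nan, np.nan)
    )
    vols = objects[objects["channel"] == channel]["volume_um3"].to_numpy()
    return GroupSummary(
        label=label,
        channel=channel,
        n_cells=int(len(sub)),
        cluster_positive_fraction=cluster_positive_fraction(sub),
        nuclear_fraction_median=float(med),
        nuclear_fraction_q1=float(q1),
        nuclear_fraction_q3=float(q3),
        volumes_um3=vols,
    )


def group_compare(groups: dict[str, np.ndarray], method: str = "kruskal") -> dict:
    """Compare >= 2 groups of per-cell values with a standard omnibus test.

    ``method``: "kruskal" (Kruskal-Wallis, rank-sum pairwise follow-ups) or
    "anova" (one-way ANOVA, t-test follow-ups); pairwise p-values are
    Bonferroni-corrected.  Returns a report dict with the test name,
    statistic, p-value and corrected pairwise comparisons.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    if method == "kruskal":
        stat, p = sps.kruskal(*arrays.values())
        pair_test = lambda a, b: sps.mannwhitneyu(a, b, alternative="two-sided")[1]
        name = "Kruskal-Wallis"
    elif method == "anova":
        stat, p = sps.f_oneway(*arrays.values())
        pair_test = lambda a, b: sps.ttest_ind(a, b)[1]
        name = "one-way ANOVA"
    else:
        raise ValueError(f"unknown method {method!r}")
    pairs = list(combinations(arrays, 2))
    raw = [float(pair_test(arrays[a], arrays[b])) for a, b in pairs]
    if raw:
        from statsmodels.stats.multitest import multipletests

        corrected = multipletests(raw, method="bonferroni")[1]
    else:
        corrected = []
    return {
        "test": name,
        "statistic": float(stat),
        "p_value": float(p),
        "correction": "bonferroni",
        "pairwise": [
            {"a": a, "b": b, "p_raw": pr, "p_corrected": float(pc)}
            for (a, b), pr, pc in zip(pairs, raw, corrected)
        ],
    }
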