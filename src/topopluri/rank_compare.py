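"""Design ranking, Top/Bottom-k hit calling, and group comparisons.

Designs are ranked by a pooled per-unit metric (Oct4+ cells, EdU+ cells or
total cells at 24 h); the k highest and k lowest become the TOP and BOTTOM
hit classes.  Hit groups are compared with flat-control wells by group
medians, median fold-changes and two-sided Wilcoxon rank-sum tests with the
conventional star annotation.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library_design import FLAT_CONTROL

HIT_TOP = "TOP"
HIT_BOTTOM = "BOTTOM"
HIT_NEITHER = "NEITHER"

DEFAULT_COMPARE_METRICS = (
    "n_cells_4h",
    "n_cells_24h",
    "n_oct4_pos",
    "n_edu_pos",
    "pct_oct4",
    "pct_edu",
    "n_clusters",
    "mean_cells_per_cluster",
)


def rank_designs(units: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Stable descending sort of the pooled per-design table by one metric;
    ties broken by ascending design_id.  Flat controls are excluded."""
    if metric not in units.columns:
        raise KeyError(f"metric {metric!r} not in unit summary columns")
    df = units[units["design_id"] != FLAT_CONTROL].copy()
    df = df.sort_values([metric, "design_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def call_hits(ranked: pd.DataFrame, k: int = 100) -> pd.DataFrame:
    """First k designs -> TOP, last k -> BOTTOM, the rest NEITHER."""
    n = len(ranked)
    if 2 * k > n:
        raise ValueError(f"cannot call {k} TOP + {k} BOTTOM hits from {n} designs")
    hit_class = np.full(n, HIT_NEITHER, dtype=object)
    hit_class[:k] = HIT_TOP
    hit_class[n - k :] = HIT_BOTTOM
    out = ranked[["design_id", "rank"]].copy()
    out["hit_class"] = hit_class
    return out


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        return np.nan
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def compare_groups(
    units: pd.DataFrame,
    hit_table: pd.DataFrame,
    flat_wells: pd.DataFrame,
    metrics: Sequence[str] = DEFAULT_COMPARE_METRICS,
) -> pd.DataFrame:
    """Per-metric statistics for TOP vs flat, BOTTOM vs flat and TOP vs BOTTOM.

    ``units`` are pooled per-design summaries, ``flat_wells`` are the per-well
    summaries of the flat-control wells (each readable flat well is one
    observation).  Fold-changes are ratios of medians; p-values are two-sided
    Wilcoxon rank-sum, not corrected for multiplicity; groups smaller than 3
    get a not-computable (NaN) p.
    """
    merged = units.merge(hit_table[["design_id", "hit_class"]], on="design_id", how="inner")
    groups = {
        HIT_TOP: merged[merged["hit_class"] == HIT_TOP],
        HIT_BOTTOM: merged[merged["hit_class"] == HIT_BOTTOM],
        "FLAT": flat_wells,
    }
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("all three groups (TOP, BOTTOM, FLAT) must be non-empty")
    comparisons = [(HIT_TOP, "FLAT"), (HIT_BOTTOM, "FLAT"), (HIT_TOP, HIT_BOTTOM)]
    rows = []
    for metric in metrics:
        for ga, gb in comparisons:
            a = groups[ga][metric].to_numpy(dtype=float)
            b = groups[gb][metric].to_numpy(dtype=float)
            med_a = float(np.nanmedian(a)) if len(a) else np.nan
            med_b = float(np.nanmedian(b)) if len(b) else np.nan
            fold = med_a / med_b if med_b not in (0.0,) and np.isfinite(med_b) else np.nan
            p = _ranksum_p(a, b)
            rows.append(
                {
                    "metric": metric,
                    "group_a": ga,
                    "group_b": gb,
                    "median_a": med_a,
                    "median_b": med_b,
                    "fold_change": fold,
                    "p_value": p,
                    "stars": significance_stars(p) if not np.isnan(p) else "na",
                }
            )
    return pd.DataFrame(rows)


DEFAULT_CORRELATION_PAIRS = (
    ("n_oct4_pos", "n_edu_pos"),
    ("n_oct4_pos", "n_cells_24h"),
)


def correlate_metrics(
    units: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_CORRELATION_PAIRS,
) -> pd.DataFrame:
    """Ordinary least-squares R^2 between per-design metric pairs."""
    df = units[units["design_id"] != FLAT_CONTROL]
    if len(df) < 3:
        raise ValueError("need at least 3 designs to correlate metrics")
    rows = []
    for x, y in pairs:
        sub = df[[x, y]].dropna()
        xv = sub[x].to_numpy(dtype=float)
        yv = sub[y].to_numpy(dtype=float)
        if len(sub) < 3 or xv.std() == 0 or yv.std() == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(xv, yv)[0, 1] ** 2)
        rows.append({"x": x, "y": y, "r2": r2, "n": len(sub)})
    return pd.DataFrame(rows)


def gate_cross_tab(cells: pd.DataFrame, gates: Mapping) -> tuple[pd.DataFrame, dict]:
    """Chip-pooled 2x2 contingency of gated Oct4 x EdU calls.

    Returns the count table (rows: Oct4-, Oct4+; columns: EdU-, EdU+) and the
    conditional fractions of interest.
    """
    from .quantify import apply_gates

    gated = apply_gates(cells, gates)
    o = gated["oct4_pos"].to_numpy()
    e = gated["edu_pos"].to_numpy()
    counts = pd.DataFrame(
        [
            [int((~o & ~e).sum()), int((~o & e).sum())],
            [int((o & ~e).sum()), int((o & e).sum())],
        ],
        index=pd.Index(["oct4_neg", "oct4_pos"], name="oct4"),
        columns=pd.Index(["edu_neg", "edu_pos"], name="edu"),
    )
    n_oct4 = counts.loc["oct4_pos"].sum()
    n_edu = counts["edu_pos"].sum()
    fractions = {
        "p_edu_neg_given_oct4_pos": counts.loc["oct4_pos", "edu_neg"] / n_oct4 if n_oct4 else np.nan,
        "p_edu_pos_given_oct4_pos": counts.loc["oct4_pos", "edu_pos"] / n_oct4 if n_oct4 else np.nan,
        "p_oct4_pos_given_edu_pos": counts.loc["oct4_pos", "edu_pos"] / n_edu if n_edu else np.nan,
    }
    return counts, {k: float(v) for k, v in fractions.items()}
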