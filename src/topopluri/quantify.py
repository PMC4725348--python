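"""Per-cell tables -> per-TopoUnit summaries.

Steps, in screen order: per-chip background reduction (5th-percentile
subtraction), per-chip 2.5-SD outlier removal, per-chip positive/negative
gating of each marker channel by a two-component mixture fit on log
intensity, single-linkage spatial cluster detection, per-well aggregation,
and replicate pooling across the 6 wells of a design (3 chips x 2
duplicates).  Unreadable wells are excluded from pooling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from ._base import BaseEstimator
from .library_design import FLAT_CONTROL, ChipLayout

DEFAULT_K_SD = 2.5
DEFAULT_LINKAGE_DIST = 25.0
GATED_CHANNELS = ("oct4", "edu")


def _channel_column(channel: str) -> str:
    return channel if channel.endswith("_int") else f"{channel}_int"


# ---------------------------------------------------------------------------
# Background and outliers
# ---------------------------------------------------------------------------

def reduce_background(
    cells: pd.DataFrame,
    channel: str,
    quantile: float = 0.05,
    by: str = "chip_id",
) -> pd.DataFrame:
    """Subtract the per-chip baseline (5th percentile) from a channel, clamp at 0."""
    col = _channel_column(channel)
    if col not in cells.columns:
        raise KeyError(f"channel column {col!r} not present")
    out = cells.copy()
    baseline = out.groupby(by)[col].transform(lambda v: v.quantile(quantile))
    for _, grp in out.groupby(by):
        if grp[col].nunique() <= 1:
            warnings.warn(
                f"channel {channel!r} has identical intensities within a {by} group; "
                "background reduction zeroes it"
            )
            break
    out[col] = np.maximum(out[col] - baseline, 0.0)
    return out


def remove_outliers(
    cells: pd.DataFrame,
    channel: str,
    k_sd: float = DEFAULT_K_SD,
    by: str = "chip_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop cells with |intensity - mean| > k_sd x SD, computed once per chip
    per channel (single pass, no iteration).  Zero SD removes nothing."""
    col = _channel_column(channel)
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to estimate an outlier cutoff")
    stats = cells.groupby(by)[col].agg(["mean", "std"])
    mean = cells[by].map(stats["mean"]).to_numpy()
    sd = cells[by].map(stats["std"]).fillna(0.0).to_numpy()
    with np.errstate(invalid="ignore"):
        is_outlier = np.abs(cells[col].to_numpy() - mean) > k_sd * sd
    is_outlier &= sd > 0
    return cells.loc[~is_outlier].copy(), cells.loc[is_outlier].copy()


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """Positive/negative threshold for one channel, intensity units."""

    channel: str
    threshold: float
    method: str  # "mixture" | "quantile"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("gate threshold must be > 0")


def _em_two_gaussian(
    v: np.ndarray, max_iter: int = 300, tol: float = 1e-9, sd_floor: float = 0.05
) -> dict:
    """Two-component 1-D Gaussian EM with deterministic quantile init."""
    v = np.asarray(v, dtype=float)
    mu = np.array([np.quantile(v, 0.25), np.quantile(v, 0.75)])
    sigma = np.array([max(v.std() / 2, sd_floor)] * 2)
    w = np.array([0.5, 0.5])
    ll_prev = -np.inf
    for _ in range(max_iter):
        log_dens = (
            -0.5 * ((v[:, None] - mu[None, :]) / sigma[None, :]) ** 2
            - np.log(sigma[None, :])
            - 0.5 * np.log(2 * np.pi)
            + np.log(w[None, :])
        )
        m = log_dens.max(axis=1, keepdims=True)
        dens = np.exp(log_dens - m)
        norm = dens.sum(axis=1, keepdims=True)
        resp = dens / norm
        ll = float((m.ravel() + np.log(norm.ravel())).sum())
        nk = resp.sum(axis=0)
        w = nk / v.size
        mu = (resp * v[:, None]).sum(axis=0) / nk
        sigma = np.sqrt(((resp * (v[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk))
        sigma = np.maximum(sigma, sd_floor)
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    order = np.argsort(mu)
    return {"mu": mu[order], "sigma": sigma[order], "w": w[order], "loglik": ll}


def _equal_posterior_threshold(fit: Mapping) -> float:
    """Log-scale point where the two weighted components are equally likely."""
    (m1, m2), (s1, s2), (w1, w2) = fit["mu"], fit["sigma"], fit["w"]
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = -2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m1**2 / s1**2 - m2**2 / s2**2 + 2.0 * np.log((s1 * w2) / (s2 * w1))
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            return float((m1 + m2) / 2)
        return float(-c / b)
    disc = b * b - 4 * a * c
    if disc < 0:
        return float((m1 + m2) / 2)
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots >= m1) & (roots <= m2)]
    if inside.size:
        return float(inside[0])
    return float((m1 + m2) / 2)


class MixtureGate(BaseEstimator):
    """Positive/negative gate from a two-component mixture on log intensity.

    Fits two Gaussians to ``log1p(intensity)`` and places the threshold at the
    equal-posterior point between the component means.  If the fit is
    degenerate (components too close or one nearly empty) the gate falls back
    to a fixed high quantile of the intensity distribution.

    Attributes (after fit): ``threshold_`` (intensity units), ``method_``,
    ``mixture_`` (component parameters on the log scale).
    """

    def __init__(
        self,
        min_separation: float = 1.0,
        min_weight: float = 0.02,
        fallback_quantile: float = 0.95,
    ):
        self.min_separation = min_separation
        self.min_weight = min_weight
        self.fallback_quantile = fallback_quantile

    def fit(self, intensities: np.ndarray, y=None) -> "MixtureGate":
        x = np.asarray(intensities, dtype=float)
        if x.size < 10:
            raise ValueError("need at least 10 cells to fit a gate")
        v = np.log1p(np.maximum(x, 0.0))
        fit = _em_two_gaussian(v)
        (m1, m2), (s1, s2), (w1, w2) = fit["mu"], fit["sigma"], fit["w"]
        sep = (m2 - m1) / np.sqrt((s1**2 + s2**2) / 2)
        self.mixture_ = fit
        if sep < self.min_separation or min(w1, w2) < self.min_weight:
            warnings.warn(
                "mixture fit degenerate (unimodal channel?); gate falls back to "
                f"the {self.fallback_quantile:.0%} intensity quantile"
            )
            self.threshold_ = float(np.quantile(x, self.fallback_quantile))
            self.method_ = "quantile"
        else:
            self.threshold_ = float(np.expm1(_equal_posterior_threshold(fit)))
            self.method_ = "mixture"
        return self

    def predict(self, intensities: np.ndarray) -> np.ndarray:
        return np.asarray(intensities, dtype=float) > self.threshold_


def fit_gate(cells: pd.DataFrame, channel: str, **gate_params) -> GateSpec:
    """Fit one gate on the supplied cells (callers group by chip)."""
    col = _channel_column(channel)
    gate = MixtureGate(**gate_params).fit(cells[col].to_numpy())
    return GateSpec(channel=channel, threshold=gate.threshold_, method=gate.method_)


def fit_gates(
    cells: pd.DataFrame,
    channels: Sequence[str] = GATED_CHANNELS,
    by: str = "chip_id",
    **gate_params,
) -> dict[tuple[int, str], GateSpec]:
    """Per-chip, per-channel gates: mapping (chip_id, channel) -> GateSpec."""
    gates = {}
    for chip, grp in cells.groupby(by):
        for ch in channels:
            gates[(int(chip), ch)] = fit_gate(grp, ch, **gate_params)
    return gates


def apply_gates(
    cells: pd.DataFrame, gates: Mapping[tuple[int, str], GateSpec]
) -> pd.DataFrame:
    """Add boolean ``<channel>_pos`` columns from the per-chip gates.

    Idempotent: re-applying the same gates reproduces the same calls.
    """
    out = cells.copy()
    channels = sorted({ch for (_, ch) in gates})
    for ch in channels:
        col = _channel_column(ch)
        thresholds = out["chip_id"].map({c: g.threshold for (c, ch2), g in gates.items() if ch2 == ch})
        out[f"{ch}_pos"] = out[col].to_numpy() > thresholds.to_numpy()
    return out


def gates_to_json(gates: Mapping[tuple[int, str], GateSpec]) -> str:
    return json.dumps(
        [{"chip_id": c, **asdict(g)} for (c, _), g in sorted(gates.items())], sort_keys=True
    )


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------

def detect_clusters(xy: np.ndarray, linkage_dist: float = DEFAULT_LINKAGE_DIST) -> np.ndarray:
    """Single-linkage connected components: two cells join iff their centroid
    distance is <= ``linkage_dist`` um.  Returns integer labels (first-seen
    order)."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n == 0:
        return np.zeros(0, dtype=int)
    pairs = cKDTree(xy).query_pairs(linkage_dist, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    # relabel by first occurrence for a deterministic, order-stable output
    _, first = np.unique(labels, return_index=True)
    remap = {labels[i]: rank for rank, i in enumerate(np.sort(first))}
    return np.array([remap[l] for l in labels], dtype=int)


def _well_key_offsets(cells: pd.DataFrame) -> np.ndarray:
    """Coordinates shifted so different wells can never link (wells are
    separated by >> linkage distances)."""
    key = (
        cells["chip_id"].to_numpy() * 10_000_000.0
        + cells["row"].to_numpy() * 100_000.0
        + cells["col"].to_numpy() * 1_000.0
    )
    return np.column_stack([cells["x"].to_numpy() + key, cells["y"].to_numpy()])


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

WELL_KEY = ["chip_id", "row", "col"]


def summarize_wells(
    cells: pd.DataFrame,
    gates: Mapping[tuple[int, str], GateSpec],
    layout: ChipLayout,
    unreadable: Iterable[tuple[int, int, int]] = (),
    linkage_dist: float = DEFAULT_LINKAGE_DIST,
) -> pd.DataFrame:
    """Per-well counts, percentages, medians and cluster statistics."""
    gated = apply_gates(cells, gates)
    chips = sorted(gated["chip_id"].unique())
    base = pd.concat(
        [layout.to_frame().assign(chip_id=c) for c in chips], ignore_index=True
    ).set_index(WELL_KEY)

    c4 = gated[gated["timepoint"] == 4]
    c24 = gated[gated["timepoint"] == 24].copy()

    base["n_cells_4h"] = c4.groupby(WELL_KEY).size()
    base["n_oct4_pos_4h"] = c4.groupby(WELL_KEY)["oct4_pos"].sum()
    base["n_cells_24h"] = c24.groupby(WELL_KEY).size()
    base["n_oct4_pos"] = c24.groupby(WELL_KEY)["oct4_pos"].sum()
    base["n_edu_pos"] = c24.groupby(WELL_KEY)["edu_pos"].sum()
    base["median_oct4_int"] = c24.groupby(WELL_KEY)["oct4_int"].median()

    if len(c24):
        labels = detect_clusters(_well_key_offsets(c24), linkage_dist)
        c24["_cluster"] = labels
        kc = c24.groupby(WELL_KEY)["_cluster"].nunique()
        base["n_clusters"] = kc
    else:
        base["n_clusters"] = np.nan

    count_cols = ["n_cells_4h", "n_oct4_pos_4h", "n_cells_24h", "n_oct4_pos", "n_edu_pos"]
    base[count_cols] = base[count_cols].fillna(0).astype(int)
    base["n_clusters"] = base["n_clusters"].fillna(0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        base["pct_oct4"] = np.where(
            base["n_cells_24h"] > 0, 100.0 * base["n_oct4_pos"] / base["n_cells_24h"], np.nan
        )
        base["pct_edu"] = np.where(
            base["n_cells_24h"] > 0, 100.0 * base["n_edu_pos"] / base["n_cells_24h"], np.nan
        )
        base["mean_cells_per_cluster"] = np.where(
            base["n_clusters"] > 0, base["n_cells_24h"] / base["n_clusters"], np.nan
        )

    flagged = set(tuple(int(v) for v in w) for w in unreadable)
    base = base.reset_index()
    base["unreadable"] = [
        (c, r, k) in flagged for c, r, k in zip(base["chip_id"], base["row"], base["col"])
    ]
    return base.sort_values(WELL_KEY).reset_index(drop=True)


METRIC_COLUMNS = [
    "n_cells_4h",
    "n_oct4_pos_4h",
    "n_cells_24h",
    "n_oct4_pos",
    "n_edu_pos",
    "pct_oct4",
    "pct_edu",
    "median_oct4_int",
    "n_clusters",
    "mean_cells_per_cluster",
]


def pool_units(wells: pd.DataFrame) -> pd.DataFrame:
    """Replicate pooling: mean of each per-well metric over the readable wells
    of a design.  A design with zero readable wells is emitted with NaN
    metrics and ``n_wells_used = 0``."""
    readable = wells[~wells["unreadable"]]
    pooled = readable.groupby("design_id")[METRIC_COLUMNS].mean()
    n_used = readable.groupby("design_id").size().rename("n_wells_used")
    all_ids = pd.Index(sorted(wells["design_id"].unique()), name="design_id")
    out = pooled.reindex(all_ids).join(n_used).reset_index()
    out["n_wells_used"] = out["n_wells_used"].fillna(0).astype(int)
    return out


def summarize_units(
    cells: pd.DataFrame,
    gates: Mapping[tuple[int, str], GateSpec],
    layout: ChipLayout,
    unreadable: Iterable[tuple[int, int, int]] = (),
    linkage_dist: float = DEFAULT_LINKAGE_DIST,
) -> pd.DataFrame:
    """Per-design pooled summaries (includes the flat-control pseudo-design)."""
    wells = summarize_wells(cells, gates, layout, unreadable, linkage_dist)
    return pool_units(wells)


def quantify_pipeline(
    cells: pd.DataFrame,
    layout: ChipLayout,
    unreadable: Iterable[tuple[int, int, int]] = (),
    channels: Sequence[str] = GATED_CHANNELS,
    k_sd: float = DEFAULT_K_SD,
    linkage_dist: float = DEFAULT_LINKAGE_DIST,
) -> dict:
    """Full quantification: background -> outliers -> gates -> summaries.

    Returns a dict with the filtered cells, fitted gates, per-well table and
    pooled per-design table.
    """
    work = cells
    for ch in channels:
        work = reduce_background(work, ch)
    removed_frames = []
    for ch in channels:
        work, removed = remove_outliers(work, ch, k_sd=k_sd)
        removed_frames.append(removed)
    gates = fit_gates(work, channels)
    wells = summarize_wells(work, gates, layout, unreadable, linkage_dist)
    units = pool_units(wells)
    return {
        "cells": work,
        "removed": pd.concat(removed_frames, ignore_index=True) if removed_frames else None,
        "gates": gates,
        "wells": wells,
        "units": units,
    }
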