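"""Synthetic high-content screen generator with a planted descriptor response.

Emulates the statistical structure of an iPSC TopoChip screen so every
downstream stage (quantification, ranking, modeling) is testable without any
raw data:

- 4 h: homogeneous Poisson seeding at ~100 cells/mm^2, single cells,
  descriptor-independent.
- 24 h: per-well Poisson counts scaled by a planted fold effect
  ``max_fold ** p_hit``, where ``p_hit`` is a logistic function of the
  design's standardized descriptors (pattern area, a wave-number band, FCP);
  cells are placed by a Neyman-Scott cluster process whose mean cluster size
  also grows with ``p_hit``.
- Per-cell classes: Oct4+ with probability interpolating between the non-hit
  and hit rates; EdU+ conditioned on Oct4 so that by default ~30% of Oct4+
  cells are EdU- and essentially all EdU+ cells are Oct4+.
- Intensities: class-conditional log-normal mixtures per channel plus
  additive normal background; rare multiplicative outliers.

Ground-truth columns (``truth_*``) are carried separately and are never read
by the analysis modules.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .library_design import (
    FLAT_CONTROL,
    GRID_SIDE,
    N_WELLS,
    WELL_PITCH_UM,
    ChipLayout,
)

CHANNELS = ("dapi", "oct4", "edu")

#: Well area in mm^2 (300 x 300 um).
WELL_AREA_MM2 = (WELL_PITCH_UM / 1000.0) ** 2

CELL_COLUMNS = [
    "chip_id",
    "row",
    "col",
    "design_id",
    "replicate",
    "timepoint",
    "x",
    "y",
    "dapi_int",
    "oct4_int",
    "edu_int",
    "truth_oct4",
    "truth_edu",
    "truth_cluster_id",
    "truth_outlier",
]


@dataclass
class ResponseModel:
    """Planted descriptor -> response mapping.

    ``p_hit = sigmoid(intercept + b_pa * z(pattern_area) + b_wn * z(WN) +
    b_fcp * z(fcp))`` with z-scores over the library's descriptor table.  The
    dominant (largest |coefficient|) descriptor is pattern area with a
    negative sign: small covered area favors pluripotency, high wave number
    and high FCP help, mirroring the importance ordering the screen is built
    to recover.  The defaults make the response near-threshold in pattern
    area -- the half-maximum sits around 60 um^2 on the default library, and
    designs well below/above it saturate to hit/non-hit -- so "hit" behaves
    as a class with the stated conditional Oct4/EdU rates rather than a
    continuum.
    """

    intercept: float = -10.6
    coef_pattern_area: float = -14.0
    coef_wn: float = 1.5
    coef_fcp: float = 0.75
    max_fold: float = 3.0
    p_oct4_given_hit: float = 0.85
    p_oct4_given_nonhit: float = 0.35
    p_edu_given_oct4: float = 0.70
    p_edu_given_oct4neg: float = 0.02
    wn_column: str = "WN0.2"

    def __post_init__(self) -> None:
        for name in (
            "p_oct4_given_hit",
            "p_oct4_given_nonhit",
            "p_edu_given_oct4",
            "p_edu_given_oct4neg",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.max_fold <= 0:
            raise ValueError("max_fold must be > 0")

    @classmethod
    def null(cls) -> "ResponseModel":
        """All descriptor coefficients zero: every design shares one response."""
        return cls(intercept=0.0, coef_pattern_area=0.0, coef_wn=0.0, coef_fcp=0.0)

    @property
    def dominant_descriptor(self) -> str:
        coefs = {
            "pattern_area": abs(self.coef_pattern_area),
            self.wn_column: abs(self.coef_wn),
            "fcp": abs(self.coef_fcp),
        }
        return max(coefs, key=coefs.get)


def _default_intensity() -> dict:
    # meanlog/sdlog of the class-conditional log-normal per channel
    return {
        "dapi": {"pos": [6.2146, 0.30], "neg": [6.2146, 0.30]},  # ~500 a.u., class-free
        "oct4": {"pos": [6.6846, 0.35], "neg": [4.7875, 0.35]},  # ~800 vs ~120 a.u.
        "edu": {"pos": [6.9078, 0.30], "neg": [4.3820, 0.45]},   # ~1000 vs ~80 a.u.
    }


@dataclass
class ScreenConfig:
    """Generator settings; the defaults are the study conditions."""

    seeding_density: float = 100.0       # cells/mm^2 at 4 h
    n_chips: int = 3
    base_count_24h: float = 12.0         # expected 24 h cells/well at fold 1
    background_level: float = 40.0       # additive background, intensity units
    background_sd: float = 8.0
    outlier_rate: float = 0.005          # per channel
    outlier_factor_lo: float = 5.0
    outlier_factor_hi: float = 10.0
    unreadable_rate: float = 18.0 / 1018.0
    cluster_spread_um: float = 10.0      # normal offspring spread at 24 h
    cluster_size_base: float = 2.0       # mean cells/cluster at p_hit = 0
    cluster_size_hit_bonus: float = 2.0  # extra mean cells/cluster at p_hit = 1
    oct4_rate_4h: float = 0.7            # Oct4+ fraction at seeding
    intensity: dict = field(default_factory=_default_intensity)

    def __post_init__(self) -> None:
        for name in ("outlier_rate", "unreadable_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_chips < 1:
            raise ValueError("n_chips must be >= 1")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ScreenConfig":
        return cls(**yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def planted_hit_probability(desc: pd.DataFrame, model: ResponseModel) -> pd.Series:
    """Per-design hit probability from the planted logistic formula.

    Descriptors are z-scored over the supplied table (population SD); a
    constant column contributes zero.  Indexed by design_id.
    """
    cols = ["pattern_area", model.wn_column, "fcp"]
    for c in cols:
        if c not in desc.columns:
            raise KeyError(f"descriptor table lacks required column {c!r}")
    coefs = np.array([model.coef_pattern_area, model.coef_wn, model.coef_fcp])
    X = desc[cols].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf
    z = (X - mu) / sd
    logit = model.intercept + z @ coefs
    return pd.Series(_sigmoid(logit), index=pd.Index(desc["design_id"], name="design_id"))


def ground_truth(layout: ChipLayout, model: ResponseModel, desc: pd.DataFrame) -> pd.DataFrame:
    """Exact planted probabilities per design on the chip (plus the flat row).

    Intended for the test suite: analysis modules never read it.
    """
    p_hit = planted_hit_probability(desc, model)
    placed = np.unique(layout.design_id)
    rows = []
    for did in placed:
        p = 0.0 if did == FLAT_CONTROL else float(p_hit.loc[did])
        p_oct4 = p * model.p_oct4_given_hit + (1 - p) * model.p_oct4_given_nonhit
        rows.append(
            {
                "design_id": int(did),
                "p_hit": p,
                "fold_24h": model.max_fold ** p,
                "p_oct4": p_oct4,
                "p_edu": p_oct4 * model.p_edu_given_oct4
                + (1 - p_oct4) * model.p_edu_given_oct4neg,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _draw_intensities(
    rng: np.random.Generator,
    config: ScreenConfig,
    truth_oct4: np.ndarray,
    truth_edu: np.ndarray,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    n = truth_oct4.size
    class_by_channel = {
        "dapi": np.ones(n, dtype=bool),
        "oct4": truth_oct4.astype(bool),
        "edu": truth_edu.astype(bool),
    }
    outlier_any = np.zeros(n, dtype=bool)
    out: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        pos = class_by_channel[ch]
        mlog_pos, slog_pos = config.intensity[ch]["pos"]
        mlog_neg, slog_neg = config.intensity[ch]["neg"]
        meanlog = np.where(pos, mlog_pos, mlog_neg)
        sdlog = np.where(pos, slog_pos, slog_neg)
        signal = rng.lognormal(mean=meanlog, sigma=sdlog)
        background = rng.normal(config.background_level, config.background_sd, size=n)
        values = np.maximum(signal + background, 0.0)
        is_outlier = rng.random(n) < config.outlier_rate
        factors = rng.uniform(config.outlier_factor_lo, config.outlier_factor_hi, size=n)
        values = np.where(is_outlier, values * factors, values)
        outlier_any |= is_outlier
        out[ch] = values
    return out, outlier_any


def simulate_chip(
    layout: ChipLayout,
    desc: pd.DataFrame,
    model: ResponseModel,
    config: ScreenConfig,
    seed,
    chip_id: int = 0,
) -> pd.DataFrame:
    """Per-cell table for one chip, both timepoints (4 h and 24 h)."""
    rng = np.random.default_rng(seed)
    wells = layout.to_frame()
    placed = set(np.unique(layout.design_id).tolist()) - {FLAT_CONTROL}
    missing = placed - set(desc["design_id"].tolist())
    if missing:
        raise KeyError(f"no descriptor row for design_id(s) {sorted(missing)[:5]}")
    p_hit = planted_hit_probability(desc, model)
    p_well = np.where(
        wells["design_id"].to_numpy() == FLAT_CONTROL,
        0.0,
        p_hit.reindex(wells["design_id"]).fillna(0.0).to_numpy(),
    )

    frames = []

    # ---- 4 h: homogeneous Poisson scatter, descriptor-independent --------
    lam4 = config.seeding_density * WELL_AREA_MM2
    counts4 = rng.poisson(lam4, size=N_WELLS)
    n4 = int(counts4.sum())
    well_idx4 = np.repeat(np.arange(N_WELLS), counts4)
    oct4_4 = rng.random(n4) < config.oct4_rate_4h
    edu_4 = np.where(
        oct4_4, rng.random(n4) < model.p_edu_given_oct4, rng.random(n4) < model.p_edu_given_oct4neg
    )
    xy4 = rng.uniform(0.0, WELL_PITCH_UM, size=(n4, 2))
    intens4, outlier4 = _draw_intensities(rng, config, oct4_4, edu_4)
    frames.append(
        (well_idx4, np.full(n4, 4), xy4, oct4_4, edu_4, np.full(n4, -1), outlier4, intens4)
    )

    # ---- 24 h: planted fold effect + Neyman-Scott clusters ---------------
    fold = model.max_fold ** p_well
    counts24 = rng.poisson(config.base_count_24h * fold)
    n24 = int(counts24.sum())
    mean_size = config.cluster_size_base + config.cluster_size_hit_bonus * p_well
    with np.errstate(divide="ignore", invalid="ignore"):
        extra = np.where(counts24 > 0, np.maximum(counts24 / mean_size - 1.0, 0.0), 0.0)
    k_clusters = np.where(counts24 > 0, 1 + rng.poisson(extra), 0)
    n_clusters_total = int(k_clusters.sum())
    centers = rng.uniform(0.0, WELL_PITCH_UM, size=(n_clusters_total, 2))
    cluster_offset = np.concatenate([[0], np.cumsum(k_clusters)[:-1]])
    well_idx24 = np.repeat(np.arange(N_WELLS), counts24)
    k_per_cell = np.repeat(k_clusters, counts24)
    choice = np.floor(rng.random(n24) * k_per_cell).astype(int)
    cluster_id = np.repeat(cluster_offset, counts24) + choice
    xy24 = centers[cluster_id] + rng.normal(0.0, config.cluster_spread_um, size=(n24, 2))
    xy24 = np.clip(xy24, 0.0, WELL_PITCH_UM)
    q_well = p_well * model.p_oct4_given_hit + (1 - p_well) * model.p_oct4_given_nonhit
    q_cell = np.repeat(q_well, counts24)
    oct4_24 = rng.random(n24) < q_cell
    edu_24 = np.where(
        oct4_24, rng.random(n24) < model.p_edu_given_oct4, rng.random(n24) < model.p_edu_given_oct4neg
    )
    intens24, outlier24 = _draw_intensities(rng, config, oct4_24, edu_24)
    frames.append((well_idx24, np.full(n24, 24), xy24, oct4_24, edu_24, cluster_id, outlier24, intens24))

    # ---- assemble ---------------------------------------------------------
    parts = []
    rows_grid = wells["row"].to_numpy()
    cols_grid = wells["col"].to_numpy()
    dids = wells["design_id"].to_numpy()
    reps = wells["replicate"].to_numpy()
    for well_idx, tp, xy, oct4, edu, clid, outl, intens in frames:
        parts.append(
            pd.DataFrame(
                {
                    "chip_id": np.full(well_idx.size, chip_id, dtype=int),
                    "row": rows_grid[well_idx],
                    "col": cols_grid[well_idx],
                    "design_id": dids[well_idx],
                    "replicate": reps[well_idx],
                    "timepoint": tp.astype(int),
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "dapi_int": intens["dapi"],
                    "oct4_int": intens["oct4"],
                    "edu_int": intens["edu"],
                    "truth_oct4": oct4.astype(bool),
                    "truth_edu": edu.astype(bool),
                    "truth_cluster_id": clid.astype(int),
                    "truth_outlier": outl.astype(bool),
                }
            )
        )
    cells = pd.concat(parts, ignore_index=True)
    return cells[CELL_COLUMNS]


def simulate_screen(
    layout: ChipLayout,
    desc: pd.DataFrame,
    model: ResponseModel,
    config: ScreenConfig,
    seed: int,
) -> pd.DataFrame:
    """All ``config.n_chips`` chips, each driven by an independent child seed."""
    children = np.random.SeedSequence(seed).spawn(config.n_chips)
    frames = [
        simulate_chip(layout, desc, model, config, np.random.default_rng(child), chip_id=i)
        for i, child in enumerate(children)
    ]
    return pd.concat(frames, ignore_index=True)


def mark_unreadable(
    cells: pd.DataFrame, layout: ChipLayout, rate: float, seed: int
) -> set[tuple[int, int, int]]:
    """Flag wells as unreadable uniformly at random at the given rate.

    Wells are the unique ``(chip_id, row, col)`` combinations observed in the
    cell table; both duplicates of a design may be flagged independently.
    Returns the set of flagged wells.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    wells = (
        cells[["chip_id", "row", "col"]]
        .drop_duplicates()
        .sort_values(["chip_id", "row", "col"])
        .to_numpy()
    )
    rng = np.random.default_rng(seed)
    flagged = rng.random(len(wells)) < rate
    return {tuple(int(v) for v in w) for w in wells[flagged]}
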