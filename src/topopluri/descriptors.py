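"""Per-design surface descriptors and descriptor-table decorrelation.

Descriptors quantify a feature's geometry from its binary mask and its
primitive list:

- **FCP** -- fraction of the bounding square covered by primitives
  (mask mean).
- **pattern area** -- FCP x feat_size^2, um^2; the absolute covered area.
- **wave-number bands (WN<q>)** -- the fraction of the mask's non-DC 2-D
  power spectrum lying in a radial spatial-frequency band centered at
  q cycles/um.  High WN at high q means fine-grained texture.
- **primitive statistics** -- counts per kind, total analytic primitive
  area, and mean size parameters.

Before modeling, near-collinear columns are removed with a greedy pairwise
r^2 filter (`decorrelate` / `CorrelationFilter`).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._base import BaseEstimator
from .library_design import FLAT_CONTROL, FeatureMask, TopographyDesign

DEFAULT_BAND_CENTERS = (0.2, 1.0)
DEFAULT_BANDWIDTH = 0.05


def band_column(center: float) -> str:
    """Column name for a wave-number band, e.g. 0.2 -> 'WN0.2', 1.0 -> 'WN1'."""
    return f"WN{center:g}"


def fcp(mask: FeatureMask) -> float:
    """Fraction of the feature covered by primitives: mean of the binary mask."""
    if mask.pixels.size == 0:
        raise ValueError("empty mask grid")
    return float(mask.pixels.mean())


def pattern_area(feat_size: float, fcp_value: float) -> float:
    """Covered area of one feature, um^2: feat_size^2 x FCP."""
    if not 0.0 <= fcp_value <= 1.0:
        raise ValueError("fcp must lie in [0, 1]")
    return float(feat_size) ** 2 * float(fcp_value)


def wave_numbers(
    mask: FeatureMask,
    band_centers: Sequence[float] = DEFAULT_BAND_CENTERS,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> dict[float, float]:
    """Radial spectral-energy fractions of the feature mask.

    The 2-D DFT power spectrum of the binary mask is computed on the
    unshifted periodic grid; the zero-frequency (DC) term and radial
    frequencies above the Nyquist limit ``1/(2*resolution)`` are excluded.
    Each band ``q`` collects the power at radial frequency in the half-open
    interval ``(q - bandwidth/2, q + bandwidth/2]`` (cycles/um), normalized
    by the total included power, so a set of bands partitioning the radial
    axis sums to 1.  A constant mask has no non-DC power and returns 0 for
    every band.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if any(q <= 0 for q in band_centers):
        raise ValueError("band centers must be > 0")
    px = mask.pixels.astype(float)
    n = px.shape[0]
    power = np.abs(np.fft.fft2(px)) ** 2
    freqs = np.fft.fftfreq(n, d=mask.resolution)  # cycles/um
    radial = np.hypot(freqs[:, None], freqs[None, :])
    nyquist = 1.0 / (2.0 * mask.resolution)
    included = (radial > 0) & (radial <= nyquist + 1e-12)
    total = power[included].sum()
    out: dict[float, float] = {}
    for q in band_centers:
        if total <= 0:
            out[float(q)] = 0.0
            continue
        lo, hi = q - bandwidth / 2.0, q + bandwidth / 2.0
        in_band = included & (radial > lo + 1e-12) & (radial <= hi + 1e-12)
        out[float(q)] = float(power[in_band].sum() / total)
    return out


_NUMERIC_COLUMNS = (
    "feat_size",
    "fcp",
    "pattern_area",
    "n_circles",
    "n_triangles",
    "n_lines",
    "total_primitive_area",
    "circle_diameter_mean",
    "triangle_shortest_side_mean",
    "line_length_mean",
)


def descriptor_row(
    design: TopographyDesign,
    mask: FeatureMask,
    band_centers: Sequence[float] = DEFAULT_BAND_CENTERS,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> dict:
    cover = fcp(mask)
    wn = wave_numbers(mask, band_centers, bandwidth)
    by_kind: dict[str, list] = {"circle": [], "triangle": [], "line": []}
    for p in design.primitives:
        by_kind[p.kind].append(p)
    row = {
        "design_id": design.design_id,
        "feat_size": design.feat_size,
        "fcp": cover,
        "pattern_area": pattern_area(design.feat_size, cover),
        "n_circles": len(by_kind["circle"]),
        "n_triangles": len(by_kind["triangle"]),
        "n_lines": len(by_kind["line"]),
        "total_primitive_area": sum(p.area() for p in design.primitives),
        "circle_diameter_mean": (
            float(np.mean([p.size_params[0] for p in by_kind["circle"]])) if by_kind["circle"] else 0.0
        ),
        "triangle_shortest_side_mean": (
            float(np.mean([p.size_params[0] for p in by_kind["triangle"]])) if by_kind["triangle"] else 0.0
        ),
        "line_length_mean": (
            float(np.mean([p.size_params[0] for p in by_kind["line"]])) if by_kind["line"] else 0.0
        ),
    }
    for q, val in wn.items():
        row[band_column(q)] = val
    return row


def flat_descriptor_row(
    band_centers: Sequence[float] = DEFAULT_BAND_CENTERS, design_id: int = FLAT_CONTROL
) -> dict:
    """Structural-zeros descriptor row for a flat-control surface."""
    row = {"design_id": design_id}
    row.update({c: 0.0 for c in _NUMERIC_COLUMNS})
    row.update({band_column(q): 0.0 for q in band_centers})
    return row


def descriptor_table(
    designs: Sequence[TopographyDesign],
    masks: Mapping[int, FeatureMask] | Sequence[FeatureMask],
    band_centers: Sequence[float] = DEFAULT_BAND_CENTERS,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> pd.DataFrame:
    """One descriptor row per design; ``masks`` maps design_id -> mask (or is
    a sequence parallel to ``designs``)."""
    if not isinstance(masks, Mapping):
        masks = {d.design_id: m for d, m in zip(designs, masks)}
    rows = []
    for design in designs:
        if design.design_id not in masks:
            raise KeyError(f"no mask provided for design_id {design.design_id}")
        rows.append(descriptor_row(design, masks[design.design_id], band_centers, bandwidth))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decorrelation
# ---------------------------------------------------------------------------

def decorrelate(
    table: pd.DataFrame,
    r2_threshold: float = 0.75,
    exclude: Sequence[str] = ("design_id",),
) -> tuple[list[str], pd.DataFrame]:
    """Greedy sequential decorrelation of the numeric descriptor columns.

    Columns are visited in table order -- which for descriptor tables puts
    the field's primary descriptors (feat_size, FCP, pattern area) before
    derived primitive statistics -- and a column is retained iff its squared
    Pearson correlation with every already-retained column stays at or below
    the threshold; otherwise it is dropped, recording the retained partner
    that triggered removal.  The rule is deterministic and independent of
    column units/scales.  Constant columns cannot be correlated and are
    dropped up front with a warning.

    Returns ``(retained_columns, dropped)`` where ``dropped`` records each
    removed column, the partner that triggered removal, and their r^2.
    """
    numeric = [
        c
        for c in table.columns
        if c not in exclude and pd.api.types.is_numeric_dtype(table[c])
    ]
    if len(numeric) < 2:
        raise ValueError("need at least 2 numeric columns to decorrelate")
    dropped_records = []
    cols = []
    for c in numeric:
        if table[c].nunique(dropna=False) <= 1:
            warnings.warn(f"column {c!r} is constant; excluded from correlation filtering")
            dropped_records.append({"column": c, "partner": None, "r2": np.nan, "reason": "constant"})
        else:
            cols.append(c)
    corr2 = (table[cols].corr() ** 2).to_numpy()
    retained_idx: list[int] = []
    for j in range(len(cols)):
        offender = next(
            (i for i in retained_idx if corr2[i, j] > r2_threshold), None
        )
        if offender is None:
            retained_idx.append(j)
        else:
            dropped_records.append(
                {
                    "column": cols[j],
                    "partner": cols[offender],
                    "r2": float(corr2[offender, j]),
                    "reason": "correlated",
                }
            )
    retained = [cols[i] for i in retained_idx]
    dropped = pd.DataFrame(dropped_records, columns=["column", "partner", "r2", "reason"])
    return retained, dropped


class CorrelationFilter(BaseEstimator):
    """Transformer dropping near-collinear descriptor columns (pairwise r^2).

    Parameters
    ----------
    r2_threshold : float, default 0.75
        Maximum allowed squared Pearson correlation between retained columns.
    exclude : sequence of str
        Identifier columns ignored by the filter and passed through untouched
        by :meth:`transform` when present.
    """

    def __init__(self, r2_threshold: float = 0.75, exclude: Sequence[str] = ("design_id",)):
        self.r2_threshold = r2_threshold
        self.exclude = exclude

    def fit(self, X: pd.DataFrame, y=None) -> "CorrelationFilter":
        retained, dropped = decorrelate(X, self.r2_threshold, self.exclude)
        self.retained_ = retained
        self.dropped_ = dropped
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        passthrough = [c for c in self.exclude if c in X.columns]
        return X[passthrough + self.retained_].copy()

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
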