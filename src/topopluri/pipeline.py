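"""End-to-end composition: library -> descriptors -> screen -> hits -> models.

Split in two so a fixed chip can be screened repeatedly:

- :func:`build_chip` generates the design library, renders masks, computes
  the descriptor table and lays out the chip (all deterministic per seed).
- :func:`run_screen` simulates the multi-chip screen on that chip,
  quantifies it, ranks designs and calls Top/Bottom-k hits.
- :func:`fit_models` decorrelates the descriptors of the hit designs and
  fits the classification tree and the logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import descriptors as desc_mod
from . import library_design as lib
from . import model as model_mod
from . import quantify as quant
from . import rank_compare as rank_mod
from . import synthetic_screen as screen_mod


@dataclass
class ChipBundle:
    designs: list
    desc: pd.DataFrame
    layout: lib.ChipLayout


def build_chip(
    n_designs: int = 2176,
    seed: int = 7,
    resolution: float = lib.DEFAULT_RESOLUTION,
    band_centers=desc_mod.DEFAULT_BAND_CENTERS,
) -> ChipBundle:
    designs = lib.generate_library(n_designs, seed, resolution=resolution)
    masks = {d.design_id: lib.render_feature_mask(d, resolution) for d in designs}
    desc = desc_mod.descriptor_table(designs, masks, band_centers=band_centers)
    layout = lib.layout_chip(designs, seed)
    return ChipBundle(designs=designs, desc=desc, layout=layout)


def run_screen(
    bundle: ChipBundle,
    screen_seed: int = 11,
    response: screen_mod.ResponseModel | None = None,
    config: screen_mod.ScreenConfig | None = None,
    k: int = 100,
    rank_metric: str = "n_oct4_pos",
) -> dict:
    """Simulate, quantify and rank one screen of the chip.

    Returns cells, unreadable wells, gates, per-well and pooled summaries,
    the ranked table, the hit table and the flat-control well summaries.
    """
    response = response or screen_mod.ResponseModel()
    config = config or screen_mod.ScreenConfig()
    cells = screen_mod.simulate_screen(bundle.layout, bundle.desc, response, config, screen_seed)
    unreadable = screen_mod.mark_unreadable(
        cells, bundle.layout, config.unreadable_rate, seed=screen_seed + 1
    )
    q = quant.quantify_pipeline(cells, bundle.layout, unreadable)
    units = q["units"]
    ranked = rank_mod.rank_designs(units, rank_metric)
    hits = rank_mod.call_hits(ranked, k=k)
    flat_wells = q["wells"][
        (q["wells"]["design_id"] == lib.FLAT_CONTROL) & (~q["wells"]["unreadable"])
    ]
    return {
        "response": response,
        "config": config,
        "cells": cells,
        "filtered_cells": q["cells"],
        "unreadable": unreadable,
        "gates": q["gates"],
        "wells": q["wells"],
        "units": units,
        "ranked": ranked,
        "hits": hits,
        "flat_wells": flat_wells,
    }


def modeling_table(
    bundle: ChipBundle, hits: pd.DataFrame, r2_threshold: float = 0.75
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Decorrelated descriptors of the TOP/BOTTOM designs plus binary labels
    (1 = TOP).  Returns (X, y, retained_columns)."""
    called = hits[hits["hit_class"] != rank_mod.HIT_NEITHER]
    table = bundle.desc.merge(called[["design_id", "hit_class"]], on="design_id")
    retained, _ = desc_mod.decorrelate(bundle.desc, r2_threshold)
    X = table[retained]
    y = (table["hit_class"] == rank_mod.HIT_TOP).astype(int).to_numpy()
    return X, y, retained


def fit_models(bundle: ChipBundle, hits: pd.DataFrame, seed: int = 0) -> dict:
    """Tree + logistic fits on the hit designs, with held-out evaluation."""
    X, y, retained = modeling_table(bundle, hits)
    tree = model_mod.fit_tree(X, y, seed=seed)
    logistic = model_mod.fit_logistic(X, y)
    report = model_mod.evaluate(logistic, X, y, train_frac=0.75, seed=seed)
    return {
        "X": X,
        "y": y,
        "retained": retained,
        "tree": tree,
        "logistic": logistic,
        "eval": report,
    }
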