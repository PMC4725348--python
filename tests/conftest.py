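"""Shared fixtures: one default-scale chip + screen reused across the suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import topopluri as tp
from topopluri import synthetic_screen as ss

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def chip_default():
    """Full-scale chip: 2,176 designs, rendered and described, laid out."""
    return tp.build_chip(2176, seed=7)


@pytest.fixture(scope="session")
def screen_default(chip_default):
    """One default screen (3 chips) quantified, ranked and hit-called."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tp.run_screen(chip_default, screen_seed=11)


@pytest.fixture(scope="session")
def gt_default(chip_default):
    """Planted ground truth for the default response on the default chip."""
    return ss.ground_truth(
        chip_default.layout, ss.ResponseModel(), chip_default.desc
    ).set_index("design_id")


@pytest.fixture(scope="session")
def small_chip():
    """Smaller library for cheaper whole-pipeline checks."""
    return tp.build_chip(250, seed=3)


@pytest.fixture(scope="session")
def null_screen(small_chip):
    """One-chip screen with all planted coefficients zero (exchangeable wells)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tp.run_screen(
            small_chip,
            screen_seed=5,
            response=ss.ResponseModel.null(),
            config=ss.ScreenConfig(n_chips=1),
        )
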