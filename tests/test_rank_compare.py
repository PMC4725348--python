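"""Ranking, hit calling, group comparison and metric correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import topopluri as tp
from topopluri.rank_compare import (
    HIT_BOTTOM,
    HIT_NEITHER,
    HIT_TOP,
    call_hits,
    compare_groups,
    correlate_metrics,
    gate_cross_tab,
    rank_designs,
    significance_stars,
)


def _units(values, metric="n_oct4_pos"):
    return pd.DataFrame({"design_id": range(len(values)), metric: values})


class TestRanking:
    def test_ties_broken_by_design_id(self):
        ranked = rank_designs(_units([5.0] * 4), "n_oct4_pos")
        assert ranked["design_id"].tolist() == [0, 1, 2, 3]

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(0)
        units = _units(rng.random(50))
        shuffled = units.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = rank_designs(units, "n_oct4_pos")
        b = rank_designs(shuffled, "n_oct4_pos")
        pd.testing.assert_frame_equal(a, b)

    def test_missing_metric_errors(self):
        with pytest.raises(KeyError):
            rank_designs(_units([1.0]), "nope")

    def test_top_decile_enriched_for_planted_probability(self, screen_default, gt_default):
        ranked = screen_default["ranked"]
        n = len(ranked) // 10
        top_p = gt_default.loc[ranked["design_id"].head(n), "p_hit"].mean()
        bottom_p = gt_default.loc[ranked["design_id"].tail(n), "p_hit"].mean()
        assert top_p > bottom_p


class TestCallHits:
    def test_k1_of_three(self):
        hits = call_hits(rank_designs(_units([3.0, 1.0, 2.0]), "n_oct4_pos"), k=1)
        assert (hits["hit_class"] == HIT_TOP).sum() == 1
        assert (hits["hit_class"] == HIT_BOTTOM).sum() == 1

    def test_neither_count(self):
        rng = np.random.default_rng(0)
        hits = call_hits(rank_designs(_units(rng.random(1000)), "n_oct4_pos"), k=100)
        assert (hits["hit_class"] == HIT_NEITHER).sum() == 800

    def test_top_set_prefix_stable(self):
        rng = np.random.default_rng(1)
        vals = rng.random(300)
        hits1 = call_hits(rank_designs(_units(vals), "n_oct4_pos"), k=20)
        # add designs strictly below the current bottom of the ranking
        more = _units(np.concatenate([vals, vals.min() - 1 - rng.random(50)]))
        hits2 = call_hits(rank_designs(more, "n_oct4_pos"), k=20)
        top1 = set(hits1.loc[hits1.hit_class == HIT_TOP, "design_id"])
        top2 = set(hits2.loc[hits2.hit_class == HIT_TOP, "design_id"])
        assert top1 == top2

    def test_too_few_designs(self):
        with pytest.raises(ValueError):
            call_hits(rank_designs(_units([1.0, 2.0, 3.0]), "n_oct4_pos"), k=2)

    @given(st.integers(min_value=0, max_value=3))
    def test_invariant_under_monotone_metric_transform(self, which):
        rng = np.random.default_rng(7)
        vals = rng.random(60)
        transform = [lambda v: v, lambda v: 3 * v + 2, np.expm1, lambda v: v**3][which]
        a = call_hits(rank_designs(_units(vals), "n_oct4_pos"), k=10)
        b = call_hits(rank_designs(_units(transform(vals)), "n_oct4_pos"), k=10)
        pd.testing.assert_frame_equal(a, b)


class TestCompareGroups:
    def _toy(self, rng, top_shift=0.0):
        units = pd.DataFrame(
            {
                "design_id": range(40),
                "n_cells_24h": np.r_[rng.poisson(12 + top_shift, 20), rng.poisson(12, 20)],
            }
        )
        hits = pd.DataFrame(
            {
                "design_id": range(40),
                "hit_class": [HIT_TOP] * 20 + [HIT_BOTTOM] * 20,
            }
        )
        flat = pd.DataFrame({"design_id": -1, "n_cells_24h": rng.poisson(12, 12)})
        return units, hits, flat

    def test_identical_groups_fold_one_ns(self):
        rng = np.random.default_rng(0)
        units, hits, flat = self._toy(rng)
        units["n_cells_24h"] = 12.0
        flat["n_cells_24h"] = 12.0
        out = compare_groups(units, hits, flat, metrics=("n_cells_24h",))
        assert (out["fold_change"] == 1.0).all()
        assert (out["stars"] == "ns").all()

    def test_planted_threefold_recovered(self, screen_default, gt_default):
        """TOP defined from planted truth -> measured 24 h count fold near 3."""
        gt = gt_default.drop(index=tp.FLAT_CONTROL)
        order = gt["p_hit"].sort_values(ascending=False)
        truth_hits = pd.DataFrame(
            {
                "design_id": np.r_[order.index[:100], order.index[-100:]],
                "hit_class": [HIT_TOP] * 100 + [HIT_BOTTOM] * 100,
            }
        )
        out = compare_groups(
            screen_default["units"], truth_hits, screen_default["flat_wells"],
            metrics=("n_cells_24h",),
        )
        row = out[(out.group_a == HIT_TOP) & (out.group_b == "FLAT")].iloc[0]
        assert 2.5 <= row["fold_change"] <= 3.5
        assert row["p_value"] < 0.001

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(99)
        hits = pd.DataFrame(
            {"design_id": range(200), "hit_class": [HIT_TOP] * 100 + [HIT_BOTTOM] * 100}
        )
        n_sig = 0
        n_rep = 200
        for _ in range(n_rep):
            units = pd.DataFrame(
                {"design_id": range(200), "m": rng.poisson(12, 200).astype(float)}
            )
            flat = pd.DataFrame({"design_id": -1, "m": rng.poisson(12, 12).astype(float)})
            out = compare_groups(units, hits, flat, metrics=("m",))
            n_sig += int(out[(out.group_a == HIT_TOP) & (out.group_b == "FLAT")].iloc[0].p_value < 0.05)
        assert 0.01 <= n_sig / n_rep <= 0.10

    def test_small_group_not_computable(self):
        rng = np.random.default_rng(3)
        units, hits, flat = self._toy(rng)
        out = compare_groups(units, hits, flat.head(2), metrics=("n_cells_24h",))
        row = out[(out.group_a == HIT_TOP) & (out.group_b == "FLAT")].iloc[0]
        assert np.isnan(row["p_value"]) and row["stars"] == "na"

    def test_stars_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"


class TestCorrelateMetrics:
    def test_perfect_correlation(self):
        units = pd.DataFrame(
            {"design_id": range(10), "n_oct4_pos": np.arange(10.0), "n_edu_pos": np.arange(10.0), "n_cells_24h": 1.0 + np.arange(10.0)}
        )
        out = correlate_metrics(units)
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        units = pd.DataFrame(
            {
                "design_id": range(1000),
                "n_oct4_pos": rng.normal(size=1000),
                "n_edu_pos": rng.normal(size=1000),
                "n_cells_24h": rng.normal(size=1000),
            }
        )
        out = correlate_metrics(units)
        assert (out["r2"] < 0.02).all()

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        units = pd.DataFrame(
            {"design_id": range(100), "n_oct4_pos": x, "n_edu_pos": y, "n_cells_24h": y}
        )
        scaled = units.copy()
        scaled["n_edu_pos"] = 7.0 * scaled["n_edu_pos"] - 3.0
        a = correlate_metrics(units)["r2"]
        b = correlate_metrics(scaled)["r2"]
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_zero_variance_marked(self):
        units = pd.DataFrame(
            {"design_id": range(5), "n_oct4_pos": 1.0, "n_edu_pos": np.arange(5.0), "n_cells_24h": np.arange(5.0)}
        )
        out = correlate_metrics(units)
        assert np.isnan(out["r2"].iloc[0])

    def test_screen_metrics_positively_correlated(self, screen_default):
        out = correlate_metrics(screen_default["units"])
        assert (out["r2"] > 0.5).all()


class TestCrossTabAndCoupling:
    def test_counts_conserved(self, screen_default):
        cells = screen_default["filtered_cells"]
        c24 = cells[cells.timepoint == 24]
        counts, fr = gate_cross_tab(c24, screen_default["gates"])
        assert counts.to_numpy().sum() == len(c24)

    def test_edu_mostly_within_oct4(self, screen_default):
        cells = screen_default["filtered_cells"]
        counts, fr = gate_cross_tab(cells[cells.timepoint == 24], screen_default["gates"])
        assert fr["p_oct4_pos_given_edu_pos"] > 0.9
        assert fr["p_edu_neg_given_oct4_pos"] == pytest.approx(0.30, abs=0.03)

    def test_all_double_positive(self):
        cells = pd.DataFrame(
            {"chip_id": 0, "oct4_int": [100.0] * 5, "edu_int": [100.0] * 5}
        )
        gates = {
            (0, "oct4"): tp.GateSpec("oct4", 10.0, "mixture"),
            (0, "edu"): tp.GateSpec("edu", 10.0, "mixture"),
        }
        counts, _ = gate_cross_tab(cells, gates)
        assert counts.loc["oct4_pos", "edu_pos"] == 5
        assert counts.to_numpy().sum() == 5

    def test_4h_counts_uncoupled_from_hit_class(self, screen_default):
        units = screen_default["units"]
        hits = screen_default["hits"]
        merged = units.merge(hits, on="design_id")
        called = merged[merged.hit_class != HIT_NEITHER]
        rho = stats.spearmanr(
            called["n_cells_4h"], (called["hit_class"] == HIT_TOP).astype(int)
        ).statistic
        assert abs(rho) < 0.2
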