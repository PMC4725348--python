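# topopluri

In-silico micro-topography screening for human iPSC pluripotency.

Micro-topographies — repeating patterns of micrometre-scale circles,
triangles and rectangles embossed into polystyrene — can maintain induced
pluripotent stem cells (iPSC) in the pluripotent state without any coated
extracellular-matrix proteins. TopoChip-style screens measure this by
arraying thousands of distinct topographies in duplicate micro-wells
(TopoUnits), seeding iPSC, and scoring each well by high-content imaging for
the pluripotency marker Oct4 and the S-phase marker EdU 24 h after seeding.
The analytical question is then: *which geometric properties of a
topography predict that it supports pluripotency?*

`topopluri` is a tested re-implementation of that analysis pipeline for
people who build or evaluate such screens. Because raw screen data of this
kind are generally not public, the package includes a first-class synthetic
screen generator with a planted, known descriptor→response relationship, so
every downstream stage can be validated quantitatively.

## What it does

1. **Library design** — samples a library of topography designs (primitives
   composed in a 10/20/28 μm bounding square, feature height 10 μm), renders
   binary feature masks, and lays out a 66 × 66-well chip holding every
   design in duplicate plus flat controls.
2. **Descriptors** — per design: FCP (fraction of the feature covered by
   primitives), pattern area (FeatSize² · FCP, μm²), wave-number bands
   WN*q* (fraction of the non-DC 2-D DFT power at radial spatial frequency
   *q* cycles/μm), and primitive statistics; plus greedy decorrelation of
   the table at pairwise r² ≤ 0.75.
3. **Synthetic screen** — per-cell tables with Poisson seeding
   (100 cells/mm² at 4 h), a planted logistic response
   p(hit) = σ(β₀ + βₚₐ·z(pattern area) + β_wn·z(WN0.2) + β_fcp·z(FCP))
   driving a ≤3-fold 24 h count effect and Oct4/EdU class rates,
   Neyman–Scott cell clusters, log-normal intensity mixtures, background,
   outliers and unreadable wells.
4. **Quantification** — per-chip background subtraction, 2.5-SD outlier
   removal, mixture-model Oct4/EdU gating, single-linkage cluster detection
   (25 μm), per-well aggregation and replicate pooling (3 chips × 2
   duplicates).
5. **Hit calling & statistics** — Top/Bottom-100 ranking by Oct4⁺ cells,
   comparisons against flat controls (median fold-changes, two-sided
   rank-sum tests), metric correlations, Oct4 × EdU contingency.
6. **Models** — a CART-style Gini classification tree with 10-fold
   cross-validated cost-complexity pruning (1-SE rule), and a logistic
   regression fitted by IRLS, with stratified 75/25 hold-out evaluation
   (accuracy, ROC, trapezoid AUC) and prediction of unscreened designs.

The tree, logistic model, decorrelation filter and gates are scikit-learn
style estimators (`fit` / `predict` / `get_params`), so they compose with
sklearn tooling.

## Worked example

```python
import topopluri as tp
from topopluri.rank_compare import compare_groups, gate_cross_tab

chip = tp.build_chip(n_designs=2176, seed=7)       # library + descriptors + layout
screen = tp.run_screen(chip, screen_seed=11)       # simulate, quantify, rank, call hits

counts, fractions = gate_cross_tab(
    screen["filtered_cells"].query("timepoint == 24"), screen["gates"]
)
print(f"P(EdU- | Oct4+) = {fractions['p_edu_neg_given_oct4_pos']:.3f}")

stats = compare_groups(screen["units"], screen["hits"], screen["flat_wells"],
                       metrics=("n_cells_24h", "n_oct4_pos"))
row = stats.query("metric == 'n_cells_24h' and group_a == 'TOP' and group_b == 'FLAT'").iloc[0]
print(f"TOP vs flat, 24 h cells: fold = {row.fold_change:.2f} ({row.stars})")

models = tp.fit_models(chip, screen["hits"], seed=0)
tree = models["tree"]
print(f"tree root split: {tree.root_split_feature_} <= {tree.root_split_threshold_:.1f} um^2 "
      f"({tree.n_leaves_} leaves)")
print(f"logistic hold-out: accuracy = {models['eval'].accuracy:.2f}, AUC = {models['eval'].auc:.2f}")
```

Output:

```
P(EdU- | Oct4+) = 0.312
TOP vs flat, 24 h cells: fold = 3.15 (***)
tree root split: pattern_area <= 78.6 um^2 (2 leaves)
logistic hold-out: accuracy = 1.00, AUC = 1.00
```

Reading this: the gated Oct4 × EdU cross-tabulation recovers the planted
fraction of non-cycling Oct4⁺ cells (0.30); the called Top-100 topographies
carry about the planted three-fold more cells at 24 h than flat polystyrene;
and the pruned classification tree recovers the planted dominant descriptor —
small pattern area — as its root split. Accuracy/AUC of 1.0 reflect that the
Top/Bottom extremes of a near-threshold planted response are cleanly
separable; a real screen is noisier.

The same pipeline is scriptable from the shell:

```sh
topopluri design --n 2176 --seed 7 --out designs.json
topopluri descriptors --designs designs.json --out desc.csv
topopluri simulate --designs designs.json --desc desc.csv --seed 11 --out cells.csv
topopluri quantify --cells cells.csv --designs designs.json --out units.csv
topopluri rank --units units.csv --k 100 --out hits.csv
topopluri model --desc desc.csv --hits hits.csv --seed 3 --out model.json
```

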