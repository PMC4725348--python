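"""Descriptor -> hit models: Gini classification tree and IRLS logistic fit.

`GiniTreeClassifier` is CART-style greedy binary recursive partitioning:
exhaustive search over midpoints of sorted unique values per column,
minimizing Gini impurity, grown under min_split/min_leaf/complexity stopping
rules and pruned by cost-complexity (misclassification risk) with k-fold
cross-validation and the 1-SE rule.

`IRLSLogisticRegression` is a maximum-likelihood logistic fit via iteratively
reweighted least squares with step halving (so the log-likelihood path is
non-decreasing), convergence and separation diagnostics, and Wald standard
errors.

`evaluate` holds out a stratified 25% test split and reports accuracy, the
ROC curve (threshold sweep over unique scores) and the trapezoid AUC;
`predict_new` ranks unscreened designs by fitted probability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._base import BaseEstimator, clone


def _check_X(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim != 2:
            raise ValueError("X must be 2-D")
        names = [f"x{j}" for j in range(mat.shape[1])]
    if not np.isfinite(mat).all():
        raise ValueError("X contains non-finite values")
    return mat, names


def _check_y(y, n: int) -> np.ndarray:
    y = np.asarray(y)
    if y.shape != (n,):
        raise ValueError("y length does not match X")
    classes = np.unique(y)
    if classes.size > 2:
        raise ValueError("only binary labels are supported")
    return y


# ---------------------------------------------------------------------------
# Classification tree
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("feature", "threshold", "left", "right", "counts")

    def __init__(self, counts: np.ndarray):
        self.feature: int | None = None
        self.threshold: float | None = None
        self.left: "_Node | None" = None
        self.right: "_Node | None" = None
        self.counts = counts  # class counts at node, shape (2,)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def misclassified(self) -> int:
        return self.n - int(self.counts.max())

    def copy(self) -> "_Node":
        node = _Node(self.counts.copy())
        node.feature, node.threshold = self.feature, self.threshold
        if not self.is_leaf:
            node.left = self.left.copy()
            node.right = self.right.copy()
        return node

    def to_dict(self, feature_names: Sequence[str]) -> dict:
        d = {"n": self.n, "counts": self.counts.tolist()}
        if not self.is_leaf:
            d["feature"] = feature_names[self.feature]
            d["threshold"] = self.threshold
            d["left"] = self.left.to_dict(feature_names)
            d["right"] = self.right.to_dict(feature_names)
        return d


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def best_gini_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int = 1
) -> tuple[int, float, float] | None:
    """Exhaustive best (feature, midpoint threshold) split by Gini decrease.

    Returns ``(feature, threshold, impurity_decrease)`` with the decrease
    weighted by child sizes (``gini(node) - (nl*gl + nr*gr)/n``), or None if
    no admissible split exists.  Ties go to the lowest feature index, then
    the lowest threshold.
    """
    n, p = X.shape
    counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
    node_gini = _gini(counts)
    best = None  # (decrease, feature, threshold)
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        cum1 = np.cumsum(ys)
        idx = np.nonzero(xs[:-1] < xs[1:])[0]  # split between i and i+1
        if idx.size == 0:
            continue
        nl = idx + 1
        nr = n - nl
        ok = (nl >= min_leaf) & (nr >= min_leaf)
        if not ok.any():
            continue
        idx, nl, nr = idx[ok], nl[ok], nr[ok]
        l1 = cum1[idx].astype(float)
        l0 = nl - l1
        r1 = counts[1] - l1
        r0 = nr - r1
        gl = 1.0 - (l0**2 + l1**2) / nl**2
        gr = 1.0 - (r0**2 + r1**2) / nr**2
        decrease = node_gini - (nl * gl + nr * gr) / n
        k = int(np.argmax(decrease))
        cand = (float(decrease[k]), j, float((xs[idx[k]] + xs[idx[k] + 1]) / 2.0))
        if best is None or cand[0] > best[0] + 1e-15:
            best = cand
    if best is None or best[0] <= 1e-15:
        return None
    return best[1], best[2], best[0]


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    min_split: int,
    min_leaf: int,
    cp_gate: float,
    depth: int,
    max_depth: int,
) -> _Node:
    counts = np.array([(y[idx] == 0).sum(), (y[idx] == 1).sum()], dtype=float)
    node = _Node(counts)
    if (
        depth >= max_depth
        or idx.size < min_split
        or counts.min() == 0
    ):
        return node
    found = best_gini_split(X[idx], y[idx], min_leaf)
    if found is None:
        return node
    j, thr, decrease = found
    # complexity gate on the whole-tree scale: weighted decrease vs root
    if (idx.size * decrease) < cp_gate:
        return node
    go_left = X[idx, j] <= thr
    node.feature, node.threshold = j, thr
    node.left = _grow(X, y, idx[go_left], min_split, min_leaf, cp_gate, depth + 1, max_depth)
    node.right = _grow(X, y, idx[~go_left], min_split, min_leaf, cp_gate, depth + 1, max_depth)
    return node


def _leaves_and_risk(node: _Node) -> tuple[int, int]:
    """(number of leaves, total misclassified count) of the subtree."""
    if node.is_leaf:
        return 1, node.misclassified
    ll, rl = _leaves_and_risk(node.left), _leaves_and_risk(node.right)
    return ll[0] + rl[0], ll[1] + rl[1]


def _weakest_link(node: _Node, n_total: int) -> tuple[float, list[_Node]]:
    """Minimum g(t) over internal nodes and the nodes attaining it, where
    g(t) = (R(t) - R(subtree_t)) / (leaves - 1) on the misclassification scale."""
    best_g = np.inf
    nodes: list[_Node] = []

    def visit(t: _Node):
        nonlocal best_g, nodes
        if t.is_leaf:
            return
        leaves, sub_risk = _leaves_and_risk(t)
        g = (t.misclassified - sub_risk) / (n_total * (leaves - 1))
        if g < best_g - 1e-15:
            best_g, nodes = g, [t]
        elif g <= best_g + 1e-15:
            nodes.append(t)
        visit(t.left)
        visit(t.right)

    visit(node)
    return best_g, nodes


def _prune_at(root: _Node, alpha: float, n_total: int) -> _Node:
    """Copy of the tree with every weakest link of g <= alpha collapsed."""
    tree = root.copy()
    while not tree.is_leaf:
        g, nodes = _weakest_link(tree, n_total)
        if g > alpha + 1e-12:
            break
        for t in nodes:
            t.feature = t.threshold = None
            t.left = t.right = None
    return tree


def _pruning_alphas(root: _Node, n_total: int) -> list[float]:
    """Ascending cost-complexity thresholds [0, a1, ..., ak] of the path."""
    alphas = [0.0]
    tree = root.copy()
    while not tree.is_leaf:
        g, nodes = _weakest_link(tree, n_total)
        alphas.append(max(g, alphas[-1]))
        for t in nodes:
            t.feature = t.threshold = None
            t.left = t.right = None
    return alphas


class GiniTreeClassifier(BaseEstimator):
    """CART-style binary classification tree with CV cost-complexity pruning.

    Parameters
    ----------
    min_split : int, default 20
        Minimum node size eligible for splitting.
    min_leaf : int, default 7
        Minimum child size of any split.
    cp : float, default 0.01
        Complexity gate while growing: a split must decrease the tree-level
        Gini impurity by at least ``cp`` times the root impurity.
    cv : int, default 10
        Cross-validation folds for pruning (0 disables pruning).
    one_se : bool, default True
        Select the smallest subtree within one standard error of the minimum
        cross-validated risk.
    random_state : int or None
        Seed for the stratified CV fold assignment.

    Attributes
    ----------
    tree_ : root node; ``classes_``; ``feature_names_in_``; ``n_leaves_``;
    ``alpha_`` (chosen complexity); ``cv_results_`` (alpha, cv risk, se);
    ``root_split_feature_`` / ``root_split_threshold_`` (None for a stump).
    """

    def __init__(
        self,
        min_split: int = 20,
        min_leaf: int = 7,
        cp: float = 0.01,
        cv: int = 10,
        one_se: bool = True,
        max_depth: int = 30,
        random_state=None,
    ):
        self.min_split = min_split
        self.min_leaf = min_leaf
        self.cp = cp
        self.cv = cv
        self.one_se = one_se
        self.max_depth = max_depth
        self.random_state = random_state

    # -- internals -----------------------------------------------------

    def _grow_full(self, X: np.ndarray, y: np.ndarray) -> _Node:
        n = len(y)
        root_counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
        cp_gate = self.cp * n * _gini(root_counts)
        return _grow(
            X, y, np.arange(n), self.min_split, self.min_leaf, cp_gate, 0, self.max_depth
        )

    def fit(self, X, y) -> "GiniTreeClassifier":
        Xm, names = _check_X(X)
        y = _check_y(y, len(Xm))
        classes = np.unique(y)
        self.classes_ = classes
        self.feature_names_in_ = names
        if classes.size == 1:
            warnings.warn("single-class input; fitting a single-leaf tree")
            y01 = np.zeros(len(Xm), dtype=int)
        else:
            y01 = (y == classes[1]).astype(int)
        n = len(y01)
        full = self._grow_full(Xm, y01)
        self.alpha_ = 0.0
        self.cv_results_ = None
        if self.cv and not full.is_leaf and classes.size == 2:
            alphas = _pruning_alphas(full, n)
            betas = [
                float(np.sqrt(alphas[i] * alphas[i + 1])) for i in range(len(alphas) - 1)
            ] + [alphas[-1] * 2 + 1e-9]
            folds = self._stratified_folds(y01)
            errors = np.zeros(len(betas))
            for test_idx in folds:
                train_mask = np.ones(n, dtype=bool)
                train_mask[test_idx] = False
                sub = clone(self)
                sub.cv = 0
                sub_tree = sub._grow_full(Xm[train_mask], y01[train_mask])
                for bi, beta in enumerate(betas):
                    pruned = _prune_at(sub_tree, beta, int(train_mask.sum()))
                    pred = _predict_tree(pruned, Xm[test_idx])
                    errors[bi] += (pred != y01[test_idx]).sum()
            risk = errors / n
            se = np.sqrt(risk * (1 - risk) / n)
            best = int(np.argmin(risk))
            if self.one_se:
                cutoff = risk[best] + se[best]
                admissible = np.nonzero(risk <= cutoff + 1e-15)[0]
                best = int(admissible.max())  # largest alpha = smallest tree
            self.alpha_ = float(betas[best])
            self.cv_results_ = pd.DataFrame(
                {"alpha": alphas[: len(betas)], "beta": betas, "cv_risk": risk, "se": se}
            )
            full = _prune_at(full, self.alpha_, n)
        self.tree_ = full
        self.n_leaves_ = _leaves_and_risk(full)[0]
        self.root_split_feature_ = (
            None if full.is_leaf else self.feature_names_in_[full.feature]
        )
        self.root_split_threshold_ = None if full.is_leaf else full.threshold
        return self

    def _stratified_folds(self, y01: np.ndarray) -> list[np.ndarray]:
        rng = np.random.default_rng(self.random_state)
        k = min(self.cv, int(np.bincount(y01, minlength=2).min()))
        k = max(k, 2)
        folds: list[list[int]] = [[] for _ in range(k)]
        for cls in (0, 1):
            idx = np.nonzero(y01 == cls)[0]
            idx = rng.permutation(idx)
            for i, j in enumerate(idx):
                folds[i % k].append(int(j))
        return [np.array(f, dtype=int) for f in folds]

    # -- prediction ----------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        Xm, _ = _check_X(X)
        if self.classes_.size == 1:
            return np.ones((len(Xm), 1))
        frac = _leaf_fractions(self.tree_, Xm)
        return np.column_stack([1 - frac, frac])

    def predict(self, X) -> np.ndarray:
        if self.classes_.size == 1:
            Xm, _ = _check_X(X)
            return np.full(len(Xm), self.classes_[0])
        proba = self.predict_proba(X)[:, 1]
        return self.classes_[(proba > 0.5).astype(int)]

    def to_dict(self) -> dict:
        return {
            "classes": self.classes_.tolist(),
            "alpha": self.alpha_,
            "n_leaves": self.n_leaves_,
            "tree": self.tree_.to_dict(self.feature_names_in_),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _predict_tree(node: _Node, X: np.ndarray) -> np.ndarray:
    return (_leaf_fractions(node, X) > 0.5).astype(int)


def _leaf_fractions(node: _Node, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))

    def visit(t: _Node, idx: np.ndarray):
        if t.is_leaf:
            n = t.counts.sum()
            out[idx] = (t.counts[1] / n) if n else 0.5
            return
        go_left = X[idx, t.feature] <= t.threshold
        visit(t.left, idx[go_left])
        visit(t.right, idx[~go_left])

    visit(node, np.arange(len(X)))
    return out


# ---------------------------------------------------------------------------
# Logistic regression via IRLS
# ---------------------------------------------------------------------------

class IRLSLogisticRegression(BaseEstimator):
    """Maximum-likelihood logistic regression by IRLS with step halving.

    Columns are standardized internally by default (mean 0, SD 1), so the
    reported coefficients are per-SD effects; prediction applies the stored
    transform.  Non-convergence and (quasi-)complete separation are reported
    explicitly rather than silently returned.

    Attributes: ``coef_``, ``intercept_``, ``se_``, ``z_values_``,
    ``loglik_``, ``loglik_path_`` (non-decreasing), ``converged_``,
    ``separation_``, ``n_iter_``, ``classes_``, ``feature_names_in_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100, standardize: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize

    def fit(self, X, y) -> "IRLSLogisticRegression":
        Xm, names = _check_X(X)
        y = _check_y(y, len(Xm))
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("logistic fit needs both classes present")
        self.classes_ = classes
        self.feature_names_in_ = names
        y01 = (y == classes[1]).astype(float)
        if self.standardize:
            self.mean_ = Xm.mean(axis=0)
            scale = Xm.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
            Xs = (Xm - self.mean_) / self.scale_
        else:
            self.mean_ = np.zeros(Xm.shape[1])
            self.scale_ = np.ones(Xm.shape[1])
            Xs = Xm
        A = np.column_stack([np.ones(len(Xs)), Xs])
        beta = np.zeros(A.shape[1])

        def loglik(b: np.ndarray) -> float:
            eta = A @ b
            return float(np.sum(y01 * eta - np.logaddexp(0.0, eta)))

        ll = loglik(beta)
        path = [ll]
        converged = False
        for _ in range(self.max_iter):
            eta = A @ beta
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
            w = np.clip(p * (1 - p), 1e-12, None)
            z = eta + (y01 - p) / w
            sw = np.sqrt(w)
            beta_new, *_ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
            ll_new = loglik(beta_new)
            halvings = 0
            while ll_new < ll - 1e-12 and halvings < 30:
                beta_new = (beta + beta_new) / 2.0
                ll_new = loglik(beta_new)
                halvings += 1
            beta = beta_new
            path.append(max(ll_new, ll))
            if abs(ll_new - ll) < self.tol:
                ll = ll_new
                converged = True
                break
            ll = ll_new
        eta = A @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        fitted_extreme = np.all((p > 1 - 1e-6) == (y01 == 1)) and np.all(
            (p < 1e-6) == (y01 == 0)
        )
        self.separation_ = bool(fitted_extreme and np.abs(beta).max() > 15)
        if self.separation_:
            warnings.warn(
                "perfect separation detected; coefficients are unbounded and "
                "reported at the last iterate"
            )
        if not converged:
            warnings.warn("IRLS did not converge within max_iter")
        w = np.clip(p * (1 - p), 1e-12, None)
        fisher = A.T @ (A * w[:, None])
        try:
            cov = np.linalg.inv(fisher)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(A.shape[1], np.nan)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.se_ = se
        with np.errstate(divide="ignore", invalid="ignore"):
            self.z_values_ = beta / se
        self.loglik_ = ll
        self.loglik_path_ = np.array(path)
        self.converged_ = converged
        self.n_iter_ = len(path) - 1
        return self

    def decision_function(self, X) -> np.ndarray:
        Xm, _ = _check_X(X)
        Xs = (Xm - self.mean_) / self.scale_
        return self.intercept_ + Xs @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-np.clip(self.decision_function(X), -500, 500)))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept_,
            "coefficients": dict(zip(self.feature_names_in_, self.coef_.tolist())),
            "standardize": self.standardize,
            "converged": self.converged_,
            "separation": self.separation_,
        }


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def roc_curve(y_true: np.ndarray, score: np.ndarray) -> np.ndarray:
    """ROC points by threshold sweep over the unique scores.

    Returns an array of (FPR, TPR) pairs starting at (0, 0) and ending at
    (1, 1), monotone in both axes.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(score, dtype=float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.r_[distinct, y.size - 1]
    tps = np.cumsum(y)[cut]
    fps = np.cumsum(1 - y)[cut]
    P = y.sum()
    N = y.size - P
    tpr = tps / P if P else np.zeros_like(tps, dtype=float)
    fpr = fps / N if N else np.zeros_like(fps, dtype=float)
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])


def auc_trapezoid(roc: np.ndarray) -> float:
    return float(np.trapezoid(roc[:, 1], roc[:, 0]))


@dataclass
class EvalReport:
    """Held-out evaluation of a fitted probability model."""

    accuracy: float
    auc: float
    roc: np.ndarray
    confusion: np.ndarray  # rows: true class, cols: predicted
    n_train: int
    n_test: int
    train_idx: np.ndarray = field(repr=False, default=None)
    test_idx: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "roc": self.roc.tolist(),
        }


def stratified_split(
    y: np.ndarray, train_frac: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified index split preserving class balance."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.nonzero(np.asarray(y) == cls)[0])
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1) if idx.size > 1 else idx.size
        train.extend(idx[:n_train].tolist())
        test.extend(idx[n_train:].tolist())
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


def evaluate(model, X, y, train_frac: float = 0.75, seed=0) -> EvalReport:
    """Refit a clone of ``model`` on a stratified 75% split and score the rest.

    Accuracy uses a 0.5 probability cutoff; the AUC is the trapezoid area
    under the threshold-swept ROC.  A single-class test set yields NaN AUC.
    """
    Xm, names = _check_X(X)
    y = np.asarray(y)
    train_idx, test_idx = stratified_split(y, train_frac, seed)
    fitted = clone(model)
    X_in = X.iloc if isinstance(X, pd.DataFrame) else None
    X_train = X.iloc[train_idx] if X_in is not None else Xm[train_idx]
    X_test = X.iloc[test_idx] if X_in is not None else Xm[test_idx]
    fitted.fit(X_train, y[train_idx])
    proba = fitted.predict_proba(X_test)[:, 1]
    y_test01 = (y[test_idx] == fitted.classes_[1]).astype(int)
    pred01 = (proba > 0.5).astype(int)
    accuracy = float((pred01 == y_test01).mean())
    confusion = np.array(
        [
            [(1 - y_test01)[pred01 == 0].sum(), (1 - y_test01)[pred01 == 1].sum()],
            [y_test01[pred01 == 0].sum(), y_test01[pred01 == 1].sum()],
        ],
        dtype=int,
    )
    if np.unique(y_test01).size < 2:
        roc = np.array([[0.0, 0.0], [1.0, 1.0]])
        auc = np.nan
    else:
        roc = roc_curve(y_test01, proba)
        auc = auc_trapezoid(roc)
    return EvalReport(
        accuracy=accuracy,
        auc=auc,
        roc=roc,
        confusion=confusion,
        n_train=len(train_idx),
        n_test=len(test_idx),
        train_idx=train_idx,
        test_idx=test_idx,
    )


def predict_new(model, desc_new: pd.DataFrame, n_each: int = 30) -> tuple[list, list]:
    """The ``n_each`` unscreened designs with the highest / lowest fitted hit
    probability.  The two lists are disjoint by construction."""
    if len(desc_new) < 2 * n_each:
        raise ValueError(
            f"need at least {2 * n_each} candidate designs, got {len(desc_new)}"
        )
    X = desc_new[list(model.feature_names_in_)]
    if hasattr(model, "decision_function"):
        # monotone in probability but immune to saturation ties
        score = model.decision_function(X)
    else:
        score = model.predict_proba(X)[:, 1]
    ids = desc_new["design_id"].to_numpy()
    order = np.lexsort((ids, -score))  # descending score, ties by id
    top = ids[order[:n_each]].tolist()
    bottom = ids[order[-n_each:]][::-1].tolist()
    return top, bottom


# ---------------------------------------------------------------------------
# Thin wrappers
# ---------------------------------------------------------------------------

def fit_tree(desc: pd.DataFrame, labels, seed=None, **params) -> GiniTreeClassifier:
    """Fit the CV-pruned Gini tree on a (decorrelated) descriptor table."""
    return GiniTreeClassifier(random_state=seed, **params).fit(desc, labels)


def fit_logistic(desc: pd.DataFrame, labels, **params) -> IRLSLogisticRegression:
    return IRLSLogisticRegression(**params).fit(desc, labels)
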