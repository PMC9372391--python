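"""Feature ranking: RReliefF, forest Gini importance, OOB permutation.

Three ways of weighting the 39 candidate predictors against AGB:

* **RReliefF** (regression Relief): features are min–max normalized; for
  each instance the k nearest neighbours (Manhattan distance) accumulate
  the probabilities that the target differs (N_dC), that the feature
  differs (N_dA), and both together (N_dC&dA); the weight is

      W(F) = N_dC&dA / N_dC  −  (N_dA − N_dC&dA) / (m·k − N_dC),

  i.e. the conditional-probability contrast between "feature differs given
  the prediction differs" and "feature differs given it does not".

* **RF-Gini**: the target is quantile-discretized into classes and a
  classification forest is grown; a feature's importance is the decrease
  in Gini impurity G = 1 − Σ p_v² over its splits, averaged over trees.
  A variance-reduction importance on the continuous target is available
  behind ``mode="variance"`` for comparison.

* **RF-OOB**: a regression forest; per tree the out-of-bag mean squared
  error E1 is compared with the error E2 after corrupting one feature
  among that tree's OOB samples, and IMP_F = Σ(E2 − E1)/K over the K
  trees.  Corruption is Breiman's OOB permutation by default; additive
  Gaussian noise is available behind ``corruption="gaussian"``.

All three are deterministic given their seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: forest defaults shared with the regression module: tree count, candidate
#: features per split (ceil(p/3)) and minimum leaf size
N_TREES = 500
MIN_LEAF = 5

#: metadata columns never treated as predictors in a feature table
META_COLUMNS = ("sample_id", "plot_id", "stage", "variety", "fertilizer",
                "rep")

TARGET_COLUMN = "AGB"


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Predictor columns of a feature table (everything but metadata/target)."""
    return [c for c in table.columns
            if c not in META_COLUMNS and c != TARGET_COLUMN]


def _split_xy(table: pd.DataFrame,
              features: list[str] | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    feats = features if features is not None else feature_columns(table)
    if TARGET_COLUMN not in table.columns:
        raise ValueError(f"feature table lacks target column {TARGET_COLUMN!r}")
    y = table[TARGET_COLUMN].to_numpy(dtype=np.float64)
    if np.isnan(y).any():
        raise ValueError("missing target values in feature table")
    X = table[feats].to_numpy(dtype=np.float64)
    return X, y, feats


def max_features_per_split(p: int) -> int:
    """Candidate features per split: ceil(p/3)."""
    return max(1, math.ceil(p / 3))


@dataclass
class ImportanceRanking:
    """Per-feature weights and 1-based ranks from one selection method."""

    method: str
    features: list[str]
    weights: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("importance weights must be finite")
        # stable descending sort: ties break by feature order
        order = np.argsort(-self.weights, kind="stable")
        self.ranks = np.empty(len(order), dtype=int)
        self.ranks[order] = np.arange(1, len(order) + 1)

    def top(self, n: int = 10) -> list[str]:
        """The ``min(n, p)`` best-ranked feature names."""
        order = np.argsort(self.ranks)
        return [self.features[i] for i in order[:min(n, len(order))]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.features,
            "weight": self.weights,
            "rank": self.ranks,
            "method": self.method,
            "seed": self.seed,
        })


def select_top(ranking: ImportanceRanking, n: int = 10) -> list[str]:
    """Top-n feature names; all features if fewer than n are available."""
    return ranking.top(n)


# ---------------------------------------------------------------------------
# RReliefF


def rrelieff(table: pd.DataFrame, k_neighbors: int = 10,
             n_iterations: int | None = None, seed: int = 0,
             features: list[str] | None = None) -> ImportanceRanking:
    """Regression RReliefF weights for every feature.

    Defaults follow the algorithm's common usage: all instances visited
    (``n_iterations=None`` means m = n, in which case the pass is
    sequential and the seed is inert), k = 10 neighbours, Manhattan
    distance on min–max-normalized features, uniform neighbour weights.
    Constant features receive weight exactly 0.
    """
    X, y, feats = _split_xy(table, features)
    n, p = X.shape
    if n <= k_neighbors:
        raise ValueError(f"need more samples ({n}) than neighbours "
                         f"({k_neighbors})")
    # min–max normalization; constant features flagged to stay at 0
    span = X.max(axis=0) - X.min(axis=0)
    constant = span == 0
    span_safe = np.where(constant, 1.0, span)
    Xn = (X - X.min(axis=0)) / span_safe
    Xn[:, constant] = 0.0
    y_span = y.max() - y.min()
    if y_span == 0:
        return ImportanceRanking("RReliefF", feats, np.zeros(p), seed)
    yn = (y - y.min()) / y_span

    if n_iterations is None or n_iterations >= n:
        visit = np.arange(n)
    else:
        visit = np.random.default_rng(seed).choice(n, size=n_iterations,
                                                   replace=False)
    m = len(visit)
    w = 1.0 / k_neighbors  # uniform neighbour weight
    n_dc = 0.0
    n_da = np.zeros(p)
    n_dcda = np.zeros(p)
    for i in visit:
        dist = np.abs(Xn - Xn[i]).sum(axis=1)
        dist[i] = np.inf
        nbrs = np.argsort(dist, kind="stable")[:k_neighbors]
        d_y = np.abs(yn[nbrs] - yn[i])  # prediction difference, in [0,1]
        d_f = np.abs(Xn[nbrs] - Xn[i])  # (k, p) feature differences
        n_dc += w * d_y.sum()
        n_da += w * d_f.sum(axis=0)
        n_dcda += w * (d_y[:, None] * d_f).sum(axis=0)
    total = m * k_neighbors * w  # = m with uniform weights
    if n_dc == 0 or total - n_dc == 0:
        weights = np.zeros(p)
    else:
        weights = n_dcda / n_dc - (n_da - n_dcda) / (total - n_dc)
    weights[constant] = 0.0
    return ImportanceRanking("RReliefF", feats, weights, seed)


# ---------------------------------------------------------------------------
# random-forest importances


def _classification_bins(y: np.ndarray, n_classes: int) -> np.ndarray:
    """Quantile-discretize a continuous target, shrinking if bins collapse."""
    binned = pd.qcut(y, n_classes, labels=False, duplicates="drop")
    actual = int(binned.max()) + 1
    if actual < n_classes:
        warnings.warn(
            f"quantile binning produced {actual} classes instead of "
            f"{n_classes} (duplicated quantiles)", UserWarning)
    return np.asarray(binned, dtype=int)


def rf_gini_importance(table: pd.DataFrame, n_trees: int = N_TREES,
                       n_classes: int = 4, seed: int = 0,
                       mode: str = "classification",
                       features: list[str] | None = None) -> ImportanceRanking:
    """Mean decrease in Gini impurity over a forest.

    ``mode="classification"`` (default) quantile-bins AGB into
    ``n_classes`` classes and grows a classification forest, matching the
    Gini purity criterion; ``mode="variance"`` grows a regression forest
    and reports its variance-reduction importance instead.
    """
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    X, y, feats = _split_xy(table, features)
    if len(y) < 10:
        raise ValueError("need at least 10 samples for forest importance")
    mf = max_features_per_split(X.shape[1])
    if mode == "classification":
        target = _classification_bins(y, n_classes)
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features=mf, min_samples_leaf=MIN_LEAF,
            random_state=seed, n_jobs=1)
    elif mode == "variance":
        target = y
        forest = RandomForestRegressor(
            n_estimators=n_trees, max_features=mf, min_samples_leaf=MIN_LEAF,
            random_state=seed, n_jobs=1)
    else:
        raise ValueError("mode must be 'classification' or 'variance'")
    forest.fit(X, target)
    return ImportanceRanking("RF-Gini", feats, forest.feature_importances_,
                             seed)


def rf_oob_importance(table: pd.DataFrame, n_trees: int = N_TREES,
                      seed: int = 0, corruption: str = "permute",
                      features: list[str] | None = None) -> ImportanceRanking:
    """Out-of-bag importance IMP_F = Σ(E2 − E1)/K of a regression forest.

    E1 is a tree's OOB mean squared error; E2 the error after corrupting
    one feature among that tree's OOB samples — by permutation (default)
    or by adding Gaussian noise at the feature's own standard deviation
    (``corruption="gaussian"``).  Trees with fewer than two OOB samples
    contribute 0 with a warning.
    """
    from sklearn.ensemble import RandomForestRegressor

    if corruption not in ("permute", "gaussian"):
        raise ValueError("corruption must be 'permute' or 'gaussian'")
    X, y, feats = _split_xy(table, features)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 samples for forest importance")
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=max_features_per_split(p),
        min_samples_leaf=MIN_LEAF, bootstrap=True, random_state=seed,
        n_jobs=1)
    forest.fit(X, y)
    rng = np.random.default_rng(seed)
    feature_sd = X.std(axis=0)
    imp = np.zeros(p)
    n_small = 0
    for tree, samples in zip(forest.estimators_,
                             forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), samples)
        if len(oob) < 2:
            n_small += 1
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        e1 = float(np.mean((y_oob - tree.predict(X_oob)) ** 2))
        # corrupt every feature at once, one stacked predict per tree
        stacked = np.tile(X_oob, (p, 1))
        for f in range(p):
            block = stacked[f * len(oob):(f + 1) * len(oob)]
            if corruption == "permute":
                block[:, f] = X_oob[rng.permutation(len(oob)), f]
            else:
                block[:, f] = X_oob[:, f] + rng.normal(
                    0.0, feature_sd[f], size=len(oob))
        preds = tree.predict(stacked).reshape(p, len(oob))
        e2 = np.mean((y_oob[None, :] - preds) ** 2, axis=1)
        imp += e2 - e1
    if n_small:
        warnings.warn(f"{n_small} trees had <2 OOB samples and contributed 0",
                      UserWarning)
    imp /= n_trees
    return ImportanceRanking("RF-OOB", feats, imp, seed)


# ---------------------------------------------------------------------------
# correlation screening


def correlation_screen(table: pd.DataFrame,
                       features: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation of each feature with AGB.

    Zero-variance features get r = 0 and are flagged; samples with missing
    feature values are excluded pairwise.
    """
    X, y, feats = _split_xy(table, features)
    if len(y) < 3:
        raise ValueError("need at least 3 samples for correlation screening")
    rows = []
    for i, name in enumerate(feats):
        x = X[:, i]
        ok = np.isfinite(x)
        flagged = False
        if ok.sum() < 2 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            r, flagged = 0.0, True
        else:
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        rows.append({"feature": name, "r": r, "zero_variance": flagged})
    return pd.DataFrame(rows)
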