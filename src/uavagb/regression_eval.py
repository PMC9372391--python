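"""Calibration/validation splitting, PLSR and RF regression, metrics,
and the seven-combination experiment grid.

Samples are plot × stage rows pooled across the three growth stages, split
2:1 into calibration and validation partitions stratified by stage.  Two
regressors are compared: partial least squares regression (PLSR, latent
component count chosen by 10-fold cross-validated RMSE, capped at 10) and
random forest regression (RFR, the same forest defaults the selection
module uses).  PLSR predictions are deliberately not clipped at zero so
that its characteristic negative predictions at low AGB stay observable.

Model quality is reported as R² = 1 − SS_res/SS_tot (which may go
negative on validation data), RMSE and MAE in g/m², and nRMSE = 100 ·
RMSE / mean(observed) in percent.

The four variable dimensions are SV (soil-free vegetation indices), TV
(GLCM textures of the screened band/direction), GV (canopy height and
FVC) and FDV (harmonic parameters).  The experiment grid evaluates every
combination of SV with at least one other dimension — seven in all — plus
the four selection settings (none, RReliefF, RF-Gini, RF-OOB) on the full
39-variable set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from uavagb.feature_selection import (
    MIN_LEAF,
    N_TREES,
    TARGET_COLUMN,
    ImportanceRanking,
    feature_columns,
    max_features_per_split,
    rf_gini_importance,
    rf_oob_importance,
    rrelieff,
    select_top,
)
from uavagb.frequency_features import harmonic_feature_names
from uavagb.spectral_features import VI_NAMES

DIMENSIONS: tuple[str, ...] = ("SV", "TV", "GV", "FDV")

SELECTION_METHODS: tuple[str, ...] = ("None", "RReliefF", "RF-Gini", "RF-OOB")

REGRESSIONS: tuple[str, ...] = ("PLSR", "RFR")


@dataclass(frozen=True)
class SplitSpec:
    """Calibration fraction, stratification column and seed."""

    ratio: float = 2.0 / 3.0
    stratify_by: str = "stage"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio < 1.0:
            raise ValueError("ratio must be in (0, 1)")


@dataclass
class EvalMetrics:
    """The four evaluation metrics of one model on one partition."""

    r2: float
    rmse: float
    mae: float
    nrmse: float


@dataclass
class EvalReport:
    """One row of the experiment grid."""

    selection: str
    regression: str
    combination: str
    partition: str  # "calibration" or "validation"
    metrics: EvalMetrics
    n_features: int

    def to_row(self) -> dict:
        return {
            "selection": self.selection, "regression": self.regression,
            "combination": self.combination, "partition": self.partition,
            "n_features": self.n_features, "R2": self.metrics.r2,
            "RMSE_g_m2": self.metrics.rmse, "MAE_g_m2": self.metrics.mae,
            "nRMSE_pct": self.metrics.nrmse,
        }


# ---------------------------------------------------------------------------
# splitting


def split(table: pd.DataFrame,
          spec: SplitSpec = SplitSpec()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, stratified calibration/validation partition."""
    from sklearn.model_selection import train_test_split

    if len(table) < 10:
        raise ValueError("need at least 10 samples to split")
    strata = table[spec.stratify_by]
    counts = strata.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"strata with <2 samples cannot be split: {bad}")
    cal_idx, val_idx = train_test_split(
        np.arange(len(table)), train_size=spec.ratio,
        stratify=strata.to_numpy(), random_state=spec.seed)
    return (table.iloc[np.sort(cal_idx)].reset_index(drop=True),
            table.iloc[np.sort(val_idx)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# models


@dataclass
class PLSRModel:
    """Fitted PLSR with its cross-validation-chosen component count."""

    model: object
    n_components: int
    features: list[str]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.features].to_numpy(dtype=np.float64)
        return np.asarray(self.model.predict(X)).ravel()


@dataclass
class RFRModel:
    """Fitted random-forest regressor."""

    model: object
    features: list[str]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.features].to_numpy(dtype=np.float64)
        return np.asarray(self.model.predict(X)).ravel()


def fit_plsr(calibration: pd.DataFrame, features: list[str],
             max_components: int = 10, cv_folds: int = 10,
             seed: int = 0) -> PLSRModel:
    """PLSR with component count chosen by cross-validated RMSE.

    Candidate counts run 1..min(10, p, n − 2); a singular feature block
    silently limits the usable count (scikit-learn caps the effective
    rank).  Predictions are not clipped at zero.
    """
    from sklearn.cross_decomposition import PLSRegression
    from sklearn.model_selection import KFold

    X = calibration[features].to_numpy(dtype=np.float64)
    y = calibration[TARGET_COLUMN].to_numpy(dtype=np.float64)
    n, p = X.shape
    if p < 1 or n < 4:
        raise ValueError("PLSR needs at least 1 feature and 4 samples")
    k_max = max(1, min(max_components, p, n - 2))
    folds = min(cv_folds, n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    best_k, best_rmse = 1, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(1, k_max + 1):
            sq = 0.0
            for tr, te in kf.split(X):
                m = PLSRegression(n_components=min(k, len(tr) - 1),
                                  scale=True)
                m.fit(X[tr], y[tr])
                pred = np.asarray(m.predict(X[te])).ravel()
                sq += float(((y[te] - pred) ** 2).sum())
            rmse = np.sqrt(sq / n)
            if rmse < best_rmse - 1e-12:
                best_rmse, best_k = rmse, k
        final = PLSRegression(n_components=best_k, scale=True)
        final.fit(X, y)
    return PLSRModel(model=final, n_components=best_k, features=list(features))


def fit_rfr(calibration: pd.DataFrame, features: list[str],
            seed: int = 0, n_trees: int = N_TREES) -> RFRModel:
    """Random-forest regression with the shared forest defaults."""
    from sklearn.ensemble import RandomForestRegressor

    X = calibration[features].to_numpy(dtype=np.float64)
    y = calibration[TARGET_COLUMN].to_numpy(dtype=np.float64)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=max_features_per_split(len(features)),
        min_samples_leaf=MIN_LEAF, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    return RFRModel(model=forest, features=list(features))


# ---------------------------------------------------------------------------
# metrics


def evaluate(observed: np.ndarray, predicted: np.ndarray) -> EvalMetrics:
    """R², RMSE, MAE and nRMSE of predictions against observations.

    R² = 1 − SS_res/SS_tot and may be negative for predictions worse than
    the observed mean; a constant observed vector yields R² = 0 by
    convention.  nRMSE is NaN when mean(observed) = 0.
    """
    o = np.asarray(observed, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    if o.size < 2:
        raise ValueError("need at least 2 samples to evaluate")
    ss_res = float(((o - p) ** 2).sum())
    ss_tot = float(((o - o.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / o.size))
    mae = float(np.abs(o - p).mean())
    nrmse = float("nan") if o.mean() == 0 else 100.0 * rmse / o.mean()
    return EvalMetrics(r2=r2, rmse=rmse, mae=mae, nrmse=nrmse)


# ---------------------------------------------------------------------------
# dimensions and combinations


def dimension_columns(table: pd.DataFrame) -> dict[str, list[str]]:
    """Map each variable dimension to its feature-table columns.

    SV: the six soil-free indices ``*_v``; TV: the ``TEX_*`` columns of
    the screened band/direction; GV: ``HEIGHT_m`` and ``FVC``; FDV: the 25
    harmonic parameters.
    """
    cols = set(table.columns)
    sv = [f"{n}_v" for n in VI_NAMES if f"{n}_v" in cols]
    tv = sorted(c for c in cols if c.startswith("TEX_"))
    gv = [c for c in ("HEIGHT_m", "FVC") if c in cols]
    fdv = [n for n in harmonic_feature_names() if n in cols]
    return {"SV": sv, "TV": tv, "GV": gv, "FDV": fdv}


def enumerate_combinations() -> list[tuple[str, tuple[str, ...]]]:
    """The seven dimension combinations: SV plus every non-empty subset of
    {TV, GV, FDV}, in increasing size then dimension order."""
    extras = ("TV", "GV", "FDV")
    combos: list[tuple[str, tuple[str, ...]]] = []
    for size in (1, 2, 3):
        import itertools

        for subset in itertools.combinations(extras, size):
            dims = ("SV",) + subset
            combos.append((" + ".join(dims), dims))
    return combos


# ---------------------------------------------------------------------------
# experiment driver


def _rank(method: str, table: pd.DataFrame, features: list[str],
          seed: int) -> ImportanceRanking | None:
    if method == "None":
        return None
    if method == "RReliefF":
        return rrelieff(table, seed=seed, features=features)
    if method == "RF-Gini":
        return rf_gini_importance(table, seed=seed, features=features)
    if method == "RF-OOB":
        return rf_oob_importance(table, seed=seed, features=features)
    raise ValueError(f"unknown selection method {method!r}")


def _fit_predict(regression: str, cal: pd.DataFrame, val: pd.DataFrame,
                 features: list[str], seed: int):
    if regression == "PLSR":
        model = fit_plsr(cal, features, seed=seed)
    elif regression == "RFR":
        model = fit_rfr(cal, features, seed=seed)
    else:
        raise ValueError(f"unknown regression {regression!r}")
    return model, model.predict(cal), model.predict(val)


def run_experiment(table: pd.DataFrame, spec: SplitSpec = SplitSpec(),
                   seed: int = 0, top_n: int = 10,
                   selection_methods: tuple[str, ...] = SELECTION_METHODS,
                   regressions: tuple[str, ...] = REGRESSIONS,
                   run_combinations: bool = True,
                   ) -> tuple[list[EvalReport], pd.DataFrame]:
    """Run the full selection × regression × combination grid.

    Part one ranks the complete candidate set with each selection method
    (rankings computed on the calibration partition only), keeps the top
    ``top_n`` features, and fits both regressors.  Part two, when
    ``run_combinations`` is set, repeats RF-OOB selection within each of
    the seven dimension combinations.  Returns the report rows plus an
    observed-vs-predicted table for residual diagnostics.
    """
    cal, val = split(table, spec)
    all_features = feature_columns(table)
    reports: list[EvalReport] = []
    pred_rows: list[pd.DataFrame] = []

    def record(selection: str, regression: str, combination: str,
               features: list[str]) -> None:
        _, pred_cal, pred_val = _fit_predict(regression, cal, val,
                                             features, seed)
        for part, sub, pred in (("calibration", cal, pred_cal),
                                ("validation", val, pred_val)):
            obs = sub[TARGET_COLUMN].to_numpy(dtype=np.float64)
            reports.append(EvalReport(
                selection=selection, regression=regression,
                combination=combination, partition=part,
                metrics=evaluate(obs, pred), n_features=len(features)))
            pred_rows.append(pd.DataFrame({
                "selection": selection, "regression": regression,
                "combination": combination, "partition": part,
                "plot_id": sub.get("plot_id", pd.Series(range(len(sub)))),
                "stage": sub.get("stage", pd.Series(["?"] * len(sub))),
                "observed": obs, "predicted": pred,
            }))

    for method in selection_methods:
        ranking = _rank(method, cal, all_features, seed)
        feats = all_features if ranking is None else select_top(ranking, top_n)
        for regression in regressions:
            record(method, regression, "all", feats)

    if run_combinations:
        dims = dimension_columns(table)
        for label, combo in enumerate_combinations():
            combo_features = [c for d in combo for c in dims[d]]
            ranking = rf_oob_importance(cal, seed=seed,
                                        features=combo_features)
            feats = select_top(ranking, top_n)
            for regression in regressions:
                record("RF-OOB", regression, label, feats)

    predictions = pd.concat(pred_rows, ignore_index=True)
    return reports, predictions


def reports_to_frame(reports: list[EvalReport]) -> pd.DataFrame:
    """Flatten report rows into the CSV/JSON column layout."""
    return pd.DataFrame([r.to_row() for r in reports])
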