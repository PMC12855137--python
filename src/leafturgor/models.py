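"""Predictive modeling of P_p from environment: combinations, techniques, metrics.

Four input/output combinations are compared: meteorological drivers only
(Rs, T, RH, WS, VPD) versus meteorology plus soil water content, each
predicting P_p either as one pooled series (whole-state) or with one
sub-model per diurnal state (substate, routed by the day's label). Three
regression techniques sit behind a uniform fit/predict contract: support
vector regression, gradient-boosted trees (XGBoost) and random forest.

Evaluation uses the standard regression metrics

    R^2  = 1 - sum((Y_i - y_i)^2) / sum((Y_i - Ybar)^2)
    MSE  = sum((Y_i - y_i)^2) / n
    RMSE = sqrt(MSE)
    MAE  = sum(|Y_i - y_i|) / n

with Y_i measured, y_i predicted. Substate reports pool the held-out
predictions of the per-state sub-models so all combinations are
comparable on the same rows.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .config import METEO_FACTORS

log = logging.getLogger(__name__)

TECHNIQUES = ("svm", "xgboost", "random_forest")


@dataclass(frozen=True)
class CombinationSpec:
    """One input/output combination of the model comparison."""

    id: int
    inputs: tuple[str, ...]
    output_mode: str  # {"whole_state", "substate"}


COMBINATIONS = {
    1: CombinationSpec(1, METEO_FACTORS, "whole_state"),
    2: CombinationSpec(2, METEO_FACTORS, "substate"),
    3: CombinationSpec(3, METEO_FACTORS + ("SWC",), "whole_state"),
    4: CombinationSpec(4, METEO_FACTORS + ("SWC",), "substate"),
}

#: Fixed, recorded hyperparameters (defaults) per technique.
HYPERPARAMS = {
    "svm": {"C": 10.0, "gamma": "scale", "epsilon": 0.1},
    "xgboost": {"n_estimators": 100, "max_depth": 6, "learning_rate": 0.3,
                "tree_method": "hist"},
    "random_forest": {"n_estimators": 300, "max_features": 1.0},
}

#: Small recorded grids for optional tuning (3-fold CV on the training split).
GRIDS = {
    "svm": {"svr__C": [1.0, 10.0, 100.0], "svr__epsilon": [0.05, 0.1, 0.5]},
    "xgboost": {"max_depth": [4, 6, 8], "learning_rate": [0.05, 0.1, 0.3]},
    "random_forest": {"n_estimators": [100, 200], "max_features": [1.0, "sqrt"]},
}

#: Kernel SVR scales quadratically with n; its training partition is
#: subsampled (seeded) to this many rows.
SVM_MAX_TRAIN = 3000


@dataclass
class MetricsReport:
    r2: float
    mse: float
    rmse: float
    mae: float
    n: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"r2": self.r2, "mse": self.mse, "rmse": self.rmse,
                "mae": self.mae, "n": self.n, "flags": self.flags}


def evaluate(measured, predicted) -> MetricsReport:
    """Compute R^2, MSE, RMSE and MAE of predictions against measurements.

    Requires equal-length vectors with n >= 2. Zero variance in the
    measured vector leaves R^2 undefined (NaN, flagged).
    """
    Y = np.asarray(measured, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if Y.shape != y.shape:
        raise ValueError(f"length mismatch: {Y.shape} vs {y.shape}")
    n = Y.size
    if n < 2:
        raise ValueError("at least two samples are required")
    sse = float(np.sum((Y - y) ** 2))
    sst = float(np.sum((Y - Y.mean()) ** 2))
    mse = sse / n
    report = MetricsReport(
        r2=1.0 - sse / sst if sst > 0 else float("nan"),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(Y - y))),
        n=int(n),
    )
    if sst == 0:
        report.flags.append("zero_variance_measured")
    return report


def build_feature_table(
    dataset: pd.DataFrame, day_labels: pd.DataFrame, spec: CombinationSpec
) -> pd.DataFrame:
    """Restrict the merged dataset to a combination's inputs plus metadata.

    Rows carry their day's state (so substate sub-models can be routed),
    date and treatment; rows from unclassifiable days are dropped and
    logged. Requesting an input column absent from the dataset raises.
    """
    missing = [c for c in spec.inputs if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset lacks requested input columns {missing}")
    labels = day_labels.copy()
    labels["date"] = pd.to_datetime(labels["date"]).dt.normalize()
    state_map = labels.set_index("date")["state"]

    table = dataset.copy()
    table["date"] = pd.to_datetime(table["timestamp"]).dt.normalize()
    table["state"] = table["date"].map(state_map)
    bad = table["state"].isna()
    if bad.any():
        log.info(
            "build_feature_table: dropping %d rows from %d unclassifiable/unlabeled days",
            int(bad.sum()),
            table.loc[bad, "date"].nunique(),
        )
        table = table.loc[~bad]
    keep = list(spec.inputs) + ["P_p", "state", "date"]
    if "treatment" in table.columns:
        keep.append("treatment")
    return table[keep].reset_index(drop=True)


def split_train_test(
    table: pd.DataFrame, fraction: float = 0.8, seed: int = 0, stratify: bool | None = None
) -> pd.DataFrame:
    """Seeded uniform random row split into train (``fraction``) and test.

    Returns a copy with a ``split`` column. Stratifies by day state when
    requested (default: whenever more than one state is present), keeping
    each state's 80/20 proportion within one row.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"train fraction must lie in (0, 1); got {fraction}")
    if len(table) < 10:
        raise ValueError("at least 10 rows are required for a split")
    if stratify is None:
        stratify = table["state"].nunique() > 1
    strat = table["state"] if stratify else None
    train_idx, test_idx = train_test_split(
        table.index.to_numpy(),
        train_size=fraction,
        random_state=seed % 2**31,
        stratify=strat,
    )
    out = table.copy()
    out["split"] = "test"
    out.loc[train_idx, "split"] = "train"
    return out


def make_estimator(technique: str, seed: int = 0, tune: bool = False):
    """Construct one regressor behind the uniform fit/predict contract."""
    rs = seed % 2**31
    if technique == "svm":
        est = Pipeline(
            [("scale", StandardScaler()), ("svr", SVR(**HYPERPARAMS["svm"]))]
        )
    elif technique == "xgboost":
        est = XGBRegressor(**HYPERPARAMS["xgboost"], random_state=rs, n_jobs=1)
    elif technique == "random_forest":
        est = RandomForestRegressor(
            **HYPERPARAMS["random_forest"], random_state=rs, n_jobs=1
        )
    else:
        raise ValueError(f"unknown technique {technique!r}; expected {TECHNIQUES}")
    if tune:
        est = GridSearchCV(est, GRIDS[technique], cv=3, n_jobs=1)
    return est


class TurgorPredictor:
    """A fitted P_p predictor: one estimator, or one per diurnal state.

    In substate mode prediction is routed by each row's ``state``
    annotation. Hyperparameters, seed and the combination spec are
    recorded on the instance.
    """

    def __init__(self, technique: str, spec: CombinationSpec, seed: int = 0,
                 tune: bool = False):
        self.technique = technique
        self.spec = spec
        self.seed = seed
        self.tune = tune
        self.hyperparams = dict(HYPERPARAMS[technique])
        self.models: dict[str, object] = {}

    def _fit_one(self, key: str, X: pd.DataFrame, y: np.ndarray) -> None:
        if np.std(y) == 0.0:
            warnings.warn(
                f"degenerate training target for state {key!r}; using a "
                "constant predictor",
                stacklevel=2,
            )
            model = DummyRegressor(strategy="mean")
        else:
            model = make_estimator(self.technique, seed=self.seed, tune=self.tune)
            if self.technique == "svm" and len(X) > SVM_MAX_TRAIN:
                rng = np.random.default_rng(self.seed)
                idx = rng.choice(len(X), size=SVM_MAX_TRAIN, replace=False)
                X, y = X.iloc[idx], y[idx]
        model.fit(X, y)
        self.models[key] = model

    def fit(self, table: pd.DataFrame) -> "TurgorPredictor":
        train = table.loc[table["split"] == "train"] if "split" in table else table
        if train.empty:
            raise ValueError("empty training partition")
        X = train[list(self.spec.inputs)]
        y = train["P_p"].to_numpy(dtype=float)
        if self.spec.output_mode == "substate":
            for state, group in train.groupby("state"):
                self._fit_one(
                    str(state),
                    group[list(self.spec.inputs)],
                    group["P_p"].to_numpy(dtype=float),
                )
        else:
            self._fit_one("pooled", X, y)
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.spec.inputs)]
        if self.spec.output_mode != "substate":
            return np.asarray(self.models["pooled"].predict(X), dtype=float)
        out = np.full(len(table), np.nan)
        for state, group in table.groupby("state"):
            key = str(state)
            if key not in self.models:
                raise ValueError(
                    f"no sub-model for state {key!r}; trained states: "
                    f"{sorted(self.models)}"
                )
            out[table.index.get_indexer(group.index)] = self.models[key].predict(
                group[list(self.spec.inputs)]
            )
        return out


def train(
    technique: str,
    table: pd.DataFrame,
    spec: CombinationSpec,
    seed: int = 0,
    tune: bool = False,
) -> TurgorPredictor:
    """Fit one technique on the training partition of a feature table."""
    return TurgorPredictor(technique, spec, seed=seed, tune=tune).fit(table)


def feature_importance(
    predictor: TurgorPredictor,
    table: pd.DataFrame | None = None,
    seed: int = 0,
) -> dict[str, pd.Series]:
    """Normalized feature importances per sub-model, descending.

    Tree ensembles expose native impurity importances; support-vector
    models fall back to permutation importance on the held-out partition
    (labelled via the series name ``permutation``). Importances are
    normalized to sum to 1.
    """
    out = {}
    features = list(predictor.spec.inputs)
    for key, model in predictor.models.items():
        raw = getattr(model, "best_estimator_", model)
        if hasattr(raw, "feature_importances_"):
            values = np.asarray(raw.feature_importances_, dtype=float)
            name = "impurity"
        else:
            if table is None:
                raise ValueError(
                    "permutation importance needs the evaluation table for "
                    f"technique {predictor.technique!r}"
                )
            rows = table.loc[table.get("split", "test") == "test"]
            if predictor.spec.output_mode == "substate":
                rows = rows.loc[rows["state"] == key]
            perm = permutation_importance(
                model,
                rows[features],
                rows["P_p"].to_numpy(dtype=float),
                n_repeats=5,
                random_state=seed % 2**31,
            )
            values = np.abs(perm.importances_mean)
            name = "permutation"
        total = values.sum()
        values = values / total if total > 0 else values
        out[key] = pd.Series(values, index=features, name=name).sort_values(
            ascending=False
        )
    return out


@dataclass
class ModelReport:
    technique: str
    combination: int
    treatment: str
    metrics: MetricsReport
    per_state: dict[str, MetricsReport] = field(default_factory=dict)
    importance: dict | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "technique": self.technique,
            "combination": self.combination,
            "treatment": self.treatment,
            "metrics": self.metrics.to_dict() if self.metrics else None,
            "per_state": {k: v.to_dict() for k, v in self.per_state.items()},
            "importance": {
                k: {f: float(x) for f, x in v.items()}
                for k, v in (self.importance or {}).items()
            }
            or None,
            "error": self.error,
        }


def fit_and_report(
    dataset: pd.DataFrame,
    day_labels: pd.DataFrame,
    combination: int,
    technique: str,
    treatment: str = "all",
    seed: int = 0,
    tune: bool = False,
    with_importance: bool = False,
) -> ModelReport:
    """Build features, split, fit and evaluate one configuration.

    Metrics are computed on the held-out partition; substate metrics are
    pooled over the union of per-state held-out predictions, with
    per-state reports alongside.
    """
    spec = COMBINATIONS[combination]
    table = build_feature_table(dataset, day_labels, spec)
    table = split_train_test(table, seed=seed)
    predictor = train(technique, table, spec, seed=seed, tune=tune)
    test = table.loc[table["split"] == "test"]
    predicted = predictor.predict(test)
    report = ModelReport(
        technique=technique,
        combination=combination,
        treatment=treatment,
        metrics=evaluate(test["P_p"].to_numpy(dtype=float), predicted),
    )
    if spec.output_mode == "substate":
        for state, group in test.groupby("state"):
            report.per_state[str(state)] = evaluate(
                group["P_p"].to_numpy(dtype=float),
                predictor.predict(group),
            )
    if with_importance and technique in ("xgboost", "random_forest"):
        report.importance = {
            k: v.to_dict() for k, v in feature_importance(predictor, table).items()
        }
    return report


def run_experiment_matrix(
    dataset: pd.DataFrame,
    day_labels: pd.DataFrame,
    seed: int = 0,
    techniques=TECHNIQUES,
    combinations=(1, 2, 3, 4),
    per_treatment: bool = True,
    tune: bool = False,
) -> tuple[list[ModelReport], pd.DataFrame]:
    """The full technique x combination (x treatment) comparison.

    Each configuration is fitted and scored on its held-out partition;
    individual failures are recorded in their report and do not abort the
    matrix. Returns the reports and a summary table ranked by test R^2.
    """
    if per_treatment and "treatment" in dataset.columns:
        groups = [(t, d) for t, d in dataset.groupby("treatment")]
    else:
        groups = [("all", dataset)]
    reports: list[ModelReport] = []
    for treatment, data in groups:
        labels = day_labels
        if per_treatment and "treatment" in day_labels.columns and treatment != "all":
            labels = day_labels.loc[day_labels["treatment"] == treatment]
        for combination in combinations:
            for technique in techniques:
                try:
                    reports.append(
                        fit_and_report(
                            data, labels, combination, technique,
                            treatment=str(treatment), seed=seed, tune=tune,
                        )
                    )
                except Exception as exc:  # recorded, never aborts the matrix
                    log.warning(
                        "matrix: %s/comb%s/%s failed: %s",
                        technique, combination, treatment, exc,
                    )
                    reports.append(
                        ModelReport(
                            technique=technique,
                            combination=combination,
                            treatment=str(treatment),
                            metrics=None,
                            error=str(exc),
                        )
                    )
    rows = [
        {
            "treatment": r.treatment,
            "combination": r.combination,
            "technique": r.technique,
            "r2": r.metrics.r2 if r.metrics else float("nan"),
            "mse": r.metrics.mse if r.metrics else float("nan"),
            "rmse": r.metrics.rmse if r.metrics else float("nan"),
            "mae": r.metrics.mae if r.metrics else float("nan"),
            "n_test": r.metrics.n if r.metrics else 0,
            "error": r.error or "",
        }
        for r in reports
    ]
    summary = (
        pd.DataFrame(rows)
        .sort_values("r2", ascending=False)
        .reset_index(drop=True)
    )
    return reports, summary


def benchmark_pooled_metrics(
    seasons: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    labels: dict[str, pd.DataFrame],
    combination: int = 4,
    technique: str = "random_forest",
    seed: int = 0,
) -> tuple[MetricsReport, dict[str, ModelReport]]:
    """Fit one per-treatment model per season and pool held-out predictions.

    The pooled metrics (over the union of every season's held-out rows,
    each predicted by its own treatment's model) are the benchmark's
    headline accuracy figures.
    """
    spec = COMBINATIONS[combination]
    measured, predicted = [], []
    reports = {}
    for i, (name, (dataset, _truth)) in enumerate(sorted(seasons.items())):
        table = build_feature_table(dataset, labels[name], spec)
        table = split_train_test(table, seed=seed + i)
        predictor = train(technique, table, spec, seed=seed + i)
        test = table.loc[table["split"] == "test"]
        pred = predictor.predict(test)
        measured.append(test["P_p"].to_numpy(dtype=float))
        predicted.append(pred)
        reports[name] = ModelReport(
            technique=technique,
            combination=combination,
            treatment=name,
            metrics=evaluate(test["P_p"].to_numpy(dtype=float), pred),
        )
    pooled = evaluate(np.concatenate(measured), np.concatenate(predicted))
    return pooled, reports
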