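"""Classifier comparison, tuning and repeated held-out evaluation.

The decoding question is neuron-by-neuron: can a classifier tell a neuron's
rewarded-condition feature row from its nonrewarded-condition row?  The
protocol per region:

* stratified 80/20 train/test split, repeated over random seeds (default 3);
* (optional) architecture comparison by stratified 10-fold CV on the train
  split, with the preprocessing cascade refit inside every fold;
* randomised hyperparameter tuning (default 20 candidates, stratified 5-fold
  CV); if no candidate beats the default configuration the default is kept;
* final fit on the full (preprocessed, minority-oversampled) train split and
  evaluation on the untouched test split: accuracy at probability 0.5 and AUC
  by the rank statistic (concordant-pair fraction, ties counted half).

The default roster holds three gradient-boosted tree variants (LightGBM,
XGBoost, sklearn GradientBoosting) plus classical baselines and a
label-frequency dummy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from xgboost import XGBClassifier

from .preprocess import apply_cascade, fit_cascade, oversample_minority
from .spike_features import FEATURE_NAMES

__all__ = [
    "SplitSpec",
    "ModelEval",
    "ComparisonTable",
    "ARCHITECTURES",
    "GBT_ROSTER",
    "DEFAULT_ROSTER",
    "make_model",
    "split_data",
    "compare_models",
    "tune_model",
    "evaluate",
    "run_repeats",
    "rank_auc",
    "roc_points",
    "summarize_evals",
]


# ---------------------------------------------------------------------------
# Architecture registry
# ---------------------------------------------------------------------------

def _lgbm(seed: int, **p) -> LGBMClassifier:
    return LGBMClassifier(
        random_state=seed, n_jobs=1, deterministic=True, force_row_wise=True,
        verbose=-1, **p,
    )


def _xgb(seed: int, **p) -> XGBClassifier:
    return XGBClassifier(
        random_state=seed, n_jobs=1, eval_metric="logloss", **p
    )


def _gbt(seed: int, **p) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(random_state=seed, **p)


# hyperparameter grids are fixed, documented artifact choices; values are
# sampled uniformly from each list by the tuning seed
ARCHITECTURES: dict[str, dict] = {
    "lightgbm": {
        "factory": _lgbm,
        "grid": {
            "n_estimators": [50, 100, 200, 400],
            "learning_rate": [0.01, 0.03, 0.1, 0.3],
            "num_leaves": [7, 15, 31],
            "min_child_samples": [5, 10, 20, 40],
            "subsample": [0.6, 0.8, 1.0],
            "colsample_bytree": [0.6, 0.8, 1.0],
        },
    },
    "xgboost": {
        "factory": _xgb,
        "grid": {
            "n_estimators": [50, 100, 200, 400],
            "learning_rate": [0.01, 0.03, 0.1, 0.3],
            "max_depth": [2, 3, 4, 6],
            "min_child_weight": [1, 3, 5],
            "subsample": [0.6, 0.8, 1.0],
            "colsample_bytree": [0.6, 0.8, 1.0],
        },
    },
    "gbt": {
        "factory": _gbt,
        "grid": {
            "n_estimators": [50, 100, 200],
            "learning_rate": [0.01, 0.03, 0.1, 0.3],
            "max_depth": [1, 2, 3, 4],
            "subsample": [0.6, 0.8, 1.0],
        },
    },
    "logreg": {
        "factory": lambda seed, **p: LogisticRegression(max_iter=2000, **p),
        "grid": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    },
    "lda": {
        "factory": lambda seed, **p: LinearDiscriminantAnalysis(**p),
        "grid": {},
    },
    "rf": {
        "factory": lambda seed, **p: RandomForestClassifier(
            random_state=seed, n_jobs=1, **p
        ),
        "grid": {
            "n_estimators": [100, 200, 400],
            "max_depth": [None, 4, 8],
            "min_samples_leaf": [1, 2, 5],
        },
    },
    "knn": {
        "factory": lambda seed, **p: KNeighborsClassifier(**p),
        "grid": {"n_neighbors": [3, 5, 9, 15]},
    },
    "nb": {"factory": lambda seed, **p: GaussianNB(**p), "grid": {}},
    "dummy": {
        "factory": lambda seed, **p: DummyClassifier(
            strategy="stratified", random_state=seed
        ),
        "grid": {},
    },
}

GBT_ROSTER = ("lightgbm", "xgboost", "gbt")
DEFAULT_ROSTER = GBT_ROSTER + ("logreg", "lda", "rf", "knn", "nb", "dummy")


def make_model(architecture: str, seed: int, params: Mapping | None = None):
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    return ARCHITECTURES[architecture]["factory"](seed, **dict(params or {}))


def _sample_params(grid: Mapping[str, list], rng: np.random.Generator) -> dict:
    return {k: v[rng.integers(0, len(v))] for k, v in grid.items()}


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.20
    seeds: tuple[int, ...] = (0, 1, 2)


def split_data(
    matrix: pd.DataFrame, seed: int, test_fraction: float = 0.20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split on the ``label`` column; deterministic."""
    y = matrix["label"].to_numpy()
    if min(np.bincount(y)) < 5:
        raise ValueError("each class needs at least 5 rows to stratify a split")
    train, test = train_test_split(
        matrix, test_size=test_fraction, stratify=y, random_state=seed
    )
    return train, test


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rank_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the concordant-pair fraction (Mann-Whitney), ties = 0.5.

    NaN when the test rows hold a single class.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        return float("nan")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """ROC curve (fpr, tpr) from score thresholds, endpoints included."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n1 = y.sum()
    n0 = y.size - n1
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # collapse runs of equal scores to one operating point
    last_of_run = np.r_[np.diff(s) != 0, True]
    tpr = np.r_[0.0, tps[last_of_run] / max(n1, 1)]
    fpr = np.r_[0.0, fps[last_of_run] / max(n0, 1)]
    return np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# Evaluation containers
# ---------------------------------------------------------------------------

@dataclass
class ModelEval:
    """Held-out evaluation of one region x architecture x repeat."""

    region: str
    architecture: str
    repeat: int
    accuracy: float
    auc: float
    roc: np.ndarray
    probabilities: np.ndarray
    y_true: np.ndarray
    predictions: np.ndarray
    params: dict = field(default_factory=dict)
    model: object = None
    state: object = None  # fitted PreprocessState
    test_index: np.ndarray | None = None


@dataclass
class ComparisonTable:
    """Mean/SD CV accuracy per architecture over stratified 10-fold."""

    table: pd.DataFrame  # columns: architecture, mean_accuracy, sd_accuracy, failed

    @property
    def ranking(self) -> list[str]:
        ok = self.table[~self.table["failed"]]
        return list(ok.sort_values("mean_accuracy", ascending=False)["architecture"])


# ---------------------------------------------------------------------------
# Cross-validated helpers
# ---------------------------------------------------------------------------

def _feature_frame(df: pd.DataFrame) -> pd.DataFrame:
    return df[[c for c in FEATURE_NAMES if c in df.columns]]


def _cv_accuracy(
    train: pd.DataFrame,
    architecture: str,
    params: Mapping | None,
    folds: int,
    seed: int,
    use_smote: bool = True,
) -> float:
    """Mean validation accuracy with the cascade refit inside every fold."""
    y = train["label"].to_numpy()
    X_raw = _feature_frame(train)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for k, (tr, va) in enumerate(skf.split(X_raw, y)):
        state = fit_cascade(X_raw.iloc[tr], y[tr], seed=seed)
        X_tr = apply_cascade(state, X_raw.iloc[tr])
        X_va = apply_cascade(state, X_raw.iloc[va])
        y_tr = y[tr]
        if use_smote and np.unique(y_tr).size == 2:
            X_tr, y_tr = oversample_minority(X_tr, y_tr, seed=seed + k)
        model = make_model(architecture, seed, params)
        model.fit(X_tr, y_tr)
        pred = model.predict(X_va)
        accs.append(float(np.mean(pred == y[va])))
    return float(np.mean(accs))


def compare_models(
    train: pd.DataFrame,
    roster: Sequence[str] = DEFAULT_ROSTER,
    seed: int = 0,
    folds: int = 10,
) -> ComparisonTable:
    """Rank candidate architectures by stratified k-fold CV accuracy."""
    if not roster:
        raise ValueError("empty roster")
    y = train["label"].to_numpy()
    X_raw = _feature_frame(train)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for arch in roster:
        fold_accs = []
        failed = False
        try:
            for k, (tr, va) in enumerate(skf.split(X_raw, y)):
                state = fit_cascade(X_raw.iloc[tr], y[tr], seed=seed)
                X_tr = apply_cascade(state, X_raw.iloc[tr])
                X_va = apply_cascade(state, X_raw.iloc[va])
                y_tr = y[tr]
                if np.unique(y_tr).size == 2:
                    X_tr, y_tr = oversample_minority(X_tr, y_tr, seed=seed + k)
                model = make_model(arch, seed)
                model.fit(X_tr, y_tr)
                fold_accs.append(
                    float(np.mean(model.predict(X_va) == y[va]))
                )
        except Exception:
            failed = True
        rows.append(
            {
                "architecture": arch,
                "mean_accuracy": float(np.mean(fold_accs)) if fold_accs else float("nan"),
                "sd_accuracy": float(np.std(fold_accs, ddof=1)) if len(fold_accs) > 1 else float("nan"),
                "failed": failed,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "mean_accuracy", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return ComparisonTable(table=table)


def tune_model(
    train: pd.DataFrame,
    architecture: str,
    n_iter: int = 20,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Randomised hyperparameter search; keeps the default if nothing improves.

    Returns the chosen parameter dict ({} = default configuration).
    """
    grid = ARCHITECTURES[architecture]["grid"]
    if n_iter <= 0 or not grid:
        return {}
    rng = np.random.default_rng(seed)
    best_params: dict = {}
    best_score = _cv_accuracy(train, architecture, None, folds, seed)
    for _ in range(n_iter):
        cand = _sample_params(grid, rng)
        score = _cv_accuracy(train, architecture, cand, folds, seed)
        if score > best_score:
            best_score, best_params = score, cand
    return best_params


def evaluate(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    *,
    region: str = "",
    architecture: str = "",
    repeat: int = 0,
    params: Mapping | None = None,
    state=None,
    test_index=None,
) -> ModelEval:
    """Score a fitted model on transformed test rows."""
    proba = np.asarray(model.predict_proba(X_test))[:, 1]
    pred = (proba >= 0.5).astype(int)
    acc = float(np.mean(pred == y_test))
    return ModelEval(
        region=region,
        architecture=architecture,
        repeat=repeat,
        accuracy=acc,
        auc=rank_auc(proba, y_test),
        roc=roc_points(proba, y_test),
        probabilities=proba,
        y_true=np.asarray(y_test, dtype=int),
        predictions=pred,
        params=dict(params or {}),
        model=model,
        state=state,
        test_index=np.asarray(test_index) if test_index is not None else None,
    )


def run_repeats(
    matrix: pd.DataFrame,
    architectures: Sequence[str] = GBT_ROSTER,
    seeds: Sequence[int] = (0, 1, 2),
    n_iter: int = 20,
    tune_folds: int = 5,
    region: str = "",
) -> list[ModelEval]:
    """Full split -> tune -> fit -> evaluate cycle per seed x architecture.

    Each repeat draws its own stratified 80/20 split; tuning and preprocessing
    see only the train part, and evaluation rows are never used in fitting.
    """
    evals: list[ModelEval] = []
    region = region or (matrix["region"].iloc[0] if "region" in matrix else "")
    for repeat, seed in enumerate(seeds):
        train, test = split_data(matrix, seed=seed)
        y_tr_all = train["label"].to_numpy()
        y_te = test["label"].to_numpy()
        for arch in architectures:
            params = tune_model(train, arch, n_iter=n_iter, folds=tune_folds, seed=seed)
            state = fit_cascade(_feature_frame(train), y_tr_all, seed=seed)
            X_tr = apply_cascade(state, _feature_frame(train))
            X_te = apply_cascade(state, _feature_frame(test))
            y_tr = y_tr_all
            if np.unique(y_tr).size == 2:
                X_tr, y_tr = oversample_minority(X_tr, y_tr, seed=seed)
            model = make_model(arch, seed, params)
            model.fit(X_tr, y_tr)
            evals.append(
                evaluate(
                    model,
                    X_te,
                    y_te,
                    region=region,
                    architecture=arch,
                    repeat=repeat,
                    params=params,
                    state=state,
                    test_index=test.index.to_numpy(),
                )
            )
    return evals


def summarize_evals(evals: Sequence[ModelEval]) -> pd.DataFrame:
    """Mean/SD accuracy and AUC per region x architecture across repeats."""
    df = pd.DataFrame(
        [
            {
                "region": e.region,
                "architecture": e.architecture,
                "repeat": e.repeat,
                "accuracy": e.accuracy,
                "auc": e.auc,
            }
            for e in evals
        ]
    )
    return (
        df.groupby(["region", "architecture"], sort=True)
        .agg(
            mean_accuracy=("accuracy", "mean"),
            sd_accuracy=("accuracy", "std"),
            mean_auc=("auc", "mean"),
            sd_auc=("auc", "std"),
            n_repeats=("repeat", "count"),
        )
        .reset_index()
    )
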