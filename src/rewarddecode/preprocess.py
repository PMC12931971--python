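"""Train-split-fitted preprocessing cascade for the decoding dataset.

Order of operations, all fitted on the training split only and replayed on
held-out rows from stored statistics (no test-set leakage):

1. mean imputation of missing features;
2. z-score standardisation (training mean/SD; zero-variance features dropped);
3. collinearity pruning: of any pair with |Pearson r| > 0.80, drop the feature
   less correlated (point-biserial) with the outcome label;
4. importance-based selection: keep the top 20% of features ranked by the
   split-gain importance of a gradient-boosted tree ensemble;
5. minority-class oversampling by nearest-neighbour interpolation (SMOTE),
   applied to training data only, never to evaluation rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "PreprocessState",
    "fit_impute_scale",
    "transform",
    "prune_collinear",
    "oversample_minority",
    "select_features",
    "fit_cascade",
    "apply_cascade",
]


@dataclass
class PreprocessState:
    """Fitted statistics of the cascade; sufficient to transform new rows."""

    feature_names: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    dropped: dict[str, str] = field(default_factory=dict)  # name -> reason
    retained: list[str] | None = None  # after pruning + selection

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "feature_names": self.feature_names,
                    "means": self.means,
                    "sds": self.sds,
                    "dropped": self.dropped,
                    "retained": self.retained,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path) -> "PreprocessState":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(**d)


def fit_impute_scale(train: pd.DataFrame) -> PreprocessState:
    """Fit mean imputation + z-scoring on the training feature columns.

    All-missing features and zero-variance (post-imputation) features are
    dropped with a recorded reason.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training rows")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    dropped: dict[str, str] = {}
    kept: list[str] = []
    for col in train.columns:
        x = train[col].to_numpy(dtype=float)
        obs = x[np.isfinite(x)]
        if obs.size == 0:
            dropped[col] = "all values missing in training split"
            continue
        m = float(obs.mean())
        filled = np.where(np.isfinite(x), x, m)
        sd = float(filled.std(ddof=0))
        if sd == 0:
            dropped[col] = "zero variance in training split"
            continue
        means[col] = m
        sds[col] = sd
        kept.append(col)
    return PreprocessState(feature_names=kept, means=means, sds=sds, dropped=dropped)


def transform(state: PreprocessState, data: pd.DataFrame) -> pd.DataFrame:
    """Impute + z-score rows using training statistics only."""
    cols = state.retained if state.retained is not None else state.feature_names
    out = {}
    for col in cols:
        x = data[col].to_numpy(dtype=float)
        x = np.where(np.isfinite(x), x, state.means[col])
        out[col] = (x - state.means[col]) / state.sds[col]
    return pd.DataFrame(out, index=data.index)


def prune_collinear(
    train: pd.DataFrame,
    labels: Sequence[int],
    threshold: float = 0.80,
) -> list[str]:
    """Greedy collinearity pruning at |Pearson r| > threshold (strict).

    Pairs are visited in descending |r|; from each still-intact pair the
    feature with the lower |point-biserial correlation| to the label is
    removed (ties: the lexicographically later name goes).  Returns the
    surviving feature names in original column order.
    """
    cols = list(train.columns)
    X = train.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
        label_corr = np.array(
            [abs(_pearson(X[:, j], y)) for j in range(X.shape[1])]
        )
    corr = np.nan_to_num(corr, nan=0.0)
    label_corr = np.nan_to_num(label_corr, nan=0.0)

    # strict inequality at the threshold, with a float-rounding guard so a
    # pair constructed at exactly |r| = threshold is kept
    pairs = [
        (abs(corr[i, j]), i, j)
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if abs(corr[i, j]) > threshold + 1e-12
    ]
    pairs.sort(key=lambda t: (-t[0], cols[t[1]], cols[t[2]]))
    removed: set[int] = set()
    for _, i, j in pairs:
        if i in removed or j in removed:
            continue
        li, lj = label_corr[i], label_corr[j]
        if li > lj:
            removed.add(j)
        elif lj > li:
            removed.add(i)
        else:
            removed.add(i if cols[i] > cols[j] else j)
    return [c for k, c in enumerate(cols) if k not in removed]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom) if denom > 0 else 0.0


def oversample_minority(
    train: pd.DataFrame,
    labels: Sequence[int],
    k: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """SMOTE: balance classes by interpolating between near minority rows.

    Each synthetic row is x + u * (x_nn - x) with u ~ Uniform(0, 1) and x_nn
    one of the k nearest minority neighbours of x.  Original rows are never
    altered.  Requires at least two minority rows.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("oversampling requires exactly two classes present")
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return train.copy(), y.copy()
    Xm = train.to_numpy(dtype=float)[y == minority]
    if Xm.shape[0] < 2:
        raise ValueError(
            "fewer than 2 minority rows; enable a random-duplication fallback "
            "upstream if this dataset must be used"
        )
    k_eff = min(k, Xm.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # idx[:, 0] is the point itself
    base = rng.integers(0, Xm.shape[0], size=n_needed)
    pick = rng.integers(1, k_eff + 1, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    neighbours = Xm[idx[base, pick]]
    synthetic = Xm[base] + u[:, None] * (neighbours - Xm[base])
    X_aug = pd.DataFrame(
        np.vstack([train.to_numpy(dtype=float), synthetic]), columns=train.columns
    )
    y_aug = np.concatenate([y, np.full(n_needed, minority)])
    return X_aug, y_aug


def select_features(
    train: pd.DataFrame,
    labels: Sequence[int],
    fraction: float = 0.20,
    seed: int = 0,
) -> list[str]:
    """Keep the top fraction of features by gradient-boosted split-gain.

    A LightGBM classifier is fit on the training split; features are ranked by
    gain importance and the top ceil(fraction x n_features) survive (ceil so
    the selection is never empty).  Deterministic under the seed.
    """
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("feature selection needs both classes present")
    if train.shape[1] < 5:
        raise ValueError("need at least 5 features to select from")
    model = LGBMClassifier(
        n_estimators=100,
        random_state=seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbose=-1,
        importance_type="gain",
    )
    model.fit(train.to_numpy(dtype=float), y)
    gains = model.feature_importances_
    n_keep = math.ceil(fraction * train.shape[1])
    # stable ranking: gain descending, then column order
    order = sorted(range(train.shape[1]), key=lambda j: (-gains[j], j))
    keep = sorted(order[:n_keep])
    return [train.columns[j] for j in keep]


def fit_cascade(
    train: pd.DataFrame,
    labels: Sequence[int],
    *,
    collinear_threshold: float = 0.80,
    select_fraction: float = 0.20,
    seed: int = 0,
) -> PreprocessState:
    """Fit the full impute -> scale -> prune -> select cascade on a training split."""
    state = fit_impute_scale(train)
    z = transform(state, train)
    survivors = prune_collinear(z, labels, collinear_threshold)
    for col in state.feature_names:
        if col not in survivors:
            state.dropped[col] = "collinear with a better-correlated feature"
    z = z[survivors]
    retained = select_features(z, labels, select_fraction, seed)
    for col in survivors:
        if col not in retained:
            state.dropped.setdefault(col, "below importance-selection cutoff")
    state.retained = retained
    return state


def apply_cascade(state: PreprocessState, data: pd.DataFrame) -> pd.DataFrame:
    """Transform any rows with a fitted cascade (training statistics only)."""
    return transform(state, data)
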