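"""Shapley-value interpretation of the fitted decoders.

Attributions are computed in margin (log-odds) units: for every test row the
base value E[f(X)] plus the per-feature attributions sums to the model's raw
output f(x) (additivity).  For LightGBM and XGBoost models the attributions
come from the libraries' built-in exact path-dependent tree Shapley
(``pred_contrib``); for sklearn gradient-boosted trees an exact per-tree
Shapley is computed here by enumerating feature subsets against the
cover-weighted conditional expectation of each tree (trees are additive, so
the ensemble attribution is the sum of per-tree attributions).

Downstream summaries follow the analysis protocol: per-repeat rankings by
mean |attribution|, the cross-repeat consistent top-k set, predicted
probability distribution summaries per region, and a coding-strategy report
tagging the consistent features by category (fundamental / timing / rate)
and epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import GradientBoostingClassifier
from xgboost import XGBClassifier

from .decode import ModelEval
from .spike_features import feature_schema

__all__ = [
    "ShapAttribution",
    "FeatureRanking",
    "attribute",
    "rank_features",
    "select_best_instance",
    "probability_summary",
    "strategy_report",
]


@dataclass(frozen=True)
class ShapAttribution:
    """Per-row, per-feature margin attributions with additivity guarantee."""

    feature_names: tuple[str, ...]
    values: np.ndarray       # (n_rows, n_features), log-odds units
    base_value: float        # E[f(X)] in log-odds
    fx: np.ndarray           # per-row model margin output

    def additivity_gap(self) -> float:
        """Max |base + sum(attributions) - f(x)| over rows."""
        return float(
            np.max(np.abs(self.base_value + self.values.sum(axis=1) - self.fx))
        )

    def mean_abs(self) -> pd.Series:
        return pd.Series(
            np.abs(self.values).mean(axis=0), index=list(self.feature_names)
        ).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Exact per-tree Shapley for sklearn trees
# ---------------------------------------------------------------------------

def _tree_shapley(tree, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact path-dependent Shapley values of one fitted sklearn tree.

    The value function v(S) is the tree's conditional expectation for row x
    with only the features in S fixed: at a split on a feature outside S the
    two branches are averaged with their training cover weights.  v is
    evaluated for every subset of the features the tree actually uses
    (vectorised over subsets), then combined with the classical Shapley
    weights.  Features the tree never splits on receive exactly 0.
    """
    t = tree.tree_
    used = sorted(set(int(f) for f in t.feature if f >= 0))
    phi = np.zeros(x.size)
    if not used:
        return phi, float(t.value[0].ravel()[0])
    u = len(used)
    bit = {f: i for i, f in enumerate(used)}
    n_sub = 1 << u

    def rec(node: int) -> np.ndarray:
        f = int(t.feature[node])
        if f < 0:
            return np.full(n_sub, float(t.value[node].ravel()[0]))
        left, right = int(t.children_left[node]), int(t.children_right[node])
        vl, vr = rec(left), rec(right)
        wl = t.weighted_n_node_samples[left]
        wr = t.weighted_n_node_samples[right]
        blended = (wl * vl + wr * vr) / (wl + wr)
        follow = vl if x[f] <= t.threshold[node] else vr
        in_s = (np.arange(n_sub) >> bit[f]) & 1 == 1
        return np.where(in_s, follow, blended)

    v = rec(0)
    popcount = np.array([bin(s).count("1") for s in range(n_sub)])
    fact = np.array([math.factorial(i) for i in range(u + 1)], dtype=float)
    for f in used:
        b = bit[f]
        without = (np.arange(n_sub) >> b) & 1 == 0
        s_idx = np.arange(n_sub)[without]
        sizes = popcount[s_idx]
        w = fact[sizes] * fact[u - sizes - 1] / fact[u]
        phi[f] = float(np.sum(w * (v[s_idx | (1 << b)] - v[s_idx])))
    return phi, float(v[0])


def _sklearn_gbt_attribution(
    model: GradientBoostingClassifier, X_in
) -> tuple[np.ndarray, float, np.ndarray]:
    if model.estimators_.shape[1] != 1:  # pragma: no cover
        raise ValueError("only binary gradient boosting is supported")
    X = np.asarray(X_in, dtype=float)
    lr = model.learning_rate
    n, d = X.shape
    values = np.zeros((n, d))
    base = 0.0
    trees = [est[0] for est in model.estimators_]
    for i in range(n):
        for tree in trees:
            phi, v0 = _tree_shapley(tree, X[i])
            values[i] += lr * phi
            if i == 0:
                base += lr * v0
    init = float(model._raw_predict_init(X[:1]).ravel()[0])
    fx = model.decision_function(X_in)
    return values, base + init, np.asarray(fx, dtype=float)


def attribute(model, X, feature_names: Sequence[str]) -> ShapAttribution:
    """Exact tree-Shapley attributions in log-odds for a tree-ensemble model.

    Supported families: LGBMClassifier, XGBClassifier (native contributions)
    and sklearn GradientBoostingClassifier (computed here).  ``X`` holds the
    already-preprocessed test rows (array or DataFrame) in the same column
    order as ``feature_names``.
    """
    X_in = X
    X = np.asarray(X, dtype=float)
    if isinstance(model, LGBMClassifier):
        contrib = np.asarray(model.booster_.predict(X, pred_contrib=True))
        values, base = contrib[:, :-1], float(contrib[0, -1])
        fx = np.asarray(model.booster_.predict(X, raw_score=True), dtype=float)
    elif isinstance(model, XGBClassifier):
        import xgboost as xgb

        booster = model.get_booster()
        dmat = xgb.DMatrix(X_in)
        contrib = booster.predict(dmat, pred_contribs=True)
        values, base = contrib[:, :-1], float(contrib[0, -1])
        fx = booster.predict(dmat, output_margin=True).astype(float)
    elif isinstance(model, GradientBoostingClassifier):
        values, base, fx = _sklearn_gbt_attribution(model, X_in)
    else:
        raise TypeError(
            f"unsupported model family {type(model).__name__}; supported: "
            "LGBMClassifier, XGBClassifier, GradientBoostingClassifier"
        )
    return ShapAttribution(
        feature_names=tuple(feature_names),
        values=np.asarray(values, dtype=float),
        base_value=base,
        fx=np.asarray(fx, dtype=float),
    )


# ---------------------------------------------------------------------------
# Rankings and summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureRanking:
    per_repeat: tuple[tuple[str, ...], ...]  # features ordered by mean |phi|
    k: int

    @property
    def top_k(self) -> list[set[str]]:
        return [set(order[: self.k]) for order in self.per_repeat]

    @property
    def consistent(self) -> list[str]:
        """Features in the top-k of every repeat (sorted for stability)."""
        sets = self.top_k
        common = set.intersection(*sets) if sets else set()
        return sorted(common)


def rank_features(
    attributions: Sequence[ShapAttribution], k: int = 9
) -> FeatureRanking:
    """Per-repeat mean-|attribution| orderings and their top-k intersection."""
    if not attributions:
        raise ValueError("need at least one repeat's attributions")
    orders = []
    for att in attributions:
        orders.append(tuple(att.mean_abs().index))
    return FeatureRanking(per_repeat=tuple(orders), k=k)


def select_best_instance(evals: Sequence[ModelEval]) -> ModelEval:
    """The model instance with the highest test accuracy (ties: lowest repeat)."""
    if not evals:
        raise ValueError("no evaluations given")
    return min(evals, key=lambda e: (-e.accuracy, e.repeat))


def probability_summary(evals: Sequence[ModelEval]) -> pd.DataFrame:
    """Quartiles and polarization of predicted probabilities per region x class.

    Polarization is the fraction of predicted probabilities outside
    [0.25, 0.75]; confident (categorical) decoders score high, uncertain
    decoders near 0.
    """
    rows = []
    frame = pd.DataFrame(
        [
            {"region": e.region, "proba": p, "y": y}
            for e in evals
            for p, y in zip(e.probabilities, e.y_true)
        ]
    )
    for (region, y), g in frame.groupby(["region", "y"], sort=True):
        p = g["proba"].to_numpy()
        q1, q2, q3 = np.percentile(p, [25, 50, 75])
        rows.append(
            {
                "region": region,
                "true_class": "rewarded" if y == 1 else "nonrewarded",
                "q1": q1,
                "median": q2,
                "q3": q3,
                "polarization": float(np.mean((p < 0.25) | (p > 0.75))),
                "n": p.size,
            }
        )
    return pd.DataFrame(rows)


def strategy_report(consistent_features: Sequence[str]) -> pd.DataFrame:
    """Tag consistent top features by category and epoch.

    Returns one row per feature with its group (fundamental / timing / rate),
    condition and epoch, plus aggregate columns are easy to derive:
    ``report.groupby("group").size()`` gives the category mix that
    characterises a region's coding strategy.
    """
    schema = feature_schema().set_index("name")
    rows = []
    for feat in consistent_features:
        if feat not in schema.index:
            raise KeyError(f"unknown feature {feat!r}")
        s = schema.loc[feat]
        rows.append(
            {
                "feature": feat,
                "group": s["group"],
                "condition": s["condition"],
                "epoch": s["epoch"],
            }
        )
    return pd.DataFrame(rows, columns=["feature", "group", "condition", "epoch"])
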