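"""Leakage-free preprocessing cascade: impute, scale, prune, SMOTE, select."""

import numpy as np
import pandas as pd
import pytest

from rewarddecode.preprocess import (
    PreprocessState,
    fit_cascade,
    fit_impute_scale,
    oversample_minority,
    prune_collinear,
    select_features,
    transform,
)


def _frame(cols: dict) -> pd.DataFrame:
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cols.items()})


class TestImputeScale:
    def test_training_columns_standardized(self):
        rng = np.random.default_rng(0)
        df = _frame({f"f{i}": rng.normal(i, i + 1, 50) for i in range(4)})
        state = fit_impute_scale(df)
        z = transform(state, df)
        assert np.allclose(z.mean(), 0.0, atol=1e-9)
        assert np.allclose(z.std(ddof=0), 1.0, atol=1e-9)

    def test_missing_replaced_by_training_mean(self):
        df = _frame({"a": [1.0, np.nan, 3.0], "b": [0.0, 1.0, 2.0]})
        state = fit_impute_scale(df)
        assert state.means["a"] == pytest.approx(2.0)
        z = transform(state, df)
        assert z["a"].iloc[1] == pytest.approx(0.0)  # mean maps to z = 0

    def test_constant_column_dropped(self):
        df = _frame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        state = fit_impute_scale(df)
        assert "a" not in state.feature_names
        assert "zero variance" in state.dropped["a"]

    def test_all_missing_column_dropped(self):
        df = _frame({"a": [np.nan] * 3, "b": [0.0, 1.0, 2.0]})
        state = fit_impute_scale(df)
        assert "a" in state.dropped

    def test_no_test_leakage(self):
        """Held-out transforms use training statistics only."""
        rng = np.random.default_rng(1)
        train = _frame({"a": rng.normal(0, 1, 30), "b": rng.normal(5, 2, 30)})
        test = _frame({"a": rng.normal(10, 1, 10), "b": rng.normal(-5, 2, 10)})
        state = fit_impute_scale(train)
        z1 = transform(state, test)
        state2 = fit_impute_scale(train)  # refit on train alone: identical
        z2 = transform(state2, test)
        pd.testing.assert_frame_equal(z1, z2)

    def test_state_round_trips_through_file(self, tmp_path):
        df = _frame({"a": [1.0, 2.0, 4.0], "b": [0.0, 1.0, 2.0]})
        state = fit_impute_scale(df)
        state.save(tmp_path / "state.json")
        back = PreprocessState.load(tmp_path / "state.json")
        assert back.means == state.means and back.sds == state.sds


class TestPruneCollinear:
    def test_duplicate_keeps_more_label_correlated(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 20)
        informative = y + rng.normal(0, 0.1, 40)
        copy = informative + rng.normal(0, 0.01, 40)  # collinear, noisier
        df = _frame({"informative": informative, "copy": copy + rng.normal(0, 0.2, 40)})
        kept = prune_collinear(df, y)
        assert "informative" in kept

    def test_exact_threshold_keeps_both(self):
        # construct a pair with |r| = 0.80 exactly: r is strict '>' so both stay
        rho = 0.80
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        z = x - x.mean()
        z /= np.linalg.norm(z)
        e = np.array([1.0, -1.0, 0.0, 1.0, -1.0])
        e = e - e.mean()
        e = e - (e @ z) * z  # centered and orthogonal to z
        e /= np.linalg.norm(e)
        w = rho * z + np.sqrt(1 - rho**2) * e
        df = _frame({"a": z, "b": w})
        assert np.corrcoef(z, w)[0, 1] == pytest.approx(0.80, abs=1e-12)
        kept = prune_collinear(df, [0, 0, 1, 1, 1], threshold=0.80)
        assert kept == ["a", "b"]

    def test_chain_matches_hand_worked_greedy(self):
        """A~B~C chain: greedy in descending |r| with label-correlation ties."""
        rng = np.random.default_rng(3)
        n = 200
        y = np.repeat([0, 1], n // 2).astype(float)
        a = y + rng.normal(0, 0.5, n)
        b = a + rng.normal(0, 0.25, n)
        c = b + rng.normal(0, 0.25, n)
        df = _frame({"a": a, "b": b, "c": c})
        corr = df.corr().abs()
        lab = {k: abs(np.corrcoef(df[k], y)[0, 1]) for k in df}
        # independent oracle: replay the stated greedy rule explicitly
        pairs = sorted(
            [(corr.loc[i, j], i, j) for i in df for j in df if i < j and corr.loc[i, j] > 0.8],
            key=lambda t: -t[0],
        )
        removed = set()
        for _, i, j in pairs:
            if i in removed or j in removed:
                continue
            removed.add(i if lab[i] < lab[j] else j)
        expected = [k for k in df if k not in removed]
        assert prune_collinear(df, y) == expected

    def test_output_subset_and_fixpoint(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 60)
        base = rng.normal(0, 1, (60, 3))
        df = _frame({
            "x0": base[:, 0], "x1": base[:, 0] + rng.normal(0, 0.05, 60),
            "x2": base[:, 1], "x3": base[:, 2],
        })
        kept = prune_collinear(df, y)
        assert set(kept) <= set(df.columns)
        assert prune_collinear(df[kept], y) == kept


class TestOversampleMinority:
    def test_balances_classes(self):
        rng = np.random.default_rng(5)
        X = _frame({"a": rng.normal(0, 1, 100), "b": rng.normal(0, 1, 100)})
        y = np.array([0] * 30 + [1] * 70)
        X_aug, y_aug = oversample_minority(X, y, seed=0)
        assert (y_aug == 0).sum() == (y_aug == 1).sum() == 70

    def test_originals_unaltered_and_synthetic_convex(self):
        rng = np.random.default_rng(6)
        X = _frame({"a": rng.normal(0, 1, 50), "b": rng.normal(0, 1, 50)})
        y = np.array([0] * 15 + [1] * 35)
        X_aug, y_aug = oversample_minority(X, y, k=5, seed=1)
        np.testing.assert_array_equal(X_aug.to_numpy()[:50], X.to_numpy())
        minority = X.to_numpy()[y == 0]
        synth = X_aug.to_numpy()[50:]
        # every synthetic point inside the minority bounding box (convexity)
        assert np.all(synth >= minority.min(axis=0) - 1e-12)
        assert np.all(synth <= minority.max(axis=0) + 1e-12)

    def test_k1_two_minority_points_on_segment(self):
        X = _frame({"a": [0.0, 1.0, 5.0, 6.0, 7.0, 8.0],
                    "b": [0.0, 2.0, 5.0, 6.0, 7.0, 8.0]})
        y = np.array([0, 0, 1, 1, 1, 1])
        X_aug, y_aug = oversample_minority(X, y, k=1, seed=2)
        p0, p1 = np.array([0.0, 0.0]), np.array([1.0, 2.0])
        seg = p1 - p0
        for row in X_aug.to_numpy()[6:]:
            # projection residual of (row - p0) off the segment direction is 0
            r = (row - p0) - ((row - p0) @ seg) / (seg @ seg) * seg
            assert np.linalg.norm(r) < 1e-12

    def test_single_minority_row_errors(self):
        X = _frame({"a": [0.0, 5.0, 6.0], "b": [0.0, 5.0, 6.0]})
        with pytest.raises(ValueError, match="minority"):
            oversample_minority(X, np.array([0, 1, 1]))


class TestSelectFeatures:
    def test_count_is_ceiling_of_fraction(self):
        rng = np.random.default_rng(7)
        df = _frame({f"f{i}": rng.normal(0, 1, 80) for i in range(40)})
        y = rng.integers(0, 2, 80)
        kept = select_features(df, y, fraction=0.20, seed=0)
        assert len(kept) == 8  # ceil(0.2 * 40)

    def test_planted_signal_always_retained(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 120)
        for seed in range(5):
            cols = {f"noise{i}": rng.normal(0, 1, 120) for i in range(9)}
            cols["signal"] = y + rng.normal(0, 0.1, 120)
            kept = select_features(_frame(cols), y, fraction=0.20, seed=seed)
            assert "signal" in kept

    def test_fraction_one_identity(self):
        rng = np.random.default_rng(9)
        df = _frame({f"f{i}": rng.normal(0, 1, 40) for i in range(6)})
        y = rng.integers(0, 2, 40)
        assert select_features(df, y, fraction=1.0, seed=0) == list(df.columns)

    def test_single_class_errors(self):
        rng = np.random.default_rng(10)
        df = _frame({f"f{i}": rng.normal(0, 1, 30) for i in range(6)})
        with pytest.raises(ValueError):
            select_features(df, np.zeros(30, dtype=int), seed=0)


class TestCascade:
    def test_retained_subset_and_deterministic(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 100)
        df = _frame({f"f{i}": rng.normal(0, 1, 100) for i in range(20)})
        df["dup"] = df["f0"] + rng.normal(0, 0.01, 100)
        s1 = fit_cascade(df, y, seed=3)
        s2 = fit_cascade(df, y, seed=3)
        assert s1.retained == s2.retained
        assert set(s1.retained) <= set(df.columns)
        assert not ({"f0", "dup"} <= set(s1.retained))  # collinear pair pruned
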