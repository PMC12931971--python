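"""Statistical validation of decoder performance.

Two checks mirror the analysis protocol:

* a label-shuffle permutation test per region x architecture: holding the
  model's test-set predictions fixed, the true labels are shuffled (class
  counts preserved) 1,000 times; the null accuracy is the agreement between
  fixed predictions and shuffled labels, the one-sided p-value is the
  fraction of null accuracies >= the observed one (floored at 1/n_perm), and
  Bonferroni correction uses m = n_regions x n_architectures (18 in the full
  design, giving the 0.0180 resolution limit);
* a balanced two-way ANOVA on held-out accuracies with region and model
  architecture as factors and the independent repeats as replicates,
  computed from closed-form balanced-design sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationResult",
    "AnovaTable",
    "permutation_test",
    "bonferroni",
    "two_way_anova",
]


@dataclass(frozen=True)
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_uncorrected: float
    correction_factor: int
    p_corrected: float


def permutation_test(
    predictions: Sequence[int],
    labels: Sequence[int],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    correction_factor: int = 1,
) -> PermutationResult:
    """One-sided label-shuffle test of above-chance accuracy.

    Shuffles are permutations of the label vector, so class counts are
    preserved exactly.  p_uncorrected = max(#{null >= observed}, 1) / n_perm —
    the floor reproduces the 1/n_perm resolution limit of the test.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if pred.size != y.size or y.size < 2:
        raise ValueError("predictions and labels must have equal length >= 2")
    rng = np.random.default_rng(seed)
    observed = float(np.mean(pred == y))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.mean(pred == rng.permutation(y))
    count = int(np.sum(null >= observed))
    p_unc = max(count, 1) / n_perm
    return PermutationResult(
        observed_accuracy=observed,
        null_accuracies=null,
        p_uncorrected=p_unc,
        correction_factor=correction_factor,
        p_corrected=bonferroni([p_unc], correction_factor)[0],
    )


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni correction: p -> min(1, m * p)."""
    if m < 1:
        raise ValueError("correction factor must be >= 1")
    out = []
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError("p-values must lie in [0, 1]")
        out.append(min(1.0, m * p))
    return out


@dataclass(frozen=True)
class AnovaTable:
    """Balanced two-way ANOVA with interaction."""

    table: pd.DataFrame  # index: factor_a, factor_b, interaction, error, total

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]


def two_way_anova(
    scores: Mapping[tuple[str, str], Sequence[float]],
    factor_names: tuple[str, str] = ("region", "architecture"),
) -> AnovaTable:
    """Closed-form balanced two-way ANOVA with replication.

    ``scores`` maps (level_a, level_b) cells to equal-length replicate lists
    (r >= 2).  Sums of squares follow the balanced decomposition
    SS_total = SS_A + SS_B + SS_AB + SS_error; F = MS_effect / MS_error.
    When every score is identical all SS are 0 and F is reported as 0 with
    p = 1 by convention.
    """
    a_levels = sorted({k[0] for k in scores})
    b_levels = sorted({k[1] for k in scores})
    if set(scores) != {(a, b) for a in a_levels for b in b_levels}:
        raise ValueError("unbalanced design: every (a, b) cell must be present")
    r_set = {len(v) for v in scores.values()}
    if len(r_set) != 1:
        raise ValueError("unbalanced design: all cells need the same replicate count")
    r = r_set.pop()
    if r < 2:
        raise ValueError("need at least 2 replicates per cell")

    A, B = len(a_levels), len(b_levels)
    data = np.empty((A, B, r))
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            data[i, j] = np.asarray(scores[(a, b)], dtype=float)

    grand = data.mean()
    mean_a = data.mean(axis=(1, 2))
    mean_b = data.mean(axis=(0, 2))
    mean_ab = data.mean(axis=2)

    ss_a = B * r * float(np.sum((mean_a - grand) ** 2))
    ss_b = A * r * float(np.sum((mean_b - grand) ** 2))
    ss_ab = r * float(
        np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    )
    ss_err = float(np.sum((data - mean_ab[:, :, None]) ** 2))
    ss_tot = float(np.sum((data - grand) ** 2))

    df_a, df_b = A - 1, B - 1
    df_ab = df_a * df_b
    df_err = A * B * (r - 1)

    def row(ss: float, df: int) -> dict:
        ms = ss / df if df > 0 else float("nan")
        if ss_err == 0.0:
            f = 0.0
            p = 1.0
        else:
            ms_err = ss_err / df_err
            f = ms / ms_err
            p = float(stats.f.sf(f, df, df_err))
        return {"ss": ss, "df": df, "ms": ms, "F": f, "p": p}

    table = pd.DataFrame(
        {
            factor_names[0]: row(ss_a, df_a),
            factor_names[1]: row(ss_b, df_b),
            "interaction": row(ss_ab, df_ab),
            "error": {
                "ss": ss_err,
                "df": df_err,
                "ms": ss_err / df_err,
                "F": float("nan"),
                "p": float("nan"),
            },
            "total": {
                "ss": ss_tot,
                "df": A * B * r - 1,
                "ms": float("nan"),
                "F": float("nan"),
                "p": float("nan"),
            },
        }
    ).T
    return AnovaTable(table=table)
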