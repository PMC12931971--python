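"""Per-neuron spike-train features and the decoding feature matrix.

Each neuron contributes up to two rows to the decoding dataset — one per
outcome condition (rewarded / nonrewarded) — each holding 88 named features:

* 8 *fundamental* properties, constant across a neuron's two rows: ongoing
  spike rate, spike duration, spike width, ISI variability (Cv, Lv), and three
  autocorrelogram biases (classical 0-100 ms, peak 0-50 ms, baseline
  50-250 ms medians of the normalised ACG);
* for each of the four trial conditions AC/AI/OC/OI (action/outcome x
  contra/ipsi), 8 *spike-timing* features (moments, quartiles and the KS
  uniformity statistic of relative spike times) and 12 *firing-rate* features
  (mean rate in six windows, peak rate in five windows, and the FRc rate
  change index).

Action conditions are analysed in the pre-action window [-500, 0) ms around
pedal release and outcome conditions in the post-outcome window [0, 500) ms
around reward/error-cue onset; the post-action and pre-outcome epochs are
movement-contaminated and enter only through each condition's opposite-side
mean rate and the FRc index.  Insufficient data yields masked (NaN) entries,
never silent substitutions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    AlignedSpikes,
    CONDITIONS,
    NeuronRecord,
    Session,
    Trial,
    align_spikes,
    condition_trials,
    filter_trials,
)

__all__ = [
    "FeatureConfig",
    "ISIStats",
    "ACGProfile",
    "PETH",
    "FeatureVector",
    "FEATURE_NAMES",
    "feature_schema",
    "compute_cv",
    "compute_lv",
    "compute_acg",
    "compute_peth",
    "timing_stats",
    "ks_uniform",
    "frc_index",
    "mean_rate_hz",
    "peak_rate_hz",
    "build_feature_vector",
    "build_feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
]


@dataclass(frozen=True)
class FeatureConfig:
    min_spikes: int = 10          # pooled spikes needed for timing features
    min_trials: int = 5           # trials per outcome condition to keep a row
    peth_binwidth_ms: float = 20.0
    peak_binwidth_ms: float = 10.0
    acg_binwidth_ms: float = 1.0
    acg_maxlag_ms: float = 250.0
    # "post": outcome timing window [0, 500); "full": the whole +/-500 ms
    outcome_timing_window: str = "post"
    # equalise rewarded/nonrewarded trial counts per choice side before
    # feature computation, so sample-size-dependent estimator bias (KS D,
    # peak rate, kurtosis) cannot encode the outcome label
    match_trial_counts: bool = True
    match_seed: int = 0


# ---------------------------------------------------------------------------
# ISI statistics
# ---------------------------------------------------------------------------

def compute_cv(isis: Sequence[float]) -> float:
    """Coefficient of variation of ISIs: sample SD (n-1) over mean.

    0 for perfectly regular intervals, ~1 for a Poisson train.  Returns NaN
    with fewer than two intervals.
    """
    x = np.asarray(isis, dtype=float)
    if x.size < 2:
        return float("nan")
    if np.ptp(x) == 0:
        return 0.0  # constant intervals: exactly zero, no rounding residue
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(x.std(ddof=1) / m)


def compute_lv(isis: Sequence[float]) -> float:
    """Local variation of ISIs.

    Lv = 3/(n-1) * sum_i ((I_i - I_{i+1}) / (I_i + I_{i+1}))^2 over adjacent
    interval pairs; robust to slow rate drift.  0 for regular trains and
    expectation 1 for exponential (Poisson) ISIs.  NaN with fewer than two
    intervals or when an adjacent pair sums to zero.
    """
    x = np.asarray(isis, dtype=float)
    if x.size < 2:
        return float("nan")
    a, b = x[:-1], x[1:]
    denom = a + b
    if np.any(denom == 0):
        return float("nan")
    return float(3.0 / (x.size - 1) * np.sum(((a - b) / denom) ** 2))


@dataclass(frozen=True)
class ISIStats:
    isis: np.ndarray
    n: int
    cv: float
    lv: float

    @classmethod
    def from_spike_times(cls, spike_times: np.ndarray) -> "ISIStats":
        isis = np.diff(np.asarray(spike_times, dtype=float))
        return cls(isis=isis, n=isis.size, cv=compute_cv(isis), lv=compute_lv(isis))


# ---------------------------------------------------------------------------
# Autocorrelogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ACGProfile:
    lags_ms: np.ndarray      # bin centres
    values: np.ndarray       # normalised coincidence rate (Hz per ref spike)
    classical_bias: float    # median over 0-100 ms
    peak_bias: float         # median over 0-50 ms
    baseline_bias: float     # median over 50-250 ms


def compute_acg(
    spike_times: np.ndarray,
    binwidth_ms: float = 1.0,
    maxlag_ms: float = 250.0,
) -> ACGProfile:
    """Positive-lag autocorrelogram normalised to a coincidence rate.

    Counts ordered spike pairs with lag in (0, maxlag], excluding the zero-lag
    self-pairs, and divides by (number of spikes x bin width) so a stationary
    Poisson train has an approximately flat profile at its firing rate.  The
    three biases are medians of the normalised values in their lag windows.
    """
    st = np.asarray(spike_times, dtype=float)
    edges = np.arange(0.0, maxlag_ms + binwidth_ms, binwidth_ms)
    centres = 0.5 * (edges[:-1] + edges[1:])
    if st.size < 2:
        nan = float("nan")
        return ACGProfile(centres, np.full(centres.size, np.nan), nan, nan, nan)
    maxlag_s = maxlag_ms / 1000.0
    hi = np.searchsorted(st, st + maxlag_s, side="right")
    diffs = [st[i + 1 : hi[i]] - st[i] for i in range(st.size) if hi[i] > i + 1]
    lags = np.concatenate(diffs) * 1000.0 if diffs else np.empty(0)
    counts, _ = np.histogram(lags, bins=edges)
    values = counts / (st.size * binwidth_ms / 1000.0)
    in_win = lambda lo, hi_: (centres >= lo) & (centres < hi_)
    return ACGProfile(
        lags_ms=centres,
        values=values,
        classical_bias=float(np.median(values[in_win(0, 100)])),
        peak_bias=float(np.median(values[in_win(0, 50)])),
        baseline_bias=float(np.median(values[in_win(50, 250)])),
    )


# ---------------------------------------------------------------------------
# PETH and rate features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PETH:
    bin_edges_ms: np.ndarray
    rates_hz: np.ndarray
    n_trials: int


def compute_peth(aligned: AlignedSpikes, binwidth_ms: float = 20.0) -> PETH:
    """Trial-averaged firing rate per bin: count / (n_trials x bin width)."""
    if aligned.n_trials == 0:
        raise ValueError("cannot build a PETH from zero trials")
    lo, hi = aligned.window_ms
    edges = np.arange(lo, hi + binwidth_ms, binwidth_ms)
    counts, _ = np.histogram(aligned.pooled(), bins=edges)
    rates = counts / (aligned.n_trials * binwidth_ms / 1000.0)
    return PETH(bin_edges_ms=edges, rates_hz=rates, n_trials=aligned.n_trials)


def mean_rate_hz(
    aligned: AlignedSpikes, window_ms: tuple[float, float]
) -> float:
    """Mean firing rate (Hz) of pooled spikes in a sub-window of the alignment."""
    if aligned.n_trials == 0:
        return float("nan")
    lo, hi = window_ms
    pooled = aligned.pooled()
    n = int(np.count_nonzero((pooled >= lo) & (pooled < hi)))
    return n / (aligned.n_trials * (hi - lo) / 1000.0)


def peak_rate_hz(
    aligned: AlignedSpikes,
    window_ms: tuple[float, float],
    binwidth_ms: float = 10.0,
) -> float:
    """Peak binned rate in a window, bins tiled from the window start.

    The bin width divides every canonical window so the bins tile exactly and
    the peak is always >= the window's mean rate.
    """
    if aligned.n_trials == 0:
        return float("nan")
    lo, hi = window_ms
    edges = np.arange(lo, hi + binwidth_ms, binwidth_ms)
    counts, _ = np.histogram(aligned.pooled(), bins=edges)
    rates = counts / (aligned.n_trials * binwidth_ms / 1000.0)
    return float(rates.max())


def frc_index(fr_pre: float, fr_post: float) -> float:
    """Firing-rate change index (post - pre) / (post + pre) in [-1, 1].

    Positive values mean activity increases after the trigger.  NaN when both
    rates are zero (undefined direction).
    """
    if fr_pre < 0 or fr_post < 0:
        raise ValueError("rates must be non-negative")
    if fr_pre + fr_post == 0 or not np.isfinite(fr_pre + fr_post):
        return float("nan")
    return float((fr_post - fr_pre) / (fr_post + fr_pre))


# ---------------------------------------------------------------------------
# Timing features
# ---------------------------------------------------------------------------

def timing_stats(
    aligned: AlignedSpikes, min_spikes: int = 10
) -> dict[str, float]:
    """Moments and quartiles of pooled relative spike times.

    Sample SD (n-1); skewness g1 (biased moment ratio); Pearson (non-excess)
    kurtosis; quartiles by linear interpolation.  All NaN below ``min_spikes``
    pooled spikes.
    """
    pooled = aligned.pooled()
    keys = ("mean_ms", "sd_ms", "skewness", "kurtosis", "q1_ms", "q2_ms", "q3_ms")
    if pooled.size < min_spikes:
        return {k: float("nan") for k in keys}
    q1, q2, q3 = np.percentile(pooled, [25, 50, 75])
    if np.ptp(pooled) == 0:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(pooled, bias=True))
        kurt = float(stats.kurtosis(pooled, fisher=False, bias=True))
    return {
        "mean_ms": float(pooled.mean()),
        "sd_ms": float(pooled.std(ddof=1)),
        "skewness": skew,
        "kurtosis": kurt,
        "q1_ms": float(q1),
        "q2_ms": float(q2),
        "q3_ms": float(q3),
    }


def ks_uniform(aligned: AlignedSpikes, min_spikes: int = 10) -> float:
    """KS distance between pooled spike times and uniformity on the window.

    D = sup |empirical CDF - uniform CDF| over the analysis window; 0 for
    perfectly uniform timing, approaching 1 when all spikes pile up at one
    edge.  NaN below ``min_spikes`` pooled spikes.
    """
    pooled = aligned.pooled()
    if pooled.size < min_spikes:
        return float("nan")
    lo, hi = aligned.window_ms
    res = stats.kstest(pooled, stats.uniform(loc=lo, scale=hi - lo).cdf)
    return float(res.statistic)


# ---------------------------------------------------------------------------
# Canonical 88-feature schema
# ---------------------------------------------------------------------------

FUNDAMENTAL_NAMES = (
    "ongoing_rate_hz",
    "spike_duration_ms",
    "spike_width_ms",
    "cv",
    "lv",
    "acg_bias_classical",
    "acg_bias_peak",
    "acg_bias_baseline",
)

_TIMING_KEYS = ("mean_ms", "sd_ms", "skewness", "kurtosis", "q1_ms", "q2_ms", "q3_ms")

# sub-windows (ms, relative to the trigger) on each condition's analysis side
_OUTCOME_WINDOWS = ((0, 50), (50, 100), (100, 250), (250, 500), (0, 500))
_ACTION_WINDOWS = ((-50, 0), (-100, -50), (-250, -100), (-500, -250), (-500, 0))


def _win_tag(lo: int, hi: int) -> str:
    f = lambda v: f"m{abs(v)}" if v < 0 else f"{v}"
    return f"{f(lo)}_{f(hi)}"


def _condition_feature_names(cond: str) -> list[str]:
    c = cond.lower()
    names = [f"{c}_timing_{k}" for k in _TIMING_KEYS] + [f"{c}_ks_d"]
    wins = _ACTION_WINDOWS if cond in ("AC", "AI") else _OUTCOME_WINDOWS
    opp = "post_0_500" if cond in ("AC", "AI") else "pre_m500_0"
    names += [f"{c}_mean_fr_{_win_tag(*w)}" for w in wins]
    names += [f"{c}_mean_fr_{opp}"]
    names += [f"{c}_peak_fr_{_win_tag(*w)}" for w in wins]
    names += [f"{c}_frc"]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(
    list(FUNDAMENTAL_NAMES)
    + [n for cond in CONDITIONS for n in _condition_feature_names(cond)]
)
assert len(FEATURE_NAMES) == 88


def feature_schema() -> pd.DataFrame:
    """Tabular schema: name, group (fundamental/timing/rate), condition, epoch."""
    rows = []
    for name in FEATURE_NAMES:
        if name in FUNDAMENTAL_NAMES:
            rows.append((name, "fundamental", "", ""))
            continue
        cond = name[:2].upper()
        epoch = "action" if cond in ("AC", "AI") else "outcome"
        group = "timing" if ("_timing_" in name or name.endswith("_ks_d")) else "rate"
        rows.append((name, group, cond, epoch))
    return pd.DataFrame(rows, columns=["name", "group", "condition", "epoch"])


# ---------------------------------------------------------------------------
# Feature vector / matrix assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    neuron_id: str
    condition: str  # "rewarded" | "nonrewarded"
    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.values) != set(FEATURE_NAMES):
            raise ValueError(
                f"feature vector must contain exactly the {len(FEATURE_NAMES)} "
                "canonical features"
            )

    @property
    def mask(self) -> dict[str, bool]:
        """True where a feature is missing."""
        return {k: not np.isfinite(v) for k, v in self.values.items()}


def _ongoing_rate(neuron: NeuronRecord) -> float:
    st = neuron.spike_times
    if st.size < 2 or st[-1] == st[0]:
        return float("nan")
    return float(st.size / (st[-1] - st[0]))


def fundamental_features(
    neuron: NeuronRecord, config: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    isi = ISIStats.from_spike_times(neuron.spike_times)
    acg = compute_acg(neuron.spike_times, config.acg_binwidth_ms, config.acg_maxlag_ms)
    return {
        "ongoing_rate_hz": _ongoing_rate(neuron),
        "spike_duration_ms": neuron.spike_duration_ms,
        "spike_width_ms": neuron.spike_width_ms,
        "cv": isi.cv,
        "lv": isi.lv,
        "acg_bias_classical": acg.classical_bias,
        "acg_bias_peak": acg.peak_bias,
        "acg_bias_baseline": acg.baseline_bias,
    }


def _condition_features(
    neuron: NeuronRecord,
    trials: Sequence[Trial],
    cond: str,
    config: FeatureConfig,
) -> dict[str, float]:
    c = cond.lower()
    is_action = cond in ("AC", "AI")
    trigger = "action" if is_action else "outcome"
    sel = condition_trials(neuron, trials, cond)
    out: dict[str, float] = {
        name: float("nan") for name in _condition_feature_names(cond)
    }
    if not sel:
        return out

    full = align_spikes(neuron, sel, trigger, cond, (-500.0, 500.0))
    if is_action:
        analysis_win = (-500.0, 0.0)
    elif config.outcome_timing_window == "full":
        analysis_win = (-500.0, 500.0)
    else:
        analysis_win = (0.0, 500.0)
    analysis = align_spikes(neuron, sel, trigger, cond, analysis_win)

    ts = timing_stats(analysis, config.min_spikes)
    for k in _TIMING_KEYS:
        out[f"{c}_timing_{k}"] = ts[k]
    out[f"{c}_ks_d"] = ks_uniform(analysis, config.min_spikes)

    wins = _ACTION_WINDOWS if is_action else _OUTCOME_WINDOWS
    for w in wins:
        out[f"{c}_mean_fr_{_win_tag(*w)}"] = mean_rate_hz(full, w)
        out[f"{c}_peak_fr_{_win_tag(*w)}"] = peak_rate_hz(
            full, w, config.peak_binwidth_ms
        )
    opp_tag = "post_0_500" if is_action else "pre_m500_0"
    opp_win = (0.0, 500.0) if is_action else (-500.0, 0.0)
    out[f"{c}_mean_fr_{opp_tag}"] = mean_rate_hz(full, opp_win)

    fr_pre = mean_rate_hz(full, (-500.0, 0.0))
    fr_post = mean_rate_hz(full, (0.0, 500.0))
    out[f"{c}_frc"] = frc_index(fr_pre, fr_post)
    return out


def build_feature_vector(
    neuron: NeuronRecord,
    trials: Sequence[Trial],
    outcome_condition: str,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Assemble the 88-feature vector for one neuron under one outcome label.

    ``trials`` must already be filtered; only trials whose outcome matches
    ``outcome_condition`` contribute to the task-related features.  Fundamental
    features ignore the outcome split, so a neuron's two rows share them.
    """
    if outcome_condition not in ("rewarded", "nonrewarded"):
        raise ValueError("outcome_condition must be 'rewarded' or 'nonrewarded'")
    sel = [t for t in trials if t.outcome == outcome_condition]
    values = dict(fundamental_features(neuron, config))
    for cond in CONDITIONS:
        values.update(_condition_features(neuron, sel, cond, config))
    return FeatureVector(
        neuron_id=neuron.neuron_id, condition=outcome_condition, values=values
    )


def match_trial_counts(
    trials: Sequence[Trial], seed: int = 0
) -> tuple[Trial, ...]:
    """Equalise rewarded/nonrewarded trial counts within each choice side.

    For each pedal side the majority outcome's trials are randomly subsampled
    down to the minority count (deterministic under ``seed``); ordering of the
    surviving trials is preserved.  This removes the outcome-correlated
    sample-size imbalance (~72% correct performance means far more rewarded
    trials) that would otherwise leak the label through estimators whose
    small-sample bias depends on n.
    """
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for side in ("left", "right"):
        rew = [t.trial_id for t in trials if t.choice == side and t.outcome == "rewarded"]
        non = [t.trial_id for t in trials if t.choice == side and t.outcome == "nonrewarded"]
        n = min(len(rew), len(non))
        for ids in (rew, non):
            if len(ids) > n:
                chosen = rng.choice(len(ids), size=n, replace=False)
                keep.update(ids[i] for i in chosen)
            else:
                keep.update(ids)
    return tuple(t for t in trials if t.trial_id in keep)


def build_feature_matrix(
    sessions: Iterable[Session],
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Stack feature vectors into the decoding dataset.

    Up to two rows per neuron (rewarded / nonrewarded); a row is dropped when
    its outcome condition has fewer than ``config.min_trials`` retained trials.
    The binary ``label`` column is 1 for rewarded rows.
    """
    rows = []
    n_neurons = 0
    for session in sessions:
        filtered = filter_trials(session)
        if config.match_trial_counts:
            seed = (config.match_seed * 1000003 + zlib.crc32(
                session.session_id.encode())) % (2**31)
            filtered = replace(
                filtered, trials=match_trial_counts(filtered.trials, seed)
            )
        for neuron in session.neurons:
            n_neurons += 1
            for label_name, label in (("rewarded", 1), ("nonrewarded", 0)):
                n_cond = sum(1 for t in filtered.trials if t.outcome == label_name)
                if n_cond < config.min_trials:
                    continue
                fv = build_feature_vector(neuron, filtered.trials, label_name, config)
                row = {
                    "neuron_id": neuron.neuron_id,
                    "session_id": session.session_id,
                    "region": neuron.region,
                    "condition": label_name,
                    "label": label,
                }
                row.update(fv.values)
                rows.append(row)
    if not rows:
        raise ValueError(f"no feature rows survive exclusion ({n_neurons} neurons)")
    df = pd.DataFrame(rows)
    return df[["neuron_id", "session_id", "region", "condition", "label", *FEATURE_NAMES]]


def write_feature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"neuron_id": str})
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns: {missing[:5]}...")
    return df
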