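"""Domain types and session I/O for single-unit recordings of the pedal choice task.

A *session* is one recording day: a set of single units (spike timestamps plus
waveform metadata) and a table of self-initiated choice trials.  Sessions are
stored as three plain CSV tables (neurons, spikes, trials) plus a small JSON
metadata record so that fixtures stay diff-able and dependency-free.

Conventions
-----------
* Absolute timestamps are seconds at full float precision; spike times relative
  to a trigger are milliseconds.
* All analysis windows are half-open ``[start, end)``; a spike exactly at the
  trigger (0 ms) belongs to the post-trigger window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

REGIONS = ("M1", "M2", "PPC", "LEC", "dCA1", "vCA1")
HEMISPHERES = ("left", "right")
CHOICES = ("left", "right")
OUTCOMES = ("rewarded", "nonrewarded", "immature")
CONDITIONS = ("AC", "AI", "OC", "OI")

Condition = Literal["AC", "AI", "OC", "OI"]
Trigger = Literal["action", "outcome"]


class SchemaError(ValueError):
    """A session file or record violates the documented schema."""


@dataclass(frozen=True)
class NeuronRecord:
    """One isolated single unit.

    ``spike_duration_ms`` (onset to first positive peak) and ``spike_width_ms``
    (time above half amplitude) are waveform measurements taken as given
    metadata; they are never computed from raw voltage here.
    """

    neuron_id: str
    region: str
    hemisphere: str
    spike_times: np.ndarray  # ascending, seconds
    spike_duration_ms: float
    spike_width_ms: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise SchemaError(
                f"neuron {self.neuron_id!r}: unknown region {self.region!r}; "
                f"allowed: {', '.join(REGIONS)}"
            )
        if self.hemisphere not in HEMISPHERES:
            raise SchemaError(
                f"neuron {self.neuron_id!r}: unknown hemisphere {self.hemisphere!r}"
            )
        st = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", st)
        if st.ndim != 1:
            raise SchemaError(f"neuron {self.neuron_id!r}: spike_times must be 1-D")
        if st.size > 1 and not np.all(np.diff(st) > 0):
            raise SchemaError(
                f"neuron {self.neuron_id!r}: spike times must be strictly ascending"
            )
        if not (self.spike_duration_ms > 0 and self.spike_width_ms > 0):
            raise SchemaError(
                f"neuron {self.neuron_id!r}: spike duration/width must be positive"
            )


@dataclass(frozen=True)
class Trial:
    """One self-initiated choice trial.

    ``release_time_s`` is the pedal-release event (position-threshold detection
    is upstream preprocessing).  ``outcome_time_s`` is reward-pump onset on
    rewarded trials and error-cue onset on nonrewarded trials; it is NaN for
    immature trials, which received no feedback.  ``both_forelimbs`` flags
    bilateral movement during the post-action period; such trials are excluded
    from analysis because the movement side is undefined.
    """

    trial_id: int
    release_time_s: float
    outcome_time_s: float
    choice: str
    outcome: str
    both_forelimbs: bool

    def __post_init__(self) -> None:
        if self.choice not in CHOICES:
            raise SchemaError(f"trial {self.trial_id}: unknown choice {self.choice!r}")
        if self.outcome not in OUTCOMES:
            raise SchemaError(
                f"trial {self.trial_id}: unknown outcome {self.outcome!r}"
            )
        if self.outcome != "immature" and not (
            self.outcome_time_s > self.release_time_s
        ):
            raise SchemaError(
                f"trial {self.trial_id}: outcome_time_s must exceed release_time_s"
            )


@dataclass(frozen=True)
class Session:
    """One recording session: neurons plus trial event table."""

    session_id: str
    neurons: tuple[NeuronRecord, ...]
    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "neurons", tuple(self.neurons))
        object.__setattr__(self, "trials", tuple(self.trials))
        ids = [n.neuron_id for n in self.neurons]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"session {self.session_id!r}: duplicate neuron_ids")

    def validate_span(self, margin_s: float = 120.0) -> None:
        """Check that all trial events fall within recorded spiking ± margin."""
        all_spikes = [n.spike_times for n in self.neurons if n.spike_times.size]
        if not all_spikes or not self.trials:
            return
        lo = min(s[0] for s in all_spikes) - margin_s
        hi = max(s[-1] for s in all_spikes) + margin_s
        for t in self.trials:
            times = [t.release_time_s]
            if np.isfinite(t.outcome_time_s):
                times.append(t.outcome_time_s)
            if min(times) < lo or max(times) > hi:
                raise SchemaError(
                    f"session {self.session_id!r}: trial {t.trial_id} events "
                    f"outside recorded spike span ± {margin_s} s"
                )


@dataclass(frozen=True)
class AlignedSpikes:
    """Per-trial spike times (ms) relative to a trigger, within one window."""

    trigger: str  # "action" | "outcome"
    condition: str  # AC/AI/OC/OI
    window_ms: tuple[float, float]
    trial_spikes: tuple[np.ndarray, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        lo, hi = self.window_ms
        if not lo < hi:
            raise ValueError("window start must precede window end")
        ts = tuple(np.asarray(t, dtype=float) for t in self.trial_spikes)
        object.__setattr__(self, "trial_spikes", ts)
        for t in ts:
            if t.size and (t.min() < lo or t.max() >= hi):
                raise ValueError("relative spike time outside half-open window")

    @property
    def n_trials(self) -> int:
        return len(self.trial_spikes)

    def pooled(self) -> np.ndarray:
        """All relative spike times pooled across trials, sorted."""
        if not self.trial_spikes:
            return np.empty(0)
        return np.sort(np.concatenate(self.trial_spikes))

    @property
    def total_spikes(self) -> int:
        return sum(t.size for t in self.trial_spikes)


# ---------------------------------------------------------------------------
# Session file I/O
# ---------------------------------------------------------------------------

_NEURON_COLS = ["neuron_id", "region", "hemisphere", "spike_duration_ms", "spike_width_ms"]
_SPIKE_COLS = ["neuron_id", "time_s"]
_TRIAL_COLS = [
    "trial_id",
    "release_time_s",
    "outcome_time_s",
    "choice",
    "outcome",
    "both_forelimbs",
]


def session_paths(directory: str | Path, session_id: str) -> dict[str, Path]:
    d = Path(directory)
    return {
        "neurons": d / f"{session_id}.neurons.csv",
        "spikes": d / f"{session_id}.spikes.csv",
        "trials": d / f"{session_id}.trials.csv",
        "meta": d / f"{session_id}.meta.json",
    }


def write_session(session: Session, directory: str | Path) -> dict[str, Path]:
    """Write a session as CSV tables + JSON metadata; returns the file paths.

    Timestamps are written with ``repr`` round-trip precision so that
    ``read_session(write_session(s))`` reproduces spike times bit-identically.
    """
    paths = session_paths(directory, session.session_id)
    paths["neurons"].parent.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "neuron_id": n.neuron_id,
                "region": n.region,
                "hemisphere": n.hemisphere,
                "spike_duration_ms": n.spike_duration_ms,
                "spike_width_ms": n.spike_width_ms,
            }
            for n in session.neurons
        ],
        columns=_NEURON_COLS,
    ).to_csv(paths["neurons"], index=False)

    with open(paths["spikes"], "w", encoding="utf-8") as fh:
        fh.write(",".join(_SPIKE_COLS) + "\n")
        for n in session.neurons:
            for t in n.spike_times:
                fh.write(f"{n.neuron_id},{float(t)!r}\n")

    with open(paths["trials"], "w", encoding="utf-8") as fh:
        fh.write(",".join(_TRIAL_COLS) + "\n")
        for t in session.trials:
            out = "" if not np.isfinite(t.outcome_time_s) else repr(float(t.outcome_time_s))
            fh.write(
                f"{t.trial_id},{float(t.release_time_s)!r},{out},{t.choice},"
                f"{t.outcome},{t.both_forelimbs}\n"
            )

    with open(paths["meta"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "session_id": session.session_id,
                "n_neurons": len(session.neurons),
                "n_trials": len(session.trials),
            },
            fh,
            indent=1,
        )
    return paths


def _require_cols(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table: missing column(s) {missing}")


def read_session(
    directory: str | Path, session_id: str, span_margin_s: float = 120.0
) -> Session:
    """Read and validate one session written by :func:`write_session`."""
    paths = session_paths(directory, session_id)
    for key, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing session {key} file: {p}")

    neurons_df = pd.read_csv(paths["neurons"], dtype={"neuron_id": str})
    _require_cols(neurons_df, _NEURON_COLS, "neurons")
    spikes_df = pd.read_csv(
        paths["spikes"], dtype={"neuron_id": str, "time_s": float},
        float_precision="round_trip",
    )
    _require_cols(spikes_df, _SPIKE_COLS, "spikes")
    trials_df = pd.read_csv(paths["trials"], float_precision="round_trip")
    _require_cols(trials_df, _TRIAL_COLS, "trials")

    by_neuron = {
        k: g["time_s"].to_numpy() for k, g in spikes_df.groupby("neuron_id", sort=False)
    }
    neurons = [
        NeuronRecord(
            neuron_id=row.neuron_id,
            region=row.region,
            hemisphere=row.hemisphere,
            spike_times=by_neuron.get(row.neuron_id, np.empty(0)),
            spike_duration_ms=float(row.spike_duration_ms),
            spike_width_ms=float(row.spike_width_ms),
        )
        for row in neurons_df.itertuples(index=False)
    ]

    trials = [
        Trial(
            trial_id=int(row.trial_id),
            release_time_s=float(row.release_time_s),
            outcome_time_s=(
                float(row.outcome_time_s)
                if pd.notna(row.outcome_time_s)
                else float("nan")
            ),
            choice=str(row.choice),
            outcome=str(row.outcome),
            both_forelimbs=_parse_bool(row.both_forelimbs),
        )
        for row in trials_df.itertuples(index=False)
    ]

    session = Session(session_id=session_id, neurons=neurons, trials=trials)
    session.validate_span(span_margin_s)
    return session


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise SchemaError(f"cannot parse boolean value {x!r}")


# ---------------------------------------------------------------------------
# Trial filtering, laterality, alignment
# ---------------------------------------------------------------------------

def filter_trials(session: Session) -> Session:
    """Keep trials usable for reward decoding.

    Retains trials with a defined outcome (rewarded or nonrewarded; immature
    trials received no feedback) in which only one forelimb moved during the
    post-action period.  Order is preserved; idempotent.
    """
    kept = tuple(
        t
        for t in session.trials
        if t.outcome in ("rewarded", "nonrewarded") and not t.both_forelimbs
    )
    return replace(session, trials=kept)


def classify_laterality(neuron: NeuronRecord, trial: Trial) -> str:
    """Label a trial contra/ipsi relative to the neuron's recorded hemisphere."""
    return "contra" if trial.choice != neuron.hemisphere else "ipsi"


def _trigger_time(trial: Trial, trigger: str) -> float:
    if trigger == "action":
        return trial.release_time_s
    if trigger == "outcome":
        return trial.outcome_time_s
    raise ValueError(f"unknown trigger {trigger!r}")


def condition_trials(
    neuron: NeuronRecord, trials: Iterable[Trial], condition: str
) -> list[Trial]:
    """Select the trials contributing to one AC/AI/OC/OI condition.

    Outcome labels (rewarded vs nonrewarded) are handled separately by the
    caller; the condition only fixes the trigger and the movement laterality.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    side = "contra" if condition in ("AC", "OC") else "ipsi"
    return [t for t in trials if classify_laterality(neuron, t) == side]


def align_spikes(
    neuron: NeuronRecord,
    trials: Sequence[Trial],
    trigger: str,
    condition: str,
    window_ms: tuple[float, float] = (-500.0, 500.0),
) -> AlignedSpikes:
    """Express spikes as ms relative to each trial's trigger within a window.

    Trials with zero spikes in the window are retained as empty lists so that
    ``n_trials`` counts retained trials, not spiking trials.
    """
    lo, hi = window_ms
    if not lo < hi:
        raise ValueError("window start must precede window end")
    per_trial = []
    st = neuron.spike_times
    for t in trials:
        t0 = _trigger_time(t, trigger)
        if not np.isfinite(t0):
            continue
        a = np.searchsorted(st, t0 + lo / 1000.0, side="left")
        b = np.searchsorted(st, t0 + hi / 1000.0, side="left")
        rel = (st[a:b] - t0) * 1000.0
        # guard the half-open convention against float rounding at the edges
        rel = rel[(rel >= lo) & (rel < hi)]
        per_trial.append(rel)
    return AlignedSpikes(
        trigger=trigger,
        condition=condition,
        window_ms=(lo, hi),
        trial_spikes=tuple(per_trial),
    )
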