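"""Synthetic task events and reward-modulated spike trains.

No public accession exists for the recordings this pipeline targets, so every
downstream stage is exercised on simulated sessions that emulate the study
conditions: block-structured self-initiated choice trials with >= 1 s holding,
0.3-0.7 s reward delays in 0.1 s steps, ~72% correct performance, and
region-specific reward modulation motifs:

* dCA1  - strong transient excitation shortly after reward delivery;
* vCA1  - small peak followed by post-reward suppression;
* LEC   - suppression-dominant response (negative rate-change index);
* PPC   - heterogeneous mixture of excited and suppressed subpopulations,
          with excitability linked to intrinsic burstiness;
* M2    - no mean-rate change; reward signalled only through the temporal
          distribution of spikes within the outcome window;
* M1    - weak excitation with direction-dependent timing asymmetry.

Spike trains are drawn from an inhomogeneous renewal process via
time-rescaling: with gamma ISI shape 1 this is an inhomogeneous Poisson
process; larger shapes give more regular firing (lower Lv ~ 3/(2k+1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .core_io import NeuronRecord, Session, Trial

__all__ = [
    "TaskConfig",
    "RegionArchetype",
    "EffectGradient",
    "REGION_PRESETS",
    "DEFAULT_GRADIENT",
    "simulate_task",
    "rate_function",
    "simulate_neuron",
    "simulate_study",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the self-initiated left-right pedal choice task."""

    n_trials: int = 120
    p_correct: float = 0.72
    hold_min_s: float = 1.0
    hold_mean_extra_s: float = 0.5  # exponential extra holding beyond the minimum
    delay_choices_s: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7)
    inter_trial_gap_s: float = 2.0
    p_both_forelimbs: float = 0.05
    p_immature: float = 0.05
    # block alternates after (min correct in block, accuracy over last 10) or
    # after max_block_rewards rewards
    block_criterion: tuple[int, float] = (30, 0.8)
    max_block_rewards: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.p_correct <= 1:
            raise ValueError("p_correct must lie in (0, 1]")
        if any(not 0 < d <= 2 for d in self.delay_choices_s):
            raise ValueError("delay choices must lie in (0, 2] s")


@dataclass(frozen=True)
class RegionArchetype:
    """Generative parameters for one region's reward-response motif.

    Amplitudes are in Hz; latencies/widths/durations in ms.  ``timing_shift``
    redistributes spikes within the post-outcome window on nonrewarded trials
    without changing the mean rate (strength 0-1).  ``direction_dependence``
    multiplies modulation amplitude on contralateral trials.  ``isi_shape`` is
    the gamma renewal shape: 1 = Poisson-like (Lv ~ 1), large = regular.
    """

    name: str
    baseline_log_mu: float = np.log(4.0)
    baseline_log_sigma: float = 0.6
    bump_amp_hz: float = 0.0
    bump_latency_ms: float = 60.0
    bump_width_ms: float = 40.0
    bump_frac: float = 0.0
    supp_depth: float = 0.0
    supp_onset_ms: float = 100.0
    supp_dur_ms: float = 300.0
    supp_frac: float = 0.0
    timing_shift: float = 0.0
    direction_dependence: float = 1.0
    isi_shape: float = 1.0

    def __post_init__(self) -> None:
        if self.bump_amp_hz < 0:
            raise ValueError("bump amplitude must be >= 0")
        if not 0 <= self.supp_depth <= 1:
            raise ValueError("suppression depth must lie in [0, 1]")
        for f in (self.bump_frac, self.supp_frac):
            if not 0 <= f <= 1:
                raise ValueError("neuron fractions must lie in [0, 1]")
        if not 0 <= self.timing_shift <= 1:
            raise ValueError("timing_shift must lie in [0, 1]")
        if self.isi_shape <= 0:
            raise ValueError("isi_shape must be positive")


REGION_PRESETS: dict[str, RegionArchetype] = {
    "dCA1": RegionArchetype(
        name="dCA1", bump_amp_hz=10.0, bump_latency_ms=60.0, bump_width_ms=40.0,
        bump_frac=0.7, direction_dependence=1.2,
    ),
    "vCA1": RegionArchetype(
        name="vCA1", bump_amp_hz=3.0, bump_latency_ms=80.0, bump_width_ms=50.0,
        bump_frac=0.5, supp_depth=0.7, supp_onset_ms=150.0, supp_dur_ms=350.0,
        supp_frac=0.7, direction_dependence=1.1,
    ),
    "LEC": RegionArchetype(
        name="LEC", baseline_log_mu=np.log(5.0), bump_amp_hz=1.5,
        bump_latency_ms=80.0, bump_width_ms=60.0, bump_frac=0.25,
        supp_depth=0.65, supp_onset_ms=100.0, supp_dur_ms=400.0, supp_frac=0.8,
        timing_shift=0.1,
    ),
    "PPC": RegionArchetype(
        name="PPC", bump_amp_hz=4.0, bump_latency_ms=70.0, bump_width_ms=50.0,
        bump_frac=0.4, supp_depth=0.5, supp_onset_ms=120.0, supp_dur_ms=300.0,
        supp_frac=0.35, timing_shift=0.2, direction_dependence=1.1,
        isi_shape=1.1,
    ),
    "M2": RegionArchetype(
        name="M2", baseline_log_mu=np.log(5.0), timing_shift=0.8,
    ),
    "M1": RegionArchetype(
        name="M1", baseline_log_mu=np.log(5.0), bump_amp_hz=2.0,
        bump_latency_ms=90.0, bump_width_ms=60.0, bump_frac=0.3,
        timing_shift=0.4, direction_dependence=1.5,
    ),
}


@dataclass(frozen=True)
class EffectGradient:
    """Per-region multipliers encoding the intended decoding hierarchy."""

    multipliers: Mapping[str, float] = field(
        default_factory=lambda: {
            "dCA1": 1.0, "vCA1": 0.95, "LEC": 0.65, "PPC": 0.6,
            "M2": 0.35, "M1": 0.3,
        }
    )

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.multipliers.values()):
            raise ValueError("effect multipliers must be non-negative")

    def __getitem__(self, region: str) -> float:
        return self.multipliers[region]

    @classmethod
    def zeros(cls, regions: Sequence[str] = ("M1", "M2", "PPC", "LEC", "dCA1", "vCA1")):
        return cls({r: 0.0 for r in regions})


DEFAULT_GRADIENT = EffectGradient()


# ---------------------------------------------------------------------------
# Task simulation
# ---------------------------------------------------------------------------

def simulate_task(config: TaskConfig, seed: int | np.random.Generator) -> list[Trial]:
    """Simulate one session's trial event table.

    Blocks alternate between right- and left-rewarded; each trial the animal
    releases the correct pedal with probability ``p_correct``.  Rewarded trials
    get reward-pump onset at release + delay drawn uniformly from the delay
    choices; nonrewarded trials get the error cue at the same delay mechanism.
    """
    if config.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    t = 10.0  # head start so pre-trial baselines exist
    block_side = "right" if rng.random() < 0.5 else "left"
    block_correct = 0
    block_rewards = 0
    recent: list[bool] = []
    min_correct, recent_acc = config.block_criterion

    for i in range(config.n_trials):
        hold = config.hold_min_s + rng.exponential(config.hold_mean_extra_s)
        release = t + hold
        immature = rng.random() < config.p_immature
        correct = rng.random() < config.p_correct
        choice = block_side if correct else ("left" if block_side == "right" else "right")
        delay = float(rng.choice(config.delay_choices_s))
        if immature:
            outcome = "immature"
            outcome_time = float("nan")
        else:
            outcome = "rewarded" if correct else "nonrewarded"
            outcome_time = release + delay
        trials.append(
            Trial(
                trial_id=i,
                release_time_s=release,
                outcome_time_s=outcome_time,
                choice=choice,
                outcome=outcome,
                both_forelimbs=bool(rng.random() < config.p_both_forelimbs),
            )
        )
        if not immature:
            recent.append(correct)
            recent = recent[-10:]
            if correct:
                block_correct += 1
                block_rewards += 1
            reached = (
                block_correct > min_correct
                and len(recent) == 10
                and np.mean(recent) >= recent_acc
            ) or block_rewards >= config.max_block_rewards
            if reached:
                block_side = "left" if block_side == "right" else "right"
                block_correct = 0
                block_rewards = 0
                recent = []
        t = release + delay + config.inter_trial_gap_s + rng.uniform(0.0, 1.0)
    return trials


# ---------------------------------------------------------------------------
# Firing-rate functions and renewal simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronDraw:
    """Per-neuron generative parameters sampled from an archetype.

    Population heterogeneity lives here: membership in the excited/suppressed
    subpopulations, lognormal jitter of amplitudes and widths, latency jitter,
    and a private phase for the timing-shift perturbation so that the
    direction of within-window rate redistribution varies across neurons.
    """

    baseline_hz: float
    bump_amp_hz: float        # 0 for non-members, jittered otherwise
    bump_latency_s: float
    bump_width_s: float
    supp_depth: float         # 0 for non-members
    ts_phase: float           # radians
    isi_shape: float
    spike_duration_ms: float
    spike_width_ms: float


def draw_neuron_params(
    archetype: RegionArchetype, rng: np.random.Generator
) -> NeuronDraw:
    baseline = float(
        np.exp(rng.normal(archetype.baseline_log_mu, archetype.baseline_log_sigma))
    )
    has_bump = rng.random() < archetype.bump_frac
    has_supp = rng.random() < archetype.supp_frac
    shape = archetype.isi_shape * float(np.exp(rng.normal(0.0, 0.25)))
    # excitable subpopulations fire in bursts: link membership to burstiness
    if has_bump and archetype.supp_frac > 0 and archetype.bump_frac > 0:
        shape *= 0.7
    amp = archetype.bump_amp_hz * float(np.exp(rng.normal(0.0, 0.4)))
    lat = max(0.01, archetype.bump_latency_ms / 1000.0 + rng.normal(0.0, 0.015))
    wid = archetype.bump_width_ms / 1000.0 * float(np.exp(rng.normal(0.0, 0.2)))
    depth = archetype.supp_depth * float(rng.uniform(0.7, 1.0))
    return NeuronDraw(
        baseline_hz=baseline,
        bump_amp_hz=amp if has_bump else 0.0,
        bump_latency_s=lat,
        bump_width_s=wid,
        supp_depth=depth if has_supp else 0.0,
        ts_phase=float(rng.uniform(0.0, 2.0 * np.pi)),
        isi_shape=shape,
        spike_duration_ms=float(rng.uniform(0.3, 0.9)),
        spike_width_ms=float(rng.uniform(0.15, 0.5)),
    )


def nominal_draw(archetype: RegionArchetype, baseline_hz: float = 5.0) -> NeuronDraw:
    """A deterministic draw at the archetype's nominal parameters (no jitter)."""
    return NeuronDraw(
        baseline_hz=baseline_hz,
        bump_amp_hz=archetype.bump_amp_hz,
        bump_latency_s=archetype.bump_latency_ms / 1000.0,
        bump_width_s=archetype.bump_width_ms / 1000.0,
        supp_depth=archetype.supp_depth,
        ts_phase=0.0,
        isi_shape=archetype.isi_shape,
        spike_duration_ms=0.5,
        spike_width_ms=0.3,
    )


def rate_function(
    archetype: RegionArchetype,
    trial: Trial,
    contra: bool = True,
    *,
    draw: NeuronDraw | None = None,
    effect: float = 1.0,
    gain: float = 1.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Intensity (Hz) as a function of absolute time for one trial's outcome.

    Rewarded trials receive the bump and suppression terms; nonrewarded trials
    receive only the mean-preserving timing-shift perturbation within the
    post-outcome window.  ``gain`` carries per-trial modulation variability.
    The returned function is vectorised and clipped at 0.
    """
    d = draw if draw is not None else nominal_draw(archetype)
    t_out = trial.outcome_time_s
    dir_gain = archetype.direction_dependence if contra else 1.0
    bump_amp = d.bump_amp_hz * effect * dir_gain * gain
    supp_depth = min(d.supp_depth * effect * dir_gain * gain, 0.95)
    ts = min(archetype.timing_shift * effect * dir_gain * gain, 0.95)
    lat, wid = d.bump_latency_s, d.bump_width_s
    s_on = archetype.supp_onset_ms / 1000.0
    s_dur = archetype.supp_dur_ms / 1000.0
    phase = d.ts_phase
    baseline_hz = d.baseline_hz
    rewarded = trial.outcome == "rewarded"

    def rate(time_s: np.ndarray) -> np.ndarray:
        time_s = np.asarray(time_s, dtype=float)
        lam = np.full(time_s.shape, baseline_hz)
        if not np.isfinite(t_out):
            return lam
        if rewarded:
            if bump_amp > 0:
                lam = lam + bump_amp * np.exp(
                    -0.5 * ((time_s - (t_out + lat)) / wid) ** 2
                )
            if supp_depth > 0:
                inside = (time_s >= t_out + s_on) & (time_s < t_out + s_on + s_dur)
                lam = lam - supp_depth * baseline_hz * inside
        elif ts > 0:
            # one full cosine period over the 500 ms outcome window: integral
            # is zero for any phase, so the mean rate is preserved
            inside = (time_s >= t_out) & (time_s < t_out + 0.5)
            lam = lam + baseline_hz * ts * np.cos(
                2.0 * np.pi * (time_s - t_out) / 0.5 + phase
            ) * inside
        return np.clip(lam, 0.0, None)

    return rate


def _session_intensity(
    archetype: RegionArchetype,
    trials: Sequence[Trial],
    hemisphere: str,
    draw: NeuronDraw,
    effect: float,
    grid: np.ndarray,
    gains: Sequence[float],
) -> np.ndarray:
    """Evaluate the neuron's intensity on a uniform time grid."""
    lam = np.full(grid.shape, draw.baseline_hz)
    dt = grid[1] - grid[0]
    for trial, gain in zip(trials, gains):
        t_out = trial.outcome_time_s
        if not np.isfinite(t_out):
            continue
        contra = trial.choice != hemisphere
        fn = rate_function(
            archetype, trial, contra, draw=draw, effect=effect, gain=gain
        )
        lo = max(0, int((t_out - 0.5 - grid[0]) / dt))
        hi = min(grid.size, int((t_out + 1.2 - grid[0]) / dt) + 1)
        lam[lo:hi] += fn(grid[lo:hi]) - draw.baseline_hz
    return np.clip(lam, 0.0, None)


def _renewal_spikes(
    intensity: np.ndarray, grid: np.ndarray, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Time-rescaled gamma renewal sampling on a gridded intensity.

    In rescaled time the process is a unit-rate renewal process with
    gamma(shape, 1/shape) increments; mapping event times back through the
    inverse cumulative intensity yields the inhomogeneous train.  shape = 1
    recovers the inhomogeneous Poisson process.
    """
    dt = grid[1] - grid[0]
    cum = np.concatenate([[0.0], np.cumsum(intensity) * dt])
    edges = np.concatenate([grid, [grid[-1] + dt]])
    total = cum[-1]
    if total <= 0:
        return np.empty(0)
    n_guess = int(total + 6.0 * np.sqrt(total) + 20)
    increments = rng.gamma(shape, 1.0 / shape, size=n_guess)
    rescaled = np.cumsum(increments)
    while rescaled.size and rescaled[-1] < total:
        more = rng.gamma(shape, 1.0 / shape, size=n_guess)
        rescaled = np.concatenate([rescaled, rescaled[-1] + np.cumsum(more)])
    rescaled = rescaled[rescaled < total]
    times = np.interp(rescaled, cum, edges)
    # enforce strictly ascending timestamps (degenerate only if dt-quantised)
    return np.unique(times)


def simulate_neuron(
    archetype: RegionArchetype,
    trials: Sequence[Trial],
    hemisphere: str,
    seed: int | np.random.Generator,
    *,
    effect: float = 1.0,
    neuron_id: str = "n0",
    dt: float = 0.001,
) -> NeuronRecord:
    """Simulate one neuron's full-session spike train against a trial table."""
    rng = np.random.default_rng(seed)
    draw = draw_neuron_params(archetype, rng)
    t_end = 10.0
    for t in trials:
        hi = t.outcome_time_s if np.isfinite(t.outcome_time_s) else t.release_time_s
        t_end = max(t_end, hi + 2.0)
    grid = np.arange(0.0, t_end, dt)
    # per-trial multiplicative gain on the modulation (lognormal, mean 1)
    gains = np.exp(rng.normal(-0.3**2 / 2.0, 0.3, size=len(trials)))
    lam = _session_intensity(archetype, trials, hemisphere, draw, effect, grid, gains)
    spikes = _renewal_spikes(lam, grid, draw.isi_shape, rng)
    return NeuronRecord(
        neuron_id=neuron_id,
        region=archetype.name,
        hemisphere=hemisphere,
        spike_times=spikes,
        spike_duration_ms=draw.spike_duration_ms,
        spike_width_ms=draw.spike_width_ms,
    )


def simulate_study(
    archetypes: Mapping[str, RegionArchetype] | None = None,
    gradient: EffectGradient | None = None,
    n_neurons: int = 100,
    task_config: TaskConfig | None = None,
    seed: int = 0,
    n_sessions: int = 2,
) -> dict[str, list[Session]]:
    """Simulate the whole multi-region study.

    Each region gets ``n_sessions`` sessions whose neurons split ``n_neurons``
    as evenly as possible; hemisphere is assigned per session.  Fully
    deterministic under ``seed``.
    """
    archetypes = dict(archetypes or REGION_PRESETS)
    gradient = gradient or DEFAULT_GRADIENT
    task_config = task_config or TaskConfig()
    out: dict[str, list[Session]] = {}
    for ri, (region, arch) in enumerate(sorted(archetypes.items())):
        effect = gradient[region]
        sessions = []
        counts = [
            n_neurons // n_sessions + (1 if s < n_neurons % n_sessions else 0)
            for s in range(n_sessions)
        ]
        for si, count in enumerate(counts):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(ri, si))
            )
            trials = simulate_task(task_config, rng)
            hemisphere = "left" if rng.random() < 0.5 else "right"
            neurons = [
                simulate_neuron(
                    arch,
                    trials,
                    hemisphere,
                    rng,
                    effect=effect,
                    neuron_id=f"{region}-s{si}-n{ni}",
                )
                for ni in range(count)
            ]
            sessions.append(
                Session(
                    session_id=f"{region}-s{si}", neurons=neurons, trials=trials
                )
            )
        out[region] = sessions
    return out
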