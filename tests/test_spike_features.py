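"""Feature statistics against hand arithmetic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rewarddecode as rd
from rewarddecode.core_io import AlignedSpikes, NeuronRecord, Session, Trial
from rewarddecode.spike_features import (
    FEATURE_NAMES,
    FUNDAMENTAL_NAMES,
    FeatureConfig,
    build_feature_matrix,
    build_feature_vector,
    compute_acg,
    compute_cv,
    compute_lv,
    compute_peth,
    feature_schema,
    frc_index,
    ks_uniform,
    match_trial_counts,
    mean_rate_hz,
    peak_rate_hz,
    timing_stats,
)


def _aligned(times, window=(0.0, 500.0), n_trials=1):
    """Pool all times into the first trial; pad with empty trials."""
    trials = [np.asarray(times, dtype=float)] + [np.empty(0)] * (n_trials - 1)
    return AlignedSpikes("outcome", "OC", window, tuple(trials))


class TestCvLv:
    def test_regular_isis_zero(self):
        assert compute_cv([1.0, 1.0, 1.0]) == 0.0
        assert compute_lv([1.0, 1.0, 1.0, 1.0]) == 0.0

    def test_hand_arithmetic(self):
        assert compute_cv([2.0, 4.0, 6.0]) == pytest.approx(0.5)  # mean 4, sd 2
        assert compute_lv([1.0, 3.0]) == pytest.approx(0.75)  # 3 * (2/4)^2

    def test_exponential_isis_near_one(self):
        rng = np.random.default_rng(0)
        isis = rng.exponential(1.0, size=10_000)
        assert compute_cv(isis) == pytest.approx(1.0, abs=0.05)

    def test_poisson_lv_mean_within_three_se(self):
        rng = np.random.default_rng(1)
        lvs = [compute_lv(rng.exponential(1.0, size=500)) for _ in range(200)]
        se = np.std(lvs, ddof=1) / np.sqrt(len(lvs))
        assert abs(np.mean(lvs) - 1.0) < 3 * se

    def test_insufficient_data_masked(self):
        assert np.isnan(compute_cv([1.0]))
        assert np.isnan(compute_lv([1.0]))
        assert np.isnan(compute_lv([0.0, 0.0]))  # zero-sum adjacent pair

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-3, 1e3), min_size=2, max_size=50))
    def test_nonnegative(self, isis):
        assert compute_cv(isis) >= 0
        assert compute_lv(isis) >= 0


class TestACG:
    def test_two_spikes_single_bin(self):
        acg = compute_acg(np.array([0.0, 0.010]))
        nz = np.nonzero(acg.values)[0]
        assert list(nz) == [10]  # lag bin [10, 11) ms

    def test_poisson_flat_profile(self):
        rng = np.random.default_rng(2)
        spikes = np.cumsum(rng.exponential(1 / 20.0, size=20_000))
        acg = compute_acg(spikes)
        assert 0.8 < acg.peak_bias / acg.baseline_bias < 1.2

    def test_bursty_train_peak_exceeds_baseline(self):
        # burst firing: half the ISIs short (mean 15 ms), half long (mean 1 s)
        rng = np.random.default_rng(3)
        short = rng.random(4000) < 0.5
        isis = np.where(short, rng.exponential(0.015, 4000),
                        rng.exponential(1.0, 4000))
        spikes = np.cumsum(isis)
        acg = compute_acg(spikes)
        assert acg.peak_bias > acg.baseline_bias

    def test_too_few_spikes_masked(self):
        acg = compute_acg(np.array([1.0]))
        assert np.isnan(acg.classical_bias)


class TestPETH:
    def _aligned_multi(self, per_trial, window=(0.0, 500.0)):
        return AlignedSpikes(
            "outcome", "OC", window, tuple(np.asarray(t, float) for t in per_trial)
        )

    def test_hand_rate(self):
        # 5 spikes in one 20 ms bin over 10 trials -> 25 Hz
        al = self._aligned_multi([[5.0, 6.0, 7.0, 8.0, 9.0]] + [[]] * 9)
        peth = compute_peth(al, 20.0)
        assert peth.rates_hz[0] == pytest.approx(25.0)

    def test_no_spikes_all_zero(self):
        peth = compute_peth(self._aligned_multi([[], []]), 20.0)
        assert np.all(peth.rates_hz == 0)

    def test_conservation_identity(self):
        rng = np.random.default_rng(4)
        per_trial = [rng.uniform(0, 500, rng.integers(0, 30)) for _ in range(7)]
        al = self._aligned_multi(per_trial)
        peth = compute_peth(al, 20.0)
        total = np.sum(peth.rates_hz * 0.020 * al.n_trials)
        assert total == pytest.approx(al.total_spikes)

    def test_zero_trials_error(self):
        with pytest.raises(ValueError):
            compute_peth(AlignedSpikes("outcome", "OC", (0.0, 500.0), ()))


class TestTimingStats:
    def test_hand_example(self):
        ts = timing_stats(_aligned([100.0, 200.0, 300.0]), min_spikes=3)
        assert ts["mean_ms"] == pytest.approx(200.0)
        assert ts["sd_ms"] == pytest.approx(100.0)
        assert ts["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert ts["q2_ms"] == pytest.approx(200.0)

    def test_symmetric_sample_zero_skew(self):
        ts = timing_stats(_aligned([10, 20, 30, 40, 50, 60, 70, 80, 90, 100]),
                          min_spikes=10)
        assert ts["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_below_min_spikes_all_masked(self):
        ts = timing_stats(_aligned([1.0, 2.0]), min_spikes=10)
        assert all(np.isnan(v) for v in ts.values())

    def test_oracle_equivalence_on_random_samples(self):
        """Moments/quartiles match independent brute-force formulas to 1e-9."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.uniform(0, 500, rng.integers(10, 60))
            ts = timing_stats(_aligned(x), min_spikes=10)
            n = x.size
            mu = x.sum() / n
            m2 = ((x - mu) ** 2).sum() / n
            m3 = ((x - mu) ** 3).sum() / n
            m4 = ((x - mu) ** 4).sum() / n
            assert ts["mean_ms"] == pytest.approx(mu, abs=1e-9)
            assert ts["sd_ms"] == pytest.approx(
                np.sqrt(((x - mu) ** 2).sum() / (n - 1)), abs=1e-9
            )
            assert ts["skewness"] == pytest.approx(m3 / m2**1.5, abs=1e-9)
            assert ts["kurtosis"] == pytest.approx(m4 / m2**2, abs=1e-9)
            # quartiles: linear interpolation oracle
            for q, key in ((25, "q1_ms"), (50, "q2_ms"), (75, "q3_ms")):
                xs = np.sort(x)
                h = (n - 1) * q / 100
                lo = int(np.floor(h))
                val = xs[lo] + (h - lo) * (xs[min(lo + 1, n - 1)] - xs[lo])
                assert ts[key] == pytest.approx(val, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 499.99), min_size=10, max_size=80))
    def test_quartile_ordering(self, times):
        ts = timing_stats(_aligned(times), min_spikes=10)
        assert ts["q1_ms"] <= ts["q2_ms"] <= ts["q3_ms"]
        assert 0 <= ts["q1_ms"] and ts["q3_ms"] < 500


def _ks_oracle(x, lo, hi):
    """Exhaustive sup of |ECDF - uniform CDF| over the step points."""
    xs = np.sort(np.asarray(x, float))
    n = xs.size
    F = (xs - lo) / (hi - lo)
    d_plus = np.max(np.arange(1, n + 1) / n - F)
    d_minus = np.max(F - np.arange(0, n) / n)
    return max(d_plus, d_minus)


class TestKSUniform:
    def test_all_spikes_at_window_start(self):
        x = np.zeros(20)
        d = ks_uniform(_aligned(x), min_spikes=10)
        assert d == pytest.approx(_ks_oracle(x, 0, 500), abs=1e-12)

    def test_uniform_quantiles(self):
        n = 19
        x = 500 * np.arange(1, n + 1) / (n + 1)
        d = ks_uniform(_aligned(x), min_spikes=10)
        assert d == pytest.approx(1 / (n + 1), abs=1e-12)
        assert d == pytest.approx(_ks_oracle(x, 0, 500), abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 500, 40)
        d1 = ks_uniform(_aligned(x), min_spikes=10)
        d2 = ks_uniform(_aligned(x - 500, window=(-500.0, 0.0)), min_spikes=10)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_oracle_equivalence_on_random_samples(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.uniform(0, 500, rng.integers(10, 50))
            d = ks_uniform(_aligned(x), min_spikes=10)
            assert d == pytest.approx(_ks_oracle(x, 0, 500), abs=1e-9)

    def test_below_min_spikes_masked(self):
        assert np.isnan(ks_uniform(_aligned([1.0]), min_spikes=10))


class TestFRc:
    def test_hand_arithmetic(self):
        assert frc_index(10.0, 30.0) == pytest.approx(0.5)

    def test_symmetry_and_boundaries(self):
        assert frc_index(5.0, 5.0) == 0.0
        assert frc_index(3.0, 0.0) == -1.0
        assert np.isnan(frc_index(0.0, 0.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 1e3), st.floats(0, 1e3))
    def test_bounded(self, pre, post):
        v = frc_index(pre, post)
        if not np.isnan(v):
            assert -1.0 <= v <= 1.0


@pytest.fixture(scope="module")
def session():
    trials = rd.simulate_task(rd.TaskConfig(n_trials=200), seed=0)
    neurons = [
        rd.synthetic_data.simulate_neuron(
            rd.REGION_PRESETS["dCA1"], trials, "left", 10 + i,
            neuron_id=f"n{i}",
        )
        for i in range(4)
    ]
    return Session("fx", neurons, trials)


class TestFeatureVector:

    def test_exactly_88_named_features(self, session):
        trials = rd.filter_trials(session).trials
        fv = build_feature_vector(session.neurons[0], trials, "rewarded")
        assert len(fv.values) == 88
        assert set(fv.values) == set(FEATURE_NAMES)

    def test_fundamentals_identical_across_condition_rows(self, session):
        trials = rd.filter_trials(session).trials
        a = build_feature_vector(session.neurons[0], trials, "rewarded")
        b = build_feature_vector(session.neurons[0], trials, "nonrewarded")
        for name in FUNDAMENTAL_NAMES:
            assert a.values[name] == b.values[name]

    def test_zero_spike_condition_masked_but_complete(self, session):
        silent = NeuronRecord(
            neuron_id="silent", region="dCA1", hemisphere="left",
            spike_times=np.array([0.5, 1.0]), spike_duration_ms=0.5,
            spike_width_ms=0.3,
        )
        trials = rd.filter_trials(session).trials
        fv = build_feature_vector(silent, trials, "rewarded")
        assert len(fv.values) == 88
        assert np.isnan(fv.values["oc_timing_mean_ms"])
        assert np.isnan(fv.values["oc_ks_d"])

    def test_matrix_two_rows_per_neuron(self, session):
        m = build_feature_matrix([session])
        assert len(m) == 2 * len(session.neurons)
        assert set(m["label"]) == {0, 1}
        assert (m["label"] == 1).sum() == (m["condition"] == "rewarded").sum()

    def test_min_trials_exclusion_drops_single_row(self, session):
        cfg = FeatureConfig(min_trials=10_000)
        with pytest.raises(ValueError):
            build_feature_matrix([session], cfg)
        # a condition below threshold drops only that row
        few = [t for t in session.trials if t.outcome == "rewarded"][:6]
        many = [t for t in session.trials if t.outcome == "nonrewarded"]
        s2 = Session("s2", session.neurons[:1], few + many)
        m = build_feature_matrix([s2], FeatureConfig(min_trials=5,
                                                     match_trial_counts=False))
        assert len(m) == 2
        s3 = Session("s3", session.neurons[:1], few[:2] + many)
        m3 = build_feature_matrix([s3], FeatureConfig(min_trials=5,
                                                      match_trial_counts=False))
        assert len(m3) == 1
        assert m3["condition"].iloc[0] == "nonrewarded"

    def test_peak_rate_dominates_mean_rate(self, session):
        m = build_feature_matrix([session])
        for tag in ("0_50", "50_100", "100_250", "250_500", "0_500"):
            mean = m[f"oc_mean_fr_{tag}"]
            peak = m[f"oc_peak_fr_{tag}"]
            ok = mean.notna() & peak.notna()
            assert np.all(peak[ok] >= mean[ok] - 1e-9)

    def test_all_finite_or_masked(self, session):
        m = build_feature_matrix([session])
        vals = m[list(FEATURE_NAMES)].to_numpy(float)
        assert not np.isinf(vals).any()


class TestTrialCountMatching:
    def test_counts_equalized_per_side(self):
        trials = rd.simulate_task(rd.TaskConfig(n_trials=200, p_immature=0.0), seed=1)
        matched = match_trial_counts(trials, seed=0)
        for side in ("left", "right"):
            rew = sum(1 for t in matched if t.choice == side and t.outcome == "rewarded")
            non = sum(1 for t in matched if t.choice == side and t.outcome == "nonrewarded")
            assert rew == non

    def test_deterministic(self):
        trials = rd.simulate_task(rd.TaskConfig(n_trials=100), seed=2)
        a = match_trial_counts(trials, seed=5)
        b = match_trial_counts(trials, seed=5)
        assert [t.trial_id for t in a] == [t.trial_id for t in b]


class TestSchema:
    def test_schema_tags_cover_all_features(self):
        schema = feature_schema()
        assert len(schema) == 88
        assert set(schema["group"]) == {"fundamental", "timing", "rate"}
        assert (schema["group"] == "fundamental").sum() == 8
        assert (schema["group"] == "timing").sum() == 32
        assert (schema["group"] == "rate").sum() == 48
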