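import numpy as np
import pytest
from scipy import stats

from entrainalyze.behavior import detect_saccade
from entrainalyze.core_io import write_session
from entrainalyze.synthetic_data import (
    LONG_TUNED_CURVE,
    CovariationParams,
    RateProfileParams,
    TaskParams,
    build_population,
    dentate_params,
    generate_eye_trace,
    generate_trials,
    rate_profile,
    sample_behavior,
    sample_sequence_length,
    sample_spikes,
    simulate_session,
    simulate_stim_session,
)

from conftest import make_trial


class TestGenerateTrials:
    def test_forced_length_arithmetic(self, rng):
        task = TaskParams(sequence_length_range=(2000, 2000))
        (trial,) = generate_trials(
            task, 1, rng, conditions=("missing",), isis=(400,)
        )
        np.testing.assert_array_equal(
            trial.stimulus_onsets, [0, 400, 800, 1200, 1600]
        )
        assert trial.oddball_time == 2000

    def test_isi600_sequence_at_least_3000(self, rng):
        task = TaskParams()
        trials = generate_trials(task, 300, rng, conditions=("missing",), isis=(600,))
        assert all(t.oddball_time >= 3000 for t in trials)

    def test_sequence_lengths_uniform_ks(self, rng):
        task = TaskParams()
        draws = np.array(
            [sample_sequence_length(task, 400, rng) for _ in range(10_000)]
        )
        assert draws.min() >= 2000 and draws.max() <= 4800
        ks = stats.kstest(draws, stats.uniform(2000, 2801).cdf)
        assert ks.pvalue > 0.01

    def test_deviant_always_400(self, rng):
        trials = generate_trials(TaskParams(), 200, rng)
        assert all(t.isi == 400 for t in trials if t.condition == "deviant")

    def test_n_trials_positive(self, rng):
        with pytest.raises(ValueError):
            generate_trials(TaskParams(), 0, rng)


class TestRateProfile:
    def test_zero_amplitude_flat_baseline(self):
        trial = make_trial()
        trace = rate_profile(trial, RateProfileParams(amplitude=0.0, baseline=12.0))
        assert np.all(trace.values == 12.0)

    def test_dentate_trough_at_200ms(self):
        trial = make_trial(isi=400, n_stimuli=6)
        trace = rate_profile(trial, dentate_params())
        for onset in trial.stimulus_onsets:
            seg = trace.values[onset : onset + 400]
            assert abs(int(np.argmin(seg)) - 200) <= 1

    def test_condition_gain_exact_peak_ratio(self):
        params = RateProfileParams(baseline=0.0, condition_gain=1.7)
        miss = make_trial(condition="missing")
        dev = make_trial(condition="deviant", n_stimuli=6)  # same onsets count
        dev = make_trial(condition="deviant")
        r_miss = rate_profile(miss, params).values.max()
        r_dev = rate_profile(dev, params).values.max()
        assert r_miss / r_dev == pytest.approx(1.7, rel=1e-9)

    def test_direction_gain_exact(self):
        params = RateProfileParams(baseline=0.0, direction_gain=1.08)
        contra = make_trial(direction="contra")
        ipsi = make_trial(direction="ipsi")
        ratio = (
            rate_profile(contra, params).values.max()
            / rate_profile(ipsi, params).values.max()
        )
        assert ratio == pytest.approx(1.08, rel=1e-9)

    def test_dentate_ramp_recovers_at_next_onset(self):
        for isi in (300, 400, 600):
            trial = make_trial(isi=isi, n_stimuli=6)
            trace = rate_profile(trial, dentate_params())
            baseline = dentate_params().baseline
            for onset, nxt in zip(trial.stimulus_onsets[:-1], trial.stimulus_onsets[1:]):
                seg = trace.values[onset : nxt + 1]
                # within the interval the rate is below baseline, and it is
                # back at baseline within 2 ms of the next onset
                assert np.all(seg[1:-1] <= baseline)
                assert trace.values[nxt] == pytest.approx(baseline)
                assert trace.values[nxt - 2] < baseline

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            RateProfileParams(profile_kind="cortex")


class TestSampleSpikes:
    def test_zero_rate_empty(self, rng):
        from entrainalyze.spike_density import RateTrace

        trace = RateTrace(values=np.zeros(1000), window=(0, 1000))
        assert len(sample_spikes(trace, rng).spike_times) == 0

    def test_poisson_count_mean(self, rng):
        from entrainalyze.spike_density import RateTrace

        trace = RateTrace(values=np.full(10_000, 50.0), window=(0, 10_000))
        counts = [
            len(sample_spikes(trace, np.random.default_rng(s)).spike_times)
            for s in range(1000)
        ]
        se = np.sqrt(500 / 1000)
        assert abs(np.mean(counts) - 500) < 3 * se

    def test_interspike_intervals_exponential(self, rng):
        from entrainalyze.spike_density import RateTrace

        # low rate so per-ms discretization is negligible for the KS test
        trace = RateTrace(values=np.full(60_000, 10.0), window=(0, 60_000))
        isis = []
        for s in range(10):
            t = sample_spikes(trace, np.random.default_rng(100 + s)).spike_times
            isis.extend(np.diff(t))
        ks = stats.kstest(np.array(isis), stats.expon(scale=100.0).cdf)
        assert ks.pvalue > 0.01

    def test_thinning_matches_rate(self):
        from entrainalyze.spike_density import RateTrace

        trace = RateTrace(values=np.full(20_000, 40.0), window=(0, 20_000))
        counts = [
            len(
                sample_spikes(
                    trace, np.random.default_rng(s), method="thinning"
                ).spike_times
            )
            for s in range(200)
        ]
        se = np.sqrt(800 / 200)
        assert abs(np.mean(counts) - 800) < 3 * se

    def test_expected_count_equals_rate_integral_per_profile(self):
        for name, params in {
            "inc": RateProfileParams(),
            "dec": RateProfileParams(profile_kind="caudate_decrease"),
            "den": dentate_params(),
        }.items():
            trial = make_trial()
            trace = rate_profile(trial, params)
            expected = trace.values.sum() / 1000.0
            counts = [
                len(sample_spikes(trace, np.random.default_rng(s)).spike_times)
                for s in range(300)
            ]
            se = np.sqrt(expected / 300)
            assert abs(np.mean(counts) - expected) < 3 * se, name


class TestBehaviorSampling:
    def test_zero_coupling_zero_perturbation(self, rng):
        trial = make_trial()
        cov = CovariationParams(coupling_strength=0.0)
        _, pert = sample_behavior(trial, cov, rng)
        assert np.all(pert.values == 0)

    def test_omission_locked_window_placement(self, rng):
        trial = make_trial()
        cov = CovariationParams(
            coupling_strength=0.5,
            coupling_lock="omission_locked",
            coupling_onset=-400,
            coupling_offset=-100,
        )
        for _ in range(20):
            lat, pert = sample_behavior(trial, cov, rng)
            nz = np.flatnonzero(pert.values)
            if lat == cov.latency_mean:
                assert len(nz) == 0
                continue
            assert nz[0] == trial.oddball_time - 400
            assert nz[-1] == trial.oddball_time - 100 - 1

    def test_saccade_locked_window_placement(self, rng):
        trial = make_trial()
        cov = CovariationParams(
            coupling_strength=0.5,
            coupling_lock="saccade_locked",
            coupling_onset=-300,
            coupling_offset=0,
        )
        for _ in range(20):
            lat, pert = sample_behavior(trial, cov, rng)
            nz = np.flatnonzero(pert.values)
            if lat == cov.latency_mean:
                assert len(nz) == 0
                continue
            saccade = trial.oddball_time + lat
            assert nz[0] == saccade - 300
            assert nz[-1] == min(saccade - 1, len(pert.values) - 1)

    def test_mean_latency_matches_configuration(self, rng):
        trial = make_trial()
        cov = CovariationParams()
        lats = [sample_behavior(trial, cov, rng)[0] for _ in range(5000)]
        a = (0 - cov.latency_mean) / cov.latency_sd
        b = (600 - cov.latency_mean) / cov.latency_sd
        target = stats.truncnorm(a, b, loc=cov.latency_mean, scale=cov.latency_sd)
        se = target.std() / np.sqrt(len(lats))
        assert abs(np.mean(lats) - target.mean()) < 2 * se + 0.5  # 0.5: rounding


class TestEyeTraces:
    def test_noise_free_presaccadic_velocity_zero(self, rng):
        trial = make_trial()
        eye = generate_eye_trace(trial, 250, rng, noise_sd=0.0)
        pre = slice(0, trial.oddball_time + 249)
        assert np.all(np.diff(eye.x[pre]) == 0)
        assert np.all(np.diff(eye.y[pre]) == 0)

    def test_amplitude_matches_eccentricity(self, rng):
        trial = make_trial()
        eye = generate_eye_trace(trial, 250, rng, noise_sd=0.0)
        assert abs(abs(eye.x[-1]) - 16.0) < 0.1

    def test_closed_loop_latency_recovery(self, rng):
        trial = make_trial()
        eye = generate_eye_trace(trial, 250, rng)
        ev = detect_saccade(eye, trial.oddball_time)
        assert ev is not None
        assert abs(ev.latency - 250) <= 2

    def test_ipsi_direction_sign(self, rng):
        trial = make_trial(direction="ipsi")
        eye = generate_eye_trace(trial, 250, rng, noise_sd=0.0)
        assert eye.x[-1] < 0


class TestDeterminism:
    def test_session_bit_identical_under_seed(self, tmp_path):
        kw = dict(n_trials=25, profile=RateProfileParams(), with_eyes=True, p_early=0.1)
        a = simulate_session(seed=99, **kw)
        b = simulate_session(seed=99, **kw)
        write_session(a, tmp_path / "a")
        write_session(b, tmp_path / "b")
        for name in ("trials.csv", "spikes.csv", "eye.csv", "meta.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_population_deterministic(self):
        a, ma = build_population(4, {"caudate_increase": 0.5, "dentate": 0.5}, seed=5)
        b, mb = build_population(4, {"caudate_increase": 0.5, "dentate": 0.5}, seed=5)
        assert ma == mb
        for sa, sb in zip(a, b):
            for ta, tb in zip(sa.spikes, sb.spikes):
                assert np.array_equal(ta.spike_times, tb.spike_times)


class TestBuildPopulation:
    def test_zero_neurons_empty(self):
        sessions, manifest = build_population(0, {"dentate": 1.0}, seed=1)
        assert sessions == [] and manifest == []

    def test_all_dentate_manifest(self):
        sessions, manifest = build_population(5, {"dentate": 1.0}, seed=2, n_trials=5)
        assert all(m["kind"] == "dentate" for m in manifest)
        assert all(s.structure == "dentate" for s in sessions)

    def test_mix_proportions_validated(self):
        with pytest.raises(ValueError):
            build_population(4, {"dentate": 0.6, "caudate_increase": 0.6}, seed=1)

    def test_tuning_recovery_from_manifest(self):
        from entrainalyze.response_profile import duration_tuning

        sessions, manifest = build_population(
            6,
            {"caudate_increase": 1.0},
            seed=8,
            n_trials=150,
            conditions=("missing",),
            jitter=0.1,
        )
        truth = [LONG_TUNED_CURVE[isi] for isi in (100, 200, 300, 400, 600)]
        rhos = []
        for s in sessions:
            r = duration_tuning(s)
            rhos.append(stats.spearmanr(r.normalized, truth).statistic)
        assert np.mean(rhos) > 0.9


class TestStimSession:
    def test_shift_applied_to_stim_trials_only(self):
        session = simulate_stim_session(
            400, shifts={("missing", "contra"): -40}, seed=3
        )
        lats = {}
        for t in session.trials:
            key = (t.condition, t.target_direction, t.stimulated)
            lats.setdefault(key, []).append(t.saccade_latency)
        shifted = np.mean(lats[("missing", "contra", True)])
        control = np.mean(lats[("missing", "contra", False)])
        assert shifted < control - 20
        other_s = np.mean(lats[("deviant", "ipsi", True)])
        other_c = np.mean(lats[("deviant", "ipsi", False)])
        assert abs(other_s - other_c) < 20
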