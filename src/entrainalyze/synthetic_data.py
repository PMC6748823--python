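"""Task-structured synthetic data: trials, rate profiles, Poisson spikes,
saccade behavior and eye traces.

The generator reproduces the statistical structure the analyses assume:

* increase-type striatal profiles — a transient bump after each stimulus
  (peak ~160 ms post-onset, fixed width), amplitude growing with repetition
  and scaled by ISI tuning, oddball-condition gain and target-direction
  gain;
* decrease-type profiles — the same bumps with a decaying amplitude
  schedule;
* cerebellar-nucleus-like profiles — a post-stimulus trough (~200 ms)
  followed by a linear ramp that recovers exactly at the next stimulus
  onset when ``recovery_mode='scales_with_isi'``;
* saccade latencies optionally coupled to a rate perturbation injected in a
  controllable window locked to either the omission or the saccade;
* 1 kHz eye traces with a raised-cosine saccade profile.

All randomness flows from one :class:`numpy.random.Generator`; a fixed seed
gives bit-identical sessions (and therefore bit-identical session files).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core_io import (
    CONDITIONS,
    DIRECTIONS,
    ISI_SET,
    EyeTrace,
    Session,
    SpikeTrain,
    TrialRecord,
)
from .spike_density import RateTrace

#: Default long-tuned ISI gain profile (fraction of the 600 ms response).
LONG_TUNED_CURVE = {100: 0.09, 200: 0.18, 300: 0.43, 400: 0.64, 600: 1.00}
#: Default short-tuned ISI gain profile (peaked at intermediate intervals).
SHORT_TUNED_CURVE = {100: 0.15, 200: 0.46, 300: 0.88, 400: 0.94, 600: 0.59}
#: ISI gain proportional to the interval (cerebellar-like).
PROPORTIONAL_CURVE = {isi: isi / 600 for isi in ISI_SET}

PROFILE_KINDS = ("caudate_increase", "caudate_decrease", "dentate")


@dataclass
class TaskParams:
    """Oddball-task timing parameters (ms unless noted)."""

    isi_set: tuple[int, ...] = ISI_SET
    stimulus_duration: int = 35
    sequence_length_range: tuple[int, int] = (2000, 4800)
    sequence_length_range_600: tuple[int, int] = (3000, 4800)
    pre_sequence_delay: tuple[int, int] = (100, 400)
    fixation: int = 2000
    response_window: int = 600
    target_eccentricity: float = 16.0


@dataclass
class RateProfileParams:
    """Deterministic firing-rate profile of one simulated neuron.

    ``peak_latency`` is the post-stimulus transient peak for striatal kinds
    and the trough latency for the ``dentate`` kind. The per-stimulus
    amplitude is ``amplitude * repetition_gain(k) * isi_tuning[isi] *
    condition_gain (missing only) * direction_gain (contra only)``.
    Repetition gain is the saturating ramp ``1 - b * exp(-k * isi / a)``
    with 1-based ordinal ``k`` and ``a`` in ms: entrainment builds with
    elapsed sequence time, so the gain is saturated by the pre-oddball
    interval at every ISI while still rising gradually across the early
    stimuli of a trial.
    """

    profile_kind: str = "caudate_increase"
    baseline: float = 2.0
    amplitude: float = 60.0
    peak_latency: int = 160
    transient_width: float = 140.0
    repetition_a: float = 1000.0
    repetition_b: float = 0.9
    isi_tuning: dict = field(default_factory=lambda: dict(LONG_TUNED_CURVE))
    condition_gain: float = 1.7
    direction_gain: float = 1.08
    recovery_mode: str = "scales_with_isi"
    recovery_duration: float = 140.0

    def __post_init__(self) -> None:
        if self.profile_kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile_kind {self.profile_kind!r}")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        if self.condition_gain <= 0 or self.direction_gain <= 0:
            raise ValueError("gains must be > 0")

    def repetition_gain(self, k: int, isi: int) -> float:
        """Amplitude schedule at 1-based stimulus ordinal ``k``."""
        if self.profile_kind == "caudate_decrease":
            return float(np.exp(-(k - 1) * isi / self.repetition_a))
        return float(1.0 - self.repetition_b * np.exp(-k * isi / self.repetition_a))

    def stimulus_amplitude(self, k: int, trial: TrialRecord) -> float:
        amp = (
            self.amplitude
            * self.repetition_gain(k, trial.isi)
            * self.isi_tuning[trial.isi]
        )
        if trial.condition == "missing":
            amp *= self.condition_gain
        if trial.target_direction == "contra":
            amp *= self.direction_gain
        return amp


def dentate_params(**overrides) -> RateProfileParams:
    """Convenience constructor for a cerebellar-nucleus-like profile."""
    defaults = dict(
        profile_kind="dentate",
        baseline=60.0,
        amplitude=45.0,
        peak_latency=200,
        repetition_b=0.0,  # no repetition dependence (gain is 1 everywhere)
        isi_tuning=dict(PROPORTIONAL_CURVE),
        condition_gain=1.0,
        direction_gain=1.0,
        recovery_mode="scales_with_isi",
    )
    defaults.update(overrides)
    return RateProfileParams(**defaults)


@dataclass
class CovariationParams:
    """Saccade-latency distribution and its coupling to firing rate.

    The rate perturbation is ``coupling_strength * (latency - latency_mean)``
    spikes/s, applied on ``[coupling_onset, coupling_offset)`` relative to
    the lock event (stimulus omission or saccade onset).
    """

    latency_mean: float = 350.0
    latency_sd: float = 58.0
    coupling_strength: float = 0.0
    coupling_lock: str = "omission_locked"
    coupling_onset: int = -300
    coupling_offset: int = 100

    def __post_init__(self) -> None:
        if self.coupling_offset <= self.coupling_onset:
            raise ValueError("coupling_offset must exceed coupling_onset")
        if self.coupling_lock not in ("omission_locked", "saccade_locked"):
            raise ValueError(f"unknown coupling_lock {self.coupling_lock!r}")


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------


def sample_sequence_length(task: TaskParams, isi: int, rng: np.random.Generator) -> int:
    """Uniform integer sequence length (ms) on the range valid for ``isi``."""
    lo, hi = (
        task.sequence_length_range_600
        if isi == 600
        else task.sequence_length_range
    )
    return int(rng.integers(lo, hi + 1))


def generate_trials(
    task: TaskParams,
    n_trials: int,
    rng: np.random.Generator,
    conditions: Sequence[str] = CONDITIONS,
    isis: Optional[Sequence[int]] = None,
    directions: Sequence[str] = DIRECTIONS,
    p_early: float = 0.0,
    p_miss: float = 0.0,
    latency: Optional[CovariationParams] = None,
) -> list[TrialRecord]:
    """Pseudorandom trials with task-consistent stimulus onsets.

    ``isis`` restricts the missing-condition ISIs (default: the full task
    set); deviant trials always use the 400 ms ISI. Correct trials receive a
    provisional saccade latency drawn from ``latency`` (default
    distribution) — :func:`simulate_session` replaces it with the coupled
    draw.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    cov = latency or CovariationParams()
    trials = []
    for i in range(n_trials):
        condition = conditions[int(rng.integers(len(conditions)))]
        if condition == "deviant":
            isi = 400
        else:
            pool = tuple(isis) if isis is not None else task.isi_set
            isi = int(pool[int(rng.integers(len(pool)))])
        direction = directions[int(rng.integers(len(directions)))]
        length = sample_sequence_length(task, isi, rng)
        n_stim = length // isi
        oddball = n_stim * isi
        u = rng.random()
        if u < p_early:
            outcome = "early_error"
            lat = None
            fixation = int(rng.integers(500, max(oddball, 501)))
        elif u < p_early + p_miss:
            outcome = "miss"
            lat = None
            fixation = oddball + task.response_window
        else:
            outcome = "correct"
            lat = draw_latency(cov, task, rng)
            fixation = oddball + lat
        trials.append(
            TrialRecord(
                trial_id=i,
                condition=condition,
                isi=isi,
                stimulus_onsets=np.arange(n_stim) * isi,
                oddball_time=oddball,
                target_direction=direction,
                outcome=outcome,
                saccade_latency=lat,
                fixation_duration=fixation,
            )
        )
    return trials


def draw_latency(
    cov: CovariationParams, task: TaskParams, rng: np.random.Generator
) -> int:
    """Gaussian saccade latency truncated to ``(0, response_window]``, ms."""
    for _ in range(1000):
        lat = rng.normal(cov.latency_mean, cov.latency_sd)
        if 0 < lat <= task.response_window:
            return int(round(lat))
    raise RuntimeError("latency rejection sampling failed; check parameters")


# ---------------------------------------------------------------------------
# Rate profiles
# ---------------------------------------------------------------------------


#: Baseline tail simulated beyond the response window so saccade-aligned
#: analysis windows never run off the end of the trial for any latency.
TRIAL_TAIL_MS = 400


def rate_profile(
    trial: TrialRecord,
    params: RateProfileParams,
    duration: Optional[int] = None,
    response_window: int = 600,
) -> RateTrace:
    """Deterministic nonnegative rate (spikes/s) on the trial's 1 ms grid.

    The grid is ``[0, duration)`` with ``duration`` defaulting to the
    oddball time plus ``response_window`` plus a baseline tail.
    """
    T = (
        int(duration)
        if duration is not None
        else int(trial.oddball_time) + response_window + TRIAL_TAIL_MS
    )
    t = np.arange(T, dtype=float)
    onsets = trial.stimulus_onsets
    if params.profile_kind in ("caudate_increase", "caudate_decrease"):
        rate = np.full(T, params.baseline, dtype=float)
        sigma = params.transient_width / 4.0
        for k, onset in enumerate(onsets, start=1):
            amp = params.stimulus_amplitude(k, trial)
            if amp == 0.0:
                continue
            center = onset + params.peak_latency
            lo = max(0, int(center - 5 * sigma))
            hi = min(T, int(center + 5 * sigma) + 1)
            if lo < hi:
                rate[lo:hi] += amp * np.exp(
                    -0.5 * ((t[lo:hi] - center) / sigma) ** 2
                )
    elif params.profile_kind == "dentate":
        rate = np.full(T, params.baseline, dtype=float)
        bounds = list(onsets[1:]) + [trial.oddball_time]
        for k, (onset, nxt) in enumerate(zip(onsets, bounds), start=1):
            depth = params.stimulus_amplitude(k, trial)
            interval = int(nxt - onset)
            trough = min(int(params.peak_latency), max(interval // 2, 1))
            if params.recovery_mode == "scales_with_isi":
                rec_end = interval
            elif params.recovery_mode == "fixed_duration":
                rec_end = min(interval, trough + int(params.recovery_duration))
            else:
                raise ValueError(f"unknown recovery_mode {params.recovery_mode!r}")
            seg = np.arange(interval, dtype=float)
            shape = np.zeros(interval)
            shape[: trough + 1] = seg[: trough + 1] / trough
            ramp = slice(trough + 1, rec_end)
            if rec_end > trough + 1:
                shape[ramp] = 1.0 - (seg[ramp] - trough) / (rec_end - trough)
            a, b = int(onset), min(int(onset) + interval, T)
            rate[a:b] -= depth * shape[: b - a]
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown profile_kind {params.profile_kind!r}")
    np.clip(rate, 0.0, None, out=rate)
    return RateTrace(values=rate, window=(0, T), alignment="first_stimulus", n_trials=1)


# ---------------------------------------------------------------------------
# Spiking
# ---------------------------------------------------------------------------


def sample_spikes(
    rate: RateTrace,
    rng: np.random.Generator,
    method: str = "bernoulli",
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes (integer ms) from a rate trace.

    ``bernoulli`` draws one Bernoulli per millisecond with p = rate/1000
    (accurate for rates well below 1000 spikes/s); ``thinning`` is the exact
    Lewis–Shedler algorithm with times floored to the millisecond grid.
    """
    if np.any(rate.values < 0):
        raise ValueError("rate must be nonnegative")
    start = rate.window[0]
    if method == "bernoulli":
        p = np.minimum(rate.values / 1000.0, 1.0)
        hits = np.flatnonzero(rng.random(len(p)) < p)
        times = hits + start
    elif method == "thinning":
        lam_max = float(rate.values.max())
        times_list: list[int] = []
        if lam_max > 0:
            T = len(rate.values)
            t = 0.0
            while True:
                t += rng.exponential(1000.0 / lam_max)
                if t >= T:
                    break
                if rng.random() < rate.values[int(t)] / lam_max:
                    times_list.append(int(t) + start)
        times = np.array(times_list, dtype=np.int64)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpikeTrain(trial_id=-1, spike_times=np.asarray(times, dtype=np.int64))


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


def sample_behavior(
    trial: TrialRecord,
    cov: CovariationParams,
    rng: np.random.Generator,
    task: Optional[TaskParams] = None,
) -> tuple[int, RateTrace]:
    """Draw a saccade latency and its latency-coupled rate perturbation.

    The perturbation is an additive rate trace (spikes/s, possibly
    negative) on the trial grid, nonzero only within the coupling window
    relative to the lock event (omission time, or the saccade at
    ``oddball + latency``).
    """
    task = task or TaskParams()
    if trial.outcome != "correct":
        raise ValueError("behavior is sampled for correct trials only")
    latency = draw_latency(cov, task, rng)
    T = int(trial.oddball_time) + task.response_window + TRIAL_TAIL_MS
    pert = np.zeros(T)
    if cov.coupling_strength != 0.0:
        lock = (
            int(trial.oddball_time)
            if cov.coupling_lock == "omission_locked"
            else int(trial.oddball_time) + latency
        )
        a = max(0, lock + cov.coupling_onset)
        b = min(T, lock + cov.coupling_offset)
        if a < b:
            pert[a:b] = cov.coupling_strength * (latency - cov.latency_mean)
    return latency, RateTrace(
        values=pert, window=(0, T), alignment="first_stimulus", n_trials=1
    )


def generate_eye_trace(
    trial: TrialRecord,
    latency: int,
    rng: np.random.Generator,
    task: Optional[TaskParams] = None,
    noise_sd: float = 0.1,
    saccade_duration: int = 40,
) -> EyeTrace:
    """1 kHz eye trace: fixation noise, then a raised-cosine saccade.

    The saccade starts at ``oddball_time + latency``, moves
    ``target_eccentricity`` degrees horizontally (positive for contra) in
    ``saccade_duration`` ms, with peak velocity 2·amplitude/duration (800°/s
    at the defaults) — far above the 60°/s detection criterion.
    """
    task = task or TaskParams()
    T = int(trial.oddball_time) + task.response_window + 100
    x = _fixation_noise(T, noise_sd, rng)
    y = _fixation_noise(T, noise_sd, rng)
    onset = int(trial.oddball_time) + int(latency)
    sign = 1.0 if trial.target_direction == "contra" else -1.0
    amp = sign * task.target_eccentricity
    d = int(saccade_duration)
    tt = np.arange(d, dtype=float)
    step = amp / d * (1.0 - np.cos(2.0 * np.pi * (tt + 0.5) / d))  # sums to amp
    displacement = np.zeros(T)
    a, b = onset, min(onset + d, T)
    if a < T:
        displacement[a:b] = step[: b - a]
    x = x + np.cumsum(displacement)
    return EyeTrace(trial_id=trial.trial_id, x=x, y=y)


# ---------------------------------------------------------------------------
# Sessions and populations
# ---------------------------------------------------------------------------


def simulate_session(
    n_trials: int,
    profile: RateProfileParams,
    task: Optional[TaskParams] = None,
    cov: Optional[CovariationParams] = None,
    seed: int | np.random.Generator = 0,
    neuron_id: str = "sim-000",
    conditions: Sequence[str] = CONDITIONS,
    isis: Optional[Sequence[int]] = None,
    directions: Sequence[str] = DIRECTIONS,
    p_early: float = 0.0,
    p_miss: float = 0.0,
    with_eyes: bool = False,
    spike_method: str = "bernoulli",
) -> Session:
    """End-to-end simulation of one neuron's session."""
    task = task or TaskParams()
    cov = cov or CovariationParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = generate_trials(
        task,
        n_trials,
        rng,
        conditions=conditions,
        isis=isis,
        directions=directions,
        p_early=p_early,
        p_miss=p_miss,
        latency=cov,
    )
    out_trials: list[TrialRecord] = []
    spikes: list[SpikeTrain] = []
    eyes: list[EyeTrace] = [] if with_eyes else None
    for trial in trials:
        rate = rate_profile(trial, profile, response_window=task.response_window)
        if trial.outcome == "correct":
            latency, pert = sample_behavior(trial, cov, rng, task)
            trial = replace(trial, saccade_latency=latency,
                            fixation_duration=trial.oddball_time + latency)
            rate = RateTrace(
                values=np.clip(rate.values + pert.values, 0.0, None),
                window=rate.window,
            )
            if with_eyes:
                eyes.append(generate_eye_trace(trial, latency, rng, task))
        train = sample_spikes(rate, rng, method=spike_method)
        train.trial_id = trial.trial_id
        out_trials.append(trial)
        spikes.append(train)
    structure = "dentate" if profile.profile_kind == "dentate" else "caudate"
    return Session(
        neuron_id=neuron_id,
        structure=structure,
        trials=out_trials,
        spikes=spikes,
        eyes=eyes,
        metadata={"animal": "sim", "profile_kind": profile.profile_kind},
    )


def _fixation_noise(
    n: int, sd: float, rng: np.random.Generator, corr_ms: float = 15.0
) -> np.ndarray:
    """Low-pass (drift-like) fixation noise with the requested position SD.

    White position noise at 1 kHz would imply unphysical eye velocities;
    smoothing with a Gaussian of ``corr_ms`` keeps spurious speeds well
    below the saccade-detection criterion.
    """
    if sd <= 0:
        return np.zeros(n)
    h = int(4 * corr_ms)
    t = np.arange(-h, h + 1)
    k = np.exp(-0.5 * (t / corr_ms) ** 2)
    k /= np.sqrt((k**2).sum())  # preserve the white-noise SD
    white = rng.normal(0.0, sd, n + 2 * h)
    return np.convolve(white, k, mode="valid")[:n]


def simulate_stim_session(
    n_trials: int,
    shifts: Optional[dict[tuple[str, str], float]] = None,
    sd_scale_stim: float = 1.0,
    task: Optional[TaskParams] = None,
    cov: Optional[CovariationParams] = None,
    seed: int | np.random.Generator = 0,
    session_id: str = "stim-000",
    p_stim: float = 0.5,
    with_eyes: bool = False,
) -> Session:
    """One microstimulation experiment: interleaved stimulated/control trials.

    ``shifts`` maps ``(condition, direction)`` to the latency change (ms)
    added on stimulated trials; ``sd_scale_stim`` scales the latency spread
    on stimulated trials. All trials are correct and use the 400 ms ISI;
    spike trains are empty (spiking is irrelevant to the behavioral
    statistics).
    """
    task = task or TaskParams()
    cov = cov or CovariationParams()
    shifts = shifts or {}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials_raw = generate_trials(
        task, n_trials, rng, isis=(400,), latency=cov
    )
    trials: list[TrialRecord] = []
    spikes: list[SpikeTrain] = []
    eyes: list[EyeTrace] = [] if with_eyes else None
    for trial in trials_raw:
        stimulated = bool(rng.random() < p_stim)
        lat = float(trial.saccade_latency)
        if stimulated:
            lat = cov.latency_mean + (lat - cov.latency_mean) * sd_scale_stim
            lat += shifts.get((trial.condition, trial.target_direction), 0.0)
        lat_i = int(np.clip(round(lat), 1, task.response_window))
        trial = replace(
            trial,
            stimulated=stimulated,
            saccade_latency=lat_i,
            fixation_duration=trial.oddball_time + lat_i,
        )
        trials.append(trial)
        spikes.append(SpikeTrain(trial_id=trial.trial_id, spike_times=np.array([])))
        if with_eyes:
            eyes.append(generate_eye_trace(trial, lat_i, rng, task))
    return Session(
        neuron_id=session_id,
        structure="caudate",
        trials=trials,
        spikes=spikes,
        eyes=eyes,
        metadata={"animal": "sim", "kind": "stimulation"},
    )


def _jittered(
    params: RateProfileParams, rng: np.random.Generator, jitter: float
) -> RateProfileParams:
    """Multiplicative lognormal jitter on amplitude/baseline, mild on gains."""
    if jitter <= 0:
        return params
    return replace(
        params,
        amplitude=params.amplitude * float(rng.lognormal(0.0, jitter)),
        baseline=params.baseline * float(rng.lognormal(0.0, jitter)),
        condition_gain=params.condition_gain * float(rng.lognormal(0.0, jitter / 4)),
        direction_gain=params.direction_gain * float(rng.lognormal(0.0, jitter / 8)),
    )


def build_population(
    n_neurons: int,
    mix: dict[str, float],
    task: Optional[TaskParams] = None,
    seed: int = 0,
    n_trials: int = 60,
    cov: Optional[CovariationParams] = None,
    profiles: Optional[dict[str, RateProfileParams]] = None,
    jitter: float = 0.1,
    **session_kwargs,
) -> tuple[list[Session], list[dict]]:
    """Independent seeded sessions with per-neuron parameter jitter.

    ``mix`` maps profile kinds (or names of entries in ``profiles``) to
    proportions summing to 1. Returns the sessions and a manifest of the
    ground-truth parameters actually used per neuron.
    """
    if n_neurons < 0:
        raise ValueError("n_neurons must be >= 0")
    if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("mix proportions must sum to 1")
    task = task or TaskParams()
    base_profiles = {
        "caudate_increase": RateProfileParams(profile_kind="caudate_increase"),
        "caudate_decrease": RateProfileParams(profile_kind="caudate_decrease"),
        "dentate": dentate_params(),
    }
    if profiles:
        base_profiles.update(profiles)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(n_neurons, 1))
    kinds = list(mix)
    counts = _apportion(n_neurons, [mix[k] for k in kinds])
    assignment = [k for k, c in zip(kinds, counts) for _ in range(c)]
    sessions: list[Session] = []
    manifest: list[dict] = []
    for i, kind in enumerate(assignment):
        rng = np.random.default_rng(children[i])
        params = _jittered(base_profiles[kind], rng, jitter)
        session = simulate_session(
            n_trials,
            params,
            task=task,
            cov=cov,
            seed=rng,
            neuron_id=f"sim-{i:03d}",
            **session_kwargs,
        )
        sessions.append(session)
        entry = dataclasses.asdict(params)
        entry.update(neuron_id=session.neuron_id, kind=kind)
        manifest.append(entry)
    return sessions, manifest


def _apportion(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items to the given fractions."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for j in order[:remainder]:
        counts[j] += 1
    return counts
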