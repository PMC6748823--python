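import numpy as np
import pytest

from entrainalyze.core_io import Session, SpikeTrain, TrialRecord


def make_trial(
    trial_id=0,
    condition="missing",
    isi=400,
    n_stimuli=5,
    direction="contra",
    outcome="correct",
    latency=300,
    stimulated=False,
    fixation=None,
):
    onsets = np.arange(n_stimuli) * isi
    oddball = n_stimuli * isi if condition == "missing" else int(onsets[-1])
    lat = latency if outcome == "correct" else None
    if fixation is None:
        fixation = oddball + (lat or 0)
    return TrialRecord(
        trial_id=trial_id,
        condition=condition,
        isi=isi,
        stimulus_onsets=onsets,
        oddball_time=oddball,
        target_direction=direction,
        outcome=outcome,
        saccade_latency=lat,
        fixation_duration=fixation,
        stimulated=stimulated,
    )


def make_session(trials, spike_times_by_trial=None, structure="caudate", **kw):
    spikes = [
        SpikeTrain(
            trial_id=t.trial_id,
            spike_times=np.asarray(
                (spike_times_by_trial or {}).get(t.trial_id, []), dtype=np.int64
            ),
        )
        for t in trials
    ]
    return Session(
        neuron_id=kw.pop("neuron_id", "test-000"),
        structure=structure,
        trials=trials,
        spikes=spikes,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_session():
    trials = [make_trial(trial_id=i, latency=250 + 10 * i) for i in range(4)]
    spikes = {0: [0, 100, 560], 1: [160, 1999], 2: [], 3: [1500, 1501, 2100]}
    return make_session(trials, spikes)
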