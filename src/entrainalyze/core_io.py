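"""Session data model, plain-text container I/O, trial filtering and event alignment.

A *session* holds everything recorded for one neuron/site: per-trial task
events, per-trial spike timestamps and (optionally) 1 kHz eye-position
traces. All timestamps are integer milliseconds on the trial clock whose
zero is the first stimulus onset; analysis grids are half-open ``[start,
end)`` so that one sample per millisecond tiles a window without fencepost
drift.

On disk a session is a directory of UTF-8 text files::

    trials.csv   trial_id, condition, isi_ms, n_stimuli, oddball_time_ms,
                 target_direction, outcome, saccade_latency_ms, fixation_ms,
                 stimulated
    spikes.csv   trial_id, spike_time_ms
    eye.csv      trial_id, t_ms, x_deg, y_deg        (optional)
    meta.json    neuron_id, structure, animal, ...

Stimulus onsets are implied by ``n_stimuli`` and ``isi_ms`` (onsets are
``k * isi`` for ``k = 0 .. n_stimuli - 1``); the reader reconstructs the
omission time for missing-oddball trials and cross-checks the stored value.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CONDITIONS = ("missing", "deviant")
DIRECTIONS = ("contra", "ipsi")
OUTCOMES = ("correct", "early_error", "miss")
STRUCTURES = ("caudate", "dentate")
ALIGNMENTS = ("first_stimulus", "oddball", "last_stimulus", "saccade")

#: ISIs used in the task, ms.
ISI_SET = (100, 200, 300, 400, 600)

TRIALS_COLUMNS = (
    "trial_id",
    "condition",
    "isi_ms",
    "n_stimuli",
    "oddball_time_ms",
    "target_direction",
    "outcome",
    "saccade_latency_ms",
    "fixation_ms",
    "stimulated",
)


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


class SessionParseError(ValueError):
    """A session container on disk is malformed; the message names the record."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    """Events of one trial.

    ``stimulus_onsets`` are strictly increasing with constant spacing equal
    to ``isi`` and start at 0. For missing-oddball trials ``oddball_time``
    equals the expected (omitted) next onset, i.e. ``last onset + isi``; for
    deviant trials it is the onset of the deviant stimulus.
    ``saccade_latency`` (ms from the oddball) is present iff the outcome is
    ``correct``.
    """

    trial_id: int
    condition: str
    isi: int
    stimulus_onsets: np.ndarray
    oddball_time: int
    target_direction: str
    outcome: str
    saccade_latency: Optional[int] = None
    fixation_duration: int = 0
    stimulated: bool = False

    def __post_init__(self) -> None:
        self.stimulus_onsets = np.asarray(self.stimulus_onsets, dtype=np.int64)
        self.validate()

    @property
    def n_stimuli(self) -> int:
        return int(len(self.stimulus_onsets))

    @property
    def saccade_time(self) -> Optional[int]:
        """Saccade onset on the trial clock, or None for non-correct trials."""
        if self.saccade_latency is None:
            return None
        return int(self.oddball_time + self.saccade_latency)

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"trial {self.trial_id}: unknown condition {self.condition!r}"
            )
        if self.target_direction not in DIRECTIONS:
            raise ValidationError(
                f"trial {self.trial_id}: unknown direction {self.target_direction!r}"
            )
        if self.outcome not in OUTCOMES:
            raise ValidationError(
                f"trial {self.trial_id}: unknown outcome {self.outcome!r}"
            )
        if self.n_stimuli < 1 or self.stimulus_onsets[0] != 0:
            raise ValidationError(
                f"trial {self.trial_id}: stimulus onsets must start at 0"
            )
        diffs = np.diff(self.stimulus_onsets)
        if len(diffs) and not np.all(diffs == self.isi):
            raise ValidationError(
                f"trial {self.trial_id}: onsets not evenly spaced at isi={self.isi}"
            )
        if self.condition == "missing":
            expected = int(self.stimulus_onsets[-1] + self.isi)
            if self.oddball_time != expected:
                raise ValidationError(
                    f"trial {self.trial_id}: missing-trial oddball_time "
                    f"{self.oddball_time} != last onset + isi = {expected}"
                )
        has_latency = self.saccade_latency is not None
        if has_latency != (self.outcome == "correct"):
            raise ValidationError(
                f"trial {self.trial_id}: saccade_latency must be present iff "
                f"outcome is correct (outcome={self.outcome!r})"
            )


@dataclass
class SpikeTrain:
    """Spike timestamps (ms, trial clock) of one trial, non-decreasing."""

    trial_id: int
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.int64)
        if len(self.spike_times) and np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"trial {self.trial_id}: spike times decrease")


@dataclass
class EyeTrace:
    """Eye position (deg) of one trial sampled at ``sample_rate`` Hz from t=0."""

    trial_id: int
    x: np.ndarray
    y: np.ndarray
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValidationError(f"trial {self.trial_id}: x/y length mismatch")
        if self.sample_rate <= 0:
            raise ValidationError(f"trial {self.trial_id}: sample_rate must be > 0")


@dataclass
class Session:
    """All data for one neuron/site: trials, spikes, optional eye traces."""

    neuron_id: str
    structure: str
    trials: list[TrialRecord]
    spikes: list[SpikeTrain]
    eyes: Optional[list[EyeTrace]] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValidationError(f"unknown structure {self.structure!r}")
        trial_ids = [t.trial_id for t in self.trials]
        if len(set(trial_ids)) != len(trial_ids):
            raise ValidationError("duplicate trial_ids")
        spike_ids = [s.trial_id for s in self.spikes]
        if sorted(spike_ids) != sorted(trial_ids):
            raise ValidationError("need exactly one SpikeTrain per TrialRecord")
        if self.eyes is not None:
            unknown = {e.trial_id for e in self.eyes} - set(trial_ids)
            if unknown:
                raise ValidationError(f"eye traces for unknown trials {sorted(unknown)}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def spikes_for(self, trial_id: int) -> SpikeTrain:
        for s in self.spikes:
            if s.trial_id == trial_id:
                return s
        raise KeyError(trial_id)

    def eye_for(self, trial_id: int) -> Optional[EyeTrace]:
        if self.eyes is None:
            return None
        for e in self.eyes:
            if e.trial_id == trial_id:
                return e
        return None

    def subset(self, trial_ids: Iterable[int]) -> "Session":
        """New Session restricted to ``trial_ids`` (order of appearance kept)."""
        keep = set(trial_ids)
        trials = [t for t in self.trials if t.trial_id in keep]
        spikes = [s for s in self.spikes if s.trial_id in keep]
        eyes = None
        if self.eyes is not None:
            eyes = [e for e in self.eyes if e.trial_id in keep]
        return Session(
            neuron_id=self.neuron_id,
            structure=self.structure,
            trials=trials,
            spikes=spikes,
            eyes=eyes,
            metadata=dict(self.metadata),
        )


@dataclass
class AlignedRaster:
    """Per-trial spike indicators on a 1 ms grid relative to an alignment event.

    ``indicators`` has shape ``(n_trials, end - start)``; entry ``[i, j]``
    counts spikes of trial ``i`` in the millisecond ``start + j`` relative to
    the alignment event. At the native 1 ms resolution entries are 0/1.
    """

    alignment: str
    window: tuple[int, int]
    indicators: np.ndarray
    trial_ids: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.indicators.shape[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1])


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def alignment_time(trial: TrialRecord, alignment: str) -> Optional[int]:
    """Time of the alignment event on the trial clock, or None if undefined."""
    if alignment == "first_stimulus":
        return 0
    if alignment == "oddball":
        return int(trial.oddball_time)
    if alignment == "last_stimulus":
        return int(trial.stimulus_onsets[-1])
    if alignment == "saccade":
        return trial.saccade_time
    raise ValueError(f"unknown alignment {alignment!r}")


def align_raster(
    session: Session, alignment: str, window: tuple[int, int]
) -> AlignedRaster:
    """Build a binary 1 ms raster aligned on an event.

    Trials for which the alignment event is undefined (e.g. ``saccade`` on
    error trials) are dropped with a log entry. Spikes outside the half-open
    window are discarded; a spike exactly at ``end`` is excluded.
    """
    start, end = int(window[0]), int(window[1])
    if end <= start:
        raise ValueError(f"window must have positive length, got [{start}, {end})")
    rows = []
    kept_ids = []
    for trial in session.trials:
        t_align = alignment_time(trial, alignment)
        if t_align is None:
            logger.info(
                "trial %d dropped: no %s event", trial.trial_id, alignment
            )
            continue
        offsets = session.spikes_for(trial.trial_id).spike_times - t_align - start
        row = np.zeros(end - start, dtype=np.int16)
        inside = offsets[(offsets >= 0) & (offsets < end - start)]
        np.add.at(row, inside, 1)
        rows.append(row)
        kept_ids.append(trial.trial_id)
    if not rows:
        warnings.warn(
            f"no trial has a defined {alignment!r} event; raster is empty",
            stacklevel=2,
        )
        indicators = np.zeros((0, end - start), dtype=np.int16)
    else:
        indicators = np.stack(rows)
    return AlignedRaster(
        alignment=alignment,
        window=(start, end),
        indicators=indicators,
        trial_ids=np.asarray(kept_ids, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_trials(
    session: Session,
    correct_only: bool = True,
    min_fixation: Optional[int] = 1500,
    condition: Optional[str] = None,
    isi: Optional[int] = None,
) -> Session:
    """Subset a session to trials passing the enabled rules.

    Defaults implement the standard inclusion rule: correct outcome and
    fixation maintained for more than ``min_fixation`` ms from the first
    stimulus. ``condition``/``isi`` restrict further when given. Idempotent;
    an empty result raises a warning, not an error.
    """
    keep = []
    for t in session.trials:
        if correct_only and t.outcome != "correct":
            continue
        if min_fixation is not None and not t.fixation_duration > min_fixation:
            continue
        if condition is not None and t.condition != condition:
            continue
        if isi is not None and t.isi != isi:
            continue
        keep.append(t.trial_id)
    if not keep:
        warnings.warn("filter_trials: no trials pass the filters", stacklevel=2)
    return session.subset(keep)


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------


def write_session(session: Session, path: str | Path) -> None:
    """Write a session directory (trials.csv, spikes.csv, meta.json, eye.csv).

    Output is deterministic: integer fields are written as plain decimal
    integers, eye positions with 6 decimals, so re-writing a read session is
    byte-identical.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "trials.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRIALS_COLUMNS)
        for t in session.trials:
            w.writerow(
                [
                    t.trial_id,
                    t.condition,
                    t.isi,
                    t.n_stimuli,
                    t.oddball_time,
                    t.target_direction,
                    t.outcome,
                    "" if t.saccade_latency is None else int(t.saccade_latency),
                    t.fixation_duration,
                    int(t.stimulated),
                ]
            )
    with open(path / "spikes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", "spike_time_ms"])
        for s in session.spikes:
            for st in s.spike_times:
                w.writerow([s.trial_id, int(st)])
    meta = {
        "neuron_id": session.neuron_id,
        "structure": session.structure,
        **session.metadata,
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if session.eyes is not None:
        with open(path / "eye.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["trial_id", "t_ms", "x_deg", "y_deg"])
            for e in session.eyes:
                for i in range(len(e.x)):
                    w.writerow([e.trial_id, i, f"{e.x[i]:.6f}", f"{e.y[i]:.6f}"])


def _parse_trial_row(row: dict, line_no: int) -> TrialRecord:
    try:
        isi = int(row["isi_ms"])
        n_stim = int(row["n_stimuli"])
        lat = row["saccade_latency_ms"]
        return TrialRecord(
            trial_id=int(row["trial_id"]),
            condition=row["condition"],
            isi=isi,
            stimulus_onsets=np.arange(n_stim) * isi,
            oddball_time=int(row["oddball_time_ms"]),
            target_direction=row["target_direction"],
            outcome=row["outcome"],
            saccade_latency=None if lat in ("", None) else int(lat),
            fixation_duration=int(row["fixation_ms"]),
            stimulated=bool(int(row["stimulated"])),
        )
    except (KeyError, TypeError) as exc:
        raise SessionParseError(f"trials.csv line {line_no}: missing field {exc}")
    except ValidationError:
        raise
    except ValueError as exc:
        raise SessionParseError(f"trials.csv line {line_no}: {exc}")


def read_session(path: str | Path) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    trials_file = path / "trials.csv"
    if not trials_file.exists():
        raise SessionParseError(f"{trials_file} not found")
    trials: list[TrialRecord] = []
    with open(trials_file, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != TRIALS_COLUMNS:
            raise SessionParseError(
                f"trials.csv header must be {','.join(TRIALS_COLUMNS)}"
            )
        for line_no, row in enumerate(reader, start=2):
            trials.append(_parse_trial_row(row, line_no))
    spikes_by_trial: dict[int, list[int]] = {t.trial_id: [] for t in trials}
    with open(path / "spikes.csv", newline="") as fh:
        reader = csv.DictReader(fh)
        for line_no, row in enumerate(reader, start=2):
            try:
                tid = int(row["trial_id"])
                spikes_by_trial[tid].append(int(row["spike_time_ms"]))
            except (KeyError, ValueError) as exc:
                raise SessionParseError(f"spikes.csv line {line_no}: {exc}")
            except TypeError:
                raise SessionParseError(f"spikes.csv line {line_no}: malformed row")
    spikes = [
        SpikeTrain(trial_id=t.trial_id, spike_times=np.array(spikes_by_trial[t.trial_id]))
        for t in trials
    ]
    eyes = None
    eye_file = path / "eye.csv"
    if eye_file.exists():
        xs: dict[int, list[float]] = {}
        ys: dict[int, list[float]] = {}
        with open(eye_file, newline="") as fh:
            reader = csv.DictReader(fh)
            for line_no, row in enumerate(reader, start=2):
                try:
                    tid = int(row["trial_id"])
                    xs.setdefault(tid, []).append(float(row["x_deg"]))
                    ys.setdefault(tid, []).append(float(row["y_deg"]))
                except (KeyError, ValueError) as exc:
                    raise SessionParseError(f"eye.csv line {line_no}: {exc}")
        eyes = [
            EyeTrace(trial_id=tid, x=np.array(xs[tid]), y=np.array(ys[tid]))
            for tid in sorted(xs)
        ]
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    try:
        neuron_id = meta.pop("neuron_id")
        structure = meta.pop("structure")
    except KeyError as exc:
        raise SessionParseError(f"meta.json: missing {exc}")
    try:
        return Session(
            neuron_id=neuron_id,
            structure=structure,
            trials=trials,
            spikes=spikes,
            eyes=eyes,
            metadata=meta,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
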