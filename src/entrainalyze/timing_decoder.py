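"""Threshold-crossing decoder of next-stimulus timing from population
activity, with a 1% threshold grid search and neuron-resampling bootstrap.

For each ISI the population trace aligned with the last stimulus before the
oddball is normalized between its trough and peak over ``[0, isi]``; the
predicted time for a threshold θ is the first millisecond at or after the
trough where the normalized trace reaches θ/100. The optimal θ minimizes
the squared prediction error summed over ISIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_io import Session, filter_trials
from .spike_density import KernelSpec, RateTrace, session_density


class DegenerateTraceError(ValueError):
    """The trace is flat over the analysis period (peak equals trough)."""


@dataclass
class DecoderConfig:
    theta_grid: tuple[int, ...] = tuple(range(1, 101))
    isi_subset: tuple[int, ...] = (300, 400, 600)
    trail: int = 100  # ms analyzed beyond the expected next onset
    error_summary: str = "mean_abs"  # or "rms"

    def __post_init__(self) -> None:
        if not self.isi_subset:
            raise ValueError("isi_subset must be non-empty")
        if self.error_summary not in ("mean_abs", "rms"):
            raise ValueError(f"unknown error_summary {self.error_summary!r}")


@dataclass
class PredictionTrace:
    """Trough/peak-normalized population trace for one ISI."""

    isi: int
    m: np.ndarray  # normalized trace on [0, isi + trail]
    trough_time: int
    peak_time: int
    trough: float
    peak: float


@dataclass
class DecoderResult:
    theta_star: int
    predicted: dict[int, int]  # ISI -> predicted next-stimulus time, ms
    delta_t: dict[int, int]  # ISI -> predicted - actual, ms
    objective: float  # sum of squared delta_t at theta_star, ms^2
    mean_delta: float  # mean |delta_t| (or rms), ms
    ci: Optional[tuple[float, float]] = None
    bootstrap_samples: Optional[np.ndarray] = None


def extract_prediction_trace(trace: RateTrace, isi: int) -> PredictionTrace:
    """Normalize a last-stimulus-aligned trace between its extrema on ``[0, isi]``.

    The trace window must start at 0 and extend at least to ``isi`` (any
    samples beyond, up to the trail, are normalized with the same factors
    and may exceed 1).
    """
    if trace.window[0] != 0 or trace.window[1] <= isi:
        raise ValueError(
            f"trace window {trace.window} must start at 0 and cover [0, {isi}]"
        )
    r = trace.values
    seg = r[: isi + 1]
    trough_i = int(np.argmin(seg))
    peak_i = int(np.argmax(seg))
    trough, peak = float(seg[trough_i]), float(seg[peak_i])
    if peak <= trough:
        raise DegenerateTraceError("flat population trace: peak equals trough")
    m = (r - trough) / (peak - trough)
    return PredictionTrace(
        isi=int(isi),
        m=m,
        trough_time=trough_i,
        peak_time=peak_i,
        trough=trough,
        peak=peak,
    )


def threshold_crossing(pred: PredictionTrace, theta: float) -> int:
    """First time at/after the trough where the normalized trace reaches
    ``theta`` percent; the peak time if no crossing exists in the trace."""
    level = theta / 100.0
    hits = np.flatnonzero(pred.m[pred.trough_time :] >= level)
    if len(hits) == 0:
        return pred.peak_time
    return pred.trough_time + int(hits[0])


def optimal_threshold_search(
    traces: dict[int, RateTrace],
    config: Optional[DecoderConfig] = None,
) -> DecoderResult:
    """Exhaustive search over the threshold grid minimizing Σ Δt².

    ``traces`` maps each ISI in the config subset to its population trace
    aligned with the last stimulus. Ties go to the smallest θ.
    """
    config = config or DecoderConfig()
    preds = {}
    for isi in config.isi_subset:
        if isi not in traces:
            raise ValueError(f"missing trace for ISI {isi}")
        preds[isi] = extract_prediction_trace(traces[isi], isi)
    best = None
    for theta in config.theta_grid:
        deltas = {
            isi: threshold_crossing(pred, theta) - isi for isi, pred in preds.items()
        }
        objective = float(sum(d * d for d in deltas.values()))
        if best is None or objective < best[1]:
            best = (theta, objective, deltas)
    theta_star, objective, deltas = best
    return DecoderResult(
        theta_star=int(theta_star),
        predicted={isi: isi + d for isi, d in deltas.items()},
        delta_t=deltas,
        objective=objective,
        mean_delta=summarize_errors(list(deltas.values()), config.error_summary),
    )


def summarize_errors(deltas: Sequence[float], summary: str = "mean_abs") -> float:
    arr = np.asarray(deltas, dtype=float)
    if summary == "mean_abs":
        return float(np.abs(arr).mean())
    if summary == "rms":
        return float(np.sqrt((arr**2).mean()))
    raise ValueError(f"unknown summary {summary!r}")


# ---------------------------------------------------------------------------
# Population traces and bootstrap
# ---------------------------------------------------------------------------


def per_neuron_isi_traces(
    sessions: Sequence[Session],
    config: Optional[DecoderConfig] = None,
    kernel: Optional[KernelSpec] = None,
    condition: str = "missing",
    normalization: str = "none",
) -> dict[int, np.ndarray]:
    """Per-neuron spike-density traces aligned with the last stimulus.

    Returns, per ISI, an array of shape ``(n_neurons, isi + trail + 1)``.
    ``normalization='per_neuron_max'`` scales each neuron by its maximum
    across all requested ISIs.
    """
    config = config or DecoderConfig()
    kernel = kernel or KernelSpec()
    out: dict[int, list[np.ndarray]] = {isi: [] for isi in config.isi_subset}
    for session in sessions:
        rows = {}
        for isi in config.isi_subset:
            sub = filter_trials(session, condition=condition, isi=isi)
            if sub.n_trials == 0:
                raise ValueError(
                    f"neuron {session.neuron_id} has no correct {condition} "
                    f"trials at ISI {isi}"
                )
            trace = session_density(
                sub, "last_stimulus", (0, isi + config.trail + 1), kernel
            )
            rows[isi] = trace.values
        if normalization == "per_neuron_max":
            peak = max(v.max() for v in rows.values())
            if peak > 0:
                rows = {isi: v / peak for isi, v in rows.items()}
        elif normalization != "none":
            raise ValueError(f"unknown normalization {normalization!r}")
        for isi, v in rows.items():
            out[isi].append(v)
    return {isi: np.stack(v) for isi, v in out.items()}


def population_traces(
    per_neuron: dict[int, np.ndarray],
    index: Optional[np.ndarray] = None,
) -> dict[int, RateTrace]:
    """Mean across neurons (optionally a bootstrap row index) per ISI."""
    out = {}
    for isi, mat in per_neuron.items():
        rows = mat if index is None else mat[index]
        out[isi] = RateTrace(
            values=rows.mean(axis=0),
            window=(0, mat.shape[1]),
            alignment="last_stimulus",
            n_trials=rows.shape[0],
        )
    return out


def decode_sessions(
    sessions: Sequence[Session],
    config: Optional[DecoderConfig] = None,
    kernel: Optional[KernelSpec] = None,
    condition: str = "missing",
    normalization: str = "none",
) -> DecoderResult:
    """Convenience: population traces from sessions, then threshold search."""
    config = config or DecoderConfig()
    per_neuron = per_neuron_isi_traces(
        sessions, config, kernel, condition=condition, normalization=normalization
    )
    return optimal_threshold_search(population_traces(per_neuron), config)


def bootstrap_decoder(
    sessions: Sequence[Session],
    config: Optional[DecoderConfig] = None,
    kernel: Optional[KernelSpec] = None,
    n_boot: int = 1000,
    seed: int = 0,
    condition: str = "missing",
    normalization: str = "none",
) -> DecoderResult:
    """Decoder point estimate with a percentile CI on the error summary from
    resampling neurons with replacement ``n_boot`` times."""
    if len(sessions) < 2:
        raise ValueError("bootstrap requires at least 2 neurons")
    config = config or DecoderConfig()
    per_neuron = per_neuron_isi_traces(
        sessions, config, kernel, condition=condition, normalization=normalization
    )
    result = optimal_threshold_search(population_traces(per_neuron), config)
    n = len(sessions)
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            rep = optimal_threshold_search(
                population_traces(per_neuron, idx), config
            )
        except DegenerateTraceError:
            continue
        samples.append(rep.mean_delta)
    samples_arr = np.asarray(samples)
    result.bootstrap_samples = samples_arr
    if len(samples_arr):
        result.ci = (
            float(np.percentile(samples_arr, 2.5)),
            float(np.percentile(samples_arr, 97.5)),
        )
    return result
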