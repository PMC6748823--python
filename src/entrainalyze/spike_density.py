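"""Kernel spike-density estimation and firing-modulation metrics.

Spike density is the trial-averaged per-millisecond spike probability
convolved with a unit-area Gaussian kernel and scaled to spikes/s. Firing
modulation is the max minus min of a trace over an analysis window; the
sliding 100 ms window extrema operate on raw counts, not the kernel
density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import AlignedRaster, Session, align_raster, filter_trials


@dataclass
class KernelSpec:
    """Gaussian smoothing kernel; truncated at ``truncation``·sigma and
    renormalized to unit area."""

    sigma: float = 30.0
    truncation: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def half_width(self) -> int:
        return int(np.ceil(self.truncation * self.sigma))

    def weights(self) -> np.ndarray:
        """Kernel samples on a 1 ms grid, renormalized to sum to 1."""
        h = self.half_width
        t = np.arange(-h, h + 1, dtype=float)
        w = np.exp(-0.5 * (t / self.sigma) ** 2)
        return w / w.sum()


@dataclass
class RateTrace:
    """Firing rate (spikes/s) per millisecond on ``[window[0], window[1])``."""

    values: np.ndarray
    window: tuple[int, int]
    alignment: str = "first_stimulus"
    n_trials: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.window[1] - self.window[0]:
            raise ValueError("trace length must equal window length")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1])

    def index(self, t: int) -> int:
        i = int(t) - self.window[0]
        if not 0 <= i < len(self.values):
            raise IndexError(f"time {t} outside window {self.window}")
        return i


@dataclass
class ModulationSummary:
    """Extrema of a trace over a window and their difference (spikes/s)."""

    window: tuple[int, int]
    max_value: float
    min_value: float
    max_time: int
    min_time: int

    @property
    def modulation(self) -> float:
        return self.max_value - self.min_value


def spike_density(raster: AlignedRaster, kernel: KernelSpec) -> RateTrace:
    """Kernel-smoothed trial-mean spike probability, in spikes/s.

    Samples outside the raster window are treated as zero (the raster
    carries no context); use :func:`session_density` to pad with the real
    spikes adjacent to the analysis window.
    """
    if raster.n_trials == 0:
        raise ValueError("cannot estimate density from an empty raster")
    prob = raster.indicators.mean(axis=0)
    h = kernel.half_width
    smoothed = np.convolve(prob, kernel.weights(), mode="full")[h : h + len(prob)]
    return RateTrace(
        values=smoothed * 1000.0,
        window=raster.window,
        alignment=raster.alignment,
        n_trials=raster.n_trials,
    )


def session_density(
    session: Session,
    alignment: str,
    window: tuple[int, int],
    kernel: KernelSpec,
) -> RateTrace:
    """Spike density on ``window``, computed on a window padded by the kernel
    half-width so that spikes just outside the window contribute at the
    edges, then cropped."""
    h = kernel.half_width
    padded = align_raster(session, alignment, (window[0] - h, window[1] + h))
    trace = spike_density(padded, kernel)
    return RateTrace(
        values=trace.values[h : h + (window[1] - window[0])],
        window=tuple(window),
        alignment=alignment,
        n_trials=trace.n_trials,
    )


def firing_modulation(trace: RateTrace, window: tuple[int, int]) -> ModulationSummary:
    """Max, min and their difference over ``window``; ties break earliest."""
    i0, i1 = trace.index(window[0]), int(window[1]) - trace.window[0]
    if not (0 <= i0 < i1 <= len(trace.values)):
        raise ValueError(f"window {window} outside trace window {trace.window}")
    seg = trace.values[i0:i1]
    imax = int(np.argmax(seg))
    imin = int(np.argmin(seg))
    return ModulationSummary(
        window=(int(window[0]), int(window[1])),
        max_value=float(seg[imax]),
        min_value=float(seg[imin]),
        max_time=int(window[0]) + imax,
        min_time=int(window[0]) + imin,
    )


def windowed_rate_extrema(
    raster: AlignedRaster,
    window: tuple[int, int],
    bin_ms: int = 100,
    sliding: bool = True,
) -> ModulationSummary:
    """Extremal mean firing rate in a ``bin_ms`` window placed within ``window``.

    The bin slides in 1 ms steps (or tiles disjointly when ``sliding`` is
    False); rates are raw spike counts divided by trials and bin length.
    Returned times are bin start times.
    """
    start, end = int(window[0]), int(window[1])
    if end - start < bin_ms:
        raise ValueError(f"window shorter than bin ({end - start} < {bin_ms})")
    if raster.n_trials == 0:
        raise ValueError("empty raster")
    i0 = start - raster.window[0]
    i1 = end - raster.window[0]
    if not (0 <= i0 < i1 <= raster.indicators.shape[1]):
        raise ValueError(f"window {window} outside raster window {raster.window}")
    counts = raster.indicators[:, i0:i1].sum(axis=0).astype(float)
    if sliding:
        csum = np.concatenate([[0.0], np.cumsum(counts)])
        sums = csum[bin_ms:] - csum[:-bin_ms]  # one per bin start
        starts = np.arange(start, end - bin_ms + 1)
    else:
        n_bins = (end - start) // bin_ms
        sums = counts[: n_bins * bin_ms].reshape(n_bins, bin_ms).sum(axis=1)
        starts = start + np.arange(n_bins) * bin_ms
    rates = sums / raster.n_trials / bin_ms * 1000.0
    imax = int(np.argmax(rates))
    imin = int(np.argmin(rates))
    return ModulationSummary(
        window=(start, end),
        max_value=float(rates[imax]),
        min_value=float(rates[imin]),
        max_time=int(starts[imax]),
        min_time=int(starts[imin]),
    )


def per_stimulus_series(
    session: Session,
    isi: int,
    condition: str = "missing",
    kernel: Optional[KernelSpec] = None,
    bin_ms: int = 100,
    min_trials: int = 1,
) -> list[ModulationSummary]:
    """Rate extrema for each stimulus ordinal's inter-stimulus period.

    For ordinal ``k`` the analysis period is ``[onset_k, onset_{k+1})`` on
    the first-stimulus-aligned grid (the last period ends at the expected
    next onset). Ordinals are analyzed up to the shortest sequence across
    the selected trials. With a kernel the extrema come from the smoothed
    density; otherwise from the sliding ``bin_ms`` count window.
    """
    sub = filter_trials(session, condition=condition, isi=isi)
    if sub.n_trials < min_trials:
        raise ValueError(
            f"need >= {min_trials} correct trials at isi={isi}, got {sub.n_trials}"
        )
    n_periods = min(t.n_stimuli for t in sub.trials)
    end = n_periods * isi
    out: list[ModulationSummary] = []
    if kernel is not None:
        trace = session_density(sub, "first_stimulus", (0, end), kernel)
        for k in range(n_periods):
            out.append(firing_modulation(trace, (k * isi, (k + 1) * isi)))
    else:
        raster = align_raster(sub, "first_stimulus", (0, end))
        for k in range(n_periods):
            out.append(
                windowed_rate_extrema(raster, (k * isi, (k + 1) * isi), bin_ms=bin_ms)
            )
    return out


def population_average(
    traces: Sequence[RateTrace],
    normalization: str = "none",
) -> tuple[RateTrace, np.ndarray]:
    """Pointwise mean across neurons plus t-based 95% CI half-widths.

    ``normalization='per_neuron_max'`` divides each trace by its own max
    before averaging. All traces must share the same grid.
    """
    if not traces:
        raise ValueError("no traces")
    window = traces[0].window
    alignment = traces[0].alignment
    for t in traces[1:]:
        if t.window != window:
            raise ValueError("mismatched trace windows")
    mat = np.stack([t.values for t in traces])
    if normalization == "per_neuron_max":
        peaks = mat.max(axis=1, keepdims=True)
        peaks[peaks == 0] = 1.0
        mat = mat / peaks
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    mean = mat.mean(axis=0)
    n = mat.shape[0]
    if n > 1:
        half = stats.t.ppf(0.975, n - 1) * mat.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        half = np.zeros_like(mean)
    return (
        RateTrace(values=mean, window=window, alignment=alignment, n_trials=n),
        half,
    )
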