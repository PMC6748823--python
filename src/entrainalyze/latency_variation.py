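"""Millisecond-resolution localization of neuronal correlates of trial-by-
trial saccade-latency variation.

Trials of each neuron are split into six equal latency groups; normalized
group population traces are compared with a one-way ANOVA at every
millisecond (neurons as observations), and the onset/offset of group
divergence is read off the p-value trace with a >100 ms consistency-run
rule, with a neuron-resampling bootstrap for uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import Session, filter_trials
from .spike_density import KernelSpec, session_density

logger = logging.getLogger(__name__)

#: Map from analysis alignment names to raster alignment events.
ALIGNMENT_EVENTS = {"omission": "oddball", "saccade": "saccade"}

DEFAULT_WINDOWS = {"omission": (-800, 200), "saccade": (-800, 200)}


@dataclass
class LatencyGroups:
    """Equal-sized trial groups ordered by saccade latency (shortest first)."""

    trial_ids: list[np.ndarray]
    latencies: list[np.ndarray]

    @property
    def n_groups(self) -> int:
        return len(self.trial_ids)

    @property
    def medians(self) -> np.ndarray:
        return np.array([float(np.median(l)) for l in self.latencies])


@dataclass
class VariationTiming:
    """Detected divergence timing for one alignment."""

    alignment: str
    window: tuple[int, int]
    p_trace: np.ndarray
    onset: Optional[int]
    offset: Optional[int]
    alpha: float = 0.05
    consistency_run: int = 100


@dataclass
class BootstrapTiming:
    """Percentile summary of a detected time over bootstrap replicates."""

    point: Optional[int]
    samples: np.ndarray
    n_undetected: int
    quartiles: Optional[tuple[float, float, float]] = None
    ci: Optional[tuple[float, float]] = None


def split_latency_sextiles(
    session: Session,
    isi: int = 400,
    condition: str = "missing",
    n_groups: int = 6,
    min_trials: int = 12,
) -> LatencyGroups:
    """Split correct trials into ``n_groups`` equal groups by saccade latency.

    The ``n mod n_groups`` longest-latency trials are discarded so group
    sizes are equal; sorting is stable so ties keep trial order.
    """
    sub = filter_trials(session, condition=condition, isi=isi)
    lats = np.array([t.saccade_latency for t in sub.trials], dtype=float)
    ids = np.array([t.trial_id for t in sub.trials], dtype=np.int64)
    n = len(lats)
    if n < min_trials:
        raise ValueError(
            f"neuron {session.neuron_id}: need >= {min_trials} correct "
            f"{condition} trials at isi={isi}, got {n}"
        )
    order = np.argsort(lats, kind="stable")
    keep = n - n % n_groups
    order = order[:keep]
    size = keep // n_groups
    trial_ids, latencies = [], []
    for g in range(n_groups):
        sel = order[g * size : (g + 1) * size]
        trial_ids.append(ids[sel])
        latencies.append(lats[sel])
    return LatencyGroups(trial_ids=trial_ids, latencies=latencies)


def group_density_matrices(
    sessions: Sequence[Session],
    windows: Optional[dict[str, tuple[int, int]]] = None,
    kernel: Optional[KernelSpec] = None,
    isi: int = 400,
    condition: str = "missing",
    n_groups: int = 6,
    min_trials: int = 12,
) -> dict[str, np.ndarray]:
    """Per-neuron, per-group normalized spike densities for each alignment.

    Returns, per alignment key of ``windows`` ('omission'/'saccade'), an
    array of shape ``(n_neurons, n_groups, window_length)``. Each neuron is
    normalized by its maximum across all alignments and groups. Neurons
    with too few trials are excluded with a log entry.
    """
    windows = windows or dict(DEFAULT_WINDOWS)
    kernel = kernel or KernelSpec()
    stacks: dict[str, list[np.ndarray]] = {a: [] for a in windows}
    for session in sessions:
        try:
            groups = split_latency_sextiles(
                session, isi=isi, condition=condition,
                n_groups=n_groups, min_trials=min_trials,
            )
        except ValueError as exc:
            logger.info("excluded: %s", exc)
            continue
        per_align: dict[str, np.ndarray] = {}
        for align, window in windows.items():
            event = ALIGNMENT_EVENTS[align]
            rows = []
            for gids in groups.trial_ids:
                sub = session.subset(gids)
                trace = session_density(sub, event, window, kernel)
                rows.append(trace.values)
            per_align[align] = np.stack(rows)
        peak = max(float(m.max()) for m in per_align.values())
        if peak <= 0:
            peak = 1.0
        for align, mat in per_align.items():
            stacks[align].append(mat / peak)
    if not next(iter(stacks.values())):
        raise ValueError("no neuron passed the trial-count requirement")
    return {a: np.stack(v) for a, v in stacks.items()}


def mswise_anova(matrix: np.ndarray, return_f: bool = False):
    """One-way fixed-effects ANOVA (factor: group) at every millisecond.

    ``matrix`` has shape ``(n_neurons, n_groups, T)``; neurons are the
    observations within each group. Time points with zero total variance
    get p = 1.
    """
    n, g, _ = matrix.shape
    if n < 2:
        raise ValueError("need >= 2 neurons")
    gm = matrix.mean(axis=0)  # (g, T)
    grand = gm.mean(axis=0)  # (T,)
    ssb = n * ((gm - grand) ** 2).sum(axis=0)
    ssw = ((matrix - gm[None]) ** 2).sum(axis=(0, 1))
    dfb, dfw = g - 1, g * (n - 1)
    # scale-aware zero threshold so identical inputs round to F = 0
    tol = n * g * (np.abs(matrix).max() + 1.0) ** 2 * np.finfo(float).eps * 1e3
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = np.ones_like(f)
    ok = ssw > tol
    p[ok] = stats.f.sf(f[ok], dfb, dfw)
    # diverging groups with (numerically) zero within-group variance
    exact = (~ok) & (ssb > tol)
    p[exact] = 0.0
    f[~ok] = np.where(ssb[~ok] > tol, np.inf, 0.0)
    return (p, f) if return_f else p


def _run_ends(nonsig: np.ndarray, run_samples: int) -> np.ndarray:
    """Boolean mask: True at i if nonsig[i-run+1 .. i] are all True."""
    c = np.concatenate([[0], np.cumsum(nonsig.astype(int))])
    out = np.zeros(len(nonsig), dtype=bool)
    if len(nonsig) >= run_samples:
        out[run_samples - 1 :] = (
            c[run_samples:] - c[:-run_samples]
        ) == run_samples
    return out


def detect_variation_onset(
    p_trace: np.ndarray,
    times: np.ndarray,
    alpha: float = 0.05,
    run: int = 100,
) -> Optional[int]:
    """Start of group divergence, scanning backward from the window end.

    The onset is the time immediately after the last strictly-more-than-
    ``run``-ms stretch where p stayed above ``alpha``, provided a sustained
    significant epoch (p <= alpha for more than ``run`` ms) follows it;
    None ("undetected") otherwise. Requiring the subsequent epoch to be
    sustained applies the same consistency rule to the divergence itself,
    so isolated significant blips can neither trigger nor displace an
    onset.
    """
    nonsig = p_trace > alpha
    sig = ~nonsig
    run_samples = run + 1
    ends = _run_ends(nonsig, run_samples)
    sig_run_ends = _run_ends(sig, run_samples)
    # epoch_after[i]: a sustained significant run lies entirely after i
    any_end_after = np.concatenate(
        [np.cumsum(sig_run_ends[::-1])[::-1][run_samples:], np.zeros(run_samples)]
    )
    epoch_after = any_end_after > 0
    candidates = np.flatnonzero(ends & epoch_after)
    if len(candidates) == 0:
        return None
    return int(times[candidates[-1] + 1])


def detect_variation_offset(
    p_trace: np.ndarray,
    times: np.ndarray,
    alpha: float = 0.05,
    run: int = 100,
) -> Optional[int]:
    """End of group divergence, scanning forward in time.

    The offset is the earliest time from which p stays above ``alpha`` for
    strictly more than ``run`` ms; None if no such stretch exists.
    """
    nonsig = p_trace > alpha
    run_samples = run + 1
    ends = _run_ends(nonsig, run_samples)
    starts = np.flatnonzero(ends)
    if len(starts) == 0:
        return None
    return int(times[starts[0] - (run_samples - 1)])


def analyze_variation(
    matrices: dict[str, np.ndarray],
    windows: Optional[dict[str, tuple[int, int]]] = None,
    alpha: float = 0.05,
    run: int = 100,
) -> dict[str, VariationTiming]:
    """p-value traces plus onset (omission-aligned) / offset (saccade-
    aligned) detection for each alignment present in ``matrices``."""
    windows = windows or dict(DEFAULT_WINDOWS)
    out = {}
    for align, mat in matrices.items():
        window = windows[align]
        times = np.arange(window[0], window[1])
        p = mswise_anova(mat)
        out[align] = VariationTiming(
            alignment=align,
            window=tuple(window),
            p_trace=p,
            onset=detect_variation_onset(p, times, alpha, run),
            offset=detect_variation_offset(p, times, alpha, run),
            alpha=alpha,
            consistency_run=run,
        )
    return out


def _summary(point, values: list) -> BootstrapTiming:
    detected = np.array([v for v in values if v is not None], dtype=float)
    n_undetected = len(values) - len(detected)
    quartiles = ci = None
    if len(detected):
        quartiles = tuple(float(q) for q in np.percentile(detected, [25, 50, 75]))
        ci = tuple(float(q) for q in np.percentile(detected, [2.5, 97.5]))
    return BootstrapTiming(
        point=point,
        samples=detected,
        n_undetected=n_undetected,
        quartiles=quartiles,
        ci=ci,
    )


def bootstrap_variation_timing(
    matrices: dict[str, np.ndarray],
    windows: Optional[dict[str, tuple[int, int]]] = None,
    alpha: float = 0.05,
    run: int = 100,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, BootstrapTiming]:
    """Bootstrap (resampling neurons) of the onset and offset detections.

    Returns summaries keyed ``'onset'`` (from the omission-aligned matrix)
    and ``'offset'`` (from the saccade-aligned matrix); replicates where
    detection fails are counted separately in ``n_undetected``.
    """
    windows = windows or dict(DEFAULT_WINDOWS)
    n = next(iter(matrices.values())).shape[0]
    if n < 2:
        raise ValueError("bootstrap requires >= 2 neurons")
    point = analyze_variation(matrices, windows, alpha, run)
    rng = np.random.default_rng(seed)
    onsets: list = []
    offsets: list = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        rep = analyze_variation(
            {a: m[idx] for a, m in matrices.items()}, windows, alpha, run
        )
        if "omission" in rep:
            onsets.append(rep["omission"].onset)
        if "saccade" in rep:
            offsets.append(rep["saccade"].offset)
    out = {}
    if "omission" in matrices:
        out["onset"] = _summary(point["omission"].onset, onsets)
    if "saccade" in matrices:
        out["offset"] = _summary(point["saccade"].offset, offsets)
    return out
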