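"""Neuron response characterization: increase/decrease classification,
oddball-condition and saccade-direction effects, and ISI duration tuning."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import Session, align_raster, filter_trials
from .spike_density import (
    KernelSpec,
    firing_modulation,
    per_stimulus_series,
    session_density,
    windowed_rate_extrema,
)

logger = logging.getLogger(__name__)


@dataclass
class TypeClassification:
    """Sign of the across-repetition trend of per-stimulus firing modulation."""

    label: str  # increase | decrease | flat | other
    slope: float  # modulation change per stimulus ordinal
    p_value: float


@dataclass
class TuningResult:
    """Firing modulation per ISI, normalized to the preferred interval."""

    isi_values: tuple[int, ...]
    modulation: np.ndarray
    normalized: np.ndarray
    preferred_isi: int
    label: str  # long_tuned | short_tuned


@dataclass
class ConditionContrast:
    """Missing vs deviant pre-oddball peak rates across neurons."""

    missing_max: np.ndarray
    deviant_max: np.ndarray
    significant: np.ndarray
    ratio: float
    t_statistic: float
    df: int
    p_value: float


@dataclass
class DirectionBias:
    """Contra vs ipsi pre-oddball peak rates and the through-origin slope."""

    contra_max: np.ndarray
    ipsi_max: np.ndarray
    significant: np.ndarray
    slope: float
    t_statistic: float
    df: int
    p_value: float


def classify_response_type(
    session: Session,
    isi: int = 400,
    condition: str = "missing",
    kernel: Optional[KernelSpec] = None,
    alpha: float = 0.05,
    min_stimuli: int = 4,
) -> TypeClassification:
    """Classify a neuron by the trend of per-stimulus firing modulation.

    Linear regression of modulation (max - min per inter-stimulus period)
    on the stimulus ordinal: ``increase``/``decrease`` when the slope is
    significant at ``alpha``, ``flat`` otherwise. Neurons whose mean
    modulation is below twice the spread of the per-period minima (no
    stimulus-locked modulation) are labelled ``other``.
    """
    series = per_stimulus_series(session, isi, condition=condition, kernel=kernel)
    if len(series) < min_stimuli:
        raise ValueError(
            f"need >= {min_stimuli} stimuli per trial, got {len(series)}"
        )
    mods = np.array([s.modulation for s in series])
    mins = np.array([s.min_value for s in series])
    ordinals = np.arange(1, len(series) + 1)
    fit = stats.linregress(ordinals, mods)
    base_sd = float(mins.std(ddof=1)) if len(mins) > 1 else 0.0
    if mods.mean() < 2.0 * base_sd:
        label = "other"
    elif fit.pvalue < alpha and fit.slope > 0:
        label = "increase"
    elif fit.pvalue < alpha and fit.slope < 0:
        label = "decrease"
    else:
        label = "flat"
    return TypeClassification(label=label, slope=float(fit.slope), p_value=float(fit.pvalue))


def _preoddball_max(
    session: Session,
    isi: int,
    condition: Optional[str],
    direction: Optional[str],
    window_before: int,
    bin_ms: int,
) -> tuple[float, np.ndarray]:
    """Peak sliding-window rate before the oddball plus per-trial counts at
    the peak window position (for trial-level tests)."""
    sub = filter_trials(session, condition=condition, isi=isi)
    if direction is not None:
        sub = sub.subset(
            t.trial_id for t in sub.trials if t.target_direction == direction
        )
    if sub.n_trials == 0:
        raise ValueError("no trials in cell")
    raster = align_raster(sub, "oddball", (-window_before, 0))
    ext = windowed_rate_extrema(raster, (-window_before, 0), bin_ms=bin_ms)
    i0 = ext.max_time - raster.window[0]
    trial_counts = raster.indicators[:, i0 : i0 + bin_ms].sum(axis=1)
    return ext.max_value, trial_counts


def condition_contrast(
    sessions: Sequence[Session],
    isi: int = 400,
    window_before: int = 400,
    bin_ms: int = 100,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> ConditionContrast:
    """Missing vs deviant peak pre-oddball activity across neurons.

    Per neuron: the maximal ``bin_ms`` sliding-window rate during the
    ``window_before`` ms preceding the oddball, per condition, with a
    trial-level rank-sum test at the peak window. Population: mean ratio
    and a paired t-test across neurons. Neurons lacking a condition are
    skipped with a log entry.
    """
    miss, dev, sig = [], [], []
    n_tests = len(sessions)
    for session in sessions:
        try:
            m_max, m_counts = _preoddball_max(
                session, isi, "missing", None, window_before, bin_ms
            )
            d_max, d_counts = _preoddball_max(
                session, isi, "deviant", None, window_before, bin_ms
            )
        except ValueError:
            logger.info("neuron %s skipped: missing a condition", session.neuron_id)
            continue
        miss.append(m_max)
        dev.append(d_max)
        p = stats.ranksums(m_counts, d_counts).pvalue
        thresh = alpha / n_tests if bonferroni else alpha
        sig.append(p < thresh)
    miss_arr, dev_arr = np.array(miss), np.array(dev)
    if len(miss_arr) == 0:
        raise ValueError("no neuron has both conditions")
    tres = stats.ttest_rel(miss_arr, dev_arr)
    return ConditionContrast(
        missing_max=miss_arr,
        deviant_max=dev_arr,
        significant=np.array(sig, dtype=bool),
        ratio=float(miss_arr.mean() / dev_arr.mean()),
        t_statistic=float(tres.statistic),
        df=len(miss_arr) - 1,
        p_value=float(tres.pvalue),
    )


def direction_bias(
    sessions: Sequence[Session],
    isi: int = 400,
    condition: str = "missing",
    window_before: int = 400,
    bin_ms: int = 100,
    alpha: float = 0.05,
) -> DirectionBias:
    """Contra vs ipsi peak pre-oddball activity and the regression slope
    constrained through the origin (contra = slope * ipsi)."""
    contra, ipsi, sig = [], [], []
    for session in sessions:
        try:
            c_max, c_counts = _preoddball_max(
                session, isi, condition, "contra", window_before, bin_ms
            )
            i_max, i_counts = _preoddball_max(
                session, isi, condition, "ipsi", window_before, bin_ms
            )
        except ValueError:
            logger.info("neuron %s skipped: missing a direction", session.neuron_id)
            continue
        contra.append(c_max)
        ipsi.append(i_max)
        sig.append(stats.ranksums(c_counts, i_counts).pvalue < alpha)
    contra_arr, ipsi_arr = np.array(contra), np.array(ipsi)
    if len(contra_arr) == 0:
        raise ValueError("no neuron has both directions")
    slope = slope_through_origin(contra_arr, ipsi_arr)
    tres = stats.ttest_rel(contra_arr, ipsi_arr)
    return DirectionBias(
        contra_max=contra_arr,
        ipsi_max=ipsi_arr,
        significant=np.array(sig, dtype=bool),
        slope=slope,
        t_statistic=float(tres.statistic),
        df=len(contra_arr) - 1,
        p_value=float(tres.pvalue),
    )


def slope_through_origin(y: np.ndarray, x: np.ndarray) -> float:
    """Least-squares slope of y = b*x with no intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = float(np.dot(x, x))
    if denom == 0:
        return float("nan")
    return float(np.dot(y, x) / denom)


def tuning_from_modulation(
    isi_values: Sequence[int], modulation: Sequence[float]
) -> TuningResult:
    """Normalize a modulation-per-ISI vector and assign the tuning label."""
    isi_values = tuple(int(v) for v in isi_values)
    mod_arr = np.asarray(modulation, dtype=float)
    peak = float(mod_arr.max())
    normalized = mod_arr / peak if peak > 0 else np.zeros_like(mod_arr)
    preferred = int(isi_values[int(np.argmax(mod_arr))])
    label = "long_tuned" if preferred == max(isi_values) else "short_tuned"
    return TuningResult(
        isi_values=isi_values,
        modulation=mod_arr,
        normalized=normalized,
        preferred_isi=preferred,
        label=label,
    )


def duration_tuning(
    session: Session,
    kernel: Optional[KernelSpec] = None,
    condition: str = "missing",
    min_isis: int = 3,
    min_trials: int = 5,
) -> TuningResult:
    """Firing modulation per ISI over the last full inter-stimulus period.

    For each ISI with at least ``min_trials`` correct trials, spike density
    (default kernel sigma 30 ms) is computed aligned with the last stimulus
    before the oddball, and modulation is max - min over ``[0, isi)``.
    ``long_tuned`` iff the preferred ISI is the longest tested.
    """
    kernel = kernel or KernelSpec()
    isis = sorted(
        {
            t.isi
            for t in session.trials
            if t.condition == condition and t.outcome == "correct"
        }
    )
    mods = []
    kept = []
    for isi in isis:
        sub = filter_trials(session, condition=condition, isi=isi)
        if sub.n_trials < min_trials:
            continue
        trace = session_density(sub, "last_stimulus", (0, isi), kernel)
        mods.append(firing_modulation(trace, (0, isi)).modulation)
        kept.append(isi)
    if len(kept) < min_isis:
        raise ValueError(
            f"need >= {min_isis} ISIs with >= {min_trials} trials, got {len(kept)}"
        )
    return tuning_from_modulation(kept, mods)


def tuning_population_summary(
    results: Sequence[TuningResult],
) -> dict[str, dict]:
    """Mean normalized modulation per ISI within each tuning label.

    All results contributing to a label must share the same ISI grid.
    """
    out: dict[str, dict] = {}
    for label in ("long_tuned", "short_tuned"):
        group = [r for r in results if r.label == label]
        if not group:
            continue
        grid = group[0].isi_values
        for r in group[1:]:
            if r.isi_values != grid:
                raise ValueError("mismatched ISI grids within a tuning label")
        mat = np.stack([r.normalized for r in group])
        out[label] = {
            "isi_values": grid,
            "mean_normalized": mat.mean(axis=0),
            "n": len(group),
        }
    return out
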