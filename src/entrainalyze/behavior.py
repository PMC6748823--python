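"""Saccade detection from eye velocity and microstimulation effect
statistics (latency tables, rank-sum/paired-t tests, two-way ANOVA)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import EyeTrace, Session, filter_trials


@dataclass
class SaccadeEvent:
    onset: int  # ms, trial clock
    latency: int  # ms from oddball
    peak_velocity: float  # deg/s
    amplitude: float  # deg
    direction: str  # contra | ipsi


@dataclass
class StimEffectTable:
    """Per-cell stimulation/control latency statistics plus population tests.

    ``cells`` has one row per session x condition x direction;
    ``population`` maps ``(condition, direction)`` to paired-t results on
    session medians and the mean latency-change score.
    """

    cells: pd.DataFrame
    population: dict


def _speed(eye: EyeTrace, smooth: int = 5) -> np.ndarray:
    """Angular speed (deg/s): central-difference velocity, boxcar-smoothed."""
    vx = np.gradient(eye.x) * eye.sample_rate
    vy = np.gradient(eye.y) * eye.sample_rate
    if smooth > 1:
        box = np.ones(smooth) / smooth
        vx = np.convolve(vx, box, mode="same")
        vy = np.convolve(vy, box, mode="same")
    return np.hypot(vx, vy)


def detect_saccade(
    eye: EyeTrace,
    oddball_time: int,
    threshold: float = 60.0,
    response_window: int = 600,
    sustain: int = 5,
    smooth: int = 5,
    refine: bool = True,
) -> Optional[SaccadeEvent]:
    """Detect the saccade immediately after the oddball from eye velocity.

    A candidate is the first millisecond after ``oddball_time`` where speed
    exceeds ``threshold`` deg/s for at least ``sustain`` consecutive ms.
    With ``refine`` the onset is walked back to where speed last dropped
    below ``threshold / 3``, which removes the lag of the threshold
    crossing relative to movement start. Returns None if the eye never
    crosses threshold within the response window.
    """
    end = int(oddball_time) + response_window
    if len(eye.x) < end:
        raise ValueError(
            f"eye trace ends at {len(eye.x)} ms; need coverage to {end} ms"
        )
    speed = _speed(eye, smooth=smooth)
    above = speed > threshold
    onset = None
    for t in range(int(oddball_time) + 1, end - sustain + 1):
        if above[t : t + sustain].all():
            onset = t
            break
    if onset is None:
        return None
    if refine:
        floor = threshold / 3.0
        while onset > oddball_time + 1 and speed[onset - 1] > floor:
            onset -= 1
    seg_end = min(len(eye.x) - 1, onset + 100)
    peak_velocity = float(speed[onset:seg_end].max())
    dx = float(eye.x[seg_end] - eye.x[onset])
    dy = float(eye.y[seg_end] - eye.y[onset])
    return SaccadeEvent(
        onset=int(onset),
        latency=int(onset - oddball_time),
        peak_velocity=peak_velocity,
        amplitude=float(np.hypot(dx, dy)),
        direction="contra" if dx >= 0 else "ipsi",
    )


def latency_table(
    sessions: Sequence[Session],
    alpha: float = 0.05,
    min_trials: int = 3,
) -> StimEffectTable:
    """Stimulation vs control saccade latencies per session/condition/direction.

    Medians and SDs are computed on correct trials only. Per-cell Wilcoxon
    rank-sum p-values are Bonferroni-corrected across sessions; the
    variance comparison uses a two-sided F-test. Cells with fewer than
    ``min_trials`` trials in either arm are flagged ``excluded`` and left
    out of the population paired t-tests on session medians.
    """
    n_sessions = len(sessions)
    rows = []
    for session in sessions:
        correct = filter_trials(session, correct_only=True, min_fixation=None)
        for condition in ("missing", "deviant"):
            for direction in ("contra", "ipsi"):
                cell = [
                    t
                    for t in correct.trials
                    if t.condition == condition and t.target_direction == direction
                ]
                stim = np.array(
                    [t.saccade_latency for t in cell if t.stimulated], dtype=float
                )
                ctrl = np.array(
                    [t.saccade_latency for t in cell if not t.stimulated], dtype=float
                )
                excluded = len(stim) < min_trials or len(ctrl) < min_trials
                if excluded:
                    p = f_p = np.nan
                    med_s = med_c = sd_s = sd_c = np.nan
                else:
                    p = float(stats.ranksums(stim, ctrl).pvalue)
                    med_s, med_c = float(np.median(stim)), float(np.median(ctrl))
                    sd_s = float(stim.std(ddof=1))
                    sd_c = float(ctrl.std(ddof=1))
                    f_p = _vartest_p(stim, ctrl)
                rows.append(
                    {
                        "session": session.neuron_id,
                        "condition": condition,
                        "direction": direction,
                        "n_stim": len(stim),
                        "n_control": len(ctrl),
                        "median_stim": med_s,
                        "median_control": med_c,
                        "sd_stim": sd_s,
                        "sd_control": sd_c,
                        "change": med_s - med_c,
                        "p_ranksum": p,
                        "p_corrected": min(1.0, p * n_sessions)
                        if np.isfinite(p)
                        else np.nan,
                        "f_test_p": f_p,
                        "excluded": excluded,
                    }
                )
    cells = pd.DataFrame(rows)
    cells["significant"] = cells["p_corrected"] < alpha
    population = {}
    for (condition, direction), grp in cells[~cells["excluded"]].groupby(
        ["condition", "direction"]
    ):
        if len(grp) < 2:
            continue
        tres = stats.ttest_rel(grp["median_stim"], grp["median_control"])
        population[(condition, direction)] = {
            "t": float(tres.statistic),
            "df": len(grp) - 1,
            "p": float(tres.pvalue),
            "mean_change": float(grp["change"].mean()),
            "n": len(grp),
        }
    return StimEffectTable(cells=cells, population=population)


def _vartest_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test p for equality of variances."""
    f = a.var(ddof=1) / b.var(ddof=1)
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return float(min(1.0, p))


def stim_anova(table: StimEffectTable) -> dict:
    """Two-way fixed-effects ANOVA (condition x direction) on latency-change
    scores, with post-hoc paired t-tests between directions per condition.

    Requires a balanced design: every session contributes all four cells.
    """
    cells = table.cells[~table.cells["excluded"]]
    counts = cells.groupby("session").size()
    if len(cells) == 0 or not (counts == 4).all():
        raise ValueError("unbalanced design: every session needs all 4 cells")
    y = cells["change"].to_numpy(dtype=float)
    cond = (cells["condition"] == "missing").to_numpy()
    dirn = (cells["direction"] == "contra").to_numpy()
    n_rep = len(cells) // 4
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    m_c = np.array([y[cond].mean(), y[~cond].mean()])
    m_d = np.array([y[dirn].mean(), y[~dirn].mean()])
    ss_a = 2 * n_rep * ((m_c - grand) ** 2).sum()
    ss_b = 2 * n_rep * ((m_d - grand) ** 2).sum()
    ss_cells = 0.0
    for ci in (True, False):
        for di in (True, False):
            sel = (cond == ci) & (dirn == di)
            ss_cells += n_rep * (y[sel].mean() - grand) ** 2
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_cells
    df_err = len(y) - 4
    ms_err = ss_err / df_err
    out = {"df_error": df_err}
    for name, ss in (("condition", ss_a), ("direction", ss_b), ("interaction", ss_ab)):
        f = (ss / 1.0) / ms_err if ms_err > 0 else (0.0 if ss == 0 else np.inf)
        out[f"F_{name}"] = float(f)
        out[f"p_{name}"] = float(stats.f.sf(f, 1, df_err)) if np.isfinite(f) else 0.0
    posthoc = {}
    for condition in ("missing", "deviant"):
        sub = cells[cells["condition"] == condition].pivot(
            index="session", columns="direction", values="change"
        )
        tres = stats.ttest_rel(sub["contra"], sub["ipsi"])
        posthoc[condition] = {
            "t": float(tres.statistic),
            "df": len(sub) - 1,
            "p": float(tres.pvalue),
        }
    out["posthoc"] = posthoc
    return out
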