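"""Outcome measures and statistics for plasticity protocols.

The primary observable is the synaptic AMPAR count of a PSD — free receptors
on the PSD plus all scaffold.AMPAR complexes — and its percent change over an
analysis window, ``100 * (N(t_end) - N(t_start)) / N(t_start)``.  Because the
counts are ~100-copy shot-noisy signals, window endpoints are estimated by
averaging samples over a trailing window ``[t - smooth, t]`` (30 s by
default, clipped at the trajectory start).  Trailing rather than centred
windows keep the baseline estimate free of post-induction samples when the
window opens at the induction time and keep the final estimate inside the
simulated range; the 30 s length averages over the slow occupancy
fluctuations of ~100-copy counts on their plateaus, which dominate the
replicate variance of percent changes.

Replicate summaries report mean +/- standard deviation across seeds.
Group comparisons use Welch's t by default (control and treatment replicates
use independent seeds); a seed-matched paired t is provided for parity with
the original analysis.  Multi-group comparisons use one-way ANOVA with Tukey
HSD post hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import Trajectory

__all__ = [
    "SynapticCount",
    "PercentChange",
    "StatTestResult",
    "synaptic_count",
    "synaptic_series",
    "percent_change",
    "percent_changes",
    "summarize_percent_changes",
    "compare_to_control",
    "anova_tukey",
]

DEFAULT_SMOOTH = 30.0  # s, length of the trailing endpoint-averaging window


@dataclass(frozen=True)
class SynapticCount:
    psd_index: int
    time: float
    count: float


@dataclass(frozen=True)
class PercentChange:
    psd_index: int
    window: tuple[float, float]
    value: float


@dataclass(frozen=True)
class StatTestResult:
    test: str
    statistic: float
    dof: float | tuple[float, float]
    p_value: float
    groups: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)


def synaptic_series(traj: Trajectory, psd_index: int) -> np.ndarray:
    return traj.synaptic_series(psd_index)


def _window_mean(traj: Trajectory, series: np.ndarray, t: float, smooth: float) -> float:
    """Mean of ``series`` over the trailing window ``[t - smooth, t]``."""
    if not (traj.times[0] - 1e-9 <= t <= traj.times[-1] + 1e-9):
        raise ValueError(f"time {t} outside trajectory range")
    mask = (traj.times >= t - smooth - 1e-9) & (traj.times <= t + 1e-9)
    return float(series[mask].mean())


def synaptic_count(
    traj: Trajectory, psd_index: int, t: float, smooth: float = DEFAULT_SMOOTH
) -> SynapticCount:
    """Synaptic AMPARs (free on the PSD + anchored) at time ``t``, averaged
    over the trailing ``smooth`` seconds."""
    series = traj.synaptic_series(psd_index)
    return SynapticCount(psd_index, t, _window_mean(traj, series, t, smooth))


def percent_change(
    traj: Trajectory,
    psd_index: int,
    t_start: float,
    t_end: float,
    smooth: float = DEFAULT_SMOOTH,
) -> PercentChange:
    series = traj.synaptic_series(psd_index)
    n0 = _window_mean(traj, series, t_start, smooth)
    n1 = _window_mean(traj, series, t_end, smooth)
    if n0 <= 0:
        raise ZeroDivisionError(
            f"baseline synaptic count at t={t_start} is zero; percent change undefined")
    return PercentChange(psd_index, (t_start, t_end), 100.0 * (n1 - n0) / n0)


def percent_changes(
    trajs: Sequence[Trajectory],
    psd_index: int,
    window: tuple[float, float],
    smooth: float = DEFAULT_SMOOTH,
) -> np.ndarray:
    """Per-replicate percent changes of one PSD over a window."""
    return np.array([
        percent_change(tr, psd_index, window[0], window[1], smooth).value for tr in trajs
    ])


def summarize_percent_changes(
    trajs: Sequence[Trajectory],
    window: tuple[float, float],
    psd_indices: Iterable[int] | None = None,
    smooth: float = DEFAULT_SMOOTH,
) -> pd.DataFrame:
    """Replicate summary: mean +/- STD of percent change per PSD."""
    if psd_indices is None:
        psd_indices = trajs[0].system.spine_indices()
    rows = []
    for psd in psd_indices:
        vals = percent_changes(trajs, psd, window, smooth)
        rows.append({
            "psd": psd,
            "t_start": window[0],
            "t_end": window[1],
            "mean": vals.mean(),
            "std": vals.std(ddof=1) if vals.size > 1 else np.nan,
            "n": vals.size,
        })
    return pd.DataFrame(rows)


def compare_to_control(
    sample: Sequence[float],
    control: Sequence[float],
    mode: str = "welch_t",
) -> StatTestResult:
    """Two-sample comparison of per-replicate values against a control arm."""
    a = np.asarray(sample, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per arm")
    if mode == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return StatTestResult("welch_t", float(res.statistic), float(res.df),
                              float(res.pvalue))
    if mode == "paired_t":
        if a.size != b.size:
            raise ValueError("paired mode requires equal, seed-matched sample sizes")
        res = stats.ttest_rel(a, b)
        return StatTestResult("paired_t", float(res.statistic), float(a.size - 1),
                              float(res.pvalue))
    raise ValueError(f"unknown mode {mode!r}")


def anova_tukey(groups: Sequence[Sequence[float]],
                labels: Sequence[str] | None = None) -> list[StatTestResult]:
    """One-way ANOVA followed by Tukey HSD pairwise comparisons.

    Returns the ANOVA result first, then one result per ordered pair.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("need at least 3 groups for ANOVA + Tukey")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least 2 observations")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    n_total = sum(g.size for g in arrays)
    dof = (len(arrays) - 1, n_total - len(arrays))
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: no variance anywhere, report F=0
        results = [StatTestResult("anova_oneway", 0.0, dof, 1.0, tuple(labels))]
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                results.append(StatTestResult(
                    "tukey_hsd", 0.0, dof, 1.0, (labels[i], labels[j])))
        return results
    f_res = stats.f_oneway(*arrays)
    results = [StatTestResult("anova_oneway", float(f_res.statistic), dof,
                              float(f_res.pvalue), tuple(labels))]
    tk = stats.tukey_hsd(*arrays)
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            results.append(StatTestResult(
                "tukey_hsd", float(tk.statistic[i, j]), dof,
                float(tk.pvalue[i, j]), (labels[i], labels[j])))
    return results
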