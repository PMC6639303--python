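"""Repaired/failed classification from dye-entry ΔF/F traces.

A cell that reseals its membrane stops admitting FM dye, so its ΔF/F trace
plateaus; a cell that fails to repair keeps admitting dye and its trace
keeps rising.  The classifier calls a cell repaired when the smoothed
trace's slope stays below ``slope_epsilon`` throughout a sliding window of
length ``window`` whose start falls no later than ``horizon`` seconds after
injury.  The window start of the first such window is the plateau time.
The defaults (window 20 s, slope 0.5 %·ΔF/F per second, horizon 120 s) sit
between the repair-within-a-minute behaviour of healthy cells and the
continued entry beyond two minutes seen in repair-deficient cells, and all
of them surface in the result's ``params``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .traces import KineticTrace

__all__ = ["RepairResult", "classify_repair", "cohort_repair_summary"]


@dataclass
class RepairResult:
    """Per-cell repair call with the settings that produced it."""

    trace: KineticTrace
    repaired: bool
    plateau_time: float | None      # s post-injury; present iff repaired
    final_dff: float
    saturated: bool = False
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.repaired and self.plateau_time is None:
            raise ValueError("repaired result must carry plateau_time")
        if not self.repaired and self.plateau_time is not None:
            raise ValueError("failed result must not carry plateau_time")


def classify_repair(
    trace: KineticTrace,
    window: float = 20.0,
    slope_epsilon: float = 0.005,
    horizon: float = 120.0,
    smoothing_sigma: float = 1.0,
    saturation_level: float | None = None,
) -> RepairResult:
    """Classify one dye-entry ΔF/F trace as repaired or failed.

    Parameters
    ----------
    window
        Sliding-window length in seconds over which the slope must stay low.
    slope_epsilon
        Slope threshold, ΔF/F per second.
    horizon
        Latest admissible plateau onset, seconds post-injury.
    smoothing_sigma
        Gaussian pre-smoothing of the trace, in frames.
    saturation_level
        Raw-intensity ceiling; if the trace's recorded raw maximum
        (``trace.meta['raw_max']``) reaches it, a plateau is attributed to
        detector clipping and the cell is flagged saturated, not repaired.
    """
    if trace.kind != "dff":
        raise ValueError("classify_repair needs a ΔF/F (kind='dff') trace")
    dt = trace.frame_interval
    if trace.times[-1] < horizon:
        raise ValueError(
            f"trace covers only {trace.times[-1]:.0f}s post-injury; "
            f"≥{horizon:.0f}s required for classification"
        )
    values = (
        gaussian_filter1d(trace.values, smoothing_sigma)
        if smoothing_sigma > 0
        else trace.values
    )
    slope = np.gradient(values, trace.times)
    below = slope < slope_epsilon

    w = max(int(round(window / dt)), 1)
    post = np.flatnonzero(trace.times >= 0)
    plateau_time: float | None = None
    for i in post:
        if trace.times[i] > horizon or i + w >= len(trace):
            break
        if below[i: i + w + 1].all():
            plateau_time = float(trace.times[i])
            break

    params = {
        "window": window,
        "slope_epsilon": slope_epsilon,
        "horizon": horizon,
        "smoothing_sigma": smoothing_sigma,
        "saturation_level": saturation_level,
    }
    saturated = False
    if saturation_level is not None:
        raw_max = trace.meta.get("raw_max")
        if raw_max is not None and raw_max >= saturation_level:
            saturated = True
    repaired = plateau_time is not None and not saturated
    return RepairResult(
        trace=trace,
        repaired=repaired,
        plateau_time=plateau_time if repaired else None,
        final_dff=float(values[-1]),
        saturated=saturated,
        params=params,
    )


def cohort_repair_summary(
    results: list[RepairResult],
    group_labels: list[str],
    allow_resample: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group fraction repaired and mean ± SEM ΔF/F time course.

    Returns ``(summary, timecourse)`` data frames.  All traces must share a
    time grid; with ``allow_resample=True`` mismatching traces are linearly
    resampled onto the first trace's grid, otherwise a mismatch is an error.
    """
    if len(results) != len(group_labels):
        raise ValueError("one group label per result required")
    if not results:
        raise ValueError("empty cohort")
    ref_times = results[0].trace.times
    traces = []
    for res in results:
        t = res.trace
        if len(t) == len(ref_times) and np.allclose(t.times, ref_times):
            traces.append(t.values)
        elif allow_resample:
            traces.append(np.interp(ref_times, t.times, t.values))
        else:
            raise ValueError(
                "traces have mixed time grids; pass allow_resample=True"
            )
    values = np.asarray(traces)
    labels = np.asarray(group_labels)

    rows = []
    tc_rows = []
    for group in pd.unique(labels):
        sel = labels == group
        n = int(sel.sum())
        n_rep = int(sum(r.repaired for r, s in zip(results, sel) if s))
        rows.append(
            {
                "group": group,
                "n": n,
                "n_repaired": n_rep,
                "fraction_repaired": n_rep / n,
            }
        )
        sub = values[sel]
        mean = sub.mean(axis=0)
        sem = (
            sub.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
        )
        tc_rows.append(
            pd.DataFrame(
                {"group": group, "time": ref_times, "mean_dff": mean, "sem_dff": sem}
            )
        )
    return pd.DataFrame(rows), pd.concat(tc_rows, ignore_index=True)
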