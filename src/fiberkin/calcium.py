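"""Calcium-transient detection in CSF-contacting neurons.

Traces are dF/F series recorded at 3-4 Hz over ~75 s.  The baseline is
a running low percentile (default 20th over an 8 s window) corrected by
the Gaussian quantile offset so that it estimates the true resting
level rather than its lower tail; the noise scale is the scaled median
absolute deviation of the residual about a running median.  An event is
an excursion whose peak exceeds baseline + 3 SD with at least two
consecutive supra-threshold samples (single-sample noise spikes do not
count), and whose onset and return crossings both fall inside the
recording — a transient still above threshold at the last sample is not
"completed" and is not counted.  A cell is active if it has at least
one event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import median_filter, percentile_filter

__all__ = [
    "CalciumEvent", "CalciumTraceResult", "ActivitySummary",
    "estimate_baseline", "detect_events", "analyze_trace",
    "activity_summary",
]

MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


def estimate_baseline(trace: np.ndarray, rate: float,
                      window_s: float = 8.0,
                      percentile: float = 20.0):
    """Running-percentile baseline and robust noise SD of a dF/F trace.

    The running ``percentile`` (default 20th) over ``window_s`` tracks
    slow drift while ignoring transients; since for Gaussian noise the
    p-th percentile sits z_p standard deviations below the mean, the
    offset ``-z_p * sd`` is added back so the baseline estimates the
    resting level itself.  Returns ``(baseline, noise_sd)``.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("trace must be 1-D")
    if x.size < 30:
        raise ValueError("trace too short: need >= 30 samples")
    if rate <= 0 or window_s <= 0:
        raise ValueError("rate and window_s must be positive")
    if not 0 < percentile < 50:
        raise ValueError("percentile must be in (0, 50)")

    win = max(3, int(round(window_s * rate)))
    low = percentile_filter(x, percentile, size=win, mode="nearest")
    med = median_filter(x, size=win, mode="nearest")
    resid = x - med
    sd = float(MAD_TO_SD * np.median(np.abs(resid - np.median(resid))))
    z = float(-stats.norm.ppf(percentile / 100.0))
    baseline = low + z * sd
    return baseline, sd


@dataclass
class CalciumEvent:
    start: int       # first supra-threshold sample
    peak: int
    end: int         # last supra-threshold sample
    amplitude: float  # peak dF/F above baseline


def detect_events(trace: np.ndarray, baseline: np.ndarray, noise_sd: float,
                  n_sd: float = 3.0, min_samples: int = 2,
                  return_sd: float = 1.0):
    """Completed supra-threshold transients of a trace.

    Returns ``(events, active)``.  An event must exceed
    baseline + ``n_sd`` * SD for at least ``min_samples`` consecutive
    samples (single-sample noise spikes do not count); its extent runs
    until the trace returns below baseline + ``return_sd`` * SD
    (hysteresis, so a momentary noise dip below the high threshold does
    not split or terminate a transient).  Only events whose onset and
    return both lie strictly inside the recording are counted.
    """
    x = np.asarray(trace, dtype=float)
    b = np.broadcast_to(np.asarray(baseline, dtype=float), x.shape)
    if noise_sd <= 0:
        raise ValueError("noise SD must be positive to detect events")
    hi = x > b + n_sd * noise_sd
    lo = x > b + return_sd * noise_sd
    events: list[CalciumEvent] = []
    n = x.size
    i = 0
    while i < n:
        if not lo[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and lo[j + 1]:
            j += 1
        completed = i > 0 and j < n - 1
        # longest consecutive run above the high threshold inside [i, j]
        run = best = 0
        for k in range(i, j + 1):
            run = run + 1 if hi[k] else 0
            best = max(best, run)
        if completed and best >= min_samples:
            k = i + int(np.argmax(x[i:j + 1] - b[i:j + 1]))
            events.append(CalciumEvent(
                start=i, peak=k, end=j,
                amplitude=float(x[k] - b[k]),
            ))
        i = j + 1
    return events, len(events) > 0


@dataclass
class CalciumTraceResult:
    """Per-ROI analysis: baseline, noise, events, activity."""

    baseline: np.ndarray
    noise_sd: float
    events: list = field(default_factory=list)
    active: bool = False
    rate_hz: float = 3.45
    duration_s: float = 75.0

    @property
    def events_per_min(self) -> float:
        return 60.0 * len(self.events) / self.duration_s


def analyze_trace(trace: np.ndarray, rate: float, n_sd: float = 3.0,
                  window_s: float = 8.0,
                  percentile: float = 20.0) -> CalciumTraceResult:
    """Baseline estimation plus event detection in one call."""
    baseline, sd = estimate_baseline(trace, rate, window_s, percentile)
    if sd <= 0:
        return CalciumTraceResult(baseline=baseline, noise_sd=sd,
                                  events=[], active=False, rate_hz=rate,
                                  duration_s=len(trace) / rate)
    events, active = detect_events(trace, baseline, sd, n_sd=n_sd)
    return CalciumTraceResult(baseline=baseline, noise_sd=sd, events=events,
                              active=active, rate_hz=rate,
                              duration_s=len(trace) / rate)


@dataclass
class ActivitySummary:
    per_fish: pd.DataFrame
    pct_active_test: dict | None
    events_rate_test: dict | None
    mean_active_ratio: float | None

    def summary(self) -> str:
        lines = ["Activity before/after ablation (per fish):",
                 self.per_fish.to_string(index=False)]
        if self.pct_active_test:
            lines.append(
                f"paired t-test on %active: t={self.pct_active_test['t']:.3g} "
                f"p={self.pct_active_test['p']:.3g}")
        if self.events_rate_test:
            lines.append(
                f"paired t-test on events/min: t={self.events_rate_test['t']:.3g} "
                f"p={self.events_rate_test['p']:.3g}")
        if self.mean_active_ratio is not None:
            lines.append(f"mean after/before active-cell ratio: "
                         f"{self.mean_active_ratio:.2f}")
        return "\n".join(lines)


def activity_summary(cells: pd.DataFrame,
                     duration_s: float = 75.0) -> ActivitySummary:
    """Before/after activity comparison over paired cells.

    ``cells`` needs columns ``fish``, ``cell``, ``events_before``,
    ``events_after`` (event counts per recording of ``duration_s``
    seconds for the same cell before and after the ablation).  Reports,
    per fish: percent active cells, events/min among active cells, and
    the after/before ratio of active-cell counts; paired two-tailed
    t-tests are computed across fish.
    """
    required = {"fish", "cell", "events_before", "events_after"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if cells.empty:
        raise ValueError("no paired cells")

    rows = []
    minutes = duration_s / 60.0
    for fish, grp in cells.groupby("fish"):
        nb = (grp["events_before"] > 0)
        na = (grp["events_after"] > 0)
        rows.append({
            "fish": fish,
            "n_cells": len(grp),
            "pct_active_before": 100.0 * nb.mean(),
            "pct_active_after": 100.0 * na.mean(),
            "active_ratio": (na.sum() / nb.sum()) if nb.sum() else np.nan,
            "events_per_min_before": (grp.loc[nb, "events_before"].mean() / minutes
                                      if nb.any() else np.nan),
            "events_per_min_after": (grp.loc[na, "events_after"].mean() / minutes
                                     if na.any() else np.nan),
        })
    per_fish = pd.DataFrame(rows)

    def _paired(a, b):
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 2:
            return None
        t, p = stats.ttest_rel(a[ok], b[ok])
        return {"t": float(t), "p": float(p), "n_fish": int(ok.sum())}

    return ActivitySummary(
        per_fish=per_fish,
        pct_active_test=_paired(per_fish["pct_active_before"].to_numpy(),
                                per_fish["pct_active_after"].to_numpy()),
        events_rate_test=_paired(per_fish["events_per_min_before"].to_numpy(),
                                 per_fish["events_per_min_after"].to_numpy()),
        mean_active_ratio=float(np.nanmean(per_fish["active_ratio"]))
        if per_fish["active_ratio"].notna().any() else None,
    )
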