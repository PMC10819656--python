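"""Breath-editing chain for gas-exchange recordings.

The chain mirrors standard practice for breath-by-breath VO2 analysis
and runs in a fixed order:

1. :func:`drop_flagged` — remove breaths annotated as coughs / signal
   interruptions;
2. :func:`sd3_filter` — a single-pass +-3 SD retention rule on VO2;
3. :func:`moving_average` — a centered 3-breath moving average;
4. :func:`time_bin` — a 10-s temporal average anchored at each phase
   start.

The retention rule supports two modes.  ``mode="band"`` is the literal
reading: within each scope (phase by default) the VO2 mean and SD are
computed once and breaths outside mean +- k*SD are removed.  The
default ``mode="local"`` is trend-aware: because exercise and recovery
phases contain an order-of-magnitude VO2 transient, a phase-wide band
either deletes the transient onset or is too wide to catch anything,
so deviations are instead measured from a 5-breath running median
(which reproduces any monotone trend exactly) and compared against
k times the breath-scatter scale, estimated as the SD of
linear-interpolation residuals pooled over the session.  A breath is
always removed whole (all channels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gasio import PHASES, BreathSeries, slice_phase

__all__ = [
    "CleaningReport",
    "drop_flagged",
    "sd3_filter",
    "moving_average",
    "time_bin",
    "clean",
]

_SMOOTH_CHANNELS = ["vo2", "vco2", "ve", "fr", "vt", "hr"]


@dataclass
class CleaningReport:
    """Bookkeeping for the cleaning chain."""

    n_input: int
    n_artifact_removed: int = 0
    n_sd_removed: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_artifact_removed - self.n_sd_removed

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 1.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_artifact_removed": self.n_artifact_removed,
            "n_sd_removed": self.n_sd_removed,
            "n_retained": self.n_retained,
            "retained_fraction": self.retained_fraction,
        }


def drop_flagged(series: BreathSeries) -> tuple[BreathSeries, CleaningReport]:
    """Remove breaths whose artifact flag is set (coughs, dropouts)."""
    keep = ~series.df["artifact"].to_numpy(bool)
    report = CleaningReport(n_input=len(series),
                            n_artifact_removed=int((~keep).sum()))
    return series.replace_df(series.df[keep]), report


def _interp_residuals(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of each breath against the line through its neighbours."""
    n = len(x)
    if n < 2:
        return np.zeros(n)
    pred = np.empty(n)
    if n >= 3:
        w = (t[1:-1] - t[:-2]) / (t[2:] - t[:-2])
        pred[1:-1] = x[:-2] * (1.0 - w) + x[2:] * w
    pred[0] = x[1]
    pred[-1] = x[-2]
    return x - pred


def _running_median(x: np.ndarray, half_window: int = 2) -> np.ndarray:
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        out[i] = np.median(x[max(0, i - half_window):min(n, i + half_window + 1)])
    return out


def sd3_filter(series: BreathSeries, k: float = 3.0, scope: str = "phase",
               mode: str = "local") -> tuple[BreathSeries, CleaningReport]:
    """Single-pass +-k*SD retention rule on VO2.

    Parameters
    ----------
    k
        SD multiplier of the retention band (3 in standard practice).
    scope
        ``"phase"`` (default) applies the rule within each phase
        separately; ``"session"`` over all breaths at once.
    mode
        ``"band"``: literal mean +- k*SD membership within the scope.
        ``"local"`` (default): deviation from a 5-breath running median
        against k times the session breath-scatter scale (see module
        docstring).

    Scopes with fewer than 3 breaths, or with zero scatter, are left
    untouched.  The survivors are always a subset of the input and the
    statistics are computed once, on the input (no iteration).
    """
    if mode not in ("local", "band"):
        raise ValueError(f"unknown mode {mode!r}")
    if scope not in ("phase", "session"):
        raise ValueError(f"unknown scope {scope!r}")

    t = series.times
    x = series.channel("vo2")
    n = len(series)
    if scope == "phase":
        groups = []
        for phase in PHASES:
            lo, hi = series.marks.bounds(phase)
            groups.append(np.flatnonzero((t >= lo) & (t < hi)))
        claimed = np.concatenate(groups) if groups else np.array([], int)
        rest = np.setdiff1d(np.arange(n), claimed)
        if len(rest):  # breaths at/after recovery_end
            groups.append(rest)
    else:
        groups = [np.arange(n)]

    remove = np.zeros(n, bool)
    if mode == "local":
        # one scatter scale for the whole session, pooled across scopes
        res = [_interp_residuals(t[g], x[g]) for g in groups if len(g) >= 3]
        scale = (np.concatenate(res).std(ddof=1) if res else 0.0)
        if scale > 0:
            for g in groups:
                if len(g) < 3:
                    continue
                dev = x[g] - _running_median(x[g])
                remove[g[np.abs(dev) > k * scale]] = True
    else:
        for g in groups:
            if len(g) < 3:
                continue
            mu, sd = x[g].mean(), x[g].std(ddof=1)
            if sd == 0:
                continue
            remove[g[np.abs(x[g] - mu) > k * sd]] = True

    report = CleaningReport(n_input=n, n_sd_removed=int(remove.sum()))
    return series.replace_df(series.df[~remove]), report


def moving_average(series: BreathSeries,
                   window_breaths: int = 3) -> BreathSeries:
    """Centered moving average of the numeric channels, per phase.

    The window shrinks at phase edges so the output has the same length
    (and the same breath times) as the input.  Averaging is kept within
    phases so the exercise on-transient is not smeared into baseline.
    """
    if window_breaths < 1:
        raise ValueError("window_breaths must be >= 1")
    if len(series) == 0:
        return series
    df = series.df.copy()
    t = series.times
    half = (window_breaths - 1) // 2
    extra = (window_breaths - 1) % 2  # even windows take the extra breath ahead
    for phase in PHASES:
        lo, hi = series.marks.bounds(phase)
        idx = np.flatnonzero((t >= lo) & (t < hi))
        if len(idx) == 0:
            continue
        block = df.iloc[idx][_SMOOTH_CHANNELS].to_numpy(float)
        sm = np.empty_like(block)
        m = len(idx)
        for i in range(m):
            a, b = max(0, i - half), min(m, i + half + extra + 1)
            sm[i] = block[a:b].mean(axis=0)
        df.iloc[idx, [df.columns.get_loc(c) for c in _SMOOTH_CHANNELS]] = sm
    return series.replace_df(df)


def time_bin(series: BreathSeries, width_s: float = 10.0) -> BreathSeries:
    """Temporal average into half-open bins anchored at each phase start.

    Each non-empty bin emits one sample at the bin midpoint whose
    channels are the means of the member breaths; empty bins are
    omitted.  A bin is flagged as artifact only if all members are.
    """
    if width_s <= 0:
        raise ValueError("width_s must be > 0")
    t = series.times
    rows = []
    for phase in PHASES:
        lo, hi = series.marks.bounds(phase)
        idx = np.flatnonzero((t >= lo) & (t < hi))
        if len(idx) == 0:
            continue
        sub = series.df.iloc[idx]
        bins = np.floor((sub["time"].to_numpy(float) - lo) / width_s).astype(int)
        for b in np.unique(bins):
            members = sub[bins == b]
            mid = lo + (b + 0.5) * width_s
            row = {"time": min(mid, np.nextafter(hi, lo))}
            for c in _SMOOTH_CHANNELS:
                row[c] = float(members[c].mean())
            row["artifact"] = bool(members["artifact"].all()) and len(members) > 0
            rows.append(row)
    out = pd.DataFrame(rows, columns=["time", *_SMOOTH_CHANNELS, "artifact"])
    return series.replace_df(out)


def clean(series: BreathSeries, k: float = 3.0, sd_scope: str = "phase",
          sd_mode: str = "local", ma_breaths: int = 3,
          bin_s: float | None = 10.0) -> tuple[BreathSeries, CleaningReport]:
    """Run the full editing chain; ``bin_s=None`` skips temporal binning."""
    n_input = len(series)
    series, rep_flag = drop_flagged(series)
    series, rep_sd = sd3_filter(series, k=k, scope=sd_scope, mode=sd_mode)
    series = moving_average(series, window_breaths=ma_breaths)
    if bin_s is not None:
        series = time_bin(series, width_s=bin_s)
    report = CleaningReport(n_input=n_input,
                            n_artifact_removed=rep_flag.n_artifact_removed,
                            n_sd_removed=rep_sd.n_sd_removed)
    return series, report
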