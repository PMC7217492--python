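"""Wheel-running actigraphy statistics.

Locomotor activity binned at a few minutes is summarized by the
Sokolove–Bushell chi-square periodogram (free-running period), the
non-parametric circadian rhythm analysis (NPCRA) statistics IV and IS,
daily activity onsets and the phase angle of entrainment to the light
cycle.

Intra-daily variability (IV) measures fragmentation, the frequency of
activity-rest transitions within a day: a sine wave scores ~0, i.i.d.
Gaussian noise scores ~2. Inter-daily stability (IS) measures day-to-day
pattern matching: 1 for an exactly repeating daily profile, ~0 for noise.
Both are computed on hourly-rebinned data by convention (pass
``bin_minutes=None`` to evaluate at native resolution) and are invariant
to affine transforms of the counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

__all__ = ["ActivityRecord", "NpcraResult", "PeriodogramResult",
           "chi_square_periodogram", "intradaily_variability",
           "interdaily_stability", "activity_onset", "phase_angle"]


@dataclass
class ActivityRecord:
    """Binned locomotor counts.

    counts : per-bin activity counts (non-negative).
    bin_minutes : bin width; must divide 24 h evenly.
    start_clock_time : clock hour of the first bin (default 0).
    lights_on : clock hour of lights-on, if entrained (optional).
    """

    counts: np.ndarray
    bin_minutes: float
    start_clock_time: float = 0.0
    lights_on: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (24 * 60) % self.bin_minutes != 0:
            raise ValueError("bin width must divide 24 hours evenly")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bins_per_day(self) -> int:
        return int(round(24 * 60 / self.bin_minutes))

    @property
    def n_days(self) -> float:
        return self.counts.size / self.bins_per_day


@dataclass
class NpcraResult:
    IV: float
    IS: float


@dataclass
class PeriodogramResult:
    candidate_periods: np.ndarray
    Qp: np.ndarray
    threshold: np.ndarray
    best_period: float
    significant: bool


def _rebin(record: ActivityRecord, bin_minutes: float | None) -> np.ndarray:
    if bin_minutes is None or bin_minutes == record.bin_minutes:
        return record.counts
    ratio = bin_minutes / record.bin_minutes
    if ratio < 1 or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("target bin must be an integer multiple of the native bin")
    r = int(round(ratio))
    n = (record.counts.size // r) * r
    return record.counts[:n].reshape(-1, r).sum(axis=1)


def intradaily_variability(record: ActivityRecord, bin_minutes: float | None = 60) -> float:
    """IV = n * sum (x_i - x_{i-1})^2 / ((n-1) * sum (x_i - xbar)^2)."""
    if record.n_days < 2:
        raise ValueError("need at least 2 days of data")
    x = _rebin(record, bin_minutes)
    n = x.size
    dev = x - x.mean()
    ss = float(np.sum(dev ** 2))
    if ss == 0:
        raise ValueError("degenerate input: record has zero variance")
    return n * float(np.sum(np.diff(x) ** 2)) / ((n - 1) * ss)


def interdaily_stability(record: ActivityRecord, bin_minutes: float | None = 60) -> float:
    """IS = n * sum_h (xbar_h - xbar)^2 / (p * sum_i (x_i - xbar)^2).

    xbar_h are the per-time-of-day means across whole days and p the
    number of bins per day.
    """
    x = _rebin(record, bin_minutes)
    bm = record.bin_minutes if bin_minutes is None else bin_minutes
    p = int(round(24 * 60 / bm))
    d = x.size // p
    if d < 2:
        raise ValueError("need at least 2 whole days of data")
    x = x[: d * p]
    n = x.size
    dev = x - x.mean()
    ss = float(np.sum(dev ** 2))
    if ss == 0:
        raise ValueError("degenerate input: record has zero variance")
    hourly = x.reshape(d, p).mean(axis=0)
    return n * float(np.sum((hourly - x.mean()) ** 2)) / (p * ss)


def chi_square_periodogram(record: ActivityRecord,
                           period_range: tuple[float, float] = (20.0, 28.0),
                           alpha: float = 0.001) -> PeriodogramResult:
    """Sokolove–Bushell Qp over candidate periods (bin-width steps).

    With r = N/K rows folded at period P,
    Qp(P) = r * sum_h (M_h - M)^2 / Var(all counts), which is chi-square
    with K-1 degrees of freedom under the null; the significance line is
    the (1 - alpha) quantile.
    """
    if record.n_days < 7:
        raise ValueError("need at least 7 days of data")
    x = record.counts
    n_total = x.size
    bin_h = record.bin_minutes / 60.0
    k_lo = int(np.ceil(period_range[0] / bin_h))
    k_hi = int(np.floor(period_range[1] / bin_h))
    if k_lo > k_hi or k_hi * bin_h > n_total * bin_h / 2:
        raise ValueError("period range outside the data support")
    grand = x.mean()
    var_all = float(np.mean((x - grand) ** 2))
    if var_all == 0:
        raise ValueError("degenerate input: record has zero variance")
    periods, qps, thresholds = [], [], []
    idx = np.arange(n_total)
    for K in range(k_lo, k_hi + 1):
        col = idx % K
        sums = np.bincount(col, weights=x, minlength=K)
        cnts = np.bincount(col, minlength=K)
        means = sums / cnts
        qp = (n_total / K) * float(np.sum((means - grand) ** 2)) / var_all
        periods.append(K * bin_h)
        qps.append(qp)
        thresholds.append(chi2.ppf(1 - alpha, K - 1))
    periods = np.asarray(periods)
    qps = np.asarray(qps)
    thresholds = np.asarray(thresholds)
    above = qps > thresholds
    if above.any():
        best = periods[above][np.argmax(qps[above])]
        significant = True
    else:
        best = periods[np.argmax(qps)]
        significant = False
    return PeriodogramResult(periods, qps, thresholds, float(best), significant)


def _smooth_circular(x: np.ndarray, w: int) -> np.ndarray:
    # trailing circular mean over [j-w+1, j]: never advances a rise
    if w <= 1:
        return x
    out = x.astype(float).copy()
    for k in range(1, w):
        out += np.roll(x, k)
    return out / w


def activity_onset(record: ActivityRecord, threshold_frac: float = 0.2,
                   dwell_bins: int = 3, smooth_bins: int = 3) -> np.ndarray:
    """Per-day activity onset clock time (hours); NaN for inactive days.

    Onset is the first upward threshold crossing of the smoothed daily
    profile: the first bin (treating each day circularly, so bouts that
    span midnight are handled) that follows a sub-threshold bin and stays
    above ``threshold_frac`` of the day's maximum for ``dwell_bins``
    consecutive bins. A day with no activity, or with no rest-activity
    transition at all, is flagged NaN rather than fabricated.
    """
    p = record.bins_per_day
    d = record.counts.size // p
    if d < 1:
        raise ValueError("need at least one whole day")
    days = record.counts[: d * p].reshape(d, p)
    onsets = np.full(d, np.nan)
    for i, day in enumerate(days):
        sm = _smooth_circular(day, smooth_bins)
        peak = sm.max()
        if peak <= 0:
            continue
        above = sm >= threshold_frac * peak
        for j in range(p):
            window = above[(j + np.arange(dwell_bins)) % p]
            if not above[j - 1] and window.all():
                onsets[i] = (record.start_clock_time + j * record.bin_minutes / 60.0) % 24.0
                break
    return onsets


def _circular_mean_hours(hours: np.ndarray) -> float:
    ang = 2 * np.pi * hours / 24.0
    return float(np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang))) / (2 * np.pi) * 24.0) % 24.0


def phase_angle(record: ActivityRecord, min_days: int = 10, **onset_kwargs) -> float:
    """Hours from lights-on to the (circular) mean activity onset."""
    if record.lights_on is None:
        raise ValueError("record has no light schedule (lights_on missing)")
    onsets = activity_onset(record, **onset_kwargs)
    onsets = onsets[np.isfinite(onsets)]
    if onsets.size < min_days:
        raise ValueError(f"need onsets from at least {min_days} days, got {onsets.size}")
    rel = (onsets - record.lights_on) % 24.0
    return _circular_mean_hours(rel)
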