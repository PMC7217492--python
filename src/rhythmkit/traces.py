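"""Pre-processing of fluorescence / bioluminescence time series.

Traces are per-cell or per-ROI intensity courses sampled in hours. The
operations here mirror the standard imaging-analysis chain: ROI background
subtraction, stationary-wavelet (à trous) band-pass filtering, forward
filling of tracking gaps, moving-average detrending, min–max normalization
and baseline-to-peak amplitude measurement. All operations preserve the
time grid and never reorder points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import correlate1d

__all__ = [
    "TimeSeriesTrace",
    "subtract_background",
    "atrous_decompose",
    "atrous_bandpass",
    "forward_fill",
    "detrend_moving_average",
    "normalize_minmax",
    "amplitude_percent",
]

#: B3-spline scaling kernel of the à-trous (starlet) transform.
_B3_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class TimeSeriesTrace:
    """One ROI/cell intensity course.

    Parameters
    ----------
    times : array of float
        Sample times in hours, strictly increasing.
    values : array of float
        Intensity in arbitrary units. May contain NaN where ``mask`` is
        False.
    label : str
        Free-text annotation, e.g. the processing history.
    mask : array of bool, optional
        Per-point validity. Defaults to ``isfinite(values)``.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask must match values in shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("values must be finite where mask is valid")

    def __len__(self) -> int:
        return self.times.size

    @property
    def sampling_interval(self) -> float:
        """Median sampling interval in hours."""
        return float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        dt = np.diff(self.times)
        return bool(np.allclose(dt, dt[0], rtol=rtol, atol=1e-12))

    def with_values(self, values: np.ndarray, label_suffix: str = "") -> "TimeSeriesTrace":
        label = self.label + label_suffix if label_suffix else self.label
        return replace(self, values=np.asarray(values, dtype=float),
                       label=label, mask=np.isfinite(values) & self.mask)


def _check_common_grid(a: TimeSeriesTrace, b: TimeSeriesTrace) -> None:
    if len(a) != len(b) or not np.allclose(a.times, b.times, rtol=1e-9, atol=1e-9):
        raise ValueError("traces are not on a common time grid")


def subtract_background(trace: TimeSeriesTrace, background: TimeSeriesTrace) -> TimeSeriesTrace:
    """Subtract a background ROI trace point by point (label gains ``BGS``)."""
    _check_common_grid(trace, background)
    return trace.with_values(trace.values - background.values, " BGS")


def _atrous_smooth(c: np.ndarray, level: int) -> np.ndarray:
    """One à-trous smoothing step: B3 kernel dilated by 2**level, mirror edges."""
    step = 2 ** level
    dilated = np.zeros(4 * step + 1)
    dilated[::step] = _B3_KERNEL
    return correlate1d(c, dilated, mode="mirror")


def atrous_decompose(values: np.ndarray, n_scales: int):
    """Undecimated B3-spline wavelet decomposition.

    Returns ``(details, smooth)`` where ``details`` is a list of
    ``n_scales`` arrays and ``sum(details) + smooth`` reconstructs the
    input exactly (the transform is a telescoping sum).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 ** n_scales:
        raise ValueError(
            f"need at least 2**{n_scales} points for {n_scales} scales, got {values.size}"
        )
    details = []
    c = values
    for j in range(n_scales):
        c_next = _atrous_smooth(c, j)
        details.append(c - c_next)
        c = c_next
    return details, c


def _default_scales(dt_hours: float, n_points: int,
                    band: tuple[float, float] = (2.0, 16.0)) -> list[int]:
    # detail level j carries structure on time scales ~ dt*2**j .. dt*2**(j+1)
    max_level = int(np.floor(np.log2(n_points)))
    keep = [j for j in range(max_level)
            if band[0] <= dt_hours * 2 ** (j + 1) and dt_hours * 2 ** j <= band[1]]
    return keep or [max(max_level - 1, 0)]


def atrous_bandpass(trace: TimeSeriesTrace, keep_scales=None,
                    n_scales: int | None = None,
                    include_smooth: bool = False) -> TimeSeriesTrace:
    """Band-pass filter by summing selected à-trous detail scales.

    With ``keep_scales=None`` the retained scales are those spanning
    roughly 2–16 h structure at the trace's sampling rate, which removes
    both high-frequency noise (finest scale) and the stationary
    background (final smooth). Keeping every scale plus the smooth
    reproduces the input to machine precision.
    """
    if keep_scales is None:
        keep_scales = _default_scales(trace.sampling_interval, len(trace))
    keep_scales = sorted(set(int(k) for k in keep_scales))
    if n_scales is None:
        n_scales = max(keep_scales) + 1
    if min(keep_scales) < 0 or max(keep_scales) >= n_scales:
        raise ValueError("keep_scales must lie in [0, n_scales)")
    details, smooth = atrous_decompose(trace.values, n_scales)
    out = np.zeros_like(trace.values)
    for j in keep_scales:
        out += details[j]
    if include_smooth:
        out += smooth
    return trace.with_values(out, " ATROUS")


def forward_fill(trace: TimeSeriesTrace) -> TimeSeriesTrace:
    """Replace invalid points with the last valid value (mask updated)."""
    if not trace.mask[0]:
        raise ValueError("first point is invalid; forward fill is undefined")
    values = trace.values.copy()
    idx = np.where(trace.mask, np.arange(len(trace)), 0)
    np.maximum.accumulate(idx, out=idx)
    values = values[idx]
    return TimeSeriesTrace(trace.times, values, trace.label + " FILLED",
                           mask=np.ones(len(trace), dtype=bool))


def detrend_moving_average(trace: TimeSeriesTrace, window: float = 24.0) -> TimeSeriesTrace:
    """Subtract a centred moving mean of ``window`` hours.

    Edges use truncated (shrinking) windows so the trace keeps its full
    length; a pure sinusoid whose period equals the window is preserved in
    the interior because its moving mean over a full period vanishes.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if trace.duration < window:
        raise ValueError("trace shorter than the detrending window")
    t, v = trace.times, trace.values
    half = window / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    # trapezoidal end-weighting: exact cancellation of a full-period
    # sinusoid and of symmetric linear trends in the interior
    n = hi - lo
    sums = csum[hi] - csum[lo] - 0.5 * (v[lo] + v[hi - 1])
    mean = np.where(n > 1, sums / np.maximum(n - 1, 1), v)
    return trace.with_values(v - mean, " DETR")


def normalize_minmax(trace: TimeSeriesTrace) -> TimeSeriesTrace:
    """Map values affinely onto [0, 1] (min -> 0, max -> 1)."""
    valid = trace.values[trace.mask]
    vmin, vmax = float(np.min(valid)), float(np.max(valid))
    if vmax <= vmin:
        raise ValueError("degenerate input: trace is constant, cannot min-max normalize")
    return trace.with_values((trace.values - vmin) / (vmax - vmin), " NORM")


def amplitude_percent(trace: TimeSeriesTrace, baseline_method: str | float = "cosine") -> float:
    """Baseline-to-peak amplitude as a percent of baseline.

    ``baseline_method`` may be ``"cosine"`` (mesor of a damped-cosine fit,
    falling back to the mean if the fit fails), ``"mean"``, or an explicit
    numeric baseline.
    """
    peak = float(np.max(trace.values[trace.mask]))
    if isinstance(baseline_method, (int, float)):
        baseline = float(baseline_method)
    elif baseline_method == "mean":
        baseline = float(np.mean(trace.values[trace.mask]))
    elif baseline_method == "cosine":
        from .rhythmicity import fit_damped_cosine  # deferred: avoids import cycle
        try:
            fit = fit_damped_cosine(trace)
            baseline = fit.mesor if fit.converged else float("nan")
        except Exception:
            baseline = float("nan")
        if not np.isfinite(baseline) or baseline <= 0:
            baseline = float(np.mean(trace.values[trace.mask]))
    else:
        raise ValueError(f"unknown baseline_method {baseline_method!r}")
    if baseline <= 0:
        raise ValueError("baseline estimate must be positive")
    return 100.0 * (peak - baseline) / baseline
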