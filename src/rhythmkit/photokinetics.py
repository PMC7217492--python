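"""FRAP and FLIP photobleaching kinetics.

FRAP (fluorescence recovery after photobleaching): a nuclear spot is
bleached and the recovery of fluorescence reports molecular mobility. The
recovery is double-normalized against a background ROI and an unbleached
reference ROI (correcting for acquisition bleaching), scaled so the
pre-bleach mean is 1, and fit to a multi-exponential recovery

    F(t) = floor + sum_i A_i * (1 - exp(-k_i * t)),   t >= 0 (bleach at 0)

The mobile fractions are f_i = A_i / (1 - floor) and the remainder,
1 - sum f_i, is the immobile fraction (indistinguishable from very slow
species within a finite record). Half-times are ln2/k_i.

FLIP (fluorescence loss in photobleaching): the cytoplasm is repeatedly
bleached and the loss of nuclear signal, normalized to unbleached
neighbour nuclei, reports nucleus-to-cytoplasm shuttling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize

from .traces import TimeSeriesTrace

__all__ = ["FrapCurve", "FrapFit", "FlipResult", "normalize_frap", "fit_frap",
           "select_frap_model", "flip_loss"]

LN2 = float(np.log(2.0))


@dataclass
class FrapCurve:
    """A photobleaching recovery record; time 0 is the bleach point."""

    times: np.ndarray  # seconds; pre-bleach frames have t < 0
    raw: np.ndarray
    background: np.ndarray
    reference: np.ndarray
    n_prebleach: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("raw", "background", "reference"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class FrapFit:
    f_fast: float
    f_slow: float
    f_immobile: float
    t_half_fast: float | None
    t_half_slow: float | None
    floor: float
    amplitudes: tuple
    rates: tuple
    model_order: int
    rss: float
    converged: bool


@dataclass
class FlipResult:
    percent_loss: float
    normalized: TimeSeriesTrace
    control_count: int


def normalize_frap(curve: FrapCurve) -> FrapCurve:
    """Double normalization: (raw-bg)/(ref-bg), then pre-bleach mean -> 1.

    The returned curve has zero background and unit reference, so the
    operation is idempotent.
    """
    denom = curve.reference - curve.background
    if np.any(denom <= 0):
        raise ValueError("reference must exceed background at every frame")
    corrected = (curve.raw - curve.background) / denom
    pre = corrected[: curve.n_prebleach]
    scale = float(np.mean(pre))
    if scale <= 0:
        raise ValueError("non-positive pre-bleach mean")
    norm = corrected / scale
    return FrapCurve(curve.times, norm, np.zeros_like(norm), np.ones_like(norm),
                     curve.n_prebleach)


def _recovery(t, floor, amps, rates):
    out = np.full_like(t, floor, dtype=float)
    for a, k in zip(amps, rates):
        out += a * (1.0 - np.exp(-k * t))
    return out


def _fit_order(t: np.ndarray, y: np.ndarray, order: int):
    span = t[-1] - t[0]
    floor0 = float(y[0])
    total = max(float(np.mean(y[-max(3, len(y) // 20):])) - floor0, 1e-6)
    params = Parameters()
    params.add("floor", value=floor0, min=0.0, max=1.0)
    k0s = np.geomspace(5.0 / span, 0.05 / span, order) if order > 1 else [2.0 / span]
    for i in range(order):
        params.add(f"a{i}", value=total / order, min=0.0)
        params.add(f"k{i}", value=k0s[i], min=1e-12)

    def resid(p):
        amps = [p[f"a{i}"].value for i in range(order)]
        rates = [p[f"k{i}"].value for i in range(order)]
        return _recovery(t, p["floor"].value, amps, rates) - y

    res = minimize(resid, params)
    amps = [float(res.params[f"a{i}"].value) for i in range(order)]
    rates = [float(res.params[f"k{i}"].value) for i in range(order)]
    floor = float(res.params["floor"].value)
    rss = float(np.sum(res.residual ** 2))
    return floor, amps, rates, rss, bool(res.success)


def fit_frap(curve: FrapCurve, model_order: int = 2) -> FrapFit:
    """Fit the multi-exponential recovery to a normalized FRAP curve.

    Components slower than 1/(2 * record length) cannot be separated from
    the immobile pool within the record and are folded into it. Components
    are reported fast first; fractions sum to 1.
    """
    post = curve.times >= 0
    t = curve.times[post]
    y = curve.raw[post]
    if t.size < 20:
        raise ValueError("need at least 20 post-bleach points")
    floor, amps, rates, rss, ok = _fit_order(t, y, model_order)
    span = t[-1] - t[0]
    k_min = 1.0 / (2.0 * span)
    kept = [(a, k) for a, k in zip(amps, rates) if k >= k_min and a > 0]
    kept.sort(key=lambda ak: (-ak[1], -ak[0]))  # fast first, ties by amplitude
    depth = 1.0 - floor
    if depth <= 0:
        fracs = [0.0 for _ in kept]
    else:
        fracs = [a / depth for a, _ in kept]
    f_immobile = 1.0 - sum(fracs)
    f_fast = fracs[0] if len(fracs) >= 1 else 0.0
    f_slow = fracs[1] if len(fracs) >= 2 else 0.0
    return FrapFit(
        f_fast=f_fast,
        f_slow=f_slow,
        f_immobile=f_immobile,
        t_half_fast=LN2 / kept[0][1] if len(kept) >= 1 else None,
        t_half_slow=LN2 / kept[1][1] if len(kept) >= 2 else None,
        floor=floor,
        amplitudes=tuple(a for a, _ in kept),
        rates=tuple(k for _, k in kept),
        model_order=model_order,
        rss=rss,
        converged=ok,
    )


def _aicc(n: int, rss: float, n_params: int) -> float:
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * n_params
    denom = n - n_params - 1
    return aic + (2 * n_params * (n_params + 1) / denom if denom > 0 else np.inf)


def select_frap_model(curve: FrapCurve, orders=(1, 2)) -> int:
    """Pick the recovery model order by small-sample AIC (AICc)."""
    post = curve.times >= 0
    t = curve.times[post]
    y = curve.raw[post]
    best_order, best_aicc = orders[0], np.inf
    for order in orders:
        _, _, _, rss, _ = _fit_order(t, y, order)
        a = _aicc(t.size, rss, 1 + 2 * order)
        if a < best_aicc:
            best_order, best_aicc = order, a
    return best_order


def flip_loss(nuclear: TimeSeriesTrace, controls, background: TimeSeriesTrace,
              n_prebleach: int = 5, plateau_frac: float = 0.1) -> FlipResult:
    """Percent loss of nuclear signal during repeated cytoplasmic bleaching.

    The nuclear trace is background-subtracted, divided by the mean of the
    (background-subtracted) unbleached neighbour nuclei, and scaled so the
    pre-bleach mean is 100%. ``percent_loss`` is 100 minus the mean of the
    final ``plateau_frac`` of the record.
    """
    if not controls:
        raise ValueError("need at least one unbleached control nucleus")
    ctrl = np.mean([c.values - background.values for c in controls], axis=0)
    if np.any(ctrl <= 0):
        raise ValueError("control signal must exceed background")
    norm = (nuclear.values - background.values) / ctrl
    pre = float(np.mean(norm[:n_prebleach]))
    norm_pct = 100.0 * norm / pre
    n_tail = max(1, int(round(plateau_frac * len(norm_pct))))
    loss = 100.0 - float(np.mean(norm_pct[-n_tail:]))
    out = TimeSeriesTrace(nuclear.times, norm_pct, nuclear.label + " FLIP-NORM")
    return FlipResult(percent_loss=loss, normalized=out, control_count=len(controls))
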