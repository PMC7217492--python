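"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here with the
true parameters recorded alongside, so parameter-recovery and
classification tests run with no external data. Defaults emulate the
study conditions: low-amplitude (~5% of baseline) damped circadian
oscillations on a high baseline with bleaching drift, cohorts mixing
circadian (15-30 h), ultradian (<15 h) and arrhythmic cells in roughly
45/10/45 proportions, one-phase exponential decays, two-component-plus-
immobile FRAP recoveries, one-component triplet FCS autocorrelations,
periodic activity records and lambda stacks mixed from known spectra.

Noise models: additive Gaussian for traces and FRAP curves, multiplicative
Gaussian on G-1 for FCS curves (shot-noise-like scaling). Identical
``SimConfig`` (same seed and parameters) yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .actigraphy import ActivityRecord
from .coloc import SpectraMatrix
from .fcs import BeamGeometry, FcsCurve, fcs_model
from .photokinetics import FrapCurve
from .traces import TimeSeriesTrace

__all__ = ["SimConfig", "gen_oscillatory_trace", "gen_cell_cohort", "gen_decay_course",
           "gen_frap_curve", "gen_fcs_curve", "gen_activity_record",
           "gen_lambda_stack", "gen_nuclear_mask"]


@dataclass
class SimConfig:
    """Shared simulation settings.

    sampling_interval / duration are in hours for trace-like generators and
    seconds for FRAP; noise_sd is a fraction of the baseline (traces) or of
    the signal term (FRAP, FCS). A fixed seed makes output bit-identical.
    """

    seed: int = 0
    sampling_interval: float = 0.5
    duration: float = 120.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.duration < 2 * self.sampling_interval:
            raise ValueError("duration must cover at least two samples")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def time_grid(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.sampling_interval)) + 1
        return np.arange(n) * self.sampling_interval


def gen_oscillatory_trace(baseline: float, amplitude_frac: float, period: float,
                          phase: float = 0.0, damping_rate: float = 0.0,
                          drift_slope: float = 0.0,
                          cfg: SimConfig = SimConfig(),
                          rng: np.random.Generator | None = None) -> TimeSeriesTrace:
    """Damped cosine oscillation on a high baseline with drift and noise.

    value(t) = baseline*(1 + amplitude_frac*exp(-damping_rate*t)
               *cos(2*pi*(t-phase)/period)) + drift_slope*t + noise,
    noise ~ N(0, (noise_sd*baseline)^2).
    """
    if baseline <= 0 or period <= 0:
        raise ValueError("baseline and period must be positive")
    t = cfg.time_grid()
    signal = baseline * (1.0 + amplitude_frac * np.exp(-damping_rate * t)
                         * np.cos(2 * np.pi * (t - phase) / period))
    signal = signal + drift_slope * t
    if cfg.noise_sd > 0:
        rng = cfg.rng() if rng is None else rng
        signal = signal + rng.normal(0.0, cfg.noise_sd * baseline, size=t.size)
    return TimeSeriesTrace(t, signal, label="oscillatory")


def _gen_arrhythmic(baseline: float, cfg: SimConfig, rng: np.random.Generator,
                    rho: float = 0.995, step_frac: float = 0.02) -> TimeSeriesTrace:
    """AR(1) random walk around the baseline with a reflecting floor at 0."""
    t = cfg.time_grid()
    x = np.empty(t.size)
    x[0] = 0.0
    eps = rng.normal(0.0, step_frac * baseline, size=t.size)
    for i in range(1, t.size):
        x[i] = rho * x[i - 1] + eps[i]
    values = baseline + x
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd * baseline, size=t.size)
    values = np.abs(values)  # reflecting floor at zero
    return TimeSeriesTrace(t, values, label="arrhythmic")


def gen_cell_cohort(n_circadian: int, n_ultradian: int, n_arrhythmic: int,
                    period_ranges: dict | None = None,
                    cfg: SimConfig = SimConfig(noise_sd=0.01),
                    baseline: float = 100.0, amplitude_frac: float = 0.05):
    """Mixed cohort of traces with per-trace ground truth.

    Circadian periods are drawn uniformly in 15-30 h, ultradian in 4-14 h
    (both overridable via ``period_ranges``); arrhythmic members are AR(1)
    random walks with no periodic component. Returns
    ``(traces, truth)`` where ``truth`` is a list of dicts aligned with the
    traces (every record carries its truth entry).
    """
    if min(n_circadian, n_ultradian, n_arrhythmic) < 0:
        raise ValueError("counts must be non-negative")
    total = n_circadian + n_ultradian + n_arrhythmic
    if total == 0:
        raise ValueError("empty cohort")
    ranges = {"circadian": (15.0, 30.0), "ultradian": (4.0, 14.0)}
    if period_ranges:
        ranges.update(period_ranges)
    rng = cfg.rng()
    traces, truth = [], []
    plan = (["circadian"] * n_circadian + ["ultradian"] * n_ultradian
            + ["arrhythmic"] * n_arrhythmic)
    for i, label in enumerate(plan):
        if label == "arrhythmic":
            tr = _gen_arrhythmic(baseline, cfg, rng)
            entry = {"label": label, "period_h": None, "amplitude_frac": None}
        else:
            lo, hi = ranges[label]
            period = float(rng.uniform(lo, hi))
            phase = float(rng.uniform(0, period))
            tr = gen_oscillatory_trace(baseline, amplitude_frac, period, phase,
                                       damping_rate=0.0, drift_slope=0.0,
                                       cfg=cfg, rng=rng)
            entry = {"label": label, "period_h": period, "amplitude_frac": amplitude_frac,
                     "phase_h": phase}
        tr.label = f"cell{i:04d} {label}"
        traces.append(tr)
        truth.append(entry)
    return traces, truth


def gen_decay_course(y0: float, plateau: float, k: float,
                     cfg: SimConfig = SimConfig(sampling_interval=0.1, duration=20.0)
                     ) -> TimeSeriesTrace:
    """One-phase decay Y = (Y0 - Plateau) exp(-K t) + Plateau with noise.

    Noise SD is ``cfg.noise_sd * Y0`` (additive Gaussian).
    """
    if not (y0 > plateau >= 0):
        raise ValueError("need Y0 > Plateau >= 0")
    if k <= 0:
        raise ValueError("decay rate K must be positive")
    t = cfg.time_grid()
    y = (y0 - plateau) * np.exp(-k * t) + plateau
    if cfg.noise_sd > 0:
        y = y + cfg.rng().normal(0.0, cfg.noise_sd * y0, size=t.size)
    return TimeSeriesTrace(t, y, label="decay")


def gen_frap_curve(floor: float, amp_fast: float, amp_slow: float,
                   k_fast: float, k_slow: float,
                   cfg: SimConfig = SimConfig(sampling_interval=0.5, duration=300.0),
                   n_prebleach: int = 10, background_level: float = 0.0,
                   reference_bleach_rate: float = 0.0) -> FrapCurve:
    """Two-component-plus-immobile FRAP recovery with reference channels.

    Post-bleach signal F(t) = floor + amp_fast*(1-exp(-k_fast*t)) +
    amp_slow*(1-exp(-k_slow*t)); ``n_prebleach`` pre-bleach frames sit at
    1.0. The unbleached reference decays at ``reference_bleach_rate``
    (per second) to emulate acquisition bleaching, and the same factor
    multiplies the bleached ROI. Times are seconds, 0 at the bleach point.
    """
    if not 0 <= floor < 1:
        raise ValueError("floor must be in [0, 1)")
    if amp_fast < 0 or amp_slow < 0:
        raise ValueError("amplitudes must be non-negative")
    if floor + amp_fast + amp_slow > 1 + 1e-12:
        raise ValueError("floor + amplitudes must not exceed 1")
    if (amp_fast > 0 and k_fast <= 0) or (amp_slow > 0 and k_slow <= 0):
        raise ValueError("recovery rates must be positive")
    dt = cfg.sampling_interval
    t_post = cfg.time_grid()
    t_pre = -dt * np.arange(n_prebleach, 0, -1)
    times = np.concatenate([t_pre, t_post])
    ideal = np.concatenate([
        np.ones(n_prebleach),
        floor + amp_fast * (1 - np.exp(-np.maximum(k_fast, 1e-300) * t_post))
        + amp_slow * (1 - np.exp(-np.maximum(k_slow, 1e-300) * t_post)),
    ])
    acq = np.exp(-reference_bleach_rate * (times - times[0]))
    raw = ideal * acq + background_level
    reference = acq + background_level
    background = np.full_like(times, background_level)
    if cfg.noise_sd > 0:
        raw = raw + cfg.rng().normal(0.0, cfg.noise_sd, size=times.size)
    return FrapCurve(times, raw, background, reference, n_prebleach)


def default_lag_grid(lag_min: float = 1e-6, lag_max: float = 10.0,
                     points_per_decade: int = 16) -> np.ndarray:
    """Quasi-log lag grid of a hardware correlator (1 us to 10 s)."""
    n_dec = np.log10(lag_max / lag_min)
    n = int(round(n_dec * points_per_decade)) + 1
    return np.geomspace(lag_min, lag_max, n)


def gen_fcs_curve(N: float, tauD: float, T: float = 0.0, tauT: float = 5e-6,
                  beam: BeamGeometry = BeamGeometry(),
                  cfg: SimConfig = SimConfig(),
                  lags: np.ndarray | None = None) -> FcsCurve:
    """Triplet-model autocorrelation on a log lag grid.

    Noise is multiplicative Gaussian on the fluctuation term:
    G_noisy - 1 = (G - 1) * (1 + noise_sd * N(0,1)).
    """
    if tauT >= tauD:
        raise ValueError("triplet time must be shorter than the diffusion time")
    if lags is None:
        lags = default_lag_grid()
    G = fcs_model(lags, N, tauD, T, tauT, beam)
    if cfg.noise_sd > 0:
        eps = cfg.rng().normal(0.0, cfg.noise_sd, size=lags.size)
        G = 1.0 + (G - 1.0) * (1.0 + eps)
    return FcsCurve(lags, G, run_count=1)


def gen_activity_record(pattern: str, period: float = 24.0, bin_minutes: float = 10.0,
                        days: int = 14, cfg: SimConfig = SimConfig(),
                        mean_count: float = 100.0, amplitude: float = 80.0,
                        lights_on: float | None = None) -> ActivityRecord:
    """Binned activity counts: ``sine``, ``square``, ``noise`` or
    ``repeat_template``.

    ``noise`` draws i.i.d. Gaussian counts around a large positive mean
    (IV/IS are affine-invariant, so statistics match those of pure
    Gaussian noise); ``square`` is active during the first half of each
    period; ``repeat_template`` tiles one random day exactly.
    Additional Gaussian noise of SD ``cfg.noise_sd * mean_count`` is added
    when ``cfg.noise_sd > 0``. Counts are clipped at zero.
    """
    if days < 2:
        raise ValueError("need at least 2 days")
    if (24 * 60) % bin_minutes != 0:
        raise ValueError("bin width must divide 24 hours evenly")
    per_day = int(round(24 * 60 / bin_minutes))
    n = per_day * days
    t_h = np.arange(n) * bin_minutes / 60.0
    rng = cfg.rng()
    if pattern == "sine":
        counts = mean_count + amplitude * np.sin(2 * np.pi * t_h / period)
    elif pattern == "square":
        counts = np.where((t_h % period) < period / 2, mean_count + amplitude,
                          max(mean_count - amplitude, 0.0)).astype(float)
    elif pattern == "noise":
        counts = mean_count + (amplitude / 8.0) * rng.standard_normal(n)
    elif pattern == "repeat_template":
        template = rng.uniform(0.0, mean_count + amplitude, size=per_day)
        counts = np.tile(template, days)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    if cfg.noise_sd > 0:
        counts = counts + rng.normal(0.0, cfg.noise_sd * mean_count, size=n)
    counts = np.clip(counts, 0.0, None)
    return ActivityRecord(counts, bin_minutes, start_clock_time=0.0, lights_on=lights_on)


def gen_lambda_stack(spectra: SpectraMatrix, abundance_maps: np.ndarray,
                     cfg: SimConfig = SimConfig()):
    """Lambda stack mixed from reference spectra and abundance maps.

    ``abundance_maps`` has shape (n_fluorophores, ny, nx); the stack is
    abundance x spectra (+ additive noise of SD ``noise_sd * max(stack)``).
    Returns ``(stack, truth_maps)``.
    """
    maps = np.asarray(abundance_maps, dtype=float)
    S = spectra.spectra
    if maps.ndim != 3 or maps.shape[0] != S.shape[0]:
        raise ValueError("abundance maps must be (n_fluorophores, ny, nx)")
    stack = np.einsum("fyx,fl->yxl", maps, S)
    if cfg.noise_sd > 0:
        stack = stack + cfg.rng().normal(0.0, cfg.noise_sd * stack.max(), size=stack.shape)
    return stack, maps.copy()


def gen_nuclear_mask(volume_fl: float, voxel_dims=(0.2, 0.2, 0.5),
                     cfg: SimConfig = SimConfig()):
    """Ellipsoidal binary voxel mask whose volume matches the target.

    Voxels are accumulated in order of physical distance from the mask
    centre, so the voxel-sum volume is within one voxel of ``volume_fl``.
    Returns ``(mask, truth)`` with truth holding the realized volume.
    """
    voxel_dims = np.asarray(voxel_dims, dtype=float)
    voxel_vol = float(np.prod(voxel_dims))
    if volume_fl <= 0:
        raise ValueError("target volume must be positive")
    if voxel_vol > volume_fl * (1 + 1e-9):
        raise ValueError("voxel larger than the target volume")
    n_vox = int(round(volume_fl / voxel_vol))
    radius = (3.0 * volume_fl / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = np.ceil(1.5 * radius / voxel_dims).astype(int) + 1
    grids = np.meshgrid(*[np.arange(-h, h + 1) * d for h, d in zip(half, voxel_dims)],
                        indexing="ij")
    dist = np.sqrt(sum(g ** 2 for g in grids))
    order = np.argsort(dist, axis=None, kind="stable")
    mask = np.zeros(dist.shape, dtype=bool)
    mask.flat[order[:n_vox]] = True
    truth = {"volume_fl": n_vox * voxel_vol, "target_fl": volume_fl,
             "voxel_dims": tuple(voxel_dims)}
    return mask, truth
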