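# Methods notes

This note records the models implemented, the defaults chosen where the
design was genuinely open, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer would want to know.

## Trace model and pre-processing

A per-cell fluorescence trace is modelled as

    value(t) = baseline · (1 + a · e^(−d·t) · cos(2π(t − φ)/P)) + s·t + ε,

i.e. a low-amplitude damped cosine riding on a high baseline, with a
linear bleaching/drift term and additive Gaussian noise ε ~ N(0, (σ·baseline)²).
Amplitude fraction `a` defaults to ~0.05 in cohort generation, matching
the few-percent baseline-relative oscillations typical of a constitutively
expressed clock protein (in contrast to reporters such as PER2::Luc whose
signal collapses at the nadir). Noise σ defaults to 0.01 of baseline; real
recordings do not come with a stated noise figure, so this is a package
choice exposed as a parameter.

- **À-trous band-pass.** Undecimated wavelet transform with the B3-spline
  kernel (1,4,6,4,1)/16 and mirror boundary; the detail scales plus the
  final smooth reconstruct the input exactly (a telescoping sum), which is
  asserted at ≤1e−10. Retained scales default to those spanning roughly
  2–16 h structure at the trace's sampling rate: fine scales carry
  shot/readout noise, the residual smooth carries the stationary
  background. The retained band is a tunable because no single choice is
  right for every sampling rate.
- **Moving-average detrend.** Centred time-window mean with truncated
  (shrinking) windows at the edges so traces keep full length. End points
  of each window are half-weighted (trapezoidal rule), which makes the
  mean of a full-period sinusoid cancel exactly in the interior rather
  than leaving an O(1/window) residue, and keeps symmetric linear trends
  exactly removed.
- **Amplitude percent.** 100·(peak − baseline)/baseline. "Baseline" is not
  uniquely defined for an oscillating trace; the default is the mesor of a
  damped-cosine fit, falling back to the trace mean when the fit fails or
  is non-positive; an explicit numeric baseline can be passed.

## Rhythmicity

Dominant period comes from the one-sided FFT periodogram of the
forward-filled, detrended, mean-subtracted trace. Two numerical points:

- The FFT is zero-padded (8× by default) and the peak refined, first
  parabolically on the padded grid and then by a time-domain cosine
  least-squares fit within ±5% of the spectral peak. The time-domain step
  matters: the raw spectral peak is biased by windowing and by
  interference with the negative-frequency mirror, which at periods
  approaching the record length (~30 h in a 120 h recording) displaces
  the peak by ~1% — enough to tip a boundary period across a class
  boundary.
- **Detrending before classification is linear, not moving-average.** A
  24 h moving-average detrend has transfer gain (1 − sinc(π·24/P))² that
  concentrates residual red-noise power of arrhythmic cells almost exactly
  at the 30 h boundary bin, systematically mislabelling random-walk cells
  as circadian. A least-squares line removes bleaching drift while
  preserving the >30 h band needed to call a cell arrhythmic. The
  moving-average variant remains available (`detrend="ma24"`).

Classification bins the refined dominant period: circadian within
[15, 30] h (closed interval, applied with a 1e−3 relative tolerance so an
exact-boundary period is not tipped out by round-off), ultradian below,
arrhythmic above — "arrhythmic" meaning the record is too short to
establish a longer rhythm, not proof of none. No peak-significance test
enters the three-way call; the classification follows the frequency-binning
convention and is invariant to affine intensity transforms.

The damped-cosine fit (`mesor + A·e^(−λt)·cos(2π(t−φ)/P)`) is initialized
with the spectral period, a quadrature-projection phase, and amplitude
√2·SD; RAE is SE(A)/A from the fit covariance. This is a surrogate for
bootstrap-based amplitude-error measures in dedicated rhythm software;
equivalence to any particular package is not claimed.

`phase_to_ct` maps a fluorescence peak to circadian time via
CT = (12 + 24·((Δ mod P)/P)) mod 24 with Δ the delay after the PER2
reporter peak (defined as CT12).

## Decay kinetics

One-phase decay fits are initialized with Plateau = min(Y), Y0 = max(Y)
and K from a log-linear regression of Y − Plateau; K is bounded positive
and half-life SE follows by the delta method (SE(t½) = ln2·SE(K)/K²). A
fit is flagged **extrapolated** when more than 10% of the fitted decaying
span remains at the last sample (e^(−K·T) > 0.1), i.e. the half-life is
read off the best-fit curve rather than an observed half-descent — the
situation for a ~31 h half-life observed over 70 h. mRNA fits constrain
Plateau = 0 by default (relative expression decays toward zero once
transcription stops); the constraint is toggleable. ΔΔCt normalization
uses the mean Ct of two reference genes and the time-0 sample, so the
returned series equals 1 at baseline by construction.

## FRAP / FLIP

The recovery is parameterized as exponential approach components; this is
the standard surrogate for vendor "passive diffusion" model families,
whose exact functional forms are proprietary. Half-times are reported as
ln2/k. Because an immobile pool cannot be distinguished from very slow
exchange within a finite record, any fitted component slower than
1/(2·record length) is folded into the immobile fraction. Components are
ordered fast-first with ties broken by amplitude; fractions are defined
against the bleach depth (1 − floor) and sum to 1 by construction. Model
order is chosen by AICc over orders {1, 2}. FLIP loss is quantified after
background subtraction and division by the mean of unbleached neighbour
nuclei (correcting the gradual whole-field bleaching that the long bleach
protocol causes), with the pre-bleach mean scaled to 100% and the plateau
taken as the mean of the final 10% of frames.

## FCS

The model is the standard one-component 3D-Gaussian-volume triplet
formulation (see README for the equation); the effective volume is
V_eff = π^{3/2}·ω₀³·S. Calibration defaults ω₀ = 0.2 μm, S = 5 are
typical for a 514 nm confocal setup and are overridable — derived
concentrations are only as good as this calibration. Fit weights are
inversely proportional to the local lag density on the log grid (uniform
per decade), mimicking hardware-correlator binning; on the default
geometric grid they are constant. The fit-deviation (residual) series is
retained on every fit. The product-SD propagation formula
sqrt(x̄_A²·SD_B² + x̄_B²·SD_A²) is implemented with the square root — the
radicand has squared units — and is the first-order Taylor SD of a product
of independent quantities; a Monte-Carlo check against simulated lognormal
pairs is part of the test suite.

## Actigraphy

IV and IS use the van Someren-style formulas on hourly-rebinned data by
default (`bin_minutes=None` evaluates at native resolution, which is what
makes a 6-min-sampled noiseless sine score IV ≈ 7e−4 rather than the
0.068 an hourly rebinning would give):

    IV = n·Σ(x_i − x_{i−1})² / ((n−1)·Σ(x_i − x̄)²)
    IS = n·Σ_h(x̄_h − x̄)² / (p·Σ_i(x_i − x̄)²)

These honour the printed limits: 0/2 for sine/Gaussian IV, 1/0 for a
repeating-day/noise IS. Both are affine-invariant. The χ² periodogram uses
the Sokolove–Bushell statistic in its χ²-calibrated form,
Qp(P) = r·Σ_h(M_h − M)²/Var(x) with r = N/K rows folded at period P, so
that Qp ~ χ²(K−1) under the null and the significance line (p = 0.001 by
convention, exposed as a flag) is meaningful. Onset detection: trailing
3-bin smoothing (a centred smoother advances the rise), then the first
circular upward crossing of 20% of the day's maximum that dwells for 3
bins; days without activity or without any rest–activity transition are
flagged NaN. Phase angle of entrainment is the circular mean of
(onset − lights-on) mod 24, correct for onsets straddling midnight.

## Colocalization and unmixing

Mander's thresholds default to Otsu (the common ImageJ-plug-in choice is
unspecified in most workflows); both M1 and M2 are always reported.
Percent object colocalization counts a B object when ≥50% of its area is
covered by the A∧B joint channel (nucleus-counter emulation); an
any-pixel rule is available. Unmixing solves per-pixel non-negative least
squares (unconstrained lstsq offered for speed); reference spectra are
row-normalized to unit sum and checked for linear independence.

## Synthetic data: what it does and does not show

The generators reproduce the *parametric form* of each measurement —
closed-form signals plus the stated noise model (additive Gaussian for
traces/FRAP, multiplicative on G−1 for FCS, AR(1) random walks with a
reflecting floor for arrhythmic cells so classification is non-trivial).
They do not simulate photon statistics, PSF blur, cell movement, tracking
errors, or biological heterogeneity beyond the drawn parameter ranges.
Passing parameter-recovery tests therefore demonstrates estimator
correctness and calibration under the assumed noise regimes, not
robustness to every artefact of real microscopy. Determinism: identical
`SimConfig` yields bit-identical output.

## Problem sizes and replication

Defaults used in tests and the acceptance script: 120 h traces at 0.5 h
sampling (cohorts of 100 cells), 20 h decay courses at 6-min sampling,
300 s FRAP records at 0.5 s with 10 pre-bleach frames, FCS lag grids of
~113 points spanning 1 μs–10 s (16/decade), 10–100-day activity records.
Monte-Carlo recovery checks use 100 seeded replicates; stochastic
acceptance quantities are reported as means over 10 replicate simulated
cells, mirroring the group-mean convention of per-cell measurements
(single-curve FRAP half-time estimates scatter ~10% at 1% noise, the
replicate mean ~3%).

## Known limitations

- Period estimation assumes uniform sampling (resample first otherwise).
- The RAE surrogate (covariance-based) is not numerically identical to
  bootstrap definitions used by dedicated rhythm-analysis services.
- FRAP components closer than ~5× in rate are not reliably separable.
- FCS concentrations scale with the cube of the beam-waist calibration.
- The fitted damped cosine treats damping as a free non-negative
  parameter; strongly amplifying oscillations are out of scope.
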