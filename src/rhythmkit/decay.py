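"""One-phase exponential decay fitting for protein and mRNA half-lives.

Protein stability is measured by a cycloheximide chase (translation
blocked, fluorescence decays); mRNA stability by an actinomycin-D chase
read out with qPCR and the 2^-ddCt relative-quantification method against
two reference genes. Both are fit to

    Y(X) = (Y0 - Plateau) * exp(-K * X) + Plateau

with half-life ln(2)/K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model

from .traces import TimeSeriesTrace

__all__ = ["DecayFit", "fit_one_phase_decay", "ddct_normalize", "fit_mrna_decay"]

LN2 = float(np.log(2.0))

#: fraction of the decaying span still remaining at the end of the record
#: above which the half-life is flagged as extrapolated from the best fit
EXTRAPOLATION_REMAINING = 0.1


@dataclass
class DecayFit:
    """One-phase decay estimates; ``half_life`` = ln2/K in ``units``."""

    y0: float
    plateau: float
    k: float
    half_life: float
    y0_se: float | None
    plateau_se: float | None
    k_se: float | None
    half_life_se: float | None
    rss: float
    converged: bool
    extrapolated: bool
    units: str = "hours"


def _one_phase(x, y0, plateau, k):
    return (y0 - plateau) * np.exp(-k * x) + plateau


def _fit(x: np.ndarray, y: np.ndarray, fix_plateau: float | None, units: str) -> DecayFit:
    if x.size < 5:
        raise ValueError("need at least 5 points for a one-phase decay fit")
    plateau0 = float(np.min(y)) if fix_plateau is None else fix_plateau
    y00 = float(np.max(y))
    # K init from a log-linear regression of the decaying part
    span = y - plateau0
    pos = span > 1e-12 * max(abs(y00 - plateau0), 1e-300)
    if pos.sum() >= 2:
        slope = np.polyfit(x[pos], np.log(span[pos]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1.0 / max(x[-1] - x[0], 1.0)
    model = Model(_one_phase)
    params = model.make_params(y0=y00, plateau=plateau0, k=k0)
    params["k"].set(min=1e-12)
    if fix_plateau is not None:
        params["plateau"].set(value=fix_plateau, vary=False)
    result = model.fit(y, params, x=x)
    k = float(result.params["k"].value)
    if not result.success or k <= 0:
        raise RuntimeError(f"one-phase decay fit failed: success={result.success}, K={k}")
    k_se = result.params["k"].stderr
    half = LN2 / k
    half_se = LN2 * k_se / k**2 if k_se is not None else None  # delta method
    remaining = np.exp(-k * float(x[-1] - x[0]))
    return DecayFit(
        y0=float(result.params["y0"].value),
        plateau=float(result.params["plateau"].value),
        k=k,
        half_life=half,
        y0_se=result.params["y0"].stderr,
        plateau_se=result.params["plateau"].stderr,
        k_se=k_se,
        half_life_se=half_se,
        rss=float(np.sum(result.residual ** 2)),
        converged=True,
        extrapolated=bool(remaining > EXTRAPOLATION_REMAINING),
        units=units,
    )


def fit_one_phase_decay(trace: TimeSeriesTrace, fix_plateau: float | None = None) -> DecayFit:
    """Fit Y = (Y0 - Plateau) exp(-K X) + Plateau to an intensity course.

    The fit is scale-free (works on raw or normalized data). When the
    decline is incomplete within the record (more than 10% of the fitted
    decaying span remains at the last time point) the estimate is flagged
    ``extrapolated``: the half-life then comes from the best-fit curve
    rather than an observed half-descent.
    """
    m = trace.mask
    return _fit(trace.times[m] - trace.times[m][0], trace.values[m], fix_plateau, "hours")


def ddct_normalize(course: pd.DataFrame, target_gene: str,
                   reference_genes: tuple[str, str] = ("Gapdh", "Rpl13a"),
                   baseline_time: float = 0.0) -> pd.Series:
    """2^-ddCt relative expression of ``target_gene`` versus time 0.

    ``course`` is a long table with columns ``time``, ``gene``, ``Ct``.
    Each sample is first normalised to the mean Ct of the two reference
    genes (dCt), then to the baseline time point (ddCt); the returned
    series is indexed by time and equals 1 at ``baseline_time``.
    """
    required = {"time", "gene", "Ct"}
    if not required.issubset(course.columns):
        raise ValueError(f"course must have columns {sorted(required)}")
    wide = course.pivot_table(index="time", columns="gene", values="Ct")
    for g in (target_gene, *reference_genes):
        if g not in wide.columns or wide[g].isna().any():
            raise ValueError(f"missing Ct values for gene {g!r}")
    dct = wide[target_gene] - wide[list(reference_genes)].mean(axis=1)
    if baseline_time not in dct.index:
        raise ValueError(f"baseline time {baseline_time} not present in the course")
    ddct = dct - dct.loc[baseline_time]
    rel = np.power(2.0, -ddct)
    rel.name = "relative_expression"
    return rel


def fit_mrna_decay(relative_series: pd.Series, fix_plateau: float | None = 0.0) -> DecayFit:
    """Fit a one-phase decay (minutes) to a 2^-ddCt relative-expression series.

    The plateau is constrained to 0 by default (relative expression decays
    toward zero once transcription is blocked); pass ``fix_plateau=None``
    to fit it freely.
    """
    x = np.asarray(relative_series.index, dtype=float)
    y = np.asarray(relative_series.values, dtype=float)
    order = np.argsort(x)
    fit = _fit(x[order] - x[order][0], y[order], fix_plateau, "minutes")
    return fit
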