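"""Image-level quantification: colocalization, nuclear:cytoplasmic ratio
and spectral linear unmixing of lambda stacks.

Mander's coefficients report what fraction of one channel's intensity lies
in pixels positive for the other channel. Percent object colocalization
emulates a nucleus-counting workflow: a B object counts as colocalized if
the A-and-B joint channel covers it per the overlap rule. Linear unmixing
decomposes a wavelength-resolved (lambda) stack into per-fluorophore
abundance maps given reference emission spectra, by per-pixel
(non-negative) least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from skimage.filters import threshold_otsu

__all__ = ["SpectraMatrix", "manders_coefficient", "nc_ratio",
           "percent_colocalized", "linear_unmix"]


@dataclass
class SpectraMatrix:
    """Reference emission spectra, one row per fluorophore.

    Rows are normalized to unit sum on construction; spectra must be
    non-negative and linearly independent.
    """

    wavelengths: np.ndarray  # nm
    spectra: np.ndarray  # (n_fluorophores, n_wavelengths)
    names: tuple = ()

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        S = np.asarray(self.spectra, dtype=float)
        if S.ndim != 2 or S.shape[1] != self.wavelengths.size:
            raise ValueError("spectra must be (n_fluorophores, n_wavelengths)")
        if np.any(S < 0):
            raise ValueError("spectra must be non-negative")
        sums = S.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("each spectrum must have positive total intensity")
        self.spectra = S / sums
        if np.linalg.matrix_rank(self.spectra) < S.shape[0]:
            raise ValueError("reference spectra are linearly dependent")
        if not self.names:
            self.names = tuple(f"fluor{i}" for i in range(S.shape[0]))


def manders_coefficient(channel_a: np.ndarray, channel_b: np.ndarray,
                        threshold_b: float | None = None,
                        threshold_a: float | None = None) -> tuple[float, float]:
    """Mander's M1 and M2.

    M1 = fraction of A intensity in pixels where B exceeds its threshold;
    M2 symmetric. Thresholds default to Otsu's method on each channel.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must have the same shape")
    sum_a, sum_b = a.sum(), b.sum()
    if sum_a <= 0 or sum_b <= 0:
        raise ValueError("Mander's coefficient undefined for an all-zero channel")
    tb = threshold_otsu(b) if threshold_b is None else threshold_b
    ta = threshold_otsu(a) if threshold_a is None else threshold_a
    m1 = float(a[b > tb].sum() / sum_a)
    m2 = float(b[a > ta].sum() / sum_b)
    return m1, m2


def nc_ratio(image: np.ndarray, nuclear_mask: np.ndarray,
             cytoplasm_mask: np.ndarray) -> float:
    """Mean nuclear over mean cytoplasmic intensity (masks must be disjoint)."""
    image = np.asarray(image, dtype=float)
    nuc = np.asarray(nuclear_mask, dtype=bool)
    cyt = np.asarray(cytoplasm_mask, dtype=bool)
    if nuc.shape != image.shape or cyt.shape != image.shape:
        raise ValueError("masks must match the image shape")
    if not nuc.any() or not cyt.any():
        raise ValueError("empty mask")
    if np.any(nuc & cyt):
        raise ValueError("nuclear and cytoplasmic masks overlap")
    return float(image[nuc].mean() / image[cyt].mean())


def percent_colocalized(objects_a: np.ndarray, objects_b: np.ndarray,
                        overlap_rule: str = "half") -> float:
    """Percent of B objects colocalized with the A-and-B joint channel.

    ``overlap_rule='half'`` requires >= 50% of a B object's area to be
    covered by the joint channel (nucleus-counter emulation);
    ``'any'`` accepts a single overlapping pixel.
    """
    a = np.asarray(objects_a)
    b = np.asarray(objects_b)
    if a.shape != b.shape:
        raise ValueError("label masks must have the same shape")
    labels_b = np.unique(b[b > 0])
    if labels_b.size == 0:
        raise ValueError("no objects in channel B")
    joint = (a > 0) & (b > 0)
    count = 0
    for lab in labels_b:
        footprint = b == lab
        frac = joint[footprint].mean()
        if (overlap_rule == "half" and frac >= 0.5) or (overlap_rule == "any" and frac > 0):
            count += 1
        elif overlap_rule not in ("half", "any"):
            raise ValueError(f"unknown overlap_rule {overlap_rule!r}")
    return 100.0 * count / labels_b.size


def linear_unmix(stack: np.ndarray, spectra: SpectraMatrix, nonneg: bool = True):
    """Per-pixel linear unmixing of a lambda stack.

    ``stack`` has shape (ny, nx, n_wavelengths). Returns
    ``(abundances, residual)`` with abundances (n_fluorophores, ny, nx) and
    residual the per-pixel root-sum-square reconstruction error. With
    orthogonal spectra and noiseless data the non-negative and
    unconstrained solutions coincide and the residual is zero.
    """
    stack = np.asarray(stack, dtype=float)
    S = spectra.spectra  # (F, L)
    if stack.ndim != 3 or stack.shape[2] != S.shape[1]:
        raise ValueError("stack wavelength axis does not match the spectra")
    if S.shape[1] < S.shape[0]:
        raise ValueError("need at least as many wavelengths as fluorophores")
    ny, nx, L = stack.shape
    pixels = stack.reshape(-1, L)
    A = S.T  # (L, F)
    if nonneg:
        coeffs = np.empty((pixels.shape[0], S.shape[0]))
        for i, pix in enumerate(pixels):
            coeffs[i], _ = nnls(A, pix)
    else:
        coeffs, *_ = np.linalg.lstsq(A, pixels.T, rcond=None)
        coeffs = coeffs.T
    recon = coeffs @ S
    residual = np.sqrt(np.sum((recon - pixels) ** 2, axis=1)).reshape(ny, nx)
    return coeffs.T.reshape(S.shape[0], ny, nx), residual
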