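"""Noise magnitude, radial-frequency noise power spectrum, dose ratios.

Noise magnitude is the SD of the CT number in a centred square ROI (256 x 256
pixels by default), averaged over the slices of the stack and reported with
the standard error of the per-slice SDs.

The noise power spectrum is estimated by the radial frequency method: per
slice, the detrended ROI's 2-D periodogram ``|DFT|^2 * px^2 / N^2``
(units HU^2 mm^2) is averaged across slices and binned by the Euclidean norm
of the frequency coordinates with bin width ``1/(N px)`` cycles/mm (the DFT
spacing). The zero-frequency sample is excluded and empty bins dropped; the
axis therefore extends to the corner frequency (sqrt(2) x Nyquist) so that
binning conserves total power. The unit-area normalized spectrum (the noise
*texture*, independent of magnitude) is attached whenever the area under the
curve is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .stack import ImageStack

__all__ = [
    "NoiseResult",
    "SpectrumResult",
    "DoseRatioResult",
    "noise_magnitude",
    "compute_nps",
    "normalize_nps",
    "dose_ratio_percent",
]


@dataclass
class NoiseResult:
    """Mean per-slice ROI standard deviation, with its standard error."""

    mean_sd_hu: float
    se_hu: Optional[float]   # None when only one slice is available
    n_slices: int
    roi_size: int


@dataclass
class SpectrumResult:
    """Radially binned NPS with frequency axis in cycles/mm.

    ``nps`` is in HU^2 mm^2; ``normalized_nps`` (1/(cycles/mm)) integrates to
    one over ``frequencies`` and is None for a degenerate (all-zero)
    spectrum. ``bin_counts`` is the 2-D DFT ring occupancy of each bin per
    realization, ``roi_variance`` the pooled detrended ROI variance, and
    ``twod_integral`` the full 2-D NPS integral (Parseval check).
    """

    frequencies: np.ndarray
    nps: np.ndarray
    normalized_nps: Optional[np.ndarray]
    n_realizations: int
    bin_counts: Optional[np.ndarray] = None
    roi_variance: Optional[float] = None
    twod_integral: Optional[float] = None


@dataclass
class DoseRatioResult:
    """Noise magnitude of a test condition as integer percent of a reference."""

    percent: int
    test_sd_hu: float
    reference_sd_hu: float


def _center_roi(stack: ImageStack, roi_size: int) -> np.ndarray:
    ns, ny, nx = stack.shape
    if roi_size > ny or roi_size > nx:
        raise ValueError(f"ROI size {roi_size} exceeds image size {ny}x{nx}")
    r0 = (ny - roi_size) // 2
    c0 = (nx - roi_size) // 2
    return stack.data[:, r0:r0 + roi_size, c0:c0 + roi_size].astype(np.float64)


def noise_magnitude(stack: ImageStack, roi_size: int = 256) -> NoiseResult:
    """Per-slice SD of the centred square ROI, averaged across slices."""
    roi = _center_roi(stack, roi_size)
    per_slice = roi.reshape(stack.n_slices, -1).std(axis=1, ddof=1)
    se = (float(per_slice.std(ddof=1) / math.sqrt(stack.n_slices))
          if stack.n_slices >= 2 else None)
    return NoiseResult(mean_sd_hu=float(per_slice.mean()), se_hu=se,
                       n_slices=stack.n_slices, roi_size=roi_size)


def _detrend(roi: np.ndarray, mode: str) -> np.ndarray:
    if mode == "mean":
        return roi - roi.mean(axis=(1, 2), keepdims=True)
    if mode == "plane":
        n = roi.shape[1]
        y, x = np.mgrid[:n, :n].astype(float)
        basis = np.stack([np.ones(n * n), x.ravel(), y.ravel()], axis=1)
        flat = roi.reshape(roi.shape[0], -1)
        coef, *_ = np.linalg.lstsq(basis, flat.T, rcond=None)
        return (flat - (basis @ coef).T).reshape(roi.shape)
    raise ValueError(f"unknown detrend mode {mode!r}; expected 'mean' or 'plane'")


def compute_nps(stack: ImageStack, roi_size: int = 256,
                detrend: str = "mean") -> SpectrumResult:
    """Radial-frequency NPS of the centred ROI, averaged over slices."""
    roi = _detrend(_center_roi(stack, roi_size), detrend)
    px = stack.pixel_spacing
    n = roi_size
    # slice-averaged 2-D periodogram, HU^2 mm^2
    p2d = np.zeros((n, n))
    for sl in roi:
        p2d += np.abs(np.fft.fft2(sl)) ** 2
    p2d *= px ** 2 / (n ** 2 * stack.n_slices)
    df = 1.0 / (n * px)
    f = np.fft.fftfreq(n, d=px)
    rho = np.hypot(f[:, None], f[None, :])
    k = np.rint(rho / df).astype(int).ravel()
    p = p2d.ravel()
    mask = k > 0                      # exclude the DC sample
    sums = np.bincount(k[mask], weights=p[mask])
    counts = np.bincount(k[mask])
    occupied = counts > 0
    radial = sums[occupied] / counts[occupied]
    freqs = np.flatnonzero(occupied) * df
    variance = float(roi.var())
    spec = SpectrumResult(
        frequencies=freqs,
        nps=radial,
        normalized_nps=None,
        n_realizations=stack.n_slices,
        bin_counts=counts[occupied],
        roi_variance=variance,
        twod_integral=float(p2d.sum() * df ** 2),
    )
    if np.trapezoid(spec.nps, spec.frequencies) > 0:
        spec = normalize_nps(spec)
    return spec


def normalize_nps(spectrum: SpectrumResult) -> SpectrumResult:
    """Attach the unit-area normalized NPS (trapezoidal AUC); idempotent."""
    auc = float(np.trapezoid(spectrum.nps, spectrum.frequencies))
    if auc <= 0:
        raise ValueError("cannot normalize a spectrum with zero area under the curve")
    spectrum.normalized_nps = spectrum.nps / auc
    return spectrum


def dose_ratio_percent(test_sd_hu: float, reference_sd_hu: float) -> DoseRatioResult:
    """Integer percentage (half-up rounding) of test vs reference noise SD."""
    if reference_sd_hu <= 0:
        raise ValueError("reference_sd_hu must be positive")
    if test_sd_hu < 0:
        raise ValueError("test_sd_hu must be >= 0")
    percent = int(math.floor(100.0 * test_sd_hu / reference_sd_hu + 0.5))
    return DoseRatioResult(percent=percent, test_sd_hu=test_sd_hu,
                           reference_sd_hu=reference_sd_hu)
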