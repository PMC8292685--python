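"""Low-contrast detectability support: kappa agreement and an NPW surrogate.

Human low-contrast readings cannot be regenerated by software, so this
module provides two things:

* **Cohen's kappa** for the agreement between two raters on categorical
  readings (e.g. detectable minimum diameters), with the conventional
  interpretation bands (0.01-0.20 slight, 0.21-0.40 fair, 0.41-0.60
  moderate, 0.61-0.80 substantial, 0.81-1.00 almost perfect).
* A clearly-labelled **model-observer surrogate** for the minimum detectable
  diameter: a non-prewhitening (NPW) matched filter for a disk template
  under white noise, with a Rose-type decision threshold (default 5). The
  surrogate ranks conditions by contrast-to-noise and object size; it is not
  a reproduction of human observer performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .noise import SpectrumResult

__all__ = [
    "RatingTable",
    "KappaResult",
    "DetectabilityEstimate",
    "cohens_kappa",
    "kappa_band",
    "npw_disk_snr",
    "min_detectable_diameter",
]

# upper bounds of the agreement bands
_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass
class RatingTable:
    """Paired categorical ratings of the same items by two raters."""

    items: Sequence
    rater_a: Sequence
    rater_b: Sequence
    categories: Sequence

    def __post_init__(self) -> None:
        if not (len(self.items) == len(self.rater_a) == len(self.rater_b)):
            raise ValueError("items, rater_a and rater_b must have equal length")
        cats = set(self.categories)
        for name, ratings in (("rater_a", self.rater_a), ("rater_b", self.rater_b)):
            bad = [r for r in ratings if r not in cats]
            if bad:
                raise ValueError(f"{name} contains ratings outside the "
                                 f"permitted categories: {bad}")


@dataclass
class KappaResult:
    """Chance-corrected agreement between two raters."""

    kappa: Optional[float]        # None when expected agreement == 1
    observed_agreement: float
    expected_agreement: float
    band: str


def kappa_band(kappa: float) -> str:
    """Interpretation band of a kappa value on the conventional scale."""
    if kappa < 0.01:
        return "poor"
    for upper, name in _BANDS:
        if kappa <= upper + 1e-12:
            return name
    return "almost perfect"


def cohens_kappa(ratings: RatingTable) -> KappaResult:
    """Unweighted Cohen's kappa from the raters' cross-tabulation."""
    if len(ratings.items) < 2:
        raise ValueError("kappa needs at least 2 rated items")
    cats = list(ratings.categories)
    index = {c: i for i, c in enumerate(cats)}
    n = len(ratings.items)
    table = np.zeros((len(cats), len(cats)))
    for a, b in zip(ratings.rater_a, ratings.rater_b):
        table[index[a], index[b]] += 1
    table /= n
    po = float(np.trace(table))
    pe = float(table.sum(axis=1) @ table.sum(axis=0))
    if pe >= 1.0 - 1e-12:
        # both raters constant: agreement is trivially perfect, kappa 0/0
        return KappaResult(kappa=None, observed_agreement=po,
                           expected_agreement=pe, band="undefined")
    kappa = (po - pe) / (1.0 - pe)
    return KappaResult(kappa=float(kappa), observed_agreement=po,
                       expected_agreement=pe, band=kappa_band(kappa))


# ---------------------------------------------------------------------------
# NPW matched-filter surrogate
# ---------------------------------------------------------------------------

def npw_disk_snr(diameter_mm: float, contrast_hu: float, noise_sd_hu: float,
                 pixel_spacing_mm: float,
                 nps: Optional[SpectrumResult] = None) -> float:
    """Non-prewhitening matched-filter SNR of a disk in noise.

    Under white noise the template SNR reduces to the closed form
    ``(C / sigma) * sqrt(pi d^2 / 4) / px``. When a measured noise power
    spectrum is supplied, the NPS-weighted variant
    ``SNR^2 = (int |S|^2)^2 / int |S|^2 W`` is evaluated with the disk's
    radial spectrum ``S(f) = C pi R^2 [2 J1(2 pi f R) / (2 pi f R)]`` and
    the NPS ``W`` interpolated onto a radial frequency grid.
    """
    if min(diameter_mm, contrast_hu, noise_sd_hu, pixel_spacing_mm) <= 0:
        raise ValueError("all NPW SNR inputs must be positive")
    if nps is None:
        area = math.pi * diameter_mm ** 2 / 4.0
        return (contrast_hu / noise_sd_hu) * math.sqrt(area) / pixel_spacing_mm
    from scipy.special import j1
    R = diameter_mm / 2.0
    f = np.linspace(1e-6, 1.0 / (2 * pixel_spacing_mm), 2048)
    x = 2 * np.pi * f * R
    S2 = (contrast_hu * np.pi * R ** 2 * 2 * j1(x) / x) ** 2
    W = np.interp(f, nps.frequencies, nps.nps)
    num = np.trapezoid(S2 * 2 * np.pi * f, f) ** 2
    den = np.trapezoid(S2 * W * 2 * np.pi * f, f)
    if den <= 0:
        raise ValueError("NPS-weighted SNR: spectrum has no power")
    return float(np.sqrt(num / den))


@dataclass
class DetectabilityEstimate:
    """Surrogate minimum detectable diameter over a preset diameter ladder."""

    min_detectable_diameter: Optional[float]   # None = none detectable
    per_diameter_snr: dict = field(default_factory=dict)
    threshold: float = 5.0


def min_detectable_diameter(diameters_mm: Sequence, contrast_hu: float,
                            noise_sd_hu: float, pixel_spacing_mm: float,
                            threshold: float = 5.0,
                            nps: Optional[SpectrumResult] = None
                            ) -> DetectabilityEstimate:
    """Smallest ladder diameter whose NPW SNR reaches the Rose threshold."""
    diameters = list(diameters_mm)
    if not diameters:
        raise ValueError("diameter ladder is empty")
    if any(b >= a for a, b in zip(diameters, diameters[1:])):
        raise ValueError("diameter ladder must be strictly descending")
    snrs = {d: npw_disk_snr(d, contrast_hu, noise_sd_hu, pixel_spacing_mm,
                            nps=nps) for d in diameters}
    detectable = [d for d, s in snrs.items() if s >= threshold]
    return DetectabilityEstimate(
        min_detectable_diameter=min(detectable) if detectable else None,
        per_diameter_snr=snrs,
        threshold=threshold,
    )
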