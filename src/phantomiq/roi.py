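"""Rotated line-ROI measurements: CT number and attenuation profile curves.

CT numbers of the sensitometry inserts are measured with a short line ROI
(1 x 27 pixels by default, spanning about +-5 mm) rotated around the insert
centre in 1-degree steps; every sample of every rotation on every slice is
pooled into a grand mean +- SD. Attenuation profile curves (APCs) use a
longer line (1 x 51 pixels, about +-10 mm) and report the mean and SD per
signed radial position, so a 12-mm disk appears as a plateau centred at 0.

Sampling uses bilinear interpolation by default (``interpolation="nearest"``
selects exact pixel lookup; note that bilinear interpolation at sub-pixel
positions attenuates white noise, so SD-recovery checks should use nearest).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .stack import ImageStack, mm_to_pixel

__all__ = [
    "LineROISpec",
    "RadialProfileResult",
    "CTNumberResult",
    "sample_line_profile",
    "measure_ct_number",
    "measure_apc",
]

_ORDER = {"bilinear": 1, "nearest": 0}


@dataclass(frozen=True)
class LineROISpec:
    """Rotated line ROI: odd pixel count, number of angles, angular step."""

    length_pixels: int = 27
    n_angles: int = 360
    angle_step: float = 1.0

    def __post_init__(self) -> None:
        if self.length_pixels < 1 or self.length_pixels % 2 == 0:
            raise ValueError("length_pixels must be a positive odd integer")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.n_angles * self.angle_step > 360.0 + 1e-9:
            raise ValueError("n_angles x angle_step must not exceed 360 degrees")


@dataclass
class RadialProfileResult:
    """Mean +- SD attenuation profile over all rotations and slices."""

    positions: np.ndarray      # signed distance from centre, mm
    mean_profile: np.ndarray   # HU
    sd_profile: np.ndarray     # HU
    n_profiles: int


@dataclass
class CTNumberResult:
    """Pooled CT number of an insert: grand mean and SD over all samples."""

    mean_hu: float
    sd_hu: float
    insert_label: str = ""
    sd_of_angle_means_hu: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")


def _line_coords(center_mm, angles_deg, length_pixels, shape, pixel_spacing):
    """(rows, cols) arrays of shape (n_angles, length) for all rotations."""
    offs = np.arange(length_pixels) - (length_pixels - 1) / 2.0
    ang = np.deg2rad(np.atleast_1d(np.asarray(angles_deg, dtype=float)))
    # physical direction (cos, sin), y up
    x_mm = center_mm[0] + offs[None, :] * pixel_spacing * np.cos(ang)[:, None]
    y_mm = center_mm[1] + offs[None, :] * pixel_spacing * np.sin(ang)[:, None]
    rows, cols = mm_to_pixel(x_mm, y_mm, shape, pixel_spacing)
    return rows, cols


def _check_bounds(rows, cols, shape):
    ny, nx = shape[-2], shape[-1]
    if rows.min() < 0 or cols.min() < 0 or rows.max() > ny - 1 or cols.max() > nx - 1:
        raise ValueError("line ROI exits the image bounds")


def sample_line_profile(image: np.ndarray, center_mm, angle_deg: float,
                        length_pixels: int, pixel_spacing: float,
                        interpolation: str = "bilinear") -> np.ndarray:
    """Sample ``length_pixels`` points one pixel apart along ``angle_deg``.

    Points are centred on ``center_mm`` and ordered from negative to positive
    offset along the line direction (x right, y up, angle counter-clockwise
    from +x).
    """
    rows, cols = _line_coords(center_mm, angle_deg, length_pixels,
                              image.shape, pixel_spacing)
    _check_bounds(rows, cols, image.shape)
    out = ndimage.map_coordinates(np.asarray(image, dtype=float),
                                  [rows.ravel(), cols.ravel()],
                                  order=_ORDER[interpolation], mode="nearest")
    return out.reshape(rows.shape)[0]


def _all_profiles(stack: ImageStack, center_mm, roi: LineROISpec,
                  interpolation: str) -> np.ndarray:
    """Samples of every rotated profile: shape (n_slices, n_angles, length)."""
    angles = np.arange(roi.n_angles) * roi.angle_step
    rows, cols = _line_coords(center_mm, angles, roi.length_pixels,
                              stack.shape, stack.pixel_spacing)
    _check_bounds(rows, cols, stack.shape)
    coords = [rows.ravel(), cols.ravel()]
    order = _ORDER[interpolation]
    out = np.empty((stack.n_slices, roi.n_angles, roi.length_pixels))
    for k, sl in enumerate(stack):
        out[k] = ndimage.map_coordinates(np.asarray(sl, dtype=float), coords,
                                         order=order, mode="nearest"
                                         ).reshape(rows.shape)
    return out


def measure_ct_number(stack: ImageStack, center_mm,
                      roi: Optional[LineROISpec] = None,
                      insert_label: str = "",
                      interpolation: str = "bilinear") -> CTNumberResult:
    """Grand mean +- SD over all rotated line-ROI samples and slices."""
    roi = roi or LineROISpec(length_pixels=27)
    samples = _all_profiles(stack, center_mm, roi, interpolation)
    angle_means = samples.mean(axis=2).ravel()
    return CTNumberResult(
        mean_hu=float(samples.mean()),
        sd_hu=float(samples.std(ddof=1)),
        insert_label=insert_label,
        sd_of_angle_means_hu=float(angle_means.std(ddof=1))
        if angle_means.size > 1 else None,
    )


def measure_apc(stack: ImageStack, center_mm,
                roi: Optional[LineROISpec] = None,
                interpolation: str = "bilinear") -> RadialProfileResult:
    """Mean attenuation profile curve over all rotations and slices."""
    roi = roi or LineROISpec(length_pixels=51)
    samples = _all_profiles(stack, center_mm, roi, interpolation)
    flat = samples.reshape(-1, roi.length_pixels)
    offs = (np.arange(roi.length_pixels) - (roi.length_pixels - 1) / 2.0)
    return RadialProfileResult(
        positions=offs * stack.pixel_spacing,
        mean_profile=flat.mean(axis=0),
        sd_profile=flat.std(axis=0, ddof=1) if flat.shape[0] > 1
        else np.zeros(roi.length_pixels),
        n_profiles=flat.shape[0],
    )
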