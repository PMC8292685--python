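"""Image-stack container shared by every measurement stage.

CT images are carried as a 3-D array of Hounsfield units together with the
in-plane pixel spacing and slice thickness. All geometric arguments elsewhere
in the package are given in millimetres and converted to pixels through
``pixel_spacing``; physical coordinates have their origin at the image
centre, x to the right and y up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "mm_to_pixel", "pixel_centers_mm"]


@dataclass
class ImageStack:
    """A stack of axial CT slices in Hounsfield units.

    Parameters
    ----------
    data:
        Array of shape ``(n_slices, ny, nx)`` in HU.
    pixel_spacing:
        In-plane pixel size in mm (isotropic).
    slice_thickness:
        Slice thickness in mm.
    """

    data: np.ndarray
    pixel_spacing: float
    slice_thickness: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be 2-D or 3-D")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def __iter__(self):
        return iter(self.data)


def mm_to_pixel(x_mm: float, y_mm: float, shape: tuple, pixel_spacing: float):
    """Convert physical (x right, y up, origin at centre) to (row, col).

    The centre of the image is at pixel ``((n-1)/2, (n-1)/2)``; rows increase
    downward, hence the sign flip on y.
    """
    ny, nx = shape[-2], shape[-1]
    col = (nx - 1) / 2.0 + x_mm / pixel_spacing
    row = (ny - 1) / 2.0 - y_mm / pixel_spacing
    return row, col


def pixel_centers_mm(shape: tuple, pixel_spacing: float):
    """Return 1-D arrays (x_mm of columns, y_mm of rows) of pixel centres."""
    ny, nx = shape[-2], shape[-1]
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_spacing
    y = ((ny - 1) / 2.0 - np.arange(ny)) * pixel_spacing
    return x, y
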