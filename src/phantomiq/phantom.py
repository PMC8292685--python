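"""Synthetic Catphan-style phantom generator with exactly known ground truth.

The generator produces stacks of axial CT slices that emulate the three
physical phantom modules used in CT quality assurance:

* a **uniformity** module (CTP486 analogue) — a homogeneous body used for
  noise-magnitude and noise-power-spectrum estimation;
* a **sensitometry** module (CTP404 analogue) — 12-mm disk inserts at nominal
  340 / 120 / -35 HU for CT-number and attenuation-profile measurement, plus
  a high-contrast (990 HU) disk for MTF estimation by the circular-edge
  method;
* a **low-contrast** module (CTP515 analogue) — disks of 15, 9, 8, 7, 6, 5,
  4, 3 and 2 mm diameter at the 1.0% contrast level.

Every slice is rendered on a configurable grid (default 1024 px, 400-mm
field of view, i.e. 0.390625 mm/px). Ground truth is exact by construction:

* With ``blur_sigma_mm == 0`` disks are rasterized by analytic area-fraction
  anti-aliasing (pixel value = background + contrast x fraction of the pixel
  area inside the disk), so integrated contrast equals contrast x pi r^2.
* With ``blur_sigma_mm > 0`` the scene is convolved with an isotropic
  Gaussian *in the continuous domain*: a Gaussian-blurred disk has the
  closed-form radial profile ``P(chi'^2_2(nc=(d/sigma)^2) <= (R/sigma)^2)``
  (Marcum Q), which is evaluated at pixel centres. The true modulation
  transfer function of the blurred scene is therefore exactly
  ``exp(-2 pi^2 sigma^2 f^2)``, with no pixel-aperture or kernel-sampling
  term — this is what makes closed-form MTF recovery tests possible.

Noise is applied after blurring (it models reconstruction noise, not scene
noise) and is reproducible: identical (spec, seed) pairs give bit-identical
stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import stats

from .stack import ImageStack, pixel_centers_mm

__all__ = [
    "GridSpec",
    "DiskInsert",
    "NoiseModel",
    "PhantomSpec",
    "render_noiseless_slice",
    "generate_stack",
    "catphan_presets",
    "true_mtf",
    "LOW_CONTRAST_DIAMETERS_MM",
    "AIR_HU",
]

#: HU assigned outside the phantom body.
AIR_HU = -1000.0

#: Diameter ladder of the low-contrast module, mm (largest first).
LOW_CONTRAST_DIAMETERS_MM = (15.0, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0)


# ---------------------------------------------------------------------------
# Specification types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Reconstruction grid: matrix size, field of view and slice thickness."""

    matrix_size: int = 1024
    field_of_view: float = 400.0
    slice_thickness: float = 0.5

    def __post_init__(self) -> None:
        if self.matrix_size < 64:
            raise ValueError("matrix_size must be >= 64")
        if self.field_of_view <= 0:
            raise ValueError("field_of_view must be positive")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")

    @property
    def pixel_spacing(self) -> float:
        """mm per pixel, exactly field_of_view / matrix_size."""
        return self.field_of_view / self.matrix_size


@dataclass(frozen=True)
class DiskInsert:
    """A disk-shaped insert: centre (mm from image centre), diameter, contrast."""

    center: tuple = (0.0, 0.0)
    diameter: float = 12.0
    contrast_hu: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"insert {self.label!r}: diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class NoiseModel:
    """Per-slice additive noise: magnitude, texture and seed.

    ``texture`` is one of:

    * ``"white"`` — i.i.d. Gaussian per pixel;
    * ``"gaussian_lowpass"`` — white noise filtered by a Gaussian transfer
      function ``exp(-2 pi^2 l^2 f^2)`` with ``l = correlation_length_mm``;
    * ``"target_nps"`` — white noise filtered in the frequency domain by the
      square root of ``target_nps`` (a ``(frequencies, values)`` pair in
      cycles/mm), then rescaled so the per-pixel SD equals ``sigma_hu`` in
      expectation.
    """

    sigma_hu: float = 0.0
    texture: str = "white"
    correlation_length_mm: Optional[float] = None
    target_nps: Optional[tuple] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_hu < 0:
            raise ValueError("sigma_hu must be >= 0")
        if self.texture not in ("white", "gaussian_lowpass", "target_nps"):
            raise ValueError(f"unknown noise texture {self.texture!r}")
        if self.texture == "gaussian_lowpass":
            if self.correlation_length_mm is None or self.correlation_length_mm <= 0:
                raise ValueError("gaussian_lowpass requires correlation_length_mm > 0")
        if self.texture == "target_nps" and self.target_nps is None:
            raise ValueError("target_nps texture requires a (frequencies, values) curve")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic phantom stack (the ground-truth record)."""

    grid: GridSpec = field(default_factory=GridSpec)
    background_hu: float = 0.0
    inserts: tuple = ()
    blur_sigma_mm: float = 0.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_slices: int = 1
    body_radius_mm: Optional[float] = None  # None: whole FOV is background

    def __post_init__(self) -> None:
        object.__setattr__(self, "inserts", tuple(self.inserts))
        if self.blur_sigma_mm < 0:
            raise ValueError("blur_sigma_mm must be >= 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        half_fov = self.grid.field_of_view / 2.0
        for ins in self.inserts:
            cx, cy = ins.center
            if np.hypot(cx, cy) + ins.radius > half_fov:
                raise ValueError(
                    f"insert {ins.label or ins.contrast_hu} at {ins.center} with "
                    f"diameter {ins.diameter} mm does not lie fully within the "
                    f"{self.grid.field_of_view}-mm field of view"
                )

    # -- serialization ------------------------------------------------------
    def to_yaml(self) -> str:
        d = asdict(self)
        if d["noise"]["target_nps"] is not None:
            f, v = d["noise"]["target_nps"]
            d["noise"]["target_nps"] = [list(map(float, f)), list(map(float, v))]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        d = yaml.safe_load(text)
        d["grid"] = GridSpec(**d.get("grid", {}))
        d["inserts"] = tuple(
            DiskInsert(center=tuple(i["center"]), diameter=i["diameter"],
                       contrast_hu=i["contrast_hu"], label=i.get("label", ""))
            for i in d.get("inserts", ())
        )
        nd = d.get("noise", {})
        if nd.get("target_nps") is not None:
            f, v = nd["target_nps"]
            nd["target_nps"] = (np.asarray(f, float), np.asarray(v, float))
        d["noise"] = NoiseModel(**nd)
        return cls(**d)


def true_mtf(spec: PhantomSpec, frequencies: np.ndarray) -> np.ndarray:
    """Analytic MTF of the rendered (blurred) scene: exp(-2 pi^2 sigma^2 f^2).

    Valid for ``blur_sigma_mm > 0``, where disks are rendered from the
    continuous-domain convolution. For a sharp scene the response is limited
    only by the pixel aperture of the area-fraction rasterization.
    """
    f = np.asarray(frequencies, dtype=float)
    s = spec.blur_sigma_mm
    return np.exp(-2.0 * np.pi ** 2 * s ** 2 * f ** 2)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _sharp_disk_coverage(grid: GridSpec, center_mm, radius_mm: float) -> np.ndarray:
    """Fraction of each pixel's area covered by the disk (sharp edge).

    Interior/exterior pixels are classified by centre distance; for the
    boundary ring the coverage is computed as the exact chord overlap in y,
    integrated over x by 256-point midpoint quadrature. Total coverage equals
    the analytic disk area to ~1e-3 px^2.
    """
    ps = grid.pixel_spacing
    x, y = pixel_centers_mm((grid.matrix_size, grid.matrix_size), ps)
    dx = x[None, :] - center_mm[0]
    dy = y[:, None] - center_mm[1]
    d = np.hypot(dx, dy)
    half_diag = ps * np.sqrt(0.5)
    cov = np.zeros((grid.matrix_size, grid.matrix_size))
    cov[d <= radius_mm - half_diag] = 1.0
    ring = (d > radius_mm - half_diag) & (d < radius_mm + half_diag)
    rows, cols = np.nonzero(ring)
    if rows.size == 0:
        return cov
    nq = 256
    # sub-pixel x midpoints, relative to each ring pixel's centre
    offs = (np.arange(nq) + 0.5) / nq - 0.5
    px_x = dx[0, cols][:, None] + offs[None, :] * ps     # x rel. to disk centre
    h2 = radius_mm ** 2 - px_x ** 2
    h = np.sqrt(np.clip(h2, 0.0, None))
    yc = dy[rows, 0][:, None]                            # pixel-centre y rel. to disk
    y1, y2 = yc - ps / 2.0, yc + ps / 2.0
    ylo = np.maximum(-h, y1)
    yhi = np.minimum(h, y2)
    overlap = np.clip(yhi - ylo, 0.0, None)
    overlap[h2 <= 0] = 0.0
    cov[rows, cols] = overlap.mean(axis=1) / ps
    return cov


def _blurred_disk_coverage(grid: GridSpec, center_mm, radius_mm: float,
                           sigma_mm: float) -> np.ndarray:
    """Disk indicator convolved with an isotropic Gaussian, at pixel centres.

    The convolution of a disk of radius R with N(0, sigma^2 I_2) evaluated at
    distance d from the centre is P(chi'^2_2((d/sigma)^2) <= (R/sigma)^2).
    Evaluated only inside a +-8 sigma band around the edge; 1 inside, 0 out.
    """
    ps = grid.pixel_spacing
    x, y = pixel_centers_mm((grid.matrix_size, grid.matrix_size), ps)
    d = np.hypot(x[None, :] - center_mm[0], y[:, None] - center_mm[1])
    cov = np.zeros_like(d)
    cov[d <= radius_mm - 8.0 * sigma_mm] = 1.0
    band = (d > radius_mm - 8.0 * sigma_mm) & (d < radius_mm + 8.0 * sigma_mm)
    db = d[band]
    cov[band] = stats.ncx2.cdf((radius_mm / sigma_mm) ** 2, 2,
                               (db / sigma_mm) ** 2)
    return cov


def _disk_coverage(grid: GridSpec, center_mm, radius_mm: float,
                   sigma_mm: float) -> np.ndarray:
    if sigma_mm > 0:
        return _blurred_disk_coverage(grid, center_mm, radius_mm, sigma_mm)
    return _sharp_disk_coverage(grid, center_mm, radius_mm)


def render_noiseless_slice(spec: PhantomSpec) -> np.ndarray:
    """Render one noiseless slice of the phantom in HU (float64, 2-D)."""
    n = spec.grid.matrix_size
    if spec.body_radius_mm is None:
        img = np.full((n, n), spec.background_hu, dtype=float)
    else:
        img = np.full((n, n), AIR_HU, dtype=float)
        body = _disk_coverage(spec.grid, (0.0, 0.0), spec.body_radius_mm,
                              spec.blur_sigma_mm)
        img += (spec.background_hu - AIR_HU) * body
    for ins in spec.inserts:
        img += ins.contrast_hu * _disk_coverage(spec.grid, ins.center,
                                                ins.radius, spec.blur_sigma_mm)
    return img


# ---------------------------------------------------------------------------
# Noise synthesis
# ---------------------------------------------------------------------------

def _noise_filter(noise: NoiseModel, n: int, pixel_spacing: float) -> Optional[np.ndarray]:
    """Frequency-domain filter H (unit mean-square gain) for textured noise."""
    if noise.texture == "white":
        return None
    f = np.fft.fftfreq(n, d=pixel_spacing)
    rho = np.hypot(f[:, None], f[None, :])
    if noise.texture == "gaussian_lowpass":
        ell = noise.correlation_length_mm
        H = np.exp(-2.0 * np.pi ** 2 * ell ** 2 * rho ** 2)
    else:  # target_nps
        fq, val = noise.target_nps
        fq = np.asarray(fq, float)
        val = np.clip(np.asarray(val, float), 0.0, None)
        H = np.sqrt(np.interp(rho, fq, val, left=val[0], right=val[-1]))
    ms = np.mean(H ** 2)
    if ms <= 0:
        raise ValueError("target NPS curve has zero power")
    return H / np.sqrt(ms)


def generate_stack(spec: PhantomSpec) -> ImageStack:
    """Render the noiseless scene and add independent noise per slice.

    Deterministic: the same (spec, seed) pair yields a bit-identical stack.
    The stack is stored as float32.
    """
    base = render_noiseless_slice(spec).astype(np.float32)
    n = spec.grid.matrix_size
    data = np.repeat(base[None], spec.n_slices, axis=0)
    if spec.noise.sigma_hu > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.noise.seed))
        H = _noise_filter(spec.noise, n, spec.grid.pixel_spacing)
        for k in range(spec.n_slices):
            w = rng.standard_normal((n, n))
            if H is not None:
                w = np.fft.ifft2(np.fft.fft2(w) * H).real
            data[k] += (spec.noise.sigma_hu * w).astype(np.float32)
    return ImageStack(
        data=data,
        pixel_spacing=spec.grid.pixel_spacing,
        slice_thickness=spec.grid.slice_thickness,
        metadata={"phantom_spec": spec},
    )


# ---------------------------------------------------------------------------
# Catphan-style presets
# ---------------------------------------------------------------------------

def _clock_position(hour: float, radius_mm: float) -> tuple:
    """(x, y) mm of a clock position: 12 o'clock up, clockwise."""
    ang = np.deg2rad(90.0 - 30.0 * hour)
    return (radius_mm * np.cos(ang), radius_mm * np.sin(ang))


def catphan_presets(module: str,
                    grid: Optional[GridSpec] = None,
                    noise: Optional[NoiseModel] = None,
                    blur_sigma_mm: float = 0.0,
                    n_slices: int = 1,
                    background_hu: float = 0.0,
                    body_radius_mm: float = 150.0,
                    insert_ring_radius_mm: float = 50.0,
                    hu_per_percent: float = 10.0) -> PhantomSpec:
    """Build the PhantomSpec for one of the emulated Catphan modules.

    Parameters
    ----------
    module:
        ``"sensitometry"`` — three 12-mm disks at 340/120/-35 HU at the 9,
        11 and 1 o'clock positions plus a 990-HU disk (MTF target) at
        5 o'clock; ``"uniformity"`` — no inserts; ``"low_contrast"`` — nine
        disks of 15..2 mm diameter at the 1.0% contrast level.
    hu_per_percent:
        HU corresponding to 1% contrast (default 10 HU, the common CT
        convention of a 1000-HU reference scale). The physical phantom's
        specification leaves the HU convention open, so it is a parameter.
    """
    grid = grid or GridSpec()
    noise = noise or NoiseModel()
    common = dict(grid=grid, background_hu=background_hu, noise=noise,
                  blur_sigma_mm=blur_sigma_mm, n_slices=n_slices,
                  body_radius_mm=body_radius_mm)
    if module == "uniformity":
        return PhantomSpec(inserts=(), **common)
    if module == "sensitometry":
        inserts = (
            DiskInsert(_clock_position(9, insert_ring_radius_mm), 12.0, 340.0, "high"),
            DiskInsert(_clock_position(11, insert_ring_radius_mm), 12.0, 120.0, "moderate"),
            DiskInsert(_clock_position(1, insert_ring_radius_mm), 12.0, -35.0, "low"),
            DiskInsert(_clock_position(5, insert_ring_radius_mm), 12.0, 990.0, "mtf"),
        )
        return PhantomSpec(inserts=inserts, **common)
    if module == "low_contrast":
        contrast = 1.0 * hu_per_percent
        hours = np.linspace(0.0, 12.0, len(LOW_CONTRAST_DIAMETERS_MM),
                            endpoint=False)
        inserts = tuple(
            DiskInsert(_clock_position(h, insert_ring_radius_mm), diam,
                       contrast, f"{diam:g}mm")
            for h, diam in zip(hours, LOW_CONTRAST_DIAMETERS_MM)
        )
        return PhantomSpec(inserts=inserts, **common)
    raise ValueError(f"unknown phantom module {module!r}; expected "
                     "'sensitometry', 'uniformity' or 'low_contrast'")
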