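# phantomiq

Quantitative CT image-quality assessment on synthetic Catphan-style
phantoms — for medical physicists and imaging scientists who want every
stage of a QA pipeline (noise, noise texture, spatial resolution, contrast
recovery, detectability, reader agreement) verifiable against exactly known
ground truth, without scanner data.

## What it computes

The package emulates the three phantom modules of a body-CT QA protocol on
a 1024 × 1024, 400-mm-FOV grid (0.390625 mm/px) and measures them:

* **CT number** — a 1 × 27-pixel line ROI rotated about each 12-mm insert
  centre in 1° steps over 360°; all samples of all rotations and slices are
  pooled into mean ± SD. Inserts: 340 / 120 / −35 HU (plus a 990-HU disk
  for resolution).
* **Attenuation profile curves (APC)** — the same rotation scheme with a
  1 × 51-pixel line (±10 mm), giving the mean radial profile of an insert.
* **Image noise** — SD of HU in a centred 256 × 256 ROI, averaged over 50
  sequential slices, reported as HU (SE), and expressed relative to a
  reference condition as an integer percentage (half-up rounding).
* **Noise power spectrum** — radial frequency method: per-slice 2-D
  periodogram of the detrended ROI, `NPS(f) = |DFT|² · Δx² / N²`
  (HU²·mm²), averaged over slices and binned by radial frequency with bin
  width `1/(N·Δx)`; the unit-area normalized NPS characterizes noise
  *texture* independently of magnitude.
* **MTF (circular-edge / disk method)** — signal-average 50 slices, bin
  annulus pixels around the 990-HU disk edge by radial distance into an
  oversampled edge-spread function, differentiate to the line-spread
  function, Fourier-transform to the MTF, and read off f50 and f10 (the
  frequencies where the MTF falls to 0.5 and 0.1), with their standard
  error across replicate stacks.
* **Low-contrast detectability** — a clearly-labelled non-prewhitening
  matched-filter surrogate, `SNR = (C/σ)·√(πd²/4)/Δx`, thresholded at a
  Rose criterion of 5 over the 15…2-mm diameter ladder; and **Cohen's
  kappa** with the conventional agreement bands for two-reader studies.

The phantom generator is first-class, tested code: sharp disks are
rasterized with exact area-fraction anti-aliasing; blurred disks are
rendered from the continuous-domain convolution of a disk with an isotropic
Gaussian, so the scene's true MTF is exactly `exp(−2π²σ²f²)`; noise (white,
Gaussian-low-pass, or shaped to an arbitrary target NPS) is added post-blur
and is bit-reproducible from a seed.

## Worked example

```python
import numpy as np
from phantomiq import *

grid = GridSpec(matrix_size=320, field_of_view=125.0)   # 0.390625 mm/px
spec = catphan_presets("sensitometry", grid=grid,
                       noise=NoiseModel(sigma_hu=15.0, seed=42),
                       blur_sigma_mm=0.3, n_slices=50)
stack = generate_stack(spec)

for ins in spec.inserts[:3]:
    ct = measure_ct_number(stack, ins.center, insert_label=ins.label)
    print(f"{ins.label:9s} nominal {ins.contrast_hu:6.0f} HU -> "
          f"{ct.mean_hu:7.1f} ± {ct.sd_hu:.1f} HU")

mtf = disk_mtf(stack, spec.inserts[3].center, 6.0)
print(f"f50 = {mtf.f50:.3f} cycles/mm   f10 = {mtf.f10:.3f} cycles/mm")
```

prints

```
high      nominal    340 HU ->   340.0 ± 9.6 HU
moderate  nominal    120 HU ->   120.0 ± 9.8 HU
low       nominal    -35 HU ->   -34.9 ± 9.8 HU
f50 = 0.617 cycles/mm   f10 = 1.128 cycles/mm
```

The three insert means land on their nominal values (the ±SD is the pooled
per-sample noise after bilinear interpolation), and the f50 of 0.617
cycles/mm recovers the closed-form value 0.625 cycles/mm implied by the
0.3-mm Gaussian blur to about 1%.

Full protocols (many conditions × analyses, CSV tables, provenance log) run
from YAML via the CLI:

```bash
phantomiq simulate --spec phantom.yaml --out stack --format dicom
phantomiq analyze --config protocol.yaml
phantomiq kappa --ratings ratings.csv
```

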