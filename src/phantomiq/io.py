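"""Reading and writing image stacks: DICOM series and raw+YAML pairs.

Two on-disk representations are supported:

* **DICOM series** — one CT-like file per slice; ``PixelSpacing``,
  ``SliceThickness`` and ``RescaleSlope``/``RescaleIntercept`` are honoured
  and slices are ordered by position along the stack axis. Pixel data are
  stored as int16 with slope 1 / intercept -1024, so HU values are rounded
  to the nearest integer on write (lossy for fractional HU).
* **Raw pair** — a ``.npy`` array next to a ``.yaml`` sidecar holding the
  spacing metadata; lossless, used wherever a bit-identical round trip is
  required.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import yaml

import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .stack import ImageStack

__all__ = ["save_stack_raw", "load_stack_raw",
           "save_stack_dicom", "load_stack_dicom", "load_stack"]

_INTERCEPT = -1024.0


def save_stack_raw(stack: ImageStack, path) -> None:
    """Write ``<path>.npy`` plus ``<path>.yaml`` sidecar (lossless)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), stack.data)
    meta = {
        "pixel_spacing": float(stack.pixel_spacing),
        "slice_thickness": float(stack.slice_thickness),
        "n_slices": int(stack.n_slices),
        "dtype": str(stack.data.dtype),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_stack_raw(path) -> ImageStack:
    """Load a raw pair written by :func:`save_stack_raw`."""
    path = Path(path)
    npy = path.with_suffix(".npy")
    sidecar = path.with_suffix(".yaml")
    if not npy.exists():
        raise FileNotFoundError(f"raw stack array not found: {npy}")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"raw stack {npy} has no YAML sidecar ({sidecar} missing)")
    meta = yaml.safe_load(sidecar.read_text())
    return ImageStack(data=np.load(npy),
                      pixel_spacing=float(meta["pixel_spacing"]),
                      slice_thickness=float(meta["slice_thickness"]))


def save_stack_dicom(stack: ImageStack, directory) -> None:
    """Write one DICOM file per slice into ``directory`` (int16 HU storage)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    for k, sl in enumerate(stack):
        stored = np.rint(np.asarray(sl, dtype=float) - _INTERCEPT)
        stored = np.clip(stored, -32768, 32767).astype(np.int16)
        ds = Dataset()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * stack.slice_thickness]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [stack.pixel_spacing, stack.pixel_spacing]
        ds.SliceThickness = stack.slice_thickness
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = _INTERCEPT
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.save_as(directory / f"slice_{k:04d}.dcm", enforce_file_format=True)


def load_stack_dicom(directory) -> ImageStack:
    """Read a DICOM series directory into an ImageStack (HU after rescale)."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.is_file() and p.suffix.lower() in (".dcm", ""))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = []
    for p in files:
        ds = pydicom.dcmread(p)
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"missing RescaleSlope/Intercept in {p.name}")
        datasets.append((p, ds))
    spacings = {tuple(float(v) for v in ds.PixelSpacing) for _, ds in datasets}
    if len(spacings) != 1:
        names = ", ".join(p.name for p, _ in datasets)
        raise ValueError(f"inconsistent PixelSpacing across series ({names})")
    thicknesses = {float(ds.SliceThickness) for _, ds in datasets}

    def zpos(item):
        _, ds = item
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(ds.InstanceNumber)

    zs = [zpos(it) for it in datasets]
    if len(set(zs)) != len(zs):
        raise ValueError("duplicate slice positions in DICOM series")
    datasets = [d for _, d in sorted(zip(zs, datasets), key=lambda t: t[0])]
    arrays = [ds[1].pixel_array.astype(np.float32) * float(ds[1].RescaleSlope)
              + float(ds[1].RescaleIntercept) for ds in datasets]
    (ps,) = spacings
    return ImageStack(data=np.stack(arrays),
                      pixel_spacing=ps[0],
                      slice_thickness=thicknesses.pop())


def load_stack(path) -> ImageStack:
    """Dispatch: a directory is a DICOM series, a file path a raw pair."""
    path = Path(path)
    if path.is_dir():
        return load_stack_dicom(path)
    return load_stack_raw(path)
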