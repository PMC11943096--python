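"""Reading and writing radiograph files.

Supported formats: 16-bit (or 8-bit) greyscale PNG and TIFF, and DICOM
for reading.  DICOM reads honour PhotometricInterpretation (MONOCHROME1
maps to the package's "inverted" polarity) and BitsStored, and lift the
acquisition attributes the rest of the package consumes (KVP, Exposure,
ViewPosition, PatientSex, AcquisitionDate) into ``Radiograph.meta``.
Writing targets PNG/TIFF; simulation provenance travels in a JSON
sidecar written by the CLI.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .radiograph import Radiograph

__all__ = ["read_image", "write_image"]

_PNG_EXTS = {".png"}
_TIFF_EXTS = {".tif", ".tiff"}
_DICOM_EXTS = {".dcm", ".dicom"}


def _depth_for_dtype(arr: np.ndarray) -> int:
    return 8 if arr.dtype == np.uint8 else 16


def read_image(path: str | Path) -> Radiograph:
    """Read a radiograph from PNG, TIFF or DICOM."""
    p = Path(path)
    ext = p.suffix.lower()
    if ext in _DICOM_EXTS:
        return _read_dicom(p)
    if ext in _PNG_EXTS:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(p))
    elif ext in _TIFF_EXTS:
        import tifffile

        arr = np.asarray(tifffile.imread(p))
    else:
        raise ValueError(f"unsupported image format {ext!r} ({p})")
    if arr.ndim == 3:  # greyscale stored with a redundant channel axis
        arr = arr[..., 0]
    return Radiograph(arr, bit_depth=_depth_for_dtype(arr))


def _read_dicom(path: Path) -> Radiograph:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = np.asarray(ds.pixel_array)
    bits = int(getattr(ds, "BitsStored", arr.dtype.itemsize * 8))
    bit_depth = 8 if bits <= 8 else 16
    photometric = (
        "inverted"
        if str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2")) == "MONOCHROME1"
        else "standard"
    )
    meta: dict = {}
    if getattr(ds, "KVP", None) not in (None, ""):
        meta["kvp"] = float(ds.KVP)
    exposure = getattr(ds, "Exposure", None)  # mAs
    if exposure in (None, ""):
        uas = getattr(ds, "ExposureInuAs", None)
        exposure = float(uas) / 1000.0 if uas not in (None, "") else None
    if exposure is not None:
        meta["mas"] = float(exposure)
    if getattr(ds, "ViewPosition", None) in ("PA", "AP"):
        meta["view"] = str(ds.ViewPosition)
    if getattr(ds, "PatientSex", None) in ("M", "F"):
        meta["gender"] = str(ds.PatientSex)
    acq = getattr(ds, "AcquisitionDate", None)
    if acq:
        meta["acquisition_date"] = _dt.datetime.strptime(str(acq), "%Y%m%d").date()
    return Radiograph(arr, bit_depth=bit_depth, photometric=photometric, meta=meta)


def write_image(image: Radiograph, path: str | Path) -> None:
    """Write a radiograph as PNG or TIFF at its native bit depth."""
    p = Path(path)
    ext = p.suffix.lower()
    arr = np.asarray(image.pixels).astype(image.dtype_for_depth())
    if ext in _PNG_EXTS:
        import imageio.v3 as iio

        iio.imwrite(p, arr)
    elif ext in _TIFF_EXTS:
        import tifffile

        tifffile.imwrite(p, arr)
    else:
        raise ValueError(f"unsupported output format {ext!r} ({p}); use .png/.tif")
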