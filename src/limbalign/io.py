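"""Radiograph reading, writing and window-based intensity normalization.

DICOM files are read with pydicom, honoring the window center/width tags;
8/16-bit PNG is the fallback, with full-range default windows.  The
coordinate convention throughout the package is origin at the top-left,
x rightward, y downward, 0-based, with half-open boxes.

Anonymization policy: no non-geometric DICOM tags are ever copied into
any output this package writes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = ["Radiograph", "UnreadableImageError", "load_radiograph",
           "normalize_window", "normalized", "save_png", "save_minimal_dicom"]


class UnreadableImageError(ValueError):
    """File exists but cannot be parsed as a radiograph."""


@dataclass
class Radiograph:
    """A 2-D radiograph with optional physical and window metadata."""

    pixels: np.ndarray
    window_center: float | None = None
    window_width: float | None = None
    pixel_spacing: float | None = None  # mm / px, isotropic
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise UnreadableImageError("radiograph pixels must be a non-empty 2-D array")
        if self.window_width is not None and not self.window_width > 0:
            raise ValueError("window width must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def normalize_window(pixels: np.ndarray, center: float, width: float) -> np.ndarray:
    """Window/level normalization to [0, 1].

    ``v`` maps to ``clip((v - (center - width/2)) / width, 0, 1)``; the
    map is monotone non-decreasing and idempotent on already-normalized
    input when ``center=0.5, width=1``.
    """
    if not width > 0:
        raise ValueError(f"window width must be positive, got {width}")
    v = np.asarray(pixels, dtype=float)
    return np.clip((v - (center - width / 2.0)) / width, 0.0, 1.0)


def normalized(radiograph: Radiograph) -> np.ndarray:
    """Apply the radiograph's own window (full range if absent)."""
    px = radiograph.pixels
    c, w = radiograph.window_center, radiograph.window_width
    if c is None or w is None:
        lo, hi = float(px.min()), float(px.max())
        if hi <= lo:
            return np.zeros_like(px, dtype=float)
        c, w = (hi + lo) / 2.0, hi - lo
    return normalize_window(px, c, w)


def _first_value(tag_value):
    try:
        return float(tag_value[0])
    except (TypeError, IndexError):
        return float(tag_value)


def load_radiograph(path, invert: bool = False) -> Radiograph:
    """Read a DICOM or PNG radiograph.

    DICOM window tags are captured when present; PNG defaults to the full
    dynamic range of its bit depth (window_center 127.5 / width 255 for
    8-bit).  ``invert`` flips intensities for MONOCHROME1-style display.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".dcm", ".dicom", ""):
        rad = _load_dicom(path)
    elif ext == ".png":
        rad = _load_png(path)
    else:
        raise UnreadableImageError(f"unsupported radiograph format: {path}")
    if invert:
        px = rad.pixels
        rad.pixels = px.max() + px.min() - px
    return rad


def _load_dicom(path) -> Radiograph:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as e:  # pydicom raises a zoo of types
        raise UnreadableImageError(f"cannot read DICOM {path}: {e}") from e
    if arr.ndim != 2 or arr.size == 0:
        raise UnreadableImageError(f"zero-sized or non-2D DICOM image: {path}")
    wc = _first_value(ds.WindowCenter) if "WindowCenter" in ds else None
    ww = _first_value(ds.WindowWidth) if "WindowWidth" in ds else None
    spacing = None
    if "PixelSpacing" in ds:
        spacing = float(ds.PixelSpacing[0])
    elif "ImagerPixelSpacing" in ds:
        spacing = float(ds.ImagerPixelSpacing[0])
    return Radiograph(arr.astype(float), wc, ww, spacing,
                      source_id=os.path.basename(path))


def _load_png(path) -> Radiograph:
    from PIL import Image, UnidentifiedImageError

    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "I", "I;16"):
                im = im.convert("L")
            arr = np.asarray(im)
    except UnidentifiedImageError as e:
        raise UnreadableImageError(f"cannot read PNG {path}: {e}") from e
    if arr.ndim != 2 or arr.size == 0:
        raise UnreadableImageError(f"zero-sized PNG image: {path}")
    full = 65535.0 if arr.dtype.itemsize > 1 else 255.0
    return Radiograph(arr.astype(float), window_center=full / 2.0,
                      window_width=full, source_id=os.path.basename(path))


def save_png(path, pixels01: np.ndarray, bit_depth: int = 16) -> None:
    """Write a [0,1] float image as 8- or 16-bit grayscale PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(pixels01, dtype=float), 0.0, 1.0)
    if bit_depth == 16:
        Image.fromarray((arr * 65535).round().astype(np.uint16)).save(path)
    else:
        Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)


def save_minimal_dicom(path, pixels01: np.ndarray,
                       pixel_spacing: float | None = None) -> None:
    """Write a minimal secondary-capture DICOM with window tags only.

    Deliberately carries no patient or acquisition metadata.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    arr16 = (np.clip(np.asarray(pixels01, float), 0, 1) * 4095).round().astype(np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(os.fspath(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = arr16.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 12
    ds.HighBit = 11
    ds.PixelRepresentation = 0
    ds.WindowCenter = 2048
    ds.WindowWidth = 4096
    if pixel_spacing is not None:
        ds.PixelSpacing = [pixel_spacing, pixel_spacing]
    ds.PixelData = arr16.tobytes()
    ds.save_as(path, enforce_file_format=True)
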