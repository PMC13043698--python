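"""Reading ultrasound frames and normalising them to 8-bit greyscale.

Frames come from uncompressed single-frame monochrome DICOM exports or from
8-bit greyscale PNGs. All downstream texture analysis assumes a standardised
256-level greyscale range (0-255), so anything deeper is reduced with
:func:`to_8bit` at load time. Acquisition metadata (subject, zone, machine)
may live in DICOM tags, in a sidecar JSON next to the image, or be supplied
as overrides; overrides win.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pydicom

from .errors import MissingMetadataError, UnsupportedFormatError

#: The eight imaged lung sections: left/right x anterior/lateral x upper/lower.
ZONES: tuple[str, ...] = ("LAL", "LAU", "LLL", "LLU", "RAL", "RAU", "RLL", "RLU")

#: Keys a sidecar JSON may carry.
_SIDECAR_KEYS = ("subject_id", "zone", "machine_id", "pixel_spacing_mm")


@dataclass
class UltrasoundFrame:
    """One 8-bit greyscale lung-ultrasound image with acquisition metadata.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array, grey levels 0-255, row index increasing downward.
    subject_id
        Opaque infant identifier.
    zone
        One of the eight section labels in :data:`ZONES`.
    machine_id
        Free-form ultrasound-system label (e.g. ``"venue50"``).
    pixel_spacing_mm
        Physical size of one pixel in mm, when known.
    """

    pixels: np.ndarray
    subject_id: str
    zone: str
    machine_id: str = ""
    pixel_spacing_mm: float | None = None

    height: int = field(init=False)
    width: int = field(init=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise UnsupportedFormatError(
                f"frame pixels must be 2-D, got shape {px.shape}"
            )
        if px.size == 0:
            raise UnsupportedFormatError("frame has zero pixels")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise ValueError("pixel intensities must be integers")
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel intensities outside [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        self.height, self.width = px.shape
        if self.zone not in ZONES:
            raise ValueError(f"zone {self.zone!r} not one of {ZONES}")
        if self.pixel_spacing_mm is not None and self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")


def to_8bit(raw: np.ndarray, source_max: int) -> np.ndarray:
    """Reduce a non-negative integer image to 8-bit by floor scaling.

    output = floor(raw * 255 / source_max). Deterministic, monotone, and the
    identity on 8-bit input with ``source_max=255``. A rounding variant exists
    behind :attr:`qlus.config.PipelineConfig.bit_reduction`.
    """
    return _reduce_depth(raw, source_max, mode="floor")


def _reduce_depth(raw: np.ndarray, source_max: int, mode: str = "floor") -> np.ndarray:
    if source_max < 1:
        raise ValueError(f"source_max must be >= 1, got {source_max}")
    arr = np.asarray(raw)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("raw image must have an integer dtype")
    if arr.size and (arr.min() < 0 or arr.max() > source_max):
        raise ValueError(f"raw values outside [0, {source_max}]")
    scaled = arr.astype(np.int64) * 255
    if mode == "floor":
        out = scaled // source_max
    elif mode == "round":
        out = (scaled + source_max // 2) // source_max
    else:
        raise ValueError(f"unknown bit-reduction mode {mode!r}")
    return out.astype(np.uint8)


def _load_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        return {k: data[k] for k in _SIDECAR_KEYS if k in data}
    return {}


def _read_png(path: Path) -> tuple[np.ndarray, dict]:
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise UnsupportedFormatError(
            f"{path.name}: colour/multi-channel images are not supported"
        )
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{path.name}: expected a 2-D image")
    if arr.dtype == np.uint16:
        arr = to_8bit(arr, 65535)
    elif arr.dtype != np.uint8:
        raise UnsupportedFormatError(f"{path.name}: unsupported dtype {arr.dtype}")
    return arr, {}


def _read_dicom(path: Path, bit_reduction: str) -> tuple[np.ndarray, dict]:
    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:  # pydicom raises a zoo of types here
        raise UnsupportedFormatError(f"{path.name}: cannot decode DICOM: {exc}") from exc
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError(f"{path.name}: colour DICOM not supported")
    if int(getattr(ds, "NumberOfFrames", 1)) > 1 or arr.ndim != 2:
        raise UnsupportedFormatError(f"{path.name}: multi-frame DICOM not supported")
    bits = int(getattr(ds, "BitsStored", 8))
    if bits > 8:
        arr = _reduce_depth(arr.astype(np.int64), 2**bits - 1, mode=bit_reduction)
    meta: dict = {}
    if getattr(ds, "PatientID", ""):
        meta["subject_id"] = str(ds.PatientID)
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing:
        meta["pixel_spacing_mm"] = float(spacing[0])
    return arr.astype(np.uint8), meta


def read_frame(
    path: str | Path,
    metadata_overrides: Mapping[str, object] | None = None,
    bit_reduction: str = "floor",
) -> UltrasoundFrame:
    """Read a single-frame monochrome DICOM or greyscale PNG as a frame.

    Metadata precedence: explicit ``metadata_overrides`` > sidecar JSON
    (``<stem>.json`` next to the image) > embedded DICOM tags. A frame without
    a resolvable ``subject_id`` and ``zone`` raises
    :class:`~qlus.errors.MissingMetadataError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        pixels, meta = _read_dicom(path, bit_reduction)
    else:
        pixels, meta = _read_png(path)
    meta.update(_load_sidecar(path))
    if metadata_overrides:
        meta.update({k: v for k, v in metadata_overrides.items() if v is not None})
    missing = [k for k in ("subject_id", "zone") if not meta.get(k)]
    if missing:
        raise MissingMetadataError(
            f"{path.name}: no {'/'.join(missing)} in tags, sidecar or overrides"
        )
    return UltrasoundFrame(
        pixels=pixels,
        subject_id=str(meta["subject_id"]),
        zone=str(meta["zone"]),
        machine_id=str(meta.get("machine_id", "")),
        pixel_spacing_mm=meta.get("pixel_spacing_mm"),
    )


def write_frame(frame: UltrasoundFrame, path: str | Path, sidecar: bool = True) -> None:
    """Write a frame as 8-bit PNG plus (optionally) its metadata sidecar."""
    path = Path(path)
    iio.imwrite(path, frame.pixels)
    if sidecar:
        meta = {
            "subject_id": frame.subject_id,
            "zone": frame.zone,
            "machine_id": frame.machine_id,
        }
        if frame.pixel_spacing_mm is not None:
            meta["pixel_spacing_mm"] = frame.pixel_spacing_mm
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
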