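"""Pleural/subpleural region-of-interest rules and their rasterisation.

The ROI is the band of fixed pixel depth hanging from the pleural line:
superior boundary the pleural surface itself (inclusive), lateral boundaries
the adjacent rib shadows expressed as a half-open column interval, inferior
boundary ``depth_px`` rows below the pleural line (50 px ~ 1 mm by default).
Manual delineation is emulated by authoring specs externally (JSON); nothing
here detects the pleural line automatically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateRoiError, OutOfFrameError, RoiSpecError

DEFAULT_DEPTH_PX = 50
DEFAULT_MIN_ROI_PIXELS = 100


@dataclass(frozen=True)
class RoiSpec:
    """Pleural polyline + lateral bounds + subpleural depth.

    ``pleural_polyline`` is an ordered list of (column, row) vertices tracing
    the pleural surface left to right with strictly increasing columns.
    ``lateral_bounds`` is a half-open column interval [col_min, col_max).
    Coordinates are 0-based with row increasing downward.
    """

    pleural_polyline: tuple[tuple[int, float], ...]
    lateral_bounds: tuple[int, int]
    depth_px: int = DEFAULT_DEPTH_PX

    def __post_init__(self) -> None:
        poly = tuple((int(c), float(r)) for c, r in self.pleural_polyline)
        object.__setattr__(self, "pleural_polyline", poly)
        if len(poly) < 2:
            raise RoiSpecError("pleural polyline needs at least two vertices")
        cols = [c for c, _ in poly]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise RoiSpecError("polyline columns must be strictly increasing")
        c0, c1 = (int(b) for b in self.lateral_bounds)
        object.__setattr__(self, "lateral_bounds", (c0, c1))
        if c0 >= c1:
            raise RoiSpecError(f"empty lateral interval [{c0}, {c1})")
        if c0 < cols[0] or c1 - 1 > cols[-1]:
            raise RoiSpecError(
                f"lateral bounds [{c0}, {c1}) outside polyline span "
                f"[{cols[0]}, {cols[-1]}]"
            )
        if self.depth_px < 1:
            raise RoiSpecError("depth_px must be >= 1")

    def pleural_rows(self, columns: Sequence[int] | np.ndarray) -> np.ndarray:
        """Interpolated pleural row per column, rounded half-up to an index."""
        cols = np.asarray([c for c, _ in self.pleural_polyline], dtype=float)
        rows = np.asarray([r for _, r in self.pleural_polyline], dtype=float)
        interp = np.interp(np.asarray(columns, dtype=float), cols, rows)
        return np.floor(interp + 0.5).astype(np.int64)  # round half-up

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSpec":
        data = json.loads(Path(path).read_text())
        return cls(
            pleural_polyline=tuple((c, r) for c, r in data["pleural_polyline"]),
            lateral_bounds=tuple(data["lateral_bounds"]),
            depth_px=int(data.get("depth_px", DEFAULT_DEPTH_PX)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "pleural_polyline": [[c, r] for c, r in self.pleural_polyline],
                    "lateral_bounds": list(self.lateral_bounds),
                    "depth_px": self.depth_px,
                },
                indent=1,
            )
        )


@dataclass(frozen=True)
class RoiMask:
    """Boolean pixel mask realising an :class:`RoiSpec` on one frame."""

    mask: np.ndarray
    n_pixels: int


def rasterize_roi(
    spec: RoiSpec,
    height: int,
    width: int,
    min_pixels: int = DEFAULT_MIN_ROI_PIXELS,
) -> RoiMask:
    """Rasterise an ROI spec to a pixel mask on a ``height x width`` frame.

    A pixel (column c, row r) is included iff ``col_min <= c < col_max`` and
    ``pleural_row(c) <= r < pleural_row(c) + depth_px``. The band must fit
    entirely inside the frame: truncation at the bottom edge would silently
    change the pixel count and bias every downstream feature, so it raises
    :class:`~qlus.errors.OutOfFrameError` instead.
    """
    if height < 1 or width < 1:
        raise RoiSpecError("frame dimensions must be positive")
    c0, c1 = spec.lateral_bounds
    if c0 < 0 or c1 > width:
        raise RoiSpecError(
            f"lateral bounds [{c0}, {c1}) outside frame width {width}"
        )
    cols = np.arange(c0, c1)
    top = spec.pleural_rows(cols)
    if top.min() < 0:
        raise OutOfFrameError("pleural line above the top row")
    if int(top.max()) + spec.depth_px > height:
        raise OutOfFrameError(
            f"band bottom row {int(top.max()) + spec.depth_px - 1} "
            f"exceeds frame height {height}"
        )
    mask = np.zeros((height, width), dtype=bool)
    rows = np.arange(height)[:, None]
    mask[:, c0:c1] = (rows >= top[None, :]) & (rows < top[None, :] + spec.depth_px)
    n = int(mask.sum())
    if n < min_pixels:
        raise DegenerateRoiError(f"ROI has {n} pixels, below minimum {min_pixels}")
    return RoiMask(mask=mask, n_pixels=n)


def depth_from_mm(target_mm: float, pixel_spacing_mm: float) -> int:
    """Convert a physical subpleural depth to a pixel count (round, min 1)."""
    if target_mm <= 0 or pixel_spacing_mm <= 0:
        raise ValueError("target_mm and pixel_spacing_mm must be positive")
    return max(1, int(math.floor(target_mm / pixel_spacing_mm + 0.5)))
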