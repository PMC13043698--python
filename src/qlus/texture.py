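"""Masked one-direction GLCM and the six Q-LUS texture metrics.

The grey-level co-occurrence matrix (GLCM) counts how often pairs of grey
levels occur at a fixed pixel displacement. The default displacement is
(0, 1): distance 1 at 0 degrees, i.e. left-to-right neighbours only, on the
full 256-level greyscale with no re-quantisation. A pair contributes only if
BOTH endpoints lie inside the ROI mask, which keeps rib shadows and
out-of-band pixels from contaminating the statistics.

From the normalised matrix p(i, j) the five Haralick features are

    ASM        = sum p(i,j)^2
    contrast   = sum (i-j)^2 p(i,j)
    correlation= [sum i*j*p(i,j) - mu_x*mu_y] / (sigma_x * sigma_y)
    IDM        = sum p(i,j) / (1 + (i-j)^2)
    entropy    = -sum_{p>0} p(i,j) * log p(i,j)

with mu/sigma taken from the row/column marginals. The sixth metric, the
mean grey value (MGV), is first-order: the average intensity inside the ROI.

Correlation is undefined when either marginal has zero variance (e.g. a
constant ROI); it is then reported as NaN — an explicit undefined sentinel
that downstream aggregation drops rather than imputes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateRoiError, NoPairsError, ShapeError
from .image_io import UltrasoundFrame
from .roi import RoiMask, RoiSpec, rasterize_roi

DEFAULT_LEVELS = 256
DEFAULT_OFFSET = (0, 1)  # distance 1 at 0 degrees: left-to-right neighbours

_LOG_BASES = {"ln": math.e, "log2": 2.0, "log10": 10.0}


@dataclass(frozen=True)
class Glcm:
    """A normalised grey-level co-occurrence matrix.

    ``p`` is the ``levels x levels`` probability matrix (sums to 1);
    ``n_pairs`` is the number of directed pixel pairs that contributed
    before any symmetrisation.
    """

    p: np.ndarray
    levels: int
    offset: tuple[int, int]
    symmetric: bool
    n_pairs: int

    def validate(self) -> None:
        if self.p.shape != (self.levels, self.levels):
            raise ShapeError("GLCM matrix shape does not match levels")
        if self.n_pairs < 1:
            raise NoPairsError("GLCM built from zero pairs")
        if np.any(self.p < 0) or abs(float(self.p.sum()) - 1.0) > 1e-12:
            raise ValueError("GLCM probabilities must be non-negative and sum to 1")
        if self.symmetric and not np.array_equal(self.p, self.p.T):
            raise ValueError("GLCM flagged symmetric but p != p.T")


@dataclass(frozen=True)
class TextureFeatures:
    """The six Q-LUS metrics for one frame plus bookkeeping counts.

    ``correlation`` is NaN when undefined (zero marginal variance).
    """

    mgv: float
    asm: float
    contrast: float
    correlation: float
    idm: float
    entropy: float
    n_roi_pixels: int
    n_pairs: int

    FEATURE_NAMES = ("mgv", "asm", "contrast", "correlation", "idm", "entropy")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FEATURE_NAMES}


def _check_mask(frame: UltrasoundFrame, mask: RoiMask) -> np.ndarray:
    m = mask.mask
    if m.shape != frame.pixels.shape:
        raise ShapeError(
            f"mask shape {m.shape} does not match frame shape {frame.pixels.shape}"
        )
    if not m.any():
        raise DegenerateRoiError("empty ROI mask")
    return m


def mean_grey_value(frame: UltrasoundFrame, mask: RoiMask) -> float:
    """Average pixel intensity within the ROI (first-order echogenicity)."""
    m = _check_mask(frame, mask)
    return float(frame.pixels[m].mean())


def build_glcm(
    frame: UltrasoundFrame,
    mask: RoiMask,
    offset: tuple[int, int] = DEFAULT_OFFSET,
    symmetric: bool = True,
    levels: int = DEFAULT_LEVELS,
) -> Glcm:
    """Build the masked co-occurrence matrix at one displacement.

    Counts every directed pair (pixel at (r, c), pixel at (r+dr, c+dc)) whose
    endpoints are both inside the mask; with ``symmetric`` each pair also
    contributes to the transposed cell before normalisation.
    """
    dr, dc = offset
    if (dr, dc) == (0, 0):
        raise ValueError("GLCM offset must be nonzero")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    m = _check_mask(frame, mask)
    px = frame.pixels
    if levels != 256:
        # re-quantise 0..255 onto `levels` equal bins
        px = (px.astype(np.int64) * levels) // 256
    h, w = px.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise NoPairsError(f"offset {offset} larger than the frame")
    base_m = m[r0:r1, c0:c1]
    shift_m = m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    both = base_m & shift_m
    n_pairs = int(both.sum())
    if n_pairs == 0:
        raise NoPairsError(f"no pixel pair has both endpoints masked at offset {offset}")
    i = px[r0:r1, c0:c1][both].astype(np.int64)
    j = px[r0 + dr : r1 + dr, c0 + dc : c1 + dc][both].astype(np.int64)
    counts = np.bincount(i * levels + j, minlength=levels * levels).reshape(
        levels, levels
    )
    if symmetric:
        counts = counts + counts.T
    p = counts / counts.sum()
    return Glcm(p=p, levels=levels, offset=(dr, dc), symmetric=symmetric, n_pairs=n_pairs)


def haralick_features(
    g: Glcm, entropy_base: str = "ln"
) -> tuple[float, float, float, float, float]:
    """Compute (ASM, contrast, correlation, IDM, entropy) from a GLCM.

    Entropy uses the natural log by default (0*log 0 := 0); base is
    configurable (``"ln"``, ``"log2"``, ``"log10"``). Correlation is NaN when
    sigma_x * sigma_y == 0.
    """
    g.validate()
    if entropy_base not in _LOG_BASES:
        raise ValueError(f"entropy_base must be one of {sorted(_LOG_BASES)}")
    nz_i, nz_j = np.nonzero(g.p)
    pv = g.p[nz_i, nz_j]
    d = nz_i - nz_j
    asm = float(np.square(pv).sum())
    contrast = float((d * d * pv).sum())
    idm = float((pv / (1.0 + d * d)).sum())
    entropy = float(-(pv * np.log(pv)).sum())
    if entropy_base != "ln":
        entropy /= math.log(_LOG_BASES[entropy_base])
    # marginal moments for the correlation feature
    px_marg = g.p.sum(axis=1)
    py_marg = g.p.sum(axis=0)
    levels = np.arange(g.levels, dtype=float)
    mu_x = float(levels @ px_marg)
    mu_y = float(levels @ py_marg)
    var_x = float(((levels - mu_x) ** 2) @ px_marg)
    var_y = float(((levels - mu_y) ** 2) @ py_marg)
    denom = math.sqrt(var_x) * math.sqrt(var_y)
    if denom == 0.0:
        correlation = float("nan")
    else:
        cov = float((nz_i * nz_j * pv).sum()) - mu_x * mu_y
        correlation = cov / denom
    return asm, contrast, correlation, idm, entropy


def analyze_frame(
    frame: UltrasoundFrame,
    spec: RoiSpec,
    offset: tuple[int, int] = DEFAULT_OFFSET,
    symmetric: bool = True,
    levels: int = DEFAULT_LEVELS,
    entropy_base: str = "ln",
    min_roi_pixels: int = 100,
) -> TextureFeatures:
    """Rasterise the ROI and compute all six Q-LUS metrics for one frame."""
    mask = rasterize_roi(spec, frame.height, frame.width, min_pixels=min_roi_pixels)
    mgv = mean_grey_value(frame, mask)
    g = build_glcm(frame, mask, offset=offset, symmetric=symmetric, levels=levels)
    asm, contrast, correlation, idm, entropy = haralick_features(g, entropy_base)
    return TextureFeatures(
        mgv=mgv,
        asm=asm,
        contrast=contrast,
        correlation=correlation,
        idm=idm,
        entropy=entropy,
        n_roi_pixels=mask.n_pixels,
        n_pairs=g.n_pairs,
    )
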