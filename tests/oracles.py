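"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — explicit Python loops and textbook
formulas — and shares no code with the package under test.
"""

from __future__ import annotations

import math

import numpy as np


def naive_masked_glcm(pixels, mask, offset=(0, 1), symmetric=True, levels=256):
    """Double-loop co-occurrence counts over pairs fully inside the mask."""
    dr, dc = offset
    h, w = pixels.shape
    counts: dict[tuple[int, int], int] = {}
    n_pairs = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i = int(pixels[r, c]) * levels // 256 if levels != 256 else int(pixels[r, c])
                j = int(pixels[r2, c2]) * levels // 256 if levels != 256 else int(pixels[r2, c2])
                counts[(i, j)] = counts.get((i, j), 0) + 1
                n_pairs += 1
                if symmetric:
                    counts[(j, i)] = counts.get((j, i), 0) + 1
    total = sum(counts.values())
    p = {ij: c / total for ij, c in counts.items()} if total else {}
    return p, n_pairs


def naive_haralick(p: dict[tuple[int, int], float]):
    """Textbook ASM/contrast/correlation/IDM/entropy from a sparse GLCM."""
    asm = sum(v * v for v in p.values())
    contrast = sum((i - j) ** 2 * v for (i, j), v in p.items())
    idm = sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
    entropy = -sum(v * math.log(v) for v in p.values() if v > 0)
    px: dict[int, float] = {}
    py: dict[int, float] = {}
    for (i, j), v in p.items():
        px[i] = px.get(i, 0.0) + v
        py[j] = py.get(j, 0.0) + v
    mu_x = sum(i * v for i, v in px.items())
    mu_y = sum(j * v for j, v in py.items())
    var_x = sum((i - mu_x) ** 2 * v for i, v in px.items())
    var_y = sum((j - mu_y) ** 2 * v for j, v in py.items())
    if var_x == 0 or var_y == 0:
        correlation = float("nan")
    else:
        cov = sum(i * j * v for (i, j), v in p.items()) - mu_x * mu_y
        correlation = cov / math.sqrt(var_x * var_y)
    return asm, contrast, correlation, idm, entropy


def naive_masked_features(pixels, mask, offset=(0, 1), symmetric=True, levels=256):
    """All six Q-LUS metrics via loops: MGV + the five Haralick features."""
    vals = [int(pixels[r, c]) for r in range(pixels.shape[0])
            for c in range(pixels.shape[1]) if mask[r, c]]
    mgv = sum(vals) / len(vals)
    p, n_pairs = naive_masked_glcm(pixels, mask, offset, symmetric, levels)
    return (mgv, *naive_haralick(p), n_pairs)


def naive_roi_membership(polyline, lateral_bounds, depth_px, height, width):
    """Per-pixel evaluation of the ROI membership predicate."""
    cols = [c for c, _ in polyline]
    rows = [r for _, r in polyline]

    def pleural_row(c):
        if c <= cols[0]:
            return rows[0]
        for (c0, r0), (c1, r1) in zip(polyline, polyline[1:]):
            if c0 <= c <= c1:
                t = (c - c0) / (c1 - c0)
                return r0 + t * (r1 - r0)
        return rows[-1]

    mask = np.zeros((height, width), dtype=bool)
    lo, hi = lateral_bounds
    for c in range(width):
        if not lo <= c < hi:
            continue
        top = math.floor(pleural_row(c) + 0.5)  # round half-up
        for r in range(height):
            if top <= r < top + depth_px:
                mask[r, c] = True
    return mask


def naive_spearman(x, y) -> float:
    """Rank (mean rank for ties) then the textbook Pearson formula."""

    def mid_ranks(v):
        order = sorted(range(len(v)), key=lambda k: v[k])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = mid_ranks(list(x)), mid_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
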