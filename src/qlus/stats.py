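"""Spearman correlation engine: rho, p-values, CIs, strength labels, tables.

Spearman's rank correlation (Pearson correlation of mid-ranks, ties getting
their mean rank) is the study's association measure. Significance uses the
t-approximation t = rho*sqrt((n-2)/(1-rho^2)) by default, replaced by the
exact permutation distribution at n <= 8 where full enumeration is cheap.
Confidence intervals default to a seeded bootstrap percentile (2000
resamples); a Fisher-z normal approximation is available as an alternative.

Correlation strength follows the study's categories on |rho|:
weak < 0.30 <= fair < 0.50 <= moderate < 0.70 <= strong. The printed category
bounds leave gaps (0.49 -> 0.50); half-open intervals close them.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ShapeError

logger = logging.getLogger(__name__)

SIGNIFICANCE_ALPHA = 0.05
#: Lower |rho| bound of each non-weak category, in ascending order.
STRENGTH_THRESHOLDS = (("strong", 0.70), ("moderate", 0.50), ("fair", 0.30))

DEFAULT_BOOTSTRAP_RESAMPLES = 2000
MIN_SUBJECTS_PER_CELL = 4

FEATURES = ("mgv", "asm", "contrast", "correlation", "idm", "entropy")
INDICES = ("osi", "sf_ratio")


@dataclass(frozen=True)
class CorrelationResult:
    """One cell of the correlation table (feature x index x subgroup)."""

    feature: str
    index: str
    subgroup: str
    n: int
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    strength: str
    significant: bool


def _check_xy(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ShapeError(f"x and y must be equal-length 1-D vectors, got {x.shape} vs {y.shape}")
    if x.size < min_n:
        raise DegenerateInputError(f"need at least {min_n} pairs, got {x.size}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateInputError("constant vector: Spearman rho undefined")
    return x, y


def spearman_rho(x, y) -> float:
    """Spearman's rho: Pearson correlation of mid-ranks (ties -> mean rank)."""
    x, y = _check_xy(x, y)
    return float(sps.spearmanr(x, y).statistic)


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        logger.info("|rho| = 1 with t-approximation: returning the p = 0 limit")
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def _exact_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p from the full n! permutation distribution of rho."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    sx = rx - rx.mean()
    denom_x = math.sqrt(float(sx @ sx))
    obs = None
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        py = np.asarray(perm) - ry.mean()
        denom_y = math.sqrt(float(py @ py))
        r = float(sx @ py) / (denom_x * denom_y)
        if obs is None:
            # identity permutation comes first: the observed statistic
            obs = r
        if abs(r) >= abs(obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_p(x, y, method: str = "auto") -> float:
    """Two-sided p-value for Spearman's rho.

    ``method``: ``"t"`` (t-approximation), ``"exact"`` (full permutation
    enumeration, only feasible at small n), or ``"auto"`` (exact when
    n <= 8, else t).
    """
    x, y = _check_xy(x, y)
    n = x.size
    if method == "auto":
        method = "exact" if n <= 8 else "t"
    if method == "exact":
        if n > 9:
            raise ValueError(f"exact permutation enumeration infeasible at n={n}")
        return _exact_permutation_p(x, y)
    if method == "t":
        return _t_approx_p(spearman_rho(x, y), n)
    raise ValueError(f"unknown p-value method {method!r}")


def _bootstrap_rhos(
    x: np.ndarray, y: np.ndarray, n_resamples: int, rng: np.random.Generator
) -> np.ndarray:
    n = x.size
    idx = rng.integers(0, n, size=(n_resamples, n))
    bx, by = x[idx], y[idx]
    rx = sps.rankdata(bx, axis=1)
    ry = sps.rankdata(by, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx * rx).sum(axis=1) * (ry * ry).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (rx * ry).sum(axis=1) / denom
    return rhos[np.isfinite(rhos)]  # drop resamples that drew a constant vector


def rho_ci(
    x,
    y,
    level: float = 0.95,
    method: str = "bootstrap",
    n_resamples: int = DEFAULT_BOOTSTRAP_RESAMPLES,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Confidence interval for Spearman's rho.

    ``method="bootstrap"``: seeded percentile bootstrap over subject pairs.
    ``method="fisher"``: tanh(atanh(rho) +/- z / sqrt(n - 3)); its bounds
    always lie inside [-1, 1].
    """
    x, y = _check_xy(x, y, min_n=4)
    n = x.size
    alpha = 1.0 - level
    if method == "bootstrap":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        rhos = _bootstrap_rhos(x, y, n_resamples, rng)
        if rhos.size == 0:
            raise DegenerateInputError("all bootstrap resamples degenerate")
        lo, hi = np.quantile(rhos, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)
    if method == "fisher":
        rho = spearman_rho(x, y)
        if abs(rho) >= 1.0:
            return (rho, rho)
        z = sps.norm.ppf(1 - alpha / 2)
        zr = math.atanh(rho)
        half = z / math.sqrt(n - 3)
        return (math.tanh(zr - half), math.tanh(zr + half))
    raise ValueError(f"unknown CI method {method!r}")


def classify_strength(rho: float) -> str:
    """Strength label from |rho| per the study's category bounds."""
    if math.isnan(rho) or not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho {rho} outside [-1, 1]")
    a = abs(rho)
    for label, lower in STRENGTH_THRESHOLDS:
        if a >= lower:
            return label
    return "weak"


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; the default pipeline applies none)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _cell(
    sub: pd.DataFrame,
    feature: str,
    index: str,
    subgroup: str,
    ci_method: str,
    n_resamples: int,
    rng: np.random.Generator,
    p_method: str,
) -> CorrelationResult | None:
    pair = sub[[feature, index]].dropna()
    n = len(pair)
    if n < MIN_SUBJECTS_PER_CELL:
        logger.warning(
            "cell (%s, %s, %s) omitted: only %d usable subjects", feature, index, subgroup, n
        )
        return None
    x = pair[feature].to_numpy()
    y = pair[index].to_numpy()
    try:
        rho = spearman_rho(x, y)
        p = spearman_p(x, y, method=p_method)
        lo, hi = rho_ci(x, y, method=ci_method, n_resamples=n_resamples, seed=rng)
    except DegenerateInputError as exc:
        logger.warning("cell (%s, %s, %s) degenerate: %s", feature, index, subgroup, exc)
        return None
    return CorrelationResult(
        feature=feature,
        index=index,
        subgroup=subgroup,
        n=n,
        rho=rho,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        strength=classify_strength(rho),
        significant=p < SIGNIFICANCE_ALPHA,
    )


def correlation_table(
    subjects: pd.DataFrame,
    group_by_machine: bool = True,
    ci_method: str = "bootstrap",
    n_resamples: int = DEFAULT_BOOTSTRAP_RESAMPLES,
    seed: int = 0,
    p_method: str = "t",
    adjust: str | None = None,
) -> list[CorrelationResult]:
    """Correlate every Q-LUS feature with every oxygenation index.

    ``subjects`` is a subject-level DataFrame carrying the six feature
    columns, ``osi``/``sf_ratio`` (NaN when unavailable) and ``machine_id``.
    Emits one result per (feature x index x subgroup); subgroups are the
    overall cohort plus each ultrasound machine when ``group_by_machine``.
    Subjects missing a value are dropped pairwise per cell; cells below the
    minimum subject count are omitted with a logged warning.
    """
    required = set(FEATURES) | set(INDICES)
    missing = required - set(subjects.columns)
    if missing:
        raise ShapeError(f"subject table missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    groups: list[tuple[str, pd.DataFrame]] = [("overall", subjects)]
    if group_by_machine and "machine_id" in subjects.columns:
        for machine, sub in subjects.groupby("machine_id", sort=True):
            groups.append((str(machine), sub))
    results: list[CorrelationResult] = []
    for subgroup, sub in groups:
        for feature in FEATURES:
            for index in INDICES:
                res = _cell(sub, feature, index, subgroup, ci_method, n_resamples, rng, p_method)
                if res is not None:
                    results.append(res)
    if adjust == "bh" and results:
        adj = benjamini_hochberg(np.array([r.p_value for r in results]))
        results = [
            CorrelationResult(
                feature=r.feature,
                index=r.index,
                subgroup=r.subgroup,
                n=r.n,
                rho=r.rho,
                ci_low=r.ci_low,
                ci_high=r.ci_high,
                p_value=float(q),
                strength=r.strength,
                significant=bool(q < SIGNIFICANCE_ALPHA),
            )
            for r, q in zip(results, adj)
        ]
    elif adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results


def results_to_long(results: list[CorrelationResult]) -> pd.DataFrame:
    """Long-format table: one row per (feature, index, subgroup) cell."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "index": r.index,
                "subgroup": r.subgroup,
                "n": r.n,
                "rho": r.rho,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "strength": r.strength,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def results_to_wide(results: list[CorrelationResult]) -> pd.DataFrame:
    """Study-style wide rendering: features x (subgroup, index) cells.

    Significant cells show "rho (ci_low, ci_high)"; non-significant cells
    render as "NS".
    """
    cells: dict[str, dict[tuple[str, str], str]] = {f: {} for f in FEATURES}
    for r in results:
        if r.significant:
            text = f"{r.rho:.2f} ({r.ci_low:.2f},{r.ci_high:.2f})"
        else:
            text = "NS"
        cells[r.feature][(r.subgroup, r.index)] = text
    columns = sorted({(r.subgroup, r.index) for r in results})
    table = pd.DataFrame(
        {col: [cells[f].get(col, "") for f in FEATURES] for col in columns},
        index=list(FEATURES),
    )
    table.columns = pd.MultiIndex.from_tuples(columns, names=["subgroup", "index"])
    return table
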