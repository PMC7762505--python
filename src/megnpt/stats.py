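"""Resampling inference: bootstrap tests, bootstrap correlations, BH-FDR.

Small-cohort inference is done by a nonparametric bootstrap rather than
parametric t / Pearson tests: participants are resampled with replacement
(20,000 times by default) and the significance level of a statistic is the
fraction of resampled statistics in the *smaller* of the two tails around
zero — reported as-is, without doubling, with an optional conventional
two-sided variant.  Multiplicity across the family of variable pairs is
controlled with the Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BootstrapResult",
    "bootstrap_mean_test",
    "bootstrap_correlation",
    "bh_fdr",
    "pairwise_association_scan",
]

_CHUNK = 4000  # resamples per vectorised block, bounds peak memory


@dataclass(frozen=True)
class BootstrapResult:
    """Observed statistic with its smaller-tail bootstrap p-value.

    ``n_degenerate`` counts resamples contributing to neither tail: means
    exactly zero for the mean test, or resamples where the correlation is
    undefined (zero variance) for the correlation test.
    """

    statistic: float
    p_value: float
    n_resamples: int
    n_degenerate: int
    seed: int | None


def _tail_p(n_pos: int, n_neg: int, n_resamples: int, two_sided: bool) -> float:
    p = min(n_pos, n_neg) / n_resamples
    if two_sided:
        p = min(1.0, 2.0 * p)
    return p


def bootstrap_mean_test(
    values: Sequence[float],
    n_resamples: int = 20000,
    seed: int | None = None,
    two_sided: bool = False,
) -> BootstrapResult:
    """Bootstrap one-sample test of the mean against zero.

    The mean is recomputed on ``n_resamples`` resamples drawn with
    replacement; the p-value is the smaller of the fractions of resampled
    means above and below zero.  Resampled means exactly zero fall in
    neither tail and are counted in ``n_degenerate``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("bootstrap_mean_test requires at least 2 finite values")
    if n_resamples < 1:
        raise ValueError("n_resamples must be at least 1")
    rng = np.random.default_rng(seed)
    n_pos = n_neg = 0
    for start in range(0, n_resamples, _CHUNK):
        b = min(_CHUNK, n_resamples - start)
        idx = rng.integers(0, x.size, size=(b, x.size))
        means = x[idx].mean(axis=1)
        n_pos += int(np.sum(means > 0))
        n_neg += int(np.sum(means < 0))
    return BootstrapResult(
        statistic=float(x.mean()),
        p_value=_tail_p(n_pos, n_neg, n_resamples, two_sided),
        n_resamples=n_resamples,
        n_degenerate=n_resamples - n_pos - n_neg,
        seed=seed,
    )


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally shaped 2-D arrays.

    Rows with zero variance in either array yield NaN.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = np.sum(xc * yc, axis=1)
    den = np.sqrt(np.sum(xc**2, axis=1) * np.sum(yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def bootstrap_correlation(
    x: Sequence[float],
    y: Sequence[float],
    n_resamples: int = 20000,
    seed: int | None = None,
    two_sided: bool = False,
) -> BootstrapResult:
    """Paired bootstrap of the Pearson correlation coefficient.

    Participants (x, y pairs) are resampled jointly; the p-value is the
    smaller-tail fraction of resampled coefficients around zero.  Resamples
    where either variable is constant leave the coefficient undefined; they
    are skipped and counted in ``n_degenerate``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("x and y must be finite (drop incomplete cases first)")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined: constant input vector")
    if n_resamples < 1:
        raise ValueError("n_resamples must be at least 1")
    observed = float(np.corrcoef(xa, ya)[0, 1])
    rng = np.random.default_rng(seed)
    n_pos = n_neg = n_nan = 0
    for start in range(0, n_resamples, _CHUNK):
        b = min(_CHUNK, n_resamples - start)
        idx = rng.integers(0, xa.size, size=(b, xa.size))
        r = _pearson_rows(xa[idx], ya[idx])
        n_pos += int(np.sum(r > 0))
        n_neg += int(np.sum(r < 0))
        n_nan += int(np.sum(np.isnan(r)))
    return BootstrapResult(
        statistic=observed,
        p_value=_tail_p(n_pos, n_neg, n_resamples, two_sided),
        n_resamples=n_resamples,
        n_degenerate=n_resamples - n_pos - n_neg,
        seed=seed,
    )


def bh_fdr(
    p_values: Sequence[float], q_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up control of the false discovery rate.

    Returns ``(q_values, reject)`` where q-values are the monotone-enforced
    adjusted p-values and ``reject`` marks the hypotheses rejected at
    ``q_level``: all hypotheses up to the largest sorted index i with
    ``p_(i) <= i * q / m``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q_level < 1:
        raise ValueError("q_level must lie in (0, 1)")
    reject, q_values, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q_values, reject


def _pair_seed(master: int, a: str, b: str) -> int:
    """Deterministic per-pair seed, invariant to scan order (< 2**31)."""
    lo, hi = sorted((str(a), str(b)))
    return zlib.crc32(f"{master}:{lo}|{hi}".encode()) & 0x7FFFFFFF


def pairwise_association_scan(
    table: pd.DataFrame,
    variable_family: Sequence[str],
    n_resamples: int = 20000,
    seed: int = 0,
    q_level: float = 0.05,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Bootstrap-correlation scan over all unordered variable pairs.

    Each pair is tested on its complete cases with
    :func:`bootstrap_correlation` under a per-pair seed derived from the
    master seed and the pair labels (so results do not depend on scan
    order), and a single BH family across all tested pairs yields q-values
    and rejections at ``q_level``.

    Returns a table with columns ``var_x, var_y, n, r, p, q, reject,
    n_degenerate``, sorted canonically by pair label.
    """
    family = list(dict.fromkeys(variable_family))
    if len(family) < 2:
        raise ValueError("variable family must contain at least 2 variables")
    missing = [v for v in family if v not in table.columns]
    if missing:
        raise ValueError(f"variables not in table: {missing}")
    rows = []
    for a, b in combinations(sorted(family), 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"pair ({a}, {b}) has fewer than 3 complete cases")
        xa, ya = sub[a].to_numpy(dtype=float), sub[b].to_numpy(dtype=float)
        if np.ptp(xa) == 0 or np.ptp(ya) == 0:
            warnings.warn(
                f"pair ({a}, {b}) has a constant variable; correlation undefined",
                stacklevel=2,
            )
            rows.append(
                {"var_x": a, "var_y": b, "n": len(sub), "r": np.nan, "p": np.nan,
                 "n_degenerate": n_resamples}
            )
            continue
        res = bootstrap_correlation(
            xa,
            ya,
            n_resamples=n_resamples,
            seed=_pair_seed(seed, a, b),
            two_sided=two_sided,
        )
        rows.append(
            {
                "var_x": a,
                "var_y": b,
                "n": len(sub),
                "r": res.statistic,
                "p": res.p_value,
                "n_degenerate": res.n_degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    out["reject"] = False
    tested = out["p"].notna()
    q, reject = bh_fdr(out.loc[tested, "p"].to_numpy(), q_level=q_level)
    out.loc[tested, "q"] = q
    out.loc[tested, "reject"] = reject
    out["reject"] = out["reject"].astype(bool)
    return out.sort_values(["var_x", "var_y"], ignore_index=True)
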