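"""Rank-dependent inequality measurement: fractional ranks and
concentration indices.

The concentration index of an outcome ``y`` against a socioeconomic ranking
is ``C = 2 cov_w(y, r) / mu_w(y)`` where ``r`` is the weighted fractional
rank in the socioeconomic ordering and the covariance and mean are weighted
population moments.  ``C > 0`` means the outcome is concentrated among the
better-off.

Because standardized capacity scores have mean 0, the standard index is
undefined on them; the default variant therefore maps the outcome affinely
onto [0, 1] before computing the index (``shifted_minmax``).  An Erreygers
corrected variant (``4 * mu * C`` on the [0, 1] scale) is also available.
Every result names its variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

VARIANTS = ("standard", "shifted_minmax", "erreygers")


@dataclass
class ConcentrationResult:
    """A concentration index with its context and optional bootstrap CI."""

    value: float
    variant: str
    mu: float
    n: int
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    B: int | None = None
    seed: int | None = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        s = f"ConcentrationResult(value={self.value:.6g}, variant={self.variant!r}, n={self.n}"
        if self.ci_low is not None:
            s += f", 95% CI [{self.ci_low:.6g}, {self.ci_high:.6g}]"
        return s + ")"


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty input")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    return w


def fractional_rank(
    ranking_values: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted fractional ranks in (0, 1) of the socioeconomic ordering.

    In sorted order, ``r_i = (cumulative weight of strictly lower units +
    w_i / 2) / total weight``; tied units all receive the weighted average
    rank of their tie group.  The weighted mean of the ranks is exactly 0.5.
    """
    v = np.asarray(ranking_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    w = np.ones_like(v) if weights is None else _check_weights(weights)
    if w.shape != v.shape:
        raise ValueError("length mismatch between values and weights")
    order = np.argsort(v, kind="stable")
    vs, ws = v[order], w[order]
    total = ws.sum()
    cum_before = np.concatenate(([0.0], np.cumsum(ws)[:-1]))
    r_sorted = (cum_before + ws / 2.0) / total
    # tie groups share the weighted average of their midpoint ranks, which
    # equals (weight below the group + group weight / 2) / total
    starts = np.concatenate(([True], vs[1:] != vs[:-1]))
    gid = np.cumsum(starts) - 1
    gw = np.bincount(gid, weights=ws)
    gwr = np.bincount(gid, weights=ws * r_sorted)
    with np.errstate(invalid="ignore"):
        gmean = np.where(gw > 0, gwr / np.where(gw > 0, gw, 1.0), 0.0)
    # zero-weight units inside a zero-weight tie group keep the midpoint rank
    r_sorted = np.where(gw[gid] > 0, gmean[gid], r_sorted)
    ranks = np.empty_like(r_sorted)
    ranks[order] = r_sorted
    return ranks


def _weighted_cov(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    mx = float(np.dot(w, x) / wsum)
    my = float(np.dot(w, y) / wsum)
    return float(np.dot(w, (x - mx) * (y - my)) / wsum)


def minmax_scale(y: np.ndarray) -> np.ndarray:
    """Affine map of y onto [0, 1]; a constant vector maps to all zeros."""
    y = np.asarray(y, dtype=float)
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi == lo:
        return np.zeros_like(y)
    return (y - lo) / (hi - lo)


def concentration_index(
    y: np.ndarray,
    ranks: np.ndarray,
    weights: np.ndarray | None = None,
    variant: str = "shifted_minmax",
) -> ConcentrationResult:
    """Weighted concentration index of ``y`` against fractional ``ranks``."""
    y = np.asarray(y, dtype=float)
    r = np.asarray(ranks, dtype=float)
    if y.shape != r.shape:
        raise ValueError("length mismatch between y and ranks")
    w = np.ones_like(y) if weights is None else _check_weights(weights)
    if w.shape != y.shape:
        raise ValueError("length mismatch between y and weights")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")

    if variant == "standard":
        yv = y
    else:
        yv = minmax_scale(y)
    wsum = w.sum()
    mu = float(np.dot(w, yv) / wsum)
    if np.allclose(yv, yv[0] if yv.size else 0.0):
        c = 0.0
    elif mu <= 0:
        if variant == "standard":
            raise ValueError(
                "standard concentration index undefined for non-positive mean "
                "outcome (e.g. standardized scores); use variant "
                "'shifted_minmax' or 'erreygers'"
            )
        c = 0.0
    else:
        c = 2.0 * _weighted_cov(yv, r, w) / mu
    if variant == "erreygers":
        c = 4.0 * mu * c
    return ConcentrationResult(
        value=float(c), variant=variant, mu=mu, n=int(y.size)
    )


def bootstrap_ci(
    data: np.ndarray | "object",
    statistic: Callable[..., float],
    B: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    level: float = 0.95,
) -> tuple[float, float, float, int]:
    """Percentile bootstrap over participant-level resamples.

    ``data`` is an array or DataFrame resampled row-wise with replacement;
    ``statistic(resampled_data)`` returns the scalar of interest.  Returns
    ``(se, ci_low, ci_high, n_degenerate)`` where degenerate resamples (the
    statistic is NaN, e.g. a constant outcome) are counted and excluded from
    the percentiles.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for percentile intervals")
    n = len(data)
    rng = np.random.default_rng(seed)
    is_frame = hasattr(data, "iloc")
    vals = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx] if is_frame else np.asarray(data)[idx]
        vals[b] = statistic(sample)
    bad = ~np.isfinite(vals)
    n_degenerate = int(bad.sum())
    good = vals[~bad]
    if good.size == 0:
        return float("nan"), float("nan"), float("nan"), n_degenerate
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(good, [alpha, 1.0 - alpha])
    return float(good.std(ddof=1)) if good.size > 1 else 0.0, float(lo), float(hi), n_degenerate


def concentration_with_ci(
    y: np.ndarray,
    ranking_values: np.ndarray,
    weights: np.ndarray | None = None,
    variant: str = "shifted_minmax",
    B: int = 1000,
    seed: int = 0,
) -> ConcentrationResult:
    """Concentration index with a participant-level percentile bootstrap CI.

    Ranks are rebuilt inside each resample so rank uncertainty is included.
    """
    y = np.asarray(y, dtype=float)
    rv = np.asarray(ranking_values, dtype=float)
    w = np.ones_like(y) if weights is None else _check_weights(weights)
    point = concentration_index(y, fractional_rank(rv, w), w, variant)

    stacked = np.column_stack([y, rv, w])

    def stat(s: np.ndarray) -> float:
        ys, rvs, ws = s[:, 0], s[:, 1], s[:, 2]
        if np.allclose(ys, ys[0]):
            return np.nan
        return concentration_index(ys, fractional_rank(rvs, ws), ws, variant).value

    se, lo, hi, _ = bootstrap_ci(stacked, stat, B=B, seed=seed)
    point.se, point.ci_low, point.ci_high = se, lo, hi
    point.B, point.seed = B, seed if isinstance(seed, int) else None
    return point
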