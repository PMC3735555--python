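"""Between-class gene filtering.

The default filter is a per-gene Welch (unequal-variance) two-sample
t-test; genes whose p-value exceeds the cutoff are dropped before
discretization.  A Brown-Forsythe spread test is available for designs
where the discriminating structure leaves class means equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ExpressionMatrix, ValidationError

__all__ = ["FilterResult", "welch_t", "t_filter", "bf_filter", "FILTERS"]


@dataclass
class FilterResult:
    kept_gene_ids: list[str]
    p_values: dict[str, float]
    alpha: float
    adjusted: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError("alpha must lie in (0, 1]")


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t statistic, Welch-Satterthwaite df and two-sided p.

    *x*, *y* have shape (genes, samples).  Degenerate genes (both groups
    zero-variance) get p = 1 for equal means, p = 0 for unequal means.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    nx, ny = x.shape[1], y.shape[1]
    if nx < 2 or ny < 2:
        raise ValidationError("each class needs at least 2 samples for the t-test")
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    sx, sy = vx / nx, vy / ny
    se2 = sx + sy
    degenerate = se2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(degenerate, np.where(mx == my, 0.0, np.inf), t)
    p = np.where(degenerate, np.where(mx == my, 1.0, 0.0), p)
    df = np.where(degenerate, np.nan, df)
    return t, df, p


def _split(matrix: ExpressionMatrix, class_a: str, class_b: str) -> tuple[np.ndarray, np.ndarray]:
    ia = matrix.class_sample_indices(class_a)
    ib = matrix.class_sample_indices(class_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValidationError(
            f"classes {class_a!r}/{class_b!r} need >= 2 samples each for filtering"
        )
    return matrix.values[:, ia], matrix.values[:, ib]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _build_result(
    matrix: ExpressionMatrix, p: np.ndarray, alpha: float, adjust: str
) -> FilterResult:
    if adjust not in ("none", "bh"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    p_map = dict(zip(matrix.gene_ids, (float(v) for v in p)))
    if adjust == "bh":
        q = _bh_adjust(p)
        q_map = dict(zip(matrix.gene_ids, (float(v) for v in q)))
        kept = [g for g, v in zip(matrix.gene_ids, q) if v <= alpha]
        return FilterResult(kept, p_map, alpha, adjusted=q_map)
    kept = [g for g, v in zip(matrix.gene_ids, p) if v <= alpha]
    return FilterResult(kept, p_map, alpha)


def t_filter(
    matrix: ExpressionMatrix,
    class_a: str,
    class_b: str,
    alpha: float = 0.05,
    *,
    adjust: str = "none",
) -> FilterResult:
    """Keep genes whose Welch t-test p-value is <= *alpha*."""
    if not (0.0 < alpha <= 1.0):
        raise ValidationError("alpha must lie in (0, 1]")
    x, y = _split(matrix, class_a, class_b)
    _, _, p = welch_t(x, y)
    return _build_result(matrix, p, alpha, adjust)


def bf_filter(
    matrix: ExpressionMatrix,
    class_a: str,
    class_b: str,
    alpha: float = 0.05,
    *,
    adjust: str = "none",
) -> FilterResult:
    """Brown-Forsythe (median-centred Levene) filter on within-class spread.

    Complements :func:`t_filter` when classes differ in dispersion rather
    than location; implemented as a Welch t-test on per-sample absolute
    deviations from the class median.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValidationError("alpha must lie in (0, 1]")
    x, y = _split(matrix, class_a, class_b)
    dx = np.abs(x - np.median(x, axis=1, keepdims=True))
    dy = np.abs(y - np.median(y, axis=1, keepdims=True))
    _, _, p = welch_t(dx, dy)
    return _build_result(matrix, p, alpha, adjust)


FILTERS = {"t": t_filter, "bf": bf_filter}
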