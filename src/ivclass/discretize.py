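"""Per-gene discretization of expression values into intervals.

Every gene's real line is partitioned into left-open/right-closed
intervals ``(lo, hi]`` whose extremes are extended to +-infinity, so any
value (including unseen test values) falls into exactly one interval.

Methods
-------
``id3``
    Supervised recursive entropy splitting: candidate cuts are midpoints
    between consecutive distinct sorted values at class-boundary points;
    each node takes the cut maximizing information gain and recurses,
    stopping on purity, small nodes or non-positive gain.
``ewib``
    Equal-width interval binning between the observed min and max.
``none``
    Pass-through: one degenerate bin per distinct observed value (cuts at
    midpoints between consecutive distinct values).
``ternary``
    Down/normal/up cuts at mean -+ z * sd of the gene's values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, Interval, ValidationError

__all__ = [
    "IntervalScheme",
    "DiscretizedMatrix",
    "discretize_gene_id3",
    "discretize_gene_ewib",
    "discretize_gene_none",
    "discretize_gene_ternary",
    "build_scheme",
    "apply_scheme",
    "METHODS",
]

METHODS = ("id3", "ewib", "none", "ternary")

_GAIN_EPS = 1e-12  # a cut must beat this to count as positive gain


# --------------------------------------------------------------------------- #
# schemes
# --------------------------------------------------------------------------- #


@dataclass
class IntervalScheme:
    """Ordered cut points per gene, defining a partition of the real line."""

    method: str
    cuts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown discretization method {self.method!r}")
        for g, c in self.cuts.items():
            arr = np.asarray(c, dtype=float)
            if arr.ndim != 1 or (arr.size > 1 and not np.all(np.diff(arr) > 0)):
                raise ValidationError(f"cut points for gene {g!r} not strictly increasing")
            self.cuts[g] = arr

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cuts)

    def n_intervals(self, gene_id: str) -> int:
        return len(self.cuts[gene_id]) + 1

    def intervals(self, gene_id: str) -> list[Interval]:
        c = self.cuts[gene_id]
        bounds = np.concatenate(([-math.inf], c, [math.inf]))
        return [Interval(float(bounds[i]), float(bounds[i + 1])) for i in range(len(bounds) - 1)]

    def interval(self, gene_id: str, index: int) -> Interval:
        c = self.cuts[gene_id]
        if not (0 <= index <= len(c)):
            raise ValidationError(f"interval index {index} out of range for {gene_id!r}")
        lo = -math.inf if index == 0 else float(c[index - 1])
        hi = math.inf if index == len(c) else float(c[index])
        return Interval(lo, hi)

    def index_of(self, gene_id: str, interval: Interval) -> int:
        c = self.cuts[gene_id]
        i = len(c) if math.isinf(interval.hi) else int(np.searchsorted(c, interval.hi, side="left"))
        if 0 <= i <= len(c) and self.interval(gene_id, i) == interval:
            return i
        raise ValidationError(f"interval {interval} not part of the scheme for {gene_id!r}")

    def locate(self, gene_id: str, values: np.ndarray | float) -> np.ndarray:
        """Index of the unique interval containing each value ((lo, hi])."""
        scalar = np.isscalar(values)
        v = np.atleast_1d(np.asarray(values, dtype=float))
        idx = np.searchsorted(self.cuts[gene_id], v, side="left")
        return int(idx[0]) if scalar else idx


@dataclass
class DiscretizedMatrix:
    """Expression matrix with each cell replaced by its interval index."""

    gene_ids: list[str]
    sample_ids: list[str]
    labels: dict[str, str]
    cells: np.ndarray  # (genes, samples) int interval indices
    scheme: IntervalScheme

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int)
        if self.cells.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("cell matrix shape mismatch")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def class_sample_indices(self, label: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.labels[s] == label],
            dtype=int,
        )

    def sample_items(self, sample_index: int) -> dict[str, int]:
        """The (gene -> interval index) item set describing one sample."""
        col = self.cells[:, sample_index]
        return {g: int(col[i]) for i, g in enumerate(self.gene_ids)}


# --------------------------------------------------------------------------- #
# per-gene discretizers
# --------------------------------------------------------------------------- #


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _id3_recurse(
    values: np.ndarray,
    codes: np.ndarray,
    n_codes: int,
    min_leaf: int,
    out: list[float],
    trace: list[tuple[float, int]] | None,
) -> None:
    """Recursive splitter on value-sorted (values, label codes)."""
    n = values.size
    counts = np.bincount(codes, minlength=n_codes)
    if n < 2 * min_leaf or np.count_nonzero(counts) <= 1:
        return

    # group equal values; a cut is allowed between groups g and g+1 unless
    # both are pure with the same class (boundary-point restriction)
    group_start = np.flatnonzero(np.concatenate(([True], np.diff(values) != 0)))
    n_groups = group_start.size
    if n_groups < 2:
        return
    group_end = np.concatenate((group_start[1:], [n]))

    # per-group class counts, then prefix sums at group boundaries
    group_counts = np.zeros((n_groups, n_codes), dtype=np.int64)
    for gi in range(n_groups):
        group_counts[gi] = np.bincount(codes[group_start[gi]:group_end[gi]], minlength=n_codes)
    prefix = np.cumsum(group_counts, axis=0)

    pure_class = np.where(
        (group_counts > 0).sum(axis=1) == 1, np.argmax(group_counts > 0, axis=1), -1
    )
    boundary = ~(
        (pure_class[:-1] >= 0) & (pure_class[:-1] == pure_class[1:])
    )
    if not boundary.any():
        return

    parent_h = _entropy(counts)
    best_gain, best_cut = -math.inf, math.nan
    for b in np.flatnonzero(boundary):
        lo_v = values[group_end[b] - 1]
        hi_v = values[group_start[b + 1]]
        cut = (lo_v + hi_v) / 2.0
        if not (lo_v < cut < hi_v):
            continue  # adjacent floats: no representable cut between them
        left = prefix[b]
        right = counts - left
        nl, nr = int(left.sum()), int(right.sum())
        gain = parent_h - (nl * _entropy(left) + nr * _entropy(right)) / n
        if gain > best_gain + 1e-15:  # strict improvement; ties keep leftmost
            best_gain = gain
            best_cut = cut
    if best_gain <= _GAIN_EPS:
        return
    if trace is not None:
        trace.append((best_gain, n))
    split = int(np.searchsorted(values, best_cut, side="left"))
    _id3_recurse(values[:split], codes[:split], n_codes, min_leaf, out, trace)
    out.append(float(best_cut))
    _id3_recurse(values[split:], codes[split:], n_codes, min_leaf, out, trace)


def discretize_gene_id3(
    values: np.ndarray,
    labels: np.ndarray,
    min_leaf: int = 2,
    *,
    trace: list[tuple[float, int]] | None = None,
) -> np.ndarray:
    """Entropy-driven supervised cut points for one gene.

    *trace*, when given, collects ``(information_gain, node_size)`` for
    every accepted cut (used by the partition property tests).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size == 0:
        raise ValidationError("cannot discretize an empty value vector")
    if values.size != labels.size:
        raise ValidationError("values and labels differ in length")
    if min_leaf < 1:
        raise ValidationError("min_leaf must be >= 1")
    _, codes = np.unique(labels, return_inverse=True)
    order = np.argsort(values, kind="stable")
    out: list[float] = []
    _id3_recurse(values[order], codes[order], int(codes.max()) + 1, min_leaf, out, trace)
    return np.asarray(out, dtype=float)


def discretize_gene_ewib(values: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equal-width cuts between min and max; constant genes get no cut."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot discretize an empty value vector")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi or n_bins == 1:
        return np.empty(0)
    return lo + (hi - lo) * np.arange(1, n_bins) / n_bins


def discretize_gene_none(values: np.ndarray) -> np.ndarray:
    """One degenerate bin per distinct value: cuts at neighbour midpoints."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot discretize an empty value vector")
    distinct = np.unique(values)
    if distinct.size < 2:
        return np.empty(0)
    return (distinct[:-1] + distinct[1:]) / 2.0


def discretize_gene_ternary(values: np.ndarray, z: float = 1.0) -> np.ndarray:
    """Two cuts at mean -+ z*sd (population sd), for down/normal/up bins."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("ternary discretization needs >= 2 values")
    if z <= 0:
        raise ValidationError("z must be positive")
    mu, sd = float(values.mean()), float(values.std(ddof=0))
    if sd == 0.0:
        return np.empty(0)
    return np.array([mu - z * sd, mu + z * sd])


# --------------------------------------------------------------------------- #
# matrix-level operations
# --------------------------------------------------------------------------- #


def build_scheme(
    matrix: ExpressionMatrix,
    method: str = "id3",
    *,
    min_leaf: int = 2,
    n_bins: int = 5,
    ternary_z: float = 1.0,
    gene_ids: list[str] | None = None,
) -> IntervalScheme:
    """Discretize every (or the given) gene of *matrix* with one method.

    Class labels are consulted only by ``id3``; the scheme is global per
    gene — per-class structure enters later, at the mining stage.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown discretization method {method!r}")
    genes = list(matrix.gene_ids) if gene_ids is None else list(gene_ids)
    index = matrix.gene_index()
    y = matrix.label_array()
    cuts: dict[str, np.ndarray] = {}
    for g in genes:
        if g not in index:
            raise ValidationError(f"unknown gene ID {g!r}")
        v = matrix.values[index[g]]
        if method == "id3":
            cuts[g] = discretize_gene_id3(v, y, min_leaf)
        elif method == "ewib":
            cuts[g] = discretize_gene_ewib(v, n_bins)
        elif method == "none":
            cuts[g] = discretize_gene_none(v)
        else:
            cuts[g] = discretize_gene_ternary(v, ternary_z) if v.size >= 2 else np.empty(0)
    return IntervalScheme(method=method, cuts=cuts)


def apply_scheme(matrix: ExpressionMatrix, scheme: IntervalScheme) -> DiscretizedMatrix:
    """Map every cell to the index of the unique interval containing it."""
    index = matrix.gene_index()
    genes = scheme.gene_ids
    cells = np.empty((len(genes), matrix.n_samples), dtype=int)
    for i, g in enumerate(genes):
        if g not in index:
            raise ValidationError(f"matrix lacks gene {g!r} required by the scheme")
        cells[i] = scheme.locate(g, matrix.values[index[g]])
    return DiscretizedMatrix(
        gene_ids=genes,
        sample_ids=list(matrix.sample_ids),
        labels=dict(matrix.labels),
        cells=cells,
        scheme=scheme,
    )
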