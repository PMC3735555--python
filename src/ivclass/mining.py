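"""Maximal frequent itemset mining over (gene, interval) transactions.

Each class's samples form one transaction database; an item is a
``(gene_id, interval_index)`` pair and a sample's transaction holds one
item per gene.  Mining is a depth-first traversal of the itemset lattice
with bitmap transaction lists and the classic maximal-mining prunings:
head-union-tail (HUT) subtree lookahead, parent-equivalence pruning,
dynamic tail reordering and subsumption checks against the growing
maximal set (held as packed bit masks for vectorized subset tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .data import ValidationError
from .discretize import DiscretizedMatrix, IntervalScheme

__all__ = [
    "Item",
    "TransactionDB",
    "MFISet",
    "support",
    "filter_small_intervals",
    "mine_mfi",
]

Item = tuple[str, int]  # (gene_id, interval index)


@dataclass
class TransactionDB:
    """Item-set transactions for the samples of one class."""

    transactions: list[frozenset[Item]]
    class_label: str | None = None

    def __post_init__(self) -> None:
        for t in self.transactions:
            genes = [g for g, _ in t]
            if len(set(genes)) != len(genes):
                raise ValidationError("a transaction holds more than one item per gene")

    @classmethod
    def from_discretized(cls, dmatrix: DiscretizedMatrix, class_label: str) -> "TransactionDB":
        idx = dmatrix.class_sample_indices(class_label)
        if idx.size == 0:
            raise ValidationError(f"no samples with class label {class_label!r}")
        txns = [
            frozenset((g, int(dmatrix.cells[i, j])) for i, g in enumerate(dmatrix.gene_ids))
            for j in idx
        ]
        return cls(transactions=txns, class_label=class_label)

    def items(self) -> list[Item]:
        """Sorted universe of items present in at least one transaction."""
        universe: set[Item] = set()
        for t in self.transactions:
            universe |= t
        return sorted(universe)

    def __len__(self) -> int:
        return len(self.transactions)


@dataclass
class MFISet:
    itemsets: list[frozenset[Item]] = field(default_factory=list)
    min_support: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 < self.min_support <= 1.0):
            raise ValidationError("min_support must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.itemsets)


def support(itemset: Iterable[Item], db: TransactionDB) -> float:
    """Fraction of transactions that are supersets of *itemset*."""
    s = frozenset(itemset)
    if not db.transactions:
        return 0.0
    return sum(1 for t in db.transactions if s <= t) / len(db.transactions)


def filter_small_intervals(
    db: TransactionDB,
    min_interval_size: float = 0.05,
    *,
    mode: str = "coverage",
    scheme: IntervalScheme | None = None,
    gene_ranges: dict[str, tuple[float, float]] | None = None,
) -> TransactionDB:
    """Drop items whose interval is too small to be trustworthy.

    ``coverage`` (default): an item must cover at least
    ``min_interval_size`` of the class's samples.  ``width``: the
    interval's finite width must be at least that fraction of the gene's
    observed training range (infinite-width extremes always pass);
    requires *scheme* and *gene_ranges*.
    """
    if not (0.0 <= min_interval_size <= 1.0):
        raise ValidationError("min_interval_size must lie in [0, 1]")
    n = len(db.transactions)
    if n == 0:
        return TransactionDB(transactions=[], class_label=db.class_label)
    if mode == "coverage":
        counts: dict[Item, int] = {}
        for t in db.transactions:
            for it in t:
                counts[it] = counts.get(it, 0) + 1
        keep = {it for it, c in counts.items() if c / n >= min_interval_size}
    elif mode == "width":
        if scheme is None or gene_ranges is None:
            raise ValidationError("width mode needs the scheme and per-gene ranges")
        keep = set()
        for t in db.transactions:
            for it in t:
                gene, idx = it
                iv = scheme.interval(gene, idx)
                if math.isinf(iv.lo) or math.isinf(iv.hi):
                    keep.add(it)
                    continue
                lo, hi = gene_ranges[gene]
                span = hi - lo
                if span <= 0 or (iv.hi - iv.lo) / span >= min_interval_size:
                    keep.add(it)
    else:
        raise ValidationError(f"unknown interval-size mode {mode!r}")
    return TransactionDB(
        transactions=[frozenset(it for it in t if it in keep) for t in db.transactions],
        class_label=db.class_label,
    )


def _min_count(min_support: float, n: int) -> int:
    # smallest integer count with count / n >= min_support (float-tolerant)
    return max(1, math.ceil(min_support * n - 1e-9))


class _MaximalStore:
    """Maximal itemsets as packed uint64 bit masks for fast subset tests.

    Single-word (<= 64 items) databases use a flat uint64 array; wider
    universes fall back to a (rows, words) matrix.
    """

    def __init__(self, n_items: int) -> None:
        self.words = max(1, (n_items + 63) // 64)
        self.count = 0
        if self.words == 1:
            self._flat = np.empty(256, dtype=np.uint64)
        else:
            self._rows = np.empty((256, self.words), dtype=np.uint64)

    def _pack(self, mask: int) -> np.ndarray:
        row = np.empty(self.words, dtype=np.uint64)
        for w in range(self.words):
            row[w] = (mask >> (64 * w)) & 0xFFFFFFFFFFFFFFFF
        return row

    def subsumed(self, mask: int) -> bool:
        """Is *mask* a subset of any stored itemset?"""
        if not self.count:
            return False
        if self.words == 1:
            m = np.uint64(mask)
            arr = self._flat[: self.count]
            return bool(((arr & m) == m).any())
        row = self._pack(mask)
        m2 = self._rows[: self.count]
        return bool(np.any(np.all((m2 & row) == row, axis=1)))

    def add(self, mask: int) -> None:
        """Insert *mask*, dropping any stored strict subsets of it."""
        if self.words == 1:
            m = np.uint64(mask)
            if self.count:
                arr = self._flat[: self.count]
                keep = (arr & m) != arr
                if not keep.all():
                    kept = arr[keep]
                    self.count = kept.shape[0]
                    self._flat[: self.count] = kept
            if self.count == self._flat.shape[0]:
                self._flat = np.concatenate([self._flat, np.empty_like(self._flat)])
            self._flat[self.count] = m
            self.count += 1
            return
        row = self._pack(mask)
        if self.count:
            m2 = self._rows[: self.count]
            keep = ~np.all((m2 & row) == m2, axis=1)
            if not keep.all():
                kept = m2[keep]
                self.count = kept.shape[0]
                self._rows[: self.count] = kept
        if self.count == self._rows.shape[0]:
            self._rows = np.vstack([self._rows, np.empty_like(self._rows)])
        self._rows[self.count] = row
        self.count += 1

    def masks(self) -> list[int]:
        if self.words == 1:
            return [int(v) for v in self._flat[: self.count]]
        out = []
        for r in range(self.count):
            mask = 0
            for w in range(self.words):
                mask |= int(self._rows[r, w]) << (64 * w)
            out.append(mask)
        return out


def mine_mfi(db: TransactionDB, min_support: float = 0.4) -> MFISet:
    """Exactly the maximal frequent itemsets of *db* at *min_support*.

    Deterministic: output sorted by size descending, then lexicographic.
    """
    result = MFISet(itemsets=[], min_support=min_support)
    n = len(db.transactions)
    if n == 0:
        return result
    items = db.items()
    if not items:
        return result

    bitmaps_by_item: dict[Item, int] = {it: 0 for it in items}
    for j, t in enumerate(db.transactions):
        bit = 1 << j
        for it in t:
            bitmaps_by_item[it] |= bit
    minc = _min_count(min_support, n)

    # static order: decreasing support then lexicographic; frequent only
    frequent = sorted(
        (it for it in items if bitmaps_by_item[it].bit_count() >= minc),
        key=lambda it: (-bitmaps_by_item[it].bit_count(), it),
    )
    if not frequent:
        return result
    k = len(frequent)
    bitmaps = [bitmaps_by_item[it] for it in frequent]
    store = _MaximalStore(k)
    full = (1 << n) - 1

    def dfs(head_mask: int, head_bits: int, tail: list[int]) -> None:
        # parent equivalence: absorb tail items present in every head
        # transaction, and keep only frequent extensions
        exts: list[tuple[int, int]] = []
        for i in tail:
            b = head_bits & bitmaps[i]
            c = b.bit_count()
            if c < minc:
                continue
            if b == head_bits:
                head_mask |= 1 << i
            else:
                exts.append((i, b))
        if not exts:
            if head_mask and not store.subsumed(head_mask):
                store.add(head_mask)
            return
        union = head_mask
        for i, _ in exts:
            union |= 1 << i
        if store.subsumed(union):
            return  # everything below is inside a known maximal itemset
        # HUT lookahead: if head plus the whole tail is frequent, record it
        hut = head_bits
        for _, b in exts:
            hut &= b
            if hut.bit_count() < minc:
                break
        if hut.bit_count() >= minc:
            store.add(union)
            return
        # dynamic reordering: most frequent extension first
        exts.sort(key=lambda e: -e[1].bit_count())
        rest = [i for i, _ in exts]
        for idx, (i, b) in enumerate(exts):
            dfs(head_mask | (1 << i), b, rest[idx + 1:])

    dfs(0, full, list(range(k)))

    itemsets = []
    for mask in store.masks():
        itemsets.append(frozenset(frequent[i] for i in range(k) if mask >> i & 1))
    result.itemsets = sorted(itemsets, key=lambda s: (-len(s), sorted(s)))
    return result
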