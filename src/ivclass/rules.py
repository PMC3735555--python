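"""From per-class maximal frequent itemsets to pruned association rules.

Each MFI of class ``c`` becomes one candidate rule ``antecedent -> c``.
Support is the class-local containment fraction; confidence is computed
over the whole training set, ``P(class = c | sample contains antecedent)``.
The leave-one-gene-out pruner then greedily removes antecedent items whose
absence does not hurt training accuracy.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .classify import SCORE_VARIANTS
from .data import Rule, RuleItem, RuleSet, ValidationError
from .discretize import DiscretizedMatrix
from .mining import Item, MFISet

__all__ = ["rules_from_mfis", "loo_prune_rules"]


class _ItemIndicators:
    """Lazily cached per-item boolean containment vectors over samples."""

    def __init__(self, dmatrix: DiscretizedMatrix) -> None:
        self._dm = dmatrix
        self._row = {g: i for i, g in enumerate(dmatrix.gene_ids)}
        self._cache: dict[Item, np.ndarray] = {}

    def __call__(self, item: Item) -> np.ndarray:
        vec = self._cache.get(item)
        if vec is None:
            gene, idx = item
            if gene not in self._row:
                raise ValidationError(f"discretized matrix lacks gene {gene!r}")
            vec = self._dm.cells[self._row[gene]] == idx
            self._cache[item] = vec
        return vec

    def containment(self, itemset: Sequence[Item]) -> np.ndarray:
        mask = np.ones(len(self._dm.sample_ids), dtype=bool)
        for item in itemset:
            mask &= self(item)
        return mask


def _items_to_antecedent(dmatrix: DiscretizedMatrix, itemset: Sequence[Item]) -> tuple[RuleItem, ...]:
    return tuple(
        RuleItem(gene, dmatrix.scheme.interval(gene, idx)) for gene, idx in sorted(itemset)
    )


def rules_from_mfis(
    mfis_by_class: Mapping[str, MFISet],
    dmatrix: DiscretizedMatrix,
    min_confidence: float = 0.05,
) -> RuleSet:
    """One candidate rule per MFI; keep those meeting *min_confidence*.

    Candidates contained in zero training samples are dropped (their
    confidence is undefined).
    """
    if not (0.0 <= min_confidence <= 1.0):
        raise ValidationError("min_confidence must lie in [0, 1]")
    ind = _ItemIndicators(dmatrix)
    y = np.array([dmatrix.labels[s] for s in dmatrix.sample_ids], dtype=object)
    rules: list[Rule] = []
    for c in sorted(mfis_by_class):
        in_class = y == c
        n_class = int(in_class.sum())
        for itemset in mfis_by_class[c].itemsets:
            mask = ind.containment(sorted(itemset))
            total = int(mask.sum())
            if total == 0:
                continue
            hits = int(mask[in_class].sum())
            conf = hits / total
            if conf < min_confidence:
                continue
            rules.append(
                Rule(
                    antecedent=_items_to_antecedent(dmatrix, itemset),
                    consequent_class=c,
                    support=hits / n_class,
                    confidence=conf,
                )
            )
    return RuleSet(rules=rules, min_confidence=min_confidence)


def _canonical_rule_order(rules: Sequence[Rule]) -> list[int]:
    return sorted(
        range(len(rules)),
        key=lambda i: (
            -len(rules[i].antecedent),
            rules[i].consequent_class,
            tuple((it.gene_id, it.interval.lo, it.interval.hi) for it in rules[i].antecedent),
        ),
    )


def loo_prune_rules(
    ruleset: RuleSet,
    dmatrix: DiscretizedMatrix,
    variant: str = "f1",
    *,
    max_passes: int = 50,
) -> RuleSet:
    """Greedy leave-one-gene-out pruning of rule antecedents.

    For each rule (canonical order: larger first) and each of its items in
    lexicographic gene order, tentatively drop the item and re-evaluate
    training accuracy with the modified rule set; keep the removal when
    accuracy does not decrease.  A rule is never reduced below one item.
    Afterwards support/confidence are recomputed; rules falling below the
    confidence threshold (or duplicating another antecedent) are dropped.
    The whole procedure repeats until the rule set stops changing, so the
    operation is idempotent.

    Prediction with a fixed rule set does not depend on the other training
    samples, so held-one-out accuracy over the training set equals plain
    training accuracy; the latter is what is computed here.
    """
    prev: list[Rule] | None = None
    current = ruleset
    for _ in range(10):
        if prev is not None and current.rules == prev:
            break
        prev = current.rules
        current = _prune_once(current, dmatrix, variant, max_passes=max_passes)
    return current


def _prune_once(
    ruleset: RuleSet,
    dmatrix: DiscretizedMatrix,
    variant: str = "f1",
    *,
    max_passes: int = 50,
) -> RuleSet:
    fn = SCORE_VARIANTS.get(variant)
    if fn is None:
        raise ValidationError(f"unknown score variant {variant!r}")
    classes = dmatrix.classes
    if len(classes) < 2 or not ruleset.rules:
        return ruleset
    n = len(dmatrix.sample_ids)
    y_true = np.array([dmatrix.labels[s] for s in dmatrix.sample_ids], dtype=object)
    class_counts = {c: int((y_true == c).sum()) for c in classes}
    # tie preference: majority class first, then lexicographic label
    pref = sorted(classes, key=lambda c: (-class_counts[c], c))
    pidx = {c: i for i, c in enumerate(pref)}
    y_pref = np.array([pidx[v] for v in y_true])
    ind = _ItemIndicators(dmatrix)

    order = _canonical_rule_order(ruleset.rules)
    work: list[dict] = []
    n_rules = np.zeros(len(pref))
    for i in order:
        r = ruleset.rules[i]
        items: list[Item] = [
            (it.gene_id, dmatrix.scheme.index_of(it.gene_id, it.interval))
            for it in r.antecedent
        ]
        m = np.zeros(n)
        for item in items:
            m = m + ind(item)
        ci = pidx[r.consequent_class]
        n_rules[ci] += 1
        work.append({"ci": ci, "class": r.consequent_class, "items": items, "m": m})

    sums = np.zeros((len(pref), n))
    for w in work:
        w["term"] = np.asarray(fn(w["m"] / len(w["items"])), dtype=float)
        sums[w["ci"]] += w["term"]
    inv = np.where(n_rules > 0, 1.0 / np.maximum(n_rules, 1), 0.0)[:, None]

    two_class = len(pref) == 2
    if two_class:
        want_first = y_pref == 0  # samples whose true class is the preferred one

    def accuracy(s: np.ndarray) -> float:
        if two_class:
            # ties go to the preferred (majority-first) class
            first = s[0] * inv[0, 0] >= s[1] * inv[1, 0]
            return float(np.mean(first == want_first))
        pred = np.argmax(s * inv, axis=0)
        return float(np.mean(pred == y_pref))

    acc = accuracy(sums)
    trial = sums.copy()
    for _ in range(max_passes):
        changed = False
        for w in work:
            ci = w["ci"]
            # walk items in lexicographic gene order; after an accepted
            # removal continue with the items after it (suffix), evaluating
            # every candidate removal of the suffix in one batch
            pos = 0
            while len(w["items"]) > 1:
                items = sorted(w["items"])
                if pos >= len(items):
                    break
                suffix = items[pos:]
                stack = np.stack([ind(it) for it in suffix]).astype(float)
                m_all = w["m"][None, :] - stack  # (|suffix|, n)
                term_all = np.asarray(fn(m_all / (len(items) - 1)), dtype=float)
                base = sums[ci] - w["term"]
                if two_class:
                    scores_all = (base[None, :] + term_all) * inv[ci, 0]
                    other = sums[1 - ci] * inv[1 - ci, 0]
                    if ci == 0:
                        first = scores_all >= other[None, :]
                    else:
                        first = other[None, :] >= scores_all
                    acc_all = np.mean(first == want_first[None, :], axis=1)
                else:
                    acc_all = np.empty(len(suffix))
                    for t_i in range(len(suffix)):
                        np.copyto(trial, sums)
                        trial[ci] = base + term_all[t_i]
                        acc_all[t_i] = accuracy(trial)
                hit = np.flatnonzero(acc_all >= acc)
                if hit.size == 0:
                    break
                j = int(hit[0])
                w["items"].remove(suffix[j])
                w["m"] = m_all[j]
                sums[ci] = base + term_all[j]
                w["term"] = term_all[j]
                acc = float(acc_all[j])
                changed = True
                pos += j
        if not changed:
            break

    # rebuild: recompute stats, enforce min_confidence, drop duplicates
    pruned: list[Rule] = []
    seen: set[tuple] = set()
    for w in work:
        items = sorted(w["items"])
        key = (w["class"], tuple(items))
        if key in seen:
            continue
        seen.add(key)
        mask = ind.containment(items)
        total = int(mask.sum())
        if total == 0:
            continue
        in_class = y_true == w["class"]
        hits = int(mask[in_class].sum())
        conf = hits / total
        if conf < ruleset.min_confidence:
            continue
        pruned.append(
            Rule(
                antecedent=_items_to_antecedent(dmatrix, items),
                consequent_class=w["class"],
                support=hits / int(in_class.sum()),
                confidence=conf,
            )
        )
    order = _canonical_rule_order(pruned)
    return RuleSet(rules=[pruned[i] for i in order], min_confidence=ruleset.min_confidence)
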