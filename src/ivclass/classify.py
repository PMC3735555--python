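"""Rule-satisfaction scoring and class assignment.

A sample is scored against class ``c`` as the mean, over the class's
rules, of a satisfaction function of the matched-item fraction
``m / |antecedent|``:

* ``f1`` — the fraction itself (linear partial credit);
* ``f2`` — the squared fraction (rewards near-complete satisfaction).

The sample is assigned to the class whose rules are maximally satisfied;
ties break toward the class with more training samples, then toward the
lexicographically smaller label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .data import Rule, RuleSet, ValidationError

__all__ = [
    "ClassScore",
    "SCORE_VARIANTS",
    "rule_match_fraction",
    "score",
    "predict",
    "predict_multiclass_ova",
    "score_matrix",
]

SCORE_VARIANTS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "f1": lambda x: x,
    "f2": lambda x: x * x,
}


@dataclass
class ClassScore:
    scores: dict[str, float]
    predicted_class: str
    margin: float

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValidationError("margin must be non-negative")


def _variant_fn(variant: str) -> Callable[[np.ndarray], np.ndarray]:
    try:
        return SCORE_VARIANTS[variant]
    except KeyError:
        raise ValidationError(f"unknown score variant {variant!r}") from None


def rule_match_fraction(sample: Mapping[str, float], rule: Rule) -> float:
    """``m / |antecedent|`` where m counts antecedent items containing the
    sample's expression value for that gene.

    *sample* maps gene_id -> expression value; every antecedent gene must
    be present.
    """
    m = 0
    for it in rule.antecedent:
        if it.gene_id not in sample:
            raise ValidationError(f"sample lacks gene {it.gene_id!r} required by a rule")
        if it.interval.contains(sample[it.gene_id]):
            m += 1
    return m / len(rule.antecedent)


def score(sample: Mapping[str, float], rules: Sequence[Rule], variant: str = "f1") -> float:
    """Mean rule satisfaction ``S(u, c)``; an empty rule list scores 0."""
    fn = _variant_fn(variant)
    if not rules:
        return 0.0
    total = 0.0
    for r in rules:
        total += float(fn(np.float64(rule_match_fraction(sample, r))))
    return total / len(rules)


def _rank_classes(
    scores: Mapping[str, float], class_counts: Mapping[str, int]
) -> list[str]:
    # best first: score desc, then training-size desc, then label asc
    return sorted(scores, key=lambda c: (-scores[c], -class_counts.get(c, 0), c))


def predict(
    sample: Mapping[str, float],
    ruleset: RuleSet | Mapping[str, Sequence[Rule]],
    class_counts: Mapping[str, int],
    variant: str = "f1",
) -> ClassScore:
    """Assign the class whose rules are maximally satisfied.

    *class_counts* must list every candidate class (classes with no rules
    score 0) and provides the majority tie-break.
    """
    by_class = ruleset.by_class() if isinstance(ruleset, RuleSet) else dict(ruleset)
    classes = sorted(set(class_counts) | set(by_class))
    if len(classes) < 2:
        raise ValidationError("prediction needs at least 2 candidate classes")
    scores = {c: score(sample, by_class.get(c, ()), variant) for c in classes}
    ranked = _rank_classes(scores, class_counts)
    best, second = ranked[0], ranked[1]
    return ClassScore(
        scores=scores,
        predicted_class=best,
        margin=scores[best] - scores[second],
    )


def predict_multiclass_ova(
    sample: Mapping[str, float],
    binary_scores: Mapping[str, tuple[float, float]],
    class_counts: Mapping[str, int],
) -> tuple[str, dict[str, float]]:
    """One-versus-all decision from per-class (S_class, S_rest) pairs.

    Each entry of *binary_scores* comes from a binary model of class k
    against the pooled rest; the prediction is the class with the largest
    margin ``S(u, k) - S(u, rest_k)``, same tie rule as :func:`predict`.
    """
    if len(binary_scores) < 2:
        raise ValidationError("one-versus-all needs at least 2 classes")
    margins = {c: s_own - s_rest for c, (s_own, s_rest) in binary_scores.items()}
    ranked = _rank_classes(margins, class_counts)
    return ranked[0], margins


# --------------------------------------------------------------------------- #
# vectorized scoring (shared by evaluation and pruning)
# --------------------------------------------------------------------------- #


def score_matrix(
    values: np.ndarray,
    gene_row: Mapping[str, int],
    rules_by_class: Mapping[str, Sequence[Rule]],
    classes: Sequence[str],
    variant: str = "f1",
) -> np.ndarray:
    """Scores for all samples at once: array of shape (classes, samples).

    *values* is the raw (genes, samples) matrix and *gene_row* maps
    gene_id -> row index within it.
    """
    fn = _variant_fn(variant)
    n = values.shape[1]
    out = np.zeros((len(classes), n))
    for ci, c in enumerate(classes):
        rules = rules_by_class.get(c, ())
        if not rules:
            continue
        acc = np.zeros(n)
        for r in rules:
            m = np.zeros(n)
            for it in r.antecedent:
                if it.gene_id not in gene_row:
                    raise ValidationError(
                        f"matrix lacks gene {it.gene_id!r} required by a rule"
                    )
                m += it.interval.contains_array(values[gene_row[it.gene_id]])
            acc += fn(m / len(r.antecedent))
        out[ci] = acc / len(rules)
    return out


def decide(
    scores: np.ndarray, classes: Sequence[str], class_counts: Mapping[str, int]
) -> np.ndarray:
    """Vectorized argmax with (majority, lexicographic) tie-breaking."""
    order = sorted(range(len(classes)), key=lambda i: (-class_counts.get(classes[i], 0), classes[i]))
    reordered = scores[order]
    winner = np.argmax(reordered, axis=0)  # first max wins -> preferred class
    labels = np.array([classes[i] for i in order], dtype=object)
    return labels[winner]
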