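"""End-to-end training pipeline and the persisted model artifact.

``fit`` chains gene filtering, discretization, interval-size filtering,
per-class maximal-itemset mining, rule generation and (optionally)
leave-one-gene-out pruning.  Binary problems train directly; with three or
more classes a one-versus-all ensemble of binary submodels is built, each
with its own filtering/discretization/mining.  Models persist as
versioned, human-auditable JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from . import __version__
from .classify import SCORE_VARIANTS, decide, score_matrix
from .data import (
    ExpressionMatrix,
    Interval,
    Rule,
    RuleItem,
    RuleSet,
    ValidationError,
    format_float,
    parse_float,
)
from .discretize import METHODS, IntervalScheme, apply_scheme, build_scheme
from .filtering import FILTERS
from .mining import TransactionDB, filter_small_intervals, mine_mfi
from .rules import loo_prune_rules, rules_from_mfis

__all__ = [
    "RunConfig",
    "BinaryModel",
    "OvaModel",
    "REST_LABEL",
    "fit",
    "fit_binary",
    "predict_labels",
    "save_model",
    "load_model",
]

log = logging.getLogger("ivclass")

REST_LABEL = "__rest__"
MODEL_FORMAT_VERSION = 1


@dataclass
class RunConfig:
    """All pipeline hyperparameters, with their default values."""

    alpha: float = 0.05
    adjust: str = "none"
    gene_filter: str = "t"
    discretizer: str = "id3"
    bins: int = 5
    min_leaf: int = 2
    ternary_z: float = 1.0
    minsup: float = 0.4
    min_interval_size: float = 0.05
    interval_size_mode: str = "coverage"
    min_confidence: float = 0.05
    score: str = "f1"
    prune: bool = True
    positive_class: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError("alpha must lie in (0, 1]")
        if self.adjust not in ("none", "bh"):
            raise ValidationError(f"unknown adjustment {self.adjust!r}")
        if self.gene_filter not in FILTERS:
            raise ValidationError(f"unknown gene filter {self.gene_filter!r}")
        if self.discretizer not in METHODS:
            raise ValidationError(f"unknown discretizer {self.discretizer!r}")
        if self.bins < 1 or self.min_leaf < 1:
            raise ValidationError("bins and min_leaf must be >= 1")
        if not (0.0 < self.minsup <= 1.0):
            raise ValidationError("minsup must lie in (0, 1]")
        for name in ("min_interval_size", "min_confidence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.interval_size_mode not in ("coverage", "width"):
            raise ValidationError(f"unknown interval_size_mode {self.interval_size_mode!r}")
        if self.score not in SCORE_VARIANTS:
            raise ValidationError(f"unknown score variant {self.score!r}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValidationError(f"unknown configuration keys: {unknown}")
        return cls(**mapping)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BinaryModel:
    classes: tuple[str, str]
    class_counts: dict[str, int]
    scheme: IntervalScheme
    ruleset: RuleSet
    config: RunConfig
    kept_genes: list[str] = field(default_factory=list)

    def rule_genes(self) -> list[str]:
        genes: set[str] = set()
        for r in self.ruleset.rules:
            genes.update(r.genes)
        return sorted(genes)

    def score_samples(self, matrix: ExpressionMatrix) -> np.ndarray:
        """(2, n_samples) scores in the order of ``self.classes``."""
        for g in self.rule_genes():
            if g not in set(matrix.gene_ids):
                raise ValidationError(f"input matrix lacks gene {g!r} used by the model")
        return score_matrix(
            matrix.values,
            matrix.gene_index(),
            self.ruleset.by_class(),
            list(self.classes),
            self.config.score,
        )

    def decision_statistic(self, matrix: ExpressionMatrix, positive: str) -> np.ndarray:
        """d(u) = S(u, positive) - S(u, negative) per sample."""
        if positive not in self.classes:
            raise ValidationError(f"unknown positive class {positive!r}")
        scores = self.score_samples(matrix)
        pi = self.classes.index(positive)
        return scores[pi] - scores[1 - pi]

    def predict_matrix(self, matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
        scores = self.score_samples(matrix)
        pred = decide(scores, list(self.classes), self.class_counts)
        return pred, scores


@dataclass
class OvaModel:
    classes: list[str]
    class_counts: dict[str, int]
    submodels: dict[str, BinaryModel]  # class k -> (k vs REST_LABEL) model
    config: RunConfig

    def margins(self, matrix: ExpressionMatrix) -> np.ndarray:
        """(K, n_samples) one-versus-all margins."""
        out = np.zeros((len(self.classes), matrix.n_samples))
        for ci, c in enumerate(self.classes):
            sub = self.submodels[c]
            scores = sub.score_samples(matrix)
            own = sub.classes.index(c)
            out[ci] = scores[own] - scores[1 - own]
        return out

    def predict_matrix(self, matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
        margins = self.margins(matrix)
        pred = decide(margins, self.classes, self.class_counts)
        return pred, margins


def fit_binary(matrix: ExpressionMatrix, config: RunConfig) -> BinaryModel:
    classes = matrix.classes
    if len(classes) != 2:
        raise ValidationError(f"binary training needs exactly 2 classes, got {classes}")
    a, b = classes
    filt = FILTERS[config.gene_filter](
        matrix, a, b, alpha=config.alpha, adjust=config.adjust
    )
    kept = filt.kept_gene_ids
    log.info("filter: kept %d/%d genes (alpha=%g)", len(kept), matrix.n_genes, config.alpha)

    scheme = build_scheme(
        matrix,
        config.discretizer,
        min_leaf=config.min_leaf,
        n_bins=config.bins,
        ternary_z=config.ternary_z,
        gene_ids=kept,
    )
    dmatrix = apply_scheme(matrix, scheme)
    if kept:
        mean_iv = sum(scheme.n_intervals(g) for g in kept) / len(kept)
        log.info("discretize (%s): %.2f intervals/gene", config.discretizer, mean_iv)

    gene_ranges = None
    if config.interval_size_mode == "width":
        gi = matrix.gene_index()
        gene_ranges = {
            g: (float(matrix.values[gi[g]].min()), float(matrix.values[gi[g]].max()))
            for g in kept
        }
    mfis = {}
    for c in classes:
        db = TransactionDB.from_discretized(dmatrix, c)
        db = filter_small_intervals(
            db,
            config.min_interval_size,
            mode=config.interval_size_mode,
            scheme=scheme,
            gene_ranges=gene_ranges,
        )
        mfis[c] = mine_mfi(db, config.minsup)
        log.info("mine: class %s -> %d maximal itemsets", c, len(mfis[c]))

    ruleset = rules_from_mfis(mfis, dmatrix, config.min_confidence)
    log.info("rules: %d candidates kept at min_confidence=%g", len(ruleset), config.min_confidence)
    if config.prune:
        ruleset = loo_prune_rules(ruleset, dmatrix, config.score)
        log.info("prune: %d rules after leave-one-gene-out pruning", len(ruleset))

    return BinaryModel(
        classes=(a, b),
        class_counts=matrix.class_counts(),
        scheme=scheme,
        ruleset=ruleset,
        config=config,
        kept_genes=kept,
    )


def fit(matrix: ExpressionMatrix, config: RunConfig) -> BinaryModel | OvaModel:
    """Train a binary model, or a one-versus-all ensemble for K > 2."""
    classes = matrix.classes
    if len(classes) < 2:
        raise ValidationError("training requires at least 2 classes")
    if len(classes) == 2:
        return fit_binary(matrix, config)
    if REST_LABEL in classes:
        raise ValidationError(f"class label {REST_LABEL!r} is reserved")
    submodels = {}
    for c in classes:
        binary = matrix.relabel({k: (c if k == c else REST_LABEL) for k in classes})
        log.info("one-versus-all: training %s vs rest", c)
        submodels[c] = fit_binary(binary, config)
    return OvaModel(
        classes=classes,
        class_counts=matrix.class_counts(),
        submodels=submodels,
        config=config,
    )


def predict_labels(model: BinaryModel | OvaModel, matrix: ExpressionMatrix) -> dict:
    """Per-sample predictions with scores and margins.

    Returns a dict with keys ``classes``, ``predicted`` (n,), ``scores``
    (K, n) and ``margin`` (n,).
    """
    pred, scores = model.predict_matrix(matrix)
    part = np.partition(scores, -2, axis=0) if scores.shape[0] > 1 else scores
    margin = part[-1] - part[-2]
    return {
        "classes": list(model.classes),
        "predicted": pred,
        "scores": scores,
        "margin": margin,
    }


# --------------------------------------------------------------------------- #
# model persistence (versioned JSON, human-auditable)
# --------------------------------------------------------------------------- #


def _scheme_to_json(scheme: IntervalScheme) -> dict:
    return {
        "method": scheme.method,
        "cuts": {g: [format_float(c) for c in scheme.cuts[g]] for g in scheme.gene_ids},
    }


def _scheme_from_json(obj: dict) -> IntervalScheme:
    return IntervalScheme(
        method=obj["method"],
        cuts={g: np.array([parse_float(c) for c in cs]) for g, cs in obj["cuts"].items()},
    )


def _ruleset_to_json(rs: RuleSet) -> dict:
    return {
        "min_confidence": rs.min_confidence,
        "rules": [
            {
                "class": r.consequent_class,
                "items": [
                    [it.gene_id, format_float(it.interval.lo), format_float(it.interval.hi)]
                    for it in r.antecedent
                ],
                "support": r.support,
                "confidence": r.confidence,
            }
            for r in rs.rules
        ],
    }


def _ruleset_from_json(obj: dict) -> RuleSet:
    rules = [
        Rule(
            antecedent=tuple(
                RuleItem(g, Interval(parse_float(lo), parse_float(hi)))
                for g, lo, hi in r["items"]
            ),
            consequent_class=r["class"],
            support=r["support"],
            confidence=r["confidence"],
        )
        for r in obj["rules"]
    ]
    return RuleSet(rules=rules, min_confidence=obj["min_confidence"])


def _binary_to_json(m: BinaryModel) -> dict:
    return {
        "kind": "binary",
        "classes": list(m.classes),
        "class_counts": m.class_counts,
        "kept_genes": m.kept_genes,
        "scheme": _scheme_to_json(m.scheme),
        "rules": _ruleset_to_json(m.ruleset),
        "config": m.config.to_dict(),
    }


def _binary_from_json(obj: dict) -> BinaryModel:
    return BinaryModel(
        classes=tuple(obj["classes"]),
        class_counts={k: int(v) for k, v in obj["class_counts"].items()},
        scheme=_scheme_from_json(obj["scheme"]),
        ruleset=_ruleset_from_json(obj["rules"]),
        config=RunConfig.from_mapping(obj["config"]),
        kept_genes=list(obj["kept_genes"]),
    )


def save_model(model: BinaryModel | OvaModel, path: str) -> None:
    if isinstance(model, BinaryModel):
        payload = _binary_to_json(model)
    else:
        payload = {
            "kind": "ova",
            "classes": model.classes,
            "class_counts": model.class_counts,
            "submodels": {c: _binary_to_json(m) for c, m in model.submodels.items()},
            "config": model.config.to_dict(),
        }
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "generator": f"ivclass {__version__}",
        "model": payload,
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path: str) -> BinaryModel | OvaModel:
    with open(path, "rt", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"unreadable model file {path}: {exc}") from exc
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(f"unsupported model format version in {path}")
    obj = doc["model"]
    if obj["kind"] == "binary":
        return _binary_from_json(obj)
    if obj["kind"] == "ova":
        return OvaModel(
            classes=list(obj["classes"]),
            class_counts={k: int(v) for k, v in obj["class_counts"].items()},
            submodels={c: _binary_from_json(m) for c, m in obj["submodels"].items()},
            config=RunConfig.from_mapping(obj["config"]),
        )
    raise ValidationError(f"unknown model kind {obj.get('kind')!r}")
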