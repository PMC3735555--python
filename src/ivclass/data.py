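"""Core data types and text readers/writers.

An expression matrix is a tab-delimited file with sample IDs in the header
row and gene IDs in the first column; labels are a two-column (sample,
class) TSV.  Rules serialize one per line as ``GENE[lo,hi], ...<TAB>class``
with open-ended bounds rendered as ``-inf``/``+inf``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "ExpressionMatrix",
    "Interval",
    "RuleItem",
    "Rule",
    "RuleSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "read_rules",
    "write_rules",
    "format_float",
    "parse_float",
]


class ParseError(ValueError):
    """A file could not be parsed (CLI exit code 3)."""


class ValidationError(ValueError):
    """Inputs parsed but violate a contract (CLI exit code 2)."""


# --------------------------------------------------------------------------- #
# expression matrix
# --------------------------------------------------------------------------- #


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with per-sample class labels.

    Parameters
    ----------
    gene_ids : ordered unique gene identifiers (rows).
    sample_ids : ordered unique sample identifiers (columns).
    values : float array of shape ``(len(gene_ids), len(sample_ids))``.
    labels : mapping sample_id -> class label; may cover >= 2 classes for
        training but single-class matrices are allowed for prediction input
        (pass ``require_labels=False`` semantics by giving every sample a
        placeholder label).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must form a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicate gene ID {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample ID {dup!r}")
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise ValidationError(f"samples without class label: {missing[:5]}")
        extra = [s for s in self.labels if s not in set(self.sample_ids)]
        if extra:
            raise ValidationError(f"labelled samples absent from matrix: {extra[:5]}")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            g, s = bad[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    # -- convenience ------------------------------------------------------- #

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> list[str]:
        """Distinct class labels, lexicographically sorted."""
        return sorted(set(self.labels.values()))

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.sample_ids], dtype=object)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sample_ids:
            counts[self.labels[s]] = counts.get(self.labels[s], 0) + 1
        return counts

    def class_sample_indices(self, label: str) -> np.ndarray:
        if label not in set(self.labels.values()):
            raise ValidationError(f"unknown class label {label!r}")
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.labels[s] == label],
            dtype=int,
        )

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = list(indices)
        sids = [self.sample_ids[i] for i in idx]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=sids,
            values=self.values[:, idx].copy(),
            labels={s: self.labels[s] for s in sids},
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = self.gene_index()
        rows = []
        for g in gene_ids:
            if g not in index:
                raise ValidationError(f"unknown gene ID {g!r}")
            rows.append(index[g])
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :].copy(),
            labels=dict(self.labels),
        )

    def relabel(self, mapping: Mapping[str, str]) -> "ExpressionMatrix":
        """Return a copy with every class label passed through *mapping*."""
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            labels={s: mapping[c] for s, c in self.labels.items()},
        )


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return ""


def _parse_cell(token: str, gene: str, sample: str) -> float:
    try:
        v = float(token)
    except (TypeError, ValueError):
        raise ParseError(
            f"malformed numeric cell {token!r} at gene {gene!r}, sample {sample!r}"
        ) from None
    if not math.isfinite(v):
        raise ParseError(
            f"non-finite cell {token!r} at gene {gene!r}, sample {sample!r}"
        )
    return v


def read_labels(path: str) -> dict[str, str]:
    """Read a two-column (sample_id, class) tab-delimited file."""
    labels: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 2 tab-separated columns")
            sample, cls = parts[0].strip(), parts[1].strip()
            if not sample or not cls:
                raise ParseError(f"{path}:{ln}: empty sample ID or class label")
            if sample in labels:
                raise ValidationError(f"{path}:{ln}: duplicate sample ID {sample!r}")
            labels[sample] = cls
    return labels


def write_labels(labels: Mapping[str, str], path: str, order: Sequence[str] | None = None) -> None:
    sids = list(order) if order is not None else list(labels)
    with open(path, "wt", encoding="utf-8") as fh:
        for s in sids:
            fh.write(f"{s}\t{labels[s]}\n")


def read_expression_matrix(
    matrix_path: str,
    labels_path: str | None = None,
    *,
    transpose: bool = False,
    require_two_classes: bool = True,
) -> ExpressionMatrix:
    """Load a tab-delimited matrix (genes in rows) plus its label file.

    Lines starting with ``#`` (GCT-like preamble) are skipped.  With
    ``transpose=True`` the file is interpreted as samples-in-rows.  When
    *labels_path* is None every sample receives the placeholder label
    ``"?"`` (prediction input); ``require_two_classes`` is then ignored.
    """
    try:
        df = pd.read_csv(
            matrix_path, sep="\t", index_col=0, comment="#", dtype=str,
            header=0, skip_blank_lines=True, na_filter=False,
        )
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise ParseError(f"cannot read matrix file {matrix_path}: {exc}") from exc
    if transpose:
        df = df.T
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    raw = df.to_numpy()
    try:
        values = raw.astype(float)
        if not np.isfinite(values).all():
            raise ValueError
    except (TypeError, ValueError):
        # slow path: locate the offending cell for a precise error message
        values = np.empty(raw.shape, dtype=float)
        for i, g in enumerate(gene_ids):
            for j, s in enumerate(sample_ids):
                values[i, j] = _parse_cell(raw[i, j], g, s)

    if labels_path is None:
        labels = {s: "?" for s in sample_ids}
    else:
        labels = read_labels(labels_path)
        matrix_samples = set(sample_ids)
        missing = [s for s in sample_ids if s not in labels]
        if missing:
            raise ValidationError(
                f"matrix samples missing from labels file: {missing[:5]}"
            )
        extra = [s for s in labels if s not in matrix_samples]
        if extra:
            raise ValidationError(
                f"labels file samples absent from matrix: {extra[:5]}"
            )
    m = ExpressionMatrix(gene_ids, sample_ids, values, labels)
    if labels_path is not None and require_two_classes and len(m.classes) < 2:
        raise ValidationError("training requires at least 2 distinct class labels")
    return m


def write_expression_matrix(matrix: ExpressionMatrix, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, g in enumerate(matrix.gene_ids):
            row = "\t".join(format_float(v) for v in matrix.values[i])
            fh.write(f"{g}\t{row}\n")


# --------------------------------------------------------------------------- #
# intervals and rules
# --------------------------------------------------------------------------- #


@dataclass(frozen=True, order=True)
class Interval:
    """Left-open, right-closed interval ``(lo, hi]``; bounds may be infinite."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.hi):
            raise ValidationError(f"interval bounds out of order: ({self.lo}, {self.hi}]")

    def contains(self, value: float) -> bool:
        return self.lo < value <= self.hi

    def contains_array(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return (values > self.lo) & (values <= self.hi)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"({format_float(self.lo)},{format_float(self.hi)}]"


@dataclass(frozen=True, order=True)
class RuleItem:
    """A (gene, expression interval) pair."""

    gene_id: str
    interval: Interval


@dataclass(frozen=True)
class Rule:
    antecedent: tuple[RuleItem, ...]
    consequent_class: str
    support: float = 0.0
    confidence: float = 0.0

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ValidationError("rule antecedent must be non-empty")
        object.__setattr__(
            self, "antecedent", tuple(sorted(self.antecedent, key=lambda it: it.gene_id))
        )
        genes = [it.gene_id for it in self.antecedent]
        if len(set(genes)) != len(genes):
            raise ValidationError("rule antecedent holds more than one item per gene")
        for name in ("support", "confidence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"rule {name} {v} outside [0, 1]")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(it.gene_id for it in self.antecedent)

    def __len__(self) -> int:
        return len(self.antecedent)


@dataclass
class RuleSet:
    """Per-class association rules sharing one confidence threshold."""

    rules: list[Rule] = field(default_factory=list)
    min_confidence: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ValidationError("min_confidence outside [0, 1]")
        # NOTE: confidence >= min_confidence is guaranteed by the rule
        # builder, not re-checked here: rules serialized without stats
        # legitimately carry confidence 0.
        seen: set[tuple] = set()
        for r in self.rules:
            key = (r.consequent_class, r.antecedent)
            if key in seen:
                raise ValidationError(
                    f"duplicate antecedent within class {r.consequent_class!r}"
                )
            seen.add(key)

    def by_class(self) -> dict[str, list[Rule]]:
        out: dict[str, list[Rule]] = {}
        for r in self.rules:
            out.setdefault(r.consequent_class, []).append(r)
        return out

    def __len__(self) -> int:
        return len(self.rules)


# --------------------------------------------------------------------------- #
# rule (de)serialization
# --------------------------------------------------------------------------- #

_ITEM_RE = re.compile(r"\s*([^\[\],]+?)\s*\[\s*([^,\]]+)\s*,\s*([^,\]]+)\s*\]\s*")


def format_float(v: float) -> str:
    if math.isinf(v):
        return "+inf" if v > 0 else "-inf"
    return repr(float(v))


def parse_float(token: str) -> float:
    t = token.strip()
    if t in ("+inf", "inf", "Inf", "+Inf"):
        return math.inf
    if t in ("-inf", "-Inf"):
        return -math.inf
    return float(t)


def _format_rule(rule: Rule, include_stats: bool) -> str:
    items = ", ".join(
        f"{it.gene_id}[{format_float(it.interval.lo)},{format_float(it.interval.hi)}]"
        for it in rule.antecedent
    )
    line = f"{items}\t{rule.consequent_class}"
    if include_stats:
        line += (
            f"\tsupport={format_float(rule.support)}"
            f"\tconfidence={format_float(rule.confidence)}"
        )
    return line


def _parse_item(token: str, where: str) -> RuleItem:
    m = _ITEM_RE.fullmatch(token)
    if not m:
        raise ParseError(f"{where}: unparsable rule item {token!r}")
    gene, lo_s, hi_s = m.group(1), m.group(2), m.group(3)
    try:
        lo, hi = parse_float(lo_s), parse_float(hi_s)
    except ValueError:
        raise ParseError(f"{where}: bad interval bounds in {token!r}") from None
    try:
        return RuleItem(gene, Interval(lo, hi))
    except ValidationError as exc:
        raise ParseError(f"{where}: {exc}") from None


def write_rules(ruleset: RuleSet, path: str, *, include_stats: bool = True) -> None:
    """Serialize rules, one per line, gene[lo,hi] items then class label."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# min_confidence={format_float(ruleset.min_confidence)}\n")
        for r in ruleset.rules:
            fh.write(_format_rule(r, include_stats) + "\n")


def rule_to_line(rule: Rule, *, include_stats: bool = False) -> str:
    """Render a single rule in the human-readable line format."""
    return _format_rule(rule, include_stats)


def read_rules(path: str) -> RuleSet:
    rules: list[Rule] = []
    min_confidence = 0.05
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.search(r"min_confidence\s*=\s*(\S+)", line)
                if m:
                    min_confidence = parse_float(m.group(1))
                continue
            where = f"{path}:{ln}"
            parts = line.split("\t")
            if len(parts) not in (2, 4):
                raise ParseError(f"{where}: expected 2 or 4 tab-separated fields")
            # items are separated by commas, but intervals contain commas
            # too, so split on the closing bracket instead
            tokens = []
            for piece in parts[0].split("]"):
                piece = piece.strip().lstrip(",").strip()
                if piece:
                    tokens.append(piece + "]")
            items = [_parse_item(tok, where) for tok in tokens]
            if not items:
                raise ParseError(f"{where}: rule without antecedent items")
            support = confidence = 0.0
            if len(parts) == 4:
                for p in parts[2:]:
                    k, _, v = p.partition("=")
                    try:
                        if k == "support":
                            support = parse_float(v)
                        elif k == "confidence":
                            confidence = parse_float(v)
                        else:
                            raise ValueError
                    except ValueError:
                        raise ParseError(f"{where}: bad metadata field {p!r}") from None
            try:
                rules.append(
                    Rule(tuple(items), parts[1].strip(), support=support, confidence=confidence)
                )
            except ValidationError as exc:
                raise ParseError(f"{where}: {exc}") from None
    return RuleSet(rules=rules, min_confidence=min_confidence)
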