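import math

import numpy as np
import pytest

from ivclass import (
    ExpressionMatrix,
    Interval,
    ParseError,
    Rule,
    RuleItem,
    RuleSet,
    ValidationError,
    read_expression_matrix,
    read_rules,
    write_expression_matrix,
    write_rules,
)
from ivclass.data import read_labels, rule_to_line, write_labels


class TestExpressionMatrixValidation:
    def test_duplicate_gene_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicate gene"):
            ExpressionMatrix(
                ["g1", "g1"], ["s1"], np.zeros((2, 1)), {"s1": "a"}
            )

    def test_duplicate_sample_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicate sample"):
            ExpressionMatrix(
                ["g1"], ["s1", "s1"], np.zeros((1, 2)), {"s1": "a"}
            )

    def test_nonfinite_value_rejected(self):
        with pytest.raises(ValidationError, match="non-finite"):
            ExpressionMatrix(
                ["g1"], ["s1", "s2"], np.array([[1.0, np.nan]]), {"s1": "a", "s2": "b"}
            )

    def test_missing_label_rejected(self):
        with pytest.raises(ValidationError, match="without class label"):
            ExpressionMatrix(["g1"], ["s1"], np.zeros((1, 1)), {})

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ExpressionMatrix(["g1"], ["s1"], np.zeros((2, 2)), {"s1": "a"})


class TestReadExpressionMatrix:
    def test_well_formed_pair(self, matrix_files):
        m = read_expression_matrix(*matrix_files)
        assert m.values.shape == (3, 4)
        assert m.classes == ["x", "y"]
        assert m.gene_ids == ["gA", "gB", "gC"]
        assert m.sample_ids == ["s1", "s2", "s3", "s4"]

    def test_labels_missing_matrix_sample(self, tmp_path, matrix_files, small_matrix):
        mp, _ = matrix_files
        lp = tmp_path / "short.tsv"
        write_labels(
            {s: small_matrix.labels[s] for s in small_matrix.sample_ids[:-1]},
            str(lp),
        )
        with pytest.raises(ValidationError, match="missing from labels"):
            read_expression_matrix(mp, str(lp))

    def test_extra_label_sample_rejected(self, tmp_path, matrix_files, small_matrix):
        mp, _ = matrix_files
        lp = tmp_path / "extra.tsv"
        labels = dict(small_matrix.labels, ghost="x")
        write_labels(labels, str(lp))
        with pytest.raises(ValidationError, match="absent from matrix"):
            read_expression_matrix(mp, str(lp))

    def test_na_cell_is_parse_error_with_coordinates(self, tmp_path, matrix_files):
        _, lp = matrix_files
        mp = tmp_path / "bad.tsv"
        mp.write_text("gene_id\ts1\ts2\ts3\ts4\ngA\t1.0\tNA\t2.0\t3.0\n"
                      "gB\t0\t0\t0\t0\ngC\t0\t0\t0\t0\n")
        with pytest.raises(ParseError) as exc:
            read_expression_matrix(str(mp), lp)
        assert "gA" in str(exc.value) and "s2" in str(exc.value)

    def test_single_class_rejected_for_training(self, tmp_path, matrix_files, small_matrix):
        mp, _ = matrix_files
        lp = tmp_path / "one_class.tsv"
        write_labels({s: "only" for s in small_matrix.sample_ids}, str(lp))
        with pytest.raises(ValidationError, match="2 distinct class"):
            read_expression_matrix(mp, str(lp))

    def test_round_trip_preserves_order_and_values(self, tmp_path, small_matrix, matrix_files):
        m = read_expression_matrix(*matrix_files)
        assert m.gene_ids == small_matrix.gene_ids
        assert m.sample_ids == small_matrix.sample_ids
        np.testing.assert_array_equal(m.values, small_matrix.values)

    def test_transpose(self, tmp_path, small_matrix, matrix_files):
        _, lp = matrix_files
        mp = tmp_path / "t.tsv"
        transposed = ExpressionMatrix(
            gene_ids=small_matrix.sample_ids,
            sample_ids=small_matrix.gene_ids,
            values=small_matrix.values.T,
            labels={g: "?" for g in small_matrix.gene_ids},
        )
        write_expression_matrix(transposed, str(mp))
        m = read_expression_matrix(str(mp), lp, transpose=True)
        np.testing.assert_array_equal(m.values, small_matrix.values)

    def test_comment_lines_skipped(self, tmp_path, matrix_files):
        mp, lp = matrix_files
        original = open(mp).read()
        mp2 = tmp_path / "gct_like.tsv"
        mp2.write_text("#1.2\n" + original)
        m = read_expression_matrix(str(mp2), lp)
        assert m.values.shape == (3, 4)

    def test_scientific_notation_accepted(self, tmp_path):
        mp = tmp_path / "sci.tsv"
        mp.write_text("gene_id\ts1\ts2\ngA\t1e-3\t2.14E7\n")
        lp = tmp_path / "l.tsv"
        lp.write_text("s1\ta\ns2\tb\n")
        m = read_expression_matrix(str(mp), str(lp), require_two_classes=False)
        assert m.values[0, 1] == 2.14e7


class TestRuleModel:
    def test_empty_antecedent_rejected(self):
        with pytest.raises(ValidationError):
            Rule(antecedent=(), consequent_class="c")

    def test_two_items_same_gene_rejected(self):
        items = (
            RuleItem("g", Interval(0.0, 1.0)),
            RuleItem("g", Interval(1.0, 2.0)),
        )
        with pytest.raises(ValidationError):
            Rule(antecedent=items, consequent_class="c")

    def test_fraction_bounds_checked(self):
        item = RuleItem("g", Interval(0.0, 1.0))
        with pytest.raises(ValidationError):
            Rule(antecedent=(item,), consequent_class="c", support=1.5)

    def test_antecedent_sorted_by_gene(self):
        r = Rule(
            antecedent=(
                RuleItem("z", Interval(0, 1)),
                RuleItem("a", Interval(0, 1)),
            ),
            consequent_class="c",
        )
        assert r.genes == ("a", "z")

    def test_duplicate_antecedent_within_class_rejected(self):
        r = Rule((RuleItem("g", Interval(0, 1)),), "c", support=0.5, confidence=0.5)
        with pytest.raises(ValidationError, match="duplicate antecedent"):
            RuleSet(rules=[r, r])


class TestRuleSerialization:
    def test_table_style_line(self):
        rule = Rule(
            antecedent=(RuleItem("HOXB13", Interval(-0.68, -0.09)),),
            consequent_class="NonRecurrence",
        )
        assert rule_to_line(rule) == "HOXB13[-0.68,-0.09]\tNonRecurrence"

    def test_empty_ruleset_round_trip(self, tmp_path):
        p = tmp_path / "rules.txt"
        write_rules(RuleSet(rules=[], min_confidence=0.05), str(p))
        rs = read_rules(str(p))
        assert rs.rules == [] and rs.min_confidence == 0.05

    def test_two_rule_round_trip_identity(self, tmp_path):
        rules = RuleSet(
            rules=[
                Rule(
                    antecedent=(
                        RuleItem("IL17BR", Interval(0.79, 0.98)),
                        RuleItem("DOK2", Interval(2.29, 2.44)),
                    ),
                    consequent_class="NonRecurrence",
                    support=0.4375,
                    confidence=0.8123456789012345,
                ),
                Rule(
                    antecedent=(RuleItem("APS", Interval(0.18, math.inf)),),
                    consequent_class="Recurrence",
                    support=1 / 3,
                    confidence=0.05,
                ),
            ],
            min_confidence=0.05,
        )
        p = tmp_path / "rules.txt"
        write_rules(rules, str(p))
        back = read_rules(str(p))
        assert back.rules == rules.rules
        assert back.min_confidence == rules.min_confidence

    def test_round_trip_is_bitwise_stable(self, tmp_path):
        rules = RuleSet(
            rules=[
                Rule(
                    antecedent=(RuleItem("g", Interval(-math.inf, 0.1)),),
                    consequent_class="a",
                    support=0.123456789,
                    confidence=0.25,
                )
            ]
        )
        p1, p2 = tmp_path / "r1.txt", tmp_path / "r2.txt"
        write_rules(rules, str(p1))
        write_rules(read_rules(str(p1)), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_infinite_bounds_tokens(self, tmp_path):
        rules = RuleSet(
            rules=[
                Rule(
                    antecedent=(RuleItem("g", Interval(-math.inf, math.inf)),),
                    consequent_class="a",
                )
            ]
        )
        p = tmp_path / "r.txt"
        write_rules(rules, str(p))
        text = p.read_text()
        assert "g[-inf,+inf]" in text
        assert read_rules(str(p)).rules[0].antecedent[0].interval == Interval(-math.inf, math.inf)

    def test_unparsable_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("g[0.1,0.2]\tok\nnot a rule line\n")
        with pytest.raises(ParseError, match=":2"):
            read_rules(str(p))


def test_read_labels_rejects_duplicates(tmp_path):
    p = tmp_path / "labels.tsv"
    p.write_text("s1\ta\ns1\tb\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_labels(str(p))


def test_interval_contains_left_open():
    iv = Interval(0.0, 1.0)
    assert not iv.contains(0.0)
    assert iv.contains(1.0)
    assert iv.contains(0.5)
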