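import math
from collections import Counter

import numpy as np
import pytest

from ivclass import ExpressionMatrix, ValidationError, apply_scheme, build_scheme
from ivclass.discretize import (
    METHODS,
    IntervalScheme,
    discretize_gene_ewib,
    discretize_gene_id3,
    discretize_gene_none,
    discretize_gene_ternary,
)

# --------------------------------------------------------------------------- #
# independent ID3 oracle: plain recursive maximizer over boundary midpoints,
# entropy from Counters, identical stopping rule (pure / < 2*min_leaf /
# non-positive gain), leftmost cut on ties
# --------------------------------------------------------------------------- #


def _entropy(labels) -> float:
    n = len(labels)
    h = 0.0
    for c in Counter(labels).values():
        p = c / n
        h -= p * math.log2(p)
    return h


def _boundary_midpoints(pairs):
    # pairs sorted by value; candidate between distinct-value groups unless
    # both adjacent groups are pure with the same class
    groups = []
    for v, lab in pairs:
        if groups and groups[-1][0] == v:
            groups[-1][1].append(lab)
        else:
            groups.append((v, [lab]))
    cuts = []
    for left, right in zip(groups, groups[1:]):
        lpure = len(set(left[1])) == 1
        rpure = len(set(right[1])) == 1
        if lpure and rpure and left[1][0] == right[1][0]:
            continue
        cuts.append((left[0] + right[0]) / 2.0)
    return cuts


def oracle_id3(values, labels, min_leaf=2):
    pairs = sorted(zip(values, labels), key=lambda t: t[0])
    out = []

    def recurse(node):
        labs = [lab for _, lab in node]
        if len(node) < 2 * min_leaf or len(set(labs)) <= 1:
            return
        parent = _entropy(labs)
        best = None
        for cut in _boundary_midpoints(node):
            left = [lab for v, lab in node if v <= cut]
            right = [lab for v, lab in node if v > cut]
            gain = parent - (
                len(left) * _entropy(left) + len(right) * _entropy(right)
            ) / len(node)
            if best is None or gain > best[0] + 1e-15:
                best = (gain, cut)
        if best is None or best[0] <= 1e-12:
            return
        cut = best[1]
        recurse([p for p in node if p[0] <= cut])
        out.append(cut)
        recurse([p for p in node if p[0] > cut])

    recurse(pairs)
    return sorted(out)


class TestId3:
    def test_clean_two_cluster_split(self):
        # expected value computed with oracle_id3: single cut at 6.5
        values = np.array([1.0, 2, 3, 10, 11, 12])
        labels = np.array(list("AAABBB"))
        cuts = discretize_gene_id3(values, labels, min_leaf=1)
        np.testing.assert_array_equal(cuts, [6.5])
        assert oracle_id3(values, labels, min_leaf=1) == [6.5]

    def test_pure_node_never_split(self):
        cuts = discretize_gene_id3(np.arange(6.0), np.repeat("A", 6), min_leaf=1)
        assert cuts.size == 0

    def test_interleaved_matches_bruteforce(self):
        values = np.array([1.0, 5, 2, 6, 3, 7])
        labels = np.array(list("ABABAB"))
        got = discretize_gene_id3(values, labels, min_leaf=1)
        assert list(got) == oracle_id3(values, labels, min_leaf=1)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_vectors_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 25))
        values = np.round(rng.normal(size=n), 1)  # provoke ties
        labels = rng.choice(["A", "B", "C"][: rng.integers(2, 4)], size=n)
        min_leaf = int(rng.integers(1, 4))
        got = list(discretize_gene_id3(values, labels, min_leaf))
        assert got == pytest.approx(oracle_id3(values, labels, min_leaf))

    def test_every_cut_has_positive_gain_and_pure_nodes_stop(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            values = rng.normal(size=30)
            labels = rng.choice(["A", "B"], size=30)
            trace: list[tuple[float, int]] = []
            cuts = discretize_gene_id3(values, labels, trace=trace)
            assert len(trace) == len(cuts)
            for gain, node_size in trace:
                assert gain > 0
                assert node_size >= 4  # 2 * default min_leaf

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            discretize_gene_id3(np.array([]), np.array([]))

    def test_min_leaf_blocks_small_nodes(self):
        values = np.array([1.0, 2.0, 3.0])
        labels = np.array(list("ABA"))
        assert discretize_gene_id3(values, labels, min_leaf=2).size == 0


class TestEwib:
    def test_two_bins(self):
        np.testing.assert_allclose(discretize_gene_ewib(np.arange(10.0), 2), [4.5])

    def test_constant_vector(self):
        assert discretize_gene_ewib(np.full(5, 3.3), 4).size == 0

    def test_five_bins_of_zero_ten(self):
        np.testing.assert_allclose(
            discretize_gene_ewib(np.array([0.0, 10.0]), 5), [2, 4, 6, 8]
        )

    def test_bad_bins_rejected(self):
        with pytest.raises(ValidationError):
            discretize_gene_ewib(np.arange(4.0), 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_cuts_commute_with_affine_transform(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=20)
        a, b = 2.5, -3.0
        base = discretize_gene_ewib(v, 6)
        transformed = discretize_gene_ewib(a * v + b, 6)
        np.testing.assert_allclose(transformed, a * base + b, atol=1e-12)


class TestTernary:
    def test_standard_normal_like(self):
        v = np.array([-1.0, 1.0])  # mean 0, population sd 1
        np.testing.assert_allclose(discretize_gene_ternary(v, z=1.0), [-1, 1])

    def test_constant_vector(self):
        assert discretize_gene_ternary(np.zeros(4)).size == 0

    def test_bimodal_example(self):
        v = np.array([0.0, 0, 0, 0, 10, 10, 10, 10])
        # mean 5, population sd 5 -> cuts at 5 -+ z*5
        np.testing.assert_allclose(discretize_gene_ternary(v, z=1.0), [0.0, 10.0])

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            discretize_gene_ternary(np.array([1.0]))


class TestNone:
    def test_distinct_value_bins(self):
        np.testing.assert_allclose(
            discretize_gene_none(np.array([3.0, 1.0, 2.0, 1.0])), [1.5, 2.5]
        )

    def test_constant(self):
        assert discretize_gene_none(np.full(3, 2.0)).size == 0


class TestSchemesAndApplication:
    @pytest.mark.parametrize("method", METHODS)
    def test_partition_disjoint_exhaustive_contiguous(self, method):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(2, 40))
            values = rng.normal(size=(1, n))
            labels = {f"s{i}": rng.choice(["A", "B"]) for i in range(n)}
            m = ExpressionMatrix(["g"], list(labels), values, labels)
            scheme = build_scheme(m, method)
            ivs = scheme.intervals("g")
            assert ivs[0].lo == -math.inf and ivs[-1].hi == math.inf
            for left, right in zip(ivs, ivs[1:]):
                assert left.hi == right.lo  # contiguous and disjoint
            # every probe value lands in exactly one interval
            for probe in np.concatenate([values[0], [-1e9, 1e9]]):
                hits = [iv for iv in ivs if iv.contains(probe)]
                assert len(hits) == 1

    def test_apply_scheme_counts_sum_to_samples(self, small_matrix):
        scheme = build_scheme(small_matrix, "ewib", n_bins=3)
        dm = apply_scheme(small_matrix, scheme)
        for i, g in enumerate(dm.gene_ids):
            counts = np.bincount(dm.cells[i], minlength=scheme.n_intervals(g))
            assert counts.sum() == small_matrix.n_samples

    def test_unseen_low_value_maps_to_first_interval(self, small_matrix):
        scheme = build_scheme(small_matrix, "ewib", n_bins=4)
        assert scheme.locate("gA", -1e12) == 0
        assert scheme.locate("gA", +1e12) == scheme.n_intervals("gA") - 1

    def test_id3_scheme_is_per_gene_composition(self, small_matrix):
        scheme = build_scheme(small_matrix, "id3", min_leaf=1)
        y = small_matrix.label_array()
        for i, g in enumerate(small_matrix.gene_ids):
            expected = discretize_gene_id3(small_matrix.values[i], y, 1)
            np.testing.assert_array_equal(scheme.cuts[g], expected)

    def test_unknown_method_rejected(self, small_matrix):
        with pytest.raises(ValidationError):
            build_scheme(small_matrix, "chimerge")

    def test_scheme_index_round_trip(self, small_matrix):
        scheme = build_scheme(small_matrix, "ewib", n_bins=5)
        for g in scheme.gene_ids:
            for i in range(scheme.n_intervals(g)):
                assert scheme.index_of(g, scheme.interval(g, i)) == i

    def test_nonmonotone_cuts_rejected(self):
        with pytest.raises(ValidationError):
            IntervalScheme(method="ewib", cuts={"g": np.array([1.0, 1.0])})
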