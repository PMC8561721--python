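"""Transforms, zero replacement and the total-variance identities."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alrscan import (
    CompositionTable,
    abundance_weights,
    alr,
    close,
    clr,
    pairwise_logratios,
    replace_zeros,
    total_logratio_variance,
)
from conftest import random_table


class TestClose:
    def test_uniform_row(self):
        t = CompositionTable([[2, 2, 2, 2]], ["s1"], list("abcd"))
        assert np.allclose(close(t).values, 0.25)

    def test_rows_sum_to_one_and_idempotent(self, table_8x6):
        c1 = close(table_8x6)
        assert np.allclose(c1.values.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(close(c1).values, c1.values, atol=1e-15)

    def test_logratios_invariant_to_closure(self, table_8x6):
        before = alr(table_8x6, "c0").values
        after = alr(close(table_8x6), "c0").values
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_rejects_zeros(self):
        t = CompositionTable([[0, 1, 2]], ["s1"], list("abc"))
        with pytest.raises(ValueError, match="replace_zeros"):
            close(t)


class TestClr:
    def test_geometric_progression_row(self):
        t = CompositionTable([[1, 2, 4]], ["s1"], list("abc"))
        np.testing.assert_allclose(
            clr(t).values[0], [-math.log(2), 0.0, math.log(2)], atol=1e-12
        )

    def test_uniform_composition_is_zero(self):
        t = CompositionTable([[5, 5, 5, 5]], ["s1"], list("abcd"))
        assert np.allclose(clr(t).values, 0.0, atol=1e-15)

    def test_weighted_clr_matches_scalar_evaluation(self):
        # independent oracle: per-cell evaluation of the weighted definition
        # with explicit python loops over log X_j - sum_k c_k log X_k
        rng = np.random.default_rng(7)
        X = np.exp(rng.normal(size=(3, 4)))
        w = np.array([0.4, 0.3, 0.2, 0.1])
        t = CompositionTable(X, ["a", "b", "c"], list("wxyz"), weights=w)
        got = clr(t).values
        for i in range(3):
            wmean = sum(w[k] * math.log(X[i, k]) for k in range(4))
            for j in range(4):
                assert got[i, j] == pytest.approx(math.log(X[i, j]) - wmean, abs=1e-12)

    def test_weighted_rows_sum_to_zero(self):
        t = random_table(6, 9, seed=3, weighted=True)
        sums = clr(t).values @ t.weights
        assert np.max(np.abs(sums)) < 1e-10

    def test_matches_skbio_unweighted(self, table_8x6):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        expect = skbio_comp.clr(table_8x6.relative_abundances())
        np.testing.assert_allclose(clr(table_8x6).values, expect, atol=1e-12)

    def test_log_base_rescaling(self, table_5x4):
        nat = clr(table_5x4).values
        b2 = clr(table_5x4, log_base="2").values
        np.testing.assert_allclose(b2, nat / math.log(2), atol=1e-12)


class TestAlr:
    def test_simple_row(self):
        t = CompositionTable([[1, 2, 4]], ["s1"], list("abc"))
        np.testing.assert_allclose(alr(t, "a").values[0], [math.log(2), math.log(4)])

    def test_two_components_single_column(self):
        t = CompositionTable([[1, 3], [2, 5]], ["s1", "s2"], ["a", "b"])
        m = alr(t, "b")
        assert m.values.shape == (2, 1)
        assert m.reference == "b"

    def test_equals_clr_difference(self):
        for seed, weighted in [(1, False), (2, True)]:
            t = random_table(7, 5, seed=seed, weighted=weighted)
            z = clr(t).values
            a = alr(t, "c2").values
            expect = np.delete(z - z[:, [2]], 2, axis=1)
            np.testing.assert_allclose(a, expect, atol=1e-12)

    def test_scale_invariance(self, table_5x4):
        scaled = CompositionTable(
            table_5x4.values * np.array([[1.0], [7.0], [0.01], [3.0], [100.0]]),
            table_5x4.sample_ids,
            table_5x4.component_labels,
        )
        np.testing.assert_allclose(
            alr(scaled, "c1").values, alr(table_5x4, "c1").values, atol=1e-12
        )

    def test_unknown_reference(self, table_5x4):
        with pytest.raises(KeyError, match="nope"):
            alr(table_5x4, "nope")


class TestPairwise:
    @pytest.mark.parametrize("J,expected", [(3, 3), (10, 45)])
    def test_column_count(self, J, expected):
        t = random_table(4, J, seed=J)
        assert pairwise_logratios(t).values.shape == (4, expected)

    def test_cows_sized_column_count(self):
        # 127 components expand to 127*126/2 columns
        t = random_table(3, 127, seed=0)
        assert pairwise_logratios(t).values.shape[1] == 8001

    def test_antisymmetry(self, table_5x4):
        lr = pairwise_logratios(table_5x4)
        labels = {(n, d): i for i, (n, d) in enumerate(zip(lr.numerator_labels, lr.denominator_labels))}
        X = table_5x4.values
        cols = table_5x4.component_labels
        for (n, d), i in labels.items():
            jn, jd = cols.index(n), cols.index(d)
            np.testing.assert_allclose(lr.values[:, i], -np.log(X[:, jd] / X[:, jn]), atol=1e-12)

    def test_cap_refused_without_force(self):
        t = random_table(3, 12, seed=1)
        with pytest.raises(ValueError, match="cap"):
            pairwise_logratios(t, cap=10)
        assert pairwise_logratios(t, cap=10, force=True).values.shape[1] == 66


class TestTotalVariance:
    def test_identical_rows_zero(self):
        t = CompositionTable([[1, 2, 3]] * 4, [f"s{i}" for i in range(4)], list("abc"))
        for route in ("pairwise", "clr", "transpose"):
            assert total_logratio_variance(t, route=route).total == pytest.approx(0.0, abs=1e-14)

    def test_three_routes_agree_with_bruteforce(self):
        # oracle: explicit double summation of the defining pairwise form
        t = random_table(4, 3, seed=5)
        X, J = t.values, 3
        brute = sum(
            (1 / J**2) * np.log(X[:, j] / X[:, k]).var()
            for j, k in combinations(range(J), 2)
        )
        for route in ("pairwise", "clr", "transpose"):
            assert total_logratio_variance(t, route=route).total == pytest.approx(brute, rel=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(2, 12), st.integers(3, 12), st.integers(0, 10**6), st.booleans())
    def test_pairwise_equals_clr_route(self, I, J, seed, weighted):
        t = random_table(I, J, seed=seed, weighted=weighted)
        a = total_logratio_variance(t, route="pairwise").total
        b = total_logratio_variance(t, route="clr").total
        assert b == pytest.approx(a, rel=1e-10)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(2, 12), st.integers(3, 12), st.integers(0, 10**6))
    def test_transpose_symmetry(self, I, J, seed):
        t = random_table(I, J, seed=seed)
        a = total_logratio_variance(t, route="clr").total
        b = total_logratio_variance(t, route="transpose").total
        assert b == pytest.approx(a, rel=1e-10)

    def test_transpose_route_requires_equal_weights(self):
        t = random_table(4, 5, seed=9, weighted=True)
        with pytest.raises(ValueError, match="equal"):
            total_logratio_variance(t, route="transpose")

    def test_scale_invariance(self, table_8x6):
        rng = np.random.default_rng(0)
        scaled = CompositionTable(
            table_8x6.values * rng.uniform(0.1, 10, size=(8, 1)),
            table_8x6.sample_ids,
            table_8x6.component_labels,
        )
        assert total_logratio_variance(scaled).total == pytest.approx(
            total_logratio_variance(table_8x6).total, rel=1e-12
        )

    def test_subcompositional_coherence(self, table_8x6):
        # ratios among retained components are untouched by dropping others
        sub = close(table_8x6.subset_components(["c0", "c2", "c5"]))
        full = pairwise_logratios(table_8x6)
        small = pairwise_logratios(sub)
        pairs_small = dict(
            zip(zip(small.numerator_labels, small.denominator_labels), small.values.T)
        )
        for (n, d), col in zip(
            zip(full.numerator_labels, full.denominator_labels), full.values.T
        ):
            if (n, d) in pairs_small:
                np.testing.assert_allclose(pairs_small[(n, d)], col, atol=1e-12)

    def test_log_base_rescales_variance(self, table_5x4):
        nat = total_logratio_variance(table_5x4).total
        b10 = total_logratio_variance(table_5x4, log_base="10").total
        assert b10 == pytest.approx(nat / math.log(10) ** 2, rel=1e-12)


class TestReplaceZeros:
    def test_no_zeros_unchanged(self, table_5x4):
        out, info = replace_zeros(table_5x4)
        assert info.n_zeros == 0
        np.testing.assert_array_equal(out.values, table_5x4.values)

    def test_multiplicative_hand_oracle(self):
        # row (0, 2, 2): delta = 0.5 * smallest positive relative abundance of
        # the zero's column = 0.5 * 0.25 = 0.125; zero -> delta * rowsum = 0.5,
        # nonzeros shrunk by (1 - 0.125) to preserve the row total of 4
        t = CompositionTable([[0, 2, 2], [2, 2, 4]], ["s1", "s2"], list("abc"))
        out, info = replace_zeros(t, method="multiplicative", delta_fraction=0.5)
        assert info.n_zeros == 1
        np.testing.assert_allclose(out.values[0], [0.5, 1.75, 1.75], atol=1e-12)
        np.testing.assert_allclose(out.values[1], [2, 2, 4], atol=1e-12)
        assert out.values[0].sum() == pytest.approx(4.0)

    def test_nonzero_logratios_preserved(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 30, size=(6, 8)).astype(float)
        X[:, 0] += 1.0  # keep one column positive everywhere
        X[0, :] += 1.0
        t = CompositionTable(X, [f"s{i}" for i in range(6)], [f"c{j}" for j in range(8)])
        out, info = replace_zeros(t)
        assert info.n_zeros == int((X == 0).sum())
        assert np.all(out.values > 0)
        for i in range(6):
            nz = X[i] > 0
            idx = np.where(nz)[0]
            before = np.log(X[i, idx[:-1]] / X[i, idx[-1]])
            after = np.log(out.values[i, idx[:-1]] / out.values[i, idx[-1]])
            np.testing.assert_allclose(after, before, atol=1e-12)

    def test_zero_counts_per_component(self):
        t = CompositionTable([[0, 1, 2], [3, 0, 2], [1, 1, 1]], ["a", "b", "c"], list("xyz"))
        _, info = replace_zeros(t)
        np.testing.assert_array_equal(info.zeros_per_component, [1, 1, 0])

    def test_bayes_method_positive_and_deterministic(self):
        t = CompositionTable([[0, 5, 5], [2, 4, 4]], ["s1", "s2"], list("abc"))
        out1, _ = replace_zeros(t, method="bayes")
        out2, _ = replace_zeros(t, method="bayes")
        assert np.all(out1.values > 0)
        np.testing.assert_array_equal(out1.values, out2.values)

    def test_all_zero_row_rejected(self):
        t = CompositionTable([[0, 0, 0], [1, 2, 3]], ["s1", "s2"], list("abc"))
        with pytest.raises(ValueError, match="s1"):
            replace_zeros(t)

    def test_all_zero_column_rejected(self):
        t = CompositionTable([[0, 1, 2], [0, 2, 3]], ["s1", "s2"], list("abc"))
        with pytest.raises(ValueError, match="'a'"):
            replace_zeros(t)


class TestTableValidation:
    def test_negative_value_names_cell(self):
        with pytest.raises(ValueError, match="s2.*'b'"):
            CompositionTable([[1, 2], [3, -1]], ["s1", "s2"], ["a", "b"])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CompositionTable([[1, 2]], ["s1"], ["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            CompositionTable([[1, 2], [1, 2]], ["s1", "s1"], ["a", "b"])

    def test_weights_must_be_valid(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CompositionTable([[1, 2]], ["s1"], ["a", "b"], weights=[0.7, 0.2])
        with pytest.raises(ValueError, match="positive"):
            CompositionTable([[1, 2]], ["s1"], ["a", "b"], weights=[1.0, 0.0])

    def test_abundance_weights_sum_to_one(self, table_8x6):
        w = abundance_weights(table_8x6)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w > 0)
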