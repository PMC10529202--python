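"""Entropy statistics against frozen worked values and independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from _oracles import (
    naive_conditional_entropy,
    naive_entropy,
    naive_mce,
    naive_ratio,
    naive_row_entropies,
)
from conftest import (
    TABLE1_H_Y,
    TABLE1_H_YX,
    TABLE1_MCE,
    TABLE1_RATIO,
    TABLE1_ROW_H,
    random_tables,
)
from ordent import (
    ContingencyTable,
    DegenerateDistributionError,
    ValidationError,
    conditional_entropy,
    entropy_summary,
    mutual_conditional_entropy,
    rescaled_conditional_entropy,
    row_conditional_entropy,
    shannon_entropy,
)


def make_ct(counts):
    counts = np.asarray(counts)
    return ContingencyTable(
        tuple(str(i) for i in range(counts.shape[0])),
        tuple(str(j) for j in range(counts.shape[1])),
        counts,
    )


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "counts,base,expected",
        [
            ((1, 1, 1, 1), None, math.log(4)),  # uniform attains log K
            ((0, 0, 5, 0), None, 0.0),  # degenerate distribution
            ((1, 1, 1, 1), 2, 2.0),
            ((150, 356, 815, 656), None, TABLE1_H_Y),  # worked column margins
        ],
    )
    def test_known_values(self, counts, base, expected):
        assert shannon_entropy(counts, base=base) == pytest.approx(expected, abs=1e-6)

    def test_all_zero_vector_is_undefined(self):
        with pytest.raises(DegenerateDistributionError):
            shannon_entropy([0, 0, 0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            shannon_entropy([1, -1, 2])


class TestWorkedTable:
    """The printed 4x4 table's full entropy summary, frozen from the oracle."""

    def test_row_profile_matches_oracle_and_increases(self, table1):
        profile = row_conditional_entropy(table1)
        assert profile.h_given_x == pytest.approx(TABLE1_ROW_H, abs=1e-5)
        assert np.all(np.diff(profile.h_given_x) > 0)  # uncertainty grows with Qi level
        assert list(profile.n_per_level) == [471, 397, 605, 504]
        assert not profile.empty.any()

    def test_summary(self, table1):
        s = entropy_summary(table1)
        assert s.h_y == pytest.approx(TABLE1_H_Y, abs=1e-5)
        assert s.h_y_given_x == pytest.approx(TABLE1_H_YX, abs=1e-5)
        assert s.ratio == pytest.approx(TABLE1_RATIO, abs=1e-5)
        assert s.h_y_given_x <= s.h_y

    def test_mce_is_mean_of_both_directions(self, table1):
        expected = 0.5 * (
            rescaled_conditional_entropy(table1)
            + rescaled_conditional_entropy(table1.transpose())
        )
        assert mutual_conditional_entropy(table1) == expected
        assert mutual_conditional_entropy(table1) == pytest.approx(TABLE1_MCE, abs=1e-5)


class TestIdentities:
    def test_product_table_conditioning_is_uninformative(self):
        # counts[i][j] = a_i * b_j is exact empirical independence
        a, b = np.array([2, 5, 3]), np.array([1, 4, 2, 3])
        ct = make_ct(np.outer(a, b))
        assert conditional_entropy(ct) == pytest.approx(
            shannon_entropy(ct.col_totals), abs=1e-12
        )
        assert rescaled_conditional_entropy(ct) == pytest.approx(1.0, abs=1e-12)
        assert mutual_conditional_entropy(ct) == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_coupling_is_perfect_prediction(self):
        ct = make_ct(np.diag([3, 7, 2, 9]))
        assert conditional_entropy(ct) == 0.0
        assert rescaled_conditional_entropy(ct) == 0.0
        assert mutual_conditional_entropy(ct) == 0.0

    def test_empty_row_contributes_zero_and_is_flagged(self):
        ct = make_ct([[0, 0, 0, 0], [1, 2, 3, 4], [5, 1, 1, 1]])
        profile = row_conditional_entropy(ct)
        assert profile.h_given_x[0] == 0.0
        assert profile.empty[0] and not profile.empty[1:].any()

    def test_constant_response_ratio_is_undefined(self):
        ct = make_ct([[0, 3, 0], [0, 5, 0]])
        with pytest.raises(DegenerateDistributionError):
            rescaled_conditional_entropy(ct)
        with pytest.raises(DegenerateDistributionError):
            mutual_conditional_entropy(ct.transpose())


class TestOracleEquivalence:
    """200 random small tables vs the naive double-loop implementation."""

    def test_all_statistics_match_naive_oracle(self):
        rng = np.random.default_rng(20240901)
        for counts in random_tables(200, rng):
            ct = make_ct(counts)
            rows = counts.tolist()
            assert row_conditional_entropy(ct).h_given_x == pytest.approx(
                naive_row_entropies(rows), abs=1e-12
            )
            assert conditional_entropy(ct) == pytest.approx(
                naive_conditional_entropy(rows), abs=1e-12
            )
            assert shannon_entropy(ct.col_totals) == pytest.approx(
                naive_entropy([sum(r[j] for r in rows) for j in range(len(rows[0]))]),
                abs=1e-12,
            )
            assert rescaled_conditional_entropy(ct) == pytest.approx(
                naive_ratio(rows), abs=1e-12
            )
            assert mutual_conditional_entropy(ct) == pytest.approx(
                naive_mce(rows), abs=1e-12
            )

    def test_mce_transpose_symmetry_exact(self):
        rng = np.random.default_rng(7)
        for counts in random_tables(50, rng):
            ct = make_ct(counts)
            assert mutual_conditional_entropy(ct) == mutual_conditional_entropy(
                ct.transpose()
            )

    def test_base_change_scales_entropies_and_leaves_ratios(self):
        rng = np.random.default_rng(11)
        for counts in random_tables(50, rng):
            ct = make_ct(counts)
            nats = conditional_entropy(ct)
            bits = conditional_entropy(ct, base=2)
            assert bits == pytest.approx(nats / math.log(2), rel=1e-12, abs=1e-12)
            # ratios computed from base-2 quantities agree with the base-free ones
            h_y_bits = shannon_entropy(ct.col_totals, base=2)
            assert bits / h_y_bits == pytest.approx(
                rescaled_conditional_entropy(ct), abs=1e-12
            )


count_matrices = arrays(
    np.int64,
    st.tuples(st.integers(2, 5), st.integers(2, 5)),
    elements=st.integers(0, 20),
).filter(
    lambda m: (m.sum(axis=1) > 0).sum() >= 2 and (m.sum(axis=0) > 0).sum() >= 2
)


class TestProperties:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(counts=count_matrices)
    def test_conditioning_never_increases_entropy(self, counts):
        ct = make_ct(counts)
        h_yx = conditional_entropy(ct)
        h_y = shannon_entropy(ct.col_totals)
        assert h_yx >= -1e-12
        assert h_yx <= h_y + 1e-12
        assert h_y <= math.log(len(ct.y_levels)) + 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(counts=count_matrices, data=st.data())
    def test_label_permutation_invariance(self, counts, data):
        ct = make_ct(counts)
        kx, ky = counts.shape
        perm_x = data.draw(st.permutations(range(kx)))
        perm_y = data.draw(st.permutations(range(ky)))
        permuted = ContingencyTable(
            tuple(ct.x_levels[i] for i in perm_x),
            tuple(ct.y_levels[j] for j in perm_y),
            counts[np.ix_(perm_x, perm_y)],
        )
        assert conditional_entropy(permuted) == pytest.approx(
            conditional_entropy(ct), abs=1e-12
        )
        assert mutual_conditional_entropy(permuted) == pytest.approx(
            mutual_conditional_entropy(ct), abs=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(counts=count_matrices, factor=st.integers(2, 7))
    def test_count_scaling_invariance(self, counts, factor):
        ct, scaled = make_ct(counts), make_ct(counts * factor)
        assert conditional_entropy(scaled) == pytest.approx(
            conditional_entropy(ct), abs=1e-12
        )
        assert mutual_conditional_entropy(scaled) == pytest.approx(
            mutual_conditional_entropy(ct), abs=1e-12
        )

    def test_profile_bounds(self, table1):
        profile = row_conditional_entropy(table1)
        assert (profile.h_given_x >= 0).all()
        assert (profile.h_given_x <= math.log(4) + 1e-12).all()


class TestContingencyTableValidation:
    def test_rejects_negative_and_empty(self):
        with pytest.raises(ValidationError):
            make_ct([[1, -2], [0, 3]])
        with pytest.raises(ValidationError):
            make_ct([[0, 0], [0, 0]])

    def test_margins_sum_to_one(self, table1):
        assert table1.p_x.sum() == pytest.approx(1, abs=1e-12)
        assert table1.p_y.sum() == pytest.approx(1, abs=1e-12)
        assert table1.p_xy.sum() == pytest.approx(1, abs=1e-12)
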