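import numpy as np
import pytest

from surrqa import (
    INDEX_NAMES,
    RecurrencePlot,
    diagonal_histogram,
    recurrence_matrix,
    rqa_profile,
    series_profile,
    vertical_histogram,
)
from ._rqa_oracle import brute_fan, brute_profile


def _hist_to_lengths(hist):
    return sorted(l for l, c in enumerate(hist) for _ in range(c))


class TestFanMatrix:
    def test_column_sums_exactly_k(self, rng):
        states = rng.standard_normal((120, 4))
        rp = recurrence_matrix(states, eps=0.07)
        k = max(1, round(0.07 * 120))
        assert rp.k_neighbors == k
        assert np.all(rp.matrix.sum(axis=0) == k)

    def test_diagonal_always_set(self, rng):
        states = rng.standard_normal((50, 3))
        rp = recurrence_matrix(states, eps=0.07)
        assert np.all(np.diagonal(rp.matrix))

    def test_rr_equals_k_over_n(self, rng):
        states = rng.standard_normal((100, 2))
        rp = recurrence_matrix(states, eps=0.07)
        assert rp.matrix.mean() == rp.k_neighbors / 100

    def test_matches_brute_force_sort(self, rng):
        states = np.random.default_rng(42).standard_normal((20, 3))
        rp = recurrence_matrix(states, eps=0.2)
        assert np.array_equal(rp.matrix, brute_fan(states, rp.k_neighbors))

    def test_k1_marks_only_self(self):
        states = np.arange(10.0)[:, None]
        rp = recurrence_matrix(states, eps=0.01)
        assert rp.k_neighbors == 1
        assert np.array_equal(rp.matrix, np.eye(10, dtype=bool))

    def test_tie_break_lower_index(self):
        # states 0 and 2 equidistant from state 1: lower index must win at k=2
        states = np.array([0.0, 1.0, 2.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0])[:, None]
        rp = recurrence_matrix(states, eps=0.2)  # k=2
        col = rp.matrix[:, 1]
        assert col[1] and col[0] and not col[2]

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError):
            recurrence_matrix(rng.standard_normal((12, 2)), eps=1.0)

    def test_too_few_states_errors(self, rng):
        with pytest.raises(ValueError):
            recurrence_matrix(rng.standard_normal((5, 2)), eps=0.5)


class TestLineHistograms:
    def test_all_ones_diagonals(self):
        mat = np.ones((10, 10), dtype=bool)
        rp = RecurrencePlot(mat, 10, 1.0, theiler=0)
        hist = diagonal_histogram(rp, theiler=0)
        # off-diagonal runs: two of each length 1..9
        assert _hist_to_lengths(hist) == sorted(list(range(1, 10)) * 2)

    def test_all_zeros_empty(self):
        rp = RecurrencePlot(np.zeros((8, 8), dtype=bool), 1, 0.1, theiler=0)
        assert diagonal_histogram(rp).sum() == 0
        assert vertical_histogram(rp).sum() == 0

    def test_all_ones_verticals(self):
        mat = np.ones((10, 10), dtype=bool)
        rp = RecurrencePlot(mat, 10, 1.0, theiler=0)
        hist = vertical_histogram(rp)
        assert hist[10] == 10 and hist.sum() == 10

    def test_alternating_column_unit_runs(self):
        mat = np.zeros((10, 10), dtype=bool)
        mat[::2, 0] = True
        rp = RecurrencePlot(mat, 1, 0.1, theiler=0)
        hist = vertical_histogram(rp)
        assert hist[1] == 5 and hist[2:].sum() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_histograms_match_enumeration(self, seed):
        from .conftest import random_binary_matrix
        from ._rqa_oracle import diag_line_lengths, vert_line_lengths

        mat = random_binary_matrix(seed)
        rp = RecurrencePlot(mat, 0, 0.3, theiler=2)
        assert _hist_to_lengths(diagonal_histogram(rp)) == sorted(diag_line_lengths(mat, 2))
        assert _hist_to_lengths(vertical_histogram(rp)) == sorted(vert_line_lengths(mat))


class TestRqaProfile:
    def test_all_ones_complete_graph(self):
        mat = np.ones((20, 20), dtype=bool)
        rp = RecurrencePlot(mat, 20, 1.0, theiler=0)
        p = rqa_profile(rp, theiler=0)
        assert p.rr == 1.0
        # off-LOI diagonals include two single-point corner runs, so DET is
        # marginally below 1 while the vertical and network views are exact
        assert p.det == pytest.approx(1.0, abs=0.01)
        assert p.lam == 1.0
        assert p.cc == 1.0
        assert p.trans == 1.0

    def test_loi_only_sentinels(self):
        mat = np.eye(20, dtype=bool)
        rp = RecurrencePlot(mat, 1, 0.05, theiler=0)
        p = rqa_profile(rp, theiler=0)
        assert p.rr == pytest.approx(1 / 20)
        assert p.det == 0.0  # diagonal runs excluded with the LOI band
        assert "t1" in p.flags  # no column with two points

    def test_ranges_on_fan_plots(self, ar2s_series):
        p = series_profile(ar2s_series.values, m=5, tau=3)
        assert 0 <= p.rr <= 1 and 0 <= p.det <= 1 and 0 <= p.lam <= 1
        assert 0 <= p.rpde <= 1 and 0 <= p.cc <= 1 and 0 <= p.trans <= 1
        assert p.t1 >= 1 and p.t2 >= 1
        assert p.adl >= 2 and p.tt >= 2
        assert p.ent >= 0

    @pytest.mark.parametrize("seed", range(50))
    def test_all_indices_match_brute_force(self, seed):
        from .conftest import random_binary_matrix

        mat = random_binary_matrix(seed)
        rp = RecurrencePlot(mat, 0, 0.3, theiler=2)
        mine = rqa_profile(rp, theiler=2).as_dict()
        ref = brute_profile(mat, theiler=2)
        for name in INDEX_NAMES:
            a, b = mine[name], ref[name]
            if np.isnan(b):
                assert np.isnan(a), name
            else:
                assert a == pytest.approx(b, abs=1e-12), name

    def test_adding_point_never_shrinks_longest_lines(self, rng):
        from .conftest import random_binary_matrix

        mat = random_binary_matrix(7, n=25, density=0.2)
        rp = RecurrencePlot(mat, 0, 0.2, theiler=1)
        base = rqa_profile(rp, theiler=1)
        zeros = np.argwhere(~mat)
        r = np.random.default_rng(0)
        for i, j in zeros[r.choice(len(zeros), size=10, replace=False)]:
            mat2 = mat.copy()
            mat2[i, j] = True
            p2 = rqa_profile(RecurrencePlot(mat2, 0, 0.2, theiler=1), theiler=1)
            assert p2.lldl >= base.lldl
            assert p2.llvl >= base.llvl

    def test_unknown_index_rejected(self, rng):
        rp = recurrence_matrix(rng.standard_normal((30, 2)), eps=0.1)
        with pytest.raises(ValueError, match="unknown"):
            rqa_profile(rp, indices=["bogus"])

    def test_subset_computation_leaves_rest_nan(self, rng):
        rp = recurrence_matrix(rng.standard_normal((30, 2)), eps=0.1)
        p = rqa_profile(rp, indices=["lam"])
        assert np.isfinite(p.lam)
        assert np.isnan(p.det) and np.isnan(p.cc)
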