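import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diplohmm.matrix import GAP, AlignmentMatrix, AlignmentMatrixError

from conftest import make_matrix
from oracles import random_matrix


@st.composite
def read_intervals(draw, n_cols=6, max_rows=6):
    """Row intervals [lo, hi] over a fixed number of columns."""
    m = draw(st.integers(1, max_rows))
    rows = []
    for _ in range(m):
        lo = draw(st.integers(0, n_cols - 1))
        hi = draw(st.integers(lo, n_cols - 1))
        rows.append((lo, hi))
    return rows


def matrix_from_intervals(rows, n_cols=6):
    entries = np.full((len(rows), n_cols), GAP, dtype=np.int16)
    weights = np.zeros((len(rows), n_cols))
    for i, (lo, hi) in enumerate(rows):
        entries[i, lo : hi + 1] = 0
        weights[i, lo : hi + 1] = 30.0
    covered = (entries != GAP).any(axis=0)
    entries, weights = entries[:, covered], weights[:, covered]
    return AlignmentMatrix(
        entries,
        weights,
        np.arange(entries.shape[1]),
        [("G", "T")] * entries.shape[1],
        [f"r{i}" for i in range(len(rows))],
    )


class TestActiveRows:
    def test_internal_gap_row_stays_active(self):
        m = make_matrix(["G-T", "GGT"])
        assert 0 in m.active_rows(1)

    def test_single_column_all_rows_active(self):
        m = make_matrix(["G", "T", "G"])
        assert m.active_rows(0) == {0, 1, 2}

    def test_matches_linear_scan(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 6, 5)
            for j in range(m.n):
                expected = set()
                for i in range(m.m):
                    nongap = np.flatnonzero(m.entries[i] != GAP)
                    if nongap[0] <= j <= nongap[-1]:
                        expected.add(i)
                assert m.active_rows(j) == expected

    def test_out_of_range_raises(self):
        m = make_matrix(["GT"])
        with pytest.raises(IndexError):
            m.active_rows(2)
        with pytest.raises(IndexError):
            m.active_nonterminal_rows(-1)


class TestActiveNonterminal:
    def test_last_column_empty(self, rng):
        for _ in range(5):
            m = random_matrix(rng, 5, 4)
            assert m.active_nonterminal_rows(m.n - 1) == set()

    def test_row_ending_at_j_excluded(self):
        m = make_matrix(["GG-", "GGG"])
        assert m.active_nonterminal_rows(1) == {1}

    def test_each_row_terminal_exactly_once(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 6, 5)
            total = sum(
                len(m.active_rows(j)) - len(m.active_nonterminal_rows(j))
                for j in range(m.n)
            )
            assert total == m.m

    def test_subset_of_active(self, rng):
        m = random_matrix(rng, 6, 5)
        for j in range(m.n):
            assert m.active_nonterminal_rows(j) <= m.active_rows(j)


class TestMaxCoverage:
    def test_full_span_reads(self):
        m = make_matrix(["GGG", "GTG", "TGG", "GGT"])
        assert m.max_coverage() == 4

    def test_tiled_reads_overlap_pairwise(self):
        m = make_matrix(["GG--", "-GG-", "--GG"])
        assert m.max_coverage() == 2

    def test_equals_recomputation(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 7, 6)
            assert m.max_coverage() == max(
                len(m.active_rows(j)) for j in range(m.n)
            )


class TestIntervalProperties:
    @settings(derandomize=True, max_examples=60)
    @given(read_intervals())
    def test_terminal_once_and_nonterminal_subset(self, rows):
        m = matrix_from_intervals(rows)
        total = 0
        for j in range(m.n):
            a, ant = m.active_rows(j), m.active_nonterminal_rows(j)
            assert ant <= a
            total += len(a) - len(ant)
        assert total == m.m

    @settings(derandomize=True, max_examples=60)
    @given(read_intervals(), st.integers(1, 4))
    def test_cut_conserves_entries_and_respects_k(self, rows, k):
        m = matrix_from_intervals(rows)
        cut = m.cut_reads(k)
        assert (cut.entries != GAP).sum() == (m.entries != GAP).sum()
        for i in range(cut.m):
            assert (cut.entries[i] != GAP).sum() <= k


class TestCutReads:
    def test_five_columns_cut_to_two(self):
        m = make_matrix(["GGGGG", "TTTTT"])
        cut = m.cut_reads(2)
        frags = [i for i, r in enumerate(cut.read_ids) if r.startswith("r0/")]
        assert len(frags) == 3
        spans = [
            np.flatnonzero(cut.entries[i] != GAP) for i in frags
        ]
        assert [list(s) for s in spans] == [[0, 1], [2, 3], [4]]

    def test_large_k_is_identity(self):
        m = make_matrix(["GGG", "TTT"])
        cut = m.cut_reads(5)
        assert cut.read_ids == m.read_ids
        assert np.array_equal(cut.entries, m.entries)

    def test_nongap_entries_conserved(self, rng):
        for k in (1, 2, 3):
            m = random_matrix(rng, 6, 5)
            cut = m.cut_reads(k)
            assert (cut.entries != GAP).sum() == (m.entries != GAP).sum()
            # no fragment covers more than k columns
            for i in range(cut.m):
                cov = np.flatnonzero(cut.entries[i] != GAP)
                assert len(cov) <= k

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            make_matrix(["GT"]).cut_reads(0)


class TestDownsample:
    def _deep_matrix(self, rng, m=80, n=10):
        entries = rng.integers(0, 2, size=(m, n)).astype(np.int16)
        weights = np.full((m, n), 30.0)
        return AlignmentMatrix(
            entries, weights, np.arange(n), [("G", "T")] * n,
            [f"r{i}" for i in range(m)],
        )

    def test_target_at_current_is_identity_with_warning(self, rng):
        m = self._deep_matrix(rng)
        with pytest.warns(UserWarning):
            out = m.downsample(m.column_depths().mean(), seed=1)
        assert out is m

    def test_deterministic_under_seed(self, rng):
        m = self._deep_matrix(rng)
        a = m.downsample(20, seed=42)
        b = m.downsample(20, seed=42)
        assert a.read_ids == b.read_ids

    def test_mean_realized_depth(self, rng):
        m = self._deep_matrix(rng)
        depths = [
            m.downsample(40, seed=s).column_depths().mean() for s in range(300)
        ]
        assert abs(np.mean(depths) - 40) / 40 < 0.05


class TestInvariants:
    def test_rejects_all_gap_row(self):
        with pytest.raises(AlignmentMatrixError):
            make_matrix(["GG", "--"])

    def test_rejects_nonmonotone_positions(self):
        with pytest.raises(AlignmentMatrixError):
            make_matrix(["GG"], positions=[5, 5])

    def test_rejects_weight_on_gap(self):
        entries = np.array([[0, GAP]], dtype=np.int16)
        weights = np.array([[30.0, 1.0]])
        with pytest.raises(AlignmentMatrixError):
            AlignmentMatrix(entries, weights, [0, 1], [("G", "T")] * 2, ["r0"])


class TestTextDialect:
    def test_round_trip(self, rng):
        m = random_matrix(rng, 5, 4)
        back = AlignmentMatrix.from_text(m.to_text())
        assert np.array_equal(back.entries, m.entries)
        assert np.allclose(back.weights, m.weights)
        assert back.site_alleles == m.site_alleles
        assert back.read_ids == m.read_ids
        assert np.array_equal(back.site_positions, m.site_positions)
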