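import itertools

import numpy as np
import pytest

from softcomp.codebook import (
    ESCAPE,
    Codebook,
    build_codebook,
    codebook_checksum,
    extract_shape,
    load_codebook,
    mine_candidates,
    qualifies_as_candidate,
    save_codebook,
    score_shape,
)
from softcomp.errors import FormatError, ParameterError, StructuralError


def _brute_force_qualifies(window):
    """Direct evaluation of the row/column L0-norm inequalities."""
    w = np.asarray(window)
    m, n = w.shape
    rows_ok = all(np.count_nonzero(w[i]) >= n / 2 for i in range(m))
    cols_ok = all(np.count_nonzero(w[:, j]) >= m / 2 for j in range(n))
    return rows_ok and cols_ok


class TestCandidateCondition:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ([[1]], True),
            ([[1, 0], [0, 1]], True),
            ([[1, 0, 0]], False),
        ],
    )
    def test_stated_examples(self, window, expected):
        assert qualifies_as_candidate(np.array(window)) is expected

    def test_empty_matrix_rejected(self):
        with pytest.raises(StructuralError):
            qualifies_as_candidate(np.zeros((0, 3)))

    def test_agrees_with_brute_force_on_all_binary_3x3(self):
        for bits in itertools.product((0, 1), repeat=9):
            w = np.array(bits).reshape(3, 3)
            assert qualifies_as_candidate(w) == _brute_force_qualifies(w)


class TestExtractShape:
    def test_singleton(self):
        assert extract_shape(np.array([[2]])).cells == ((0, 0, 2),)

    def test_diagonal(self):
        assert extract_shape(np.array([[1, 0], [0, 3]])).cells == (
            (0, 0, 1),
            (1, 1, 3),
        )

    def test_anti_diagonal_has_negative_column_offset(self):
        assert extract_shape(np.array([[0, 5], [5, 0]])).cells == (
            (0, 0, 5),
            (1, -1, 5),
        )

    def test_identity_is_invariant_under_producing_window(self):
        # same nonzero pattern embedded in different qualifying windows
        a = extract_shape(np.array([[1, 0], [0, 3]]))
        b = extract_shape(np.array([[1, 0, 0], [0, 3, 0]]))
        assert a == b and hash(a) == hash(b)


class TestMining:
    def test_all_zero_corpus_yields_empty_table(self):
        assert mine_candidates([np.zeros((4, 4), dtype=int)]) == {}

    def test_empty_corpus_rejected(self):
        with pytest.raises(ParameterError):
            mine_candidates([])

    def test_hand_enumerated_2x2_plane(self):
        # 9 windows: two 1x1 singletons qualify, the 2x2 diagonal qualifies,
        # the zero 1x1s and all 1x2/2x1 windows fail the column/row condition
        table = mine_candidates([np.array([[1, 0], [0, 1]])], 2, 2)
        singleton = extract_shape(np.array([[1]]))
        diagonal = extract_shape(np.array([[1, 0], [0, 1]]))
        assert table == {singleton: 2, diagonal: 1}

    def test_tiled_motif_counted_at_least_once_per_copy(self):
        motif = np.array([[2, 1], [1, 2]])
        plane = np.zeros((12, 12), dtype=int)
        k = 0
        for r in range(0, 12, 4):
            for c in range(0, 12, 4):
                plane[r : r + 2, c : c + 2] = motif
                k += 1
        table = mine_candidates([plane])
        assert table[extract_shape(motif)] >= k


class TestScore:
    def test_size_one_reduces_to_frequency(self):
        assert score_shape(10, 1, 0.7) == 10

    def test_half_degree_example(self):
        assert score_shape(4, 4, 0.5) == pytest.approx(8.0)

    def test_degree_zero_is_pure_frequency(self):
        assert score_shape(5, 9, 0.0) == 5

    def test_monotone_in_both_arguments(self):
        for f, s in itertools.product(range(1, 6), range(1, 6)):
            assert score_shape(f + 1, s, 0.5) > score_shape(f, s, 0.5)
            assert score_shape(f, s + 1, 0.5) > score_shape(f, s, 0.5)


def _tiny_codebook(q=4):
    table = mine_candidates([np.array([[1, 0], [0, 1]])], 2, 2)
    return build_codebook(table, {0: 10, 1: 5, 2: 2, 3: 1}, capacity=16, q=q)


class TestBuildCodebook:
    def test_two_equal_shapes_plus_escape_lengths(self):
        """Huffman over frequencies (f, f, 1) gives lengths (1, 2, 2)."""
        s1 = extract_shape(np.array([[1]]))
        s2 = extract_shape(np.array([[2]]))
        cb = build_codebook({s1: 5, s2: 5}, {}, capacity=8)
        lengths = sorted(cb.shape_lengths.values())
        assert lengths == [1, 2, 2]
        assert cb.shape_lengths[ESCAPE] == 2

    def test_kraft_inequality_and_detail_completeness(self):
        cb = _tiny_codebook()
        assert sum(2.0 ** -l for l in cb.shape_lengths.values()) <= 1.0
        assert sum(2.0 ** -l for l in cb.detail_lengths.values()) == 1.0
        assert sorted(cb.detail_codes) == [0, 1, 2, 3]

    def test_capacity_too_small_rejected(self):
        s1 = extract_shape(np.array([[1]]))
        s2 = extract_shape(np.array([[2]]))
        with pytest.raises(ParameterError):
            build_codebook({s1: 1, s2: 1}, {}, capacity=2)

    def test_singletons_survive_pruning(self):
        # a high-scoring big shape must not evict observed singletons
        big = extract_shape(np.array([[1, 1], [1, 1]]))
        s1 = extract_shape(np.array([[7]]))
        cb = build_codebook({big: 100, s1: 1}, {}, capacity=2)
        assert s1 in cb.shape_freqs

    def test_empty_table_codebook_still_valid(self):
        cb = build_codebook({}, {}, capacity=1)
        assert list(cb.shape_lengths) == [ESCAPE]
        assert cb.escape_code == "0"


class TestSerialization:
    def test_empty_corpus_codebook_round_trips(self, tmp_path):
        cb = build_codebook({}, {}, capacity=1)
        path = tmp_path / "cb.sccb"
        save_codebook(cb, path)
        assert load_codebook(path) == cb

    def test_trained_codebook_round_trips_byte_exactly(self, tmp_path,
                                                       rgb_codebooks):
        cbs, _ = rgb_codebooks
        for i, cb in enumerate(cbs):
            path = tmp_path / f"cb{i}.sccb"
            save_codebook(cb, path)
            reloaded = load_codebook(path)
            assert reloaded == cb
            assert reloaded.to_bytes() == cb.to_bytes()

    def test_truncated_file_is_format_error(self, tmp_path):
        cb = _tiny_codebook()
        data = cb.to_bytes()
        for cut in (3, 10, len(data) - 1):
            path = tmp_path / "cut.sccb"
            path.write_bytes(data[:cut])
            with pytest.raises(FormatError):
                load_codebook(path)

    def test_corrupted_byte_is_format_error(self, tmp_path):
        data = bytearray(_tiny_codebook().to_bytes())
        data[len(data) // 2] ^= 0xFF
        path = tmp_path / "bad.sccb"
        path.write_bytes(bytes(data))
        with pytest.raises(FormatError):
            load_codebook(path)

    def test_checksum_is_order_sensitive(self, rgb_codebooks):
        cbs, _ = rgb_codebooks
        assert codebook_checksum(cbs) != codebook_checksum(cbs[::-1])
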