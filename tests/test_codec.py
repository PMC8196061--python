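import numpy as np
import pytest

from softcomp.codebook import ESCAPE, build_codebook, extract_shape, mine_candidates
from softcomp.codec import (
    CompressedImage,
    bit_account,
    cover_shape_layer,
    decode_detail_block,
    decode_image,
    decode_shape_block,
    encode_detail_block,
    encode_image,
    encode_shape_block,
    huffman_baseline_bits,
    paint_placements,
)
from softcomp.errors import CodebookMismatchError, FormatError
from softcomp.image import RasterImage


def _cb_for_layer(layers, q=4, capacity=64):
    """Train a tiny codebook directly on the given shape layers."""
    table = mine_candidates(layers, 4, 4)
    return build_codebook(table, {i: 1 for i in range(q)}, capacity=capacity, q=q)


def _min_cover_size(layer, cb):
    """Exhaustive minimum number of placements covering all nonzeros."""
    a = np.asarray(layer)
    rows, cols = a.shape

    def rec(covered):
        target = None
        for r in range(rows):
            for c in range(cols):
                if a[r, c] != 0 and not covered[r, c]:
                    target = (r, c)
                    break
            if target:
                break
        if target is None:
            return 0
        r, c = target
        best = None
        options = list(cb.candidates_for(int(a[r, c]))) + [ESCAPE]
        for s in options:
            cells = [(0, 0)] if s is ESCAPE else [(dr, dc) for dr, dc, _ in s.cells]
            vals = [int(a[r, c])] if s is ESCAPE else [v for _, _, v in s.cells]
            ok = True
            for (dr, dc), v in zip(cells, vals):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols) or covered[rr, cc] \
                        or a[rr, cc] != v:
                    ok = False
                    break
            if not ok:
                continue
            for dr, dc in cells:
                covered[r + dr, c + dc] = True
            sub = 1 + rec(covered)
            for dr, dc in cells:
                covered[r + dr, c + dc] = False
            if best is None or sub < best:
                best = sub
        return best

    return rec(np.zeros(a.shape, dtype=bool))


class TestCover:
    def test_all_zero_layer_has_empty_cover(self):
        cb = _cb_for_layer([np.array([[1, 0], [0, 1]])])
        assert cover_shape_layer(np.zeros((4, 4), dtype=int), cb) == []

    def test_layer_equal_to_one_codebook_shape(self):
        layer = np.array([[1, 0], [0, 1]])
        cb = _cb_for_layer([layer])
        placements = cover_shape_layer(layer, cb)
        assert len(placements) == 1
        p = placements[0]
        assert (p.row, p.col) == (0, 0)
        assert p.shape == extract_shape(layer)

    def test_tiled_motif_cover_matches_brute_force_minimum(self):
        # train on *disjoint* motif copies so the codebook's largest match
        # for the tiled layer is the 2x2 motif itself
        motif = np.array([[2, 1], [1, 2]])
        layer = np.tile(motif, (2, 2))
        train = np.zeros((10, 10), dtype=int)
        for r in (0, 4, 8):
            for c in (0, 4, 8):
                train[r : r + 2, c : c + 2] = motif
        cb = _cb_for_layer([train])
        placements = cover_shape_layer(layer, cb)
        assert len(placements) == 4
        assert all(p.shape is not ESCAPE for p in placements)
        assert _min_cover_size(layer, cb) == 4

    def test_cover_is_disjoint_and_repaints_the_layer(self, rng):
        layer = rng.integers(0, 3, size=(16, 16)) * rng.integers(1, 5, size=(16, 16))
        cb = _cb_for_layer([layer])
        placements = cover_shape_layer(layer, cb)
        seen = np.zeros(layer.shape, dtype=int)
        for p in placements:
            cells = [(0, 0)] if p.shape is ESCAPE else \
                [(dr, dc) for dr, dc, _ in p.shape.cells]
            for dr, dc in cells:
                seen[p.row + dr, p.col + dc] += 1
        assert seen.max() <= 1  # disjoint
        assert np.array_equal(seen != 0, layer != 0)  # covering
        assert np.array_equal(paint_placements(placements, 16, 16), layer)

    def test_unseen_value_goes_through_escape(self):
        cb = _cb_for_layer([np.array([[1, 0], [0, 1]])])
        placements = cover_shape_layer(np.array([[9]]), cb)
        assert placements[0].shape is ESCAPE
        assert placements[0].value == 9


class TestShapeBlock:
    def test_empty_block_holds_only_count_and_parameter(self):
        cb = _cb_for_layer([np.array([[1]])])
        data, bits, k = encode_shape_block([], cb, 4, 4)
        assert bits == 36 and k == 0
        assert decode_shape_block(data, bits, cb, 4, 4) == []

    def test_single_placement_at_origin_costs_one_location_bit(self):
        layer = np.array([[5, 0], [0, 0]])
        cb = _cb_for_layer([layer])
        placements = cover_shape_layer(layer, cb)
        data, bits, k = encode_shape_block(placements, cb, 2, 2)
        codeword_len = len(cb.shape_codes[placements[0].shape])
        assert k == 0
        assert bits == 36 + 1 + codeword_len  # fields + Rice "0" + codeword
        assert decode_shape_block(data, bits, cb, 2, 2) == placements

    def test_round_trip_on_random_layers(self, rng):
        for _ in range(10):
            layer = rng.integers(0, 4, size=(12, 9))
            cb = _cb_for_layer([layer])
            placements = cover_shape_layer(layer, cb)
            data, bits, _ = encode_shape_block(placements, cb, 12, 9)
            assert decode_shape_block(data, bits, cb, 12, 9) == placements


class TestDetailBlock:
    def test_bit_length_is_frequency_weighted_code_length(self, rng):
        detail = rng.integers(0, 4, size=(8, 8))
        cb = _cb_for_layer([np.zeros((2, 2), dtype=int) + 1])
        data, bits = encode_detail_block(detail, cb)
        expect = sum(
            np.count_nonzero(detail == s) * len(c)
            for s, c in cb.detail_codes.items()
        )
        assert bits == expect
        assert np.array_equal(decode_detail_block(data, bits, cb, 8, 8), detail)


class TestEndToEnd:
    def test_structured_images_round_trip(self, rgb_corpus, rgb_codebooks, rng):
        from softcomp.image import read_image

        _, _, test_paths = rgb_corpus
        cbs, _ = rgb_codebooks
        for path in test_paths[:3]:
            img = read_image(path)
            assert decode_image(encode_image(img, cbs), cbs) == img

    def test_uniform_noise_round_trips_via_escape(self, rgb_codebooks, rng):
        cbs, _ = rgb_codebooks
        img = RasterImage([rng.integers(0, 256, size=(16, 16)) for _ in range(3)])
        assert decode_image(encode_image(img, cbs), cbs) == img

    def test_degenerate_1x1_grayscale(self, gray_codebooks):
        cbs, _ = gray_codebooks
        img = RasterImage([[[7]]])
        assert decode_image(encode_image(img, cbs), cbs) == img

    def test_container_bytes_round_trip(self, gray_codebooks):
        cbs, _ = gray_codebooks
        img = RasterImage([np.arange(64).reshape(8, 8) % 256])
        c = encode_image(img, cbs)
        parsed = CompressedImage.from_bytes(c.to_bytes())
        assert parsed.to_bytes() == c.to_bytes()
        assert decode_image(parsed, cbs) == img

    def test_wrong_codebooks_rejected_by_checksum(self, rgb_codebooks,
                                                  gray_codebooks):
        cbs, _ = rgb_codebooks
        other = [gray_codebooks[0][0]] * 3
        img = RasterImage([np.zeros((4, 4), dtype=int)] * 3)
        c = encode_image(img, cbs)
        with pytest.raises(CodebookMismatchError):
            decode_image(c, other)

    def test_corrupted_container_is_format_error(self, gray_codebooks):
        cbs, _ = gray_codebooks
        img = RasterImage([np.zeros((4, 4), dtype=int)])
        data = bytearray(encode_image(img, cbs).to_bytes())
        data[6] ^= 0x10
        with pytest.raises(FormatError):
            CompressedImage.from_bytes(bytes(data))


class TestBitAccount:
    def test_accounting_balances_on_fixture_images(self, rgb_corpus,
                                                   rgb_codebooks):
        from softcomp.image import read_image

        _, _, test_paths = rgb_corpus
        cbs, _ = rgb_codebooks
        img = read_image(test_paths[0])
        c = encode_image(img, cbs)
        acct = bit_account(c, cbs)  # raises if any identity fails
        assert acct.total_bits == 8 * len(c.to_bytes())
        for comp, (_, sbits) in zip(acct.components, c.shape_blocks):
            assert comp.unit_bits + comp.location_bits + comp.shape_field_bits \
                == sbits

    def test_empty_shape_block_account(self, gray_codebooks):
        cbs, _ = gray_codebooks
        img = RasterImage([np.zeros((4, 4), dtype=int)])
        c = encode_image(img, cbs)
        comp = bit_account(c, cbs).components[0]
        # constant-zero plane: only the (0,0) residual is nonzero at most
        assert comp.n_units <= 1
        if comp.n_units == 0:
            assert comp.unit_bits == 0 and comp.location_bits == 0


class TestHuffmanBaseline:
    def test_constant_image_costs_one_bit_per_subpixel(self):
        img = RasterImage([np.full((8, 8), 77)] * 3)
        assert huffman_baseline_bits(img) == 3 * 64

    def test_two_valued_half_and_half(self):
        plane = np.zeros((8, 8), dtype=int)
        plane[:, 4:] = 255
        assert huffman_baseline_bits(RasterImage([plane])) == 64

    def test_never_exceeds_natural_binary(self, rng):
        img = RasterImage([rng.integers(0, 256, size=(16, 16)) for _ in range(3)])
        assert huffman_baseline_bits(img) <= 8 * 3 * 256
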