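"""End-to-end encoder/decoder and bit accounting.

Pipeline (per image)::

    split components -> RCT (3-component only) -> MED prediction
    -> sign mapping -> layer split at Q
    -> shape layer: greedy cover by codebook shapes -> (location, shape) pairs
    -> detail layer: per-symbol Huffman codewords in raster order

The shape layer is represented as placements ``(x_i, y_i, S_i)``: anchors
strictly increase in raster order, so only the *gaps* between flattened
anchor indices are coded, with a Rice code (gaps from a sparse layer are
approximately geometric).  The first delta is the absolute flat index and
each later delta is ``gap - 1``.

Total cost follows the unit/location accounting

    B = sum_i [ l_I(x_i, y_i) + l_P(x_i, y_i) ]

where ``l_I`` is the bits for the basic unit (shape codeword, or escape
codeword plus raw value) and ``l_P`` the bits for its location;
:func:`bit_account` recomputes both terms from the container and checks
they reproduce the measured block lengths exactly.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import transforms
from .codebook import (
    ESCAPE,
    ESCAPE_RAW_BITS,
    Codebook,
    codebook_checksum,
)
from .entropy import (
    BitReader,
    BitWriter,
    choose_rice_parameter,
    rice_code_length,
    rice_decode,
    rice_encode,
)
from .errors import (
    CodebookMismatchError,
    ContractError,
    FormatError,
    ParameterError,
)
from .image import RasterImage, merge_components, split_components
from .layering import LayerPair, merge_layers, split_layers

__all__ = [
    "ShapePlacement",
    "CompressedImage",
    "BitAccount",
    "ComponentAccount",
    "cover_shape_layer",
    "encode_shape_block",
    "decode_shape_block",
    "encode_detail_block",
    "decode_detail_block",
    "encode_image",
    "decode_image",
    "bit_account",
    "huffman_baseline_bits",
]

CONTAINER_MAGIC = b"SCMC"
CONTAINER_VERSION = 1
PREDICTOR_MED = 1
MAPPING_ZIGZAG = 1

# bits spent on the in-block count (32) and Rice parameter (4) fields
SHAPE_BLOCK_FIELD_BITS = 36


@dataclass(frozen=True)
class ShapePlacement:
    """A shape instance anchored at (row, col) in the shape layer.

    ``shape`` is a codebook :class:`Shape`, or ``ESCAPE`` with the raw
    shape-layer value carried in ``value``.
    """

    row: int
    col: int
    shape: object
    value: int = 0  # escape payload only


def cover_shape_layer(layer: np.ndarray, cb: Codebook) -> List[ShapePlacement]:
    """Greedy raster-order cover of the nonzero cells of a shape layer.

    At each uncovered nonzero pixel the codebook's candidate shapes for
    that anchor value are tried largest-first (then shorter codeword, then
    serialization order); a shape matches when all its cells land
    in-bounds, uncovered, and equal to the layer.  Pixels no retained
    shape matches are emitted as ESCAPE placements, so the cover always
    completes.
    """
    a = np.asarray(layer, dtype=np.int64)
    rows, cols = a.shape
    covered = np.zeros(a.shape, dtype=bool)
    placements: List[ShapePlacement] = []
    nz_rows, nz_cols = np.nonzero(a)
    for r, c in zip(nz_rows, nz_cols):
        if covered[r, c]:
            continue
        v = int(a[r, c])
        chosen = None
        for s in cb.candidates_for(v):
            ok = True
            for dr, dc, val in s.cells:
                rr, cc = r + dr, c + dc
                if (
                    rr < 0
                    or rr >= rows
                    or cc < 0
                    or cc >= cols
                    or covered[rr, cc]
                    or a[rr, cc] != val
                ):
                    ok = False
                    break
            if ok:
                chosen = s
                break
        if chosen is not None:
            for dr, dc, _ in chosen.cells:
                covered[r + dr, c + dc] = True
            placements.append(ShapePlacement(int(r), int(c), chosen))
        else:
            if v >= 1 << ESCAPE_RAW_BITS:
                raise ContractError(
                    f"shape-layer value {v} exceeds the escape field width"
                )
            covered[r, c] = True
            placements.append(ShapePlacement(int(r), int(c), ESCAPE, v))
    return placements


def _anchor_deltas(placements: Sequence[ShapePlacement], n_cols: int) -> List[int]:
    deltas = []
    prev = None
    for p in placements:
        flat = p.row * n_cols + p.col
        if prev is None:
            deltas.append(flat)
        else:
            if flat <= prev:
                raise ContractError("placement anchors must strictly increase")
            deltas.append(flat - prev - 1)
        prev = flat
    return deltas


def encode_shape_block(
    placements: Sequence[ShapePlacement],
    cb: Codebook,
    n_rows: int,
    n_cols: int,
) -> Tuple[bytes, int, int]:
    """Encode placements as count, Rice parameter, then delta+codeword pairs.

    Returns (block bytes, bit length, Rice parameter k).
    """
    deltas = _anchor_deltas(placements, n_cols)
    k = choose_rice_parameter(deltas) if deltas else 0
    w = BitWriter()
    w.write_bits(len(placements), 32)
    w.write_bits(k, 4)
    for p, d in zip(placements, deltas):
        rice_encode(w, d, k)
        if p.shape is ESCAPE:
            w.write_codeword(cb.escape_code)
            w.write_bits(p.value, ESCAPE_RAW_BITS)
        else:
            w.write_codeword(cb.shape_codes[p.shape])
    return w.getvalue(), w.bit_length, k


def decode_shape_block(
    data: bytes, bit_length: int, cb: Codebook, n_rows: int, n_cols: int
) -> List[ShapePlacement]:
    """Inverse of :func:`encode_shape_block`."""
    r = BitReader(data, bit_length)
    count = r.read_bits(32)
    k = r.read_bits(4)
    placements: List[ShapePlacement] = []
    flat = -1
    for i in range(count):
        d = rice_decode(r, k)
        flat = d if i == 0 else flat + d + 1
        row, col = divmod(flat, n_cols)
        sym = cb.shape_decoder.decode(r)
        if sym is ESCAPE:
            value = r.read_bits(ESCAPE_RAW_BITS)
            placements.append(ShapePlacement(row, col, ESCAPE, value))
        else:
            placements.append(ShapePlacement(row, col, sym))
    return placements


def paint_placements(
    placements: Sequence[ShapePlacement], n_rows: int, n_cols: int
) -> np.ndarray:
    """Rebuild a shape layer by stamping placements onto a zero plane."""
    layer = np.zeros((n_rows, n_cols), dtype=np.int64)
    for p in placements:
        if p.shape is ESCAPE:
            layer[p.row, p.col] = p.value
        else:
            for dr, dc, v in p.shape.cells:
                layer[p.row + dr, p.col + dc] = v
    return layer


def encode_detail_block(detail: np.ndarray, cb: Codebook) -> Tuple[bytes, int]:
    """Concatenated detail codewords in raster order; returns (bytes, bits)."""
    d = np.asarray(detail, dtype=np.int64)
    if d.size and (d.min() < 0 or d.max() >= cb.q):
        raise ContractError("detail symbols outside the codebook alphabet")
    codes = cb.detail_codes
    w = BitWriter()
    for sym in d.ravel():
        w.write_codeword(codes[int(sym)])
    return w.getvalue(), w.bit_length


def decode_detail_block(
    data: bytes, bit_length: int, cb: Codebook, n_rows: int, n_cols: int
) -> np.ndarray:
    r = BitReader(data, bit_length)
    dec = cb.detail_decoder
    out = np.empty(n_rows * n_cols, dtype=np.int64)
    for i in range(out.size):
        out[i] = dec.decode(r)
    return out.reshape(n_rows, n_cols)


@dataclass
class CompressedImage:
    """Parsed compressed container for one image."""

    height: int
    width: int
    components: int
    q: int
    predictor_id: int
    mapping_id: int
    codebook_crc: int
    rice_ks: List[int]
    shape_blocks: List[Tuple[bytes, int]]  # (bytes, bit length)
    detail_blocks: List[Tuple[bytes, int]]

    def to_bytes(self) -> bytes:
        out = bytearray()
        out += CONTAINER_MAGIC
        out += struct.pack(">B", CONTAINER_VERSION)
        out += struct.pack(
            ">IIBBBBI",
            self.height,
            self.width,
            self.components,
            self.q,
            self.predictor_id,
            self.mapping_id,
            self.codebook_crc,
        )
        for k, (sb, sbits), (db, dbits) in zip(
            self.rice_ks, self.shape_blocks, self.detail_blocks
        ):
            out += struct.pack(">B", k)
            out += struct.pack(">I", sbits)
            out += sb
            out += struct.pack(">I", dbits)
            out += db
        out += struct.pack(">I", zlib.crc32(bytes(out)) & 0xFFFFFFFF)
        return bytes(out)

    @classmethod
    def from_bytes(cls, data: bytes) -> "CompressedImage":
        if len(data) < 4 + 1 + 16 + 4:
            raise FormatError("compressed container is truncated")
        if data[:4] != CONTAINER_MAGIC:
            raise FormatError("bad container magic")
        (stored_crc,) = struct.unpack(">I", data[-4:])
        if zlib.crc32(data[:-4]) & 0xFFFFFFFF != stored_crc:
            raise FormatError("container CRC mismatch")
        try:
            pos = 4
            (version,) = struct.unpack_from(">B", data, pos)
            pos += 1
            if version != CONTAINER_VERSION:
                raise FormatError(f"unsupported container version {version}")
            height, width, m, q, pred, mapping, cb_crc = struct.unpack_from(
                ">IIBBBBI", data, pos
            )
            pos += 16
            rice_ks, shape_blocks, detail_blocks = [], [], []
            for _ in range(m):
                (k,) = struct.unpack_from(">B", data, pos)
                pos += 1
                (sbits,) = struct.unpack_from(">I", data, pos)
                pos += 4
                nbytes = (sbits + 7) // 8
                sb = data[pos : pos + nbytes]
                if len(sb) != nbytes:
                    raise FormatError("shape block truncated")
                pos += nbytes
                (dbits,) = struct.unpack_from(">I", data, pos)
                pos += 4
                nbytes = (dbits + 7) // 8
                db = data[pos : pos + nbytes]
                if len(db) != nbytes:
                    raise FormatError("detail block truncated")
                pos += nbytes
                rice_ks.append(k)
                shape_blocks.append((sb, sbits))
                detail_blocks.append((db, dbits))
            if pos != len(data) - 4:
                raise FormatError("container has trailing garbage")
        except struct.error as exc:
            raise FormatError(f"corrupt container: {exc}") from exc
        return cls(
            height=height,
            width=width,
            components=m,
            q=q,
            predictor_id=pred,
            mapping_id=mapping,
            codebook_crc=cb_crc,
            rice_ks=rice_ks,
            shape_blocks=shape_blocks,
            detail_blocks=detail_blocks,
        )

    @property
    def total_bits(self) -> int:
        return 8 * len(self.to_bytes())


def _transform_planes(img: RasterImage) -> List[np.ndarray]:
    """Component planes after the (optional) RCT: [Y, U, V] or [gray]."""
    planes = split_components(img)
    if img.components == 3:
        y, u, v = transforms.rct_forward(*planes)
        return [y, u, v]
    return planes


def image_to_layers(img: RasterImage, q: int) -> List[LayerPair]:
    """Full preprocessing chain: components -> RCT -> predict -> map -> split."""
    layers = []
    for plane in _transform_planes(img):
        mapped = transforms.map_to_nonneg(transforms.predict(plane))
        layers.append(split_layers(mapped, q))
    return layers


def _check_codebooks(img_components: int, cbs: Sequence[Codebook]) -> None:
    if len(cbs) != img_components:
        raise ParameterError(
            f"need {img_components} codebooks, got {len(cbs)}"
        )
    qs = {cb.q for cb in cbs}
    if len(qs) != 1:
        raise ParameterError("codebooks disagree on the layer interface Q")


def encode_image(img: RasterImage, cbs: Sequence[Codebook]) -> CompressedImage:
    """Encode an image with one trained codebook per transformed component."""
    _check_codebooks(img.components, cbs)
    q = cbs[0].q
    rice_ks: List[int] = []
    shape_blocks: List[Tuple[bytes, int]] = []
    detail_blocks: List[Tuple[bytes, int]] = []
    for lp, cb in zip(image_to_layers(img, q), cbs):
        placements = cover_shape_layer(lp.shape_layer, cb)
        sb, sbits, k = encode_shape_block(
            placements, cb, img.height, img.width
        )
        db, dbits = encode_detail_block(lp.detail_layer, cb)
        rice_ks.append(k)
        shape_blocks.append((sb, sbits))
        detail_blocks.append((db, dbits))
    return CompressedImage(
        height=img.height,
        width=img.width,
        components=img.components,
        q=q,
        predictor_id=PREDICTOR_MED,
        mapping_id=MAPPING_ZIGZAG,
        codebook_crc=codebook_checksum(cbs),
        rice_ks=rice_ks,
        shape_blocks=shape_blocks,
        detail_blocks=detail_blocks,
    )


def decode_image(c: CompressedImage, cbs: Sequence[Codebook]) -> RasterImage:
    """Exact inverse of :func:`encode_image`."""
    _check_codebooks(c.components, cbs)
    if codebook_checksum(cbs) != c.codebook_crc:
        raise CodebookMismatchError(
            "container was encoded with a different codebook set"
        )
    if c.predictor_id != PREDICTOR_MED or c.mapping_id != MAPPING_ZIGZAG:
        raise FormatError("container uses an unknown predictor or mapping")
    planes = []
    for (sb, sbits), (db, dbits), cb in zip(
        c.shape_blocks, c.detail_blocks, cbs
    ):
        placements = decode_shape_block(sb, sbits, cb, c.height, c.width)
        shape_layer = paint_placements(placements, c.height, c.width)
        detail_layer = decode_detail_block(db, dbits, cb, c.height, c.width)
        mapped = merge_layers(
            LayerPair(shape_layer=shape_layer, detail_layer=detail_layer, q=c.q)
        )
        planes.append(transforms.unpredict(transforms.unmap(mapped)))
    if c.components == 3:
        b, g, r = transforms.rct_inverse(*planes)
        return merge_components([b, g, r])
    return merge_components(planes)


@dataclass
class ComponentAccount:
    """Bit usage of one component's blocks."""

    n_units: int  # T, number of placements
    unit_bits: int  # sum of l_I: shape codewords (+ escape raw bits)
    location_bits: int  # sum of l_P: Rice-coded anchor deltas
    shape_field_bits: int  # in-block count + Rice parameter fields
    shape_block_bits: int
    shape_padding_bits: int
    detail_bits: int
    detail_padding_bits: int
    header_bits: int  # per-component k byte + two length fields

    @property
    def total_bits(self) -> int:
        return (
            self.header_bits
            + self.shape_block_bits
            + self.shape_padding_bits
            + self.detail_bits
            + self.detail_padding_bits
        )


@dataclass
class BitAccount:
    """Exact bit budget of a container, per component and in total."""

    components: List[ComponentAccount]
    header_bits: int
    crc_bits: int

    @property
    def total_bits(self) -> int:
        return (
            self.header_bits
            + self.crc_bits
            + sum(c.total_bits for c in self.components)
        )


def bit_account(c: CompressedImage, cbs: Sequence[Codebook]) -> BitAccount:
    """Recompute the unit/location bit split by re-parsing the blocks.

    The conservation identity
    ``unit_bits + location_bits + field bits == shape_block_bits``
    is asserted for every component, and the grand total equals the
    container's byte length times eight.
    """
    _check_codebooks(c.components, cbs)
    comps: List[ComponentAccount] = []
    for (sb, sbits), (db, dbits), cb, k in zip(
        c.shape_blocks, c.detail_blocks, cbs, c.rice_ks
    ):
        placements = decode_shape_block(sb, sbits, cb, c.height, c.width)
        deltas = _anchor_deltas(placements, c.width)
        loc_bits = sum(rice_code_length(d, k) for d in deltas)
        unit_bits = 0
        for p in placements:
            if p.shape is ESCAPE:
                unit_bits += len(cb.escape_code) + ESCAPE_RAW_BITS
            else:
                unit_bits += len(cb.shape_codes[p.shape])
        acct = ComponentAccount(
            n_units=len(placements),
            unit_bits=unit_bits,
            location_bits=loc_bits,
            shape_field_bits=SHAPE_BLOCK_FIELD_BITS,
            shape_block_bits=sbits,
            shape_padding_bits=8 * len(sb) - sbits,
            detail_bits=dbits,
            detail_padding_bits=8 * len(db) - dbits,
            header_bits=8 * (1 + 4 + 4),  # k byte + two 4-byte length fields
        )
        if (
            acct.unit_bits + acct.location_bits + acct.shape_field_bits
            != acct.shape_block_bits
        ):
            raise ContractError("shape-block bit accounting does not balance")
        comps.append(acct)
    account = BitAccount(
        components=comps,
        header_bits=8 * (4 + 1 + 16),  # magic + version + fixed header
        crc_bits=32,
    )
    if account.total_bits != c.total_bits:
        raise ContractError("container bit accounting does not balance")
    return account


def huffman_baseline_bits(img: RasterImage) -> int:
    """Bits for independent per-component Huffman coding of raw pixels.

    No prediction, no component transform: each component's pixel
    histogram gets an optimal prefix code and the image costs
    ``sum_s freq(s) * len(s)`` bits per component (a constant component is
    one bit per pixel, the degenerate single-symbol code).
    """
    from .entropy import huffman_code_lengths

    total = 0
    for plane in img.planes:
        vals, counts = np.unique(plane, return_counts=True)
        freqs = {int(v): int(n) for v, n in zip(vals, counts)}
        lengths = huffman_code_lengths(freqs)
        total += sum(freqs[s] * lengths[s] for s in freqs)
    return total
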