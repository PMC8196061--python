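"""Shape mining and codebook construction.

The codec's basic unit is the *shape*: a pattern of nonzero shape-layer
cells, carrying their intensity values, with offsets normalised so the
raster-first cell sits at (0, 0).  Shapes are mined from the shape layers
of a training corpus:

* a rectangular window *qualifies* as a shape candidate when every row of
  length N holds at least N/2 nonzeros and every column of length M at
  least M/2 (the L0-norm conditions, with real-valued halves);
* a qualifying window is reduced to a shape by dropping its zeros and
  re-basing offsets on the raster-first nonzero — so different windows with
  the same nonzero pattern and values collapse to the same shape;
* candidates are ranked by ``frequency * size ** shape_degree`` and the
  highest-scoring ``capacity`` of them are retained, always including every
  observed single-cell shape plus an ESCAPE pseudo-shape so any 8-bit image
  stays encodable;
* retained shapes receive canonical Huffman codewords from their mined
  frequencies; detail-layer symbols get a separate complete Huffman code
  (add-one smoothed over all Q symbols).

A codebook is a reusable trained artifact; it serialises to a compact
big-endian binary file with a trailing CRC-32.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .entropy import CanonicalDecoder, canonical_codes, huffman_code_lengths
from .errors import ContractError, FormatError, ParameterError, StructuralError

__all__ = [
    "Shape",
    "ESCAPE",
    "Codebook",
    "qualifies_as_candidate",
    "extract_shape",
    "mine_candidates",
    "score_shape",
    "build_codebook",
    "save_codebook",
    "load_codebook",
    "codebook_checksum",
]

CODEBOOK_MAGIC = b"SCCB"
CODEBOOK_VERSION = 1
ESCAPE_RAW_BITS = 16  # escape codeword is followed by this many raw value bits


class _Escape:
    """Singleton pseudo-shape guaranteeing completeness of the shape code."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "ESCAPE"


ESCAPE = _Escape()


@dataclass(frozen=True)
class Shape:
    """A set of (row-offset, col-offset) -> value cells anchored at (0, 0).

    ``cells`` is a tuple of (dr, dc, value) triples in raster order of the
    offsets; the first triple is always (0, 0, v).  Values are part of the
    shape's identity.
    """

    cells: Tuple[Tuple[int, int, int], ...]

    def __post_init__(self):
        if not self.cells:
            raise ContractError("a shape must have at least one cell")
        if (self.cells[0][0], self.cells[0][1]) != (0, 0):
            raise ContractError("shape anchor must sit at offset (0, 0)")
        offsets = [(dr, dc) for dr, dc, _ in self.cells]
        if sorted(offsets) != offsets or len(set(offsets)) != len(offsets):
            raise ContractError("shape cells must be unique and raster-sorted")
        if any(v <= 0 for _, _, v in self.cells):
            raise ContractError("shape cell values must be positive")

    @property
    def size(self) -> int:
        return len(self.cells)

    @property
    def anchor_value(self) -> int:
        return self.cells[0][2]


def _sym_key(sym):
    """Total order over {shapes, ESCAPE} for canonical code assignment."""
    if sym is ESCAPE:
        return (1, ())
    return (0, sym.cells)


def qualifies_as_candidate(window: np.ndarray) -> bool:
    """Row/column nonzero-count conditions for shape candidacy.

    True iff every row of the M x N window has at least N/2 nonzeros and
    every column at least M/2 (halves taken as real numbers).
    """
    w = np.asarray(window)
    if w.ndim != 2 or w.size == 0:
        raise StructuralError("candidate window must be a non-empty matrix")
    m, n = w.shape
    nz = w != 0
    # integer form of count >= N/2: 2*count >= N
    return bool(
        np.all(2 * nz.sum(axis=1) >= n) and np.all(2 * nz.sum(axis=0) >= m)
    )


def extract_shape(window: np.ndarray) -> Shape:
    """Drop zeros and re-base offsets on the raster-first nonzero cell."""
    w = np.asarray(window)
    rows, cols = np.nonzero(w)
    if rows.size == 0:
        raise ContractError("cannot extract a shape from an all-zero window")
    r0, c0 = int(rows[0]), int(cols[0])
    cells = tuple(
        (int(r) - r0, int(c) - c0, int(w[r, c])) for r, c in zip(rows, cols)
    )
    return Shape(cells)


def mine_candidates(
    shape_layers: Sequence[np.ndarray], h_max: int = 4, w_max: int = 4
) -> Dict[Shape, int]:
    """Count qualifying-window shapes over a corpus of shape layers.

    Every window position of every size up to (h_max, w_max) is examined;
    occurrences overlap freely (mining measures prevalence, not a cover).
    Deterministic given the corpus order.
    """
    if not shape_layers:
        raise ParameterError("cannot mine candidates from an empty corpus")
    if h_max < 1 or w_max < 1:
        raise ParameterError("window bounds must be >= 1")
    table: Dict[Shape, int] = {}
    for layer in shape_layers:
        a = np.asarray(layer, dtype=np.int64)
        if a.ndim != 2:
            raise StructuralError("shape layers must be 2-D")
        nz = a != 0
        rows, cols = a.shape
        for h in range(1, min(h_max, rows) + 1):
            for w in range(1, min(w_max, cols) + 1):
                windows_nz = sliding_window_view(nz, (h, w))
                row_ok = np.all(
                    2 * windows_nz.sum(axis=3) >= w, axis=2
                )
                col_ok = np.all(
                    2 * windows_nz.sum(axis=2) >= h, axis=2
                )
                ok = row_ok & col_ok
                for i, j in zip(*np.nonzero(ok)):
                    s = extract_shape(a[i : i + h, j : j + w])
                    table[s] = table.get(s, 0) + 1
    return table


def score_shape(frequency: int, size: int, shape_degree: float) -> float:
    """Retention score ``frequency * size ** shape_degree``."""
    if frequency < 1 or size < 1:
        raise ContractError("frequency and size must be >= 1")
    if not 0 <= shape_degree <= 1:
        raise ParameterError("shape degree must lie in [0, 1]")
    return frequency * size**shape_degree


@dataclass
class Codebook:
    """Trained shape and detail-symbol prefix codes for one component.

    Attributes
    ----------
    q : layer interface used in training.
    h_max, w_max : mining window bounds.
    shape_degree : exponent in the retention score.
    shape_freqs : mined frequency of every retained shape.
    shape_lengths : prefix-code length per retained shape and for ESCAPE.
    detail_lengths : prefix-code length per detail symbol 0..q-1 (complete).
    corpus_id, image_count : training provenance.
    """

    q: int
    h_max: int
    w_max: int
    shape_degree: float
    shape_freqs: Dict[Shape, int]
    shape_lengths: Dict[object, int]
    detail_lengths: Dict[int, int]
    corpus_id: str = ""
    image_count: int = 0

    def __post_init__(self):
        if ESCAPE not in self.shape_lengths:
            raise ContractError("shape code must include the ESCAPE codeword")
        if sorted(self.detail_lengths) != list(range(self.q)):
            raise ContractError("detail code must be complete over [0, Q-1]")
        self.shape_codes: Dict[object, str] = canonical_codes(
            self.shape_lengths, key=_sym_key
        )
        self.detail_codes: Dict[int, str] = canonical_codes(self.detail_lengths)
        self.escape_code: str = self.shape_codes[ESCAPE]
        self._shape_decoder = CanonicalDecoder(self.shape_codes)
        self._detail_decoder = CanonicalDecoder(self.detail_codes)
        # shapes that can anchor at a pixel of a given value, in the
        # encoder's priority order: larger first, then shorter codeword,
        # then serialization order
        buckets: Dict[int, List[Shape]] = {}
        for s in self.shape_freqs:
            buckets.setdefault(s.anchor_value, []).append(s)
        for v, shapes in buckets.items():
            shapes.sort(
                key=lambda s: (-s.size, len(self.shape_codes[s]), s.cells)
            )
        self._buckets = buckets

    def candidates_for(self, value: int) -> Sequence[Shape]:
        return self._buckets.get(value, ())

    @property
    def shape_decoder(self) -> CanonicalDecoder:
        return self._shape_decoder

    @property
    def detail_decoder(self) -> CanonicalDecoder:
        return self._detail_decoder

    def __eq__(self, other) -> bool:
        if not isinstance(other, Codebook):
            return NotImplemented
        return self.to_bytes() == other.to_bytes()

    def to_bytes(self) -> bytes:
        """Serialise to the big-endian codebook file format (CRC-tailed)."""
        out = bytearray()
        out += CODEBOOK_MAGIC
        out += struct.pack(">B", CODEBOOK_VERSION)
        degree_fp = int(round(self.shape_degree * 4096))  # 4.12 fixed point
        out += struct.pack(">BBBH", self.q, self.h_max, self.w_max, degree_fp)
        cid = self.corpus_id.encode("utf-8")
        out += struct.pack(">H", len(cid)) + cid
        out += struct.pack(">I", self.image_count)
        out += struct.pack(">B", self.shape_lengths[ESCAPE])
        shapes = sorted(self.shape_freqs, key=lambda s: s.cells)
        out += struct.pack(">I", len(shapes))
        for s in shapes:
            out += struct.pack(">B", s.size)
            for dr, dc, v in s.cells:
                out += struct.pack(">bbH", dr, dc, v)
            out += struct.pack(">IB", self.shape_freqs[s], self.shape_lengths[s])
        for sym in range(self.q):
            out += struct.pack(">B", self.detail_lengths[sym])
        out += struct.pack(">I", zlib.crc32(bytes(out)) & 0xFFFFFFFF)
        return bytes(out)

    @classmethod
    def from_bytes(cls, data: bytes) -> "Codebook":
        if len(data) < 4 + 1 + 5 + 2 + 4 + 1 + 4 + 4:
            raise FormatError("codebook file is truncated")
        if data[:4] != CODEBOOK_MAGIC:
            raise FormatError("bad codebook magic")
        stored_crc = struct.unpack(">I", data[-4:])[0]
        if zlib.crc32(data[:-4]) & 0xFFFFFFFF != stored_crc:
            raise FormatError("codebook CRC mismatch")
        try:
            pos = 4
            (version,) = struct.unpack_from(">B", data, pos)
            pos += 1
            if version != CODEBOOK_VERSION:
                raise FormatError(f"unsupported codebook version {version}")
            q, h_max, w_max, degree_fp = struct.unpack_from(">BBBH", data, pos)
            pos += 5
            (cid_len,) = struct.unpack_from(">H", data, pos)
            pos += 2
            corpus_id = data[pos : pos + cid_len].decode("utf-8")
            pos += cid_len
            (image_count,) = struct.unpack_from(">I", data, pos)
            pos += 4
            (escape_len,) = struct.unpack_from(">B", data, pos)
            pos += 1
            (n_shapes,) = struct.unpack_from(">I", data, pos)
            pos += 4
            shape_freqs: Dict[Shape, int] = {}
            shape_lengths: Dict[object, int] = {ESCAPE: escape_len}
            for _ in range(n_shapes):
                (ncells,) = struct.unpack_from(">B", data, pos)
                pos += 1
                cells = []
                for _ in range(ncells):
                    dr, dc, v = struct.unpack_from(">bbH", data, pos)
                    pos += 4
                    cells.append((dr, dc, v))
                freq, length = struct.unpack_from(">IB", data, pos)
                pos += 5
                s = Shape(tuple(cells))
                shape_freqs[s] = freq
                shape_lengths[s] = length
            detail_lengths = {}
            for sym in range(q):
                (detail_lengths[sym],) = struct.unpack_from(">B", data, pos)
                pos += 1
            if pos != len(data) - 4:
                raise FormatError("codebook file has trailing garbage")
        except (struct.error, IndexError, ContractError) as exc:
            raise FormatError(f"corrupt codebook file: {exc}") from exc
        return cls(
            q=q,
            h_max=h_max,
            w_max=w_max,
            shape_degree=degree_fp / 4096.0,
            shape_freqs=shape_freqs,
            shape_lengths=shape_lengths,
            detail_lengths=detail_lengths,
            corpus_id=corpus_id,
            image_count=image_count,
        )


def build_codebook(
    table: Mapping[Shape, int],
    detail_freqs: Mapping[int, int],
    capacity: int = 4096,
    *,
    q: int = 4,
    h_max: int = 4,
    w_max: int = 4,
    shape_degree: float = 0.5,
    corpus_id: str = "",
    image_count: int = 0,
) -> Codebook:
    """Prune the mined table and assign prefix codewords.

    Retains the ``capacity`` highest-scoring shapes (ties: larger size,
    then lexicographic cells), always keeping every observed singleton
    shape; ESCAPE is added on top with frequency 1.  Detail symbol counts
    are add-one smoothed so the detail code covers all Q symbols.
    """
    singletons = {s for s in table if s.size == 1}
    if capacity < len(singletons) + 1:
        raise ParameterError(
            f"capacity {capacity} cannot hold {len(singletons)} singletons "
            "plus the escape codeword"
        )
    ranked = sorted(
        table,
        key=lambda s: (
            -score_shape(table[s], s.size, shape_degree),
            -s.size,
            s.cells,
        ),
    )
    retained = set(singletons)
    for s in ranked:
        if len(retained) >= capacity:
            break
        retained.add(s)
    shape_freqs = {s: int(table[s]) for s in retained}
    huff_input: Dict[object, int] = dict(shape_freqs)
    huff_input[ESCAPE] = 1
    shape_lengths = huffman_code_lengths(huff_input, key=_sym_key)
    smoothed = {sym: int(detail_freqs.get(sym, 0)) + 1 for sym in range(q)}
    detail_lengths = huffman_code_lengths(smoothed)
    return Codebook(
        q=q,
        h_max=h_max,
        w_max=w_max,
        shape_degree=shape_degree,
        shape_freqs=shape_freqs,
        shape_lengths=shape_lengths,
        detail_lengths=detail_lengths,
        corpus_id=corpus_id,
        image_count=image_count,
    )


def save_codebook(cb: Codebook, path) -> None:
    with open(path, "wb") as fh:
        fh.write(cb.to_bytes())


def load_codebook(path) -> Codebook:
    with open(path, "rb") as fh:
        data = fh.read()
    return Codebook.from_bytes(data)


def codebook_checksum(codebooks: Iterable[Codebook]) -> int:
    """CRC-32 over the concatenated serialised codebooks (order matters)."""
    crc = 0
    for cb in codebooks:
        crc = zlib.crc32(cb.to_bytes(), crc)
    return crc & 0xFFFFFFFF
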