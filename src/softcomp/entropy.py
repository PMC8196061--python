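"""Bit-level coding primitives: bit buffers, Rice codes, canonical Huffman.

Conventions (fixed so streams are reproducible across platforms):

* bits are written most-significant-bit first within each byte;
* unary is a run of ones terminated by a single zero;
* a Rice code with parameter k writes the quotient ``v >> k`` in unary
  followed by the k low bits of v in binary — total length
  ``(v >> k) + 1 + k`` bits;
* Huffman codes are *canonical*: only the code lengths matter, the actual
  codewords are reassigned by (length, symbol-order), so a codebook file
  needs to store lengths only.
"""

from __future__ import annotations

import heapq
from typing import Callable, Dict, Hashable, Iterable, List, Mapping, Tuple

from .errors import ContractError, ParameterError, TruncationError

__all__ = [
    "BitWriter",
    "BitReader",
    "rice_encode",
    "rice_decode",
    "rice_code_length",
    "choose_rice_parameter",
    "huffman_code_lengths",
    "canonical_codes",
    "CanonicalDecoder",
]

MAX_RICE_K = 15


class BitWriter:
    """Append-only MSB-first bit buffer."""

    def __init__(self):
        self._buf = bytearray()
        self._acc = 0
        self._n = 0  # pending bits, always < 8

    def write_bits(self, value: int, n: int) -> None:
        if n < 0 or value < 0 or (n < value.bit_length()):
            raise ContractError(f"cannot write value {value} in {n} bits")
        if n == 0:
            return
        self._acc = (self._acc << n) | value
        self._n += n
        while self._n >= 8:
            self._n -= 8
            self._buf.append((self._acc >> self._n) & 0xFF)
        self._acc &= (1 << self._n) - 1

    def write_unary(self, q: int) -> None:
        """q ones followed by a terminating zero."""
        if q < 0:
            raise ContractError("unary argument must be non-negative")
        # write in chunks to keep accumulator small for large q
        while q >= 32:
            self.write_bits((1 << 32) - 1, 32)
            q -= 32
        self.write_bits(((1 << q) - 1) << 1, q + 1)

    def write_codeword(self, code: str) -> None:
        """Write a codeword given as a '0'/'1' string."""
        if code:
            self.write_bits(int(code, 2), len(code))

    @property
    def bit_length(self) -> int:
        return 8 * len(self._buf) + self._n

    def getvalue(self) -> bytes:
        """Byte string, final partial byte zero-padded on the right."""
        out = bytearray(self._buf)
        if self._n:
            out.append((self._acc << (8 - self._n)) & 0xFF)
        return bytes(out)

    def to_bitstring(self) -> str:
        bits = "".join(f"{byte:08b}" for byte in self._buf)
        if self._n:
            bits += f"{self._acc:0{self._n}b}"
        return bits


class BitReader:
    """MSB-first reader over a byte string with a hard bit limit."""

    def __init__(self, data: bytes, bit_length: int | None = None):
        self._data = data
        self._nbits = 8 * len(data) if bit_length is None else bit_length
        if self._nbits > 8 * len(data):
            raise ContractError("declared bit length exceeds the buffer")
        self._pos = 0

    @property
    def bits_remaining(self) -> int:
        return self._nbits - self._pos

    @property
    def position(self) -> int:
        return self._pos

    def read_bit(self) -> int:
        if self._pos >= self._nbits:
            raise TruncationError("bit stream exhausted")
        byte = self._data[self._pos >> 3]
        bit = (byte >> (7 - (self._pos & 7))) & 1
        self._pos += 1
        return bit

    def read_bits(self, n: int) -> int:
        if n < 0:
            raise ContractError("cannot read a negative bit count")
        if self._pos + n > self._nbits:
            raise TruncationError("bit stream exhausted mid-field")
        value = 0
        pos = self._pos
        data = self._data
        for _ in range(n):
            value = (value << 1) | ((data[pos >> 3] >> (7 - (pos & 7))) & 1)
            pos += 1
        self._pos = pos
        return value

    def read_unary(self) -> int:
        q = 0
        while self.read_bit():
            q += 1
        return q


def rice_code_length(value: int, k: int) -> int:
    if value < 0:
        raise ContractError("Rice codes require non-negative values")
    return (value >> k) + 1 + k


def rice_encode(writer: BitWriter, value: int, k: int) -> int:
    """Append the Rice codeword for ``value``; returns its bit length."""
    if value < 0:
        raise ContractError("Rice codes require non-negative values")
    if not (0 <= k <= MAX_RICE_K):
        raise ParameterError(f"Rice parameter must be in [0, {MAX_RICE_K}]")
    writer.write_unary(value >> k)
    writer.write_bits(value & ((1 << k) - 1), k)
    return rice_code_length(value, k)


def rice_decode(reader: BitReader, k: int) -> int:
    q = reader.read_unary()
    r = reader.read_bits(k)
    return (q << k) | r


def choose_rice_parameter(values: Iterable[int]) -> int:
    """The k in [0, 15] minimising the total coded length; ties -> smaller k."""
    vals = list(values)
    if not vals:
        raise ParameterError("cannot choose a Rice parameter for no values")
    best_k = 0
    best_total = None
    n = len(vals)
    for k in range(MAX_RICE_K + 1):
        total = sum(v >> k for v in vals) + n * (1 + k)
        if best_total is None or total < best_total:
            best_total = total
            best_k = k
    return best_k


def huffman_code_lengths(freqs: Mapping[Hashable, int],
                         key: Callable = None) -> Dict[Hashable, int]:
    """Optimal prefix-code lengths for the given symbol frequencies.

    Tie-breaking is made deterministic by seeding the heap with symbols in
    ``key`` order (default: natural sort of the symbols) and by an
    insertion counter, so equal-frequency merges are stable.
    A single-symbol alphabet gets length 1.
    """
    if not freqs:
        raise ContractError("empty alphabet")
    if any(c < 1 for c in freqs.values()):
        raise ContractError("all frequencies must be >= 1")
    symbols = sorted(freqs, key=key) if key else sorted(freqs)
    if len(symbols) == 1:
        return {symbols[0]: 1}
    counter = 0
    heap: List[Tuple[int, int, list]] = []
    for s in symbols:
        heapq.heappush(heap, (freqs[s], counter, [s]))
        counter += 1
    depths = {s: 0 for s in symbols}
    while len(heap) > 1:
        f1, _, s1 = heapq.heappop(heap)
        f2, _, s2 = heapq.heappop(heap)
        for s in s1:
            depths[s] += 1
        for s in s2:
            depths[s] += 1
        heapq.heappush(heap, (f1 + f2, counter, s1 + s2))
        counter += 1
    return depths


def canonical_codes(lengths: Mapping[Hashable, int],
                    key: Callable = None) -> Dict[Hashable, str]:
    """Canonical codewords (as '0'/'1' strings) from code lengths.

    Symbols are ordered by (length, key) and assigned increment-and-shift
    codes, so the mapping is reproducible from the lengths alone.
    """
    if not lengths:
        raise ContractError("empty alphabet")
    kraft = sum(2.0 ** -l for l in lengths.values())
    if kraft > 1 + 1e-9:
        raise ContractError(f"code lengths violate the Kraft inequality ({kraft})")
    keyfn = key if key else (lambda s: s)
    ordered = sorted(lengths, key=lambda s: (lengths[s], keyfn(s)))
    codes: Dict[Hashable, str] = {}
    code = 0
    prev_len = lengths[ordered[0]]
    for sym in ordered:
        length = lengths[sym]
        code <<= length - prev_len
        codes[sym] = format(code, f"0{length}b")
        code += 1
        prev_len = length
    return codes


class CanonicalDecoder:
    """Decode symbols from a :class:`BitReader` given canonical codewords."""

    def __init__(self, codes: Mapping[Hashable, str]):
        self._table = {(len(c), int(c, 2)): s for s, c in codes.items()}
        self._max_len = max(len(c) for c in codes.values())

    def decode(self, reader: BitReader) -> Hashable:
        value = 0
        length = 0
        table = self._table
        while length <= self._max_len:
            value = (value << 1) | reader.read_bit()
            length += 1
            sym = table.get((length, value), _MISSING)
            if sym is not _MISSING:
                return sym
        raise TruncationError("no codeword matched within the maximum length")


class _Missing:
    __slots__ = ()


_MISSING = _Missing()
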