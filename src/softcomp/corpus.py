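"""Corpus-level operations: training codebooks, file coding, statistics.

Compression is reported two ways, both derived from the same container
bit count (header included):

* compression ratio = 8·m·M·N / coded bits (natural binary cost over
  coded cost; higher is better);
* bpsp = coded bits / (m·M·N), bits per sub-pixel, so ratio = 8 / bpsp.

Corpus summaries give mean / min / max / population variance of the
per-image ratio, alongside a raw-pixel Huffman baseline (independent
per-component coding, no prediction or transform) and, when the source
file is a PNG, the stock PNG size for reference.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .codebook import Codebook, build_codebook, mine_candidates
from .codec import (
    CompressedImage,
    decode_image,
    encode_image,
    huffman_baseline_bits,
    image_to_layers,
)
from .errors import FormatError, InputError
from .image import RasterImage, read_image, write_image

__all__ = [
    "TrainingLog",
    "train_codebooks",
    "encode_file",
    "decode_file",
    "ImageStats",
    "CorpusReport",
    "corpus_stats",
]


@dataclass
class TrainingLog:
    """Shape counts per transformed component, before and after pruning."""

    image_count: int
    candidates_before: List[int]
    retained_after: List[int]


def train_codebooks(
    image_paths: Sequence,
    *,
    q: int = 4,
    h_max: int = 4,
    w_max: int = 4,
    shape_degree: float = 0.5,
    capacity: int = 4096,
    corpus_id: str = "",
) -> Tuple[List[Codebook], TrainingLog]:
    """Train one codebook per transformed component from a corpus.

    Every image runs through the full preprocessing chain; shape layers
    feed the candidate miner and detail layers feed the detail-symbol
    histogram, independently per component index (Y, U, V for color
    corpora; the single plane for grayscale).
    """
    if not image_paths:
        raise InputError("training corpus is empty")
    n_components: Optional[int] = None
    shape_layers: List[List[np.ndarray]] = []
    detail_freqs: List[Dict[int, int]] = []
    for path in image_paths:
        img = read_image(path)
        if n_components is None:
            n_components = img.components
            shape_layers = [[] for _ in range(n_components)]
            detail_freqs = [{} for _ in range(n_components)]
        elif img.components != n_components:
            raise InputError(
                f"mixed component counts in corpus ({path!r})"
            )
        for ci, lp in enumerate(image_to_layers(img, q)):
            shape_layers[ci].append(lp.shape_layer)
            vals, counts = np.unique(lp.detail_layer, return_counts=True)
            for v, n in zip(vals, counts):
                detail_freqs[ci][int(v)] = detail_freqs[ci].get(int(v), 0) + int(n)
    codebooks: List[Codebook] = []
    before: List[int] = []
    after: List[int] = []
    for ci in range(n_components):
        table = mine_candidates(shape_layers[ci], h_max=h_max, w_max=w_max)
        cb = build_codebook(
            table,
            detail_freqs[ci],
            capacity=capacity,
            q=q,
            h_max=h_max,
            w_max=w_max,
            shape_degree=shape_degree,
            corpus_id=corpus_id,
            image_count=len(image_paths),
        )
        codebooks.append(cb)
        before.append(len(table))
        after.append(len(cb.shape_freqs))
    log = TrainingLog(
        image_count=len(image_paths),
        candidates_before=before,
        retained_after=after,
    )
    return codebooks, log


def encode_file(image_path, cbs: Sequence[Codebook], out_path) -> CompressedImage:
    """Encode a PNG to a compressed container file."""
    img = read_image(image_path)
    c = encode_image(img, cbs)
    with open(out_path, "wb") as fh:
        fh.write(c.to_bytes())
    return c


def decode_file(in_path, cbs: Sequence[Codebook], image_out) -> RasterImage:
    """Decode a compressed container file back to a PNG."""
    with open(in_path, "rb") as fh:
        data = fh.read()
    img = decode_image(CompressedImage.from_bytes(data), cbs)
    write_image(img, image_out)
    return img


@dataclass
class ImageStats:
    path: str
    sub_pixels: int  # m * M * N
    compressed_bits: int
    ratio: float
    bpsp: float
    huffman_bits: int
    huffman_ratio: float
    png_bytes: Optional[int] = None


@dataclass
class CorpusReport:
    """Per-image compression figures and their summary statistics."""

    images: List[ImageStats]
    mean_ratio: float
    min_ratio: float
    max_ratio: float
    var_ratio: float  # population variance
    mean_bpsp: float
    mean_huffman_ratio: float

    def to_text(self) -> str:
        lines = [
            "# Corpus compression report",
            "# ratio = 8*m*M*N / container bits (header included);"
            " bpsp = 8 / ratio",
            "# variance is the population variance of the per-image ratio",
            f"{'image':<28}{'ratio':>8}{'bpsp':>8}{'huffman':>9}{'png_B':>9}",
        ]
        for s in self.images:
            png = str(s.png_bytes) if s.png_bytes is not None else "-"
            lines.append(
                f"{Path(s.path).name:<28}{s.ratio:>8.3f}{s.bpsp:>8.3f}"
                f"{s.huffman_ratio:>9.3f}{png:>9}"
            )
        lines += [
            "",
            f"mean ratio     {self.mean_ratio:.4f}",
            f"min ratio      {self.min_ratio:.4f}",
            f"max ratio      {self.max_ratio:.4f}",
            f"variance       {self.var_ratio:.4f}",
            f"mean bpsp      {self.mean_bpsp:.4f}",
            f"mean huffman   {self.mean_huffman_ratio:.4f}",
        ]
        return "\n".join(lines)

    def to_csv(self) -> str:
        rows = ["image,sub_pixels,compressed_bits,ratio,bpsp,huffman_ratio,png_bytes"]
        for s in self.images:
            png = s.png_bytes if s.png_bytes is not None else ""
            rows.append(
                f"{Path(s.path).name},{s.sub_pixels},{s.compressed_bits},"
                f"{s.ratio:.6f},{s.bpsp:.6f},{s.huffman_ratio:.6f},{png}"
            )
        return "\n".join(rows)


def corpus_stats(
    image_paths: Sequence, cbs: Sequence[Codebook]
) -> CorpusReport:
    """Encode every image and tabulate ratios against the Huffman baseline."""
    if not image_paths:
        raise InputError("statistics corpus is empty")
    stats: List[ImageStats] = []
    for path in image_paths:
        img = read_image(path)
        c = encode_image(img, cbs)
        bits = c.total_bits
        sub_pixels = img.components * img.height * img.width
        raw_bits = 8 * sub_pixels
        hbits = huffman_baseline_bits(img)
        png_bytes = None
        p = Path(path)
        if p.suffix.lower() == ".png":
            png_bytes = os.path.getsize(p)
        stats.append(
            ImageStats(
                path=str(path),
                sub_pixels=sub_pixels,
                compressed_bits=bits,
                ratio=raw_bits / bits,
                bpsp=bits / sub_pixels,
                huffman_bits=hbits,
                huffman_ratio=raw_bits / hbits,
                png_bytes=png_bytes,
            )
        )
    ratios = np.array([s.ratio for s in stats])
    return CorpusReport(
        images=stats,
        mean_ratio=float(ratios.mean()),
        min_ratio=float(ratios.min()),
        max_ratio=float(ratios.max()),
        var_ratio=float(ratios.var()),  # population variance
        mean_bpsp=float(np.mean([s.bpsp for s in stats])),
        mean_huffman_ratio=float(np.mean([s.huffman_ratio for s in stats])),
    )
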