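"""Raster image container, PNG I/O and planar decomposition.

The codec works on integer component *planes*.  A plane is a plain 2-D
``numpy`` integer array; :class:`RasterImage` bundles one plane (grayscale)
or three planes in fixed **B, G, R** order (color).  Component order is part
of the container contract and is recorded in the compressed header, so both
ends of the pipeline agree without side channels.

Only 8-bit depth is supported: every transform downstream (the reversible
color transform, the residual mapping, the layer split) assumes the
``[0, 255]`` input range.
"""

from __future__ import annotations

import struct
from typing import List, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import (
    ContractError,
    InputError,
    StructuralError,
    UnsupportedFormatError,
    ValueRangeError,
)

PLANE_DTYPE = np.int64

__all__ = [
    "RasterImage",
    "read_image",
    "write_image",
    "split_components",
    "merge_components",
    "read_raw_plane",
    "write_raw_plane",
]


class RasterImage:
    """An 8-bit raster image with 1 or 3 component planes.

    Parameters
    ----------
    planes:
        Sequence of 1 or 3 equally-sized 2-D integer arrays with values in
        ``[0, 255]``.  For color images the order is B, G, R.
    """

    def __init__(self, planes: Sequence[np.ndarray]):
        if len(planes) not in (1, 3):
            raise StructuralError(
                f"expected 1 or 3 component planes, got {len(planes)}"
            )
        arrays = []
        shape = None
        for p in planes:
            a = np.asarray(p, dtype=PLANE_DTYPE)
            if a.ndim != 2 or a.size == 0:
                raise StructuralError("each plane must be a non-empty 2-D grid")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise StructuralError(
                    f"plane shape {a.shape} differs from {shape}"
                )
            if a.min() < 0 or a.max() > 255:
                raise ValueRangeError("pixel values must lie in [0, 255]")
            arrays.append(a)
        self.planes = tuple(arrays)

    @property
    def height(self) -> int:
        return self.planes[0].shape[0]

    @property
    def width(self) -> int:
        return self.planes[0].shape[1]

    @property
    def components(self) -> int:
        return len(self.planes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RasterImage):
            return NotImplemented
        return self.components == other.components and all(
            np.array_equal(a, b) for a, b in zip(self.planes, other.planes)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"RasterImage({self.height}x{self.width}, "
            f"components={self.components})"
        )


def read_image(path) -> RasterImage:
    """Read an 8-bit grayscale or RGB PNG into a :class:`RasterImage`.

    Color images are decomposed into B, G, R planes (in that order).
    Palette images without transparency are expanded to RGB; anything with
    an alpha channel or more than 8 bits per sample is rejected.
    """
    try:
        im = Image.open(path)
        im.load()
    except (OSError, UnidentifiedImageError) as exc:
        raise InputError(f"cannot read image {path!r}: {exc}") from exc
    if im.mode == "P":
        if "transparency" in im.info:
            raise UnsupportedFormatError(
                "palette PNG with transparency is not supported"
            )
        im = im.convert("RGB")
    if im.mode == "L":
        return RasterImage([np.asarray(im, dtype=PLANE_DTYPE)])
    if im.mode == "RGB":
        rgb = np.asarray(im, dtype=PLANE_DTYPE)
        # component order is B, G, R
        return RasterImage([rgb[:, :, 2], rgb[:, :, 1], rgb[:, :, 0]])
    raise UnsupportedFormatError(
        f"unsupported pixel mode {im.mode!r}; need 8-bit grayscale or RGB"
    )


def write_image(img: RasterImage, path) -> None:
    """Write a :class:`RasterImage` as a lossless PNG."""
    if not isinstance(img, RasterImage):
        raise ContractError("write_image expects a RasterImage")
    if img.components == 1:
        pil = Image.fromarray(img.planes[0].astype(np.uint8), mode="L")
    else:
        b, g, r = img.planes
        rgb = np.stack([r, g, b], axis=2).astype(np.uint8)
        pil = Image.fromarray(rgb, mode="RGB")
    try:
        pil.save(path, format="PNG")
    except OSError as exc:
        raise InputError(f"cannot write image {path!r}: {exc}") from exc


def split_components(img: RasterImage) -> List[np.ndarray]:
    """Decompose an image into its component planes (B, G, R order)."""
    return [p.copy() for p in img.planes]


def merge_components(planes: Sequence[np.ndarray]) -> RasterImage:
    """Inverse of :func:`split_components`."""
    return RasterImage(planes)


def write_raw_plane(plane: np.ndarray, path) -> None:
    """Dump a [0,255] plane as ``>II`` height/width header + row-major bytes."""
    a = np.asarray(plane)
    if a.min() < 0 or a.max() > 255:
        raise ValueRangeError("raw planar dump requires values in [0, 255]")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", a.shape[0], a.shape[1]))
        fh.write(a.astype(np.uint8).tobytes())


def read_raw_plane(path) -> np.ndarray:
    with open(path, "rb") as fh:
        head = fh.read(8)
        if len(head) != 8:
            raise InputError(f"truncated raw plane file {path!r}")
        h, w = struct.unpack(">II", head)
        body = fh.read(h * w)
        if len(body) != h * w:
            raise InputError(f"raw plane file {path!r} is short")
    return np.frombuffer(body, dtype=np.uint8).reshape(h, w).astype(PLANE_DTYPE)
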