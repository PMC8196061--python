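"""Shape-layer / detail-layer split of a mapped residual plane.

The mapped residual plane is separated at the *layer interface* Q
(default 4) by quotient and remainder:

    shape_layer  = value div Q      (sparse: zero wherever value < Q)
    detail_layer = value mod Q      (dense: defined at every pixel)

Most MED residuals on smooth imagery have magnitude below 2, so their
mapped values fall below 4 and the shape layer is mostly zero — the sparse,
structured part that shape/location coding targets — while the detail layer
is noise-like and goes to a plain per-symbol entropy code.  The pair
reconstructs the mapped plane exactly: value = shape * Q + detail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ParameterError, ValueRangeError

__all__ = ["LayerPair", "split_layers", "merge_layers", "sparsity"]


@dataclass
class LayerPair:
    shape_layer: np.ndarray
    detail_layer: np.ndarray
    q: int


def split_layers(mapped: np.ndarray, q: int = 4) -> LayerPair:
    """Split a non-negative plane into shape and detail layers at interface q."""
    if q < 2:
        raise ParameterError(f"layer interface must be >= 2, got {q}")
    m = np.asarray(mapped, dtype=np.int64)
    if m.size and m.min() < 0:
        raise ValueRangeError("mapped plane must be non-negative")
    return LayerPair(shape_layer=m // q, detail_layer=m % q, q=q)


def merge_layers(lp: LayerPair) -> np.ndarray:
    """Exact inverse of :func:`split_layers`."""
    shape = np.asarray(lp.shape_layer, dtype=np.int64)
    detail = np.asarray(lp.detail_layer, dtype=np.int64)
    if shape.shape != detail.shape:
        raise ContractError("layer shapes differ")
    if detail.size and (detail.min() < 0 or detail.max() >= lp.q):
        raise ContractError(f"detail values must lie in [0, {lp.q - 1}]")
    return shape * lp.q + detail


def sparsity(lp: LayerPair) -> float:
    """Fraction of zero entries in the shape layer, in [0, 1]."""
    return float(np.mean(np.asarray(lp.shape_layer) == 0))
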