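"""Exactly-invertible per-pixel transforms.

Three stages, each a bijection so the decoder can undo them bit-exactly:

1. **Reversible component transform (RCT)** — the integer RGB↔YUV pair used
   by lossless JPEG2000::

       Y = floor((R + 2G + B) / 4)      G = Y - floor((U + V) / 4)
       V = R - G                        R = V + G
       U = B - G                        B = U + G

   The floor is the true mathematical floor (toward −∞), which is what makes
   the inverse exact when U + V is negative.

2. **Prediction** — each pixel is replaced by its difference from the
   JPEG-LS median (MED) prediction over the left, above and above-left
   causal neighbours, with out-of-bounds neighbours read as zero.  MED acts
   as a rudimentary edge detector: it picks min(a, b) across a horizontal
   edge, max(a, b) across a vertical one, and the planar extrapolation
   a + b - c otherwise.

3. **Sign mapping** — the signed residual is folded onto the non-negative
   integers by interleaving: 0, -1, 1, -2, 2, ... → 0, 1, 2, 3, 4, ...
   Small-magnitude residuals get small codes, which is what the layer split
   downstream exploits.
"""

from __future__ import annotations

import numpy as np

from .errors import StructuralError

__all__ = [
    "rct_forward",
    "rct_inverse",
    "predict",
    "unpredict",
    "map_to_nonneg",
    "unmap",
]


def _check_same_shape(*planes: np.ndarray) -> None:
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise StructuralError(f"component planes differ in shape: {shapes}")


def rct_forward(b: np.ndarray, g: np.ndarray, r: np.ndarray):
    """Forward reversible component transform; returns (Y, U, V)."""
    b = np.asarray(b, dtype=np.int64)
    g = np.asarray(g, dtype=np.int64)
    r = np.asarray(r, dtype=np.int64)
    _check_same_shape(b, g, r)
    y = (r + 2 * g + b) // 4  # numpy // floors toward -inf
    v = r - g
    u = b - g
    return y, u, v


def rct_inverse(y: np.ndarray, u: np.ndarray, v: np.ndarray):
    """Inverse reversible component transform; returns (B, G, R)."""
    y = np.asarray(y, dtype=np.int64)
    u = np.asarray(u, dtype=np.int64)
    v = np.asarray(v, dtype=np.int64)
    _check_same_shape(y, u, v)
    g = y - (u + v) // 4
    r = v + g
    b = u + g
    return b, g, r


def _med(a, b, c):
    """JPEG-LS median predictor, elementwise."""
    mn = np.minimum(a, b)
    mx = np.maximum(a, b)
    return np.where(c >= mx, mn, np.where(c <= mn, mx, a + b - c))


def predict(plane: np.ndarray) -> np.ndarray:
    """Residual plane: pixel minus its MED prediction (zero boundary)."""
    p = np.asarray(plane, dtype=np.int64)
    a = np.zeros_like(p)
    a[:, 1:] = p[:, :-1]  # left
    b = np.zeros_like(p)
    b[1:, :] = p[:-1, :]  # above
    c = np.zeros_like(p)
    c[1:, 1:] = p[:-1, :-1]  # above-left
    return p - _med(a, b, c)


def unpredict(res: np.ndarray) -> np.ndarray:
    """Rebuild the plane from MED residuals in raster order.

    Sequential by necessity: each prediction reads reconstructed
    neighbours, so rows cannot be vectorised.
    """
    r = np.asarray(res, dtype=np.int64)
    m, n = r.shape
    out = np.zeros((m, n), dtype=np.int64)
    for i in range(m):
        row = out[i]
        above = out[i - 1] if i else None
        for j in range(n):
            a = row[j - 1] if j else 0
            b = above[j] if i else 0
            c = above[j - 1] if (i and j) else 0
            if a < b:
                mn, mx = a, b
            else:
                mn, mx = b, a
            if c >= mx:
                pred = mn
            elif c <= mn:
                pred = mx
            else:
                pred = a + b - c
            row[j] = r[i, j] + pred
    return out


def map_to_nonneg(res: np.ndarray) -> np.ndarray:
    """Zigzag-fold signed residuals: e >= 0 -> 2e, e < 0 -> -2e - 1."""
    r = np.asarray(res, dtype=np.int64)
    return np.where(r >= 0, 2 * r, -2 * r - 1)


def unmap(mapped: np.ndarray) -> np.ndarray:
    """Inverse of :func:`map_to_nonneg`."""
    m = np.asarray(mapped, dtype=np.int64)
    return np.where(m % 2 == 0, m // 2, -(m + 1) // 2)
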