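"""Deterministic synthetic image corpora for training and evaluation.

The generator emulates the statistical structure the codec exploits in
cell-microscopy imagery without shipping any real dataset:

* a smooth low-frequency background (integer ramps), standing in for the
  slide illumination field;
* a small *motif bank* of elliptical blobs shared across the corpus, so
  the same local patterns recur from image to image (the mutual-similarity
  property that makes a mined codebook transfer from a training split to a
  test split);
* bounded integer pixel noise, so images are similar in general but
  different in detail;
* for 3-component images, channels derived from a shared luminance field
  plus per-channel offsets, giving the strong inter-channel correlation
  the reversible color transform removes.

All synthesis is integer-only, so a given spec and seed regenerate a
byte-identical image on any platform.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .errors import InputError, ParameterError
from .image import RasterImage, write_image

__all__ = ["FixtureSpec", "generate_image", "generate_corpus"]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic image (or, with a shared bank seed, a corpus)."""

    seed: int = 0
    height: int = 64
    width: int = 64
    components: int = 3
    motif_count: int = 6
    motif_radius: Tuple[int, int] = (2, 6)
    gradient_amplitude: int = 60
    noise_amplitude: int = 1
    channel_mode: str = "shared-luminance"  # or "independent"
    motif_bank_size: int = 8
    motif_bank_seed: int | None = None  # defaults to `seed`

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        data = json.loads(text)
        if "motif_radius" in data:
            data["motif_radius"] = tuple(data["motif_radius"])
        return cls(**data)


def _motif_bank(spec: FixtureSpec) -> List[Tuple[np.ndarray, int]]:
    """Elliptical (mask, intensity-delta) motifs shared across a corpus."""
    bank_seed = spec.seed if spec.motif_bank_seed is None else spec.motif_bank_seed
    rng = np.random.default_rng(bank_seed)
    lo, hi = spec.motif_radius
    bank = []
    for _ in range(spec.motif_bank_size):
        ry = int(rng.integers(lo, hi + 1))
        rx = int(rng.integers(lo, hi + 1))
        yy, xx = np.mgrid[-ry : ry + 1, -rx : rx + 1]
        # integer ellipse test: (y/ry)^2 + (x/rx)^2 <= 1
        mask = (yy * yy * rx * rx + xx * xx * ry * ry) <= (ry * ry * rx * rx)
        delta = int(rng.integers(25, 76)) * int(rng.choice([-1, 1]))
        bank.append((mask, delta))
    return bank


def _luminance_field(spec: FixtureSpec, rng: np.random.Generator,
                     bank) -> np.ndarray:
    m, n = spec.height, spec.width
    rr = np.arange(m).reshape(-1, 1)
    cc = np.arange(n).reshape(1, -1)
    amp = spec.gradient_amplitude
    base = 120 + (amp * rr) // max(m - 1, 1) + (amp * cc) // (2 * max(n - 1, 1))
    field_ = np.broadcast_to(base, (m, n)).copy()
    for _ in range(spec.motif_count):
        mask, delta = bank[int(rng.integers(len(bank)))]
        mh, mw = mask.shape
        r0 = int(rng.integers(-mh + 1, m))
        c0 = int(rng.integers(-mw + 1, n))
        r1, c1 = min(r0 + mh, m), min(c0 + mw, n)
        rs, cs = max(r0, 0), max(c0, 0)
        sub = mask[rs - r0 : r1 - r0, cs - c0 : c1 - c0]
        field_[rs:r1, cs:c1] += delta * sub
    if spec.noise_amplitude > 0:
        field_ = field_ + rng.integers(
            -spec.noise_amplitude, spec.noise_amplitude + 1, size=(m, n)
        )
    return field_


def generate_image(spec: FixtureSpec) -> RasterImage:
    """Render one deterministic synthetic image from a spec."""
    if spec.components not in (1, 3):
        raise ParameterError("components must be 1 or 3")
    if spec.height < 1 or spec.width < 1:
        raise ParameterError("image dimensions must be >= 1")
    bank = _motif_bank(spec)
    rng = np.random.default_rng(spec.seed)
    if spec.components == 1:
        lum = _luminance_field(spec, rng, bank)
        return RasterImage([np.clip(lum, 0, 255)])
    if spec.channel_mode == "shared-luminance":
        lum = _luminance_field(spec, rng, bank)
        offsets = rng.integers(-25, 26, size=3)
        planes = [np.clip(lum + int(o), 0, 255) for o in offsets]  # B, G, R
    elif spec.channel_mode == "independent":
        planes = [
            np.clip(_luminance_field(spec, rng, bank), 0, 255) for _ in range(3)
        ]
    else:
        raise ParameterError(f"unknown channel mode {spec.channel_mode!r}")
    return RasterImage(planes)


def generate_corpus(
    spec: FixtureSpec, n_train: int, n_test: int, outdir
) -> Tuple[List[Path], List[Path]]:
    """Write a train/test split of PNGs with disjoint per-image seeds.

    The motif bank is pinned to the corpus-level seed so every image —
    train or test — draws from the same pattern vocabulary.
    """
    if n_train < 1 or n_test < 1:
        raise ParameterError("train and test counts must be >= 1")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create corpus directory: {exc}") from exc
    bank_seed = spec.seed if spec.motif_bank_seed is None else spec.motif_bank_seed
    train_paths, test_paths = [], []
    for i in range(n_train):
        s = FixtureSpec(**{**asdict(spec),
                           "seed": spec.seed * 100003 + 1000 + i,
                           "motif_bank_seed": bank_seed})
        s.motif_radius = tuple(s.motif_radius)
        path = outdir / f"train_{i:03d}.png"
        write_image(generate_image(s), path)
        train_paths.append(path)
    for i in range(n_test):
        s = FixtureSpec(**{**asdict(spec),
                           "seed": spec.seed * 100003 + 500000 + i,
                           "motif_bank_seed": bank_seed})
        s.motif_radius = tuple(s.motif_radius)
        path = outdir / f"test_{i:03d}.png"
        write_image(generate_image(s), path)
        test_paths.append(path)
    return train_paths, test_paths
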