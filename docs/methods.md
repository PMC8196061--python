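# Methods

## The representation

An image is modelled as T basic units with explicit locations; its cost is
`B = Σᵢ [l_I(xᵢ,yᵢ) + l_P(xᵢ,yᵢ)]`. Soft compression chooses the unit to
be a *shape* — a pattern of nonzero mapped-residual cells with their
values, offsets normalised so the raster-first cell is the anchor at
(0, 0). Shapes are discovered by mining a training corpus rather than
designed, so the codebook reflects the recurring micro-structure of a
particular image class. The encoder never requires the codebook to fit the
image: single-cell shapes for every value seen in training, plus an ESCAPE
codeword carrying a 16-bit raw value, guarantee a complete code and hence
losslessness on arbitrary 8-bit input.

## Pipeline stages and their exactness

Each preprocessing stage is an integer bijection, verified by exhaustive
or property tests:

* **RCT** (3-component only): Y = ⌊(R+2G+B)/4⌋, V = R−G, U = B−G; inverse
  G = Y − ⌊(U+V)/4⌋, R = V+G, B = U+G. The floor is toward −∞, which is
  required for exact inversion when U+V < 0. Component order is fixed to
  B, G, R at the container boundary.
* **Prediction**: JPEG-LS MED over left/above/above-left with zero
  boundary. The corpus-mining literature leaves the predictor open; MED is
  integer-exact, strong on smooth imagery, and cheap. The predictor id is
  a header byte so alternatives can coexist.
* **Mapping**: the standard zigzag interleave m(e) = 2e (e ≥ 0),
  −2e−1 (e < 0). Only non-negativity is required downstream; the
  interleave additionally makes m monotone in |e|, so the layer split
  separates magnitude, not sign.
* **Layer split**: quotient/remainder by the layer interface Q. We read
  "interface = 4" as a divisor: the shape layer holds the high part
  (zero wherever the mapped value < Q, hence sparse), the detail layer the
  low ⌈log₂Q⌉ bits (dense, near-uniform). A thresholding interpretation
  (route the whole value to one layer) would also be invertible; the
  divisor form was chosen because it makes the detail alphabet exactly
  {0..Q−1} and therefore always completely codable. Q is a header field.

## Codebook training

Candidate windows up to H_max × W_max = 4×4 are accepted when every row of
length N has ≥ N/2 nonzeros and every column of length M has ≥ M/2 (halves
taken as reals, so a length-3 row needs 2). Zeros are dropped and offsets
re-based on the raster-first nonzero, so distinct windows with the same
pattern collapse to one shape; shape identity includes the cell values.
Mining counts overlapping occurrences — it measures prevalence, while the
encoder's cover must partition pixels and is therefore non-overlapping.

Retention scores each shape as `frequency · size^degree` with degree 0.5;
the `capacity` (default 4096) best shapes are kept in one pruning pass
after mining, with observed singletons always force-included. The 4×4
window cap and one-shot pruning bound memory against the combinatorial
explosion of large patterns; at the corpus sizes used here the cap rarely
binds except on the detail-rich Y component. Codeword assignment is
canonical Huffman over mined frequencies (ESCAPE gets frequency 1); detail
symbols get a separate canonical Huffman code over add-one-smoothed counts
so all Q symbols are codable. Ties everywhere break on the serialized cell
tuple, making retraining byte-deterministic.

## Encoding details

The cover scans the shape layer in raster order; at each uncovered nonzero
pixel, candidate shapes whose anchor value matches are tried largest-first
(then shorter codeword, then serialization order) and the first full match
is placed. Largest-first is a deliberate greedy heuristic: a minimum
placement cover is NP-hard in general, and on constructed toy instances
the greedy result matches the brute-force minimum (tested). Anchors
strictly increase, so locations are coded as Rice-coded gaps (first delta
absolute, then gap − 1); the Rice parameter k is chosen per component per
image by exact minimisation over k ∈ [0, 15] and stored in the block.

The container is big-endian with a CRC-32 tail: magic, version,
dimensions, component count, Q, predictor and mapping ids, a CRC-32 of the
serialized codebook set (codebooks travel out-of-band, trained once and
reused), then per component the Rice parameter and bit-exact shape and
detail blocks. Bit accounting re-derives Σl_I (unit bits, escape raw bits
included) and Σl_P (location bits) by re-parsing the blocks and asserts
`Σl_I + Σl_P + 36 field bits = shape-block length` and that the grand
total equals the container byte length × 8.

## Synthetic corpora

The fixture generator emulates the statistics the codec exploits in
stained-cell imagery: an integer low-frequency illumination ramp, blob
motifs drawn from a bank shared across the corpus (mutual similarity —
the reason a mined codebook transfers from a training split to a test
split), ±1 integer pixel noise, and, for color, channels offset from a
shared luminance field (strong inter-channel correlation for the RCT to
remove). Synthesis is integer-only and keyed to a seed, so corpora
regenerate byte-identically.

Default study conditions: 64×64 3-component images, 30 training and 20
test images, motif bank of 8, 6 motifs per image. These sizes keep the
full train/encode/verify cycle at desk scale (seconds) while leaving the
shape layer genuinely sparse (measured mean sparsity ≈ 0.92 at Q = 4).

What passing on these corpora shows: exact losslessness, stage
invertibility, completeness on adversarial inputs, and a large measured
gap over the raw-pixel Huffman baseline (≈4.8× vs ≈1.2×), i.e. the
shape/location representation captures spatial structure the baseline
cannot. What it does not show: performance on real stained-slide datasets,
whose texture, bit-depth artifacts and acquisition noise the generator
does not model, nor superiority over strong engineered codecs — at these
tiny image sizes the container is within a few percent of stock PNG, and
no claim is made either way.

## Numerical and degenerate-input choices

* All arithmetic is int64; no floating point touches the coded path
  (scores and Kraft checks are the only float uses).
* 1×1 images, constant images, and all-corner RCT triples are covered by
  tests; prediction treats out-of-bounds neighbours as 0, so a 1×1 plane's
  residual is its value.
* Escape values are bounded by the mapped-residual range (≤ 1020 for
  U/V planes at 8 bits), comfortably inside the 16-bit raw field.
* Population (not sample) variance in corpus reports.
* Compressed bits count the whole container, header and CRC included —
  the conservative convention for reported ratios.

## Known limitations

* The greedy cover has no optimality guarantee off the tested toys.
* One codebook set per component index; no cross-component sharing.
* Mining is O(H_max·W_max·M·N) per image in vectorised numpy but shape
  extraction is per-qualifying-window Python; very dense shape layers
  (e.g. noise at low Q) train slowly.
* 8-bit depth only; no tiling, progressive decoding, or region-of-interest
  modes.
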