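# softcomp

Lossless "soft" compression for 8-bit single- and multi-component images —
the kind of cell-microscopy and clinical imagery where exact reconstruction
is mandatory (a lossy artifact can look like pathology) and where images of
the same tissue class are *mutually similar*: alike in broad structure,
different in pixel-level detail.

Classical entropy coders spend bits only on *coding redundancy* (suboptimal
symbol codes); they ignore *spatial redundancy* because pixel locations are
implied by raster order. Soft compression attacks both at once by changing
the basic unit from the pixel to the **shape**: a recurring pattern of
residual cells, mined from a training corpus, placed explicitly at coded
locations. An image costs

    B = Σᵢ [ l_I(xᵢ, yᵢ) + l_P(xᵢ, yᵢ) ]

bits, where the sum runs over the T basic units, `l_I` is the bits for unit
i itself and `l_P` the bits for its location. Plain Huffman coding is the
degenerate case T = M·N, l_P = 0.

## Pipeline

Encoding a color image runs, per image:

1. **Component split** into B, G, R planes, then the reversible component
   transform of lossless JPEG2000 (Y = ⌊(R+2G+B)/4⌋, V = R−G, U = B−G);
   grayscale images skip this step.
2. **Prediction** with the JPEG-LS median (MED) predictor; each plane
   becomes a residual plane concentrated near zero.
3. **Sign mapping** 0, −1, 1, −2, 2, … → 0, 1, 2, 3, 4, … so residuals are
   non-negative.
4. **Layer split** at the layer interface Q = 4: quotient → sparse *shape
   layer*, remainder → dense *detail layer* (shape·Q + detail is exact).
5. **Shape layer**: greedy raster cover by codebook shapes; each placement
   is coded as a Rice-coded gap between flattened anchor indices (the gaps
   of a sparse layer are approximately geometric) plus the shape's Huffman
   codeword. An ESCAPE codeword carrying a raw value keeps every input
   encodable.
6. **Detail layer**: one corpus-trained Huffman codeword per pixel, raster
   order.

Codebooks are trained once per corpus and component by mining all windows
up to 4×4 whose every row/column is at least half nonzero (the candidacy
condition), deduplicating window patterns into value-bearing shapes,
ranking them by `frequency · size^0.5`, and assigning canonical Huffman
codewords. Decoding inverts each stage exactly; a CRC-32 and a codebook
checksum in the container header catch corruption and codebook mismatch.

## Worked example

```
$ softcomp gen-fixtures demo --seed 0 --train 8 --test 4 --size 64
wrote 8 train + 4 test images to demo
$ softcomp train demo cb
trained on 12 images
  cb.y.sccb: 3462 candidate shapes -> 3462 retained
  cb.u.sccb: 160 candidate shapes -> 160 retained
  cb.v.sccb: 132 candidate shapes -> 132 retained
$ softcomp encode demo/test_000.png cb test_000.scmc
demo/test_000.png -> test_000.scmc (2608 bytes)
$ softcomp decode test_000.scmc cb roundtrip.png   # pixel-identical PNG
$ softcomp stats demo cb
image                          ratio    bpsp  huffman    png_B
test_000.png                   4.712   1.698    1.222     2487
...
mean ratio     4.8036
mean bpsp      1.6656
mean huffman   1.2276
```

The *ratio* column is natural-binary bits (8 per sub-pixel) divided by the
compressed container bits, so `ratio = 8 / bpsp`; *huffman* is the same
ratio for independent raw-pixel Huffman coding of each component — the
gap between the two columns (≈4.8× vs ≈1.2×) is the spatial redundancy the
shape/location representation removes on these synthetic corpora. Decoding
`test_000.scmc` reproduces `test_000.png` pixel for pixel.

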