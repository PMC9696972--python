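# simlbp

A toolkit for the **symmetric inline matrix LBP (SIM-LBP)** visual descriptor —
a local-binary-pattern variant designed to enhance facial-feature boundaries
(eyes, brows, nose, mouth) in single-channel images for facial-expression
recognition, with deliberate robustness to illumination changes.

The package provides:

- the SIM-LBP per-pixel 3×3 transform and whole-image application,
- a canonical classic-LBP baseline for side-by-side comparison,
- grid-cell normalised histogram features with named facial-feature
  look-up windows and a chi-square nearest-neighbour classifier,
- confusion-matrix metrics (per-class precision, recall, F1, one-vs-rest
  accuracy, overall accuracy),
- a deterministic synthetic **face-phantom** generator (controllable
  expression geometry, illumination offset/gradient, blur, noise) so every
  descriptor claim is testable without downloading a face dataset,
- a `simlbp` command-line interface tying it together.

## The descriptor

For the 3×3 window around each pixel, with columns labelled
`SL1..SL3`, `SC1..SC3`, `SR1..SR3` (top to bottom), six signed comparison
pairs are formed:

- vertical, anchored at the centre column: `(SLᵢ − SCᵢ, SRᵢ − SCᵢ)` for `i = 1..3`;
- horizontal, anchored at the middle row: `(SX1 − SX2, SX3 − SX2)` for each
  column `X ∈ {L, C, R}`.

Each pair `(x, y)` yields a *feature-coefficient value*

```
fcv = mean(x, y) / σ²(x, y),   σ²(x, y) = ((x − y)/2)²   (population variance)
```

with a configurable fallback (default 0) when the variance is zero.  Each
pair element is binarised by `1 if (element − fcv) ≥ 0 else 0` (ties → 1).
The three vertical bit pairs fill the left/right cells of one 3×3 binary
matrix, the three horizontal pairs the top/bottom cells of another; the two
matrices are OR-merged (the centre cell stays 0), the 8 perimeter bits are
read clockwise from the top-left cell, and the *weighted pixel value*
`WPV = Σᵢ bitᵢ · 2^i` (i = 0 at top-left by default) becomes the output
intensity.  Because every stage reads only intensity *differences*, the
coded image is bit-invariant under any clip-free uniform illumination shift.

All underdetermined conventions (sign of the differences, coefficient
formula, bit significance, border padding) are explicit `TransformConfig`
options; the defaults are documented in `docs/methods.md`.

## Worked example

```python
>>> import numpy as np
>>> from simlbp import PixelWindow3x3, TransformConfig, sim_lbp_pixel, sim_lbp_transform
>>> w = PixelWindow3x3(SL=(10, 40, 70), SC=(20, 50, 80), SR=(30, 60, 90))
>>> sim_lbp_pixel(w, TransformConfig())
124
>>> img = np.array([[10, 20, 30], [40, 50, 60], [70, 80, 90]], dtype=np.uint8)
>>> sim_lbp_transform(img, TransformConfig(padding="crop"))
array([[124]], dtype=uint8)
>>> sim_lbp_transform(np.full((3, 3), 50, dtype=np.uint8))   # flat region
array([[255, 255, 255],
       [255, 255, 255],
       [255, 255, 255]], dtype=uint8)
```

The `124` arises from pairs `(−10, +10)` / `(−30, +30)` (coefficients all 0
because the pair means are 0), bit pairs `(0, 1)`, merged matrix
`[[0,0,1],[0,0,1],[1,1,1]]` and clockwise code `(0,0,1,1,1,1,1,0)` →
`4+8+16+32+64 = 124`.  A flat window gives 255: zero variance triggers the
fallback coefficient and the tie rule sets every bit.

From the shell:

```
simlbp synth --out phantoms --n 5 --seed 7
simlbp transform phantoms/smile_0000.png coded.png --mode sim
simlbp compare phantoms/smile_0000.png side_by_side/
simlbp demo --seed 42 --n 40 --illum-shift 40 --out demo_out
```

`simlbp demo` generates a two-class phantom set (smile vs frown mouth arc),
splits it 50/50, classifies grid-histogram features by chi-square nearest
neighbour, and repeats with a +40 uniform illumination shift applied to the
test images.  A representative report (seed 42, 40 phantoms/class): SIM-LBP
accuracy 1.00 both with and without the shift (features bit-identical),
raw-pixel-histogram baseline 1.00 clean but 0.875 shifted — the descriptor,
not the classifier, carries the illumination robustness.

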