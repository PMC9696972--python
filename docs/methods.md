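# Methods

## The SIM-LBP operator

SIM-LBP is a 3×3 local binary pattern variant built from *paired* signed
differences rather than the classic eight neighbour-vs-centre comparisons.
Window intensities are labelled by column (`SL1..SL3`, `SC1..SC3`,
`SR1..SR3`, top to bottom).  The stages are:

1. **Comparison pairs.**  Three vertical pairs anchored at the centre
   column, `(SLᵢ − SCᵢ, SRᵢ − SCᵢ)`, and three horizontal pairs anchored at
   the middle row, `(SX1 − SX2, SX3 − SX2)` for `X ∈ {L, C, R}`.  First
   element from the left/above neighbour, second from the right/below.
2. **Feature coefficients.**  Per pair `(x, y)`:
   `fcv = mean(x, y) / σ²(x, y)` with the population variance of the
   two-element set, `σ² = ((x − y)/2)²`.
3. **Binarisation.**  `bit = 1 iff (element − fcv) ≥ 0`; the tie maps to 1.
4. **Symmetric split + OR merge.**  Vertical pair *i* fills row *i*'s
   left/right cells of a 3×3 bit matrix; horizontal pair *j* fills column
   *j*'s top/bottom cells of a second matrix; the two are OR-merged.
   Neither split ever writes the centre cell, so the merge has exactly 8
   informative bits.
5. **Code.**  The perimeter is read clockwise from the top-left cell
   (TL, TC, TR, MR, BR, BC, BL, ML) and converted to a byte,
   `WPV = Σ bitᵢ·2^i` with i = 0 at the top-left.

Because stages 1–4 consume only differences (in the default and
`global_sum` coefficient modes), the coded image is *exactly* invariant
under any uniform intensity shift that does not clip — the property the
robustness experiments probe.  The `center_pixel` mode (below) breaks this
by construction.

### Resolved conventions

The operator's published description leaves several choices open; each is a
`TransformConfig` field so alternatives remain explorable:

| field | default | alternatives | why this default |
|---|---|---|---|
| `sign_convention` | `neighbor_minus_center` | `center_minus_neighbor` | matches the step-by-step construction of the pairs (e.g. "SL1 minus SL2" for the first horizontal element) |
| `coefficient_mode` | `pair_mean_over_variance` | `global_sum`, `center_pixel` | a per-pair mean/variance ratio is the only reading that gives each pair its own finite threshold; `global_sum` treats the six terms as one summed threshold; `center_pixel` thresholds against the raw anchor intensities |
| `zero_variance_fallback` | `0.0` | any finite value | equal pair elements make the ratio undefined; 0 plus the tie rule sends flat regions to code 255, a deterministic, recognisable value |
| `bit_order` | `lsb_at_top_left` | `msb_at_top_left` | reading the flattened array left-to-right as `Σ 2^i·bitᵢ` puts i = 0 first |
| `padding` | `replicate` | `reflect`, `zero`, `crop` | keeps output size equal to input size for full-size coded images; `crop` gives the pure no-padding interior |

Ties binarise to 1 everywhere (`≥`), in both SIM-LBP and the classic
baseline.  Differences and coefficients are computed in float arithmetic;
only the final code is cast to uint8.

### Classic-LBP baseline

The canonical 3×3 operator: each perimeter neighbour, clockwise from
top-left, yields `1 iff neighbour ≥ centre`, weighted identically to the
SIM-LBP code.  It shares the padding/bit-order conventions so coded images
are comparable cell-for-cell.  Its defining invariance — unchanged under
any strictly increasing remapping of the image's intensities — is tested
with random strictly increasing lookup tables.

### Oracle strategy

Both transforms have two independent code paths: a vectorised numpy
implementation and a naive per-pixel loop literally composing the stage
functions.  Equality is asserted bit-exactly on seeded random images with
all 48 combinations of the convention fields cycled across them.  The test
and the acceptance script use 50 images of 8×8 to 64×64 pixels — sizes at
which the naive loop is still fast while exercising every padding path.

## Feature extraction

The coded image is partitioned into a `grid_rows × grid_cols` grid
(default 8×8) of near-equal rectangles; remainder pixels extend the last
row/column of cells, so the partition is exact and cells are never empty.
Each cell contributes a normalised histogram with `bins` bins (default
256, the identity binning on byte codes; bin `b` collects intensities `v`
with `⌊v·bins/256⌋ = b`).  Count-weighted cell histograms therefore
recombine exactly to the global histogram — the conservation property the
tests assert.

Look-up windows are *named half-open rectangles of grid cells* (not pixel
ROIs): selecting cells keeps the feature a sub-vector of the full grid
feature and makes templates resolution-independent.  The shipped template
(`simlbp/data/lookup_windows_8x8.json`) is a heuristic layout for a frontal
face on an 8×8 grid — eyes/brows in the upper-middle cells, mouth
lower-middle — not a fitted model.

Histogram matching uses the chi-square distance
`Σ (h1−h2)²/(h1+h2)` (zero-denominator terms skipped) with a
nearest-neighbour rule; ties break toward the earliest reference, which
makes classification order-deterministic.

## Evaluation metrics

From a confusion matrix with sorted distinct labels: per class, precision
`tp/(tp+fp)`, recall `tp/(tp+fn)`, F1 as the harmonic mean
`2·pr·rc/(pr+rc)`, and one-vs-rest accuracy `(tp+tn)/total`; overall
accuracy is `trace/total`.  A zero denominator yields an explicit missing
value (`None`/NaN), never a silent 0, so class averages stay honest.  The
suite asserts the multiclass identity micro-precision = micro-recall =
overall accuracy.  (A printed variant of the F1 formula circulates with
`2·(tp+fp+fn)` in the denominator; it is dimensionally inconsistent with a
score in [0, 1], and the harmonic mean is used here.)

## Synthetic face phantoms

`generate_face_phantom` renders a deterministic grayscale stand-in for a
frontal expression photograph: a mid-gray face oval (intensity 150) on a
dark background (30), elliptical eyes and angled brow strokes (ink 60), and
a parabolic mouth arc whose signed `mouth_curvature` bends the corners up
(smile-like) or down (frown-like).  Rendering order: geometry → linear
illumination (uniform `illumination_offset` plus a left-to-right
`illumination_gradient` ramp) → Gaussian blur (`blur_sigma`) → additive
Gaussian noise (`noise_sd`, seeded generator) → clip to [0, 255] → uint8.
Illumination precedes the linear blur and the seeded noise, so a clip-free
offset shifts every output pixel by exactly that amount — the property that
lets invariance be asserted bit-for-bit.

Defaults: 128×128 pixels, `eye_sep` 0.30 of width, `blur_sigma` 1.0 px and
`noise_sd` 2.0 intensity units — mild camera-like softness and sensor noise
that leave peak intensities near 150, comfortably clip-free under the +40
shifts used in the experiments.  `generate_dataset` jitters *geometry*
fields only (defaults: `eye_sep` σ=0.01, `brow_angle` σ=3°,
`mouth_curvature` σ=0.08) around per-class templates; illumination, blur
and noise levels stay at template values so perturbation experiments
control them explicitly.  One seeded generator per call drives all jitter
and per-image noise seeds — no global random state, and the whole set
regenerates byte-identically from its arguments.

The phantoms emulate only the coarse feature layout of a face.  They have
no skin texture, pose, identity variation or occlusion, so green tests
demonstrate the descriptor's arithmetic properties (invariances,
determinism, discriminability of local texture differences), not
recognition performance on real faces.

## The demonstration experiment

Two classes (`smile`: mouth_curvature +0.5, `frown`: −0.5), 40 phantoms
each by default, stratified 50/50 split, full-grid 8×8×256 histogram
features, chi-square nearest neighbour.  The test set is additionally
re-evaluated after a +40 uniform illumination offset: SIM-LBP and classic
LBP features are bit-identical under the shift (their accuracy change is
exactly zero), while the raw-pixel-histogram control loses accuracy because
its bins move wholesale.  Problem sizes (40/class, 128×128) keep a full run
under half a minute on one CPU while leaving the nearest-neighbour problem
non-trivial.

Degenerate splits: a class with one item is placed in both halves so a
report is still produced; otherwise every class contributes at least one
item to each half.

## Known limitations

- The descriptor is defined for single-channel 8-bit images; colour input
  is reduced by ITU-R 601 luma (0.299/0.587/0.114) at load time.
- Uniform-pattern (59-bin) compression, multiscale block LBP, and
  spatio-temporal variants are out of scope.
- The illumination invariance is exact only while no pixel clips at 0 or
  255; real low-light images saturate and the guarantee degrades at the
  clipped pixels.
- Phantom-based accuracies say nothing quantitative about real-face
  datasets; they are controlled demonstrations of descriptor properties.
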