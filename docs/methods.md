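# Methods

`cardioslide` implements an image-analysis pipeline for classifying
cardiac biopsy fluorescence slides at two levels: diagnosing disease
from nuclear morphology (single DAPI channel) and predicting treatment
response from DNA-damage burden (paired DAPI + γ-H2A.X channels).
This note records the model choices, the parameters that matter, and
what the synthetic data does and does not establish.

## Nucleus segmentation

A slide is processed as a five-step deterministic recipe:

1. **Grayscale.** 3-channel input is collapsed with BT.601 luminance
   weights (0.299, 0.587, 0.114); single-channel input passes through.
2. **Bicubic enlargement.** The slide is enlarged by an integer factor
   per axis with the Keys convolution kernel (a = −0.5), corner-aligned
   coordinates and clamped edges. The default factor is 4 per axis — a
   16-fold *area* enlargement. Cardiac nuclei are only a few pixels
   across at acquisition resolution, so contouring operates on the
   enlarged grid. The interpolation is implemented in-package as a
   separable convolution because the exact kernel and grid convention
   are part of the contract the tests verify against a direct
   per-pixel evaluation; corner alignment makes a factor of 1 the
   identity and keeps corner pixels exact.
3. **Otsu binarization.** The global threshold maximizes between-class
   variance of the intensity histogram; ties go to the lowest
   threshold; foreground is *strictly greater* than the threshold
   (the strict inequality is a convention we fix and document, since
   either choice is defensible). A constant image has no threshold:
   segmentation returns an empty result with a warning.
4. **Morphological gradient.** Dilation minus erosion with a 3×3
   square structuring element, one iteration, reflect border padding
   (no spurious contour at the slide edge). This outlines each
   nucleus as a closed ring.
5. **Labeling and extraction.** 8-connected components of the contour
   mask are labeled; each component's *pixel-count* area is measured
   in the enlarged frame, components with area ≤ 512 px (inclusive)
   survive, and their tight bounding rectangles are cropped out of the
   enlarged grayscale slide.

Design points that were genuinely open: the area cap is applied to the
contour component (areas are measured on the "outlined objects", i.e.
the gradient mask), in enlarged-frame units, because filtering happens
after enlargement; objects touching the border are kept; no minimum
area is enforced by default (`min_area_px = 1` is exposed for noise
experiments); crops are tight (no padding) — classifier-side resizing
absorbs geometry. With 4× enlargement the ring of a nucleus of
original radius 3–8 px has ~150–450 contour pixels, so the 512-px cap
retains single nuclei while discarding large fused or smeared regions.

## Dual-stain composites and tiling

Brightness/contrast is normalised per channel from the histogram: the
cut intensities are where the cumulative histogram passes
`saturation_fraction` of the pixels from each tail (default 0.0035,
the familiar automatic-adjustment convention), and `[low, high]` maps
linearly to full range with rounding, via a per-intensity lookup
table. The composite places the auto-contrasted nuclei channel in
blue and the damage channel in red (conventional fluorophore display;
the mapping is configurable — classifiers only need consistency).

Composites are tiled into non-overlapping `patch_size × patch_size`
tiles (default 128), stride = patch size, row-major, partial edge
tiles dropped: exactly `⌊H/s⌋·⌊W/s⌋` patches. A stitched slide of
8064 × 10240 px therefore yields 5040 patches. Non-overlapping tiling
is the only grid consistent with every patient contributing an
identical patch count from same-size slides. Each patch inherits its
patient's outcome label (weak labeling).

## Dataset construction

Splits assign whole *patients*, never images: per class, a seeded
permutation selects the requested train/test patient counts, and all
of a patient's items inherit the assignment. Every manifest validates
patient exclusivity and path uniqueness on construction; violations
are hard errors. Training manifests are augmented by the four
right-angle rotations — exact pixel permutations, never interpolated —
recorded as row tags (`rot0/rot90/rot180/rot270`) and materialised at
load time, so augmentation quadruples the manifest without
quadrupling disk I/O. Test data is never augmented.

## Patch classifiers

Both backends expose the same `fit`/`predict_proba` contract over
manifests, so aggregation and evaluation are backend-agnostic:

* `transformer_small` — a compact Vision Transformer written in NumPy
  (float64, CPU): linear 8×8 patch embedding, learned positional
  embeddings, pre-norm blocks of multi-head self-attention plus a
  GELU MLP, final layer norm, mean pooling, two-logit softmax head.
  Reference width 128, depth 4, 4 heads; trained from scratch with
  Adam (lr 10⁻³) on cross-entropy. Backpropagation is hand-derived
  and verified against central finite differences in the test suite.
  Training is exactly reproducible from the config seed (pure NumPy,
  no threading nondeterminism).
* `intensity_baseline` — logistic regression on per-channel mean and
  standard deviation (6 features, standardised). It is deliberately
  close to the Bayes rule of the synthetic damage effect and serves
  as the fast sanity backend.

Inputs are resized aspect-preserving (longer side to `input_size`,
bicubic), zero-padded bottom/right to square, scaled to [0, 1], and
gray inputs are replicated to 3 channels. Model state serialises as a
flat array dict with a JSON header (config + training-manifest
digest) and round-trips bit-identically.

## Aggregation and metrics

A patient's predicted label is the majority of patch votes at the
decision threshold (default 0.5). An exact tie — possible with even
patch counts — falls back to comparing the patient's mean score to
the threshold and is flagged `tie_broken`. The mean is computed over
sorted scores so the vote is exactly permutation-invariant.

ROC uses the distinct-score threshold sweep with tied scores grouped;
the trapezoidal area then equals the pair-counting probability
P(score⁺ > score⁻) + ½P(equal), an identity the tests assert on random
tables. The PR area uses step-wise (right-continuous) interpolation —
the conservative convention, equal to average precision. Both are
undefined for single-class inputs and raise rather than guess.

## Synthetic slides

The generator emulates the statistical structure the pipeline
assumes, with all randomness drawn from one seed:

* nuclei: non-overlapping filled ellipses (rejection-sampled with a
  4 px margin), semi-major axis ~ N(5, 1) px clipped at 1.5, rendered
  at intensity 180 on a background of 20 with Gaussian noise (σ = 8),
  8-bit. Radii are kept small on purpose so the enlargement step is
  exercised in its intended regime.
* damage channel: per nucleus, Poisson(`foci_rate`) punctate foci of
  radius 1.5 px at intensity 200, placed uniformly inside the
  ellipse, over the same background/noise model.
* class effects: diagnosis-track classes differ in nucleus size and
  eccentricity (control: radius 4.5, eccentricity 0.25; diseased:
  radius 6.0, eccentricity 0.75); prognosis-track classes differ in
  `foci_rate` (responder 0.5, non-responder 5 foci per nucleus).
  These encode the biological premises — altered nuclear morphology
  in disease, elevated DNA damage in poor prognosis — with effect
  sizes chosen to be nearly separable at desk scale, since the real
  effect sizes are not published.

Ground truth records per-nucleus centroid, axes, orientation,
analytic area (πab) and focus count. Analytic and rasterised areas
agree within rasterisation error (≤10 % for radii ≥ 4 px).

What the generator does **not** model: overlapping/clumped nuclei,
point-spread blur, illumination gradients, stitching seams,
out-of-focus planes, staining variability between batches. Passing
tests therefore demonstrate that the pipeline's machinery is correct
and that it recovers a class signal it is pointed at — not that real
biopsy images are this separable, nor that real-data accuracies carry
over.

## Problem sizes used by the checks

The dataset-count checks run the real tiling code on full-size
(8064 × 10240) synthetic slides for a 23 + 23-patient cohort split
16 + 16 / 7 + 7. The end-to-end study uses a deliberately small
condition — 8 patients per class on 256 × 384 slides (6 patches per
patient), 25 nuclei per slide, the 0.5-vs-5 foci effect, and a reduced
transformer (input 32, width 32, depth 2, 4 epochs) averaged over
three seeds — sized so the whole study trains from scratch on one CPU
core in seconds while the class effect remains near-separable.

## Known limitations

* The segmentation does not split touching nuclei (no watershed); the
  generator's non-overlap guarantee sidesteps this, real tissue would
  not.
* Otsu is global; slides with strong illumination gradients would
  need local thresholding.
* The NumPy transformer is CPU-sized; it accepts but does not ship
  pretrained weights, and nothing here reproduces large-scale
  pretraining.
* Patient labels are consumed as given metadata; the clinical
  response definition travels as free-text provenance only.
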