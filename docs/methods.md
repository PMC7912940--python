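# Methods

## The problem and the model

`msbrainseg` implements a pixel-wise sliding-window classifier for brain-tumor
segmentation and typing on single-modality (T1-CE) 2D MRI slices.  Each pixel
of a slice is classified from its N × N neighborhood into one of four labels —
0 healthy, 1 meningioma, 2 glioma, 3 pituitary tumor — by a convolutional
network with **three parallel pathways** operating at different kernel scales.
No skull stripping or other anatomical preprocessing is performed; the model
must learn to reject bright non-cerebral structures on its own.

The reference configuration (`NetworkConfig()` defaults) is:

* input window 65 × 65 (one grayscale channel);
* pathways with 11 × 11, 7 × 7 and 3 × 3 kernels carrying 128, 96 and 64
  feature maps; each pathway is two stages of
  `conv (same padding) → ReLU → max-pool (3 × 3, stride 2, ceiling sizing)`;
* pathway outputs (each 16 × 16) concatenated along the feature axis into
  288 maps, then `conv 3 × 3 → 128 maps → ReLU → max-pool (2 × 2, stride 2)`;
* flatten (128 × 8 × 8 = 8192 features) → dropout 0.5 → fully connected → 4 →
  softmax.

Two printed constraints pin the unstated details: the flattened feature count
(8192) and the total trainable-parameter count (2,856,932).  Same-padding
convolutions with ceiling-mode pooling are the unique natural convention under
which both hold simultaneously: the spatial trace is 65 → 32 → 16 → 8 and the
parameter budget decomposes as 2,492,256 (three biased conv pairs) + 331,904
(biased 288→128 concat conv) + 32,772 (biased 8192→4 layer).  Both the closed
form (`count_parameters`) and instantiation-based enumeration are exposed, and
the test suite asserts their agreement on random configurations.

The network is implemented directly in NumPy (float32).  Convolutions are
computed with im2col and a single wide GEMM per layer, in a
channels-first-of-batch layout that keeps single-CPU BLAS throughput high;
layers exceeding a 256 MB column-buffer budget fall back to one GEMM per
kernel offset.  Every layer carries an explicit backward pass; gradients are
verified against central differences in the test suite (the float32 forward
pass limits agreement to about 1–5 % relative on individual weights, which
the test tolerances reflect).

## Training pipeline

Per cross-validation fold, in order:

1. **Elastic augmentation** (`augment_fold`): each training slice is
   duplicated once by a smooth random deformation — per-pixel uniform [−1, 1]
   displacement fields, Gaussian-smoothed with bandwidth σ and scaled to
   magnitude α; the image is resampled bilinearly, the mask with
   nearest-neighbor (so it stays binary), and the border polyline is
   re-derived from the warped mask.  Defaults scale with resolution
   (α = 0.1 × side, σ = 0.02 × side), since the transform itself has no
   published parameter values.
2. **Window sampling** (`sample_windows`): 150 windows centered on tumor
   pixels and 325 on healthy pixels per slice (defaults), drawn uniformly
   without replacement.  Negative centers are drawn from *all* non-tumor
   pixels — skull and background included — because the method performs no
   skull stripping and must learn those negatives.  Windows overrunning the
   image edge are zero-padded.  The 150/325 ratio is the only class-balance
   mechanism; no loss re-weighting is applied.
3. **Standardization** (`fit_standardization`): one global pixel mean and
   standard deviation pooled over all training windows; the same statistics
   are reused unchanged on test windows.
4. **Optimization**: shuffled mini-batch SGD with momentum 0.9, categorical
   cross-entropy (the natural choice for a softmax head; no loss is published
   for this architecture), starting learning rate 0.005 with a stepwise decay
   (× 0.1 by default) every 20 epochs, 80 epochs, dropout active.

Inference (`segment_slice`) slides the window over every stride-th pixel,
standardizes with the training statistics, and writes the argmax class at the
center; ties break toward the smallest label.  Stride 1 reproduces the
per-pixel procedure exactly; for stride > 1 (a desk-scale extension)
unsampled pixels take the label of their nearest sampled center, ties toward
the top-left.

Slice-level typing (`classify_slice`) computes per-class ratios
f_l = |{P = l}| / |{P > 0}|, zeroes ratios at or below the confidence
threshold τ_c (strict inequality survives), and returns the argmax of the
survivors, or −1 (non-classified) when none survive.  Reported accuracy
divides the confusion-matrix diagonal by *all* slices, non-classified ones
included — the convention is forced by the published confusion-matrix
arithmetic (2984/3064 → 0.973 truncated).  Printed 3-decimal summary values
are *truncations*, not roundings, and `macro_average(..., truncate=True)` /
`ConfusionReport.accuracy_printed` reproduce that convention; per-class
sensitivities are rounded to two decimals.

One documented tension: the published prose describes the displayed
segmentation as {P > 0} while the metric definitions score
P1 = {P = l_gt}.  Both are implemented — overlays paint {P > 0}, metrics use
P1 — and the two are not reconciled here either.

## The phantom generator

Real data (3064 slices, 233 patients, classes 708/1426/930) is never required
by the tests.  `generate_phantom` emulates the record structure and the
statistical challenges of such slices at configurable resolution:

* a dark background, a bright elliptical **skull ring** (not stripped), a
  smooth brain interior, and a bright **sinus-like midline structure**
  present in *every* slice (it is anatomy, not a class marker) — the known
  source of pituitary-tumor confusion;
* exactly one lesion per slice with class-distinct texture and placement:
  class 1 bright, homogeneous, attached to the skull ring; class 2 darker,
  heterogeneous (high local variance), deep in the parenchyma; class 3
  intermediate, just superior to the sinus structure near the inferior
  midline;
* a binary mask, an ordered border polyline (8-connected boundary pixels,
  angle-ordered), and patient ids shared by consecutive slices so
  patient-aware folds are meaningful.

Intensities are floats in [0, 1]; standardization later removes the scale, so
nothing depends on matching the arbitrary integer scale of real scanners.
Texture parameters (base intensity, contrast, spatial frequency, homogeneity)
are configurable per class; the defaults make the three classes statistically
distinct (the suite asserts, among others, that within-lesion local variance
of class 2 exceeds class 1 by a wide margin on 20 slices per class).

What the phantoms do **not** emulate: bias fields, k-space artifacts, partial
volume effects, multiple lesions, anatomical variability of real brains, or
realistic tumor texture.  Tests passing on phantoms therefore demonstrate
that the pipeline's machinery — sampling, training, inference, aggregation,
scoring — behaves as specified, not that the reported real-data accuracy
transfers.

## Desk-scale profile

Training the reference configuration is a multi-day job (dense sliding-window
inference alone evaluates one 65 × 65 window per pixel).  The package
therefore fixes a scaled profile (`profiles.desk_profile`) used by the
end-to-end tests: 60 phantom slices at 128 px (20 per class, 2 slices per
patient), a toy network with window 13, kernels (5, 3, 3), maps (16, 12, 8),
24 concat maps and dropout 0.25; 20 positive + 45 negative windows per slice
(the reference 150/325 ratio, scaled); elastic α = 12.8, σ = 2.56; 10 epochs;
stride-8 inference; τ_c = 0.

Because the schedule is 8× shorter than the reference 80 epochs, the profile
compensates on the optimization side: batch 64 instead of 128 (twice the SGD
steps per epoch) and learning rate 0.01 instead of 0.005, with lighter
dropout (0.25) appropriate for a 96-feature head.  With the reference
settings the 10-epoch run under-trains the hardest class boundary
(meningioma-like vs pituitary-like — both bright lesions adjacent to bright
structures); with the scaled settings a full 5-fold cross-validation reaches
slice-classification accuracy of roughly 0.85–0.95 depending on the seed, in
about two minutes on one CPU.

## Numerical and design choices

* **Coordinates** are 0-based (row, col) everywhere; the real-data reader
  converts from the source's 1-based vectors and resolves its undocumented
  axis order by validating border points against the mask (the interpretation
  matching foreground on ≥ 50 % of points wins).
* **Fold construction**: when stored fold indices exist they are used
  verbatim; otherwise `make_stratified_folds` builds seeded, stratified,
  patient-aware folds (largest patient groups first, each to the lightest
  fold).  For 3064 records in 5 folds the test-set sizes come out in
  {612, 613} — note 5 × 612 ≠ 3064, so the published "612 per fold" cannot be
  exact; no claim is made of matching the dataset's own shipped indices.
* **Tie-breaks**: pixel argmax and slice argmax both break toward the
  smallest label; pooling argmax takes the first maximum (deterministic
  backward pass).
* **Degenerate inputs**: an all-healthy label map is non-classified (−1);
  Dice is 1 when prediction and truth are both empty (unreachable for valid
  records, which must contain tumor pixels); pttas is 0 when no pixel is
  labeled tumor; zero pooled variance raises instead of standardizing.
* **Determinism**: every stochastic stage (phantom geometry, elastic fields,
  window sampling, weight init, shuffling, dropout) draws from its own
  `SeedSequence`-derived stream, so identical seeds reproduce records,
  models, and evaluation reports bit for bit on the same platform/BLAS.
  Cross-platform bit-identity of float32 GEMMs is not guaranteed.

## Known limitations

* The NumPy network trains desk-scale configurations comfortably but is not
  meant for the full 80-epoch, 512 px, stride-1 regime; that remains a
  GPU-scale undertaking.
* Slice-level calls at large inference strides rest on few sampled centers
  per lesion (a 10 px-radius lesion at stride 8 contributes ~3–6 windows), so
  stride is a speed/robustness trade-off, not a free parameter.
* The phantom generator's texture statistics are a stand-in; no claim is made
  that they match real tumor appearance, and model selection on phantoms does
  not transfer to clinical data.
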