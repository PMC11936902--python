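# Methods

## The registration problem

Dynamic chest radiograph sequences image the lungs during free breathing.
Quantitative analysis of lung motion (diaphragm excursion, airflow
surrogates, air-trapping localisation) requires a point-to-point
correspondence between frames — a dense 2-D displacement field per ordered
frame pair.  `lungreg` implements a fully automatic three-stage pipeline:

1. **Segmentation** — a U-Net-style encoder-decoder predicts a lung-field
   probability map per frame; thresholding (default 0.5, strict `>`)
   yields a binary mask.
2. **Lung-field extraction** — the mask, with lung pixels set to 1 and
   background to 0, multiplies the frame pixel-wise, keeping the original
   grayscale inside the lung field and exactly zero outside.
3. **Deformable registration** — a convolutional deformation predictor
   ("VectorCNN") maps a (source, target) lung-field pair to a two-plane
   displacement field `T`; a differentiable warper resamples the source by
   `T`.

## Conventions

* Rasters are H×W arrays in [0, 1]; row 0 is the image top; indices are
  0-based.  Masks are strictly binary.
* Displacement fields are **backward maps in pixel units**: the warped
  output at pixel `p` samples the input at `p + (dx, dy)`, `dx` along
  columns and `dy` along rows.  Images are sampled bilinearly, masks by
  nearest neighbour (then re-binarized).  With `zeros` padding a sample
  with any out-of-bounds bilinear corner blends toward 0, the same
  convention on the evaluation and the differentiable training path (the
  two samplers agree to float32 precision and are tested against each
  other).
* Fields are serialized as a small self-describing binary: magic `LRF1`,
  little-endian uint32 height/width, then the dx and dy planes as
  little-endian float32, row-major.  Round trips are bit-exact.

## Training objective

For source image `I`, target `J`, their masks `S_I`, `S_J` and the
predicted field `T`, the training loss is

```
Loss = -λ_NCC · NCC(I∘T, J) + λ_TV · TV(T) + λ_BCE · BCE(S_I∘T, S_J)
       + λ_L2 · ‖enc(S_I∘T) − enc(S_J)‖²
```

with weights λ_NCC = 1.0, λ_TV = 5·10⁻⁵, λ_BCE = 1.0, λ_L2 = 0.1 and
ε = 10⁻⁵ in the NCC denominator.

Numerical choices that the formulas leave open:

* **NCC ε placement.**  The denominator is `sqrt(Var(I∘T)·Var(J) + ε)` —
  a single guard under the root covers both degenerate variances, so a
  constant image yields loss 0 rather than NaN.  The library also carries
  both printed algebraic forms of NCC (central moments vs
  `E[X²] − (E X)²`) as an internal cross-check; they agree to 10⁻⁸ on
  random inputs.
* **TV form.**  Implemented exactly as printed, anisotropically: the
  x-plane is differenced along rows, the y-plane along columns, each term
  is the mean absolute forward difference, and the two means are averaged.
  A `full` mode differencing both planes along both axes is available but
  not the default.  (The printed anisotropic form may be a typographical
  compression of full TV; we keep fidelity first.)
* **Latent penalty normalisation.**  The printed divisor is ambiguous
  between `n` and `n²` for an n×n code; we use the mean over all `n²`
  entries, consistent with a "mean squared error" reading.
* **BCE clamp.**  Warped-mask probabilities are clamped to
  `[10⁻⁷, 1 − 10⁻⁷]` before the logs.
* **Soft vs hard mask warping.**  During training masks are warped
  bilinearly (soft) so the overlap and latent penalties stay
  differentiable; evaluation warps masks by nearest neighbour (hard).
  Both paths are exposed.

## Anatomical constraint

A denoising autoencoder is trained first on binary lung masks (corrupted
by independent pixel flips, rate 0.05) to reconstruct the clean mask under
binary cross-entropy.  Its encoder — convolutions with 2× average pooling
down to a single-channel n×n grid, n = image_size/2^depth (6×6 at the
default 96 px, depth 4) — is then frozen; during registration training the
squared distance between the codes of the warped source mask and of the
target mask penalises anatomically implausible warps.  Heart labels play
no role anywhere: masks contain lung fields only.  The autoencoder has no
skip connections, so the bottleneck code must carry the shape information.

## Three-step training (V1 → V2 → V3)

The deformation predictor trains on a corpus of *static* images with lung
masks, in three cascaded steps:

1. **Initial (V1)** — all ordered pairs of full images (n² − n of them;
   the full-scale protocol pairs 787 images into 618,582).  At desk scale
   each epoch draws `pairs_per_epoch` pairs uniformly without replacement.
2. **Enhanced (V2)** — pairs (image → affine-transformed image), one fresh
   affine draw per image per epoch.  The same draw transforms the image
   (bilinear) and its mask (nearest): augmentation consistency is load-
   bearing, because the overlap and latent terms compare the warped source
   mask to the *affine* mask.
3. **Final (V3)** — the same pairing scheme on *extracted lung fields*.

Design choices where the protocol was open:

* Pair direction in steps 2–3 is source = original, target = affine; an
  `include_reversed` flag adds the opposite direction.
* Fresh affine draws per epoch (rather than one fixed set) give richer
  simulated breathing at a small corpus size.
* The encoder is trained first and frozen through all three steps.
* Optimiser: Adam, constant learning rate, with global gradient-norm
  clipping (default 0.5).  Clipping matters: the warp's gradient is
  locally rough (piecewise-bilinear), and un-clipped runs occasionally
  jump to large fields whose samples fall outside the image, where the
  zeros padding kills the NCC gradient and training stalls.  The default
  learning rate is 1.5·10⁻³ for the registration steps and 2·10⁻³ for the
  auxiliary models — chosen for reliable convergence of these small
  models within a few hundred optimisation steps.

## Synthetic breathing phantom

No public dynamic radiograph sequence backs this package, so every claim
is validated on a seeded phantom that emulates a posteroanterior chest
radiograph: two vertically elongated super-elliptical bright lung fields
(seed-jittered centres, axes and exponents) on a darker thorax, with two
texture components *fixed in material coordinates* so they move with the
tissue — rib-like horizontal bands (period ≈ 0.10–0.14 of the image side)
and a broadband vascular-like texture (a sum of eight random-orientation
sinusoids, wavelengths 0.06–0.22 of the image side).  The broadband
component is essential, not cosmetic: bands alone are periodic in one
direction, so in-plane motion would be partly unobservable to an
intensity-matching registrar (the aperture problem) — a degeneracy real
lung fields, with their vascular markings, do not have.

Breathing is modelled as a diaphragm-dominant vertical displacement,
`amplitude · sin(π·phase) · lung_height`, weighted by a smoothstep ramp
that is 0 at the lung apex and 1 at and below the base, plus a small
lateral expansion (25 % of the vertical term) away from the midline.
Frames are rendered by inverting the forward motion map with a fixed-point
iteration (the motion is a small smooth perturbation of the identity, so
the iteration converges geometrically); the **ground-truth field that
warps frame k onto frame 0 is then the analytic forward displacement
itself**, with no numerical inversion error.  Additive Gaussian intensity
noise (SD 0.01) is drawn per (seed, phase) and clipped to [0, 1].

Defaults: 96×96 frames, 11 frames per cycle, amplitude 0.15 (the
diaphragm analogue descends ≈ 7.5 px at full inspiration), texture
strength 0.4.  What the phantom does **not** emulate: projection physics,
cardiac motion and heart shadow, pathology, exposure drift, scatter,
anatomic variability beyond smooth shape jitter.  Passing tests therefore
demonstrate the correctness and internal consistency of the pipeline and
the direction of the training-scheme effect — not clinical-grade accuracy
on real radiographs.

## Evaluation

DSC, Hausdorff distance, average symmetric surface distance and mean
squared intensity distance, over all ordered frame pairs (n² − n; 110 for
an 11-frame cycle).  HD and ASSD operate on boundary pixel sets
(foreground pixels with a 4-neighbour background pixel; the image border
counts as background) via exact Euclidean distance transforms; a flag
switches HD to full-region point sets.  The printed ASSD formula sums each
boundary point's distance to its own surface (identically zero); this is
presumed a typographical error and the standard symmetric definition is
implemented — both directed sums over the opposite boundary, divided by
the total boundary count.  MSD is computed on [0, 1] intensities and
reported at a configurable intensity scale (×255 by default in reports,
for comparability with 8-bit conventions).  Empty-mask pairs get
DSC(∅,∅) = 1 by convention; their distances are flagged NaN, warned
about, and excluded from aggregates.  Paired significance uses the
two-sided Wilcoxon signed-rank test by default (no normality assumption on
110 paired differences), with a paired t-test option; identical columns
report p = 1.

The ablation harness evaluates five arms over the same pair set:
unregistered baseline on full frames, the same baseline with MSD on
extracted lung fields, V1 and V2 on full frames, and V3 on lung fields.
Because V3 registers lung fields, its MSD is compared like-for-like
against the lung-field baseline; both baselines are always reported.

## Reference desk-scale conditions

Fixed in `lungreg.experiments`: a training corpus of 60 static phantoms
(seed-jittered anatomies frozen at uniformly random breathing phases,
amplitude 0.15); autoencoder 20 epochs; segmenter 16 epochs on 40 of the
60 images; step 1 for 10 epochs × 96 pairs; steps 2–3 for 10 epochs over
the 60 (image → affine) pairs; an 11-frame held-out test cycle whose
anatomy seed is disjoint from the corpus.  On one CPU core a full
pipeline trains in roughly four minutes.  At these conditions the
published ablation *ordering* reproduces — V3 beats both the unregistered
baseline and V1 on Dice, and V1 can dip below the baseline, as in the
original ablation — while the magnitudes differ, as expected at phantom
scale.

## What the method does and does not recover

The composite objective is boundary-dominant: in a lung-field image the
bright lung region carries almost all of the intensity variance, and the
overlap and latent penalties constrain mask shape, while the TV weight
(5·10⁻⁵) provides essentially no interior coupling.  Trained models
therefore align lung *morphology* very well — on phantom pairs related by
a known pure translation the warped-mask Dice reaches ≈ 0.99 — while the
*interior* of the displacement field is only weakly determined: the mean
in-mask displacement on such pairs is recovered with an error of roughly
2 px at the reference conditions (the acceptance script reports this as
`translation_recovery_mean_error_px`).  All of the evaluation metrics the
pipeline targets (DSC, HD, ASSD, MSD) are boundary- or intensity-based
and are insensitive to this, but the fields should not be read as
point-wise tissue trajectories without further regularisation.

## Known limitations

* The deformation model is a free-form displacement field with a weak TV
  penalty; folding is possible and no diffeomorphic guarantee is made
  (the Jacobian-determinant metric is deliberately out of scope).
* The networks are small (≈ 10⁵ parameters) and CPU-oriented; they are
  not meant to transfer to real 512×512 radiographs without retraining.
* The affine augmentation simulates breathing only coarsely; step 2/3
  training never sees true non-affine deformation, exactly as in the
  protocol it follows.
* Stochastic conclusions (ablation ordering, translation recovery) hold
  as medians over seeds at the stated conditions, not for every seed.
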