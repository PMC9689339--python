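# Methods

## Overview

`gliopipe` implements a three-stage analysis of axial brain-MR slice
stacks:

1. **Slice triage** — a compact CNN labels each slice tumorous or
   non-tumorous; non-tumorous slices are excluded from further work.
2. **Tumor segmentation** — a neighboring fuzzy-c-means (FCM) pipeline
   extracts the tumor region on each tumorous slice and refines it with
   morphology and seeded region growing.
3. **Subregion classification** — a second CNN assigns the segmented tumor
   crop to one of the four glioma sub-compartments (necrosis, edema,
   non-enhancing, enhancing; BraTS label codes 1–4).

Everything is exercised on seeded synthetic phantoms, so the behavior of
every stage is testable without external imaging data.

## Neighboring fuzzy c-means

Standard FCM on a slice with intensities `x_i` alternates

    u_ip = [ Σ_k (d_ip / d_ik)^(2/(q−1)) ]^(−1),   d_ip = |x_i − y_p|
    y_p  = Σ_i u_ip^q x_i / Σ_i u_ip^q

minimizing `Σ_i Σ_p u_ip^q d_ip²`. The neighboring variant replaces each
pixel's feature `x_i` by its mean over a window of consecutive slices —
the slice itself plus `window_halfwidth` slices on each side (2 by
default, a 5-slice window) — before clustering. When the tumor
cross-section varies smoothly through the stack, this attenuates per-slice
noise by roughly √5 at the cost of slight blur where the boundary moves
between slices. Window indices past the first or last slice replicate the
edge slice (`clamp`, default) or are dropped (`shrink`).

Numerical choices:

- `c = 4` clusters (background+CSF, grey matter, white matter, tumor),
  `q = 2`, tolerance `1e-5` on the max centroid change, 100 iterations cap.
- Initial centroids at the `(2p+1)/2c` quantiles of the feature values;
  if the histogram is so peaked that quantiles coincide, an even spread
  over `[min, max]` is used instead. Both rules are deterministic and
  seed-free. An explicit `initial_centroids` override exists; permuting it
  permutes cluster indices but not the induced partition.
- A pixel exactly coinciding with a centroid receives one-hot membership.
- Requesting more clusters than distinct feature values is an error.

The binarization step keeps the pixels whose largest membership belongs to
the cluster with the largest centroid — the premise being that tumor
tissue is hyperintense in the modalities modelled here. Ties resolve
toward the brighter cluster. A soft membership cutoff is available through
the state object but argmax is the default.

## Segmentation pipeline

Per tumorous slice, in order: percentile contrast stretch saturating the
lowest and highest 1% of pixels; FCM on the window-averaged (or single)
enhanced slice; brightest-cluster binarization; removal of connected
components below 256 px (8-connectivity; components of exactly 256 px
survive); morphological gap filling with a 2×2 square structuring element;
roundness scoring `4πA/P²` of each remaining component with the perimeter
taken from the traced outline; selection of the roundest object (ties:
larger area, then smaller centroid); seeded region growing from the
selected object.

Design notes:

- Gap filling defaults to closing (dilate–erode) because its purpose is to
  fill small gaps; the literal erode-then-dilate order is available as
  `fill_order="open"`. Closing is computed on a padded domain so the
  result matches the infinite-domain composition regardless of array
  borders.
- The 256 px area threshold is calibrated to 240×240 slices; the benchmark
  suite scales it by pixel count when slices are smaller
  (`256·HW/240²`).
- Region growing adds any 8-neighbor of the region whose intensity lies
  within `τ` of the running region mean, recomputing the mean each sweep.
  `τ` defaults to 0.15 × the intensity standard deviation inside the
  brain (non-background pixels of the enhanced slice); no published
  tolerance exists for this step.
- A slice on which no component survives yields an empty final mask, not
  an error. All intermediate masks are retained in the result object.

On non-tumorous slices, the roundest surviving object is still returned
whenever any component passes the area filter — white matter virtually
always does — so the segmentation stage alone does not detect absence of
tumor. Tumor-free slices are excluded by the stage-1 classifier; the
benchmark records the (near-zero) fraction of clean slices that come out
empty as an honest fixture rather than asserting otherwise.

## CNN architectures and training engine

Three fixed architectures for 30×30×1 grayscale inputs, with exact
parameter accounting (conv: `f·(k²·c_in+1)`; dense: `units·(in+1)`):

| model | layers | total parameters (2 classes) |
|---|---|---|
| 1 | conv 5×5×16, pool, dropout 0.2, pool, dense 256/64/out | 217,954 |
| 2 | conv 3×3×30, pool, conv 3×3×15, pool, dropout, dense 128/50/out | 80,165 |
| 3 | conv 3×3×30, pool, conv 3×3×60, dropout, conv 3×3×30, pool, dense 256/64/out | 241,624 |

Conventions required to reproduce the published shape chains: valid
padding, stride 1; 2×2 max-pooling with stride 2 and **ceiling** output on
odd extents (pad right/bottom), which is what turns 13×13 into 7×7 in
model 1; hidden dense layers ReLU; the output layer is softmax (a 2-unit
ReLU output cannot produce class probabilities, so the "ReLU" annotation
on the final layers of models 1–2 is implemented as softmax). Model 2's
published Dense-2 parameter cell (6,528) contradicts the layer's own
formula `50·128+50 = 6,450`; the build follows the closed form, hence the
total 80,165 rather than the published 80,243. Model 3 is published with
a 2-unit head; `num_classes` is a parameter (4 for the glioma task, which
adds 130 parameters: 241,754).

The training engine is a self-contained numpy implementation: im2col
convolution, ceiling max-pool with argmax bookkeeping, inverted dropout
(active only in training), softmax cross-entropy, Adam (`lr 1e-3`,
β₁ 0.9, β₂ 0.999). Gradients are verified against numerical
differentiation in the test suite. Defaults follow the study protocol:
batch 100 / 8 epochs for the binary stage, batch 200 / 8 epochs for the
multiclass stage. Dataset splits default to 60/20/20, configurable.

Inputs: the binary stage min-max normalizes the whole slice and bilinearly
resizes it to 30×30 (half-pixel-center sampling); the multiclass stage
crops the tumor bounding box, zeroes pixels outside the tumor mask, pads
to a centered square, then resizes the same way. How the original work
mapped 240×240 slices to 30×30 inputs is not stated; this policy is ours.

## Synthetic phantoms

Each phantom slice contains a skull-stripped brain ellipse (background
exactly zero, as in BraTS-style preprocessed data) with three tissue
bands — CSF 0.15, grey matter 0.45, white matter 0.65 — plus a low-order
polynomial bias field (amplitude 0.05) and additive Gaussian noise
(σ = 0.08 inside the brain, a white-matter SNR of ≈8), clipped to [0, 1].

The tumor is quasi-circular with concentric sub-compartments (necrotic
core 0.40, then non-enhancing 0.82, enhancing rim 0.95, edema halo 0.80;
radial extents 25/15/35/25% of the radius). Its center drifts linearly
across slices and its radius follows an ellipsoid-like profile
`r(t) = r₀·(1 − 0.2·cos²(πt))`, so the cross-section tapers smoothly
toward both ends of the tumorous slice range (adjacent-slice area changes
stay under 20%). Default geometry: 240×240×31 voxels, base radius 34 px,
tumor on slices 8–22. Generation is bit-reproducible for a fixed seed.

These conditions were chosen so the phantom expresses the premises the
method is built on: the tumor is hyperintense; its cross-section varies
smoothly, so 5-slice averaging helps; and part of the tumor (the
infiltrative edema fringe at 0.80) lies close to the white-matter/tumor
clustering boundary, which is exactly the inhomogeneity regime in which
single-slice FCM degrades and the neighboring window pays off. With all
compartments far from the boundary the single-slice baseline is nearly
perfect and the window buys nothing; the defaults deliberately sit in the
regime the method targets.

What the phantoms do **not** emulate: MR physics (k-space, relaxation,
partial-volume mixtures), anatomical variability, multi-modality
registration, non-elliptical tumors, and spatially correlated noise.
Passing benchmarks on phantoms therefore demonstrates algorithmic
correctness and the claimed relative ordering of the two FCM variants
under the stated conditions — not clinical performance.

## Benchmark suite and problem sizes

The default segmentation benchmark generates 20 seeded phantoms of
41×96×96 voxels with the tumor spanning roughly 60–75% of the slices.
The slice count is kept high while the in-plane size is reduced because
isotropic shrinking would over-represent tumor-end slices (whose 5-slice
windows reach past the tumor): in a 155-slice clinical volume such slices
are a small minority of tumorous slices. The smallest tumor cross-section
stays near 4% of the slice area; below roughly that fraction the fourth
FCM centroid can no longer anchor on the tumor intensity population
(measured empirically) and both variants degrade.

On this suite the neighboring pipeline reaches a mean Dice of ≈0.88
against the complete-tumor ground truth versus ≈0.78 for the
standard-FCM variant of the same pipeline; the binary CNN reaches 100% on
a separable bright-vs-dark patch set and the 4-class CNN ≈90% macro
accuracy on sub-compartment crops (values recomputed by
`scripts/acceptance.py`, not hard-coded).

## Known limitations

- FCM operates on intensity alone (1-D features); no spatial regularization
  beyond the inter-slice window.
- The roundness selector always returns an object when one survives the
  area filter, so stage 2 cannot by itself declare a slice tumor-free.
- The 4-class stage classifies one crop per tumor (dominant compartment),
  not per-pixel sub-compartment maps.
- The numpy training engine is single-threaded and intended for the small
  tabulated models, not general deep learning.
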