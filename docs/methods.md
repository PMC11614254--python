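# Methods

This note records the scientific and numerical choices behind `ctlabel`: the
models and conventions implemented, the parameters that matter, what the
phantom generator does and does not emulate, and the decisions taken where
the design was genuinely open.

## HU calibration and windowing

DICOM stored values are converted to Hounsfield units with the per-file
rescale slope and intercept *before* windowing; the window center (50 HU)
and width (400 HU) are only meaningful on the calibrated HU scale. The
window transform follows the DICOM linear VOI convention — the (w_c − 0.5)
and (w_l − 1) terms place the half-intensity point at the window center and
make the edges land at w_c − 0.5 ± (w_l − 1)/2 — so −150 HU maps to y_min
and 249 HU to y_max under the defaults. The result is rounded to the nearest
integer, half away from zero (the convention is unobservable except exactly
at .5 boundaries; it is fixed so the array path and the scalar oracle agree
bit-for-bit). Slices are stored as 16-bit grayscale PNG; masks as 8-bit
{0, 255} PNG — a reader encountering any other mask value fails loudly
rather than guessing a dialect. Slice files are named
`<patientID>_<index>.png` with 0-based, 4-digit zero-padded indices;
ordering follows the image position projected on the stack normal, with
instance number as fallback.

## Phantom generator

The generator emulates the structure of an abdominal CT dataset, not its
physics. Each scan is a body ellipse of soft tissue (default 55 HU) in air
(−1000 HU) with additive Gaussian noise (default SD 10 HU). The target is an
axis-rotated super-ellipse (exponent 2.5, elongated ≈2.5:1) at 90 HU on a
contiguous central half of the slices, its cross-sectional area tapering to
40% from head to tail — a crude pancreas head-body-tail profile. The
35 HU organ/background contrast with 10 HU noise mimics the regime where
neighbouring soft-tissue organs have similar attenuation; distractor blobs
within ±15 HU of the target force the model to learn shape and position, not
a threshold. Distractors are rejection-sampled so they never touch the
target mask, keeping ground truth unambiguous.

Per-scan seeds are spawned from the master seed via `SeedSequence`, and an
organ-absent fraction is assigned to evenly spaced scan indices, so datasets
are bit-reproducible. What the phantom does *not* model: reconstruction
kernels, beam hardening, partial-volume effects, anatomical variability,
pathology. Passing desk-scale tests therefore demonstrates that the
pipeline's plumbing, losses, metrics and training dynamics are correct — not
that the network reaches clinical accuracy on real CT.

## Network

The encoder is a basic-block residual network (depth 18 or 34; 34 is the
default) adapted to one input channel; the stem downsamples with a 7×7
stride-2 convolution followed by a 2×2 max-pool. The U-Net decoder
upsamples ×2 five times (nearest neighbour), concatenating the encoder
feature of matching resolution, with two conv-BN-ReLU blocks per stage and
decoder widths (256, 128, 64, 32, 16). The FPN decoder projects the 1/4…1/32
features to a shared pyramid width (256), merges them top-down by addition,
applies a 3×3 head per level, sums at 1/4 scale and upsamples to full
resolution. `width_multiplier` scales every channel count, so desk-scale
tests train the same architecture at 1/4 or 1/8 width. Inputs must be
divisible by 32 (five downsamplings); the network is fully convolutional, so
training on 448×448 crops and predicting on full 512×512 slices needs no
resizing. Binarisation uses probability ≥ 0.5, boundary included.

Everything runs on `ctlabel.nn`, a reverse-mode autodiff engine over numpy
arrays written for this package: convolution is evaluated as kh·kw strided
BLAS contractions, batch normalisation uses the standard closed-form
backward, max-pooling records argmax indices for exact gradient routing.
The engine is gradient-checked against central finite differences in the
test suite. Weights are serialized as `.npz` with the architecture spec
embedded; loading into a mismatched architecture is an error, not a silent
reinterpretation.

## Training protocol

Full-scale defaults: Adam with lr 1e-4 and weight decay 1e-4 (L2 folded into
the gradient), batch 16, 50 epochs, learning rate ×0.1 after epochs 20, 30
and 40 (`lr_at_epoch(e) = lr0 · 0.1^(#milestones ≤ e)`), Focal Tversky loss
with α = 0.7, β = 0.3, γ = 0.75 and +1 smoothing. Soft (probabilistic)
confusion counts are used in the loss, pooled over the batch; hard integer
counts everywhere in evaluation. Final-epoch weights are kept; there is no
early stopping or best-epoch selection. Cross-validation folds are patient
partitions from scikit-learn's GroupKFold with seeded shuffling, applied
after a 20% patient-level hold-out; merged multi-source datasets prefix
patient keys with their source so grouping survives concatenation.

One widely reproduced statement of the Focal Tversky formula reads TI^γ,
which is maximal for perfect predictions and cannot serve as a loss; the
package implements (1 − TI)^γ as in the originating literature and exposes
the other form behind `form="printed"` for comparison.

**Augmentation interpretation.** The augmentation table this protocol
follows leaves some units ambiguous; the package fixes them as: rotation
±5 degrees (±5 radians would be ±286°, incompatible with anatomical
augmentation practice); flips have probability 0.5 and no parameters;
[0.5, 1.8] is the gamma-correction range; [30, 100] are brightness/contrast
deltas on the 8-bit intensity scale (divided by 255 for normalised images);
salt-and-pepper replaces a 0.1 fraction of pixels; Gaussian noise SD is 0.5%
of the dynamic range; cutout zeroes a square covering 20% of the image area
(image only — masking the label under a cutout would teach hallucination).
Geometric transforms are composed into one affine map applied bilinearly to
the image and nearest-neighbour to the mask; the output size always equals
the crop size (centre crop when the random crop does not fire). All ranges
are config fields and can be overridden.

**Desk-scale configuration.** CI and the acceptance script train a
width-0.25, depth-34 model on 64×64 phantom slices for 30 epochs with
batch 4 and lr 1e-3, milestones (15, 22, 27). The smaller batch and larger
rate are the one-time desk-scale adaptation: 30 epochs over 32 slices is
only 240 optimiser steps, where the full-scale lr 1e-4/batch 16 settings
have barely left initialisation. The capacity check trains on organ-bearing
slices only (as in the retraining stage, which filters empty slices); the
evaluation model trains on all slices including organ-absent scans (as in
initial training), which is what teaches the network to stay silent on empty
slices.

## Evaluation conventions

Scan-level metrics pool pixel counts over the whole volume and compute
DSC/recall/precision once per scan (a per-slice mode exists behind a flag);
dataset summaries are mean ± sample SD (n−1), with SD defined as 0 for a
single scan. Degenerate cases, where the ratios are 0/0: two empty masks
have DSC 1.0, and an empty prediction has precision 1.0. Slice-level
detection: ground truth present and any overlap → TP; present and no
overlap → FN (including the nonempty-but-disjoint case — the miss dominates,
and the slice is not double-counted as FP); absent with nonempty
prediction → FP; both empty → TN. Detection ratios with a zero denominator
are reported as missing, never as 0.

## Annotation sessions

Event times are supplied by the caller (from logs or an external clock),
never measured inside the library, so session summaries are deterministic
and replayable. The exported JSON log (proposals plus the ordered event
list, masks run-length encoded) is the source of truth: importing replays
every event, reproducing final masks bit-exactly. Summary ratio fields
(time per slice, averages per scan) are always derived from the stored
totals — recorded per-scan averages in a log are never trusted over its own
totals, a rule adopted after observing published tables whose printed
averages disagree with their printed totals. Reported ratios round to one
decimal, half away from zero.

"Accepted without revision" is counted per slice: an accept event not
followed by region edits on that slice, divided by the number of slices that
received at least one review event (reviewed slices are the ones with organ
activity; untouched slices carry no information about revision effort).
Speed-up between an assisted and a manual session is the ratio of their
per-slice times. Across several datasets the pooled ratio (totals summed
first) and the mean of per-dataset ratios genuinely differ — for the worked
totals in the tests they are ≈3.15 and ≈3.49 — so the report prints both
rather than privileging either aggregation.

## Known limitations

- The autodiff engine is single-threaded numpy; full-scale 512×512 training
  at width 1.0 is possible but slow — the package's reproducible runs are
  desk-scale by design, and the full-scale protocol is expressed in the
  defaults rather than exercised in CI.
- Pretrained encoder weights are an off-by-default hook (`pretrained=True`
  requires externally supplied weights via `load_weights`); no download is
  performed, and transfer-learning effects are therefore not reproduced.
- The phantom's simplicity means desk-scale accuracy numbers (e.g. holdout
  DSC ≈ 0.66 from the acceptance script's evaluation run) characterise the
  pipeline, not clinical performance.
- Multi-frame DICOM, non-axial reformats and DICOM-SEG export are out of
  scope; phase filtering is a manifest tag only.
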