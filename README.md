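# ctlabel

Headless toolkit for deep-learning-assisted annotation of organs in abdominal
CT, with the pancreas as the working example. It covers the full workflow a
research group needs to bootstrap a segmentation dataset: converting DICOM CT
series into a windowed PNG slice store, training a convolutional
encoder–decoder to segment the organ, evaluating segmentation and slice-level
detection quality, and running model-assisted annotation sessions whose
timing and revision statistics quantify how much reviewer time the model
saves. A deterministic phantom generator produces CT-like volumes with
pancreas-like ground truth, so every stage is testable without patient data.

## Who it is for

Medical-imaging researchers who need labelled CT volumes faster than fully
manual contouring allows: the segmentation model proposes a mask for every
axial slice, a reviewer accepts or corrects each proposal, and the corrected
dataset feeds the next training round. All components are importable library
functions; a thin `ctlabel` command-line interface wraps them for shell use.

## The model and the mathematics

**Windowing.** CT intensities are calibrated Hounsfield units (HU). A window
with center w_c and width w_l is mapped linearly onto the integer output
range [y_min, y_max]:

    y = ((x − (w_c − 0.5)) / (w_l − 1) + 0.5) · (y_max − y_min) + y_min

with values outside the window clamped. Defaults: w_c = 50 HU,
w_l = 400 HU, 16-bit output (0–65535) — the soft-tissue window in which
abdominal organs are best separated.

**Segmentation network.** A residual encoder (34-layer basic-block variant by
default) feeds either a U-Net decoder (skip concatenation at every
resolution) or a Feature Pyramid Network decoder. The network maps a
single-channel slice to a per-pixel foreground probability via a sigmoid; a
pixel is foreground when its probability is ≥ 0.5. The implementation runs on
a small numpy reverse-mode autodiff engine included in the package
(`ctlabel.nn`), so no GPU or deep-learning framework is required.

**Loss.** Training minimises the Focal Tversky loss. With soft counts
TP = Σ p·t, FP = Σ p·(1−t), FN = Σ (1−p)·t over a batch,

    TI = (TP + 1) / (TP + α·FP + β·FN + 1),   loss = (1 − TI)^γ

with α = 0.7, β = 0.3, γ = 0.75 — an asymmetric generalisation of the Dice
loss suited to small structures.

**Protocol.** Adam (lr 1e-4, weight decay 1e-4), batch 16, 50 epochs, learning
rate ×0.1 after epochs 20/30/40; a 20% patient-level hold-out and 5-fold
patient-grouped cross-validation so no patient's slices straddle train and
validation; the training-table augmentations (±5° rotation, 0.6–1.4 scaling,
±80 px translation, 448×448 random crop, flips, gamma, brightness/contrast,
salt-and-pepper and Gaussian noise, Gaussian/median blur, cutout — each with
probability 0.5). Every field is overridable for desk-scale runs.

**Evaluation.** DSC = 2TP/(2TP+FP+FN), recall and precision, pooled per scan
volume and summarised as mean ± sample SD; slice-level detection
(TP when prediction and ground truth overlap anywhere on a slice) summarised
by accuracy, specificity, sensitivity, PPV and NPV.

## Worked example

```python
import numpy as np
from ctlabel import (PhantomConfig, generate_dataset, ModelSpec, build_model,
                     TrainConfig, train, merge_datasets, filter_empty_slices)

manifests = generate_dataset(4, PhantomConfig(n_slices=16, size=64),
                             seed=42, out_dir="scratch/store")
records = filter_empty_slices(merge_datasets(manifests))[:32]
model = build_model(ModelSpec(width_multiplier=0.25), seed=7)
cfg = TrainConfig(epochs=30, batch_size=4, lr0=1e-3,
                  milestones=(15, 22, 27), seed=7)
model, history = train(model, records, cfg)
print(f"final training DSC {history[-1]['train_dsc']:.3f}")
```

prints (about a minute on one CPU core):

```
final training DSC 0.880
```

i.e. a width-0.25 variant of the network fits 32 organ-bearing phantom
slices to a Dice overlap of 0.88 in 30 epochs — the overfit-capacity check
that the architecture, loss and optimiser plumbing learn at all.

Session accounting works directly from logged totals. For one dataset a
reviewer annotated 1313 slices across 32 scans in 3223 s with model
assistance, and 926 slices across 32 scans in 8486 s manually:

```python
from ctlabel import SessionSummary, compare_sessions
assisted = SessionSummary(n_scans=32, total_time_s=3223, total_slices=1313)
manual = SessionSummary(n_scans=32, total_time_s=8486, total_slices=926)
print(assisted.rounded()["time_per_slice_s"],
      manual.rounded()["time_per_slice_s"])
print(round(compare_sessions(assisted, manual)["speedup_per_slice"], 2))
```

```
2.5 9.2
3.73
```

— 2.5 s per slice with assistance versus 9.2 s manually, a 3.73× per-slice
speed-up on this dataset.

## Command-line interface

```
ctlabel convert  --in <dicom_dir> --out <dir> --center 50 --width 400 --bits 16
ctlabel phantom  --scans 4 --size 64 --seed 0 --out <dir>
ctlabel train    --config train.yaml --data <store> --out <run_dir>
ctlabel predict  --model <weights.npz> --in <scan_dir> --out <mask_dir>
ctlabel evaluate --pred <mask_dir> --gt <store> --per volume --out metrics.csv
ctlabel annotate --model <weights.npz> --scan <scan_dir> --out session.json
ctlabel report   --sessions assisted.json manual.json --out report.csv
```
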