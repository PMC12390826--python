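# Methods

This note records the model as implemented, the conventions chosen where
the architecture family admits more than one reading, the synthetic data
the tests run on, and what passing those tests does and does not show.

## Model

**Backbone (`resnet18*`).** Stem = Conv(7×7) → BatchNorm → ReLU →
MaxPool(3×3, stride 2, padding 1). Two stem geometries are provided:

* `standard` (default): stride 2, padding 3 — the usual ResNet18 stem, so
  a 256×256 single-channel input yields a 64×64×64 map;
* `literal`: stride 1, no padding (7×7 on 256×256 gives a 250×250 pre-pool
  map). This variant exists because the stem is sometimes described this
  way for this architecture family; it is not the default because the rest
  of the network is explicitly ResNet18-shaped and the downstream feature
  sizes only work out with the strided stem.

Four stages of two residual units with 64/128/256/512 channels follow.
Stage entry (stages 2–4) downsamples with a stride-2 first convolution and
a 1×1 stride-2 projection shortcut. All residual 3×3 convolutions use
padding 1 — the additive skip forces shape preservation, so a "no padding"
residual conv is not realisable. The residual unit applies its second ReLU
*before* the addition (`y = (ReLU(BN(Conv(·))))² + x`); a
`preadd_relu=False` flag restores the canonical post-addition ReLU. The
head is global average pooling → affine map to 2 classes → LogSoftmax,
computed stably by max subtraction.

**CAAFE block.** Inserted after the second residual unit of a stage (all
four stages in the `full` variant), preserving shape exactly. Three
parallel serial branches of 3×3 convolutions with dilation schedules
(1,1), (1,2,3) and (1,3,5); every dilated conv uses padding = dilation so
the intermediate maps stay aligned for channel concatenation. Each branch
concatenates its intermediate outputs (arity 2, 3, 3), fuses back to C
channels with a 1×1 convolution and batch-normalises. All 3×3 branch
convs preserve the channel count C: the final elementwise sum
F₁+F₂+F₃+F₄ requires every term to share the input's shape, and keeping C
fixed is the minimal convention that guarantees it. Receptive fields of
the three branches are 1 + Σ2dᵢ = 5, 13, 19 pixels; the test suite
verifies this with an impulse probe and a gradient probe.

Two deliberately configurable points:

* *Inter-conv ReLU* (default on). The branch equations compose bare
  convolutions, which would collapse each serial path into a single linear
  map; a ReLU after each 3×3 conv preserves the intended multiscale
  nonlinearity. `inter_conv_activation=False` gives the literal linear
  composition, which is also what the receptive-field probes use.
* *Branch-1 arity* (default 2). The first branch concatenates the outputs
  of its two convolutions; `branch1_include_input=True` additionally
  prepends the branch input, for the reading in which branch 1 integrates
  initial, transitional and final features. The default follows the
  narrower formula; the switch exists because the two readings disagree
  and the choice is not decidable from the architecture alone.

**Channel attention (CAM).** Global-average and global-max channel
descriptors pass through one shared two-layer bottleneck
(C → max(1, C/16) → C, ReLU between, biases zero-initialised), are summed
and logistic-squashed, giving per-channel gates strictly inside (0,1)
(exactly 0.5 for a zeroed bottleneck). Only channel attention is used
inside CAAFE — no spatial branch. The SE baseline uses the average
descriptor only; the CBAM baseline adds a 7×7 spatial-attention gate after
the channel gate. Both are placed at the same four insertion points as
CAAFE so ablation comparisons are architecture-controlled. If the
reduction ratio exceeds the channel count the bottleneck clamps to width 1
and warns.

No activation follows the block's four-term sum; the next stage's
convolution acts on it directly.

**Numerics.** The numpy engine stores float32 parameters initialised with
fan-in He-normal draws from a generator seeded per model build, so a seed
fully determines initialisation and inference outputs. Batch norm uses
eps 1e-5, momentum 0.1 and running statistics in inference mode.
Convolution is evaluated as an im2col matrix product; the backward pass is
its exact adjoint (verified against central finite differences at 1e-5).
Checkpoints are `.npz` files with a version field; attention-block keys
are ignored when loaded into a plain backbone, which is what makes the
reduction identity testable with shared weights.

## Training and evaluation

Defaults follow the study recipe: SGD with learning rate 0.001, weight
decay 1e-5, momentum 0.7, batch size 16, cross-entropy over the LogSoftmax
output, up to 40 epochs, augmentation on the training split only. The
checkpoint with the best validation accuracy is retained (the selection
rule had to be fixed somewhere; best-val-accuracy is the conventional
choice). Augmentation: rotation uniform in ±15°, horizontal flip p=0.5,
brightness/contrast jitter factor 0.2, hue ±0.05 — magnitudes are
conventional defaults, configurable; saturation and hue draws are made for
reproducibility but act as identities on single-channel images.

Metrics are accuracy, precision, recall and F1 (harmonic mean of precision
and recall) as percentages, from exact confusion counts; zero-denominator
cases return 0 with a `degenerate` flag. The positive class is the
majority (poor-prognosis) class — with that convention an all-positive
classifier shows recall 100% and precision = accuracy = test prevalence,
the structural pattern degenerate models produce on imbalanced cohorts.
AUC uses the Mann–Whitney rank statistic with average ranks on ties,
which equals trapezoidal ROC integration; it is undefined (raises) on
single-class label sets. The ablation harness trains any subset of
{`resnet18*`, `+B1`, `+B1B2`, `+B1B2B3`, `full`, `se`, `cbam`} on shared
seeded splits and tabulates the metric columns; cumulative variants have
strictly increasing parameter counts (11.17M → 11.50M → 12.81M → 18.07M →
39.07M).

## Data handling

Volumes are sliced along the first voxel axis (configurable, since stored
orientation varies); each slice is resized to the square target with
bilinear interpolation, then min–max scaled to [0,1] — scaling after
resizing so a non-constant slice always spans the full 16-bit PNG range.
All-zero slices are dropped and logged (disableable). Splits are
patient-grouped by default: fractions 70/10/20 apportioned over patients
by largest remainder under a seeded shuffle, so no patient's slices cross
a split boundary; a slice-level split is available. DICOM series with
gaps in instance numbers are rejected with the missing instances listed
rather than silently stacked.

## Synthetic data

The generator emulates the *structure* of the task, not MRI appearance:
grayscale square slices (side 64 in tests, 256 for demos), per-patient
volumes, class imbalance 407/1477 ≈ 0.2755 favourable. Class 0 is a
smooth low-contrast field (broad Gaussian bump, amplitude 0.08, on a
correlated background); class 1 adds an irregular bright blob (wobbly-edge
disc, radius 0.2 × side, intensity 0.9) carrying fine-scale texture
(σ = 1 px) inside it, plus pixel noise (sd 0.05) for both classes. The
two texture scales exist specifically so the dilated branches have signal
at more than one receptive field. Default cohort: 24 patients × 8 slices
= 192 slices, a deliberate desk-scale size that keeps a full training run
around half a minute per fit on one core. Everything derives from
`SeedSequence([seed, patient_index])`, so artifacts are byte-identical
across runs.

By construction the class mean-intensity gap exceeds three within-class
standard deviations, so the set is learnable: the full model reaches ≥90%
(in practice 100%) validation accuracy within a few epochs. Passing this
shows the forward/backward passes, optimiser, splits and metrics work end
to end; it says nothing about accuracy on real MRI, where the
discriminative signal is far subtler and the published cohort is private.

## Known limitations

* CPU-only and unbatched in the library sense: the numpy engine is exact
  but slow compared to GPU frameworks; realistic 256×256 training is
  possible but lengthy.
* Binary classification only; multi-class would need only a wider head
  but is untested.
* No tumour-region annotations, registration or bias-field correction are
  consumed; slices inherit the patient label wholesale.
* Slice-level metrics are the default report; patient-level aggregation
  (majority vote over a patient's slices) is easy to compute from the
  manifest but is not a separate tested code path.
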