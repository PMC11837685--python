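# Methods

This note documents the modelling assumptions, parameter choices and
known limitations of the `swayclass` pipeline. Empirical figures quoted
here are the ones the test suite and `scripts/acceptance.py` compute.

## The analysis pipeline

The pipeline classifies quiet-stance body sway as PD-like vs
healthy-control-like from the time–frequency content of four signals:
the anterior–posterior (a–p) and medio-lateral (m-l) displacement of
the center of pressure (COP) and of the center of mass (COM). Each
(parameter, direction) arm is analysed independently.

### Kinematics

- **COP** from four balance-board corner loads by moment balance (see
  README for the formula). Axis conventions are fixed by the package —
  m-l positive right, a–p positive forward, corners ordered top-left,
  top-right, bottom-left, bottom-right — because consumer devices do
  not document theirs. COP is guaranteed to lie inside the sensor
  rectangle for any nonnegative loads; a zero total load raises.
- **COM** from 25-joint skeleton tracking via a bundled Winter-style
  anthropometric table (`swayclass/data/segment_model.yaml`): eleven
  segments (merged trunk+head, and per side upper arm, forearm+hand,
  thigh, shank, foot) with mass fractions summing to 1 and
  segment-center fractions along the proximal→distal axis. Which of the
  25 tracked joints delimit the "relevant" segments is a package
  decision, not a device constraint; the table is a data file, editable
  without touching code.
- **Tracking gaps**: per joint coordinate, NaN runs ≤ 0.5 s are filled
  by linear interpolation; longer runs leave frames invalid. Trials
  whose valid-frame fraction falls below 0.9 are discarded and logged.

### Time–frequency representation

- Detrend = mean subtraction only (no slope removal).
- Resampling to 50 Hz with a Gaussian moving-average kernel,
  σ = 1/60 s, evaluated over a symmetric ±5σ window with normalized
  weights. The closed-form transfer `exp(-2π²f²σ²)` attenuates 0.5 Hz
  by ~0.14 % and 10 Hz by ~10 %; tests check the measured response
  against this formula.
- Continuous wavelet transform with generalized Morse wavelets,
  shape γ = 3 and order β = 20 (time-bandwidth product βγ = 60 — β is a
  free choice here, configurable, with the common default for γ = 3
  analytic analysis), unit-peak ("bandpass") normalization, analytic
  (positive frequencies only), computed by FFT with full reflection
  padding on both sides. The cone of influence is not masked.
- Frequency grid: 250 bands descending geometrically from 15 Hz at
  2^(-1/36) per band (36 voices per octave). The 250th band lands at
  ≈ 0.124 Hz; a grid spanning exactly [0.12, 15] Hz would need ~251
  bands, so the band count wins over the printed lower edge.
- Energy = |W|² (squared magnitude). Configurable to |W| since the
  choice is not dictated by the representation itself; all tests use
  the default.
- A 30 s trial yields a 250 × 1500 matrix cut into six contiguous
  250 × 250 samples; segmentation refuses non-divisible lengths rather
  than silently truncating. Pixels stay full-precision floats end to
  end; 8-bit grayscale appears only in optional PNG export.

### Dataset protocol

- Balancing: the larger group is subsampled to the smaller group's size
  (15 per group in the full design), freshly per replicate.
- Subject-wise split: 11 train / 4 validation subjects per group in the
  full design; all samples of a subject land on one side, and an
  automated audit asserts disjointness in every replicate. Subjects
  with fewer than 60 samples (trial dropout) are kept; the 660/240
  sample counts hold only for complete subjects and are asserted only
  there.
- Normalization: one global scalar mean/sd over all training pixels,
  applied unchanged to validation. Degenerate (constant) training
  pixels raise.
- Shuffled-label null: labels are permuted **per sample** (not per
  subject), deliberately breaking the label–subject association; the
  split still uses the true subject→group structure, mirroring a
  protocol in which participants, not labels, are re-assigned. This is
  a leakage-prone but faithful design choice; chance-level performance
  of this arm is exactly the point of the null.

### Classifier and training

The network is three convolution (+ReLU) + max-pool stages and three
dense layers ending in two class scores, trained **full batch** — the
entire training tensor in one Adam step per epoch — with cross-entropy
loss, coupled L2 weight decay (added to the raw gradient, the classical
Adam formulation), learning rate 1e-4, weight decay 1e-3, 1000 epochs
in the full design. Softmax of the scores gives the PD probability
used for ROC/PR analysis; argmax gives the decision.

The engine is pure numpy (float32, NHWC, im2col + BLAS matmuls, exact
gradients verified against central differences in the test suite), so a
(data, config, seed) triple reproduces the training trajectory
bitwise on one machine. Because training is full-batch on a constant
tensor, the first layer's im2col expansion is computed once per run and
reused every epoch. The recorded curve stores per epoch the training
loss/accuracy of the gradient-producing forward pass and the validation
loss/accuracy after the step, so its last row scores the returned
parameters.

Free architecture parameters (the protocol fixes only the 3/3/3
structure) default to 3×3 kernels, stride 1, 2×2 pools, channels
(8, 16, 32) and dense widths (128, 32, 2) — the smallest plausible net
for 250 × 250 inputs.

### The reduced benchmark preset

Replicate studies at the full design (250 replicates × 1000 epochs) are
a GPU-scale workload. `ModelConfig.reduced_benchmark()` plus
`ProtocolConfig.reduced()` define the package's desk-scale preset, used
by the acceptance benchmark and sized for single-CPU runs:

- 10 replicates, 200 epochs, 8 subjects per group split 6/2;
- channels (4, 8, 16); a 10 × 10 patch-embedding first convolution
  (kernel 10, stride 10) followed by two 3 × 3 stride-1 convolutions;
- max pooling along the **time axis only** — (1,4), (1,2), (1,2) — so
  the feature extractor keeps its 26-band frequency resolution through
  the last convolutional layer. This matters for attribution: Grad-CAM
  inherits the last conv layer's spatial grid, and with square pools
  that grid has too few frequency rows to resolve a 1 Hz boundary.
  Pooling time only is cheap in information terms because the class
  signal is stationary over a 5 s segment by construction;
- dense widths (64, 32, 2); learning rate 5e-4, scaled up because the
  epoch budget is 5× shorter than the full design's (lr × epochs
  roughly conserved); weight decay unchanged at 1e-3.

On the synthetic benchmark (below) this preset reaches ~99 % mean
subject-wise validation accuracy in ~40 s per replicate on one CPU.

### Evaluation and the null comparison

Per replicate: accuracy, sensitivity, specificity, precision, F1 (PD
positive), ROC AUC and PR AUC (threshold sweep over the PD
probability; trapezoidal ROC integration, step-interpolated PR via the
average-precision formulation). Undefined values — precision with no
positive calls, AUCs on a single-class validation set — are reported
as NaN, excluded from means, and counted in the report. Arms are
compared with Welch's unequal-variance t-test on final validation
accuracies at α = 0.05.

### Grad-CAM attribution

Hooked at the last convolutional layer (post-ReLU activations, before
the final pool): channel weights are the spatial means of the
target-class logit gradients; the rectified weighted activation sum is
bilinearly upsampled to 250 × 250. Samples are grouped by *decoded*
(predicted) class and averaged unnormalized; per-map unit-max
normalization is applied only for PNG visualization. The summary
statistic is the fraction of heatmap mass at frequency rows above 1 Hz.
A class with no decoded samples yields an empty, flagged map; all-zero
gradients yield an all-zero, flagged map.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not balance physiology:

- **Baseline**: per-channel colored Gaussian noise with PSD ∝ 1/f^1.5
  and 5 mm RMS, synthesized exactly in the frequency domain —
  plausible stabilogram magnitudes and spectral slope for quiet stance.
- **Class signal**: the PD-like group's PSD is multiplied by
  `band_gain` (default 4) inside [1, 10] Hz, placing the
  discriminative structure above 1 Hz. Because the gain enters the
  spectrum directly, Welch estimation recovers it as the in-band power
  ratio (tested at n = 200 trials).
- **Per-subject random effects**: the band gain is jittered by a
  log-normal factor (σ = 0.15) per subject, so subject-wise splits are
  genuinely harder than sample-wise ones.
- **Trial dropout**: Bernoulli per trial, 10 % (PD) / 3 % (HC),
  emulating tracking loss; logged, and reproducing the binomial rate
  over many subjects.
- **Raw representations**: board loads by bilinear weight distribution
  plus a COP-preserving "twist" noise mode (round trip through the COP
  formula exact to machine precision); skeletons by height-proportional
  inverted-pendulum displacement of a canonical 25-joint pose,
  normalized so the model-weighted COM reproduces the input exactly,
  plus 1 mm marker jitter.
- **Rates**: board 100 Hz, skeleton 30 Hz (typical device rates);
  the COP and COM trajectories of a trial are independent draws from
  the same class spec, not a coupled biomechanical pair.

What passing tests on this generator do **not** show: that the method
separates real PD from HC sway. Real stabilograms have nonstationary,
non-Gaussian structure, coupled COP/COM dynamics, intermittent
ballistic corrections, and unknown effect sizes; the synthetic effect
size is a free parameter, not an estimate of any recorded cohort. The
tests certify the machinery — shapes, contracts, leakage-freedom,
learning dynamics, null behaviour, attribution localization — under
known ground truth.

## Numerical choices and degenerate inputs

- All stochastic stages draw from `numpy.random.Generator` seeded via
  `SeedSequence`; the orchestrator derives per-stage substreams by
  hashing stage names, so adding a stage never perturbs earlier draws.
  Replicates spawn independent (split, model, shuffle) seed triples.
- Pooling crops trailing rows/columns when the extent does not divide
  the pool size; pool-gradient ties share the gradient (tied zeros are
  subsequently masked by ReLU).
- Non-finite training loss aborts with diagnostics rather than
  continuing silently.
- Replicate failures are recorded in the report (and fail the
  orchestrated pipeline loudly); they are never swallowed.
- `SpectrogramSample` accepts any 2-D nonnegative matrix so the tools
  compose at toy sizes; the 250 × 250 shape is asserted where the full
  pipeline guarantees it.

## The acceptance benchmark

`scripts/acceptance.py --seed S --out F` regenerates everything from
scratch: an 8 + 8-subject cohort (band gain 4), the m-l COP spectrogram
dataset, per-sample label shuffling, and 10 replicates × 200 epochs
under the 6/2 subject-wise protocol; it writes the mean final
validation accuracy of the shuffled arm in percent. With separable
data the same protocol reaches > 95 % accuracy (tested in
`tests/test_acceptance.py`); with shuffled labels it stays at chance
(~50 %), and Welch's test separates the arms decisively. Runtime is
~10 minutes on one CPU; the problem sizes (8 + 8 subjects, 10
replicates, 200 epochs) are the package's reduced study design.

## Known limitations

- No biomechanically faithful full-body dynamics, medication state,
  tremor, or clinical-score correlations in the generator.
- The full 250 × 1000 protocol is implemented but impractical without
  substantial CPU time; all shipped evidence uses the reduced preset.
- Grad-CAM resolution is bounded by the last conv layer's grid; the
  default full-design architecture (square pools) trades frequency
  resolution for capacity and its attribution is correspondingly
  coarser than the reduced preset's.
- The optional ingestion path for recorded data is the documented
  board/skeleton CSV layout; no device drivers or download adapters.
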