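# Methods

## Problem setting

Surface electromyography (sEMG) records the summed electrical activity of
muscle over the skin from `C` electrode channels. Gesture recognition
segments the stream into fixed-duration windows (250 ms, advanced every
50 ms), assigns each window a gesture class, and trains a classifier on the
windowed data. With large gesture vocabularies (up to 53 classes, rest
included), the temporal fine structure of the signal carries class
information that simple amplitude summaries do not.

## The concatenate-feature-fusion (CFF) strategy

Convolutional front ends reduce dimensionality either by max-pooling or by a
strided convolution. Each discards information in a characteristic way:

- **Max-pooling** `z_t = max(y_t, …, y_{t+s−1})` is featurewise and
  parameter-free: it is exactly invariant to any permutation of samples
  within a pooling window, so within-window temporal order is lost
  (`s − 1` samples discarded per step).
- **Strided convolution** `y_t = Σ_j c_j x_{s(t−1)+j}` mixes features and
  keeps context, but is non-injective: any kernel with ≥ 2 nonzero weights
  has a nontrivial null space, so distinct inputs collide onto identical
  outputs. With kernel `(−1, 1, 2)`, inputs `(1, 1, 1)` and `(3, 1, 2)`
  both map to 2.

The CFF block applies both reducers to the same map *in parallel* and
concatenates the results channelwise (pool channels first). Two inputs that
collide under one branch are distinguished by the other; the randomized
triple construction in the test suite confirms no joint collisions among
constructed cases. A stack of `n` 1-stride kernel-`k` convolutions has
receptive field `n(k−1)+1`, verified against brute-force sensitivity
counting for `n ≤ 4, k ≤ 5`.

## Architectures

Both classifiers are time-distributed CNNs over frame sequences feeding a
single-layer LSTM:

| RCNN | CFF-RCNN |
|---|---|
| Conv 64, k=3, BN, ReLU | Conv 64, k=3, BN, ReLU |
| MaxPool 2 | **MaxPool 2 ∥ Conv 64 k=3 s=2 → concat (128 ch)** |
| Conv 64, k=3, BN, ReLU | Conv 64, k=3, BN, ReLU |
| MaxPool 2 | MaxPool 2 |
| Flatten, FC 512, FC 512, FC 128 | Flatten, FC 512, FC 512, FC 128 |
| LSTM 512, dropout 0.5 | LSTM 512, dropout 0.5 |
| FC G, softmax | FC G, softmax |

The parameter difference between the variants is exactly the stride-2 conv
branch plus the widening of the second conv from 64 to 128 input channels
(asserted in the tests). Batch normalization covers the 1-stride
convolutions only; the stride-2 branch is left un-normalized by default
(configurable), and the second max-pool stays a plain pool in both variants.

**Branch shape matching.** Concatenation requires both branches to emit the
same spatial extent. The stride-2 conv uses same padding (`ceil(L/2)`
outputs); the pool runs in *ceil mode* — the final window at an odd edge is
truncated rather than dropped — so both branches always emit `ceil(L/2)`.
Plain edge-truncating pooling would emit `floor(L/2)` and the block could
not be built on odd extents.

**Sequences.** The architecture is defined over frame sequences
`X = {X_1 … X_T}`; `T` is a free parameter (`seq_len`, default 1, i.e. each
window classified independently with the LSTM acting as a gated
transformation). The CNN applies identically to each frame.

## Training

SGD with momentum 0.95, learning rate 0.002, weight decay 0.0005, minibatch
20. The loss is the cross-entropy form `−[y log ŷ + (1−y) log(1−ŷ)]`
applied elementwise to the softmax output and summed over classes (the
binary-cross-entropy-with-softmax idiom); standard categorical cross-entropy
is available via `TrainConfig.loss="categorical"`. Labels are one-hot
encoded; frames are z-scored per channel with statistics estimated on the
training split only (optionally followed by min–max rescaling to the
training range). Weight initialization is fan-based (He for conv/dense,
Glorot for the LSTM, forget-gate bias 1) from the experiment seed; identical
seeds reproduce identical histories on one device.

The engine behind these models is a compact numpy implementation with
hand-written backward passes for every layer, verified against central
finite differences (relative error ≲ 1e−5) in the test suite.

## Windowing and frames

`N = round(window_ms · fs / 1000)` samples per window (500 at 2 kHz, 25 at
100 Hz), hop `N − round(overlap_ms · fs / 1000)` (100 and 5 respectively) —
integer sample arithmetic, no drift. Each `N × C` window is reshaped to a
`(W, H, C_out)` frame. Two fixed bijections are provided: channel-preserving
(`frame[w,h,c] = window[w·H+h, c]`, e.g. `(5, 100, 12)` for 500 × 12) and
channel-folding (time-major flatten, channel fastest, refolded row-major,
e.g. `(5, 25, 2)` for 25 × 10); both round-trip bit-exactly. A window takes
the majority per-sample label (ties toward the smaller id; configurable
purity threshold for dropping mixed windows). Rest (label 0) is a class by
default and can be excluded.

## Classic features and baselines

Hudgins-style per-channel definitions over each window: MAV `(1/N)Σ|x_t|`;
WL `Σ|x_t − x_{t−1}|`; ZC counts sign changes with jump ≥ threshold; SSC
counts interior points with `(x_t − x_{t−1})(x_t − x_{t+1}) > 0` and above
threshold. Thresholds default to 0. Baselines: PCA→KNN, LDA→KNN (k = 5,
Euclidean; components default `min(4C, 20)` and `G − 1`), and a 100-200-160
fully connected net with ReLU, dropout 0.5, softmax, the same SGDM optimizer
family, batch 32. Projections are fitted on training folds only.

## Synthetic data

sEMG during contraction is modeled as amplitude-modulated Gaussian noise —
a standard surrogate: for class `g`, channel `c`, the movement-block signal
is `env_{g,c}(t)·n₁(t) + σ_bg·n₂(t)` with iid standard normal noise, and
rest blocks are pure background noise with
`σ_bg = RMS(env) · 10^(−SNR_dB/20)`. Envelope shapes: flat, ramp_up,
ramp_down (the exact time-reverse of ramp_up), burst. Recordings follow the
repetition protocol of the public sEMG benchmarks: per gesture, `reps`
movement blocks separated by rest, with per-sample labels and repetition
counters, exportable in the same `.mat` field layout the reader consumes.

Defaults — the study conditions for all in-package experiments — are G=6,
C=4, fs=200 Hz, 6 repetitions, 1 s movements, 0.5 s rests, SNR 20 dB:
small enough that a full segment→train→compare cycle runs in minutes on one
CPU. Default class envelopes are flat with a distinct pair of strong
channels per class (cycling over channel pairs), making classes separable
by amplitude features alone, as real distinct gestures typically are.

**The order-confusable pair** is the targeted stress case: class A ramps up
(0.2 → 1 × peak over the block), class B is its exact mirror, identical
peaks on all channels. Every window of one class has a mirrored window of
the other with identical sorted amplitude content; only temporal order
differs. Consequently window-max and MAV statistics are distributionally
identical across classes (amplitude-only classifiers sit at chance), while
within-window envelope slope remains learnable by temporal models.

What this generator does *not* emulate: motor-unit action-potential trains,
recruitment/firing-rate structure, electrode lift-off, power-line
interference, fatigue drift, inter-session electrode shift. Passing tests
demonstrate the pipeline's mechanics and the order-information argument,
not benchmark-level accuracy on real recordings.

## The directional comparison experiment

`run_confusable_comparison` trains both variants on the confusable pair for
5 seeds at 20 epochs each and records final validation accuracy, plus an
amplitude-only control (per-channel MAV + LDA/KNN on the same split).

Validation is **repetition-disjoint** by design: consecutive windows overlap
by 80 %, so a window-level random split places near-duplicates of validation
windows in the training set; both models then saturate and the comparison
measures optimizer noise. Holding out whole repetitions measures
generalization to unseen executions — the regime where the temporal
information preserved by the fusion block matters. (The window-level random
split remains the `TrainConfig` default for general use, with the
repetition split recommended for honest evaluation.)

Problem sizes used by the default suite and the acceptance script: 192
movement windows per recording (2 classes × 6 reps × 16 windows), frames
(5, 10, 4), full-size models (64 filters, FC 512/512/128, LSTM 512,
~2 M parameters), 20 epochs, 5 seeds.

## Statistics

Paired model accuracies are compared with the Wilcoxon matched-pairs
signed-ranks test, two-sided, α = 0.05. Zero differences are dropped, tied
magnitudes take midranks, and for ≤ 25 nonzero pairs the p-value is exact:
the null distribution of the positive-rank sum is built by dynamic
programming over all sign assignments (midranks doubled to integers). The
test suite checks it against brute-force 2ⁿ enumeration for n ≤ 12 and
against `scipy.stats.wilcoxon` in the tie-free case. Beyond 25 pairs a
tie-corrected normal approximation is used. All differences zero is
reported as degenerate with p = 1, never significant.

Epochs-to-threshold tables report the first epoch whose validation accuracy
reaches a threshold (sentinel "not reached"); wall-clock columns are
recorded for information but never asserted — they are hardware-dependent.

## Known limitations

- The LSTM default `seq_len = 1` exercises the architecture but not long
  recurrences; multi-step sequences are supported and gradient-checked.
- The numpy engine is single-threaded per op and intended for the package's
  experiment scale, not for benchmark-size training.
- The confusable-pair effect size at this scale is modest (a few
  percentage points of validation accuracy); the experiment is directional,
  not a magnitude estimate.
- Real-benchmark accuracies require the external databases and are out of
  scope; the `.mat` import path exists for users who have them.
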