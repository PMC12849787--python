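# Methods

## Problem and model

The package detects epileptic seizures in multi-channel scalp EEG recorded
in a bipolar montage. The classifier treats each 1-s window of the
recording as a *functional-connectivity graph* and a short run of
consecutive windows as a *temporal sequence*:

1. **Graph construction.** For a window with channels `x_1 .. x_M`, the
   pairwise Pearson matrix `r_ij = C(x_i, x_j) / (S(x_i) S(x_j))` is
   thresholded: channels i and j are connected iff `|r_ij| >= tau`
   (default `tau = 0.3`). Self-loops are always present, so every node has
   a non-empty neighborhood. The raw window samples are the node features.
2. **Spatial encoder.** Two multi-head graph-attention layers. A head with
   shared map `W` and attention vector `a` scores each edge
   `e_ij = LeakyReLU(a^T [W h_i || W h_j])` (slope 0.2), normalizes over
   the first-order neighborhood with a softmax, and aggregates
   `sum_j alpha_ij W h_j`. The Q = 8 heads are **averaged** (not
   concatenated) in both layers before the ELU nonlinearity; dropout sits
   between the layers.
3. **Temporal encoder.** Each of the N = 8 windows of a sample passes the
   (shared-weight) spatial encoder; the flattened maps are projected to
   width D, a learned class token is prepended, and a fixed sinusoidal
   positional table is added. L = 4 pre-norm residual blocks
   (`H' = MSA(LN(H)) + H`; `H_out = MLP(LN(H')) + H'`) feed a
   LayerNorm + linear + softmax head read off the class token.
4. **Loss.** Focal loss
   `FL = -alpha (1-p)^gamma log p` (y = 1) /
   `-(1-alpha) p^gamma log(1-p)` (y = 0) with `gamma = 2`,
   `alpha = 0.25`, optimized with Adam (lr 0.001, batch 64). Note that at
   `gamma = 0` this is the *alpha-weighted* cross-entropy; it coincides
   with CE/2 only at `alpha = 0.5`, which is exactly what the analytic
   tests assert.

### Numerical core

No GPU framework is used: the models run on a small reverse-mode
automatic-differentiation engine over float64 numpy arrays
(`seizformer.autodiff`), with exactly the operation set the two encoders
need. Gradient correctness is established by central-difference checks in
the test suite (relative tolerance 1e-4 to 1e-6 depending on the
composite), and both encoders are verified against independent loop-based
dense oracles to 1e-10. The GAT projection is deliberately computed as one
flat `(batch*M, F) x (F, Q*F')` GEMM; broadcasting the head axis through a
batched matmul is algebraically identical but materializes a
`(batch, Q, F, F')` gradient intermediate that dominates training time.

## Protocol

* **Windowing.** 1-s windows, overlap 0.5; `K = floor((T - w)/step) + 1`
  windows with the trailing remainder dropped (60 s -> 119 windows).
  Starts are computed in seconds and rounded to the nearest sample.
* **Labeling.** A window is ictal iff at least 50 % of its span lies inside
  an annotated seizure interval; a tie at exactly 50 % counts as seizure
  (sensitivity-favoring). Intervals are half-open `[start, end)` seconds.
* **Sequences.** N = 8 consecutive windows form one classification sample;
  its label is the majority of the window labels, ties toward seizure. The
  default stride is one window step; scaled-down runs use non-overlapping
  sequences (stride = N) to cut sample count, not model capacity.
* **Cross-validation.** Stratified ten-fold. The default fold scheme cuts
  each class's samples into *time-contiguous* blocks, so overlapping
  neighbors cannot straddle the train/test boundary; a `random` scheme
  (shuffle within class) is available for protocols that ignore leakage.
  Per fold: z-score statistics (per-channel mean/std, floor 1e-8) are
  fitted on the training samples only; the training minority class is
  oversampled with replacement to 1:1; the test fold is never oversampled
  or refitted.
* **Operating point.** Focal loss with `alpha != 0.5` re-weights the two
  classes, which systematically biases the fitted probabilities away from
  the 0.5 posterior cut (for `gamma = 0` the fitted optimum at true
  posterior q is `alpha q / (alpha q + (1-alpha)(1-q))`, so the
  accuracy-optimal decision sits at `p = alpha`, not 0.5). The default
  decision rule therefore selects the accuracy-maximizing threshold on
  each fold's *unbalanced training* scores (ties toward the lower,
  sensitivity-favoring cut) and applies it unchanged to the test fold;
  a fixed numeric threshold is available via `decision_threshold`.
  AUC is rank-based and unaffected.
* **Metrics.** Accuracy, sensitivity, specificity, harmonic-mean F1 and
  tie-corrected Mann-Whitney AUC per fold; aggregates are the mean and the
  population (÷k) standard deviation across folds. Zero-denominator
  metrics report 0.0 with a warning, never NaN.

## Synthetic subjects

The generator provides the study conditions for every test, since the
clinical corpora the method targets are access-restricted.

* **Background.** Each channel is
  `sqrt(rho) * L + sqrt(1 - rho) * n_i` where `L` and `n_i` are
  unit-variance 0.5–30 Hz band-limited noises; the expected pairwise
  Pearson correlation is then exactly `rho = base_coupling` (default 0.3).
  Channels are scaled to a 20 uV RMS.
* **Seizures.** Interval count is Poisson (`seizure_rate`, default 20 per
  3000-s record), lengths uniform in 40–110 s, placed with >= 10 s gaps;
  the defaults give an expected ictal burden of about half the record,
  mirroring a single-subject protocol that uses equal durations of ictal
  and interictal signal. If a drawn count cannot fit, it is truncated to
  the largest count that does (an error is raised only when not even one
  fits). Inside an interval the background is re-mixed toward
  `seizure_coupling` (default 0.8) variance-preservingly, and a coherent
  oscillation at `osc_freq_hz` (default 4 Hz, 10 % frequency jitter,
  half-amplitude harmonic at 2f) raises the RMS by `seizure_amp_gain`
  (default 3). Onset/offset are ramped over 1 s with a raised cosine.
* **What this does not emulate:** artifacts (eye blinks, electrode pops,
  muscle), non-stationary background, patient-to-patient morphology
  variation, realistic seizure evolution. Passing tests therefore show the
  *method and implementation* are sound on data matching its assumptions;
  they say nothing about clinical performance.

## Numerical choices and conventions

* Band-pass: zero-phase Butterworth, 0.5–48 Hz. The default order is 8 —
  effectively a 16th-order magnitude response after the forward–backward
  pass — chosen so a mains-frequency (60 Hz) tone leaks below 5 % RMS;
  a 4th-order design only reaches ~13 %.
* Degenerate (zero-variance) channels have correlation 0 to everything and
  keep only their self-loop; `pearson` returns 0 rather than NaN.
* Negative correlations count toward edges via `|r|`: strong
  anticorrelation is still functional coupling.
* Strength bands on `|r|` are left-closed, right-open except the top band:
  [0, .2) very weak, [.2, .4) weak, [.4, .6) moderate, [.6, .8) strong,
  [.8, 1] very strong.
* Probabilities are clamped to `[1e-7, 1 - 1e-7]` before logarithms.
* Initialization is Xavier-uniform from one seeded generator per model;
  training shuffling, oversampling and dropout all derive from named,
  seeded generators — two runs with the same config and seed are
  bit-identical.
* EDF export writes plain 16-bit EDF (one data record per second) and
  quantizes against the ASCII-parsed physical-range header values, so the
  round-trip error is bounded by range/2^15; seizure annotations travel in
  a CSV sidecar (`start_s,end_s,label`).

## Problem sizes used by the shipped runs

The scaled-down end-to-end runs (acceptance test and
`scripts/acceptance.py`) use one 3000-s, 16-channel subject: 5999 windows,
~750 non-overlapping 8-window sequences, ten folds, 10 epochs, D = 32,
F' = 8 with the full 8 heads and depth 4. These widths were chosen as the
package's reference small configuration; the architecture defaults
(D = 128, F' = 64, 100 epochs) remain the full-size configuration.

## Known limitations

* The temporal tokenization treats N consecutive windows as one sample;
  this is one concrete reading of "the decision uses the states before and
  after the current moment", and other groupings (e.g. a sliding decision
  over a long context) are not implemented.
* No event-based seizure metrics (onset latency, false alarms per hour).
* Fold assignment by contiguous time blocks trades a little stratification
  exactness for leakage control; with heavily clustered seizures the folds
  can differ in difficulty, which shows up as a larger across-fold std.
* The autodiff engine is correctness-first: single-threaded float64 numpy,
  no kernel fusion; full-size configurations train accordingly slowly.
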