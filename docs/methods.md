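# Methods

## Model and procedure

`p300select` treats P300 detection as binary classification of epoched
EEG trials (target vs. nontarget) and treats channel selection plus
classifier tuning as one 65-dimensional optimization problem. The
pipeline is:

1. **Epochs.** Trials span [−100, 1000) ms around stimulus onset at
   250 Hz (275 samples). Windows are half-open throughout, so sample
   counts are exact; a closed [0, 1000] ms interval would double-count
   the boundary sample.
2. **Preprocessing.** Zero-phase 3rd-order Butterworth band-pass
   (0.1–8 Hz) applied per trial and channel, baseline correction by the
   [−100, 0) ms mean, then decimation of the [0, 1000) ms segment by
   non-overlapping 10-sample block means → 25 features per channel,
   concatenated channel-major (25–1600 features depending on selection).
3. **Classifier.** Regularized FDA: w = (S_W + λI)⁻¹(m₁ − m₋₁), with
   S_W the unnormalized within-class scatter. A sample is scored by
   s(z) = ⟨w, z⟩ and classified to the class minimizing
   (s − μ_j)²/σ_j² over the training-score class statistics.
4. **Fitness.** F = w₁·f₁ + w₂·f₂ with f₁ the geometric mean of the
   per-class accuracies from 10-fold stratified CV (confusion counts
   pooled across folds before computing rates) and
   f₂ = (N_Ch − n + 1)/N_Ch.
5. **Search.** Hybrid real–binary PSO: 30 particles, ≤100 iterations,
   c₁ = c₂ = 2, inertia 0.9 → 0.4 linearly for the real coordinate and
   constant 1 for the bits, velocity clamps ±0.1 (real) and ±6 (binary),
   invisible-wall boundary handling, termination at fitness 1 or the
   iteration cap.
6. **Validation.** Stratified 50/50 train/test split by
   (class, direction, session); the search sees the training half only.
   A final FDA model is fit on all training trials with the selected
   (λ, channels) and judged on the test half. Score averaging over
   M = 2…10 same-class test trials (drawn with replacement from a fixed
   seeded master list, one list reused across configurations) traces the
   accuracy-vs-throughput curve. Pareto extraction over all visited
   (channel count, f₁) positions exposes the trade-off boundary.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `ProtocolSpec.trials_per_session` | 150 | oddball session length |
| `ProtocolSpec.target_fraction` | 0.20 | exact per-session target rate |
| `ProtocolSpec.fs` | 250 Hz | sampling rate; 250 samples in [0,1000) ms decimate to exactly 25 features/channel |
| `ErpSpec.amplitude` / `noise_sd` | 5 / 10 µV | P300 bump height and per-sample noise SD — the study-like low-SNR condition |
| `ErpSpec.p300_peak_ms` / `p300_width_ms` | 350 / 120 ms | Gaussian bump location/scale |
| `ErpSpec.noise_color_exponent` | 1 | 1/f spectral slope of the noise |
| `SwarmConfig.*` | see above | study configuration of the PSO |
| `FitnessWeights` | presets `case1`…`case8` | (w₁, w₂) from (1.00, 0.00) to (0.35, 0.65) |

λ decoding is exponential (λ = 10^(5a)) so that uniform steps in a sweep
the regularizer across ten orders of magnitude.

## What the synthetic generator does and does not emulate

The generator reproduces the statistical skeleton the method relies on:
exact per-session target counts at shuffled positions, a unimodal positive
deflection confined to a known channel subset on target trials only,
optional Gaussian latency jitter, and per-channel independent
1/f-colored Gaussian noise with analytically normalized variance (the DC
gain is zero, so epochs are zero-mean). It does **not** model volume
conduction or any spatial noise covariance, ocular/muscle artifacts,
inter-trial dependence, or continuous recordings (epochs are synthesized
directly). Consequently, passing tests demonstrate that the algorithm
recovers informative channels and calibrates λ under the assumed
signal-plus-independent-noise model; they do not certify performance on
real EEG, where spatially correlated noise can make additional channels
informative through noise cancellation.

Because sessions are generated independently from derived sub-seeds,
datasets are bit-reproducible from a single integer seed.

## Numerical choices

- **Eq. solve.** (S_W + λI)w = m₁ − m₋₁ is solved by Cholesky
  factorization (falling back to a symmetric solve, then least squares,
  under extreme ill-conditioning), never by explicit inversion. With
  λ = 0 the Cholesky factorization doubles as the singularity check and
  rank deficiency raises an informative error.
- **Zero-phase filtering** uses `filtfilt` with Gustafsson initial
  conditions: the 0.1 Hz lower cutoff has a settling time far longer than
  one epoch, so the default reflection padding leaves large edge
  transients on 1.1 s epochs; Gustafsson's least-squares initial state
  minimizes them while preserving linearity and zero phase.
- **Score variances** use the unbiased (n−1) denominator; each class
  needs ≥2 training samples. Degenerate zero-variance scores raise.
- **Ties** in the Mahalanobis rule break to nontarget (the conservative
  choice for the rare-target oddball), and pbest/gbest update on strict
  improvement only, so earlier positions win ties and runs replay
  exactly from the seed.
- **Fold assignment** is frozen once per search (one fold seed, scikit-
  learn stratified K-fold), making fitness a pure function of the
  particle; evaluated positions are cached by (a rounded to 1e−12, bit
  string).
- **Fast CV path.** The evaluator precomputes each fold's full-montage
  within-class scatter and class-mean difference once per search; since
  features are channel-blocked, a particle evaluation reduces to a
  submatrix slice plus one SPD solve per fold. This is algebraically
  identical to refitting per fold, and the test suite asserts equality of
  the pooled confusion counts against the plain reference implementation.
- **Real coordinate is never clipped**; the invisible wall alone handles
  excursions. Initial velocities are zero, initial a ~ U[−1, 1], initial
  bits Bernoulli(0.5).
- **Split rounding.** Odd strata alternate which side receives the extra
  trial, keeping the halves at exactly 900/900 under the default design.

## Open design decisions taken

- The averaged-trial score is the mean of the members' *projection
  scores*, classified with the single-trial training statistics — no
  averaged-trial training set exists in the procedure, and averaging the
  class rule itself is not meaningful.
- The master list indexes the test set only: score averaging is an
  evaluation-time construct.
- The per-trial `direction` metadata records the session's target
  direction (six directions × two sessions = twelve strata per class),
  which is what the stratified split balances.
- Channel indices are 0-based in code; montage names (Biosemi 64 layout
  when the montage has 64 electrodes) carry the human-readable labels.

## Test problem sizes

End-to-end properties run at reduced scale chosen for CI-class hardware:
planted-channel recovery uses a 24-channel montage with 1200 trials,
amplitude 8 µV / noise 5 µV (a clear-separation regime; the generator's
defaults are noisier), 30 particles × 100 iterations over 5 seeds, plus
one full 64-channel run at 30 iterations. On very small montages the
per-channel parsimony increment w₂/N_Ch becomes comparable to the
accuracy gained by a second informative channel, turning the
one-vs-two-channel outcome into a coin flip; 24 channels keeps the
trade-off geometry of the full montage while remaining fast. The
weight-sweep trend runs at 16 channels × 600 trials with 20 particles ×
40 iterations, which is enough to reproduce the monotone decrease of the
median selected-channel count as w₂/w₁ grows.

## Known limitations

- Epoch-wise filtering at 0.1 Hz retains some low-frequency edge bias
  even with Gustafsson initial conditions; a continuous-recording filter
  mode would avoid it but continuous data are out of scope.
- The PSO is a stochastic heuristic: it is not guaranteed to find the
  global optimum, and with strong parsimony weights it can settle on a
  proper subset of the truly informative channels when that subset
  already saturates CV accuracy.
- The chance band used in null-data tests ([0.35, 0.65] geometric-mean
  accuracy) is an empirical band for ~900-trial, 20%-target designs, not
  an analytic confidence interval.
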