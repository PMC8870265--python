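# Methods

## Stimulus model

All targets flicker with the same 63-bit m-sequence (length 2⁶ − 1,
balanced: 32 ones / 31 zeros, two-valued cyclic autocorrelation 63 / −1)
at a 60 Hz bit update, so a cycle lasts 1.05 s. Target *k* uses the
base code circularly left-shifted by ((k − 1)·2) mod 63 bits. The
shift convention deserves a note: a uniform 2-bit grid starting at 0
keeps target 1 identical to the base code and gives 32 distinct phases;
the alternative convention that shifts target k ≥ 2 by k·2 bits (leaving
a 4-bit gap after target 1 and wrapping target 32 to shift 1) is
available via `make_code_set(..., convention="literal")`. A degree-6
LFSR generator (`lfsr_m_sequence`) can regenerate maximal sequences; it
is validated through the balance/autocorrelation invariants rather than
bit-for-bit against the default literal.

In the sample domain each bit is held for FS/60 samples (10 at the
default FS = 600 Hz); a two-cycle trial is n = 1.05·600·2 = 1260
samples, and a 6-block session contains 6 × 32 = 192 trials.

## Synthetic EEG generator

The generator produces exactly the statistical structure the classifier
assumes — no more:

* **Evoked kernel**: a difference-of-gammas impulse response (positive
  lobe peaking at a subject-specific latency drawn uniformly from
  0.09–0.15 s, negative lobe at 1.6× that latency, 0.25 s support,
  unit RMS). The steady-state single-channel response of a target is
  the circular convolution of its zero-mean sample-domain code cycle
  with the kernel, tiled over the trial.
* **Spatial mixing**: one unit-norm 16-channel vector per subject — a
  Gaussian profile centred on the posterior (high-index) channels with
  per-channel perturbations — multiplying the response into all
  channels (rank-1 spatial structure).
* **Noise**: per-channel 1/f-shaped noise (70% of power) plus white
  noise (30%), with a 10% common-mode component shared across channels.
  Noise is scaled so that (evoked power)/(noise power) equals the
  subject's `snr_scale`.
* **Subject spread**: the evoked amplitude is log-normal(0, 0.25),
  entering the effective SNR quadratically; per-trial latency jitter is
  normal with SD 2 ms.
* **Session effects**, drawn once per session and applied to all its
  blocks: amplitude gain ~ log-normal(0, 0.1), latency shift ~
  normal(0, 5 ms), a smooth relative kernel perturbation with SD 0.15,
  and a noise gain ~ log-normal(0, 0.1). These make a model trained on
  one day transfer imperfectly to the other, which is the phenomenon
  the block-composition protocols measure.

**SNR calibration.** The default `snr_scale = 0.17` (a config constant,
not hard-coded in the pipeline) was calibrated once so that
intra-session leave-one-block-out accuracy of the default study lands
in the mid-90s (percent) — the operating point of a well-functioning
cVEP system — and then frozen. A scan on calibration seeds gave
90.3% / 93.7% / 96.1% intra-session accuracy at snr_scale
0.14 / 0.16 / 0.18, with inter-session accuracy ~27 points lower
throughout.

What the generator does **not** emulate: eye blinks and movement
artifacts, electrode geometry and re-referencing, amplifier
characteristics, non-stationarity within a session, and any
non-rank-1 spatial structure of real VEPs. Passing tests therefore
demonstrate correctness of the *pipeline* under its own model
assumptions, not decoding performance on real EEG.

All randomness flows from integer seeds through
`numpy.random.SeedSequence([seed, subject, session, ...])` spawns;
identical (seed, config) pairs reproduce datasets bit-exactly.

## Filter bank

Five band-pass sub-bands share the 60 Hz upper edge with lower edges
6, 14, 22, 30, 38 Hz; each is a 4th-order Butterworth realized as
second-order sections (stable at order 4 and FS = 600 Hz) and applied
forward–reverse (zero-phase), so the effective magnitude response is
the squared single-pass response. Trials are short (1260 samples), so
the signal is reflect-padded by one settling length at both ends before
the two-pass filtering and trimmed afterwards; the padding scheme is
this implementation's own choice. Sub-band correlations are combined
with weights aₖ ∝ k^(−1.25) + 0.25, normalized to sum to one
(0.386, 0.207, 0.156, 0.132, 0.119 for K = 5).

## Spatial filtering (CCA)

For class *i* the filter **w**ᵢ is the X-side weight of the first
canonical correlation between the horizontally concatenated training
trials and the tiled class template. The solver whitens both
auto-covariances with Cholesky factors and takes the leading singular
pair of the whitened cross-covariance. Numerical choices:

* rows are standardized to unit variance internally (CCA is invariant
  to per-variable rescaling; doing it explicitly keeps the ridge term
  acting on an identically scaled problem, making the solver invariant
  to input rescaling to ~1e-9);
* a ridge λ = 1e-8 · trace/m is added to both auto-covariances, since
  concatenated short trials at m = 16 channels can be near-singular;
* the sign indeterminacy is pinned by flipping each weight vector so
  its largest-magnitude entry is positive, and class filters are
  rescaled to unit Euclidean norm (correlation scores are unaffected);
* filters and templates are computed **per sub-band**. Whether the
  original pipeline reused one broadband filter across sub-bands is
  unknowable from its description; per-band filtering matches ensemble
  task-related component analysis practice and is adopted here.

The test suite cross-checks the solver against a brute-force angle-grid
oracle on 2-row instances, the classical generalized-eigenvalue
formulation, and scikit-learn's NIPALS CCA.

## Classification

A test trial is sub-band decomposed, projected through the sub-band's
ensemble matrix **W**ₖ (m × K), and correlated with each class's
projected template using the Pearson correlation of the flattened
n × K matrices; the per-band correlations are combined with the aₖ
weights. The published decision-rule notation compares training
quantities with themselves and cannot literally score an unseen trial;
this implementation substitutes the test trial for the second argument,
which is the standard ensemble-TRCA reading. Scores are convex
combinations of correlations and hence lie in [−1, 1]; argmax ties
break toward the lowest class index for determinism. Trials are scored
on the full two-cycle window; there is no sliding-window or
early-stopping logic.

## Evaluation protocols

Blocks 1–6 belong to session 1, blocks 7–12 to session 2, and
seq = 1, 7, 2, 8, 3, 9, 4, 10, 5, 11, 6, 12 interleaves the days.

* **Cross-session**: same-session cells use leave-one-block-out
  (6 folds: 5-block model, 1 test block); cross-session cells train on
  all 6 source blocks and test each of the other day's 6 blocks.
  Intra-session accuracy is *defined* as the LOO average (not
  resubstitution).
* **Stepwise**: for a held-out test block, it is removed from seq and
  the model at step s is the first s entries of the remaining 11-block
  order.
* **Variants**: V1 tests {12} with the other 11 blocks as model; V2
  tests {12, 6}, model seq minus {6, 12}; V3 tests {12, 6, 11} with
  blocks 1–10 in seq order minus block 6 as model (block 11 stays out
  of the model even though the two-block variant kept 11 — implemented
  literally as specified); V4 tests {12, 6, 11, 5}, model blocks 1–10
  minus {5, 6}; V5 tests {12, 6, 11, 5, 10}, model blocks 1–9 minus
  {5, 6}.
* **Cross-subject**: cell (i, j) applies subject i's session model to
  subject j's blocks; diagonal cells coincide with the cross-session
  plans.

Accuracies are fractions internally and percentages in reports;
per-subject table entries average over test blocks, and mean/SD rows
aggregate across subjects with the sample SD. ITR uses N = 32 and
T = 2.1 + 1.0 = 3.1 s and is floored to 0 at or below chance
(P ≤ 1/32), because the raw formula turns positive again below chance;
the unfloored value remains available as `itr_raw`.

## Problem sizes in the test suite

Structural tests run on reduced studies (1–2 subjects, 1–2 blocks,
sometimes 2–8 channels) — the pipeline is size-agnostic and the
reduced settings exercise identical code paths. The statistical
acceptance checks use the full 6-block two-session structure at the
default 16-channel/600 Hz geometry: 20 seeded single-subject studies
for the stepwise-growth and intra/inter-session ordering checks, and
50 blocks for the label-shuffle chance-level check. These sizes give
standard errors well below the effect sizes being asserted.

## Known limitations

* The generator's rank-1 spatial model makes spatial filtering easier
  than on real EEG; absolute accuracies are calibrated, not predicted.
* Session effects are stationary within a session; real inter-session
  variation also includes electrode repositioning with montage-level
  consequences the mixing-vector model does not capture.
* The dataset container stores arrays in HDF5 (or CSV); no vendor EEG
  formats are read.
* Statistical significance testing across protocol cells is out of
  scope.
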