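# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what is simulated, how each
stage is defined mathematically, and what the synthetic results do and do
not demonstrate.

## Paradigm model

Thirty classes (26 letters plus comma, period, space, delete) are assigned
to three auditory streams by QWERTY row: Q–P → high, A–L plus comma → mid,
Z–M plus space/delete/period → low; class ids run top row first, in
keyboard order. Each *sequence* presents every class exactly once as ten
triplets cycling the streams in the fixed order low, mid, high; within a
stream the ten stimuli are an independent uniform permutation per sequence.
This cyclic interleaving is one reading of "once per stream, in row order";
a block reading (all ten low, then mid, then high) would defeat stream
segregation, which requires alternation, so interleaving is the default.
Consequences used as test oracles: onsets lie on the SOA grid (event *i* at
`i·SOA`), the within-stream inter-stimulus interval is exactly `3·SOA`, and
a 15-sequence trial holds 450 stimuli ending at 89.8 s.

A default session is 6 offline runs × 5 trials (a seeded permutation of
all 30 classes, so each is targeted once — 13,500 training stimuli, 450 of
them targets) plus 3 online runs × 5 trials over 15 distinct seeded targets.
The original study's exact online target letters are not published, so the
subset is a seeded draw, overridable in the session plan. Seeding uses one
master seed with `SeedSequence` spawn keys per purpose (plan, per-trial
schedule, per-run synthesis, per-repeat sub-sampling), so every artifact is
reproducible bit-for-bit and no two stages share a stream.

## Synthetic EEG

The generator is a linear superposition model, not a biophysical one:

- **ERP components** are raised cosines `a/2·(1 + cos(2π(t−c)/w))` on
  `|t−c| ≤ w/2`. Defaults: N2 (center 0.40 s, width 0.20 s, −2 µV,
  frontal), P300 (0.65 s, 0.30 s, +4 µV, centro-parietal), N700 (0.95 s,
  0.15 s, −1.5 µV, central). The reported morphology constrains windows
  and polarities only; amplitudes and topographies are this package's
  choices and are never used as quantitative ground truth. Templates are
  sampled on the exact time grid (latencies, including the optional
  Gaussian jitter of SD 0.02 s, are not quantized to samples), which makes
  superposition identities exact in tests.
- **Topographies** are named channel-weight maps (max |w| = 1) over a
  default 8-channel 10–20 subset (Fz, FCz, Cz, CPz, Pz, Oz, C3, C4) —
  adequate for decoding tests; 64-channel/1 kHz generation is a config
  change away.
- **Steady-state response**: one sine cycle per stimulus at 1/SOA (5 Hz),
  auditory-weighted, amplitude 1 µV; during stimulation the cycles tile
  into a continuous oscillation, reproducing the SOA-locked pattern seen
  in non-target averages.
- **Noise**: independent unit-RMS `1/f` sources (spectral exponent 1.0)
  mixed by a seeded, diagonally dominant unit-row-norm matrix, scaled to
  8 µV RMS per channel — a realistic broadband background for 1–40 Hz EEG.
- **Blinks** (off by default): Poisson raised-cosine frontal bumps plus an
  `EOGv` channel carrying the same trace with 1 µV sensor noise; enabled
  only for artifact-handling tests.

Because the SOA (0.2 s) is shorter than the template extent (~1.1 s),
epochs neighbouring a target carry shifted target-like waveforms — the
overlap structure real recordings show. What the generator does *not*
emulate: non-stationarities (drowsiness, impedance drift), inter-trial ERP
variability beyond latency jitter, realistic artifact taxonomies, volume
conduction from a head model, or attention lapses. Passing tests therefore
demonstrate the correctness and internal consistency of the processing
chain at a plausible SNR, not expected accuracy on human data.

Per-participant difficulty is a single SNR multiplier on all component
amplitudes, letting group-level statistics (bootstrap over participants)
be exercised with heterogeneous simulated users.

## Preprocessing conventions

- Filtering is one forward pass of an order-2 Butterworth band-pass
  (second-order sections), i.e. causal, as in an online system; no
  zero-phase filtering anywhere.
- Epochs are half-open `[tmin, tmax)` windows with the onset sample at
  t = 0, so the sample count is exactly `round((tmax − tmin)·fs)`. Windows
  past a run's end draw zeros (the run is treated as zero-padded), matching
  the handling of trials near the end of a recording.
- No baseline correction is applied anywhere; features use only the
  `[0, Tmax)` part, the −0.1 s prefix exists for inspection/plotting.
- Post-hoc analyses follow the order filter → epoch → downsample (polyphase,
  to 128 Hz). Interval means bin samples *by time* (`floor((t−start)/bin)`),
  since at 128 Hz a 0.1 s bin holds a non-integer 12.8 samples; bins of 12
  and 13 samples then partition the window exactly.
- EOG handling: the decomposition (PCA to 15 components, then FastICA) is
  delegated to scikit-learn; this package's contract is the selection rule —
  per EOG channel, the source with maximal |Pearson r| (ties to the lowest
  index, de-duplicated across EOG channels) — and removal by zeroing
  selected sources before reconstruction. |r| rather than signed r is used
  because a source's sign is arbitrary.

## Decoding

**Shrinkage LDA.** With class means `m1` (target), `m0` and class-centered
data, the pooled within-class covariance uses the unbiased `N − 2`
denominator and is shrunk toward the scaled identity,
`Sw = (1−λ)S + λ(tr S/p)I`, with λ the Ledoit–Wolf intensity (scikit-learn
estimate). Then `w = Sw⁻¹(m1 − m0)` and `b` places the projected midpoint
of the class means at zero. Since the trial decision compares only relative
score magnitudes within a trial, any monotone bias convention is
decision-equivalent; the midpoint is chosen for interpretability
(`dᵢ = wᵀxᵢ + b` is a signed hyperplane distance, positive toward targets).

**xDAWN.** Filters solve the generalized eigenproblem of the evoked
covariance `P Pᵀ/T` (P the target-average prototype) against the total
covariance of all epochs, maximizing the evoked signal-to-signal-plus-noise
ratio; the top components (default 2) are kept in non-increasing eigenvalue
order, a trace-scaled jitter (1e−10) guards rank deficiency, and each
filter's sign is fixed by making its largest-magnitude coefficient
positive. Spatial *patterns* (`Cx·w`) are stored for inspection.

**Riemannian pipeline.** Each xDAWN-filtered epoch X is stacked under the
filtered prototype and the second moment of `[P; X]` (no mean removal)
gives a `2n×2n` SPD matrix whose cross block carries the epoch–prototype
covariance; plain per-epoch covariance would discard the evoked mean, which
is the discriminative quantity, so the prototype-augmented form is used.
A trace-scaled ridge (1e−8) keeps matrices SPD. The affine-invariant
geometric mean is computed by the standard fixed-point iteration
(whiten, average matrix logs, retract; tolerance 1e−8, max 50 iterations,
warning on non-convergence), and matrices are mapped to its tangent space
by `upper-vec(log(G^{−1/2} C G^{−1/2}))` with off-diagonals scaled by √2,
so a vector's norm equals the affine-invariant distance to the reference.
Tangent vectors are classified with the same shrinkage LDA.

## Decisions and stopping

Per trial, the class with the highest mean score over the stimuli
considered wins; ties break to the lowest class id, and classes not yet
presented are excluded from the argmax. Elapsed selection time follows
`T = (Nₛ−1)·SOA + Tmax`.

Dynamic stopping: after a minimum number of complete sequences
(2–14), the rule is evaluated after *every* stimulus: the current best
class is re-identified from running means, and its scores are tested
against the *pooled* scores of the other 29 classes with a one-sided
Welch t-test; the trial ends at the first p < α (default 0.05). Pooling
(one test per evaluation) rather than 29 pairwise tests matches a single
Welch comparison per check and keeps the α interpretable; re-identifying
the best class at each evaluation avoids freezing an early wrong leader.
Degenerate inputs (both variances zero) take p = 0.5 by convention at equal
means — a stream of identical scores never stops early. As α → 0 the rule
provably never triggers and reduces to the full-length decision, an
invariant the tests exercise.

## Metrics

Wolpaw ITR: `R = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))` bits/trial
with the `x log₂ x → 0` limits at P ∈ {0, 1}, and `B = R·60/T` bits/min.
Under dynamic stopping T is the mean elapsed selection time across a
participant's trials; under full-length/static protocols it is the fixed
trial duration. Accuracy CIs are Wilson score intervals (z = 1.959964 at
95%), mapped bound-wise through the ITR formula for ITR CIs; group CIs are
percentile bootstrap over participants (10,000 resamples). The percentile
variant is slightly anti-conservative for very small groups (measured
coverage ~0.90 at n = 10 versus ~0.94 at n = 40 in the Monte-Carlo test);
it is kept for its simplicity and transparency. AUC is the rank statistic
(ties half-weighted), delegated to scikit-learn and cross-checked against
the normalized Mann–Whitney U in tests; signed-r² is the signed squared
point-biserial correlation — note its magnitude carries a `p(1−p)` factor,
so under the 1:29 imbalance even strong effects yield values of order 0.01.

## Experiment harness

The online replica trains on all offline runs (no artifact removal, as in
the original online pipeline) and decodes online trials full-length. The
stopping sweep evaluates static stopping at every cumulative sequence
(1–15) and dynamic stopping at every minimum sequence count (2–14),
reporting accuracy, mean selection time and ITR, plus the three
row-selection criteria (max accuracy; max ITR; max ITR subject to
accuracy ≥ 0.7). The imbalance experiment retains all 450 target samples
and sub-samples non-targets to ratios {1, 5, 10, 20, 29} (ratio 29 uses
all 13,050 non-targets), retraining the LDA per seeded repeat. The
parameter grid varies high-pass {0.1, 0.5, 1} Hz, low-pass {8, 15, 20, 40}
Hz and epoch length {0.5, 1, 1.5, 2} s over the three pipelines with
3-fold cross-validation that never splits a run (default folds: runs 1–2 /
3–4 / 5–6, configurable since the original fold composition is not
published), scoring stimulus-level AUC.

## Problem sizes and tolerances in the test suite

Simulations in the tests are sized for a laptop-class single core: the
high-SNR end-to-end check uses one full-scale session (6 offline + 3
online runs, 15 sequences); the chance-level check uses 300 trials of 5
sequences (letter accuracy under the null does not depend on the sequence
count); the imbalance check uses ratios {1, 5, 29} × 3 repeats and asserts
the direction of the effect, not magnitudes; the grid test uses a reduced
2×2 grid. Closed-form quantities are asserted at the display precision
(2 decimals); floating identities at 1e−8–1e−12; stochastic properties at
fixed recorded seeds with explicitly stated bands (binomial 95% band for
chance accuracy, ±0.01 for the Welch type-I rate at 20,000 draws).

## Known limitations

- The synthetic generator's amplitude/topography defaults are plausible but
  uncalibrated; absolute synthetic accuracies should not be compared to
  human results.
- No EEGNet-style neural pipeline is included; the pipeline registry
  accepts external scorers through the fit/score-per-event contract.
- Readers for vendor EEG formats (BrainVision, EDF) are not bundled;
  recordings enter either from the generator or from the HDF5 + events-TSV
  interchange format.
- The "statistical chance level" (a citation-based threshold distinct from
  1/N) is not computed; chance is assessed against the theoretical 1/30
  with binomial bands.
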