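# Methods

`vigilwatch` implements an EEG-based vigilance assessment chain and a
synthetic-data generator that makes every stage of that chain testable
end to end. This note documents the models, the parameters that matter,
and the design decisions taken where more than one reasonable choice
existed.

## The vigilance model

Vigilance is treated as a latent state v(t) ∈ [0, 1] (1 = fully alert)
that declines with time on a monotonous task. Its neurophysiological
signature is a multiplicative change of EEG band power in specific
(scalp area, frequency band) combinations: parietal alpha, frontal beta
and frontal gamma power all *increase* as vigilance falls. The assessment
pipeline estimates a scalar **vigilance index** (VI) per 2-s epoch as the
score of a linear discriminant trained to separate labelled high-vigilance
(label 1) and low-vigilance (label 0) task blocks.

### Signal conditioning

* **Filtering.** 5th-order Butterworth band-pass, 1–40 Hz, applied
  forward–backward (zero phase) so epoch timing is preserved; an optional
  50 Hz notch (Q = 30) covers the mains-contaminated laboratory dialect.
  Zero-phase application is a deliberate choice for offline analysis: the
  filter family and order leave phase behaviour open, and phase fidelity
  matters when overlapping epochs are cut from the filtered trace.
* **Ocular correction.** A dedicated ocular channel (Fpz) is regressed out
  of every other channel. The regression coefficient is estimated over
  blink-active samples only (|ocular| > 3 robust SDs from its median),
  where the blink source dominates the brain background; the scaled ocular
  trace is then subtracted everywhere. After correction the ocular channel
  is dropped: it still carries the raw blinks and has no analysis role.
* **Epoching.** Left-aligned half-open windows of 2 s shifted by 0.125 s
  (sample-quantised: 31 samples at 250 Hz, 32 at 256 Hz); the last partial
  window is dropped, so `n_epochs = floor((T − 2)/0.125) + 1`.
* **Artifact rejection.** An epoch is rejected when *any* channel violates
  *any* of three criteria: |sample| > 100 µV (amplitude), OLS linear-fit
  slope > 10 µV/s (trend), consecutive-sample difference > 25 µV (step).
  Reasons accumulate per epoch. The per-channel/any-criterion rule is the
  conservative reading of a per-epoch rejection scheme; the trend
  criterion is read as an ordinary least-squares line fit per channel per
  epoch, the simplest estimator consistent with "slope of the trend".

A practical note on planted-artifact recovery: with overlapping epochs an
epoch that overlaps an artifact window by only a few samples carries
sub-threshold artifact energy *by construction*, and the 1 Hz zero-phase
highpass removes most of the low-frequency structure the trend criterion
targets (ramps below roughly 300 µV over 2 s and steps below roughly
100 µV become invisible downstream of the filter). The test-suite therefore
asserts exact recovery on epochs that overlap a window by at least 0.75 s
(unfiltered chain) and event-level detection with zero false alarms on the
filtered chain, rather than per-epoch identity.

### Spectral features

* Per-epoch PSD: single-taper periodogram with a full-epoch periodic
  Hanning window, density scaling, 0.5 Hz resolution for 2-s epochs.
  (Implemented as one batched rfft; equality with
  `scipy.signal.periodogram` is asserted in the tests.)
* **IAF.** The individual alpha frequency is the prominent maximum of the
  channel-averaged posterior-channel spectrum within 7–13 Hz, estimated
  from ≥ 30 s of eyes-closed rest. A maximum is trusted only if it exceeds
  twice the in-range median power; otherwise the estimate falls back to
  10 Hz with a logged warning. The prominence guard is what turns "argmax"
  into "peak": on a peakless spectrum the argmax is an arbitrary noise bin.
* **Bands** are anchored to the IAF: theta [IAF−6, IAF−2), alpha
  [IAF−2, IAF+2), beta [IAF+2, IAF+16), gamma [IAF+16, IAF+30), half-open
  so bin-centre membership never double-counts an edge bin.
* **Band power** = mean in-band PSD × band width (µV²); integration keeps
  units coherent across bands of different widths.
* **Baseline normalisation** subtracts the per-column mean of the
  eyes-open rest (OA/REF) features from every task row, on the linear
  power scale (the literal reading of "subtracting the baseline");
  normalised tables are flagged and refuse a second normalisation.

### SWLDA and the vigilance index

The discriminant is stepwise linear discriminant analysis: OLS regression
of the 1/0 labels on (channel, band) features with iterative forward entry
and backward removal.

* Entry: the excluded feature with the smallest partial-t p-value joins if
  p < α_enter = 0.05; ties break by p-value then lexicographic name.
* Removal: included features with p > α_remove = 0.1 leave, worst first.
* Iteration stops on no change, on revisiting a previous feature set
  (cycle guard), or at 60 iterations. Re-entry of a removed feature is
  allowed, as in classic stepwise.
* The forward step uses the partial-correlation identity — the p-value of
  a candidate's coefficient equals the p-value of the correlation between
  the current residuals of y and of the candidate — so one residualisation
  of all candidates replaces one OLS refit per candidate. Equivalence with
  the naive per-candidate refit is asserted in the tests.
* An empty model (nothing enters) is valid: the VI is then the constant
  mean label. The VI is deliberately *not* clamped to [0, 1].

### The configuration ladder

Channel reduction proceeds in four nested configurations:

1. **AllCh** — every montage channel except central (FC*, C*, CP*) and
   prefrontal (Fp*) sites. Central sites overlie motor cortex and would
   let hand-movement counts masquerade as vigilance; prefrontal sites
   carry ocular residue.
2. **HV-LV** — features whose across-subject high- vs low-vigilance
   difference is significant (Wilcoxon signed rank on per-subject mean
   band powers, p < 0.05), pruned of redundancy: same-area channels whose
   per-subject HV−LV changes do not differ significantly are represented
   only by the channel with the larger |mean HV − mean LV| gap.
3. **LAB** — the union over subjects of the SWLDA-selected features on the
   HV-LV configuration. The union (rather than intersection) matches the
   feature-map construction, where a feature's colour encodes the number
   of subjects selecting it.
4. **2Ch** — per band, the most-selected channel in the cross-subject
   feature map; the union is reduced (or padded by the next-most-selected
   channel) to exactly two channels.

Group-level statistics (signed rank across subjects) are used for the
HV-LV stage because the resulting configurations are cohort-level objects;
a per-subject epoch-level variant would make the configuration depend on a
single subject's noise. With fewer than 6 subjects the signed rank cannot
reach p < 0.05 and the ladder truncates at AllCh with a warning — a
resolution limit of the test, not a bug.

### Evaluation battery

* **ROC.** AUC by trapezoid (ties half-credited, equal to the
  Mann–Whitney probability — asserted against `scipy.stats.mannwhitneyu`);
  maximum accuracy over a threshold sweep of midpoints between adjacent
  distinct scores plus sentinels. High vigilance is predicted at
  score ≥ threshold.
* **Group comparisons.** Kruskal–Wallis (tie-corrected) as the omnibus;
  Tukey HSD applied to rank-transformed data as the post-hoc, keeping the
  post-hoc on the same (rank) scale as the omnibus.
* **Paired contrasts.** Wilcoxon signed rank; exact null for ≤ 25 non-zero
  differences, normal approximation with continuity correction beyond.
* **rmcorr.** Repeated-measures correlation via the ANCOVA decomposition:
  y on x with subject-specific intercepts and a common slope;
  r = sign(slope)·√(SSx/(SSx+SSE)), dof = N − k − 1, two-sided p. The
  implementation is checked against the within-subject-centring oracle
  (to 1e-10) and against `pingouin.rm_corr`.
* **VI trend.** Per-block mean VI, least-squares slope over block index,
  and a first-vs-last-block signed-rank contrast across subjects (defined
  for ≥ 5 subjects).

### Study replicas

*Experiment 1 (PVT).* Each subject performs two sessions: 1 min eyes-open
(OA), 1 min eyes-closed (OC), then 10 task blocks. Blocks 1 (high) and 9
(low) train the SWLDA; four validations follow — train session 1 → test
session 2's labelled blocks, the reverse, and two within-session
validations scoring all held-out blocks to track the VI over time. The VI
is correlated with per-block mean reaction time via rmcorr (expected
negative: RT rises as vigilance falls).

*Experiment 2 (ATM).* A 3-block calibration scenario (first block high,
last low) trains the models; two further monotonous supervision scenarios
(BASELINE, SOLUTION) are the test sets, labelled by their first/last
blocks. The laboratory LAB configuration transfers by intersection with
the 16-channel field montage. The LAB VI is correlated (rmcorr) with every
other configuration's VI; planted-effect worlds give positive correlations
throughout.

## The synthetic-data generator

Each channel is a sum of:

* 1/f^γ coloured background noise (γ = 1 by default, RMS 4 µV across the
  synthesised band) — the minimal stationary EEG-like background;
* band-limited Gaussian components per modulated (area, band): a
  narrowband (±0.6 Hz) alpha oscillator centred at the subject's IAF on
  posterior channels, and broadband beta/gamma components on frontal
  channels. Component amplitude is scaled by `effect^( (1−v(t)) / 2 )`, so
  the *power* between vigilance 1 and 0 scales by the configured effect
  size;
* a Poisson train (15/min) of ~400 ms biphasic blink transients on an
  ocular source, mixed into channels with distance-decaying coefficients
  (Fp 1.0, AF 0.55, F 0.30, FC 0.12, C 0.06, far field 0.02);
* planted artifacts of the three rejection classes: tapered saturation
  plateaus (amplitude), monotone slow ramps (trend), and persistent DC
  level shifts whose jump sample violates the step criterion.

Default effect sizes — parietal alpha 2.0, frontal beta 1.5, frontal
gamma 1.5 — encode the reported *directions* of the vigilance signature at
magnitudes typical of moderate-to-large spectral effects; no quantitative
effect sizes are published for this design, so these are free parameters
of the generator, fixed once. Each modulated component carries 9× the
background's in-band power (`oscillator_snr`). The dominance serves the
power-calibration contract: the realised high/low band-power ratio
includes the unmodulated background, so the measured ratio is
(1 + snr·E)/(1 + snr) — within 5% of E at snr = 9, and inside the ±10%
band the tests check. The flip side is a spectrum whose beta/gamma share
is larger than typical resting EEG; amplitudes are scaled (background
4 µV RMS) so that clean synthetic signal never trips the absolute-valued
rejection criteria.

What the generator deliberately does **not** model: volume conduction and
channel covariance (channels are independent given the latent state),
non-stationary background, alpha reactivity to eye closure, EMG, and any
direct effect of the task on the EEG beyond the latent-state coupling.
Passing tests therefore demonstrate that the *analysis chain* recovers the
structure it assumes — not that real EEG satisfies those assumptions.

Reaction times are lognormal per trial (σ = 0.2) with a per-block median
drifting linearly from 250 ms (vigilance 1) to 400 ms (vigilance 0),
~12 trials/min; lapses are RTs above 500 ms. This reproduces the
qualitative behavioural finding (RT increases with time on task) without
asserting unpublished quantitative dynamics.

Everything is deterministic given the spec's seed: identical
`SimulationSpec`s produce bit-identical recordings.

## Problem sizes

The default study configurations carry the full protocol layout
(61-channel montage at 250 Hz, two 10 × 1-min PVT sessions; 16 channels at
256 Hz, 3 × 5-min calibration and 45-min scenarios, 13/10 subjects). The
test-suite and the reproduction script run the same designs at desk scale
via `vigilwatch.presets`: 16- or 8-channel montages, 10 × 24 s (or
10 × 18 s) PVT blocks, 3 × 40 s scenarios, 30 s rest segments, cohorts of
3–6 subjects. Block counts, training-block assignment (1 vs 9; first vs
last), rest/task structure, epoch grid, thresholds and effect sizes are
unchanged — only durations, montage and cohort size shrink. Per-subject
signed-rank resolution is the binding constraint on cohort size (≥ 6 for
the HV-LV statistics).

## Numerical choices

* Epoch tensors are float32 (µV-scale data; the heavy 16× window overlap
  makes float64 wasteful); all statistics are computed in float64.
* OLS fits use `lstsq`; rank-deficient designs are detected and the
  offending candidate skipped (forward) or the latest entrant dropped
  (backward), with a log line.
* Signed-rank tests on identical vectors are treated as maximally
  non-significant (p = 1) inside the channel statistics, where "identical"
  means "no evidence of difference", not an error.
* EDF export quantises to int16 over each channel's observed range
  (1-s records, integer sampling rates); reading goes through `mne`, which
  doubles as an independent check of the writer.

## Known limitations

* The generator's independent-channel assumption makes same-area channels
  redundant only through their shared *statistical* structure, not through
  genuine volume conduction; redundancy pruning is exercised, but its
  realised channel choices on synthetic cohorts are noise-driven.
* The 2Ch construction pads or trims to exactly two channels; in worlds
  where one channel dominates every band the padded second channel is
  weakly informative.
* maxACC is optimistically biased on small test sets (threshold chosen on
  the test scores themselves), exactly as in the original evaluation
  protocol; AUC is the more stable quantity.
* With fewer than ~6 subjects the ladder degrades gracefully to AllCh;
  cohort-level conclusions need the signed rank to have resolution.
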