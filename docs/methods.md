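# Methods

This note documents the models, estimators and design choices behind
`mi-adapt`, what the synthetic-data generator does and does not emulate,
and the numerical conventions that matter for reproducing its output.

## Synthetic EEG model

Each channel is

    x_c(t) = A · [ n_c(t) + √snr · o_c(t) ]

where `n_c` is unit-RMS pink noise (1/f^γ amplitude spectrum, γ = 1 by
default, independent per channel) and `o_c` is a sum of unit-RMS
narrow-band oscillators, rescaled by 1/√(number of oscillators) so total
oscillatory power stays at `snr` relative to the noise.  `A` is a
nominal microvolt scale (10 µV); absolute scale is irrelevant to every
downstream statistic (WPLI, CSP and Pearson correlations are
scale-invariant, and classifier features are standardized).

**Oscillators** are constant-amplitude phase-diffusion sinusoids:
`z(t) = exp(i φ(t))` with `φ` advancing at the band's centre frequency
plus Gaussian increments whose variance sets a Lorentzian linewidth of
about half the band width.  This produces the analytic, band-limited
phase structure a phase-lag estimator needs, at negligible cost.

**Coupling.**  A coupling entry (a, b, band, lag, strength s, task)
makes channel b's band component
`s·z_a·e^(−i·lag) + (1−s)·z_b_own` inside the task's imagery windows
(everywhere, if no task is given).  At s = 1 and lag π/2 every
cross-spectral observation has the same imaginary sign, so WPLI
saturates at 1; at s = 0 the channels are independent.

**ERD.**  An entry (task, channels, band, attenuation a) multiplies the
band amplitude on the listed channels by (1 − a) inside that task's
imagery windows, emulating event-related desynchronization.  Power in
the attenuated windows is predicted by
`(1 + snr(1−a)²)/(1 + snr)` relative to rest, which the tests verify.

**Seeding.**  One master seed; per-subject substreams are children of
`numpy.random.SeedSequence(master)` (two children per subject: signal
and schedule), folded to 31-bit integers.  Identical seeds reproduce
cohorts bit-for-bit; subjects are mutually independent.

**What is not modelled:** volume conduction / leadfields (channels are
only correlated where a coupling entry says so), ocular and muscular
artifacts, electrode drift, and between-session nonstationarity.
Passing tests therefore demonstrate estimator correctness and pipeline
integrity on signals with known ground truth, not robustness to real
recording artifacts.

## Paradigm and preprocessing

The default paradigm is 5 sets × 40 trials (each of the four tasks 10
times per set, order randomized per set), 7 s imagery + 5 s rest —
200 trials, 50 per task.  Preprocessing runs in a fixed, logged order:

1. channel selection to the canonical 60-electrode set, with bad
   channels replaced by an inverse-distance-weighted average of their 4
   nearest kept neighbours (template 10-20 positions, top-view
   projection).  Spherical-spline interpolation is out of scope; the
   simple rule is adequate for synthetic data and exactly testable.
2. common average reference;
3. downsampling to 250 Hz (integer ratio, internal anti-alias low-pass
   at 80% of the target Nyquist);
4. zero-phase FIR band-pass 1–40 Hz.  Filter order is
   3·fs/transition_bw rounded to the nearest even integer (type-I
   linear phase), Hanning window, 1 Hz transition by default.  The
   symmetric kernel is applied once on a reflection-padded signal with
   centred convolution, which compensates the group delay exactly —
   equivalent in phase to forward–backward filtering but with the
   designed (not squared) magnitude response;
5. epoch extraction.  The imagery window defaults to seconds 1–4 after
   onset (skipping 1 s of reaction time; the offset is a config knob,
   since the exact latency is a free choice), i.e. 750 samples at
   250 Hz.  Keeping 35 of 50 trials per task emulates manual artifact
   screening with a deterministic, artifact-motivated proxy: the 35
   epochs with the smallest peak-to-peak amplitude, ties broken by
   trial order.

A `denoise_hook` slot is provided where a component-based cleaning step
(e.g. ICA) would sit in a real-data analysis; it defaults to identity.

## Feature extraction

All four extractors are scikit-learn transformers over
`(epochs, channels, samples)` arrays; anything trainable is fitted on
training folds only.

- **PSD** — multitaper power spectral density (`mne`,
  `normalization="full"` so values are a physical density in
  units²/Hz), averaged over 8–30 Hz, for the 21-channel sensorimotor
  strip (FC5…FC6, C5…C6, CP5…CP6; config-overridable).
- **WPD+DWT** — the selected channels are averaged into one signal per
  epoch (keeping the canonical 36-column layout; a per-channel mode
  would multiply the dimension by the channel count).  Six DWT
  sub-bands (5-level decomposition: A5, D5…D1) and the six level-3
  wavelet-packet leaves with the greatest frequency overlap with
  8–30 Hz (ties broken by ascending leaf frequency) each contribute
  mean, standard deviation and mean power of their coefficients.
  Mother wavelet db4 by default; Daubechies, Symlets, Haar and Coiflets
  families are accepted.
- **RF (Riemannian)** — per filter-bank band, the epoch covariance on
  the 21-channel subset (trace-normalized, diagonal-loaded by
  ε·tr(C)/p with ε = 10⁻⁶) and its affine-invariant distances
  δ(C, Ḡ₁), δ(C, Ḡ₂) to the two class Karcher means,
  δ(A,B) = √Σ ln²λᵢ(A⁻¹B).  The Karcher mean is iterated tangent-space
  averaging with a step size that halves whenever the mean tangent norm
  stops decreasing — the plain fixed-point iteration oscillates on the
  near-rank-deficient covariances of narrow-band epochs.  A
  tangent-space parameterization (`TangentFeatures`, vectorized
  upper-triangular `log(Ḡ^(−1/2) C Ḡ^(−1/2))` with √2 off-diagonals) is
  provided as an alternative; the distance features are the default
  because they keep the canonical 12-column dimension.
- **FBCSP** — per band of the default bank (contiguous 4-Hz bands
  8–12 … 28–32 Hz, the standard choice covering the 8–30 Hz focus), CSP
  filters from the generalized eigenproblem of (C₁, C₁+C₂) (two pairs
  from the spectrum ends → 4 log-normalized-variance features), 24
  columns total.  Mutual-information scores per band (equal-frequency
  histogram estimator, 4 bins — the plug-in bias
  (bins−1)(classes−1)/(2N ln2) stays under 0.05 bits at N ≈ 70) are
  computed and reported as a band ranking, but no columns are dropped
  by default, preserving the fixed 24-column contract; MI-based
  selection is available through the reported scores.

## Adaptability

For each of the six canonical task pairs, stratified 10-fold CV of a
linear SVM (C = 1; the common deterministic default for MI-BCI when no
kernel is specified) with per-fold feature standardization.  PSD and
wavelet features carry no trainable state, so they are computed once
per epoch and cross-validated as a matrix; CSP- and Riemannian-based
features are refitted inside each training fold.  The adaptability
score is the arithmetic mean of the six pairwise accuracies; a 3-pair
variant (tongue excluded) is also reported.  Cross-method consistency
is a subjects × methods Pearson grid.

## Connectivity and networks

**WPLI.**  Per channel pair: band-pass each epoch (same FIR rule as
preprocessing with a 1 Hz transition, but the order is capped so the
kernel fits inside the epoch — the full rule at 250 Hz produces a
750-tap kernel, as long as the epoch itself), Hilbert transform, trim
5% of samples at each epoch edge against filter/Hilbert transients,
then pool every remaining time sample of every retained epoch as one
cross-spectral observation.  The estimator is
|mean im S| / mean |im S| with 0/0 defined as 0 (no phase asymmetry).
The imaginary part is computed in explicit real arithmetic
(im_a·re_b − re_a·im_b) so that identical channels produce an exact
zero and the 0/0 convention actually fires.  Networks are computed per
task from that task's own epochs.  Band definitions: α 8–12, β1 13–20,
β2 20–30 Hz.

**Thresholding.**  Keep the ⌊0.10·1770⌉ = 177 largest off-diagonal
upper-triangle weights (round half up; zero weights never retained;
ties at the cut broken by (row, column) order), symmetrize, binarize.

**Graph metrics** (binary, on the thresholded adjacency): degree by row
sum; clustering 2eᵢ/(kᵢ(kᵢ−1)); nodal path length as the mean BFS
distance to reachable nodes (NaN for isolated nodes); local efficiency
as the mean inverse distance within the subgraph induced by a node's
neighbours (0 for degree < 2); betweenness as unnormalized
shortest-path counting, endpoints excluded, one count per unordered
pair.  Implemented with networkx and verified exactly against an
exhaustive simple-path-enumeration oracle on random small graphs.
Hemispheric summaries average each nodal metric over the 15 key
electrodes per hemisphere (NaN-aware, so isolated nodes contribute no
path-length term); the characteristic path length L is computed over
the 30-electrode union with distances measured on the **full** graph
(not the hemisphere subgraph — distances through the other hemisphere
count), and unreachable pairs are excluded from the mean with a logged
count rather than mapped to ∞ or N (keeps L finite on sparse top-10%
graphs; a harmonic-mean alternative would change the scale of L).
Differences are left − right.

## Screening

Pearson r with the two-sided p from t = r√(n−2)/√(1−r²).  The
significance rule is conjunctive: p < α **and** |r| > r_min (absolute
value, since negative correlations are reported as significant too).
r_min defaults to 0.273 — the critical r of the two-sided 5% test
computed with df = 50, the convention that matches a 50-subject cohort
quoted threshold; the conventional df = n−2 gives 0.279 at n = 50, and
p-values here always use df = n−2.  No multiple-testing correction is
applied by default; a Benjamini–Hochberg column is available as a
clearly labelled extension.

## Gradient cohorts and the recovery experiment

`run_study` cohorts give subject i a skill level sᵢ on a linear grid
(0.1–1.0 by default) that drives two causally separate observables:

- ERD depth 0.3·sᵢ on task-specific motor channels → class
  separability → adaptability;
- tongue-conditional β2 coupling of strength 0.8·sᵢ on 12
  right-hemisphere electrode pairs → right-hemisphere degree (KR) of
  the tongue-task β2 network.

The default effect sizes (snr = 0.15, the gains above) were chosen once
so that simulated adaptability spans roughly 0.5–1.0 with a
low-performer tail, matching the spread real MI-BCI cohorts show, and
so the coupled edges move through the top-10% retention boundary across
the skill range rather than saturating it.

The recovery experiment (`recovery_experiment`) simulates independent
gradient cohorts, runs the full pipeline per subject (simulate →
preprocess → PSD adaptability → WPLI → threshold → hemispheric degree)
and screens KR against adaptability.  Problem sizes are scaled for
routine runs: 24 subjects per replicate (about half the full 50-subject
design), the 30 key-electrode montage, one set of 64 trials (16 per
task), 3 s imagery / 1.5 s rest at 250 Hz, and a 2.5-s epoch window.
The 24-subject size was chosen because the underlying KR–adaptability
correlation under these conditions is ≈ 0.7, and a significance test at
n = 10 (critical r ≈ 0.63) is underpowered by construction — the scaled
experiment should test recovery of the association, not the sample-size
frontier.  The screen's type-I error is measured separately on fully
independent property/score vectors at n = 50.

## Numerical conventions and edge cases

- Filter orders round to the nearest even integer (type-I FIR); epoch-
  level filters cap the order at about a third of the epoch length.
- WPLI weights are clipped to [0, 1] after the ratio; the numerator
  can never exceed the denominator analytically (triangle inequality),
  so clipping only absorbs rounding.
- Covariances are diagonal-loaded before any eigendecomposition; a
  matrix still non-SPD after loading is an error, not a warning.
- The Karcher mean raises after 50 damped iterations without reaching a
  1e-8 mean-tangent norm, reporting the last norm.
- Proportional thresholding is deterministic under ties ((row, column)
  lexicographic order at the cut).
- EDF export quantizes to 16 bits per channel with a symmetric physical
  range per channel; round-trip error is bounded by ~6·10⁻⁵ of the
  channel's peak amplitude.

## Known limitations

- No volume-conduction model: zero-lag spurious connectivity, the main
  real-world confounder WPLI is designed to resist, is absent from the
  generator, so WPLI's robustness advantage is asserted analytically
  (zero-lag → exact 0) rather than demonstrated on realistic mixtures.
- The manual-screening proxy (peak-to-peak retention) and the simple
  neighbour-average interpolation are stand-ins for interactive
  curation steps; both are deterministic and documented, but neither
  reproduces expert judgement.
- The 21-channel subset and the filter bank are fixed conventional
  choices exposed in config, not optimized per subject.
- Classification uses a linear kernel with C = 1 throughout; no
  hyperparameter search, by design.
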