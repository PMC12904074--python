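# Methods

This note documents the models and estimators implemented in `oscibar`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data validation does and does not establish.

## Data model and conventions

A recording is a `[n_regions × n_samples]` LFP matrix in microvolts at
`fs = 1000` Hz with region labels (default OB, aPC, LEC), plus per-unit
sorted spike times in seconds. Time is in seconds; sample indices are
`floor(t·fs)`; every epoch interval is half-open `[start, end)`, so
adjacent epochs tile a recording without double-counting. Frequency bands
are θ = 3–12 Hz, β = 15–35 Hz, γ = 36–95 Hz (closed intervals). All
validation is eager at construction/load so errors carry file context. No
line-noise notch is applied by default; an analysis that needs one should
filter before calling the estimators (50 Hz sits inside the γ band, so a
notch visibly dents γ power — this is deliberate and documented rather than
silently applied).

## Spectral estimators

*PSD.* Welch averaging of Hann-windowed periodograms, one-sided, density
scaling; defaults 2-s segments with 50 % overlap, giving 0.5-Hz resolution
(enough to resolve the 3-Hz θ edge). *Band power* integrates the PSD by
trapezoid over bins whose centers fall in the closed band and is reported
as `10·log10(P / 1 µV²)` dB. The dB reference is a package convention;
absolute levels are only meaningful relative to the simulator calibration,
while differences (group effects, gain checks) are reference-free. A zero
signal yields `−inf` with an explicit flag rather than an error.

*Coherence.* Welch magnitude-squared coherence (msc); the per-band summary
is the mean of `sqrt(msc)` over in-band bins. The square-root (coherence
magnitude) scale is used because cross-regional coherence values in this
literature (~0.27–0.62) are magnitudes, not msc. Estimates from fewer than
8 Welch segments carry a strong positive bias and are flagged `high_bias`.

*Cross-correlation.* Coefficient normalization (zero-lag autocorrelation
product), so `r(0)` is the Pearson correlation; the coupling index is
`max |r(lag)|` over `±max_lag`. Ties break toward lag 0, then the negative
lag — an arbitrary but deterministic convention.

## Band-limited phase and amplitude

Band-pass filtering is a 4th-order Butterworth applied forward–backward
(zero phase by construction), followed by the Hilbert analytic signal.
Phase follows the cosine convention (0 at a peak). Spike phases are linear
interpolations of the *unwrapped* phase, avoiding ±π discontinuity
artifacts, then re-wrapped.

*PAC.* The modulation index is Tort's KL-based MI: γ amplitude is averaged
in 18 θ-phase bins, the profile is normalized to sum 1, and
`MI = KL(P‖uniform)/log 18 ∈ [0, 1]`. The estimator was chosen because
values of the magnitude reported for this preparation (~0.003) are
characteristic of the Tort MI; a mean-vector-length estimator is available
via `method="mvl"`. An empty phase bin raises an error advising a longer
signal rather than returning a biased value.

*Spike-phase locking.* `MRL = |mean(e^{iφ})|`, preferred phase is the
circular mean, and non-uniformity is the standard Rayleigh approximation
`p = exp(√(1+4n+4(n²−R²)) − (1+2n))`, clamped into (0, 1]. A unit is
classified phase-locked when `p < 0.05` **and** it has ≥ 20 spikes; the
low-n guard protects against the positive small-sample bias of the MRL.
MRL is also the "consistency" metric reported for spike-triggered rhythm
analyses. Spike-triggered averages drop spikes whose window would cross a
recording edge and report the usable count.

## The Barcode method

The pipeline characterizes recurring cross-regional co-activation motifs:

1. **Masked EMD** per region. For each mask frequency of a descending
   octave ladder (`fs/4, fs/8, …`, 8 rungs by default), the next IMF is the
   average of first IMFs sifted from `x + mask` over 4 equispaced mask
   phases (the masks cancel in the average); one refinement pass at the
   same frequency collects the ~10 % coherent remainder the first pass
   leaves. Sifting uses cubic-spline envelopes through extrema with
   mirrored end padding and an SD-style stopping rule (tol 0.2, ≤ 12
   iterations). Mask amplitude is 2× the running residual's SD. The sum of
   IMFs plus residual equals the input to floating precision by
   construction, and the decomposition is exactly scale-equivariant up to
   float rounding.
2. **Band assignment.** Each IMF joins the band containing its
   amplitude-weighted mean instantaneous frequency; IMFs between bands are
   dropped; multiple IMFs in one band sum their Hilbert envelopes. This
   rule is deterministic and bandwise-complete. A band with no IMF becomes
   a zero channel and is flagged.
3. **Amplitude matrix.** Channels are ordered region-major then band-order.
   Standardization divides by the per-channel SD *without* mean removal —
   envelopes are nonnegative and the ICA step centers features itself.
4. **Co-participation features.** Per non-overlapping 250-ms window, the
   window-mean channel vector `v` is expanded to the upper triangle
   (including diagonal) of `v·vᵀ`. The diagonal stays because the outer
   product's self-terms carry within-channel power. Window means (rather
   than point samples every 250 ms) reduce variance; this reading of
   "sampling every 250 ms" is an interpretation and is flagged as such.
5. **ICA.** Features are centered, PCA-whitened to `n_barcodes` dimensions
   (default 8; the original count is not reported), and unmixed by seeded
   fixed-point ICA (log-cosh contrast, deflation). **A barcode is the
   unit-norm, sign-fixed *pattern* of one independent component — the
   column of the fitted mixing matrix pulled back to feature space — not
   the unmixing filter row.** This is a deliberate design decision: under
   nuisance covariance an unmixing filter is reshaped away from the motif
   it detects (the classic filters-vs-patterns distinction), and planted
   motifs are recovered by mixing patterns at cosine > 0.9 where filters
   plateau near 0.5–0.9. Patterns are also what barcode grid graphics
   render. Sign is fixed by making the largest-|w| element positive.
6. **Strength and score.** Strength is the dot product of each barcode with
   the *raw*-amplitude co-participation features, one value per 250-ms
   window. The behavior score of a barcode is the ROC-AUC with which its
   per-epoch mean strength separates a positive condition (e.g. novel)
   from a contrast condition; 0.5 is uninformative. The score formula is
   this package's own definition (the original "score" is not specified).

ICA is fit per recording by default; concatenating subjects is the caller's
choice (stack their feature matrices before `fit_barcodes`).

## Decoding and forecasting

The familiar-vs-novel decoder follows the animal-wise protocol exactly:
each of `n_iter = 500` iterations draws a random 80 % of *subjects* as the
training set (so no subject's trials straddle the split), balances training
classes by random down-sampling, z-scores features on training statistics,
fits a linear SVM with C = 1, and pools accuracy over held-out trials.
Splits that leave a class empty on either side are redrawn (≤ 100 tries).
Rebalancing happens per iteration. The chance interval is `0.5 ± 2·SD` of
null mean accuracies from `n_shuffles = 100` label permutations *within
subject* (preserving each subject's class counts — a stricter null than
global shuffling); decoding is significant when the mean accuracy leaves
the interval. The SVM is solved in the primal by liblinear (squared-hinge,
L2, C = 1) through scikit-learn's solver binding, chosen so the full
500-iteration × 100-shuffle protocol runs in minutes on one CPU; a unit
test pins its solutions to the public `LinearSVC(C=1, dual=False)`
estimator.

Forecasting trains a seeded random forest (500 trees) on early per-subject
features against a later binary outcome (impaired = later discrimination
index below 0, configurable), with a subject-level 80/20 split, held-out
ROC-AUC, and confusion matrices at a 0.5 score threshold.

## Behavioral indices

`DI = (T_novel − T_familiar)/(T_novel + T_familiar)` over exploration
seconds summed from the event table; errors when both times are zero.
Habituation curves list per-presentation exploration seconds in time order;
dishabituation is the first novel presentation minus the last habituation
presentation before it.

## The synthetic cohort generator

Each region's LFP is `Σ oscillators + 1/f^α Gaussian noise`
(α = 1, σ = 15 µV). An oscillator is
`A(t)·cos(2πf·t + W(t))` with Wiener phase diffusion `W` (θ: 4, β: 12,
γ: 40 rad²/s), giving Lorentzian-ish band-limited lines so that coherence
below 1 and realistic linewidths are achievable. PAC is multiplicative on
the fast envelope, `A(t) = A₀(1 + m·cos(φ_θ − φ₀))`, matching the Tort
generative model. Spikes are inhomogeneous Poisson with the von Mises rate
`r(t) = r₀·e^{κ·cos(θ(t)−μ)}/I₀(κ)` sampled by exact thinning against the
ceiling `r₀e^κ/I₀(κ)`, so the expected rate is `r₀` for every κ and the
asymptotic MRL is the Bessel ratio `I₁(κ)/I₀(κ)`. The modulating phase is
the same band-passed Hilbert phase the analysis extracts.

Cross-region coherence is planted by two coupled mechanisms sharing one
knob `c` (the in-band shared power fraction): the 1/f noise of the linked
pair shares a band-limited common source (`X_r = √(1−c)·N_r + √c·S`, exact
in-band coherence magnitude `c`), and the pair's band oscillators are split
into a shared-phase part carrying power fraction `c` plus an independent
remainder. Oscillator lines alone cannot reach a band-mean coherence of
0.6 over a 59-Hz band because the bins away from the line are
noise-dominated; coupling both components makes the band-mean track `c`.

Co-activation motifs are planted by band-passing each loaded (region, band)
component and re-injecting it with envelope gain `1 + g·z(t)`, where `z` is
a rectified, smoothed Gaussian latent (SD 1.5, τ = 0.5 s) shared across the
motif's channels and nonzero only inside its activation epochs. The
generator records the motif's *co-participation signature* — the normalized
mean feature difference between active and inactive windows, computed from
its own Butterworth-envelope channels — so recovery tests compare the
masked-EMD/ICA route against an independently derived ground truth.
Activation epochs used in validation are independent random blocks:
mutually exclusive activations are statistically *dependent* sources and
measurably bias ICA.

Behavior: alternating novel/familiar exploration bouts whose
gamma-distributed durations encode a group DI target; bout means are scaled
to fit the recording duration while preserving the novel/familiar ratio.
The neural–behavioral link for decoding multiplies the OB θ component by
`1 + gain` inside novel epochs (control gain 0.35, lesion 0.05); `gain = 0`
gives the null world used for chance calibration. A separate
habituation–dishabituation generator produces decaying sniff-time sequences
with group-dependent rebound at odor switches.

### Group defaults and calibration

The control/lesion defaults encode the effect directions and magnitudes
characteristic of a unilateral 6-OHDA lesion preparation: OB γ power
21.5 → 19.2 dB, OB θ 34.8 → 32.0 dB, aPC θ 33.1 → 30.3 dB, LEC θ
34.5 → 37.2 dB, OB–aPC γ coherence 0.62 → 0.40, OB–LEC θ coherence
0.27 → 0.43, θ→γ MI 0.0034 → ~0.0018, doubled unit base rate (5 → 10 Hz),
γ locking κ 0.85 → 0.20 (≈ 75 % MRL reduction) with θ locking κ = 0.8 in
both groups, and NOR DI +0.31 → −0.085. The mapping from generator knobs to
*measured* values (oscillator amplitude → band dB including the 1/f
pedestal and the novelty gain; coherence knob → band-mean estimate; PAC
depth m → measured MI under envelope-noise dilution) was established once
by a simulation sweep and the resulting constants are frozen in
`simulate.py`; they are defaults describing the simulated preparation, not
tuning dials.

## What the validation shows — and does not

The test suite validates every estimator against planted truth: Bessel-ratio
MRL recovery, quadrature-oracle PAC with strict depth monotonicity, the
coherence–SNR closed form `msc = SNR/(1+SNR)`, exact EMD completeness and
two-tone separation, Hungarian-matched barcode recovery (all three planted
motifs at cosine > 0.9 in ≥ 8/10 seeds) with activation ROC > 0.8, decoding
chance-interval calibration (null cohorts inside the interval ≥ 95 %) and
power (planted d = 1.5 detected ≥ 90 %), forecast AUC bounds, and the
direction of every planted group effect at rank-sum p < 0.05 in an
8-per-group cohort.

The generator is a phenomenological stand-in, not a biophysical model: it
has stationary noise, sinusoidal carriers with diffusing phase, no
respiration-locked sniffing dynamics, no volume conduction or shared
reference artifacts, no electrode drift, and Poisson (not bursting) spike
trains. Passing tests therefore demonstrate that the estimators recover
what they claim *under the stated generative model*, with correct nulls and
calibrated error rates — not that real recordings satisfy that model.
Absolute dB levels, decoding accuracies and barcode counts on real data
will differ; the invariants (monotonicity, calibration, completeness,
equivariance) are the transferable guarantees.

## Problem sizes in the standard validation run

Validation problem sizes were chosen as the smallest that leave the
oracles' sampling error well inside the asserted tolerances: 600-s
recordings (~3000 spikes) for the locking oracle; 100-s signals for
PAC/coherence; 300-s, 3-region recordings for barcode recovery (10 seeds);
decoding calibration on 100 null cohorts (6 subjects × 10 trials/condition)
and 50 effect cohorts (14 subjects × 40 trials/condition) at 50
cross-validation iterations and 100 shuffles; the direction-of-effect
cohort at 8 subjects/group × 120 s. The acceptance script uses the same
machinery at slightly smaller counts and reports every quantity it
computes.
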