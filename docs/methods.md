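# Methods

This note documents the models, estimators and design choices behind
`eegcomplexity`, in the order the pipeline runs them.

## Band-pass filtering

Each channel is filtered into δ 1–4, θ 4–8, α 8–13, β 13–30 and γ 30–45 Hz
with a linear-phase FIR band-pass designed by the window method (Hann
window, `scipy.signal.firwin`). The tap count is set from the narrower of
the two available transition regions — half the low band edge below, the
gap to Nyquist above — which keeps stopband attenuation at the Hann
window's ≈44 dB one octave outside the band. The odd-length symmetric
kernel is applied by centred FFT convolution, so the group delay is exactly
compensated (zero-phase: an in-band tone's input/output cross-correlation
peaks at lag 0) and output length equals input length. Tests check the
filter against an ideal FFT-zeroing oracle (in-band tone retained at
≥ 0.95 amplitude, out-of-band at ≤ 0.05).

## Tsallis entropy

The default estimator (`histogram_zscore`) z-scores the band-filtered
signal, histograms it into B equal-width bins spanning ±4 sd (outliers are
clipped into the edge bins, keeping bin widths bounded under heavy tails),
and evaluates S_q = (1 − Σ p_i^q)/(q − 1).

* **q = 2** by default. With q = 2 the statistic is 1 − Σ p_i², which has
  a closed form on uniform occupancy ((1 − 1/B), e.g. 0.75 for B = 4) used
  as an exact oracle; q is exposed in `TEConfig` and recorded with every
  result.
* **B = 100** bins: at the default 180 s × 1000 Hz epoch this leaves
  ≈ 1800 samples per bin in expectation.
* z-scoring makes the estimate invariant to amplitude scaling — the
  property that motivates entropy over band power, since tissue
  attenuation rescales amplitude but hardly shifts frequency content.
* A constant signal is defined to have entropy 0; optional
  `max_entropy` normalization divides by (1 − B^(1−q))/(q − 1).

A second estimator (`spectral_ratio`) applies the same functional to the
normalized, re-binned power spectrum, so complexity reflects the balance
of rapid versus slow oscillations rather than the amplitude histogram.
The estimator registry (`register_estimator`) accepts further variants;
all downstream code is estimator-agnostic. Absolute TE values depend on
the estimator and its settings, so only within-configuration comparisons
are meaningful.

## Relative band power

Band power is the variance of the same FIR-filtered signal used for
entropy (tests confirm agreement with periodogram integration within a few
percent); relative BP divides by the sum over the five canonical bands, so
fractions add to one and are scale-free. The five-band denominator is a
deliberate choice — it makes the quantity a closed composition rather than
depending on an arbitrary total-power bandwidth.

## Regions of interest

Electrodes map to ten scalp regions (frontal/central/parietal/temporal/
occipital × left/right) through an explicit lookup table; no geometric
inference is attempted, and electrodes labelled `excluded` (neck, ears,
cheeks in real montages) are skipped everywhere. ROI **means** feed the
eyes-closed→eyes-open transition contrasts; ROI **medians** feed the
extreme-group regional summaries; the **global median** over all included
electrodes is the per-subject scalar entering the decline regressions.
Preprocessing (artifact removal, re-referencing, bad-channel handling) is
out of scope: the package assumes cleaned, condition-segmented input and
does not re-reference, so users must not double-reference upstream data.
Recordings shorter than 170 s are rejected; 180 s is the reference epoch
(between 170 and 180 s the entropy estimates are indistinguishable in
practice, which the epoch-robustness test asserts at < 2 %).

## Reliable change

For test t with reliability RS_t, SE_M = sd_baseline·√(1 − RS),
S_diff = √(2·SE_M²), RCI = Δscore / S_diff. Choices the formula leaves
open:

* **Baseline SD source**: the analysis cohort's own observed baseline SDs
  (per test), overridable with external norms.
* **Direction**: results are reported decline-positive. Tests where a
  higher score means better performance are sign-flipped before averaging;
  latency/omission tests enter unflipped. The convention is recorded in
  the result object.
* **Aggregation**: per-test RCIs average into the four domain scores
  (attention, executive, visuo-constructive, working memory), and the
  overall RCI is the mean of the domains — legitimate because the RCI is
  already standardized. A subject with no observed test in a domain gets a
  missing overall RCI; missing values are never silently zeroed, they flow
  to the imputation stage.

## Multiple imputation and pooling

Missing score entries are imputed by chained equations: each incomplete
column is regressed on all other columns with a Bayesian linear model
(posterior draws of coefficients and residual variance), and missing cells
are filled by predictive-mean matching (k = 5 donors), which keeps
imputations on the observed support. The regressions are ridge-stabilised
(λ = 10⁻³ on standardized predictors) so the wide panel — 16 tests × 3
visits = 48 columns against ~42 subjects — remains well-posed. Five sweeps
per imputation, m = 20 imputations, all deterministic given the seed. The
imputer is implemented in-house so the vote and pooling logic are testable
hermetically; its limiting behaviour is pinned by tests (no missing data →
input returned exactly; MCAR linear data → slope recovered within pooled
error; 0 % missingness → complete-data OLS to 10⁻⁶).

Two imputation levels are provided: `score` (impute raw scores, then
compute RCIs per completed dataset — the default, matching the principle
that every available test at every visit informs the fill-in) and `rci`
(impute the 16 per-test RCIs directly — statistically close and an order
of magnitude cheaper, used for replicated simulations).

Confounder selection runs per imputed dataset: forward stepwise from the
forced EEG predictor over {age, education, sex, disease duration, LED,
sleepiness}, adding the candidate with the smallest partial-F p while it
is below α_enter = 0.05 (the entry criterion is not separately specified
anywhere, so the analysis α is reused). A confounder enters the final
model only if selected in a strict majority (> m/2) of datasets — a tie is
not a majority. The predictor of interest is always forced in, never
competing with the confounders (the alternative — letting it compete — is
a one-line change but would make "predictor p-value" ill-defined when it
drops out).

Per-dataset OLS fits are pooled by Rubin's rules: Q̄ (mean estimate), W̄
(mean squared SE), B (between-imputation variance), T = W̄ + (1 + 1/m)·B,
with Barnard–Rubin small-sample degrees of freedom (appropriate at n = 42;
B = 0 reduces df to the observed-data value). Adjusted R² is reported as
the mean over imputations — a pooled-R² variant would also be defensible;
the label says which is used. LMG importance is computed exactly by subset
enumeration (R² over all 2^p submodels, increments weighted by
|S|!(p−|S|−1)!/p!), refusing p > 8; shares sum to the full-model R² by
construction and are averaged over imputations.

## Group statistics

Mann–Whitney U uses exact enumeration for combined n ≤ 12 without ties and
the tie-corrected normal approximation otherwise (via scipy, cross-checked
against a full enumeration oracle). Welch's t uses Satterthwaite degrees
of freedom. Holm–Šidák step-down adjustment is applied over the family of
all band × condition comparisons in one analysis call (the family is
configurable). Electrode-level pooled comparisons (thousands of electrode
values per group) treat non-independent within-subject values as
observations; this mirrors the target analysis and is flagged in the log,
with a subject-median variant available. Histogram comparisons between
unequal groups use proportions over shared Freedman–Diaconis edges.
Extreme-group summaries (top/bottom k = 10 by overall RCI, ties broken by
subject id) deliberately compute **no** hypothesis tests: conditioning on
extreme outcomes inflates significance.

## Stability resampling

Global band entropy is recomputed over n = 100 contiguous epochs of 180 s
placed uniformly at random in a longer recording (epochs may overlap —
unavoidable for 100 epochs in a ~400 s recording). The recording is
filtered once and epochs are sliced from the filtered signal. The report
carries mean, sd and CV; for stationary synthetic input the CV is far
below the 5 % bound the acceptance test asserts.

## The synthetic cohort

The generator's defaults are the emulated study design: 42 patients and 24
controls, 213 electrodes at 1000 Hz, 180 s per condition, 16 tests at
three visits with 5.5 % missing entries and m = 20 imputations downstream.

**EEG model.** Per region of interest: one narrowband Gaussian rhythm per
band (raised-cosine spectral shoulders) plus, in the theta band, K
independent *bursting* pacemakers — sinusoidal carriers gated by squared
slowly-varying Gaussian envelopes (knots every 1.5 s). A single bursting
source is intermittent and heavy-tailed (peaked amplitude density, low
Tsallis entropy); superposing K independent sources Gaussianizes the sum
with excess kurtosis ∝ 1/K, so entropy rises monotonically with the number
of pacemakers at fixed band power. K is the subject's latent theta
complexity (patients centred at 5 oscillators, controls at 8, sd 2).
Components are shared across a region's channels with channel-specific
gains (fixed by seed); each channel adds independent 1/f^β noise (β = 1,
total sd 3 µV against band amplitudes of 3.5–6 µV, so the θ-band noise
floor stays well below the oscillator power). In the eyes-open condition
α amplitudes are multiplied by `berger_factor` = 0.3. Because only α is
suppressed, relative θ power rises slightly on eye opening (the five-band
denominator shrinks); α was given a modest share (~0.12) so this
mechanical shift stays small — the α/θ dissociation the transition
contrast asserts.

**Latent structure.** EC and EO complexity latents share a common factor
with weight λ = 0.3 (corr λ² = 0.09). No study-prescribed generative value
exists for the within-subject EC↔EO correlation; λ is exposed, and the
default was chosen once so the eyes-closed pathway behaves as a near-null
in the decline regression. The 3-year decline (overall-RCI units,
decline-positive) is
`−0.8·z_EO + 0·z_EC + 0.25·z_age + 0.5·ε` — coupling through the eyes-open
latent only, a mild real age confound, and noise.

**Scores.** All tests are standardized (mean 100, sd 15); true score
change at horizon h converts from RCI units via S_diff per test, with the
sign following the test's orientation. Measurement error is sized so each
test's test–retest reliability equals its configured RS (verified
empirically within ±0.05 at n = 500). Missingness is MAR: the cell-wise
probability scales with observed disease duration only (normalized to the
configured mean rate), so the imputation model's assumptions hold by
construction.

**What the generator does not emulate:** volume conduction and field
spread, artifacts (blinks, ECG, muscle), non-stationarity across the
session, learning/practice effects in repeated testing, and genuinely
informative missingness. Passing tests therefore show the *analysis chain*
is correct and well-calibrated under the assumed data structure, not that
real EEG satisfies that structure.

## Problem sizes in tests and the acceptance script

Replicated simulations run at a reduced montage (10 electrodes, one per
region), 100 Hz sampling and 172 s per condition. These choices preserve
everything the statistics see — all five bands fit below the 50 Hz
Nyquist, the epoch is above the 170 s validity floor, and subject numbers,
missingness, coupling and m = 20 are unchanged — while making 50-replicate
power studies and 400-replicate type-I studies routine. The type-I study
additionally drives the inference chain with the latent complexity itself
in place of its EEG estimate: under the null the (separately tested,
monotone) estimation step cannot create an association, and skipping
signal synthesis is what makes ≥ 400 replicates cheap. The 213-electrode
cardinality checks run on signals at the reduced rate and duration.

## Known limitations

* The Tsallis estimator here is the package's own histogram formulation;
  published absolute TE ranges obtained with other estimators are not
  comparable and are not targeted.
* The imputer is a compact chained-equations implementation (Bayesian
  ridge + PMM), not a full reimplementation of any reference package;
  categorical variables beyond binary coding are unsupported.
* Exact LMG enumeration caps at 8 predictors; no sampling approximation
  is provided.
* Electrode-level group tests inherit the within-subject dependence of
  their design; treat those p-values as descriptive.
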