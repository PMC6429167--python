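# Methods

This note documents the models, numerical choices and limitations behind
`moodquant`, in the order the pipeline runs.

## Synthetic cohort model

The generator emulates the study design the analysis assumes: 9 subjects,
2 weeks, two resting-state forehead EEG sessions per day (morning and
evening) with a 40-item diary at each session.

**Latent mood trajectory.** For subject *s* at session time *t*:

    L(t) = baseline + trend(day(t)) + d·1[morning] + ε,  ε ~ N(0, σ_L²)

with baseline 10, week-1 slope −0.8/day (mood improves under therapy),
week-2 slope +0.8/day for "rebound" subjects (fraction 4/9 by default,
assigned deterministically to the first subjects) and −0.4/day otherwise,
diurnal amplitude d = 2 (mood is worse in the morning), and σ_L = 0.3 by
default. Higher latent = more depressed; the same sign convention is used
by the FPC orientation rule, so one convention holds end-to-end.

**Diary.** Item k scores `clip(round(50 + loading_k·L + noise), 1, 100)`.
Default loadings: +2.0 for depression–dejection items, +1.5 for the other
negative-mood categories, −1.5 for vigor and self-mood items; diary noise
sd 5 (the "low noise" study setting uses 2). Integer rounding means a
noiseless item correlates with the latent at r ≈ 0.998 rather than
exactly 1 — a property the tests assert at r > 0.995.

**EEG.** Per channel: unit-RMS 1/f-colored noise (spectral shaping of
white noise) scaled to 4 µV RMS, plus one sinusoid per band at the band
centers 3/6/12/24/48 Hz with amplitudes 8/6/·/4/2 µV and independent
random phases. The alpha amplitude is the coupling channel:

    A_alpha = max(6 + 0.8·coupling·L, 0.5) µV,

monotone in coupling·latent. Samples are quantized to a 12-bit uniform
grid over ±100 µV, emulating the stated ADC precision without modelling
the amplifier. The model is deliberately phenomenological — additive
oscillations, no blinks/EMG, no biophysics — sufficient for band-power,
wavelet and entropy features to respond to the latent. Passing the
recovery tests therefore shows the pipeline recovers a planted
band-power–mood coupling; it does not certify performance on clinical
EEG, where coupling is weaker, nonstationary and artifact-laden.

All randomness derives from `SeedSequence([seed, stream, subject,
session])`, so cohorts are bit-reproducible regardless of generation
order.

## Preprocessing

* Segments: 50 % overlap, half-open windows `[start, start+L)`, 0-based;
  trailing partial windows dropped, so a recording of N samples yields
  `floor((N−L)/(L/2)) + 1` segments per channel. Default segment length
  10 s (5120 samples): long enough for 2 Hz delta resolution and stable
  entropy estimates, short enough for ~59 segments per 5-min session.
* Denoising: 8-level `db5` DWT; soft shrinkage of all detail layers with
  the universal threshold σ√(2 ln N), σ = MAD(D1)/0.6745, applied
  level-independently. Threshold 0 reproduces the input to ~1e−12.
* Boundary handling uses **periodization** rather than symmetric padding:
  it keeps the transform exactly orthogonal, so the single-branch
  subband series sum back to the input and the branch energies add to the
  signal energy to 1e−8, properties the test suite relies on. The cost —
  wrap-around edge effects — is negligible for 10-s stationary segments
  whose length is a multiple of 2⁸.
* Subbands: single-branch inverse transforms of detail layers D3–D7,
  which at 512 Hz correspond to gamma/beta/alpha/theta/delta; D1, D2, D8
  and the approximation are kept as residual branches. Other sampling
  rates are rejected unless the caller explicitly opts out, because the
  layer↔band mapping is rate-specific.

## Feature catalog (176 per channel)

The four block totals (54/54/56/12) are met by this package's canonical
layout, chosen so every named feature of the rule vocabulary resolves:

* time (9 × 6 series): mean, std, min, max, p25, median, p75, excess
  kurtosis, skewness. "prctile" is read as the quartile triple. Constant
  series get kurtosis = skewness = 0 rather than an error.
* frequency (8 × 6 + 6 ratios): Welch PSD with 1-s Hamming windows, 50 %
  overlap (1 Hz resolution, ≥ 19 averages per 10-s segment); absolute
  power `<series>_psd` (integrated PSD — `alpha_psd` is the alpha
  subband's), relative power against the denoised 2–64 Hz total,
  peak/mean/median frequency, 95 % spectral edge, spectral entropy, PSD
  maximum; ratios beta/theta (relative and absolute — numerically equal
  because relative powers share one denominator, but both names are part
  of the catalog), theta/alpha, alpha/beta, (delta+theta)/(alpha+beta),
  gamma/beta. Zero-power denominators yield 0 with a warning.
* wavelet (11 × 5 layers + 1): statistics of detail coefficients CD3–CD7
  of the *denoised* signal (mean, std, min, max, median, sum, energy,
  kurtosis, skewness, max |·|, energy share vs all 8 detail layers), plus
  the wavelet entropy −Σ pⱼ ln pⱼ over the 8 layer energies (0 ≤ WE ≤
  ln 8). `original_<stat>_CD<j>` names are registered as aliases of the
  `denoised_` features, since the layers are computed from the denoised
  segment.
* nonlinear (2 × 6): C0 complexity (spectral threshold r = 5: components
  with |F|² ≤ r·mean are the irregular part; C0 = irregular power /
  total power) and approximate entropy ApEn(m = 2, r = 0.2·sd), standard
  template-matching with self-matches and Chebyshev distance. ApEn is
  quadratic in length and is computed on the first 1024 samples of each
  series (a common series length for ApEn at m = 2); the cap is a
  parameter of `ExtractionParams`.

Whether the published 176 dimensions are per channel or pooled is
ambiguous; per-channel is adopted because the rule vocabulary conditions
on specific electrodes. Session-level vectors are unweighted means of
segment vectors.

## FPC curve

Columns are centered but not variance-scaled (all items share the 1–100
scale). The top eigenvector of the covariance is taken via PCA; the sign
is fixed by requiring a non-negative mean loading on depression–dejection
items (duplicating the data cannot flip it). Weeks for the diurnal and
trend summaries are 7 × 24 h blocks from the subject's first session
(no calendar anchor exists). Weekly least-squares slopes classify the
curve: declined (s₁ < 0, s₂ ≤ 0), rebounded (s₁ < 0, s₂ > 0), otherwise
"other"; slopes below 1e−12 relative magnitude are treated as zero so
numerically flat curves do not misclassify.

## Regression and validation

Features are z-scored with statistics fitted on the training partition
only (the standardizer travels with the model; a canary test checks no
test statistics leak). Trees are scikit-learn CART regressors grown to
full depth on bootstrap resamples with `mtry` candidate features per
split, then flattened to plain arrays that both `predict` and the rule
engine traverse — this is what makes rule application bit-identical to
prediction. Bootstrap stays on even for ntree = 1 ("forest" implies
bagging); a switch disables it for deterministic unit tests.

Channel mode defaults to `concat` (352 columns, `fp1__`/`fp2__`
prefixes); `fp1`, `fp2` and `mean` are available. LOPOCV iterates
subjects in sorted order; subjects with < 3 sessions are skipped with a
warning (their correlation is undefined); constant held-out predictions
score CC = 0 with a warning rather than erroring. The p value is the
two-sided t-test on n−2 degrees of freedom.

Grid search: ntree ∈ {1, 11, …, 491}, mtry ∈ {1, 6, …, 96}; winner by
maximum mean CC, ties by minimum mean p, then smaller ntree, then smaller
mtry. The reduced grid {1, 101, 241} × {1, 16, 66} is a strict subset of
the full grid's cells, so its winner equals the full grid's restricted
winner by construction.

## Rule export

Left branches (x ≤ threshold) render `lessThanOrEqual`, right branches
`greaterThan`; ties go left, matching the trees. Only the `greaterThan`
clause appears in published exemplars (which show a simplified single
chain); the `lessThanOrEqual` spelling for the other branch is this
package's convention. Thresholds and leaf values are rendered with full
`repr` precision so `parse(render(rule)) == rule` and rule application
equals prediction exactly, with no floating-point divergence. Multi-tree
models export one rule group per tree; the file header documents that the
forest output is the mean of the fired leaf values. The annotation export
is a flat CSV + triple-style text (feature — source — electrode —
description); a full OWL ontology and a live reasoner are out of scope,
the flat export preserves the leaf-level content.

## Reference study sizes

The acceptance study runs the full design (9 subjects × 14 days × 2
sessions/day) with coupling 3.0 and diary noise 2 ("strong coupling, low
noise"), against a coupling-0 null. Per-session EEG duration is 20 s
(three 10-s overlapping segments per channel) instead of the full 5 min:
session features are segment averages either way, and 20 s keeps the
~500-recording study tractable on a single CPU without changing the
cohort design. With these conditions the study achieves LOPOCV mean CC
≈ 0.99 and the null stays ≈ 0.15 mean |CC|.

## Known limitations

* The EEG generator has no artifacts, nonstationarity or inter-subject
  variability in the coupling map; recovery numbers are upper bounds.
* The layer↔band mapping and the Welch defaults assume 512 Hz.
* The CLI's `fpc` output persists the curve values but not the loading
  vector; downstream pairing needs only the values.
* `beta_theta_rel_ratio` and `beta_theta_abs_ratio` coincide numerically
  by construction; both exist because both names are part of the catalog
  contract.
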