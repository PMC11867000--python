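# Methods

This note documents the models, estimators and design decisions behind
`neurocrit`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the synthetic-data tests do
and do not establish about real recordings.

## Narrowband decomposition

Parcel time series are filtered with complex Morlet wavelets

w(t) = C · exp(−t² / 2σ_t²) · exp(i·2πft),  σ_t = m / (2πf),

with width parameter m = 5 by default, truncated at ±3σ_t and normalized to
unit L2 energy. The default filterbank places 32 center frequencies
log-equidistantly between 2 and 90 Hz. The amplitude envelope is the modulus
of the same-length convolution; a `valid_range` excluding ±3σ_t at each edge
is attached to every envelope and honored by all downstream estimators, so
filter edge transients never enter a DFA or fE/I window. The exact
normalization and truncation of the wavelet are implementation choices (only
m is externally fixed); both only affect the envelope by a global scale and
an edge margin, and both estimators are scale-invariant.

The wavelet power spectrum assigns each grid frequency the mean squared
envelope over the valid range and normalizes each parcel's spectrum to sum
to one over the grid — "normalized PSD" here means sum-to-one per parcel,
making spectra comparable across subjects with different absolute signal
scales. The alpha-peak estimator searches a configurable band (default
7–13 Hz) for a local maximum of the parcel-mean spectrum and flags the
result when the in-band spectrum is monotone (band-edge argmax), since an
edge "peak" usually means there is no alpha peak to find.

## DFA

For an envelope A(t) sampled at fs, the profile is the cumulative sum of
A − mean(A). Ten log-spaced window sizes span the fit range (default
2–25 s); windows overlap 50%; each window is linearly detrended; F(s) is
the square root of the residual variance pooled across windows (pooled RMS
rather than mean-of-RMS — the two differ negligibly for the window counts
used, and pooling weights every sample equally). The exponent is the slope
of log₁₀F vs log₁₀s under iteratively reweighted least squares with Tukey
bisquare weights (tuning constant 4.685, ≤50 iterations, tolerance 1e-8).
The robust fit can differ from an ordinary least-squares slope by a few
hundredths on single realizations whose log–log plot has one outlying
window size; the test suite therefore validates the fluctuation function
against a brute-force oracle at OLS-slope precision and the robust exponent
at a wider band.

Calibration (reproduced by `scripts/acceptance.py` and the test suite):
i.i.d. Gaussian envelopes yield a mean exponent of 0.50 (±0.03 over 50
realizations of 300 s at 250 Hz); fractional Gaussian noise with
H ∈ {0.6, 0.75, 0.9} is recovered within ±0.1; the cumulative sum of white
noise gives the Brownian limit ≈ 1.5.

## fE/I

Windows of 40 oscillation cycles (length round(40·fs/f) samples, 80%
overlap) each contribute a mean amplitude w_amp and a normalized detrended
fluctuation w_nF: the cumulative sum of the demeaned window amplitude is
divided by w_amp, linearly detrended, and its SD taken. Then
fE/I = 1 − r(w_amp, w_nF) with r Pearson's correlation. Zero-amplitude
windows are dropped with a logged warning; fewer than 20 usable windows is
an error. The 80% overlap follows the measure's reference implementation;
halving it changes single-realization values by less than their seed-to-seed
spread (the windows are strongly autocorrelated either way, so overlap
mostly trades variance for sample count). w_nF is computed from the whole
window, without sub-window aggregation.

Values are only interpretable near criticality: any parcel × frequency cell
whose DFA exponent does not exceed 0.6 is masked invalid (NaN), excluded
from every average, and the count of valid cells is reported alongside
whole-brain means.

## Frequency bands and aggregation

The band registry defaults to theta 4–7, alpha 7–12, beta 12–30 Hz with
half-open membership [lo, hi), so 12 Hz belongs to beta. (Published figure
panels are inconsistent about the beta upper edge — 22 vs 30 Hz; the
registry follows the wider definition used for feature construction, and is
configurable.) Band averages exclude invalid cells; an all-invalid group is
NaN rather than silently zero.

## Synthetic data

The generator's purpose is parameter recovery: signals with *known* Hurst
exponents and *known* amplitude–fluctuation coupling, so the estimators can
be tested against ground truth.

**fGn.** Fractional Gaussian noise is generated exactly by circulant
embedding: the 2n-point circulant extension of the closed-form fGn
autocovariance is diagonalized by the FFT and Gaussian noise is shaped by
the eigenvalue square roots. The embedding is positive semidefinite for fGn;
a clipping fallback with a warning guards the general case. Exactness is
verified by ensemble autocovariance tests. Note that *sample*
autocorrelations of a single long-memory realization are biased downward
when the sample mean is subtracted; validation uses known-zero-mean
estimators.

**Oscillation.** A carrier sin(2πf₀t + φ) is modulated by the envelope
exp(σ·fGn(H)) with σ = 0.25, plus a 1/f background at a configurable
oscillation-to-background ratio (default 5). The lognormal map is the right
null construction for fE/I: it is multiplicative, so a window's absolute
fluctuation scale tracks its amplitude level and the *normalized*
fluctuation is level-independent — the uncoupled regime then sits at
fE/I ≈ 1 by construction. (A shifted-linear map 1 + σ·fGn was evaluated and
rejected: its absolute fluctuation is level-independent, which makes
normalized fluctuation fall with amplitude and biases fE/I to ≈1.15. The
lognormal map's residual convexity bias is O(σ²) ≈ 0.01 at the default σ.)

**Coupling.** The coupling parameter γ rescales each 40-cycle window's
deviations around its own mean by exp(γ·z), where z is the z-scored window
amplitude. γ = 0 is the exact identity — no extra noise is injected, so the
uncoupled regime inherits the envelope's scaling structure unchanged (DFA
recovers H, fE/I ≈ 1). γ > 0 amplifies fluctuations in high-amplitude
windows (fE/I < 1, inhibition-like), γ < 0 in low-amplitude windows
(fE/I > 1, excitation-like); ±0.5 are the canonical regimes and give 100%
sign-correct fE/I in the calibration runs. An earlier design that *injected*
window-scaled multiplicative noise was abandoned: lognormal noise injection
couples a window's realized mean and spread through convexity even at γ = 0
(biasing fE/I to ≈0.85), and the added short-memory noise diluted the DFA
exponent well below the Hurst target.

**Cohorts.** The feature-level mode samples per-subject DFA/fE/I maps
directly: a baseline DFA spectrum with a broad alpha–beta peak (≈0.72 at
11 Hz over a 0.58 floor) and a slightly inhibition-dominated fE/I baseline
(0.88–0.92), plus band-limited group shifts, a subject random effect
(SD 0.03) and frequency-smoothed parcel noise (SD 0.04). Default group
shifts encode the direction of the published effects — alpha/beta DFA
attenuation ordered HC > SCD > MCI, elevated fE/I in MCI, a small
(sub-significance) fE/I decrease in SCD — with magnitudes (0.01–0.05) chosen
once to produce clearly detectable but not saturated contrasts at the
published sample sizes (116/85/142); the source reports no numeric effect
sizes for these shifts, so they are configuration, not calibration.
Covariates (age, six medial-temporal-lobe volumes) are drawn from the
published group means/SDs; MMSE is generated with a positive dependence on
each subject's alpha DFA so criticality–cognition correlations exist by
construction. Cross-sectional MMSE group levels are not tabulated in the
source and follow standard clinical ranges. The signal-level mode generates
actual multi-parcel time series (default fixture scale: 20 parcels, 120 s at
250 Hz, one carrier) with group-dependent Hurst and coupling, and produces
the same direction of contrasts through the full estimation chain; the
400-parcel × 32-frequency study scale is not desk-feasible at the signal
level, which is why the feature-level mode exists. The longitudinal
generator produces stable (n = 22) and progressive (n = 23) MCI subcohorts
at two timepoints, with follow-up shifts only in the progressive group and
MMSE drawn from the published subcohort summaries.

What passing tests on these cohorts establish: that the estimators recover
planted parameters, that the statistics detect planted contrasts at
plausible effect sizes and stay calibrated under the null, and that the
classification protocol is leak-free. What they do not establish: anything
about real MEG — the generator has no cross-parcel correlation structure,
no 1/f-exponent differences between groups, no artifacts, and Gaussian
covariates.

## Group statistics

Whole-brain analysis runs a Kruskal–Wallis omnibus (tie-corrected,
chi-square reference) per frequency across the three cohorts plus pairwise
rank-sum contrasts; parcel-level analysis runs pairwise contrasts per
parcel × frequency. BH-FDR is applied per family — whole-brain families at
q = 0.1, the single parcel-level family spanning all parcels × frequencies ×
contrasts (400·32·3 = 38,400 tests at full scale) at q = 0.2 — followed by
an alpha screen (0.05/0.01) on adjusted p-values. The published verbal
description of the correction ("dividing by total number of tests, then
multiplying by q") is not a coherent procedure; standard step-up BH is
implemented and validated against a literal brute-force step-up oracle.
Effect sizes: η² = (H − k + 1)/(n − k) for the omnibus and r = |Z|/√N for
pairwise contrasts (the source reports only thresholds for both, not
formulas; these are the standard rank-based definitions). "Wilcoxon test"
between cohorts means the independent-samples rank-sum test except where
paired samples are explicit (longitudinal within-group contrasts); both
forms are exposed. Exact p-values are used for small samples without ties.
Confidence intervals use the percentile bootstrap of the mean with 10,000
resamples. Spearman correlations optionally partial out a covariate by
residualizing the *ranks* on it by least squares (linear-on-ranks, matching
the rank-based context); summary t-tests use the pooled-variance Student
form with df = n₁ + n₂ − 2.

## Classification

Features: DFA and fE/I averaged per (band × functional system) over a
parcel mask — 2 × 3 × 7 = 42 functional columns — plus six MTL volumes.
The mask defaults to parcels with a significant (uncorrected, rank-sum)
pairwise contrast *derived from training rows only*; the published protocol
derives masks from group statistics without describing train/test
separation, which is a leakage risk, so the train-derived mask is the
default and an all-parcels mask is available for comparison. Z-scoring
parameters and the mRMR ranking are refit inside every leave-one-out fold.

mRMR uses the mutual-information-difference scheme on equal-frequency
discretized features (√n bins). The kNN grid search reads "10 < k < 20" and
"5 < Nf < 35" as strict integer bounds (k ∈ 11…19, Nf ∈ 6…34), scores each
cell by leave-one-out AUC on the 75% training split (stratified,
seed-controlled), and breaks ties toward fewer features then smaller k. The
LOO implementation accumulates squared distances over mRMR-ranked feature
prefixes — a rank-1 update per added feature — and is verified to equal
brute-force per-row refits exactly. Held-out evaluation reports accuracy,
balanced accuracy, precision, recall and trapezoid AUC of the
neighbor-fraction score; fitted models carry the training subject ids and
refuse to evaluate overlapping test rows. Feature attribution uses
permutation importance (mean held-out AUC drop over shuffles) rather than
SHAP. Under label permutation the mean LOO AUC carries a small pessimistic
bias of order 1/(n−1) — deleting a row underrepresents its own class among
the neighbors — which is visible at toy sample sizes and negligible at the
cohort sizes used.

## Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng` seeded per stage
  (SHA-256 of run seed + stage name), making every artifact byte-stable
  under a fixed seed.
- Degenerate inputs fail loudly: too-short signals name the required
  length, empty bands name the band, schema-mismatched files name both
  versions, and config validation names the offending field.
- Robust-fit degeneracy (exact linear log–log plots) falls back to uniform
  weights; zero-variance correlation inputs yield NaN ("undefined-marked")
  rather than raising.
- Default problem sizes in tests and the acceptance script (e.g. 300-s
  surrogates, 50–100 seeds, a 100-parcel variant of the 343-subject
  end-to-end run) were chosen as the smallest sizes at which the Monte-Carlo
  error is comfortably inside each tolerance.

## Known limitations

- The fE/I null calibration (fE/I = 1 at γ = 0) is a property of the
  lognormal envelope construction; envelopes with heavier tails or
  level-dependent volatility would shift the uncoupled baseline.
- The lognormal map preserves the *order* of autocorrelations, not their
  exact values, so DFA recovery of H from the oscillation generator is
  approximate (well within ±0.1 at σ = 0.25).
- Feature-level cohort maps are sampled, not computed from signals, so they
  bypass the filter/estimator chain; the signal-level mode covers that
  chain at reduced scale.
- No cross-parcel dependence is modelled; parcel-level FDR calibration on
  synthetic cohorts is therefore an independent-tests scenario, more
  benign than real spatially correlated maps.
- Real-data ingestion is limited to the HDF5/CSV containers; no sensor-space
  preprocessing, source reconstruction or volumetry is included.
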