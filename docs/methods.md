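# Methods

This note records the models, conventions and design choices behind
`ushrv`, in the order data flow through the pipeline.

## Data model

An RR series is an ordered sequence of strictly positive inter-beat
intervals in milliseconds. Beat times are derived, not stored: t₀ = 0 at
the first beat and tᵢ = tᵢ₋₁ + rrᵢ/1000 (seconds), so the run duration
equals Σrr/1000. Interval rrᵢ is attributed to the span (tᵢ₋₁, tᵢ].
No ectopic-beat or outlier-RR correction is applied: the package
consumes RR series as given, and cleaning is the caller's concern.

A study is a set of runs with unique (subject, run) labels. Runs enter
the reliability analysis only if strictly longer than the reference
window (180 s by default); the filter is strict so that every surviving
run hosts more than one reference placement.

## Sliding windows

Windows cover half-open spans [k·step, k·step + w) advancing by a 1-s
hop; a run of duration D holds ⌊(D − w)/step⌋ + 1 placements of window
w. An RR interval belongs to a placement iff its whole attributed span
lies inside — intervals are never split and never counted twice within
a placement. Each measurement is stamped with the placement's center
time, so vectors from different window sizes share a common time axis.
On the default grid (180, 170, …, 10 s) all centers fall on the 1-s
lattice; for custom grids with half-step parity offsets, alignment
snaps to the nearest short-vector center, ties toward earlier time.

Segments with fewer than 4 RR intervals yield the undefined marker
(NaN) for all features — ApEn with m = 2 needs at least 4 points — and
undefined values are excluded pairwise from every statistic, with drop
counts logged. Whether a window must contain a minimum number of beats
is genuinely open; 4 is this package's floor and is applied uniformly.

## Feature bank

Thirty-one features, partitioned 6/3/6/16 over time, geometric,
non-linear and frequency domains. Conventions that materially affect
small windows:

* **Standard deviations** use the sample (N−1) denominator throughout
  (SDNN, SDSD, SD1, SD2). On 10-s windows (≈12 beats) the
  population/sample choice is material; the sample convention matches
  common HRV practice. Two identities follow and are tested:
  SD1 = SDSD/√2 exactly, and RMSSD² = ((N−2)/(N−1))·SDSD² + mean(d)².
* **SD1/SD2** are computed by direct 45° rotation of the Poincaré
  cloud, not via the SDNN/SDSD approximation, which can go negative on
  ultra-short alternating segments.
* **TI/TINN** use the standard 1/128-s (≈7.8125 ms) histogram bins
  anchored at 0. TINN's triangle base (M, N) is found by exhaustive
  search over bin-edge pairs bracketing the modal bin, apex fixed at
  the modal bin's center and height, minimizing summed squared error;
  a single-occupied-bin histogram gives TINN = 0.
* **SI** (Baevsky) uses a separate 50-ms histogram whose bins are
  *centered* on multiples of 50 ms; Mo is the modal bin center in
  seconds, AMo the modal percentage, MxDMn the RR range in seconds;
  SI = AMo/(2·Mo·MxDMn), undefined when the segment is constant.
* **ApEn** uses m = 2, r = 0.2·SDNN of the segment, Chebyshev distance,
  self-matches included — the conventional defaults.
* **PTM** is the mean Euclidean distance between consecutive Poincaré
  points: (1/(N−2))·Σ‖(d_i, d_{i+1})‖ with d the successive-difference
  series. This adopted definition is the simplest measure of
  point-to-point temporal variation of the Poincaré cloud and is
  labeled as such here.
* **KFD** follows the waveform convention (unit abscissa spacing):
  L = Σ|dᵢ|, d = max|rrᵢ − rr₁|, n = N−1,
  KFD = log₁₀n / (log₁₀n + log₁₀(d/L)). The denominator can approach 0
  on short alternating segments; the value is then capped (default 10,
  configurable) and flagged in the log. Constant segments are
  undefined.
* **HFD** uses kmax = min(8, ⌊(N−1)/2⌋) by default so the scale range
  adapts to the window size, with the standard
  (N−1)/(⌊(N−m)/k⌋·k) length normalization.
* **Spectra**: the tachogram (RR vs interval-end beat time) is
  cubic-spline resampled at 4 Hz across the window, mean-removed, and a
  Hann-tapered single-segment periodogram taken with density scaling
  (the integral over frequency recovers the detrended variance up to
  taper leakage). No Welch averaging: a 10-s window has too few samples
  to split. Frequencies below 1/w — which cannot complete a cycle
  inside the window — are discarded, so for a 10-s window the VLF band
  (upper edge 0.04 Hz, slowest period 25 s) is empty and its features
  undefined.
* **Band features**: bands are left-open/right-closed — VLF (0, 0.04],
  LF (0.04, 0.15], HF (0.15, 0.4] Hz — so they partition (0, 0.4].
  Band powers integrate the piecewise-linear PSD with interpolated
  values at the exact band edges; consequently totPow = VLF + LF + HF
  identically and the normalized powers (100·X/totPow) sum to 100 to
  machine precision. Total power is the normalization base for all
  three normalized powers so that VLFnu is well-defined. Band peaks are
  reported in Hz (the natural unit of a frequency location); the
  "normalized peak" is the PSD value at the peak divided by the summed
  PSD over (0, 0.4].

## Reliability statistics

* **Normality screen**: one-sample KS against N(0,1) on standardized
  values. Standardizing before a plain KS test biases the p-value
  upward (the Lilliefors caveat); the screen reports plain KS values
  as-is and is used only to justify non-parametric tests downstream.
* **Acceptance matrix**: per run and (feature, window), a two-sided
  Wilcoxon rank-sum test between the *full* short-window and reference
  vectors — the rank-sum test does not need equal lengths, so no
  alignment is applied here. The exact null distribution (full
  enumeration over C(n₁+n₂, n₁) allocations, tie-aware mid-ranks,
  two-sided p = min(1, 2·min(tails))) is used when both vectors have
  ≤ 10 values; otherwise the tie-corrected normal approximation.
  A cell is 100·(#runs with p > α)/(#runs tested), α = 0.05 by default
  and no multiple-testing correction — the per-cell percentages are
  descriptive; a Benjamini–Hochberg flag is deliberately out of the
  default path.
* **Correlation summary**: Spearman's ρ on aligned vectors per run
  (mid-ranks; exact permutation p for n ≤ 9, t-approximation above),
  then per cell the percentage of significantly correlated runs and
  the Fisher-z mean with weights nᵢ − 3, ρ clipped at 1 − 10⁻¹² before
  atanh. Runs with undefined ρ (constant vectors) or fewer than 4
  aligned pairs are dropped and counted, never imputed.
* **Trend regressions**: OLS on x = (180 − w)/10 ∈ {0…17}; constant
  responses get slope 0 and undefined R².
* **Bland–Altman**: aligned differences short − reference; bias is the
  median and the limits of agreement the 2.5th/97.5th percentiles
  (linear-interpolation definition), requiring ≥ 10 pairs. By
  construction the within-limits fraction sits in [0.94, 0.96] for
  n ≥ 200 i.i.d. differences.

The reference column of every summary is an identity by construction
(100 % acceptance, ρ̄ = 1, bias 0) and is asserted on every synthetic
study in the test suite.

## Synthetic generator

The generator emulates the target study class: ~21 subjects × up to 4
runs, durations 200–900 s, mean RR 600–1100 ms, LF and HF oscillatory
modulation, beat-wise Gaussian noise, optional piecewise segment shifts
emulating cognitive-load changes. Defaults: mean RR 800 ms, LF 30 ms at
0.10 Hz, HF 25 ms at 0.25 Hz, noise SD 15 ms — mid-band frequencies and
amplitudes giving clearly resolvable spectral peaks at physiological
variability levels.

Beats follow rrᵢ = mean + A_LF·sin(2πf_LF·tᵢ₋₁) + A_HF·sin(2πf_HF·tᵢ₋₁)
+ εᵢ with the clock advanced by the drawn interval. This beat-domain
modulation is an auditable approximation of integral-pulse-frequency
modulation: it places spectral peaks at the configured frequencies
(verified by the spectral-recovery tests) but does not model respiratory
physiology, baroreflex feedback or ectopic beats. Draws at or below a
250 ms floor are resampled and counted. Per-subject jitter (additive
mean-RR offset, multiplicative amplitude scale) and per-run seeds are
derived deterministically from the master seed by hashing the labels,
so studies are reproducible while runs stay independent. Configurations
that cannot produce reliably positive intervals
(mean ≤ A_LF + A_HF + 5·noise) are rejected up front.

What passing tests on this generator do **not** show: robustness to
artifact-laden or ectopic-contaminated recordings, to respiratory
nonstationarity, or to the heavier-tailed variability of real cognitive
load; the generator establishes correctness of the pipeline's
bookkeeping and statistics, not physiological validity of any
particular feature.

## Problem sizes

The test suite and the acceptance script run scaled-down studies chosen
to exercise every code path at interactive cost: one full 31 × 18
extraction on a 600-s run; parameter recovery on 3 runs of 220–280 s at
the 180-s window; type-I calibration over 500 replicates of 30/35-point
samples; degradation of mNN's Fisher-mean correlation on a 24-run study
(200–320 s) at the 180/170/10-s windows. The generator's own defaults
keep the full emulated scale (21 × 4, 200–900 s) for users who want it.

## Known limitations

* PTM's definition varies across the literature; the mean
  consecutive-point distance used here is one defensible choice and is
  flagged in this note rather than silently assumed canonical.
* The periodogram on very short windows (10–30 s) has coarse frequency
  resolution (Δf = 1/w); band peaks at those sizes quantize to a few
  attainable values.
* The KS screen's standardization bias is reported, not corrected.
* Exact rank-sum enumeration is limited to both n ≤ 10 (beyond that the
  tie-corrected normal approximation is accurate and fast).
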