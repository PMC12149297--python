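# Methods

This note records how each stage of the pipeline is defined, which choices
were genuinely open, and what the synthetic validation does and does not
establish.

## Preprocessing

Recordings are assumed to arrive already artifact-cleaned (the heavy
artifact removal — artifact subspace reconstruction, ICA component
rejection — belongs to dataset curation, not this package). The pipeline
then applies:

- **Band-pass 1–45 Hz**: 4th-order Butterworth, applied forward–backward
  (`sosfiltfilt`), i.e. zero phase. Zero-phase filtering is deliberate: the
  fractal estimators operate on waveform shape, which a causal filter would
  distort. Forward–backward application squares the magnitude response, so
  attenuation one octave outside the passband exceeds 40 dB.
- **Common average reference**: per-sample channel mean subtracted; a
  projection (idempotent).
- **Epoch selection**: the *earliest* contiguous 15 s window in which no
  sample on any channel exceeds ±100 µV. The amplitude criterion is the
  conventional scalp-EEG rejection threshold; the earliest-window rule is a
  convention — nothing in the data dictates where a clean epoch is taken,
  so per-subject values on real data can shift slightly with a different
  convention. The selection is invariant to data after the chosen window.
- **Narrowband 8–13 Hz** (for LRTC only): window-method FIR, 2 Hz
  transition width (Hamming, ≈3.3·fs/2 taps, forced odd), zero-phase via
  `filtfilt`. The Hilbert amplitude envelope is trimmed by 1 s per side,
  which exceeds the FIR group delay (0.83 s at 500 Hz); a seed-matched
  comparison of 1 s vs 2 s trims showed no measurable difference in
  downstream DFA exponents, so the cheaper trim is kept.

## Relative band power

Welch periodograms with 2 s Hamming segments and 50% overlap give 0.5 Hz
native resolution; the public `power_spectrum` re-grids to 1 Hz steps by
bin summation. Band powers integrate the native bins with half-open edges
(δ [1,4) … γ [30,45] closed), so every bin belongs to exactly one band and
the five relative powers sum to 1 to machine precision. Normalisation is
by the five-band union (1–45 Hz), making the ratios scale-invariant.

## Fractal dimension

Both estimators see the broadband (1–45 Hz) epoch.

**Box counting.** Each channel is normalised to the unit square (time →
[0,1], amplitude min–max → [0,1]); for box sizes ε = 2⁻ʲ the number of grid
boxes crossed by the linear interpolant is counted (per time column, every
box between the column's min and max is crossed, by continuity), and FD is
the least-squares slope of log N(ε) vs log(1/ε), clamped to [1,2]. The
ladder runs j = 1…⌊log₂N⌋−4: at finer scales the interpolant is resolution
limited (locally straight between samples), which drags the apparent slope
toward 1; stopping four octaves above the sample spacing removes that bias
(white noise then measures ≈1.87 rather than 1.84). Constant signals
return exactly 1 and are flagged degenerate.

**Higuchi.** Mean curve lengths L(k) with the standard
(N−1)/(n_mk·k²) normalisation; FD is the slope of log L(k) vs log(1/k).
The step grid is every integer up to kmax ≤ 64, else integers 1–16 plus 25
log-spaced values, bounding cost at O(N·|k|). kmax is valid whenever every
offset contributes at least one increment (kmax ≤ N/2) — this matters
because the windowed estimator runs kmax = 126 on 1 s windows at 500 Hz.
Per-epoch values are means over non-overlapping 1 s windows (trailing
partial window dropped); box counting uses the whole epoch, matching the
two estimators' conventional usage. Defaults: kmax 126 at 500 Hz, 32 at
128 Hz.

**kmax scan.** For kmax selection the cohort curve (19-channel-average HFD
per subject at each tested kmax) is computed once on the union step grid
and refitted per kmax; the selected value is the tested kmax whose
across-subject mean is closest to the median of the curve (ties to the
smaller kmax). "Corresponds to the median HFD" is ambiguous between this
reading and a per-kmax median across subjects; the implemented rule is
recorded in the scan output so the convention is auditable.

## DFA of the alpha envelope

The envelope is mean-centred and cumulatively summed; for each window size
n the profile is segmented at 50% overlap, each segment linearly
detrended, and F(n) is the mean RMS residual. Window sizes are 10
log-spaced (base-10) values spanning 0.8–30 s — "10 windows" is read as 10
window *sizes*, the toolbox convention for this parameter — and α is the
log₁₀F vs log₁₀n slope restricted to 2–25 s (six sizes fall inside), with
the fit's RMS residual reported as a power-law goodness diagnostic. Linear
(order-1) detrending. Sizes shorter than 4 samples are skipped with a
warning. An explicit size grid can be passed where a different convention
must be matched.

Calibration (seeded, 300 s at 500 Hz): direct DFA gives α = 0.500 ± 0.03
on white noise, ≈1.0 on pink noise, and recovers fractional-Gaussian-noise
Hurst exponents over H ∈ [0.6, 0.9] with |bias| < 0.05. The full pipeline
(filter → envelope → DFA) on white noise yields α ≈ 0.55 rather than
0.500: the Hilbert envelope of 5 Hz-wide noise carries ≈0.2 s short-range
autocorrelation, which inflates the fluctuation function at the short end
of the fit range — the familiar finite-window DFA crossover. The local
log–log slope of the averaged fluctuation function decays monotonically
(≈0.60 across 2.7–6 s windows, ≈0.52 at 20–30 s), so a fit over 2–25 s
mixes the biased short windows in. This is a property of the procedure
(an ideal circularly band-limited envelope with no filter edges
reproduces it), not of the implementation; envelope-based exponents near
0.5 should be read as "white-noise-like" with that ≈+0.05 floor offset in
mind.

DFA requires 300 s of data and is automatically skipped (with a manifest
log entry) for shorter recordings; the 128 Hz/8 s dataset dialect forbids
it outright.

## Group statistics

Regional summaries are arithmetic means over the fixed rostral/caudal
7-channel sets; asymmetry = rostral − caudal (positive = rostral
dominance). ANOVA reports standard degrees of freedom (k−1, N−k) and
r² = SSB/SST. Tukey HSD adjusted p-values come from the studentized-range
distribution; the pairwise pooled t (df = n₁+n₂−2) and Cohen's d (pooled
SD) are reported alongside because those are the quantities conventionally
printed next to the adjusted p. Pillai's trace is computed directly from
the eigenvalues of W⁻¹B with the standard F approximation; because the
five relative powers sum to 1 their covariance is singular, so the joint
band-power MANOVA drops gamma and tests the four remaining bands.
Mann–Whitney U uses the min(U₁,U₂) convention with exact p where scipy's
policy allows and the tie-corrected normal approximation otherwise.
Channelwise t-maps apply Benjamini–Hochberg correction within each
metric × comparison family of 19 channels — not pooled across families.
D'Agostino–Pearson normality is computed as a reported diagnostic only; no
automatic test switching is performed (dataset-2-style analyses opt into
Mann–Whitney via configuration).

## Synthetic cohorts

`gen_cohort` emulates the statistical structure the analysis targets, per
channel: band-limited Gaussian noise per canonical band scaled by the
group's amplitude profile; an arrhythmic 1/f^β "backbone" confined to
1–45 Hz with the alpha band notched out; an alpha carrier (9–11 Hz,
subject-specific) amplitude-modulated by fractional Gaussian noise whose
Hurst exponent is set per region and group; and a 0.3 µV white sensor
floor. fGn/fBm use exact Davies–Harte circulant embedding, so Hurst
targets are unbiased. Determinism is per-subject: seeds are spawned from
the master seed, and regeneration is bit-identical.

Two implementation details matter and were found the hard way: the
backbone must be band-limited to the analysis band, because a unit-variance
power law with β > 1 concentrates its variance below the 1 Hz high-pass
edge in proportion to record length (a 300 s record would silently lose
the planted complexity structure); and it must be notched out of 8–13 Hz
so the planted envelope Hurst exponents are not diluted by arrhythmic
in-band noise.

Default profiles plant the dementia-EEG pattern: patient-like groups raise
δ/θ and suppress α amplitudes, steepen the backbone (smoother signal,
lower FD), and lower envelope H (0.78 → ~0.71 rostral / ~0.66 caudal); the
rostrocaudal complexity gradient — carried jointly by a slope (β ± 0.4)
and an amplitude (±0.2) gradient, since box-counting FD responds weakly to
slope alone — has opposite sign for the AD-like (rostral FD dominance) and
FTD-like (caudal FD dominance) groups. Subject jitter (log-normal σ = 0.3
on amplitudes, σ = 0.1 on β, σ = 0.06 on H) sets planted contrasts at
Cohen's d ≈ 1–2.5 for n = 20 per group, the scale at which such cohort
effects are typically reported. Group sizes default to 20/20/20 at 500 Hz
and 300 s, which keeps the full end-to-end validation a few minutes of
compute.

What passing synthetic tests shows: the estimators recover planted
spectral, fractal and scaling structure at realistic effect sizes, and the
statistics detect it. What it does not show: robustness to volume
conduction (channels are generated independently — no leadfield), real
artifact topographies, non-stationarity across the recording, or
inter-channel correlation structure; conclusions about real cohorts still
require real data.

## Numerical conventions and degenerate inputs

Constant signals: FD reported as 1 (flagged); DFA raises (no power law to
fit, F(n) ≡ 0). Relative band power of an all-zero channel is NaN. Epoch
selection failures and any per-subject stage error are logged in the run
manifest and do not abort the cohort; the pipeline exits nonzero if any
subject failed. All result tables are written with fixed float formatting
and hashed into the manifest, so identical config + inputs give
byte-identical outputs.

## Known limitations

- Box-counting FD compresses differences near the top of its range; group
  contrasts in the 1.7–1.8 region are detectable but small in absolute
  units (the asymmetry index works on differences of ≈0.01–0.05).
- Envelope-based DFA has the ≈+0.05 white-noise floor discussed above;
  comparisons between groups are unaffected, absolute values should not be
  over-read.
- The EDF writer emits minimal 16-bit EDF (±1000 µV physical range, 1 s
  records, integer sampling rates); it is meant for interchange of cleaned
  data, not raw clinical archives.
- EEGLAB `.set` support covers the common single-file, old-style MAT
  layout.
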