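# Methods

This note records the models, conventions and numerical choices behind the
package, in the spirit of a statistics-package methods appendix: enough
detail to re-derive every default, and explicit about what the synthetic
validation does and does not establish.

## Preprocessing

EEG is band-pass filtered 1.5–60 Hz with a 4th-order Butterworth applied
forward–backward (`sosfiltfilt`), i.e. zero-phase; phase preservation
matters because the connectivity stage measures phase relations. The first
and last 30 s of each task recording are discarded (movement-artifact
guard). Artifact handling is a windowed amplitude-rejection stage: 1-s
windows in which any channel's peak median-centred amplitude exceeds 10
robust standard deviations (MAD × 1.4826) of that channel are dropped and
the survivors concatenated. The robust scale estimate means a spike cannot
inflate its own rejection threshold. This simple stage stands in for
subspace-reconstruction/ICA artifact chains, which target human artifact
classes (muscle, ocular, cardiac-field) that the synthetic data does not
contain; on real recordings it is a coarse filter, and the rejected
fraction is logged per subject and condition so its bite is visible.

## Spectral analysis and FAA

Spectra are Welch averages of Hann-tapered 2-s windows with 50% overlap and
density scaling, giving 0.5-Hz resolution and Parseval consistency (total
integral ≈ time-domain variance; verified to 5% in tests). Band power is a
trapezoidal integral over the band, relative to the 1–60 Hz integral. Two
band dialects are kept and selected explicitly by callers: the sensor
scheme (1–4/4–8/8–13/13–30/30–60 Hz), whose five bands tile 1–60 Hz so
relative powers sum to 1, and the source scheme
(1–3.5/4–8/8.5–13/13.5–30/30.5–60 Hz) used for ROI-level analyses. A
"spectral step" display parameter seen in some acquisition-software plugins
has no meaning at 0.5-Hz resolution and is deliberately not represented.

FAA = relative alpha (8–13 Hz) at F4 minus F3, on raw power fractions
(no log transform): relative power is used for its test–retest reliability
and scale invariance, and raw fractions keep scores in the small
(±0.01–0.05) range typical of asymmetry indices. Topographic contrasts
subtract each subject's mean across electrodes within a band before
testing, so maps show deviation topography rather than global power.

## Lorenz-plot HRV

From centred interval pairs, SD1 = sd((RRIₙ₊₁−RRIₙ)/√2) and
SD2 = sd((RRIₙ₊₁+RRIₙ)/√2), sample (n−1) SDs, equivalent to rotating the
Poincaré cloud by 45° and taking coordinate SDs (tested exactly against
that construction). Conventions that required a decision:

* **Axis pairing.** T = 4·SD1 (transverse) and L = 4·SD2 (longitudinal),
  so CSI = L/T = SD2/SD1. This is the Toichi formulation and the only
  pairing under which resting CSI exceeds 1 (typical values ≈ 2), as normal
  RR series have more slow than fast variability.
* **CVI logarithm.** CVI = log₁₀(L·T) by default. The natural-log variant
  appears in parts of the literature, but resting values near 4–5 (e.g.
  ≈ 4.2 at RRI ≈ 790 ms, SD1 = 20 ms, SD2 = 45 ms) are only produced by
  log₁₀ (ln would give ≈ 9.7). The base is switchable (`log_base`,
  pipeline option `cvi_log_base`).
* Degenerate geometry is flagged, never a silent infinity: CSI is NaN only
  when SD1 = 0 (an all-alternating series has CSI = 0 legitimately), CVI is
  NaN when either spread is 0.

Change scores are last-minute minus first-minute values, beats assigned to
segments by the time of the R-peak closing each interval. When reading RRI
text files an interval-range sanity filter (300–2000 ms) drops
non-physiological beats and reports the count; no interpolation of ectopic
beats is attempted. The optional R-peak detector uses adaptive amplitude
thresholding (half of peak amplitude, 250-ms refractory period) with two
plausibility guards (amplitude crest factor ≥ 5 robust SDs; median interval
≥ 300 ms) so that structureless signals raise an error instead of
returning noise intervals.

## Lagged phase synchronization

The phase-synchronization (unit-modulus) variant is used: within each 2-s
Hann window and each in-band frequency bin, Fourier coefficients are
normalised to unit modulus, and the complex coherency ρ of a pair is the
average of zᵢ·conj(zⱼ) over all window-bin samples. LPS = Im(ρ)²/(1−Re(ρ)²),
clipped to [0, 1]. When 1−Re(ρ)² < 10⁻¹², the pair is perfectly
synchronized at zero lag, carries no lagged component, and the value is
defined as 0.

Properties relied on downstream, all tested: exact symmetry, exact
amplitude invariance, suppression of instantaneous mixing to the
independent-noise bias level (bias |ρ| ~ K^(−1/2) for K window-bin
samples), and near-maximal response to pure delays. Two estimator
facts worth knowing: (1) averaging ρ across in-band bins means a pure delay
τ produces a phase ramp across the band; the band value is attenuated by
roughly sinc(π·Δf·τ), so delays beyond ~1/(2·bandwidth) self-cancel —
couplings are physiologically meaningful for lags of a few tens of
milliseconds; (2) windowed segment-edge mismatch adds further attenuation,
so a perfect 25-ms delay measures LPS ≈ 0.85–0.9 rather than 1.0. Tests
assert > 0.8 for this case.

## Statistics

* Routing: Shapiro–Wilk on paired differences at α = 0.05 → paired t
  (d = mean/sd of differences = t/√n) or Wilcoxon signed-rank (zeros
  dropped, mid-ranks for ties, W = positive-rank sum). The Wilcoxon p is
  exact (dynamic-programming enumeration of the null, verified against all
  2¹⁰ sign assignments) when there are no ties or zeros and n ≤ 25;
  otherwise the continuity-corrected normal approximation
  z = (|W − n(n+1)/4| − 0.5)/√(n(n+1)(2n+1)/24). Both modes are exposed
  because half-integer W values (tied ranks) rule out naive exact
  enumeration.
* Effect labels: d = 0.2/0.5/0.8 and r = 0.1/0.3/0.5 for
  small/medium/large, on absolute values. Tiers: p < 0.05 significant,
  0.05 ≤ p < 0.10 trend (half-open: exactly 0.05 is a trend, exactly 0.10
  is ns).
* BH-FDR: statsmodels' step-up implementation behind the module surface,
  verified against hand-applied step-up.
* Max-statistic permutation: per-site paired t with per-subject sign flips
  (condition contrasts) or per-site Pearson r with subject shuffles of the
  index (correlations); corrected p per site = proportion of permutations,
  plus the observed arrangement, whose maximum |statistic| over sites
  reaches the site's observed value. Corrected p is floored at
  1/(n_perm+1), never undercuts the site's own permutation p, and an
  exhaustive 2ⁿ mode exists for small n (used to validate the Monte-Carlo
  path to within 0.02). Zero-variance sites are flagged; the permutation
  seed is a required, logged parameter.
* Sample size: the normal-approximation closed form
  n = ⌈((z₁₋α/₂ + z_power)/d)²⌉ (32 at d = 0.5, α = 0.05, power = 0.80) is
  the default; an exact noncentral-t mode (statsmodels iteration, giving
  34) is available. An attrition-margin helper inflates n by a fraction
  (5% → 34).

## The synthetic cohort: what it emulates and what it does not

EEG channels are sums of band-limited processes — white noise zero-phase
filtered into each sensor band, normalised to unit variance, scaled by a
per-band amplitude (defaults 8/6/10/4/2 in delta/theta/alpha/beta/gamma,
arbitrary units) — plus 1/f background (SD 5). This matches the broadband
character of EEG and makes Parseval oracles straightforward: expected
relative band power is computable from amplitudes alone (filter-skirt
leakage keeps agreement to ~10% on dominant bands). The F3/F4 asymmetry
knob scales F4's alpha amplitude by (1+s) and F3's by (1−s).

ROI series are built the same way (source bands); a coupling
(a, b, band, lag, strength) replaces b's band component with
strength·delay(a, lag) + √(1−strength²)·independent noise, preserving
variance. Lag 0 produces pure zero-lag mixing, which LPS must ignore.

RR series are mean + slow AR(1) + fast white + linear trend. The AR(1)
coefficient φ is chosen adaptively: SD1² = σ²ₛ(1−φ) + σ²_w and
SD2² = σ²ₛ(1+φ) + σ²_w are solved for the component variances, with the
smallest feasible |φ| (1.1× the feasibility bound, floored at 0.6) so the
slow component stays short-memory and finite-series SD2 estimates stay
tight. Finite 400-beat series still estimate SD2 with ~7% sampling SD and
a small downward bias, hence the empirical 15% recovery tolerance,
calibrated by replicate pilots. A fast-spread trend (ms/min on the white
component's SD, pivoted at mid-series so whole-task indices stay at target)
emulates within-task autonomic drift; it moves CSI change without moving
total CSI.

The paired cohort applies condition effects additively on generator
parameters with Gaussian subject random intercepts — the simplest structure
under which paired tests are exactly appropriate. Defaults encode the study
conditions the pipeline targets: n = 31 subjects, 1000-Hz 19-channel
montage, ~4-min tasks, an FAA contrast sized near d ≈ 0.5 around a small
negative baseline (scores ≈ −0.01), resting RRI ≈ 790 ms with SD1 = 20 ms /
SD2 = 45 ms (CSI ≈ 2.25, CVI ≈ 4.2), and a fast-spread trend contrast that
yields CSI changes near −0.26 (altruistic) vs +0.11 (selfish), d ≈ 0.4.
Condition order is recorded per subject (counterbalancing flag). The
subject-effect distribution is assumed Gaussian; nothing in the design
pins down its true shape, so this is a documented assumption, not an
inference.

Known departures from real data: no eye-blink/muscle/cardiac-field
artifacts (hence the simple rejection stage suffices by construction), no
forward-modelled volume conduction on the scalp channels (zero-lag mixing
is exercised at ROI level instead), no ECG waveform morphology or
respiration coupling, and RRI trends are linear. A side effect of driving
CSI change through the fast spread alone is a correlated CVI change of the
opposite sign (CVI ∝ log SD1·SD2), which a two-knob autonomic model would
decouple; it is visible in cohort runs as a positive CVI-change tendency in
the altruistic condition. Passing tests therefore establish estimator and
inference correctness under a known generative model — not robustness to
human-data artifact structure.

## Problem sizes and determinism

Tests and the acceptance script run scaled problems chosen to keep full
runs inside a few minutes on one CPU: 250-Hz (or 128-Hz fixture) sampling,
2–4-channel/4-ROI montages for pipeline round-trips, 400-beat RR series,
100-replicate sign-recovery runs, 200–500-cohort calibration loops with
500–5000 permutations. Calibration of the endpoint statistics uses the
cohort generator's endpoint-level model directly (paired Gaussian draws
with the configured effect size), which is what makes 500-cohort loops
cheap; full-signal cohorts exercise the same statistics at smaller counts.
Generator defaults are never scaled: they encode the target study design.

All randomness flows from explicit seeds through per-subject,
per-condition, per-stream `SeedSequence` children, so identical
configurations are bit-reproducible; pipeline outputs carry no timestamps
and identical run configurations produce byte-identical reports (tested).
Output floats are written with fixed formatting (`%.10g` in reports,
`%.8e` for simulated matrices — round-tripping a written cohort reproduces
analysis results to ~1e-4 relative, not bit-identically).
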