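# Methods

This note documents the models, numerical choices and validation design
behind `oscistate`, in the order the pipeline runs.

## Generative model of the synthetic cohort

The synthetic generator emulates a discrete-state view of resting-state
sensor dynamics. A recording is

    x(t) = a(t) · m[s(t)] + Σ · ε(t)

where `s(t)` is a hidden state sequence over K unit-norm topographies
`m_1..m_K`, `a(t)` is a band-limited oscillatory amplitude, and `ε` is
i.i.d. unit Gaussian per channel with per-channel scale `Σ`.

**Topographies.** Rows are drawn as zero-mean unit-norm Gaussian vectors
with pairwise |Pearson r| bounded by `max_abs_corr` (default 0.3 —
comfortably above the ~1/√204 ≈ 0.07 similarity of random 204-channel
maps, so accepted draws are realistic yet distinct). With
`max_abs_corr = 0` the rows are made exactly orthogonal by zero-mean
Gram-Schmidt; in the degenerate K = n_channels case a zero-mean
orthogonal set does not exist and a plain random orthonormal basis is
returned instead.

**Dwell times.** Segment durations follow a gamma distribution with shape
2 — positive and right-skewed like empirical microstate duration
histograms — truncated below at `min_dur_s` (default 0.02 s), with the
scale solved numerically so that the *truncated* mean equals the
requested `mean_dur_s` (default 0.08 s). Calibrating the truncated rather
than the untruncated mean matters: naive rejection truncation at 0.03 s
inflates a nominal 0.1 s mean to ~0.111 s. Successive states always
differ and transitions are uniform over the remaining states, so long-run
coverage is symmetric at 1/K.

**Carrier.** `a(t)` is white Gaussian noise band-filtered to the
recording's band and scaled so the per-sample vector SNR (RMS carrier
amplitude over expected noise-vector norm) equals the requested `snr`
(default 3). Filtered noise rather than a pure tone is used so the GFP
has genuine, irregularly spaced local maxima; a sinusoid would make every
peak identical. The carrier's own filter is an order-8 two-pass
Butterworth per direction — deliberately steeper than the analysis
filter — so that ≥ 90% of the alpha carrier's power lies inside 8–13 Hz.

**Channel types.** Channels are tagged MAG/COMB (102 + 102 by default)
and the noise scale can differ per type. Setting magnetometer noise above
gradiometer noise reproduces, qualitatively, the empirical finding that
four-class templates explain far more variance on combined gradiometers
than on magnetometers.

**What the generator does not emulate:** sensor geometry beyond type
labels, head movement, environmental interference and its vendor-specific
removal, 1/f background spectra, inter-subject topography variability
(subjects share planted maps unless given different seeds), and
state-dependent spectral content. Passing recovery tests therefore
demonstrates algorithmic correctness under the discrete-state model, not
performance on real recordings.

## Preprocessing

Band filtering follows the two-pass design: an order-4 Butterworth
high-pass applied forward–backward, then an order-4 low-pass applied
forward–backward (zero phase; effective attenuation twice the nominal
order per edge). One consequence is honest and documented: narrow bands
whose edges are ratio-close droop mid-band. The cascade's gain at 10 Hz
in the 8–13 Hz band is 0.77 (order 4 per pass), reaching 0.95 only around
order 8; tests check the filter against its analytic magnitude response
rather than pretending the droop away. The filter order is exposed in the
configuration.

Resampling to 250 Hz is polyphase with anti-alias filtering; upsampling
is refused. Planar-gradiometer pairs combine as the root sum of squares
per sample (an RMS variant, ÷√2, differs only by a global constant).
Before clustering, the magnetometer and combined-gradiometer blocks are
concatenated; because fT and gradient-derived amplitudes are not
commensurate, the default scaling divides each type block by its pooled
standard deviation (`per-type-z`). `none` and `per-channel-z` are
available; whether the original analysis harmonized units is unknown, so
this is a documented package choice.

## Clustering numerics

- **Assignment** is by squared cosine similarity (raw, not demeaned),
  ties to the lowest state index. **Selection and reporting** use GEV,
  whose spatial correlation `r_t` is channel-demeaned Pearson. The GEV
  formula is the standard GFP-weighted squared-correlation definition;
  GFP uses the population (÷N) standard deviation — the sample variant
  differs by a constant that cancels in GEV.
- **Centroid update**: first principal eigenvector of the members'
  outer-product sum. An arithmetic mean is not polarity-invariant and
  would cancel sign-flipped members; the eigenvector update maximizes the
  summed squared projections.
- **Sign convention**: each map's largest-|value| channel is positive, so
  reruns are bit-reproducible.
- **Empty clusters** are re-seeded from the worst-fit map (keeps K fixed).
- **Convergence**: label stability or GEV gain < 1e-8, capped at 500
  iterations; within a restart the best-GEV iterate is kept so a terminal
  fluctuation cannot degrade the result. 20 random restarts by default;
  the highest-GEV restart wins, and all restart GEVs are retained for
  audit.
- **GFP peaks** are strict interior local maxima; plateaus and endpoints
  are excluded. No pre-normalization of samples is applied before
  clustering (cosine assignment is scale-free anyway); a config flag
  could add it without changing the contract.

A caveat established during validation: on *unstructured* random map
sets, the fixed points of the cosine-assignment iteration miss the
brute-force GEV optimum in roughly 17% of small instances regardless of
restart count, because the assignment metric (cosine) and the objective
(GFP-weighted Pearson GEV) are not identical. On clustered inputs — the
regime the algorithm is designed for — the restarted search attains the
enumerated optimum essentially always (~100% at noise σ = 0.3 on planted
two-state instances). The equivalence suite therefore uses clustered
instances and this note records the unstructured behavior.

## Group level, backfitting, parameters

Group templates come from re-clustering the pooled subject maps (two
levels); re-ordering evaluates all K! permutations against the reference
templates and maximizes Σ|r| (polarity ignored — |r| rather than signed r,
consistent with polarity-invariant maps), also returning the aligning
signs. Re-ordering never changes map content, only order and sign.

**Backfit mode.** The default labels the GFP peaks and assigns every
other sample the label of its nearest peak (`peak-interp`). This is a
deliberate design choice for band-limited data: the oscillatory carrier
passes through zero twice per cycle, and at those instants the sample is
noise with no usable topography, so labelling every sample independently
(`continuous` mode, also available) fragments genuine state runs and
biases mean duration downward by roughly 45% at SNR 3, while
peak-anchored labelling recovers planted dwell times within a few
percent. Plausibly for the same reason, published alpha-band durations
(~0.14 s) exceed the alpha half-period, which per-sample labelling of
oscillatory data cannot produce. Zero-variance samples inherit the
previous label; a minimum-duration smoother exists but is off by default.

Parameters per state: duration = mean maximal-run length (s), occurrence
= runs per second, coverage = sample fraction. The identities
`Σ coverage = 1` and `coverage = duration × occurrence` hold to rounding
for every label sequence and are asserted property-style in the tests.

The sensor-type GEV contrast restricts maps and data to one channel type,
re-normalizes the maps, backfits on the subset and computes GEV there.

## Cohort statistics

- Homogeneity gate: Levene's test, mean-centered; Tamhane's T2 iff
  p < α_homog (default 0.05), else Tukey's HSD. A degenerate Levene
  statistic (identical spreads) counts as homogeneous.
- Tukey(-Kramer): q from the studentized range with (k, N−k); checked in
  the tests against an independent implementation.
- Tamhane's T2: Welch t per pair with Welch–Satterthwaite degrees of
  freedom and a Šidák-type adjustment `1−(1−p)^m` over the m pairs (some
  packages use a multivariate-t bound instead; the Šidák form is the
  classical definition).
- Chi-square tests use no continuity correction — this is what reproduces
  the published demographics statistics exactly; ambidextrous
  participants are kept as a third handedness category and excluded from
  right/left tests.
- Bonferroni family size defaults to m = 24 (one parameter across 4
  states × 6 bands) and is configurable; raw p-values are always reported
  alongside.
- Standardized regression z-scores response and predictors and fits OLS
  without intercept, so single-predictor betas equal Pearson r; rank
  deficiency is refused with the collinear columns named.
- The ANOVA layer's calibration is simulated: with 5 groups × 50
  subjects, null rejection stays within Monte-Carlo error of α, and a one
  pooled-SD shift in one group is detected at the Bonferroni-corrected
  level in ≥ 95% of replicates.

## Validation problem sizes

The recovery experiment uses 6 subjects × 60 s at 204 channels, 250 Hz,
alpha band, SNR 3, mean dwell 0.08 s — large enough for ~1,300 GFP peaks
per subject and stable group templates, small enough to run in well under
a minute. The clustering-equivalence suite uses 100 instances of 8 maps ×
6 channels (K = 2), where the 2^8 assignments can be enumerated exactly.
The sensor-contrast simulation uses 100 recordings of 6 s at 40 channels
with magnetometer noise at 5× the gradiometer level. All generators are
pure functions of their seeds; every randomized experiment is seeded.

## Known limitations

- No temporal syntax (transition matrices, Markov tests) and no source
  reconstruction; K ≠ 4 is supported but unvalidated.
- The FIF reader ingests whatever channel set MNE exposes; bad-channel
  handling, artifact rejection and vendor denoising are out of scope —
  the pipeline expects already-clean matrices.
- Cohort-level effect sizes from real aging data are not reproducible
  from synthetic input; the statistics layer is validated for
  calibration, not for reproducing any particular cohort's F or r values.
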