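# Methods

## Avalanche definition and detection

Each channel is z-scored once, globally, using the mean and SD of its
retained (artifact-free) samples; the time axis is preserved and masked
samples are excluded from every downstream statistic.  An excursion is a
sample with |z| strictly greater than θ (ties at exactly θ are measure-zero;
a convention has to be fixed and we use the strict one).  An avalanche is a
maximal run of samples with at least one excursion on at least one channel.
Runs adjacent to a masked sample are discarded, because a truncated run
would bias both its size and duration; runs touching the first or last
sample of the recording are kept.

The default size is the *integrated* supra-threshold amplitude,
s = Σ_channels Σ_supra |z| · (1/fs), in units of SD·s.  Integration makes
sizes comparable across recordings sampled at different rates (the cohorts
this analysis targets mix 128/256/512 Hz) and admits sizes below θ — a raw
per-sample sum could never fall below ≈ θ, which would make small fit
ranges unusable.  The per-sample sum (SD units) is kept as an option.

The default threshold θ = 2 SD is motivated by the Gaussian-deviation
check: the pooled amplitude density of sleep EEG starts exceeding its best
(least-squares) Gaussian fit around ±2 SD.  `gaussianity_report` localizes
that onset as the smallest |z| whose relative excess over the fit exceeds a
tolerance (default 0.5) for three consecutive 0.1-SD bins with at least 5
samples each; a pure-Gaussian input yields an infinite onset.

## Power-law inference

Sizes and durations are fitted with the *bounded* continuous power law
p(x) = C x^−γ on [xmin, xmax], C = (γ−1)/(xmin^(1−γ) − xmax^(1−γ)), by
maximizing the exact truncated log-likelihood with a 1-D bounded
optimization (γ ∈ (1, 25], xatol 1e-10).  With xmax → ∞ this reduces to the
Hill estimator 1 + n/Σ ln(x_i/xmin) (checked to 1e-6 in the tests).
Integer-valued samples (branching-process sizes and durations) are treated
as continuous; at the fit ranges used the resulting bias is small compared
with the stated tolerances (for the duration exponent at xmin = 5 it is
roughly +0.1, visible in the worked example).

Goodness of fit is the KS distance D = sup|F_data − F_fit| over the fitted
range, evaluated at the empirical jump points with both one-sided limits.
Model preference against a truncated exponential (rate fitted by MLE on the
identical support, negative rates allowed) is the pointwise log-likelihood
ratio R = Σ[ln p_pl(x_i) − ln p_exp(x_i)], with a two-sided p value from
the Vuong normal approximation R/(sd(d_i)·√n) ~ N(0,1); this approximation
is what the field's standard tooling uses, and a permutation alternative is
unnecessary at the sample sizes involved here.

The systematic error of an exponent is the SD of the MLE over a grid of fit
ranges — xmin from a fixed list, xmax drawn uniformly (seeded) from an
interval.  Default grids: sizes xmin ∈ {0.5, 1, 2, 3, 4} with 10 xmax in
[550, 1000]; durations xmin ∈ {0.025, 0.03, 0.035, 0.04} s with 10 xmax in
[0.7, 1.6] s.  Default headline fit ranges (sizes [1, 800] SD·s, durations
[0.03, 1.0] s) are the midpoints of those grids; the exact published ranges
are not printed anywhere, so this is a package decision, exposed in the
configuration.

⟨s⟩(T) is estimated by log-binning durations, taking the arithmetic mean
size per bin, and regressing log mean size on log bin center by least
squares separately below and above a crossover (default 0.4 s, matching the
onset of the duration cutoff).  The crackling-noise check compares the
measured k with (α−1)/(τ−1), propagating exponent uncertainties to first
order (delta method) and flagging consistency when the difference is within
the quadrature-combined uncertainty.

## Branching-parameter estimators

Two estimators are provided.  On ground-truth branching samples,
`estimate_branching_ratio` averages (generation-2 activations)/(generation-1
activations) over *all* avalanches, counting extinct ones as 0; this is an
unbiased estimate of the offspring mean, so it reads 1.0 at criticality.
On detected catalogs, `estimate_branching_parameter` discretizes each
avalanche into bins (default 4 sample intervals — the reference definition
leaves the bin width open, so it is exposed as configuration), counts
channel-events (contiguous per-channel supra-threshold runs, assigned to
the bin where they start), and averages bin-2/bin-1 ratios over avalanches
spanning at least two bins.  The survival conditioning biases this second
estimator upward only when bin-1 counts are near 1; on multichannel data
bin-1 counts are typically larger and the bias is small.

## Synthetic ground truth

The generators exist to validate the pipeline end-to-end; none of them is a
claim about the generative process of real sleep EEG.

**Branching process.**  Fully connected (mean-field): one seed unit, every
active unit spawns offspring independently, total activation per generation
absorbed at `n_units` (reproducing the finite-size cutoff of a finite
electrode array) and capped at `max_generations` (default 2000).  The
default offspring law is geometric on {0, 1, 2, ...} — the classical
exactly-solvable Galton–Watson choice — with Poisson available as an
option.  Both are critical at offspring mean 1 and share the MF-DP
exponents, but the finite-duration correction to ⟨s⟩(T) ∝ T² scales
inversely with the offspring variance: with Poisson offspring (variance 1)
the log-log slope over durations of 3–30 generations is ≈ 1.71, whereas the
geometric law (variance 2 at criticality) reaches ≈ 1.88, inside the ±0.15
recovery band the validation demands of that window.  ⟨s⟩(T)/T² converges
to 1/6 for the geometric law.  Generations map to seconds through
`dt_step` (default 0.01 s) when durations must live on the detector's axis.

**Hypnogram.**  Semi-Markov: each NREM–REM cycle is the stage template
N1 → N2 → N3 → N2 → REM with exponential dwell times (means 180/610/600/500 s;
N2 is visited twice per cycle) truncated at one 30-s epoch.  The dwell
means reproduce the cohort-average stage shares (N1 7.2%, N2 48.5%,
N3 24.0%, REM 20.3%) in expectation; realized shares fluctuate with the
exponential dwells, so fraction checks are asymptotic (long-night) checks.
Wake epochs are not generated: the analysis targets artifact-free total
sleep time, where waking segments have already been removed.

**CAP.**  Within each maximal same-stage NREM run, a stationary alternating
renewal process of CAP sequences and NCAP gaps: the run starts inside a
sequence with probability equal to the stage's target CAP rate (41.7/48.4/
53.4% for N1/N2/N3), sequence lengths are exponential (mean 4.55 min, at
least two A–B cycles), and gap lengths are exponential with mean sized to
the target rate, floored at 65 s so gaps are NCAP by construction.  Phase
durations are normal draws clipped to [2, 60] s with subtype-specific means
(A1 6.42 s, A2 8.63 s, A3 12.72 s, B 20.67 s) and stage-specific subtype
mixes (A1-dominant in N3, A3-dominant in N1).

**Surrogate recordings.**  I.i.d. standard-Gaussian background per channel
plus injected bursts: a Poisson process whose rate is the base rate
(0.06 s⁻¹) times a stage multiplier (N3 3 > N2 2 > N1 1 > REM 0.5 > W 0)
times, within NREM, a CAP-phase multiplier (A1 6 > A2 4 > A3 2.5 > NCAP
0.7 > B 0.4).  Each burst adds a clipped half-sine envelope (floor 0.75 of
the 20-SD amplitude) to half the channels for a bounded-power-law duration
(exponent 2 on [0.2, 5] s).  The amplitude and rate are set so that, after
z-scoring inflates the channel SD (to ≈ 3.3 with these defaults), the
burst floor stays above 3 SD — keeping every injected interval detectable
across the whole 1–3 SD threshold sweep — while background crossings at
θ = 1 remain rare.  What the surrogate deliberately lacks: realistic EEG
spectra (spindles, K-complexes, alpha), channel correlations in the
background, arousals, and REM CAP (CAP does not occur in REM).  Passing the
surrogate tests therefore demonstrates correctness of the detection and
coupling machinery, not that real sleep EEG is critical.

**Interval recovery metric.**  Injected-burst recovery is scored by the
area Jaccard between the union of ground-truth intervals and the union of
detected avalanches that intersect at least one ground-truth interval.
Unmatched (background-triggered) detections are excluded by construction:
with n i.i.d. Gaussian channels a per-sample any-channel |z| > 2 crossing
is common (≈ 31% at n = 8 before variance inflation), so an unrestricted
union Jaccard would measure the background false-alarm rate rather than
boundary fidelity; false alarms are visible separately in the catalog
counts.

## Density, φ, and group statistics

F_av(t) is the fraction of a u0 = 10 s sliding window occupied by
avalanches, computed by cumulative sums with a default stride of one sample
(configurable for speed; summaries are stride-invariant within tolerance).
Windows intersecting masked time are marked invalid.  N_av and ⟨T⟩ assign
each avalanche to the window containing its onset.  Stage summaries
attribute windows to stages by window center; the first/last N3 comparison
uses the first and last maximal contiguous N3 runs and a Welch two-sample t
statistic on their window densities.

φ coefficients are Pearson correlations of per-sample binary indicators
over all retained samples of the recording (equivalently the 2×2
contingency φ).  CAP-sequence spans require at least `min_cycles` = 2
consecutive A–B cycles with inter-phase gaps ≤ 60 s (the atlas convention;
published sequences are typically 5–6 cycles); NCAP is derived as NREM time
outside CAP sequences rather than read from file.  Group comparisons gate
on per-group Shapiro–Wilk at 0.05: all-normal → one-way ANOVA with pairwise
Welch t tests, otherwise Kruskal–Wallis with pairwise Mann–Whitney; both
with Bonferroni adjustment, and a paired t test for paired two-group
designs.

## Problem sizes and determinism

Validation and acceptance runs use 1–2 × 10⁵ branching avalanches (seconds
of CPU) and surrogate nights of 1–4 NREM–REM cycles at 128 Hz with 8
channels (tens of seconds end-to-end) — sizes at which every tolerance
above has comfortable Monte-Carlo margin.  All simulators are deterministic
given their seed (same seed ⇒ bit-identical output), and the pipeline
report is byte-identical under a fixed configuration.

## Known limitations

- The continuous MLE applied to integer durations overestimates α by ≈ 0.1
  at xmin = 5; a discrete MLE would remove this but the continuous form is
  the field's standard and stays within the stated tolerances.
- ⟨s⟩(T) approaches its asymptotic slope slowly from below; k estimated
  over short-duration windows underestimates 2 even at criticality (the
  same effect limits real recordings, where the scaling regime is bounded
  by the cutoff).
- The catalog-level branching estimator depends on the bin width, whose
  reference definition is not fully specified; it is a configuration
  parameter, defaulting to 4 sample intervals.
- The surrogate's background is spatially white; detection statistics on
  real, spatially correlated EEG will differ (e.g. higher any-channel
  crossing rates at low thresholds).
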