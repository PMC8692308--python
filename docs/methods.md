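# Methods

This note records the models, conventions and numerical choices behind
`cardiosym`, and what the synthetic cohorts do and do not establish.

## Symbolic dynamics of RR intervals

A segment of successive RR intervals (ms) is quantised over its own
range `[min, max]` into ξ equal-width bins, half-open `[lo, hi)` with
the last bin closed at the maximum, giving symbols 0…ξ−1. Overlapping
3-symbol words (stride 1) are classified by the number of adjacent
unequal pairs: 0 → V0, 1 → V1, 2 → V2. The V2 family merges the
monotone ("like", 2LV) and direction-reversing ("unlike", 2UV)
two-variation patterns in all reports; the split is retained on the
profile object for cross-checks against the source symbolic-analysis
method. Percentages are 100 × family count / word count, with
`n_words = ⌊(n_beats − 3)/stride⌋ + 1`.

Choices the family definitions leave open, and how they are fixed here:

- ξ = 6 levels and full-range uniform quantisation, the standard
  construction in the symbolic HRV literature; ξ and the stride are
  configuration, not constants.
- Bins are built **per segment** (each segment's own range), matching
  the standard method; per-recording binning can be emulated by passing
  a whole recording as one segment.
- A degenerate segment (range below 10⁻⁹ ms) maps every beat to symbol
  0, hence V0 = 100%: the limit of vanishing variability is the total
  absence of variation patterns, not an error.

Consequences used as test invariants: percentages always sum to 100;
profiles are invariant under adding a constant to all intervals and
under positive rescaling; of all 216 three-symbol words at ξ = 6,
exactly 6/60/150 fall in V0/V1/V2.

## Preprocessing

**Artifact filter.** Beat i is flagged when it deviates from the median
of `RR[i−2..i+2]` (window truncated at the edges) by more than a
fraction (default 0.2) of that median, and is replaced by the median.
More than 5% replacements logs a warning; more than 20% rejects the
segment. The 20%-of-local-median threshold is conventional HRV
practice for ectopy/trigger artifacts.

**Smoothness-priors detrending.** The slow trend of a segment z is the
minimiser of ‖z − x‖² + λ²‖D₂x‖², i.e. `trend = (I + λ²D₂ᵀD₂)⁻¹z`
with D₂ the (n−2)×n second-difference operator; the detrended series
is z − trend. λ defaults to 500, the value conventional for short HRV
recordings; it enters squared, the method's canonical form. The normal
matrix is symmetric positive-definite pentadiagonal and is solved with
a banded Cholesky factorisation (`scipy.linalg.solveh_banded`), O(n):
10⁵ beats solve in ≈0.35 s. Identities: λ = 0 returns the input
untouched; any affine-in-index input is removed exactly (second
differences annihilate it); the operator is linear. Detrending is
applied before symbolisation by default and can be disabled in the run
configuration.

**Segment selection.** Supine recordings contribute the beats whose
occurrence times fall in `[0, 300)` s, first beat at t = 0. Time-trial
recordings contribute a 1000-beat window chosen by a deterministic
stationarity score replacing the original workflow's visual
inspection: the window is split into 4 quarters and scored by
`max_q |mean_q − mean| / sd + max_q |sd_q/sd − 1|`; candidate starts at
stride 50 (plus the last feasible start), minimum score wins, ties to
the earliest start. When a full-trial recording is analysed, thirds
are defined **by beat count** (a documented choice — elapsed time or
distance would also be defensible) and the search is confined to the
designated third; per-moment recordings are searched whole.

## Default Bayes factors and corrected odds

Pairwise condition contrasts use the one-sample (paired-differences)
JZS default t test: effect size δ ~ Cauchy(0, r), r = 1/√2. Writing
the Cauchy as a normal scale mixture with mixing variance g·r²,
g ~ InverseGamma(1/2, 1/2), the Bayes factor is

    BF10 = ∫₀^∞ (1+Ngr²)^{-1/2} (1 + t²/((1+Ngr²)ν))^{-(ν+1)/2} π(g) dg
           / (1 + t²/ν)^{-(ν+1)/2},

with N the number of pairs and ν = N − 1 (an independent-samples form
is available through the `df` argument with N the effective sample
size). The integral is computed in log space under the bounding
transform u = g/(1+g) by adaptive quadrature (relative tolerance
10⁻⁹); the implementation agrees with a 2×10⁶-draw Monte-Carlo
evaluation of the same mixture within Monte-Carlo error across a
(t, n) grid, and with an independent library implementation to 10⁻⁶
relative.

Multiplicity over the k(k−1)/2 pairwise contrasts of k conditions is
handled on the prior odds: the prior probability that **all** nulls
hold is fixed at 0.5, and with independent per-comparison priors the
per-comparison null probability is p₀ = 0.5^(2/k), prior odds
(1−p₀)/p₀ — 0.58740 for k = 3 (displayed as 0.587). The printed-table
convention reproduced by the report layer: posterior odds = prior
odds × BF10 (both at full precision, rounded to 2 dp only on
emission), replication probability = 100·BF10/(BF10+1) (1 dp), BF10
uncorrected (3 dp). Evidence bands follow the Lee–Wagenmakers scale;
band edges belong to the stronger band and BF10 = 1 is labelled
anecdotal-for-H1 by convention. Cross-k behaviour of the prior-odds
formula is a convention of this package; only k = 3 is anchored by the
published tables. The prior odds can also be set directly.

## Repeated-measures ANOVA

The crossover is fully within-subject, so the "mixed" omnibus test is
implemented as a one- or two-way fully-repeated decomposition (a true
between+within layout is out of scope): for factors A (treatment) and
B (measure/context), sums of squares for S, A, B, A×B and the error
terms A×S, B×S, A×B×S, with F_effect = MS_effect/MS_effect×S. Partial
η² is SS_effect/(SS_effect + SS_error). Sphericity per effect uses the
orthonormal-contrast covariance S̃ (Helmert-style contrasts; Kronecker
products for the interaction): Mauchly's
W = det(S̃)/[tr(S̃)/p]^p with the standard chi-square approximation,
and Greenhouse–Geisser ε̂ = tr(S̃)²/(p·tr(S̃²)), clipped to
[1/p, 1]. The GG correction multiplies both degrees of freedom and is
applied when Mauchly's p < 0.05 (configurable to always/never). A
singular contrast covariance (n − 1 ≤ p) sets W = 0 and treats
sphericity as rejected. Tukey HSD post hocs compare the first factor's
marginal means with the studentized-range distribution on the
within-subject error term, by default only when the omnibus effect is
significant at α = 0.05.

Variables are routed to this ANOVA only when every condition cell
passes Shapiro–Wilk at α = 0.05; otherwise Kruskal–Wallis (rank-based,
tie-corrected) is used. Which variables fail the gate is data-driven.

Validation: the decomposition equals an explicit mean-subtraction
oracle on small tables; one-way F/p/ε̂/W agree with pingouin to ≥1e−6;
a 500-replicate null simulation (compound-symmetric data, n = 14,
m = 3) keeps the realised type-I error inside [3.5%, 6.5%].

## A-priori sample size

Power for the one-group within-factor design uses the noncentral F
distribution with noncentrality λ = f²·N·m·ε/(1−ρ), numerator df
(m−1)ε and denominator df (N−1)(m−1)ε, the conventions of the
standard a-priori calculator for this design; ρ defaults to 0.5 and
ε to 1 (these reproduce the two published sample sizes and are exposed
as parameters). The smallest sufficient N is found by upward scan from
2 — power is monotone in N, so the scan is exact. f = 0.36 gives
N = 14 and f = 0.41 gives N = 12 at α = 0.05, power 0.80, m = 3.

## Synthetic cohort generator

There is no public generative model for the study's recordings, so the
generator is a transparent beat-domain construction rather than an
integral-pulse-frequency-modulation model: per beat i at running beat
time t_i,

    RR_i = mean_rr + A_LF·sin(2π f_LF t_i) + A_HF·sin(2π f_HF t_i)
           + drift·i + ε_i,   ε_i ~ N(0, σ²).

Beat-domain sampling is deliberate: the symbolic analysis consumes
beats, not continuous time, and the two amplitudes give direct,
monotone control of the quantities the analysis measures (A_HF raises
V2%, A_LF and drift raise V0% — verified as rank correlations over a
profile grid). Parameters are validated so that the worst-case
excursion (amplitudes + accumulated drift + 5σ) keeps every interval
inside the physiological band (200, 2500) ms.

Default study conditions: 14 subjects × {PP, PC, CC} × three supine
contexts (mean RR 900 ms, LF 25 ms at 0.1 Hz, HF 30 ms at 0.25 Hz,
identical across conditions — the study found no supine differences)
and three time-trial contexts (mean RR 450/400/380 ms with the
respiratory band at 0.4 Hz; HF amplitude rising towards the final
moment, and larger under PC/CC — 16 and 15 ms vs 6 ms for PP — with
smaller LF/drift, reflecting the reported vagal elevation whose exact
magnitudes are not published and therefore remain configuration).
Time-trial outcomes: completion time means 1480 s for PP with
configured deltas −43.4 s (PC) and −39.3 s (CC); per-third power means
around 199.67 W, placebo ramping (188→207 W) while caffeine holds
quasi-stable, matching the reported overall deltas (+6.17/+5.55 W).
Between-subject structure is a shared subject effect on time (SD 60 s)
and power (SD 15 W) plus a log-normal subject multiplier (SD 0.15) on
both oscillation amplitudes; residual SDs 18 s and 6 W. Supine
recordings are 420 beats (≥300 s at 900 ms), time-trial recordings
1200 beats.

Randomness is split per recording with `SeedSequence(master,
spawn_key=(subject, condition_index, context_index))` and per subject
with a similarly keyed stream, so enlarging a cohort never perturbs
existing draws; a fixed master seed makes the whole study
bit-reproducible.

What the generator does **not** emulate: real RR series'
nonstationarity within segments, respiratory frequency variation,
ectopic beats (the artifact filter is exercised with synthetic spikes
instead), 1/f long-range correlations, and any caffeine
pharmacokinetics. Passing recovery tests therefore shows the pipeline
detects effects of the configured form and size under well-behaved
noise — not that the published group means would be reproduced from
raw recordings, which are not available.

## Ergometry utilities

Wmax extrapolation keeps the source protocol's printed divisor 113 as
the default (`output + (t/113)·45`); because 113 W is also the
protocol's starting load, the printed formula may be a transcription of
the conventional 120-s-stage form, so a 120 divisor is selectable.
The caffeine dose helper is the 6 mg·kg⁻¹ product, rounded to 2 dp.

## Problem sizes and runtime

Simulation-backed checks use sizes chosen to make the suite quick to
iterate while keeping sampling error well below the margins asserted:
20 replicate cohorts for effect recovery (final-moment contexts only,
where the configured effect lives), 500 replicates for the type-I
error band, 2×10⁶ Monte-Carlo draws per Bayes-factor grid cell, and
200-subject cohorts for delta-recovery checks. The full default
pipeline (14×3×6 recordings) runs in about 2 s.

## Known limitations

- The stationarity selector is a surrogate for expert visual
  inspection; its score is a heuristic and is exposed as configuration.
- The two-way decomposition requires a complete balanced crossover;
  missing cells are rejected rather than imputed.
- Mauchly's p uses the standard chi-square approximation, which is
  conservative at very small n.
- The Bayes layer covers pairwise default t tests only (no Bayesian
  model averaging across ANOVA models).
- Frequency-domain HRV indices (LF/HF power), Poincaré and entropy
  measures are out of scope.
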