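# Methods

This note documents the models, the numerical and design choices behind
them, what the synthetic-data generator does and does not emulate, and the
known limitations.

## From feeder visits to residual series

Feeder visits are summed per integer age-day; a day without any visit is a
gap, never a zero. Visit-level cleaning applies three configurable
plausibility rules (non-negative intake; per-visit maximum, default 5 kg;
per-animal-day total maximum, default 10 kg), each logged with removal
counts. The analysis window is ages 99–140 days inclusive (42 daily
slots); animals with fewer than 10 observed days, or any run of more than
3 consecutive missing days inside the window, are excluded. Both bounds
read literally: "fewer than 10" is < 10, "more than 3 consecutive" is a
gap of ≥ 4 days.

Smoothing uses a centred moving median (window 5, odd windows only) over
the *observed* values: gaps are skipped, not imputed, and a smoothed value
is reported only at observed positions whose window holds at least 3
observations. A per-animal OLS of the smoothed series on age provides the
linear growth trend; residuals are smoothed − predicted.

Why residual-based: raw FCD variance grows mechanically with the animal
(growth trend) and is contaminated by day-scale white noise; the median
filter suppresses the noise and the regression removes the trend, leaving
deviations that plausibly reflect perturbation responses.

## The four indicators

- **lag1** — r₁ = Σ(eₜ−ē)(eₜ₊₁−ē)/Σ(eₜ−ē)², products only over
  adjacent-day pairs with both members observed (pairs straddling a gap
  are dropped; nothing is imputed). Undefined (and flagged) at zero
  residual variance.
- **lnvar** — ln of the sample variance (n−1). Zero variance maps to a
  missing value rather than −∞.
- **maxarea** — negative runs are maximal blocks of consecutive observed
  days with eₜ < 0 and length ≥ 3 ("more than two days"); a gap terminates
  a run. Each run's area is the trapezoidal integral of −eₜ at unit day
  spacing (a constant depth c over L days gives c·(L−1)); maxarea is the
  ln of the largest run area, missing when no run qualifies (those animals
  are excluded from maxarea analyses). No interpolation of zero crossings
  beyond the run.
- **summin** — the sum of residual values at strict interior local minima
  (both adjacent-day neighbours observed and strictly larger; plateaus and
  endpoints never qualify). Zero when no minimum exists.

summin runs opposite in sign to the other three (more negative = more
dips = less resilient). The class assignment still applies one common
rule to all four indicators; `invert_summin` swaps the H/L ends for
summin when the inverted reading is wanted, and is off by default.

Class labels are assigned within breed by equal-frequency rank binning
(ntile semantics, larger bins first, ties resolved by first occurrence):
the lowest 5% bin of an indicator is H, the highest 5% bin is L, the
47.5–52.5% band (bins 20–21 of 40) is M. For n animals per breed each
class holds ⌈0.05·n⌉ ± 1. At least 20 animals per breed are required.

A nuance worth knowing: adding a constant to every FCD value leaves all
four indicators exactly unchanged (absorbed by the regression intercept),
but adding a linear-in-age term changes them very slightly, because a
moving median does not commute with a trend — the trend can change which
window element is the median. The OLS stage itself absorbs linear terms
exactly; the tests check each identity at the stage where it is exact.

## Compositional analyses

Sample filter: total count < 700 removed (strict). ASV filter: prevalence
(fraction of retained samples with count > 0) < 0.05 removed (strict),
applied after the sample filter. CLR transform: zeros replaced by a
constant pseudo-count, default 0.65 × the smallest nonzero count of the
table (the usual const-replacement convention; the multiplier is
configurable), then x → ln x − mean(ln x) per row, so rows sum to zero to
1e−10. Aitchison distance is the Euclidean distance between CLR rows.
α-diversity (Shannon in nats, inverse Simpson) is computed on the raw,
unfiltered counts; outliers beyond the Tukey fences (1.5×IQR outside the
quartiles, strict) are removed before diversity regressions.

The microbial similarity kernel column-standardises the filtered CLR
matrix (zero-variance columns dropped with a warning) and takes
K = XXᵀ/p, p the number of ASVs — the same scaling convention as a
genomic relationship matrix, giving a mean diagonal near 1 and
guaranteeing positive semi-definiteness.

## PERMANOVA

The distance matrix is Gower-centred (G = −½ J D² J) and partitioned by
sequential (Type-I) projections of the cumulative design: room, then
breed, then the indicator, so the indicator's sum of squares is
conditional on the housing and breed covariates. Pseudo-F uses the full
model's residual. p-values come from free (unrestricted) permutation of
sample labels, p = (#{F* ≥ F} + 1)/(n_perm + 1) with 1000 permutations by
default; an exact mode enumerates all n! label orders for n ≤ 8.
Rank-deficient terms are dropped with a warning; constant indicators are
an error. VarExp is 100·SS_term/SS_total.

## Microbiability

Model: y = 1μ + Z_E u_E + Z_S u_S + m + e with u_E ~ N(0, Iσ²_E) over pen
levels, u_S ~ N(0, Iσ²_S) over sire-within-breed levels (sire codes are
composed as breed:sire, absorbing breed means; the sire×pen interaction
is not modelled, matching a design that spreads half-sibs across pens),
m ~ N(0, Kσ²_M), e ~ N(0, Iσ²_e), all components mutually independent.
m² = σ²_M/(σ²_M + σ²_E + σ²_S + σ²_e) per draw.

Gibbs sampling uses the spectral reparameterisation of the kernel effect:
with K = U Λ Uᵀ (eigenvalues below 1e−8 of the maximum dropped) and
m = Uα, the full conditional of α has diagonal precision
1/σ²_e + 1/(λᵢσ²_M), so a sweep costs O(n²) (the Uᵀr projection) instead
of O(n³). Variances have scaled-inverse-χ² full conditionals. Defaults:
70,000 iterations, 10,000 burn-in, thinning 50 (the standard run
profile); shorter profiles are adequate for recovery experiments and are
what the test suite uses. Summaries: posterior median of m², shortest-
window HPD95 (exhaustive search over the sorted draws), per-component
fraction medians, and Geweke Z per chain (means of the first 10% vs last
50%, variances from Bartlett-windowed spectral density at zero with a
√n lag cutoff).

**Priors.** Each variance carries a scaled-inverse-χ² prior with df 2 and
mode at 2% of the phenotypic variance. This is a deliberate choice: the
σ²_M/σ²_e ratio is identified only through the spread of K's eigenvalues,
which at n ≈ 500 makes the likelihood quite flat, and an informative
prior that splits the variance equally across the four components drags
the m² posterior toward the prior ratio — on responses simulated
independently of the kernel it inflates the m² median to ≈ 0.12 where a
maximum-likelihood grid puts σ²_M at exactly zero. With the
weakly-informative default the same null responses give medians near
0.03–0.04 and planted signals are recovered without attenuation.
Doubling the prior df moves the posterior median by less than 0.03 on
the standard synthetic fixture; the prior is configurable
(`prior_df`, `prior_mode_fraction`).

## PLS-DA

Classes are one-hot encoded and regressed on the centred, unit-variance-
scaled CLR features by PLS2 (NIPALS, via scikit-learn's `PLSRegression`);
the class score is the indicator-regression output and the predicted
label its argmax. The workflow is: 50/50 train/test split stratified by
breed × class (⌈n/2⌉ vs ⌊n/2⌋ per cell, odd units by seeded coin flip);
component count chosen by mean macro one-vs-rest AUC under repeated
stratified 4-fold CV (50 repeats by default), ties to the smaller model;
then iterative feature elimination dropping the ⌊0.2·p⌋ (at least 1)
lowest-VIP features per iteration — VIPⱼ = √(p·Σₐ SSYₐ(w_{ja}/‖wₐ‖)²/Σₐ SSYₐ),
so mean squared VIP is 1 — refitting and recording the CV AUC, stopping at
the first non-improvement or below 5 features, and returning the
best-AUC iteration. The component count is fixed after the initial
selection (re-selection per iteration would multiply cost for little
benefit at these sizes). A `vip_mode="share"` variant removes the
features making up the lowest 20% of cumulative squared VIP instead of
the lowest 20% by count.

Evaluation on the held-out set: per-class one-vs-rest AUC via the
Mann–Whitney U identity (half credit for ties; identical to trapezoidal
ROC integration), overall AUC as the unweighted macro average, a 3×3
confusion matrix from argmax labels, and one-sided Mann–Whitney tests of
the class scores (positives > negatives) as the Wilcoxon significance of
each class AUC.

## Synthetic cohorts

The generator emulates the study design rather than any particular data
set: 528 animals by default in breed proportions 153/193/182, housed in
breed-homogeneous pens (8 rooms × 8 pens), sires (27/27/44 per breed)
nested in breed with each sire's offspring dealt round-robin across that
breed's pens so half-sibs do not share a pen when capacity allows.

Feed intake: FCD = start + slope·(age − 99) + pen effect + AR(1) noise
(φ = 0.3, sd 0.15 kg — the autocorrelation gives lag1 recoverable
signal), with start ~ N(2.2, 0.25) kg/day and slope ~ N(0.025, 0.005)
kg/day² as realistic grower-pig values; each animal has one
intake-depression event with probability 0.3 (duration uniform on 3–7
days, depth uniform on 0.5–1.5 kg/day), recorded in the truth object.
Negative days are floored at zero and flagged. Days are split into 1–8
visits by a Dirichlet draw that conserves the daily total exactly; 1% of
days are missing at random.

Microbiome: per-ASV log-normal baselines (sd 2) plus per-animal noise
(sd 1) plus four shared community-gradient factors (loading sd 0.5) — the
gradients matter: iid per-ASV noise would give the CLR covariance an
unrealistically isotropic spectrum, whereas real gut communities covary
along a few dominant gradients, which is also precisely what identifies
the kernel variance component. Counts are multinomial at log-normal
depths (median ≈ 20,000); 5% of samples are planted below depth 700 to
exercise the filter. The planted indicator is m + pen + sire + residual
with variance shares (default m² = 0.10, pen 0.25, sire 0.055) realised
exactly up to the recorded truth; the microbial effect m = Xb is built on
the column-standardised CLR of the observed filtered counts (b nonzero
for 50 informative ASVs), so the analysis-side kernel is correctly
specified under the generator. `effect_scale="latent"` plants the effect
on the noise-free latent composition instead — measurement noise then
attenuates recovery, a useful robustness probe — and `effect_scale="raw"`
uses raw relative abundances, a deliberate kernel misspecification.

What the generator does **not** emulate: taxonomy and phylogeny, real
zero-inflation patterns beyond multinomial sampling, diet or age drift of
the community, any built-in coupling between the *feed-derived*
indicators and the microbiome (the planted indicator carries the
microbial signal; lnvar computed from simulated feed data is independent
of the simulated counts), litter/dam effects, or seasonal environment.
Passing tests therefore demonstrate the correctness and calibration of
the estimators under the stated generative assumptions, not the
biological effect sizes to be expected in real cohorts.

## Problem sizes and numerical choices

The test suite runs recovery experiments at n = 500 animals with the
reduced chain profile (6,000 iterations / 1,000 burn-in / thin 10), 20
replicates for HPD coverage, 500 null simulations with 199 permutations
for PERMANOVA type-I calibration, and a 192-animal end-to-end pipeline
determinism check; these sizes give stable statistics while keeping the
suite fast. Tolerances: oracle equivalence at 1e−10; CLR row sums at
1e−10; PSD tolerance −1e−8·trace/n; SS additivity at 1e−8 relative.
Ties: ntile binning resolves ties by first occurrence; AUC gives half
credit; component selection prefers fewer components. Degenerate inputs
(zero residual variance, all-zero count rows, constant indicators,
zero-variance features/columns) raise or produce flagged missing values
rather than silent numbers.

## Limitations

- Microbiability at n ≈ 500 is weakly identified; HPD95 intervals are
  wide (±0.1 around a median of 0.3) and estimates for small m² sit on a
  likelihood plateau where the (deliberately weak) prior still
  contributes a floor of a few percent.
- The PERMANOVA permutations are free; no restriction by room or pen, so
  strong block structure in the distances inflates neither the test under
  the null used here, but restricted permutation schemes are not offered.
- PLS-DA class sizes are 5% tails; at a few hundred animals the held-out
  evaluation rests on ~10–20 animals per class and is accordingly noisy.
- The visit-cleaning rules are plausibility defaults, not a validated
  site-specific protocol; override them to match local feeder behaviour.
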