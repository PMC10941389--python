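# resilink

Quantifying the link between gut microbial composition and feed-intake
resilience in growing pigs.

Resilience — an animal's capacity to stay on, or quickly return to, its
expected performance trajectory under perturbation — is not directly
observable. `resilink` estimates it from the day-to-day variability of
electronically recorded feed consumption, then asks how much of that
variability the gut microbiota explains.

## The indicators

Per animal, daily feed consumption (FCD, kg/day, the sum of per-visit
intakes over a 24-h age-day) is smoothed with a centred 5-day moving
median and detrended by an ordinary least-squares regression of the
smoothed series on age. The residuals e_t feed four scalar indicators:

| Indicator | Definition | Reads as |
| --- | --- | --- |
| `lag1` | sample lag-1 autocorrelation of e_t | persistence of deviations |
| `lnvar` | ln of the residual sample variance | overall day-to-day volatility |
| `maxarea` | ln of the largest trapezoidal area of a run of ≥3 consecutive negative-residual days | worst intake-depression episode |
| `summin` | sum of e_t at strict interior local minima | accumulated transient dips |

Low variability means high resilience. Within each breed, animals in the
lowest 5% of an indicator form the H (high-resilience) class, the highest
5% the L class, and the central 47.5–52.5% band the M control class.

## The microbiome analyses

From an ASV count table (samples × ASVs), samples with total count < 700
and ASVs with prevalence < 0.05 are dropped; zeros are replaced with a
constant pseudo-count and the table is centred-log-ratio (CLR)
transformed. On that basis the package computes

- **PERMANOVA** of the Aitchison (Euclidean-on-CLR) distance matrix on
  room + breed + indicator (sequential sums of squares, permutation
  p-values), reporting the percent of compositional variance an indicator
  explains;
- **α-diversity regressions** (Shannon, inverse Simpson on unfiltered
  counts, Tukey-fence outlier removal) on each indicator, optionally
  adjusted for room and breed, plus class-wise Kolmogorov–Smirnov tests;
- **microbiability** m² = σ²_M / (σ²_M + σ²_E + σ²_S + σ²_e): the fraction
  of indicator variance attributable to the microbial similarity kernel
  K = XXᵀ/p of the column-standardised CLR matrix, estimated by a Gibbs
  sampler for y = 1μ + Z_E u_E + Z_S u_S + m + e with pen, sire-within-breed
  and kernel (m ~ N(0, Kσ²_M)) random effects, reported as the posterior
  median with the shortest 95% highest-posterior-density interval and
  Geweke Z convergence diagnostics;
- **PLS-DA** classification of the L/M/H classes from CLR profiles, with
  AUC-driven component selection under repeated stratified 4-fold
  cross-validation, iterative elimination of the lowest-20% VIP features,
  and held-out per-class one-vs-rest AUC, ROC, confusion matrix and
  one-sided Mann–Whitney significance.

A synthetic-cohort generator (`resilink.synthdata`) emulates the study
design — three breeds in breed-homogeneous pens across 8 rooms, sires
nested in breed, linear intake growth with AR(1) noise and stochastic
multi-day intake-depression events, and ASV counts with community-gradient
structure and a planted microbial variance share — recording every
stochastic contribution so recovery tests can compare estimates against
realised ground truth.

## Worked example

```python
from resilink import feedclean, indicators, microbiome, association, synthdata
from resilink.microbiability import MicrobiabilityModel

cfg = synthdata.SimulationConfig(n_animals=500, target_m2=0.10)
meta = synthdata.simulate_cohort(cfg, seed=1)
visits, _ = synthdata.simulate_feed_intake(cfg, meta, seed=2)
counts, planted, truth = synthdata.simulate_microbiome(cfg, meta, seed=3)

series, log = feedclean.run_feedclean(visits)        # clean -> daily -> filters
ind = indicators.compute_indicators(series)          # lag1, lnvar, maxarea, summin
prep = microbiome.prepare_microbiome(counts)         # filters, CLR, distance, kernel

data = meta.join(planted.rename("planted"))
model = MicrobiabilityModel.from_dataframe(data, "planted", prep["kernel"])
print(model.fit(n_iter=12_000, burn_in=2_000, thin=10, seed=4).summary())
```

```
Microbiability (Bayesian kernel variance components)
  retained draws : 1000 (iters=12000, burn-in=2000, thin=10)
  m2 median      : 0.082
  m2 HPD95       : [0.022, 0.192]
  variance-fraction medians:
    sigma2_m     : 0.082  (Geweke Z +1.18)
    sigma2_pen   : 0.246  (Geweke Z -0.27)
    sigma2_sire  : 0.070  (Geweke Z +2.74)
    sigma2_resid : 0.589  (Geweke Z -2.02)
```

The posterior median recovers the planted microbial share of 0.10 — the
pen, sire and residual fractions likewise sit near their planted shares
(0.25, 0.055, 0.595) — and the HPD interval conveys how weakly a
variance ratio of this size is identified at n = 500.

The same objects drive the other analyses, e.g.
`association.permanova(prep["distance"], covars, ["room_id", "breed", "lnvar"])`
returns a results object whose `summary()` prints the familiar
SumSq / F / Pr(>F) / VarExp table.

A command-line interface mirrors the library:
`resilink simulate | feedclean | phenotype | microbiome | associate |
microbiability | plsda | run`, the last driving the whole pipeline from a
YAML config with per-stage seeds, manifests, and byte-identical reruns.

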