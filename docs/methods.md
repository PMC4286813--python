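# Methods

## The stage ontology

All tables are expressed over a fixed eight-level ontology of lateral-root
primordium (LRP) development: stages I–VII (pericycle divisions through the
dome pushing past the cortex) and E, the emerged lateral root. The grouping
"late" = {VII, E} and "early" = {I–IV} follows the convention used in staging
studies to summarise whether a genotype's primordium population is shifted
toward emergence. The ontology is closed: unknown labels are rejected at
parse time rather than coerced, so count vectors are always conformable.
Stage "0" (pre-division priming) is not scored in these assays and is not a
level; the induced-assay `NONE` category (no primordium initiated yet) is a
separate sentinel, recorded but excluded from stage-distribution
proportions.

## The randomization GLRT

Per-genotype stage counts pooled across 20–60 roots typically leave many
stages with fewer than five observations, invalidating the χ² approximation.
The test therefore uses the multinomial deviance

    T = 2 [ ℓ_a(p̂_a) + ℓ_b(p̂_b) − ℓ_a(p̂₀) − ℓ_b(p̂₀) ] = 2 Σ O ln(O/E)

with the null MLE p̂₀ the pooled frequencies, and generates its null
distribution by parametric randomization: B replicate datasets are drawn as
independent multinomials at the observed group sizes from p̂₀, the statistic
is recomputed for each (re-pooling within each replicate), and the p-value is
the fraction at least as extreme as the observed statistic.

Numerical and design choices:

* **Deviance form.** Any strictly monotone transform of the likelihood ratio
  gives the same randomization p-value, because the identical statistic is
  applied to observed and replicate data; the factor 2 is adopted so the
  large-sample law is χ² with 7 degrees of freedom, used as a cross-check
  (Kolmogorov–Smirnov distance ≈ 0.015–0.02 at n = 500 per group, 2000
  replicates), never as the reported p-value.
* **Ties.** "At least as extreme" is `≥` by default, which is conservative
  when the observed statistic is 0 (identical tables give p = 1 exactly).
  Strict `>` and the add-one estimator (1 + #{T* ≥ T})/(B + 1) are
  selectable. Replicate statistics are compared to the observed one with a
  relative tolerance of 1e-9 because the two are computed by different
  algebraic routes; without it, exact ties (notably at T = 0) would be lost
  to rounding.
* **Empty levels.** Stages empty in both groups contribute 0 to the
  statistic and are retained; levels with positive pooled frequency can be
  resampled to zero in replicates, which the xlogy convention 0·ln 0 = 0
  handles without special cases.
* **B.** Default 10 000; below 100 is refused, below 1000 warned, since the
  p-value resolution is 1/B.
* **RNG.** One integer seed determines the whole result; calibration
  replicates draw their streams from `SeedSequence.spawn`, so results do not
  depend on execution order.
* **Scope.** Comparisons are pairwise (each genotype against a reference);
  no pooled multi-genotype test and no multiple-testing correction by
  default, matching how staging contrasts are conventionally reported. A
  Bonferroni adjustment, where wanted, is a one-line wrapper.

The exact-enumeration oracle (`exact_pvalue`) computes the B→∞ limit by
summing exact multinomial null probabilities over every outcome pair on the
levels with positive pooled frequency. It is feasible only for small tables
(the state count is checked against a budget) and exists to validate the
randomization procedure: at B = 10 000 the Monte-Carlo p lies within
4·√(p(1−p)/B) of the exact p on every enumerable table tested.

## Phenometrics

* Emerged-LR density: emerged LRs / PR length, per seedling; zero-LR roots
  are legal observations contributing zero (dropping them would bias the
  mean upward).
* Branching density: emerged LRs / span from the most shootward to the most
  rootward emerged LR. Undefined below two LRs; such roots are excluded from
  branching-density summaries (a convention, since the metric's source
  definition does not fix it).
* Stage distributions can be formed on two bases: pooled counts (one
  multinomial sample; SEs from √(p(1−p)/n) at n = pooled LRP count) or the
  mean of per-root percentage vectors (each root weighted equally; SEs are
  SEMs across roots; roots with zero scored LRPs are excluded since their
  percentage vector is undefined). Proportions live on [0, 1] internally and
  are scaled ×100 only for display.
* Density comparisons use Welch's unequal-variance t-test by default —
  a robust default when only "pairwise t-tests" is specified — with
  Student's pooled-variance variant behind a flag.

## The synthetic-data generator

The generator emulates the statistical structure of two assay designs, not
their biology. LRP development is a linear continuous-time Markov chain
I → II → … → VII → E with independent stage dwell times, Exponential with
exit rate `stage_rates[s] × multiplier(genotype)` (Erlang-k with the same
mean is available for less dispersed timing). A single per-genotype
multiplier encodes globally faster (> 1) or slower (< 1) initiation and
progression — the 1-D summary that matches the qualitative mutant /
overexpressor signatures these assays detect, and that keeps recovery
identifiable.

Default conditions (set once, in the scenario object, not in code paths):

| parameter | default | rationale |
|---|---|---|
| stage exit rates | 0.13 h⁻¹ × 7 | places the wild-type median induced LRP at ~stage III by 18 h and ~VI by 42 h, spanning the assay's two scoring times |
| initiation lag mean | 2 h | short exponential delay from gravistimulus to first division |
| observation times | 18, 42 h | the induction assay's scoring design |
| initiation intensity | 3 cm⁻¹ | with the rates above, yields wild-type emerged-LR densities ≈ 1.3 LR/cm |
| PR length | 6 ± 1 cm (truncated > 0) | 10-day-old seedling scale |
| LRP age horizon | 96 h | ages ~ Uniform(0, 96 h) approximate steady ongoing initiation along a growing root; gives a realistic mix of pre-emergence stages (~50% late in wild type) |
| roots per genotype | 30 | mid-range of the 20–60 seedlings such surveys use |
| multipliers | 1.0 / 1.5 / 0.67 | wild type, a faster loss-of-function mutant, a slower overexpressor |

**Induced assay** (`simulate_induced`): per seedling, one primordium
initiates after the lag and progresses through the chain; its stage is
recorded at each observation time (NONE before initiation; E absorbing).
**Whole-root survey** (`simulate_whole_root`): per root, PR length is
truncated-normal, the LRP count Poisson(intensity × length), each LRP's age
uniform on the horizon and its stage read off the dwell-time chain; emerged
LRs get uniform positions for the branching-zone metric.

What the generator does *not* emulate: root growth dynamics and the
resulting spatial age gradient of primordia, priming periodicity, arrest or
death of primordia, between-seedling rate heterogeneity, and observer
staging error. Passing tests therefore demonstrate the statistical
machinery's correctness and its power under idealized multinomial sampling,
not performance under real-data artefacts such as overdispersion across
roots — with pooled counts, genotype-level overdispersion would make the
test anticonservative, which is why per-root summaries are kept alongside.

## Multiplier recovery

Induced-assay data are snapshots: stage occupancy at fixed times. Under the
chain, occupancy probabilities are phase-type and computed by matrix
exponential of the generator (optional lag state → 7×k Erlang sub-phases →
absorbing E). With baseline rates and lag known, the genotype multiplier m
is estimated by maximising Σ counts·log P_m(stage at t) over log m
(bounded scalar minimisation, |log m| ≤ 7, xatol 1e-8); the standard error
comes from the observed information via central differences on log m, with
Wald intervals back-transformed (asymmetric in m). Degenerate data — every
record NONE, or every record already emerged — carry no information about m
(the likelihood is monotone in m) and raise a non-identifiability error
rather than returning a boundary estimate. The initiation lag is treated as
a known nuisance parameter supplied by the caller: NONE records are
uninterpretable without it.

At the default conditions, 1000 seedlings scored at 18 h and 42 h recover
multipliers of 1.0 and 1.5 to within a few percent.

## Problem sizes in tests and the acceptance script

Oracle agreement uses 1000 random 2×8 tables; exact-vs-randomization checks
use 21 tables with group totals ≤ 8 and ≤ 3 active levels at B = 10 000;
type-I calibration uses 500 replicates at B = 1000 (n = 40 per group,
uniform 4-level null); the χ²₇ cross-check uses 2000 null replicates at
n = 500 per group; pipeline power uses 200 replicates of the 30-root,
B = 2000 design. These sizes give Monte-Carlo uncertainty comfortably inside
each check's margin while keeping the full suite fast.
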