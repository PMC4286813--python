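# rootstage

Statistics for lateral-root primordium (LRP) staging assays in root-system
architecture phenotyping.

When lateral-root development is scored in *Arabidopsis*-style assays, each
seedling yields a handful of primordia classified into eight ordered
morphological stages — I through VII, plus E for an emerged lateral root.
Per-genotype, per-stage counts are typically far too sparse for a chi-squared
test (many cells hold 0–3 observations), which is exactly the situation this
package addresses. It provides:

* **A randomization GLRT for stage distributions.** For two genotypes with
  stage-count vectors *a* and *b* (totals n_a, n_b), the test statistic is the
  multinomial deviance

      T = 2 [ ℓ_a(p̂_a) + ℓ_b(p̂_b) − ℓ_a(p̂₀) − ℓ_b(p̂₀) ]
        = 2 Σ O ln(O/E),

  where the alternative MLEs p̂_a, p̂_b are the groups' own frequencies and
  the null MLE p̂₀ = (a+b)/(n_a+n_b) is the pooled frequency vector. Instead
  of the unreliable χ² reference, the null distribution is generated by
  parametric randomization: B = 10 000 replicate datasets a\* ~ Mult(n_a, p̂₀),
  b\* ~ Mult(n_b, p̂₀), with p the fraction of replicate statistics at least
  as extreme as the observed one. An exact-enumeration oracle, a χ²₇
  large-sample cross-check, and type-I/power calibration routines verify the
  procedure behaves as a test.
* **Phenometrics.** Emerged-LR density (LRs per cm of primary root, per
  seedling), branching-zone density, stage-distribution summaries with
  standard-error-of-a-proportion error bars (√(p(1−p)/n)), and pairwise
  Welch t-tests on densities.
* **A stage-progression simulator.** LRP development as a continuous-time
  Markov chain I → … → VII → E with per-genotype rate multipliers, emulating
  both whole-root staging surveys and the gravistimulated single-LRP
  induction time course (stages scored 18 h and 42 h post-stimulus) — plus
  maximum-likelihood recovery of a genotype's progression multiplier from
  snapshot data (`StageProgressionModel.fit()`).

## Worked example

Simulate a 30-roots-per-genotype survey of a wild-type and a mutant whose
stage-progression rates are 1.5× faster, then test whether their stage
distributions differ:

```python
from rootstage import (ProgressionScenario, simulate_whole_root, pool_by_genotype,
                       randomization_test, density_summaries, stage_distribution)

scenario = ProgressionScenario(
    genotype_multipliers={"wildtype": 1.0, "mutant": 1.5}, n_roots=30)
obs = simulate_whole_root(scenario, seed=42)
tables = {t.genotype: t for t in pool_by_genotype(obs)}

for d in density_summaries(obs):
    print(f"{d.genotype:9s} emerged-LR density {d.mean_density:.2f} +/- {d.se:.2f} LR/cm (n={d.n})")
for g, t in tables.items():
    dist = stage_distribution(t)
    print(f"{g:9s} late-stage (VII+E) fraction {100*dist.late_fraction():.1f}% of {dist.n} LRPs")

res = randomization_test(tables["wildtype"].pooled, tables["mutant"].pooled,
                         B=10_000, seed=42)
print(res.summary())
```

prints

```
mutant    emerged-LR density 1.92 +/- 0.10 LR/cm (n=30)
wildtype  emerged-LR density 1.28 +/- 0.10 LR/cm (n=30)
mutant    late-stage (VII+E) fraction 71.7% of 547 LRPs
wildtype  late-stage (VII+E) fraction 51.4% of 512 LRPs
Randomization GLRT on stage distributions
---------------------------------------------
G statistic                   50.2081
p-value (     geq)             0.0000
randomization replicates        10000
group totals (n_a, n_b)  (512, 547)
seed                               42
```

The faster genotype shows the classic signature: higher emerged-LR density,
a late-shifted stage distribution, and a G statistic far in the tail of the
randomization null (none of the 10 000 replicates reached it, so the
estimated p is below 1/10 000).

The same pipeline is scriptable from the shell:

```
rootstage simulate  --config examples/scenario.yaml --out-roots roots.csv --out-induced induced.csv --seed 7
rootstage summarize --roots roots.csv --out summary.csv
rootstage test      --roots roots.csv --reference Col0 -B 10000 --seed 1 --out glrt.csv
rootstage calibrate --config examples/calibration.yaml --out calibration.csv
```

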