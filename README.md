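# mitodyn

Mitochondrial heteroplasmy — the coexistence of non-identical mitogenomes
within one individual — is central to hypotheses linking oxidative damage,
mitochondrial mutation accumulation and ageing. Testing those hypotheses in
a wild population takes a chain of methods: deep-sequencing pileups of a
~16 kb circular mitogenome, a caller sensitive to minor-allele frequencies
(MAF) of ~1%, a benchmarking protocol to pick and trust that caller,
quality-control screens, mutation-spectrum characterization, and count
regressions with resampling to relate heteroplasmy burden to age across
cohorts and recaptured individuals.

`mitodyn` implements that chain as a tested, desk-scale Python package.
Every stage runs on synthetic data generated in-package, so the pipeline
and all of its statistical behaviour can be exercised without any
sequencing data; real annotated-variant and sample tables can be supplied
as plain TSV to the characterization and inference layers.

## What is implemented

* **Synthetic data** (`mitodyn.simulate`, `mitodyn.genome`): random
  annotated circular mitogenomes; planted truth variants in sets of 100 at
  MAF 1, 4, 7, 10 and 15%, with positions colliding between sets excluded
  from all of them; per-site pileup simulation (Poisson depth, binomial
  minor alleles, uniform substitution errors); and a population generator
  producing age-cohort sample tables and heteroplasmy call tables with
  negative-binomial counts, a four-class mutation spectrum, low-frequency
  skewed MAFs, sequencing batches, multi-year recaptures with per-site
  persistence, and sporadic oxidative "spike" events.
* **Calling** (`mitodyn.calling`): circular handling by copying the first
  and last 500 bp to the opposite ends with an invertible coordinate map;
  an exact binomial-tail caller against the pileup's error rate with
  Bonferroni correction across assayed sites; retention filters MAF > 1%,
  depth > 1000X, and primer/repeat masks; duplicate detections from the
  circular pads merged back to original coordinates.
* **Evaluation** (`mitodyn.evaluation`): Power (true sites called),
  Accuracy (called true sites with predicted frequency within ±0.01 of
  truth), false-positive rate, and the composite score

  `score = Power × Accuracy × (1 − FPR)  ∈ [0, 1]`,

  over a 50X–25,000X coverage grid, for any caller conforming to a
  one-function interface.
* **QC** (`mitodyn.qc`): the duplicate-treatment concordance screen
  (IQR outlier removal, cutoff = ⌊mean + 2·sd⌋ of retained differences)
  and the 1000X mean-coverage filter.
* **Characterization** (`mitodyn.characterize`): the four substitution
  classes (G:C↔A:T transitions; G:C↔T:A oxidative, A:T↔T:A and G:C↔C:G
  transversions), Ts/Tv, coding-effect annotation under the vertebrate
  mitochondrial code, KS / Mann-Whitney spectrum comparisons, Pearson χ²
  partition enrichment, and private/shared site partitioning.
* **Inference** (`mitodyn.inference`): NB2 GLM of heteroplasmy count on
  age (log link), AICc, Cook's-distance influence diagnostics,
  1000-replicate case or parametric bootstrap, 1000-replicate
  recapture-choice permutation, Kruskal-Wallis batch tests, and
  longitudinal change/sharing summaries.
* **I/O + CLI** (`mitodyn.formats`, `mitodyn.cli`): TSV and single-sample
  VCF v4.2 call tables, YAML run configuration, and the `mitodyn` command
  (`sim`, `call`, `evaluate`, `qc`, `characterize`, `fit-age`,
  `longitudinal`).

## Worked example

```python
import mitodyn as md

genome = md.generate_mitogenome(16211, seed=11)
truth = md.generate_truth_set(genome, seed=12)
print(len(truth), truth.n_excluded_sites)
# 496 2          <- 500 drawn, 2 sites collided between frequency sets

pileup = md.simulate_pileup(genome, truth, coverage=5000,
                            error_rate=0.001, seed=13)
calls = md.call_sites(pileup)
m = md.evaluate_calls(truth, calls, n_assayable_sites=17211)
print(f"power={m.power:.3f} accuracy={m.accuracy:.3f} "
      f"fpr={m.fpr:.5f} score={m.score:.3f}")
# power=1.000 accuracy=0.986 fpr=0.00000 score=0.986
```

Every planted variant is recovered at 5000X (power 1); 98.6% of the
recovered variants have an estimated MAF within ±0.01 of the planted
frequency; no false site is called among the assayable non-variant
positions, so the composite score is 0.986. At 50X the same caller's power
collapses below 50%, which is why samples averaging under 1000X are
discarded by `mitodyn.qc.coverage_filter`.

For the population layer:

```python
pop = md.simulate_population(seed=3)
data = md.inference.age_association_dataset(pop)
fit = md.fit_nb_glm(data["count"], data["age_num"])
print(f"slope={fit.slope:.4f} (SE {fit.se_slope:.4f}, p={fit.p_slope:.4f})")
# slope=0.1674 (SE 0.0452, p=0.0002)
```

The generator plants a log-linear age effect of 0.1289 on heteroplasmy
counts; one realization of 167 individuals recovers a slope of 0.167 with
Wald SE 0.045.

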