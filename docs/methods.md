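# Methods

This note records the models behind each stage of the pipeline, the
parameters that matter, the numerical and design choices taken where the
procedure was genuinely open, and what the synthetic data can and cannot
show about real sequencing data.

## Pileup simulation and the caller it feeds

Read-level simulation is deliberately out of scope: every downstream
metric in this package consumes per-site base counts, so the simulator
works at count level. At each of the L sites, depth is Poisson around the
nominal coverage (`exact_mode` pins depth to the nominal value and the
minor-allele count to `round(f · depth)`, giving deterministic fixtures);
at a planted variant the minor-allele count is Binomial(depth, f); then
every observed base is independently mis-read with probability
`error_rate`, uniformly into the three other bases. The default
`error_rate = 0.001` is a typical post-QC Illumina substitution rate; it
is a scalar, so context-dependent error (motif, strand, cycle) is not
represented. Consequences: the benchmark here cannot reproduce published
per-caller score curves built on read-level error models, and
base-quality recalibration has no meaning at this level (a documented
fidelity gap). What the benchmark does preserve is the structure of the
protocol: truth design, coverage grid, metric definitions and the
composite score.

The native caller tests the minor-allele count at each covered site
against an exact binomial null with per-specific-base error probability
`error_rate · 2/3`, and applies Bonferroni correction across assayed
sites (α = 0.05 by default). It is LoFreq-like in spirit — a raw-count
significance test rather than a likelihood-ratio genotyper — and exists
so the scoring framework has a system under test; alternative callers
plug in through the one-function `Caller` interface.

### Truth-set design

Variants are planted in independent sets of 100 at MAF 1, 4, 7, 10 and
15%. Positions drawn in two or more sets are excluded *from every set
they occurred in*; with the full-size genome this removes a handful of
sites per run (500 − 2·k survivors for k pairwise collisions), and on a
500-site genome the surviving count has closed-form expectation
500·(4/5)⁴ = 204.8, which the test suite verifies by simulation.

### Metric conventions

The phrase "proportion of true sites with predicted frequency within
±0.01" is implemented inclusively and conditionally on detection
(denominator = called true sites), so Accuracy measures frequency
estimation and Power measures detection, as distinct failure modes; the
unconditional denominator is available as a switch. FPR uses assayable
non-variant sites as denominator, with the 1−precision reading available
as a switch. Both switches default to the convention used throughout the
package's own analyses.

## Circular coordinates

The extension copies the last `pad` bases in front and the first `pad`
bases behind (default pad 500, giving 17,211 extended positions for the
16,211 bp default genome). The map back is total: extended position j ≤
pad maps to L − pad + j; pad < j ≤ pad + L maps to j − pad; larger j wraps
to j − pad − L. Duplicate detections of one original site are collapsed
keeping the deeper record. A rotation test (call on a rotated genome,
un-rotate, compare) guards the arithmetic.

## Filters and QC rules

Retention thresholds are strict inequalities — MAF > 1%, depth > 1000X —
following the wording they implement; the boundary convention is a
documented open point, and a planted variant at exactly 1% therefore
survives the *caller* but not the *filter*. The duplicate-concordance
rule operates on per-sample absolute count differences between the
duplicates-retained and duplicates-removed runs: differences more than
2 IQR below Q1 or above Q3 are discarded (quartiles by linear
interpolation — the convention is configurable because the original is
unstated), and the cutoff is ⌊mean + 2·sd⌋ of the remainder (sample sd).
Only the upward cutoff is applied, since differences are non-negative.
The coverage filter drops samples *below* 1000X mean coverage, so the
boundary sample is retained.

## Mutation classes and coding effects

The four strand-symmetric classes partition the 12 ordered substitutions:
G:C↔A:T (transitions, 4 ordered pairs), G:C↔T:A (oxidative transversions,
4 pairs), A:T↔T:A (2), G:C↔C:G (2). Ts/Tv is transitions over all
transversions and is reported as undefined (None) when there are no
transversions. Translation uses the vertebrate mitochondrial code
(NCBI table 2) — the organism forces it; TGA = Trp is the classic
divergence from the standard code. For minus-strand genes the codon is
read from the reverse complement and the substituted base is
complemented. A position inside two protein features is annotated against
both. Deleteriousness of nonsynonymous changes is a pluggable scorer; the
default labels a replacement Deleterious when its BLOSUM62 score is
negative. This is a crude conservation-free stand-in for alignment-based
scores such as PROVEAN and is not comparable with published
Deleterious/Neutral counts.

χ² enrichment uses the 2×2 heteroplasmic/homoplasmic × in-bin/out-bin
table without Yates correction (configurable); the enrichment flag
compares the statistic with a caller-supplied df=1 critical value (3.841
for p<0.05, 10.828 for p<0.001).

## The population generator

The generator's defaults are the study conditions the rest of the
package is exercised under:

| parameter | default | meaning |
|---|---|---|
| cohort sizes | 88/26/22/12/3/3/13 for ages 0–6+ | 167 unique individuals; the oldest cohort is coded age 6 |
| NB intercept, slope | −0.1288, 0.1289 | log-linear age effect on counts |
| NB dispersion θ | 2.0 | moderate overdispersion (Var = μ + μ²/θ); ∞ gives the Poisson limit |
| class mixture | 0.606 / 0.319 / 0.075 / 0 | marginal class probabilities |
| P(MAF < 5%) | 0.776 | sets the rate of a truncated-exponential MAF law on (1%, 50%] |
| batches | 4, assigned at random | no built-in batch effect (null for the KW test) |
| recapture design | 3×4, 8×3, 10×2 years | 21 recaptured individuals, 56 samples, 2013–2016 |
| persistence | 0.15 | per-site probability a previous year's site is seen again |
| spike probability | 0.05 per sample | oxidative spike events of 4 + Poisson(1) extra calls |
| hotspots | 40 sites, 25% of fresh calls | recurrently heteroplasmic sites that create sharing |

Sampling proceeds in two passes. The structural pass draws per-sample
count targets NB(μ(age), θ), carries each previous-year site forward with
the persistence probability, and adds spike calls. The assignment pass
then draws classes, positions, alleles and MAFs. Spike calls are forced
into the oxidative class — that is the phenomenon they model — so the
class vector applied to non-spike calls is corrected using the realized
spike load such that the *marginal* mixture matches the configured
targets in expectation. This keeps "oxidative transversions concentrated
in few individuals" compatible with a stable marginal spectrum, and makes
the ±2% calibration check a property of the construction rather than a
tuned constant. The MAF law is Exponential truncated to (1%, 50%] with
rate chosen in closed form from the configured P(MAF<5%); persisted sites
keep their MAF up to a small lognormal jitter (σ = 0.2 on the log scale),
emulating the year-to-year frequency stability of persistent
heteroplasmies.

What the generator does *not* emulate: maternal inheritance structure
(shared sites arise from hotspots, not pedigree), tissue specificity,
batch-correlated artefacts, length heteroplasmy, and any mechanistic
link between oxidative spikes and subsequent counts beyond persistence.
Passing tests therefore demonstrate the correctness of the analysis
chain under these stated conditions, not the biology of any real
population.

## Inference

The age model is an NB2 GLM fit by full maximum likelihood
(statsmodels), reporting Wald tests, θ = 1/α, and
AICc = AIC + 2k(k+1)/(n−k−1) with k = 3 (two coefficients plus the
dispersion). The oldest cohort label "6+" is coded as 6; unusable ages
are excluded by the caller. Cook's distances come from the GLM influence
machinery with the MLE dispersion held fixed; the default flag threshold
is 8/(n − 2k) with k = 2 coefficients, and removal of flagged points is
an explicit user action, never automatic. The bootstrap defaults to case
resampling with replacement (B = 1000), with a parametric option
(responses simulated from the fitted NB) behind a flag; both are
reported because both conventions are in circulation, and replicates
that fail to converge are dropped and counted. The recapture permutation
draws one usable-age sample per individual uniformly at random, refits,
and reports the fraction of replicates with Wald p < 0.05 plus the mean
and range of the slope; no influence removal happens inside replicates.
The batch test is Kruskal-Wallis with tie correction; for tiny inputs an
exact permutation-enumeration p-value is available (`method="exact"`),
and a degenerate all-identical input returns statistic 0, p = 1.

Longitudinal summaries classify each pair of successive observations as
increase / decrease / no change; only consecutive-year intervals enter
the mean/sd, with non-consecutive gaps flagged and excluded (matching
how sparse recapture series are handled). Sharing counts distinct
(individual, site) pairs — a site is matched across years by position
*and* minor allele — seen at ≥ 2 time-points, and at all of an
individual's time-points. Signed interval changes telescope to
(last − first) count per individual, which the tests assert on every
synthetic history.

## Problem sizes and determinism

Every generator and resampling routine takes a seed and is byte-stable
given it. The shipped test suite and the acceptance script are sized for
a single CPU: full-genome (16,211 bp) benchmarks, populations of ~200
samples, 10,000-call calibration runs, B = 1000 bootstrap and permutation
replicates in the acceptance script and smaller B in unit tests. These
sizes are the package's chosen study scale; all of them are parameters.

## Known limitations

* No read-level realism (mapping, duplicates, quality strings, BQSR);
  the pipeline starts at pileups by design.
* Indels and length heteroplasmy are out of scope; point heteroplasmy
  only.
* The default deleteriousness scorer is not PROVEAN-equivalent.
* The batch-random-effect mixed model is intentionally absent: with the
  generator's batch-null design (and in the motivating analyses) the
  random-effect variance collapses to zero, so the plain GLM is the
  supported model.
* Printed-literature Ts/Tv values for this kind of data can be
  inconsistent with printed class fractions (different denominators);
  this package always computes Ts/Tv as transitions over all
  transversions of the same call set.
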