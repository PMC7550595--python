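# Methods

## The mixed-mating model

Each seed of an open-pollinated family is selfed with probability
1 − *t* or outcrossed with probability *t*. Conditional on the true
maternal genotype, a selfed seed is the random union of two maternal
gametes; an outcrossed seed receives one maternal gamete and one pollen
allele drawn from a population pollen-frequency vector. Pollen and ovule
frequencies are estimated separately by default (they were heterogeneous
in the motivating data); pooling is an option (`EMOptions.pool_pollen_ovule`).

Null alleles are part of the likelihood, not a preprocessing fix. A
locus flagged for nulls carries a NULL class in its pollen and ovule
vectors, and a scored phenotype is matched against every true genotype
that masks to it: an apparent homozygote (*k*,*k*) ↔ {(*k*,*k*),
(*k*,NULL)}; an untyped individual at a null locus ↔ (NULL,NULL).
Missing data at a null-free locus contributes likelihood 1. These
phenotype distributions sum to one over the observable phenotype space
for any maternal genotype, rate and null frequency (tested by exhaustive
enumeration).

Maternal genotypes are integrated, not hard-assigned: a recorded
heterozygous mother is a point mass, an apparent homozygote at a null
locus keeps both null-consistent candidates, and an unrecorded mother is
integrated over the family's allele support, with prior
P(*kk*) = *p*² + *Fp*(1 − *p*), P(*jk*) = 2*p*<sub>j</sub>*p*<sub>k</sub>(1 − *F*).
The inbreeding coefficient *F* of the maternal parents is estimated from
this prior term.

### Estimation

The per-population composite log-likelihood is the sum over loci of
family log-likelihoods (maternal candidates integrated per locus). Each
iteration:

1. exact 1-D maximization of each single-locus rate *t*<sub>s,j</sub>
   (bounded golden-section search on the exact per-locus likelihood);
2. expected-count updates of pollen frequencies (posterior paternal-allele
   counts over outcross-weighted cells), ovule frequencies (posterior
   maternal-genotype counts) and a 1-D maximization for *F*;
3. the frequency/F block is reverted if it ever decreases the composite
   log-likelihood (this can only happen when a rate sits above 1, where
   the EM weights leave [0,1]), so the reported log-likelihood is
   non-decreasing by construction — a property the tests assert on 50
   random datasets.

Convergence is |Δ log L| < 1e-6 (`tol`), at most 300 iterations
(`max_iter`); frequencies initialize at observed counts (plus 1/2
pseudo-count), *t* at 0.9, *F* at 0. After convergence the multilocus
rate *t*<sub>m</sub> is the 1-D maximizer of the multilocus mixture
likelihood Σ<sub>o</sub> log(*t*·Π<sub>j</sub>Ā<sub>oj</sub> +
(1 − *t*)·Π<sub>j</sub>S̄<sub>oj</sub>), with the per-locus outcross/self
likelihoods marginalized over the maternal posterior. On a single-locus
dataset with frequencies held fixed this maximizer agrees with a dense
grid search of the exact likelihood to < 2e-3 (tested).

**Rates above 1.** *t* is not clamped to [0,1] by default: excess progeny
heterozygosity pushes the maximum-likelihood rate past 1, and the
estimator follows it as far as every per-offspring mixture term stays
positive (data-dependent upper bound, capped at 1.99). Truncation to 1.0
is applied only when averaging rates across populations, matching the
convention of the published summaries. `constrain_t_to_unit=True`
restores the [0,1] constraint.

### Correlation parameters (two-stage)

After the EM converges, the correlations are maximized on pairwise
composite likelihoods over sib pairs — a deliberate two-stage deviation
from a joint fit, chosen for stability:

* **r<sub>p</sub>** (correlation of paternity): a pair of outcrossed sibs
  shares one father with probability *r*<sub>p</sub>. With the father at
  HWE in the pollen pool, the shared-father pair likelihood per locus has
  the closed form ½Σ<sub>a</sub>p<sub>a</sub>q₁(a)q₂(a) + ½Ā₁Ā₂ where
  q<sub>i</sub>(a) is sib *i*'s likelihood given paternal allele *a*;
  independent fathers give Ā₁Ā₂. Multilocus values are products over
  loci (father genotypes are independent across loci). Pairs are
  weighted by their posterior probability of being both outcrossed;
  *r*<sub>p(s)</sub> is the mean of per-locus maximizers. The search is
  bounded to the interval on which every pair likelihood is positive, so
  negative estimates are attainable (and occur in the motivating data).
* **r<sub>s</sub>** (correlation of selfing among families): exchangeable
  correlated-Bernoulli pair model, P(both selfed) = s² + r<sub>s</sub>s(1−s)
  with s = 1 − *t*<sub>m</sub>; undefined (NaN) when s ≤ 0 — which
  includes every population fitted at *t*<sub>m</sub> ≥ 1.
* **r<sub>loci</sub>**: mean over locus pairs of the correlation, across
  offspring, of per-locus posterior selfing indicators.

The exact internal parameterization of r<sub>s</sub> and r<sub>loci</sub>
in the classic MLTR program is not published; these operational
definitions are validated by simulation recovery only (boundary designs
recover r<sub>s</sub> ≥ 0.8 when families are all-selfed/all-outcrossed,
|r<sub>s</sub>| ≤ 0.15 under homogeneous selfing at 100 families).

### Bootstrap

Standard errors resample whole families (progeny arrays) with
replacement and refit; the default B = 1000 matches the convention of
this analysis type, while the bundled acceptance run uses B = 50 per
population to keep the full six-population pipeline within a desk-scale
runtime (the estimator, not the SE resolution, is the object under
test). Failed replicates are dropped and counted. Everything is
deterministic given the seed.

## Genotyping-error screens

All three diagnostics compare observed genotype counts with Monte-Carlo
randomizations of the pooled allele list (random re-pairing of the 2N
gene copies; 1000 reps and α = 0.05 by default — the classic defaults,
none being published for the motivating study):

* **null alleles** — total homozygote excess significant *and* evenly
  spread: at least half of the allele classes in positive excess, no
  class contributing more than half the total. The verbal "evenly
  distributed" criterion had to be operationalized; this rule holds the
  false-positive rate at ≤ α on clean data while flagging a 0.2-frequency
  null at n = 150 with power ≥ 0.8 (both tested).
* **stutter** — significant deficit of heterozygotes exactly one repeat
  unit apart together with an overall homozygote excess.
* **large-allele dropout** — Spearman rank correlation of per-class
  homozygote excess with allele size, two-sided permutation test.

Null-allele frequency ("oosterhout" method): with null frequency ν the
visible frequencies are the apparent ones times (1 − ν), and the
expected apparent homozygosity among typed individuals is
[(1 − ν)Σa² + 2ν]/(1 + ν) — monotone in ν, solved to 1e-6 against the
observed homozygosity. Brookfield's (He − Ho)/(1 + He) and Chakraborty's
(He − Ho)/(He + Ho) closed forms are retained as cross-checks; the
iterative estimator is unbiased under the generative null model (it
inverts it exactly in expectation) while Brookfield's is slightly
conservative (they agree within 0.03 at n ≥ 300, ν = 0.15; tested).

Screening pools all families of a population as if unrelated. Progeny
arrays are *not* unrelated — sibs share maternal alleles — so the
randomization null is an approximation that inflates homozygote-excess
signals somewhat; on the synthetic study this shows up as occasional
null-allele false positives at clean loci. This bias is inherent to
pooled screening of family data and is documented rather than corrected.

## Population structure

The differentiation estimator is frequency-based with an **unweighted**
mean frequency p̄<sub>jk</sub> across populations (the formula as printed
in the motivating analysis; Weir–Cockerham weights by sample size — a
size-weighted p̄ is available as an option for comparison). Two
properties are consequences of the printed form and are covered by
oracle tests: F<sub>st</sub> ≥ 0 always, and the (r − 1) divisor lets
the estimator exceed 1 — two populations fixed for different alleles
give exactly 2.0. Sample sizes n<sub>i</sub> are counted in individuals;
the estimator is invariant to uniform rescaling of all n<sub>i</sub>
(tested), so the individuals-vs-genes convention only moves the χ²
statistic, not F<sub>st</sub>. The multilocus value is the ratio of
summed numerators to summed denominators; pairwise matrices apply the
same machinery at r = 2.

Distances are great-circle (haversine, Earth radius 6371.0088 km) on the
population coordinates, natural log in the Rousset regression. OLS
coefficient p-values are reported alongside a one-sided Mantel
permutation p for the slope, because the 15 pairwise F<sub>st</sub>
values share populations and are not independent.

## The synthetic-data generator

The generator emulates the field design the estimators assume: Dirichlet
ancestral frequencies evolved by multinomial drift with island or
stepping-stone migration (frequency-level, not individual-based — only
frequency statistics are consumed downstream); mothers drawn from exact
inbreeding-adjusted genotype probabilities; family-shared selfing status
with probability r<sub>s</sub> (giving sib pairs exactly that
correlation); one shared father per family with probability
r<sub>p</sub>; biparental inbreeding as fathers who are half-relatives
of the mother (one gamete drawn from the maternal genotype) — a simple
mechanism that provably separates t<sub>m</sub> from t<sub>s</sub>; and
genotyping errors applied to true genotypes (deterministic null masking,
one-repeat stutter rescoring, size-rank-weighted dropout). All
randomness flows from one seed through `numpy.random.SeedSequence`
spawning.

The `study-like` preset reproduces the published sampling frame: six
populations at the published coordinates and altitudes, family counts
(23, 12, 16, 20, 24, 30) and seed totals (132, 64, 90, 119, 138, 300),
eight loci with allele counts (14, 44, 30, 30, 5, 24, 47, 14) spaced one
repeat apart within the published size ranges, null alleles at frequency
0.15 at the loci flagged per population in the published screening, and
per-population selfing rates in the reported 0–0.16 range with paternity
correlations in 0–0.45. Stepping-stone migration (m = 0.05, N<sub>e</sub> = 50,
100 generations) along the west-to-east chain produces an
isolation-by-distance signal; these values were fixed once as a
realistic regime for strongly differentiated SSR data.

What the generator does **not** emulate: microsatellite mutation,
selection, overlapping generations, within-population spatial genetic
structure, allele-size homoplasy, and dependence of null alleles on
primer-binding genealogy. Passing recovery tests therefore demonstrate
estimator correctness under the model's own assumptions, not robustness
to every field complication.

## Numerical choices

* Likelihood floors at 1e-300 before logs; candidate priors clipped at 0.
* 1-D maximizations use bounded Brent (`scipy.optimize.minimize_scalar`,
  xatol 1e-8 for rates, 1e-6 for F and correlations).
* Correlation searches are restricted to the interval keeping every pair
  likelihood positive (data-dependent; may exclude −1 or +1).
* Ties in modal maternal genotypes resolve by dict insertion order
  (canonical genotype enumeration), making runs reproducible.
* Monomorphic loci are excluded from t<sub>s</sub> averaging and from
  screening (`NotScreenableError`); an all-monomorphic population is an
  estimation error.
* Degenerate inputs: F<sub>st</sub> with a zero denominator is reported
  missing; pairs with F<sub>st</sub> = 1 are excluded from the IBD
  transform with a warning; r<sub>s</sub> at s = 0 and N<sub>ep</sub> at
  r<sub>p(m)</sub> ≤ 0 are NaN.

## Problem sizes used in validation

Recovery batteries run at the study's design scale: 50 replicates of 30
families × 10 seeds × 8 loci (8 alleles each) for t<sub>m</sub>
(observed bias ≈ 0.001, RMSE ≈ 0.02 at t = 0.85), 100 families for
r<sub>p</sub> (±0.1), n = 300 for null-frequency recovery (±0.05), 100
clean replicates for screen false-positive rates, and 20 stepping-stone
replicates for the isolation-by-distance Mantel test. The acceptance
script repeats these from scratch and additionally runs the full
six-population pipeline with a B = 50 family bootstrap.

## Known limitations

* The multilocus likelihood marginalizes maternal candidates per locus
  before forming the cross-locus product, which slightly decouples the
  shared selfing status from maternal uncertainty; with recorded mothers
  (the motivating design) the approximation is exact except at
  null-flagged homozygous loci.
* Pooled-family screening inflates homozygote-excess signals (above).
* The two-stage correlation estimators condition on the converged
  rates/frequencies; their bootstrap SEs include that conditioning.
* The island-model gene-flow relation is treated as an exact algebraic
  identity for inversion purposes and is not itself validated against
  simulation.
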