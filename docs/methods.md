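# Methods

## Generative model

A two-locus penetrance model consists of minor allele frequencies
`q1, q2 ∈ (0, 0.5]` and a 3×3 table `p_ij = P(case | dose1 = i,
dose2 = j)`. The loci are assumed to be in Hardy-Weinberg equilibrium
and in linkage equilibrium with each other, so the joint genotype
frequency is the outer product of the two HWE margins
`((1−q)², 2q(1−q), q²)`. Derived quantities:

- prevalence `K = Σ_ij f_ij p_ij`;
- heritability `h² = Σ_ij f_ij (p_ij − K)² / (K(1−K))`, the
  penetrance-variance definition used by table-based epistasis
  simulators;
- marginal penetrances `m1_i = Σ_j P(dose2 = j) p_ij` (flat margins mean
  no single-locus effect).

Balanced case-control data are drawn directly from the analytic
conditionals `P(cell | case) = f_ij p_ij / K` and
`P(cell | control) = f_ij (1 − p_ij)/(1 − K)` (exactly n/2 of each
status, multinomial over cells, rows shuffled). This is equivalent in
distribution to sampling a population and rejecting until the quotas are
met, but runs in deterministic time even at prevalence 0.02.

## Bundled scenario tables

Fifteen models covering every MAF pair from {0.1, 0.2, 0.3, 0.4, 0.5}
are bundled as a digest-checked YAML fixture. All fifteen encode a
heritability of 0.005 to within ~5e−5, and fourteen imply the design
prevalence of 0.50 to within 1e−3. One table (Scenario 11, MAF 0.5/0.1)
implies K ≈ 0.328 despite an exactly on-design h²; no rearrangement of
its nine printed values can reach K = 0.5, so the table is internally
consistent as published but off its stated design prevalence. It is
retained verbatim: the test suite documents the anomaly, and the
balanced sampler is well defined for any K ∈ (0, 1). The prevalence
summary reported by `scripts/acceptance.py` is therefore the median over
the fifteen models.

Matrix orientation is rows = SNP1 dose, columns = SNP2 dose; the
orientation and the row/column grouping of the fixture were validated by
requiring the (K, h²) design constants to hold simultaneously, which
pins them uniquely.

## Splitting

Both splitters fix the global train size at `floor(f·n)` (`f` = 2/3 by
default) so the two methods are always compared at identical partition
sizes. The traditional splitter takes a uniform random subset. PICV
apportions the global total over the 9 genotype strata by largest
remainder: stratum k of size `m_k` receives `floor(f·m_k)` or
`ceil(f·m_k)` training members, with the largest fractional parts
rounded up (ties broken toward larger strata, then lower stratum index,
so apportionment is deterministic given the data). Strata of size 1–2
may land entirely in one partition; this is logged at debug level.
PICV stratifies by genotype only, not genotype×status, so within-stratum
case proportions can still drift between partitions. Arbitrary integer
strata are accepted behind an explicit `generic=True` flag, which is the
extension point for binned continuous variables.

## Logistic models

SNPs enter as 3-level categorical variables under treatment coding with
reference genotype (0, 0) (any full-rank coding gives the same fitted
probabilities; the likelihood-ratio statistic is invariant to the
reference choice, which is tested). The interaction model adds the four
non-reference dummy products, making it saturated on the 9 cells when no
covariates are present; its MLE is then the observed per-cell case
fraction, used as an exact fast path. The covariate-free main-effects
model is fit by IRLS on the 9 aggregated binomial cells; fits with
covariates use individual-level IRLS. Both routes are required (by test)
to match a direct individual-level Newton fit to 1e−8 in log-likelihood.
Log-likelihoods are always reported on the Bernoulli scale so nested
fits are directly comparable; the interaction LRT has df = 4 on
full-cell data (df is computed from actual parameter counts when cells
or levels are empty).

Degenerate situations are data, not crashes: an all-case or all-control
cell saturates at probability 1 or 0 and is flagged; a genotype cell
absent from training drops its interaction dummy, and test rows in that
cell are predicted from the main-effects part of the fit; IRLS is capped
at 100 iterations and non-convergence is flagged on the fit object.
Classification uses `P(case) > cutoff` with ties assigned to control.

## Consistency statistics

Sensitivity, specificity, PPV and NPV carry NaN when their denominator
is zero; gaps |train − test| propagate NaN, and a replicate enters a
method comparison only if its gap is defined for both methods (pairwise
exclusion, with drop counts reported). The one-sided two-sample KS
statistic is `D = max(0, sup_x ECDF_picv(x) − ECDF_trad(x))` over the
pooled points, with the asymptotic p-value `exp(−2 D² n_a n_b /
(n_a + n_b))` capped at 1; a label-permutation p-value is available for
small samples. Medians of even-length gap samples are the mean of the
two central order statistics; "PICV smaller" indicators use strict
inequality, with ties counting as not smaller.

## Study orchestration and seeding

Each replicate simulates a fresh dataset and applies both splitters to
it (paired design; pairing reduces the Monte-Carlo variance of the
between-method comparison without changing either method's marginal gap
distribution). Unpaired and re-split-one-fixed-dataset modes exist as
flags; in testing, the re-split mode produced the same qualitative
conclusions. Every random draw descends from a counter-based seed
`SeedSequence(base_seed, (scenario_index, replicate))`, so any table
cell is reproducible in isolation and scenarios are embarrassingly
parallel. Replicate failures are recorded with reasons and a scenario
with more than 10% failures is marked invalid.

## Which measures PICV improves, and why

In this harness PICV strongly tightens train/test consistency of
sensitivity and specificity, while PPV and NPV improve only marginally.
The structure of the measures explains this. Sensitivity and specificity
have partition-level denominators (the case or control count of the
partition) and numerators tied to how much genotype mass falls in the
predicted-positive cells; the traditional splitter perturbs that mass
allocation between partitions, and PICV removes exactly that
perturbation. PPV and NPV, by contrast, are cell-total-weighted averages
of per-cell case fractions over the predicted-positive (or negative)
cells: fluctuations in the cell totals move numerator and denominator
together and cancel to first order, so their dominant noise is the
within-cell split of cases — which stratifying on genotype alone cannot
reduce. Stratifying on genotype×status would, but is a different method.
Median and maximum gaps favor PICV for all four measures in most
scenarios.

## Problem sizes used in the checks

The acceptance computations run the 15 bundled scenarios at n = 2000
with 200 paired replicates each (interaction model), which resolves the
sensitivity effect (one-sided KS D ≈ 0.10–0.15) in nearly all scenarios;
at 1000 replicates all 15 reject. Auxiliary calibrations use 2000
null-model replicates at n = 1000 for the LRT type-I error and 1000
random instances for the KS brute-force comparison.

## Known limitations

- The simulator models two unlinked loci only: no linkage
  disequilibrium, genotyping error, missingness or population structure,
  and covariates are never simulated (the covariate interface exists for
  real-data LRT use). Passing tests therefore speak to the splitting
  methodology, not to robustness against those real-data features.
- Only single 2/3–1/3 splits are implemented, not k-fold or nested
  variants.
- The asymptotic one-sided KS p-value is conservative at small sample
  sizes; use the permutation option below ~30 gaps per arm.
- No multiple-testing correction is applied across the scenario × measure
  × model grid of KS comparisons; each test is at α = 0.05.
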