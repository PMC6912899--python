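# Methods

## Demographic model

Two populations of constant effective sizes `N1` and `N2` (all sizes in
*gene copies*; diploid individuals carry two, mtDNA one) descend from an
ancestral population of size `N_anc` that split `t2` generations before
sampling. Migration is bidirectional, not necessarily symmetric, and
expressed backward in time: `m12` is the per-generation probability that a
lineage now in population 1 traces back to population 2. The four scenarios
differ only in the migration window: `[0, t2)` (scenario 1), `[t1, t2)`
(scenario 2, recent isolation), none (scenario 3), `[0, t1)` (scenario 4,
recent migration). Windows are half-open in generations before present;
the boundary cases collapse scenarios onto each other exactly (scenario 2
with `t1 = 0` is scenario 1, scenario 4 with `t1 = t2` is scenario 1,
scenario 1 without migration is scenario 3), which the tests verify
bit-exactly under shared seeds.

Each parameter draw yields a *paired* dataset. Both marker classes share
`t1`, `t2` and the scenario but have their own sizes, migration and
mutation rates — the mitochondrial effective size is free to be much
smaller than the nuclear one, which is exactly the degree of freedom needed
to explain strong mitochondrial alongside weak nuclear differentiation
without invoking sex-biased dispersal. Genealogies are drawn independently
given the shared history.

Ancestry and mutation are delegated to msprime. Gene-copy sizes are
converted to msprime population sizes so that two lineages in a population
of `N` gene copies coalesce at rate `1/N` per generation regardless of
ploidy. The 25 microsatellite loci are simulated as independent single-site
replicates; internally the per-locus genealogies are packed into one tree
sequence (locus `l` spanning the unit interval `[l, l+1)`) so a single
mutation pass covers all loci — a performance device only, the law of the
process is unchanged.

## Mutation models

*Microsatellites.* Generalized stepwise model on a bounded repeat-count
state space `[1, 100]` (ancestral state 50): a mutation shifts the count by
±k with k geometric(`p_gsm`), default `p_gsm = 0.22`, a common literature
value for the multi-step tail; `p_gsm = 0` degenerates to the strict
single-step model. Steps that would leave the state space are redistributed
by row renormalisation of the transition matrix, making the lower bound a
reflecting floor — allele sizes can never reach zero. Allele sizes are kept
on the repeat scale throughout; no fragment-length conversion exists in the
package because every statistic depends only on differences between counts.

*mtDNA.* Finite-sites mutation on a 2,516-bp non-recombining fragment with
transition probability `kappa_like = 0.7` per substitution (an HKY rate
matrix with kappa = 2·0.7/0.3 ≈ 4.67 under equal base frequencies).
Invariant sites receive i.i.d. random background bases; only segregating
columns carry signal, so this choice affects no statistic.

## Priors

Reference priors are deliberately broad: `N` log-uniform on [10², 10⁶] gene
copies per marker class, `t2` log-uniform on [10², 10⁶] generations,
`t1 = u·t2` with `u ~ Uniform(0, 1)` (so the constraint `t1 ≤ t2` holds by
construction), migration rates log-uniform on [10⁻⁶, 10⁻²], microsatellite
mutation rate log-uniform on [10⁻⁴, 10⁻³] per locus per generation, mtDNA
rate log-uniform on [10⁻⁹, 10⁻⁷] per site per generation. All are
overridable through `PriorSpec.with_overrides`.

## Summary statistics

The 19-statistic vector is fixed in name and order (`STAT_NAMES`).
Degenerate values (no segregating sites, monomorphic samples) map to 0
rather than NaN so no reference-table row is ever dropped — random forests
handle constant features gracefully, whereas dropping rows would distort
the prior. Fu's Fs uses `ln(S'/(1-S'))` with `S' = P(K ≥ k_obs)` under the
Ewens sampling distribution; the allele count K is a sum of independent
Bernoulli(θ/(θ+i)) indicators, so `S'` is computed by a stable
Poisson-binomial convolution rather than Stirling numbers (the tests check
it against exact Stirling enumeration). The mtDNA F_ST in the vector is
haplotype-frequency based (identity distances); the distance-based Φ_ST
belongs to the classical toolbox instead.

A note on finite-sample behaviour that the tests encode deliberately: the
unbiased Weir–Cockerham and Nei–Chesser estimators are *not* exactly zero
on two identical finite samples — F_ST, F_IS and Jost's D all carry a small
negative (or positive, for F_IS) O(1/n) term that vanishes as n grows.
The oracle tests pin the estimators to independent transcriptions of the
published formulas; the "no differentiation" tests assert the small-bias
behaviour rather than an exact zero.

## ABC random forests

Model choice trains a 500-tree classification forest (features-per-split
√p, unlimited depth) on the statistics plus the `n_scenarios − 1` linear
discriminant projections; LDA is fitted on the reference with scenario
labels and the observed vector is projected with the same axes. Vote
percentages are the share of trees voting each scenario on the observed
vector; ties break to the lowest scenario id (logged). The prior error rate
is the out-of-bag misclassification rate. The posterior probability of the
selected scenario is a regression-forest estimate of P(correct | statistics)
trained on the out-of-bag correctness indicators and evaluated at the
observed vector. Replicated analyses subsample the reference pool
scenario-balanced and report mean votes with standard errors.

Parameter estimation uses quantile regression forests: training points
sharing leaves with the query define posterior weights (per tree,
`1/leaf_size` for co-resident points, averaged over trees), from which
expectation, median, variance and the 2.5%/97.5% quantiles are read. All
regression forests (parameter forests and the posterior-probability
regressor) use the regression default `mtry = p/3`; the `√p` rule applies
to the classification forest only, following the usual split between the
two forest families.
Parameters with log-uniform priors are estimated on the log10 scale and
back-transformed via `10^x` for reporting. POD validation reports
`NMSE = mean((θ̂−θ)²)/Var(θ)`, `NMAE = mean|θ̂−θ| / mean|θ−mean(θ)|`,
relative credible-interval width `(q97.5−q2.5)/|median|` (mean and median
over PODs) and empirical 95%-interval coverage; these formulas are stated
here because alternative definitions exist, and they are computed on the
estimation (log10) scale.

## Classical statistics

Rarefied allelic richness uses the hypergeometric closed form
`A_r = Σ_alleles [1 − C(N−N_i, g)/C(N, g)]`; private allelic richness is
Kalinowski's product form (probability present in the focal rarefied sample
times the probability absent from every other location's rarefied sample).
AMOVA decomposes squared distances (allele-identity 0/1 per gene copy for
microsatellites, raw pairwise difference counts for sequences — no
substitution-model correction) over up to three levels with the standard
mean-square equations; permutation schemes are units-among-locations
(within groups) for Φ_SC and whole-locations-among-groups for Φ_CT.
Neutrality tests build their null from neutral constant-size coalescent
simulations conditioned on the observed θ̂_π (JC69 on the observed sequence
length); Fu's Fs is tested one-tailed low, Tajima's D two-tailed. The LD
scan estimates two-locus haplotype frequencies from unphased genotypes by
EM (40 iterations from linkage equilibrium) and compares against the
allele-frequency product by likelihood ratio, with the null built by
permuting one locus's genotypes among individuals. A single resampling
engine (permutations + Benjamini–Hochberg at α = 0.05) backs all
differentiation p-values, including Jost's D, for which the original
package used a bootstrap the source does not specify.

## Synthetic study

The study template fixes eleven locations in three regions with the
empirical per-marker sample sizes (e.g. 126 genotyped / 38 sequenced at the
largest location; 44/23 at the second), 25 loci and the 2,516-bp fragment.
Regions are internally connected island models (within-region migration
`10⁻³`–`5·10⁻²` depending on regime). The **discordant** regime uses large
nuclear sizes (2·10⁵ gene copies per location), small mitochondrial sizes
(2·10³), an inter-regional split 2·10⁴ generations ago and a much deeper
Atlantic split (4·10⁵): drift since the split is negligible for the nuclear
markers (F_ST ≈ t/(2N) ≈ 0.05 before mutation further erodes it) but strong
for mtDNA (t/N ≈ 10), reproducing the qualitative mito-nuclear discordance
the scenario comparison is designed to explain. These parameters are the
package's own defaults tuned to that qualitative pattern, not estimates of
any real population. The generator does not emulate genotyping artefacts
(null alleles, allele dropout, size homoplasy beyond the bounded state
space) or within-location spatial structure, so passing tests say nothing
about robustness to those features of real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale as the package's
default experiment sizes: 5,000 reference rows per scenario for model-
choice calibration, 10,000 training rows and 200 PODs for parameter
recovery, 500–800 rows per scenario for end-to-end demonstrations; the full
study scale (200,000 per scenario, 100,000 for estimation, 1,000 PODs) is
reachable through `PipelineConfig`. Permutation and simulation p-values use
the `(hits + 1)/(n + 1)` estimator. All randomness flows from
`numpy.random.Generator` seeds; msprime seeds are drawn from the same
stream, keeping every pipeline stage reproducible from `(seed, config)`.

## What a single mitochondrial locus can and cannot estimate

Under the broad default priors the mitochondrial effective sizes are only
weakly identifiable: the mtDNA statistics constrain θ = 2Nµ L, and with µ
log-uniform over two decades the best possible point estimate of log10 N
inherits the full mutation-rate uncertainty — an NMSE floor of roughly
Var(log10 µ)/Var(log10 N) ≈ 0.25 even before the monomorphic low-θ region
of the prior is counted. The validation experiments reflect this: nuclear
(25-locus) sizes recover with NMSE ≈ 0.09–0.10 and rank correlation ≈ 0.95
at 10,000 training rows, while the single-locus mitochondrial sizes sit
near NMSE ≈ 0.5 with rank correlation ≈ 0.7 — yet their 95% credible
intervals remain honestly calibrated (coverage ≈ 0.92). Sharper mtDNA
size estimates require an externally calibrated substitution rate, i.e. a
much tighter `mu_mt` prior.

## Known limitations

* Microsatellite state space is bounded ([1, 100] by default); at extreme
  θ = 2Nµ the allele-size walk saturates the range and MGW compresses — a
  real feature of bounded microsatellite evolution, but the bound itself is
  a modelling choice.
* The Genepop reader labels populations from the first individual id of
  each `Pop` block (`RUN_01` → `RUN`); files not following that convention
  need a user-supplied sample map.
* Model-choice posterior probabilities are only as calibrated as the
  out-of-bag correctness regression; at small reference sizes they are
  noisy, which the replicate machinery quantifies but does not remove.
* The three-level AMOVA assumes every location belongs to exactly one
  group; unbalanced designs are handled by the standard unequal-size
  coefficients, not by weighting schemes.
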