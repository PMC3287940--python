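# Methods

## Binary multilocus genotypes

Within a gene, each individual's diploid allele count (0/1/2 copies of the
non-common allele) at each site is collapsed to a bit: 0 iff homozygous
for the common allele, 1 otherwise.  Heterozygous and homozygous-rare
carriers are pooled deliberately — rare variants are almost never seen in
two copies, and phasing them is unreliable, so carrier status is the
robust unit of information.  By default the reference allele is treated as
the common allele (the convention of curated simulated exomes); for field
VCFs, `polarize=True` re-polarizes each site to the sample-major allele,
with ties keeping the reference.  Missing genotypes are not modelled: the
default policy codes them as common (conservative toward the null, count
logged per gene), and a strict policy turns them into errors.

## The lexical genotype tree

All individuals start at the root.  Sites are processed in a fixed order —
genomic position by default; carrier-frequency orderings are available —
and every current leaf whose members differ at the site splits, 0-carriers
to `child0`, 1-carriers to `child1`.  Consequences used by the scan:

- leaves biject with the distinct observed BMGs, and their member counts
  partition the sample;
- two BMGs first differing at site *t* separate exactly when *t* is
  processed, so genotypes one mutation apart always cluster;
- node count is at most 2·(#distinct BMGs) − 1, i.e. linear in the sample.

Node patterns (partial BMGs with `#` at sites on which members differ) are
derived on demand from the member sets and the bit matrix rather than
stored, keeping memory linear in individuals.  Node ids follow
construction (breadth-first) order, making exports deterministic.  Trees
serialize to DOT for display and to a lossless JSON schema.

## Node statistic and score transform

Node *i* with members *j* = 1…*n<sub>i</sub>* is scored with
z<sub>i</sub> = √n<sub>i</sub>(x̄<sub>i</sub> − x̄)/s, where x̄ and s are the
mean and sample (n−1) standard deviation of the trait over all
individuals.  x̄ and s depend only on the trait multiset, so they are
computed once and reused across permutation replicates.  Exact identities
used as test oracles: the root's z is 0, Σ<sub>leaves</sub>
√n<sub>i</sub>·z<sub>i</sub> = 0, and z is invariant under positive affine
trait transforms.

The transform f maps z to the non-negative score the scan sums.  The
default is f(z) = z² — two-sided, monotone in |z|, so that both high- and
low-trait carrier clusters count as signal; |z| and the one-sided
max(z, 0)² are selectable.

## The disjoint-node scan statistic

S<sub>j</sub> is the maximum of Σ f(z) over antichains of at most *j*
nodes (no selected node an ancestor of another).  The post-order dynamic
program uses

    best(v, m) = max( f(z_v),  max_{m0+m1=m} best(c0, m0) + best(c1, m1) )

with best(·, 0) = 0 and the empty selection allowed everywhere, giving all
of S₁…S<sub>k</sub> in one O(#nodes·k²) pass.  The "at most" convention
makes S<sub>j</sub> non-decreasing in *j* and means a negative-scored
branch (possible under non-default transforms) contributes zero rather
than a forced pick.  Ties among maximizing antichains break toward fewer
nodes, then the lexicographically smallest id sequence.  The default
budget is k = 10; the power experiments report S₁ and S₅.  An exhaustive
antichain enumerator (guarded to ≤ 30 nodes) serves as an independent
oracle in the tests.

## Permutation significance

The null distribution of S<sub>k</sub> is not analytically available, and
plain trait shuffling is invalid in structured samples, so replicates
relabel trait values uniformly at random **within each population
stratum**: every population's trait multiset — hence mean and sd — is
preserved exactly; singleton strata are fixed points.  p-values use the
add-one estimator p<sub>j</sub> = (1 + #{S<sub>j</sub>* ≥
S<sub>j</sub>})/(n_reps + 1), never zero, minimum 1/(n_reps + 1).

The tree is fixed under the null, so replicates only re-score nodes.  The
engine is batched: a replicate-by-individual matrix of permuted traits
yields all leaf sums in one matrix product, internal sums by child
addition in post-order, and the dynamic program runs vectorized across the
batch (default 2,000 replicates per batch, ~10 ms per gene per thousand
replicates at n = 700).  Per-gene RNG substreams derive from the master
seed and a hash of the gene label, so scan output is bit-identical across
runs, gene orderings and thread counts.  Genes with no BMG variation are
flagged degenerate (S ≡ 0, p ≡ 1).  Multiplicity across genes is handled
by the Bonferroni helper (α/#genes, computed exactly); significance is
reported per S<sub>j</sub> with no correction across *j*, and that
multiplicity is documented rather than corrected.

## Residual phenotypes

`residualize` fits the trait on candidate covariates (Age, Sex, Smoke,
optionally the first N principal-component loadings of the column-centered
allele-count matrix; N = 6 by default) and removes, one term per step, the
term whose removal most decreases BIC, until no removal decreases it (ties
drop the smallest |t|; the intercept always stays; aliased or constant
candidates are dropped up front with a log line).  The standardized
residuals (sample-sd denominator) are the derived phenotype.
`refit_selected` re-estimates an already-selected model on replicate data
without re-selection, as one does when a model chosen on a discovery
dataset is applied to further replicates.  Per-individual heterozygosity
is the fraction of non-missing sites called heterozygous; PC score signs
are fixed (largest-magnitude coordinate positive) so loadings are
reproducible.

## The simulator

`synthetic_data.simulate` emulates a mini-exome study of unrelated
individuals from several populations.  Defaults: 7 populations × 100
individuals, 100 genes × 7 sites, Balding–Nichols divergence F = 0.05,
ancestral frequencies Beta(0.5, 8) clipped to [0.001, 0.5] (heavily
rare-skewed, mean ≈ 0.06), Age ~ N(45, 12²) with population mean offsets
(sd 5 years), Sex ~ Bernoulli(0.5), Smoke ~ Bernoulli(0.25), trait effects
0.02/year of age and 0.25 for smoking, unit Gaussian noise.  Causal genes
act through carrier indicators — β trait-sd per carried causal variant,
matching the collapsing the test targets — using *true* genotypes, while
the scan sees observed ones.  A causal gene whose chosen sites have no
carrier is regenerated with bounded, logged retries.

The optional heterozygosity–trait confound models uneven sequencing
coverage as heterozygote dropout: individual *i* has d<sub>i</sub> ~
U(0, `het_dropout_max`), and each true heterozygote is observed as
homozygous-reference with probability d<sub>i</sub>.  Dropout changes the
expected allele dosage, so the observed-heterozygosity axis becomes a
leading principal component of the allele counts — which is exactly why PC
residualization can remove the confound, and why a variance-only mechanism
(e.g. an inbreeding coefficient) would not be visible to PCA.  The trait
then loads on standardized observed heterozygosity with weight γ;
γ = 0.212 yields a planted trait–heterozygosity correlation of ≈ 0.2 given
the default covariate variances.

What the simulator does **not** model: linkage disequilibrium between
sites (sites are exchangeable given population frequencies), sequencing
reads, genotyping error beyond the dropout channel, relatedness, and
non-Gaussian traits.  Passing calibration/power tests on these data
therefore demonstrate the statistical machinery, not robustness to LD or
pedigree structure in real cohorts.

## Experiments and problem sizes

- *Calibration*: 1,000 null genes, 2 populations × 100 with a one-sd
  between-population trait shift and F = 0.10, 999 replicates per gene.
  Stratified permutation rejects S₅ at ≈ 0.05; an unstratified shuffle on
  the same data inflates several-fold.
- *Power*: 200 genes, 20 causal with four 0.5-sd carrier-effect variants
  each, default 7 × 100 geometry.  S₅ beats S₁ when effects are spread
  over several variants, because disjoint nodes pick up distinct carrier
  subsets.
- *Confound*: 1,000 null genes at 7 × 100 with the dropout confound and
  γ = 0.212.  The raw-trait scan inflates despite stratified permutation
  (the confound varies within populations); residualizing on Age/Sex/Smoke
  + PC1–6 restores nominal calibration.
- *Selection recovery*: 100 replicates of n = 500 with a β = 2 Age effect
  (noise sd 5); backwards-BIC retains Age alone in ≈ 97% of replicates
  (each null covariate survives with the χ²₁ > log n probability ≈ 0.013).

`scripts/acceptance.py` runs the same experiments at 400 genes for the two
1,000-gene studies — the package's choice of a size that keeps the full
script under a couple of minutes while leaving Monte-Carlo error on a
rejection rate near 0.05 at about ±0.011.

## Numerical choices and known limitations

- Permutation comparisons use plain `>=` on floating-point statistics; the
  observed S is computed through the same vectorized path as the
  replicates, so a no-op permutation reproduces it exactly.
- The dynamic program and the enumerator agree exactly (not merely within
  tolerance) on random instances; antichain tie-breaking is deterministic.
- BIC stepwise selection is greedy; it is order-invariant over candidates
  but, like all stepwise procedures, not guaranteed to find the global BIC
  optimum.
- The strength of the confound experiment's inflation depends steeply on
  the *realized* trait–heterozygosity correlation of the simulated
  dataset, whose sampling noise at n = 700 is ≈ ±0.04 around the planted
  0.2; datasets at the low edge show little detectable inflation at
  α = 0.05.  The experiment is therefore run (and reported) at fixed
  seeds, and the realized correlation is always reported alongside the
  rejection rates.
- PC residualization needs enough sites for the heterozygosity axis to be
  estimable: with a few hundred rare sites PCA cannot isolate it, and the
  confound survives residualization.  Around a thousand sites suffice at
  n ≈ 300–700 under the default spectrum.
- Heterozygosity of an all-missing individual is NaN and flagged, never
  silently zero.
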