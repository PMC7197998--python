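# Methods

This note documents the statistical procedures mdrkit implements, the
choices made where conventions differ, and what the synthetic-data tests
do and do not establish.

## Data model and genotype coding

Genotypes are coded as counts of the **minor allele as estimated in the
control group** (0/1/2, `-1` missing).  On input, a column whose coded
allele has a control-group frequency strictly above 0.5 is flipped 0↔2
(and its allele metadata swapped); an exact 50/50 tie keeps the coding as
given, and in the allele-pair dialect ties are broken alphabetically.
Consequence: `write ∘ read` is bit-identical whenever the written coding
already counts the control-minor allele — which holds for every dataset
that satisfies the package's own orientation convention — and reading an
arbitrary file is idempotent after the first normalization.  Positions are
opaque `chr:pos` strings; no coordinate arithmetic is done.

Missing-data policy is per analysis: descriptive counts are over typed
genotypes only; MDR excludes an individual from a combination only when a
genotype at one of *that combination's* SNPs is missing (per-combination
deletion, maximizing data use; per-SNP typed totals in real panels differ
for exactly this reason); entropy measures delete listwise per node/pair
and recompute the phenotype entropy on the same subsample; logistic models
drop rows missing the focal SNP.

## Descriptive genetics

Allele counts derive from genotype counts (minor = n1 + 2·n2 out of
2·n_typed).  Hardy-Weinberg equilibrium is the Pearson chi-square on the
three genotype classes against (p², 2pq, q²)·n from the sample allele
frequency, 1 df, **no continuity correction** — the correction-free form
is what reproduces published HWE columns computed by standard software;
monomorphic SNPs return chi² = 0, p = 1.  Frequencies are rounded (one
decimal percent) only at the rendering layer.

## Association

* **Fisher 2×2**: two-sided by the probability-mass criterion (sum over
  margin-fixed tables with probability ≤ observed), via scipy; the
  reported OR is the sample ad/bc by default (conditional MLE optional).
  The doubling convention, which some packages use, can differ in the
  third decimal; this is documented because printed p-values from older
  software sometimes reflect it.
* **Freeman–Halton r×c**: complete enumeration over margin-fixed tables
  with log-probabilities from `gammaln`, same probability-mass criterion
  with a 1e-7 relative tolerance against round-off.  A product bound on
  the enumeration size raises a capacity error suggesting Monte-Carlo for
  infeasible tables.  No scipy/statsmodels implementation exists, so this
  is hand-written; its test oracle is a separate integer-arithmetic
  enumerator.
* **Codominant logistic regression**: maximum likelihood via statsmodels
  GLM/IRLS; the SNP enters as heterozygote and minor-homozygote indicators
  against the major-homozygote reference; Wald OR, 95% CI
  (exp(β ± 1.96·se)) and p per term.  A genotype class with zero cases or
  zero controls **separates** the likelihood: that term is reported
  non-estimable (the table renders "−") and its individuals are dropped so
  the remaining coefficients equal the MLE of the reduced model.  No Firth
  or exact-logistic rescue — separation is a reportable finding at these
  sample sizes, not a numerical nuisance.  Covariates: age and BMI as
  given, sex as a male indicator; admixture proportions are consumed as
  pre-computed columns, and with k summing to one the caller should enter
  k−1 of them to avoid collinearity (the design matrix is rank-checked and
  collinearity raised explicitly).
* **Interaction corroboration**: main-effect genotype codes (additive
  allele counts by default; dominant carrier indicators optionally, since
  a heterozygote-driven checkerboard is orthogonal to an additive×additive
  product) plus all product terms up to the full k-way product; the
  reported p is the Wald test of the highest-order product.
* **Bonferroni**: α/m at full precision; display truncates to three
  decimals (0.05/9 renders as 0.005).  Allele-row ORs are reported
  unadjusted — whether published allele rows were covariate-adjusted is
  generally ambiguous, and the unadjusted OR is the reproducible choice.
* **Two-sample summary t**: pooled-variance Student t from summary
  statistics (not Welch), matching the convention of clinical tables that
  cite "Student's t-test".

## The MDR engine

Cells are high-risk when `cases/n_cases ≥ T · controls/n_controls`
(cross-multiplied in integers, so a cell with controls = 0 and cases > 0
is high-risk and ties **at** the threshold are high — "met or exceeded");
cells unseen in training are *unknown*.  At prediction time unknown cells
default to **low-risk** (conservative), with `high` and `exclude`
(drop those individuals from the BA denominator) as options; reference
MDR software does not document its rule, so it is exposed.

Folds are stratified by phenotype via a seeded shuffle and dealt
round-robin, and the same partition is shared across all sizes and
combinations so CVC values are comparable.  The per-size winner maximizes
mean training BA with ties broken toward the lexicographically first
SNP-id combination (CVC depends on this, hence it is fixed and
documented).  Reported train/test BA is the mean over folds.  Inside
cross-validation a partition that loses all its valid cases or controls
(possible after per-combination deletion on small data) scores the
undefined sensitivity/specificity component as a neutral 0.5; the public
`balanced_accuracy` still raises on single-class truth.

The permutation test permutes the phenotype alone (covariates ride along;
they do not enter MDR), repeats the full size-k search per relabeling on
the **same fold partition** — exchangeable under the null, and necessary
for the vectorized evaluation — and reports
p = (#{permuted best test BA ≥ observed} + 1)/(B + 1) ∈ [1/(B+1), 1].

Implementation: each combination becomes a one-hot cell-membership matrix
U (3^k × n), so case counts per cell for B phenotype vectors at once are
the single product U·Y with Y (n × B); labeling, prediction and BA are
similarly batched.  Sums of 0/1 values and integer cross-multiplications
are exact in float64, so the vectorized engine is bit-identical to a naive
dict-based implementation — asserted exactly, per fold and per cell, on
100 random instances in the test suite.

## Entropy measures

Plug-in (maximum-likelihood) Shannon estimates, log base 2.  The pairwise
interaction information IG(A;B;C) = I(A,B;C) − I(A;C) − I(B;C) uses the
joint 9-level attribute on the identical sample, so the chain identity
holds to machine precision.  No bias correction: plug-in MI is biased up
by ≈ df/(2n ln 2), and IG inherits a net positive bias of ≈ 4/(2n ln 2)
bits for 3×3×2 attributes (~1.3% of H(C) at n ≈ 239).  Null edges in the
tests are therefore asserted to center on zero *within* that allowance;
percentages are relative to H(C), matching the "% of entropy explained"
semantics of MDR interaction maps.

## Synthetic data generator

The generator emulates the motivating study's conditions — defaults: 92
cases / 147 controls, nine unlinked biallelic SNPs at Mexican-population
MAFs (0.42, 0.30, 0.13, 0.23, 0.38, 0.31, 0.29, 0.13, 0.27), HWE
genotypes, covariates age 47.2±12.4 / 40.9±12.0 years, BMI 29.0±4.19 /
24.8±4.38 kg/m², female fraction 87% / 71.4% (case/control), admixture
proportions Dirichlet(5.0, 3.5, 0.8) (≈ 0.54/0.38/0.08 mean ancestry,
typical of admixed Mexico City samples).  Disease is assigned by a
penetrance model and case/control quotas filled by rejection sampling
(bounded at 10^7 draws), mirroring case-control ascertainment.  The XOR
penetrance (baseline + effect iff exactly one locus heterozygous) is the
canonical purely epistatic pattern: at P(het) = 0.5 both marginals are
flat at baseline + effect/2.  One global seed is split into independent
streams (genotypes, disease, covariates, missingness) via
`numpy.random.SeedSequence.spawn`.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure (the panel convention is LD-free SNPs), population
stratification (admixture covariates are independent of genotype unless a
confounding hook is wired in by the caller), genotyping error beyond
uniform dropout, and quantitative phenotypes.  Passing tests therefore
demonstrate correctness of the algorithms under the stated sampling model,
not robustness to LD or confounding in real panels.

## Validation problem sizes

The acceptance checks run: exact engine-vs-naive-oracle agreement on 100
random instances (≤ 40 individuals × ≤ 4 SNPs); planted-XOR recovery
(baseline 0.05, effect 0.4, MAF 0.3, 400/400) over 100 replicates with a
≥ 95% recovery requirement; and null calibration of the permutation test
(study-sized datasets, k = 2, 99 permutations, 200 replicates, rejection
rate required within 5% ± 3%).  These sizes give binomial standard errors
small enough for the stated bands while keeping a full run in the minutes
range on one core.

## Known limitations

* The Freeman–Halton test is enumeration-only; large sparse tables need an
  external Monte-Carlo approach.
* Balanced accuracies, CVC and permutation p's published from
  individual-level data cannot be reproduced from printed summary tables
  alone; the package reproduces every derivable quantity (allele rows,
  HWE column, demographic tests, thresholds) and validates the rest
  against oracles and planted-truth simulations.
* MDR here is the classical dichotomous-phenotype form: no covariate
  adjustment inside the search (the score-based generalized variant is out
  of scope), no model-based MDR, single-threaded search up to k = 5.
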