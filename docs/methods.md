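# Methods

## Model

`riskfield` models a binary phenotype as a conditional random field on the
space spanned by subjects' genotypes. For subject i with covariates X_i and
genes k = 1..K,

    Y_i = mu_i + sum_k gamma_k sum_{j != i} s_ij^(k) Y_j + e_i,
    mu_i = logistic(X_i beta),

so a subject's phenotype is its GLM mean plus a similarity-weighted sum of
the other subjects' phenotypes. `gamma_k >= 0` means gene k's genotypic
neighborhoods are phenotypically coherent — the gene is predictive.

The similarity is a weighted identity-by-state share over a gene's variants,

    s_ij = sum_l w_l (2 - |g_il - g_jl|) / (2 sum_l w_l),

with dosages g in {0, 1, 2} (minor-allele counts) and MAF-based weights.
Normalization to [0, 1] makes gamma comparable across genes; an unnormalized
variant is available (`normalize=False`) and differs only by a per-gene scale
that the gamma estimate absorbs. The diagonal is zero: a subject never
predicts itself.

### Weight schemes

| scheme | w(q)              | emphasis |
|--------|-------------------|----------|
| UW     | 1                 | none (flat) |
| BETA   | Beta(q; 1, 25) pdf = 25(1-q)^24 | strongly rare |
| WSS    | 1/sqrt(q(1-q))    | rare (Madsen–Browning form) |
| LOG    | \|log10 q\|       | intermediate |

Weights are computed from **training-set** MAF only and frozen for
prediction; variants monomorphic in a training split are dropped from that
split's kernel (their weights are undefined). All four schemes are finite and
strictly positive on q in (0, 0.5], which the QC step guarantees by removing
MAF-zero variants.

## Estimating gamma

Given mu-hat from an independent-Bernoulli logistic fit, the model is linear
in gamma, so the unbiased estimating equations Z'(Y - mu - Z gamma) = 0
reduce to normal equations (identity working covariance). Two instantiations
of the Z columns are implemented.

**Plain** (`estimator="plain"`, also the `estimate_gamma` default contract):
z_k = S_k Y, solved by rank-revealing least squares. This is the literal
autoregressive form; it satisfies Z'(y - mu - Z gamma-hat) = 0 to 1e-8 on
every fit and recovers gamma exactly on data constructed to satisfy
y - mu = gamma S y.

**Adjusted** (default for fitting and forward selection). The plain form is
statistically misbehaved for IBS-type kernels, for two reasons we observed
and characterized during development:

1. *Self-exclusion leak.* Off-diagonal IBS similarities share a large
   baseline s-bar ≈ 0.9 (most pairs share most alleles at most sites). With
   mu estimated, sum(y - mu) = 0, so the quadratic form driving gamma-hat
   satisfies r'S r ≈ s-bar[(sum r)^2 - sum r^2] + signal = -s-bar n sigma^2 +
   signal: the estimate is biased negative regardless of the gene, and the
   -s-bar y_i component inside z dominates the fitted in-sample scores, so
   even pure-noise genes look strongly "predictive" in sample.
2. *Mean cancellation.* The z columns have nonzero means; without an
   intercept in the solve, multi-gene fits spend huge offsetting
   coefficients canceling constants.

The adjusted estimator fixes both while keeping the estimating-equation
structure: it targets the centered residual r = y - mu, row-centers each
zero-diagonal kernel over its off-diagonal entries,

    z_k,i = sum_{j != i} (s_ij - s-bar_i)(y_j - mu_j),

which cancels the self-exclusion term exactly, and solves the normal
equations jointly with the mean-model design columns (intercept +
covariates), whose coefficient delta is kept as a linear mean correction.
Prediction applies the same construction to new subjects:

    score_a = mu_a + X_a delta + sum_k gamma_k sum_j (s_aj - s-bar_a)(y_j - mu_j).

Under the adjusted estimator, gamma is positive for predictive genes
(empirically in 100/100 seeded replicates with a strong single gene), exactly
invariant to swapping case/control labels (scores complement: score' =
1 - score), and centered near zero for noise genes.

## Forward selection

Starting from the covariate-only model, each step fits every remaining gene
under every configured weight scheme (gamma refit for the enlarged model) and
keeps the pair with the maximum **in-sample** AUC; cross-validation is
reserved for size selection, which keeps the cost at O(steps × genes ×
schemes) fits. Ties are broken lexicographically (gene input order, then
scheme order UW < BETA < WSS < LOG) at an AUC tolerance of 1e-10. A gene's
scheme is fixed when the gene enters and never revised.

Model size is chosen by stratified K-fold cross-validation (default K = 5;
stratification keeps cases and controls in every validation fold). Each fold
re-runs the whole forward path on its training part, scores its validation
part at every size (size 0 is the mean model, AUC 0.5), and the smallest size
attaining the maximum mean validation AUC is chosen (parsimony on ties). The
final model is the forward path of that size refit on all training data.

Candidate evaluation never materializes N×N similarity matrices: S v and
S_cross v are computed as O(nm) matrix-vector products via the decomposition
|a-b| = a + b - 2 min(a,b) with min(a,b) = 1[a>=1]1[b>=1] + 1[a>=2]1[b>=2]
for integer dosages (explicit matrices and a weighted-Manhattan fallback
cover imputed fractional dosages). The action and matrix paths are
cross-checked in the tests.

## Evaluation

AUC uses the tie-aware pairwise kernel (1 if a case outscores a control, 0.5
on ties), computed with midranks in O(n log n); the tests verify exact
equality with the double-loop kernel on tied data. ROC curves are produced at
every unique score and their trapezoidal area equals the pairwise AUC to
1e-12.

## Baselines

- **SVM**: linear support vector machine (C = 1) on all raw dosages,
  decision values as risk scores. A radial kernel is available via the
  `kernel` argument.
- **MSVM**: per common variant (training MAF >= 0.05), a two-sided Fisher
  exact test on the 2×2 minor/major allele-count table (2N alleles per
  group); variants with p < 0.001 are kept. Each gene's rare variants
  (MAF < 0.05) are collapsed to a binary carrier indicator (the original CMC
  construction; a count mode is not provided). The combined matrix feeds a
  linear SVM; if no common variant survives, the CMC columns are used alone
  with a warning. Allele orientation is frozen at training time. The Fisher
  p-value is computed with exact integer combinatorics over the shared
  hypergeometric denominator, so it matches brute-force enumeration bit for
  bit.

## Synthetic data

`make_replicate` emulates the reference study design:

| parameter | default | meaning |
|-----------|---------|---------|
| n_subjects | 1092 | panel size; split 750 train / 342 test |
| n_causal_genes / n_noise_genes | 2 / 3 | genes with / without causal SNVs |
| snvs_per_gene | 200 | variants per gene |
| causal_fraction | 1/3 | fraction of a causal gene's SNVs that are causal |
| disease_model | S1 | effect shape: S1 equal, S2 ~ Beta(1,25), S3 ~ WSS, S4 ~ log |
| prevalence_target | 0.5 | calibrated via the intercept (Brent root finding, error < 1e-6) |
| oracle_auc_target | 0.80 | effect scale calibrated by bisection so the true-linear-predictor AUC hits this |
| maf_low / maf_high | 0.001 / 0.5 | log-uniform MAF spectrum (63% of mass below 0.05, 46% below 0.01) |

MAFs are log-uniform (strongly rare-skewed); genotypes are independent
Binomial(2, MAF) draws (Hardy–Weinberg), with in-sample-monomorphic columns
resampled up to 10 times and then dropped. Phenotypes follow an additive
logistic model over the causal SNVs; effect sizes use the generating MAF
while the fitted kernels use sample MAF, mimicking the real situation where
truth is unknown. Effect signs are all positive by default
(`sign_flip_fraction` enables mixed directions). When `effect_scale` is not
given, it is calibrated per replicate so the oracle (true linear predictor)
AUC on that replicate's panel hits `oracle_auc_target`; this anchors every
experiment to a known amount of extractable signal instead of an arbitrary
coefficient value.

**What the generator does not emulate:** linkage disequilibrium, population
structure, genotyping error, and quantitative phenotypes. The LD omission
matters for interpreting results: with real sequence data, a causal rare
variant is tagged by its haplotype, so a gene-wide IBS kernel picks up causal
sharing through linked sites; with independent sites each causal variant
informs the kernel only through its own column. Passing tests therefore
demonstrate calibration, selection behavior and method ordering — not the
absolute accuracy attainable on real, LD-structured genomes. Concretely, at
the default rare-variant design (S2, oracle AUC 0.80, half of causal-gene
SNVs causal) the forward-selected model reaches a mean held-out AUC of about
0.66 — clearly above the SVM (~0.56) and MSVM (~0.54) baselines and with the
correct genes and weights selected, but below what the same oracle signal
would support with LD present.

## Numerical choices

- Logistic mean fit: IRLS (statsmodels GLM), tolerance 1e-8, max 100
  iterations; perfect separation and rank-deficient designs are errors.
- Linear solves: SVD-based least squares (`lstsq`); rank deficiency is an
  error in strict mode, a warned minimum-norm solution otherwise.
- AUC comparisons in forward selection use a 1e-10 tolerance; degenerate
  all-tie score vectors evaluate to AUC 0.5.
- Missing dosages: QC drops variants then subjects with missing rate > 0.1
  (configurable), removes MAF-zero variants, and mean-imputes the remainder
  so kernels stay dense.
- Minor-allele recoding is per dataset at load time and per training set
  inside the baselines; the IBS kernel itself is invariant to allele
  orientation (|g_i - g_j| is unchanged by g -> 2 - g).

## Known limitations

- No LD or population structure in the simulator (see above).
- The method selects whole genes; it cannot remove noise SNVs inside a
  selected gene.
- No standard errors or tests for gamma; the model is built for prediction,
  not inference.
- Binary phenotypes only (logit link).
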