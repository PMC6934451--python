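# Methods

## Model and assumptions

The package treats mRNA expression Y of one gene and the coded genotypes of
the n SNPs in a chromosomal region of interest (ROI) as jointly observed on
the same samples. Its working assumptions are:

1. a small number (1–4) of common, cis-acting, biallelic regulatory
   variants contribute *additively* to Y (Fisher genotypic values −a, 0,
   +a per genotype class; no dominance or epistasis);
2. every other SNP correlates with Y only through LD with those variants;
3. genotypes are coded 0/1/2 minor-allele counts (fractional imputed
   dosages are accepted — all statistics are correlation-based).

Under assumption 2, a non-regulatory SNP_A added to the set of proxies
(iSNPs) cannot increase the multiple coefficient of determination
R²_M = CᵀR⁻¹C. Imposing this constraint yields a quadratic in r_YA whose
discriminant vanishes, so r_YA = −β/2α is the unique admissible value, and

    R²_A = (Σₖ r_{Y,iSNPₖ} b₁,ₖ₊₁)² / b₁₁²,

where b₁ⱼ are first-row entries of the adjugate of the (p+1)×(p+1)
correlation matrix of [SNP_A, iSNP₁..iSNPₚ] (SNP_A in row/column 1, so
b₁₁ is the determinant of the iSNP block). `corrmath.predict_r2_general`
implements this for p ≤ 4; `predict_r2_closed_form` evaluates the explicit
1- and 2-iSNP formulas (R²_B r²_AB, and
[R_B(r_AB − r_BC r_AC) + R_C(r_AC − r_AB r_BC)]²/(1 − r_BC²)²) purely as an
independent cross-check. `count_expansion_terms` symbolically expands the
numerator by the Leibniz permutation sum without collecting like terms and
confirms the polynomial sizes (16 and 324 additive terms for the 3- and
4-SNP systems) that make hand manipulation impractical; the numeric code
never touches those expansions.

The per-target computation used inside model scoring exploits that the
first adjugate row of the augmented matrix is linear in the target column:
b₁,ₖ₊₁ = −(adj(R)·a)ₖ with b₁₁ = det R, so the predicted vector over all
ROI SNPs is a single matrix product, `(A adj(R) c)² / det(R)²`. A test pins
its exact agreement with the literal per-SNP adjugate route, which remains
the reference implementation.

## Model search and scores

Candidates for iSNP status are ROI SNPs with nominal single-SNP p < 0.05
(slope t-test, two-sided), collapsed to one representative per
duplicate-genotype group (lowest genomic position). All subsets of size
1..max_isnps (default 3, maximum 4) are enumerated exhaustively; a
configurable budget cap (default 200 000 models) guards the combinatorics.
Scores per model:

* **NRMSE** (default criterion, minimized): RMSE between estimated and
  predicted R² over *all* ROI SNPs, divided by the max−min spread of the
  estimated values. The normalizer is dataset-constant, so rankings are
  identical to plain RMSE (tested); it only scales the reported number.
* **adjusted R²_model**: adjusted R² of the OLS of estimated on predicted
  R² (n = #ROI SNPs, one predictor) — the goodness-of-fit number displayed
  on the R²-R² plot.
* **R²_M** of the iSNP set, and the **sum of the iSNPs' estimated R²**.
* **AIC/BIC** from the Gaussian likelihood of the multiple OLS of
  expression on the iSNP genotypes, computed analytically from R²_M, the
  expression total sum of squares and n (identical to the direct OLS; the
  parameter count includes intercept and residual variance). An alternative
  would be information criteria on the estimated-vs-predicted regression;
  the expression-on-genotypes form is the standard likelihood-based usage
  and is what we implement.

Predicted values above 1 — possible when the sample correlation
configuration is not positive semidefinite, typically near-collinear
targets — are *not* clipped: they enter the NRMSE as-is (penalizing the
model) and raise a warning, so pathological configurations stay visible.
Exactly collinear iSNP sets (|det R| below 1e−12 relative scale, or
reciprocal condition below 1e−10 for R²_M) invalidate the model with a
logged message naming the worst pair; the search skips them. Ties in
ranking break lexicographically on the iSNP id list, making the search
fully deterministic.

## Family parsing

Each ROI SNP is assigned to the iSNP with which its genotype r² is maximal,
provided that r² ≥ 0.2 (configurable; the threshold is our choice — the
visual grouping the method produces has no canonical cutoff). Ties break
toward the iSNP with larger estimated R². Every iSNP heads its own family.
The R²-Δ² plot draws, per iSNP j, the line r²(i, j)·R²_est(j) over SNPs i,
so each line touches its own iSNP's bar exactly.

## Simulator

Populations are drawn from haplotype frequency vectors over 2–5 SNP
blocks: two independent haplotypes per individual (HWE), genotype = minor
allele count, expression = Σ aⱼ·gⱼ + N(0, σ). Frequency vectors come either
from a Dirichlet draw (concentration α; sparser α < 1 concentrates mass on
few haplotypes and raises typical LD) or from an explicit LD
parameterization (per-SNP MAF plus pairwise D and, for three loci, D_ABC)
through the Bennett-style decomposition with D defined on minor alleles
(D_AB = f(minor,minor) − p_A p_B). The decomposition is validated by an
exact round trip: recomputing the D coefficients from the returned
frequencies recovers the inputs to 1e−12, a property any valid sign
convention must satisfy and which therefore anchors ours. Multi-block ROIs
concatenate independent blocks, so cross-block LD is zero and block labels
are usable ground truth for family parsing.

Study-condition defaults, chosen once:

* population size n = 1000 per simulated dataset;
* validation experiment (estimated vs predicted R²_A): 1000 datasets per
  2-/3-/4-regulatory-variant system; additive effects uniform on
  [0.8, 2.0] expression units per minor allele against unit residual SD
  (strong cis-eQTL heritability), Dirichlet α = 0.3 with implied MAF ≥ 0.05
  and pairwise r² ≤ 0.95. The sparse Dirichlet is what produces a *wide*
  range of pairwise LD — and hence of true R²_A — rather than piling all
  targets near zero, which is the regime the identity-line comparison is
  about. With a flat Dirichlet the median true R²_A is below 0.01 and the
  comparison degenerates into sampling noise.
* recovery experiment: 40-SNP ROI as 8 independent 5-SNP blocks
  (α = 0.6, MAF ≥ 0.05), two causal SNPs in different blocks with designed
  population R² 0.25 and 0.10, 100 replicates.

What the generator does **not** emulate: realistic LD decay along the
chromosome (blocks are exchangeable and mutually independent), allele
frequency spectra from demography, dominance/epistasis, expression
covariates or batch structure, and >5-SNP haplotype systems. Passing tests
therefore demonstrate the correctness of the mathematics and the behavior
of the search under the assumed generative model — not robustness to
violations of additivity or to trans effects in real data.

## Numerical choices

* Adjugates are computed by explicit cofactor minors (matrices are ≤ 5×5);
  `adjugate` is defined for singular inputs and satisfies
  m·adj(m) = det(m)·I to 1e−10 in tests.
* Near-singularity: reciprocal condition < 1e−10 (R²_M) or relative
  |det| < 1e−12 (prediction) raises a collinearity error naming the most
  correlated pair — LD ≈ 1 iSNP pairs must fail loudly, not produce huge
  predictions.
* Missing dosages are mean-imputed per SNP before any correlation; counts
  are logged. Expression is used as provided; any covariate regression or
  normalization is upstream of this package.
* Monomorphic SNPs get r_y = 0, p = 1, zero LD to everything (flagged, with
  a warning), and are excluded from the candidate list but retained as
  prediction targets.
* NRMSE with a degenerate (zero-spread) estimated-R² vector falls back to
  plain RMSE; adjusted R²_model is NaN when either vector is constant.
* Random correlation configurations for the mathematical sweeps come from
  a Gram construction (G Gᵀ normalized to unit diagonal, G with m+2
  Gaussian columns), rejecting draws with |r| > 0.98 or reciprocal
  condition < 1e−6.
* All simulation randomness flows through a single `numpy` Generator per
  experiment, seeded explicitly; replicate streams are drawn sequentially
  from it, so any replicate is reproducible by replaying from the seed.

## Known limitations

* The vanishing of the constraint-quadratic discriminant is verified
  numerically for p ≤ 4 (deviation < 1e−10 over thousands of random PSD
  configurations) but not proven symbolically here.
* Model-selection p-values are deliberately not provided: the scores
  quantify agreement, not evidence against a null, and the search will
  parse statistical noise as readily as true signal in underpowered data.
* AIC/BIC are one of two defensible constructions (see above); rankings by
  either construction differ only through the likelihood term.
* The candidate shortlist (p < 0.05, dedup) means a true regulatory variant
  whose single-SNP association is insignificant cannot be selected as an
  iSNP, though it still contributes to every model's NRMSE as a target.
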