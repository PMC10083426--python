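# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Models

**Stage 1 — spatial adjustment.** Each field trial is analysed per trait as
`y = X β + e`, with fixed accession and replicate effects and
`e ~ N(0, σ² · AR1(ρ_row) ⊗ AR1(ρ_col))` over the plot grid (1-based row and
column indices; distance is index difference, not metres). The two
autocorrelations are profiled out of the restricted likelihood: a coarse grid
(default step 0.05 over ±0.9; the analysis scripts use 0.1 for speed) followed
by Nelder–Mead refinement to 1e-4, with generalized least squares for β at
each candidate. Missing or unused plots are handled by restricting the
Kronecker covariance to observed cells. Reported BLUEs are replicate-adjusted
least-squares means; with ρ = 0 and a balanced design they reduce to ordinary
adjusted means (tested). No nugget term and no stage-1 row/column random
effects are fitted: stage 1 is kept to the minimal accession + AR-error model,
and row/column random terms are instead available in the plot-level
multi-trait fit (`include_rowcol`). Stage-2 models consume the BLUEs
unweighted; stage-1 standard errors are reported but not propagated.

**Stage 2 — GBLUP.** With `G` the VanRaden method-1 relationship matrix on
observed allele frequencies (ridge `1e-6` on the diagonal):

* univariate: `y = μ + g + e`, `g ~ N(0, G σ²_A)`, `e ~ N(0, I σ²_e)`. A
  single eigendecomposition of `G` reduces REML to a 1-D profile over the
  variance ratio, optimized on the log scale over `[1e-6, 1e6]`.
* multi-trait (2–3 traits): genetic covariance `T` with `g ~ N(0, G ⊗ T)` and
  residual covariance `R` coupling traits within an accession. Complete,
  balanced records use a canonical transformation — rotating every trait by
  the eigenvectors of `G` factorizes the likelihood into n independent t×t
  blocks `Σᵢ = dᵢT + R` — giving O(n t³) iterations. Records missing for a
  subset of traits (the CV1 path) and multi-kernel models use a dense
  covariance AI-REML with the same conventions; the two routes agree to
  optimizer tolerance (tested).
* g×E: `y = site + g + gE + e` with `gE ~ N(0, (I_site ⊗ G) σ²_gxe)` —
  interaction deviations independent across sites with a common variance.
  The "combined" GEBV used for g×E-based selection is the main effect `g`
  alone, the across-site transferable component; site deviations are
  reported separately.

**Optimizer.** Average-information (Newton) REML. Variance (diagonal)
parameters step on the log scale — multiplicative updates that respect
positivity and keep boundary-inflated curvature from freezing the remaining
parameters — with Marquardt damping escalated when a step fails and step
halving within each damping level, so the restricted likelihood is monotone
by construction (asserted in tests). Convergence: relative log-likelihood
change < 1e-8 with parameter change < 1e-6 (or four consecutive sub-1e-9
relative improvements, which catches constrained boundary optima); at most
500 iterations, after which a convergence error reports the gradient norm.
Variance floors are `1e-8 ×` the per-trait phenotypic variance; covariance
matrices are bent — off-diagonals scaled exactly onto the cap — whenever an
implied correlation magnitude would exceed 0.999.

**Derived parameters.** `h² = σ²_A/(σ²_A+σ²_e)` per trait;
`r_A = cov_A/√(σ²_Ax σ²_Ay)` (clipped to ±0.999); phenotypic versions use
`T + R`. GEBVs are conditional means of `g`, reported as deviations from
their population mean. Standard errors of components come from the inverse
average-information matrix.

**Cross-validation.** Folds are seeded near-equal partitions (five folds,
five repeats). Accuracy is the plain Pearson correlation between validation
GEBVs and held-out BLUEs — not divided by √h², since the quantity of interest
is the correlation itself. Variance components are re-estimated inside every
fold from the records visible under the scenario: under CV1 the visible set
includes the validation accessions' secondary-trait BLUEs (that is the
scenario's point), under CV2 only the training block. CV1 fits are
warm-started from the balanced training-only fit, which changes only the
optimization path, not the optimum.

**Selection.** Top `floor(0.2 n)` accessions, ties broken by ascending id.
`S` = mean(selected) − mean(all) on the evaluation site's values; `R = h²S`
with the evaluation site's univariate h² (even when the index mixed several
traits — the response is reported per trait); percentage gain
`= 100 · R / (evaluation-site population mean)`, a definition chosen so that
absolute gains pair with percentages the way breeders quote them. MTGS1
standardizes GEBVs before equal weighting; the Smith–Hazel index `b = P⁻¹g`
is applied to raw GEBVs because the weights already carry units, and `g` is
taken literally as the vector of additive genetic variances (the classical
economic-weight formulation coincides when genetic covariances vanish).

## Synthetic-data generator

The generator emulates the study design: ~350 inbred accessions × thousands
of biallelic SNPs (allele frequencies uniform on a MAF range, Hardy–Weinberg
binomial dosages, marker-wise completely-at-random missingness), 2 replicates
per site in a row-column layout with replicates as contiguous column blocks
and complete randomization within replicate, and plot values

    site mean + g + gE + row + column + AR1⊗AR1 residual.

Three deliberate choices:

* **Exact-covariance breeding values.** Marker effects are i.i.d. normal but
  linearly rescaled so the *sample* covariance of `g` equals `T_target`
  exactly. Recovery tests then measure estimator error only, not Monte-Carlo
  drift in the truth; it also shrinks the per-seed spread of ĥ² noticeably.
* **Genetic g×E.** Interaction deviations are independent marker-effect draws
  per site (rescaled to `σ²_gxe`), so their covariance across accessions
  follows the realized kinship within each site. i.i.d. deviations would be
  statistically indistinguishable from residual error when each accession has
  one record per site, making `σ²_gxe` unidentifiable.
* **Accession-level shortcut.** `simulate_accession_means` emits
  `site mean + g + gE + e`, `e ~ N(0, R_target)` — what stage-1 BLUEs
  estimate — so stage-2 studies (recovery, CV, selection) run at scale
  without re-fitting the spatial stage each time. The full plot-level route
  remains the end-to-end path and is exercised by the pipeline tests.

Defaults follow the study's published structure: four focal traits
(GY, PH, DF, OL) with the optimal-site additive variances
(0.68, 176, 9.6, 11.7) and residual variances (0.56, 62, 3.6, 3.1), GY–PH
genetic correlation 0.45, GY–DF 0.1, GY–OL 0.19; site means chosen so a
~0.7 t/ha yield gain at the optimal site is roughly a 23 % increase
(3.0 / 1.7 / 1.0 / 1.1 t/ha); ρ_row = ρ_col = 0.4; g×E variance 0.3 × the
additive variance; 2 replicates on a 20 × 36 grid. Pair-specific correlations
not reported for the remaining trait pairs are set to small round values.

**What the generator does not emulate** — hence what passing tests do *not*
show about real data: linkage disequilibrium and population structure
(markers are independent, so GRM off-diagonals are small and h²/r_A estimates
are noisier than in a structured panel, and prediction accuracies are lower
than the real study's 0.28–0.61); per-site genetic variances (a single
`T_target` serves all sites, so the study's pattern of collapsed genetic
variance at stressed sites — the main driver of its cross-site percentage
asymmetries — is out of reach); pedigree relatedness; non-normal residuals;
and informative missingness.

## Problem sizes and stochastic properties

Simulation-based checks run at the sizes stated in their docstrings: variance
and correlation recovery at n = 300 accessions × 2000 markers with 20
replicate seeds; cross-validation properties at the same scale; g×E recovery
and gain balancing at n = 200 × 3 sites. With independent markers the
per-seed sampling spread of genomic ĥ² is ≈ 0.2 and of r̂_A larger still
(boundary estimates at ±0.999 occur); assertions therefore target means over
seeds, and individual-seed estimates should not be over-read. The g×E
gain-balance check uses equal site means so that percentage-gain denominators
do not mask the cross-site decay of single-site selection — with graded means
the denominator effect can reverse the comparison even though the absolute
responses behave as expected.

## Degenerate inputs and tie-breaks

All-missing markers are flagged, never silently dropped; imputation refuses
them by name. Monomorphic-only panels raise on GRM construction. A constant
phenotype returns floored components and zero GEBVs. Duplicated-trait fits
land on the correlation cap (0.999). kNN imputation breaks modal-dosage ties
toward the lower dosage; selection ties break by accession id; fold sizes
differ by at most one. The AR1 builder rejects |ρ| ≥ 1; saturated spatial
designs (zero residual degrees of freedom) return the GLS estimates with a
zero variance rather than dividing by zero.

## Known limitations

Stage-1 uncertainty is not propagated to stage 2 (unweighted two-stage
analysis). The multi-trait engine is dense — fine for panels of a few
hundred accessions, not for tens of thousands. The g×E model assumes a
common interaction variance across sites (no factor-analytic structure).
Smith–Hazel weights use the literal genetic-variance vector rather than
elicited economic weights. LD-aware imputation is out of scope; the provided
fillers are adequate because downstream results are insensitive to
imputation quality at the simulated missingness levels.
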