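# Methods

## Model

For each of P populations, phenotypes follow

    y_i = X_i b_i + Z_i a_i + W_i d_i + e_i

with population-specific fixed effects b_i (an intercept and a genomic
inbreeding covariate at minimum; user covariates allowed), additive SNP
effects a_i under the gene-content coding Z_i = dosage − 1 ∈ {−1, 0, 1},
dominance SNP effects d_i under the heterozygote indicator W_i ∈ {0, 1},
and independent residuals with population-specific variances σ²_{e,i}.
Marker effects are correlated across populations per SNP:

    Var(a) = G0a ⊗ I_m,   Var(d) = G0d ⊗ I_m,

where G0a and G0d are P×P symmetric positive-definite covariance matrices
in marker-effect-variance units. Every individual carries one record in one
population. The individual-level consequences are

    G_A = { Z_i σ_{a,ij} Z_j' },  G_D = { W_i σ_{d,ij} W_j' },
    V   = G_A + G_D + R,          R = diag(σ²_{e,pop(record)}).

The genomic inbreeding covariate is observed homozygosity
F = 1 − (#heterozygous SNPs)/m. Fitting it gives dominance effects a prior
mean of zero; any bounded homozygosity measure would do, and this one is
simple, exact under the integer coding, and requires no allele-frequency
convention.

Assumptions: variance components known; one record per individual; no
pedigree information; SNP panel shared across populations; no missing
genotypes (rejected, not imputed, to preserve the exact integer codings on
which the block-structure tests rest).

## The four solvers

All four compute the same GLS fixed effects and BLUP random effects; they
differ in which system is formed.

**SNP-BLUP** (`snp_blup`). Henderson's MME in marker effects, ordering
[β; a_1..a_P; d_1..d_P]. The random part mixes dense within-population
cross-product blocks (Z_i'Z_i σ_e⁻², Z_i'W_i σ_e⁻²) with identity blocks
I g^{ij} from the inverse effect covariances and zero cross-population
additive×dominance blocks; 2Pm random equations, invariant to n. Because
the dense/identity mixture defeats generic sparse solvers, the LHS is
stored dense and factorized by Cholesky; the explicit inverse is formed
only when prediction-error variances are requested.

**Standard multiple-trait GBLUP** (`gblup.build_standard_system`). Each
individual gets one additive and one dominance value per population
("trait"), trait-major ordering, 2Pn random equations. The prior precision
is kron(G0a⁻¹, (G*_A)⁻¹) with G*_A = {Z_i Z_j'} left deliberately unscaled
(all scaling enters through g^{kl}); the trait-major ordering makes the
assembled blocks literally equal G*^{(ij)} g^{kl}, which the element-level
tests exploit. The data part links each record only to its own
population's trait copy; additive×dominance cross blocks are I σ_e⁻² on
matched records. The dominance part mirrors the additive pattern by
symmetry (the natural extension of the displayed additive structure).

**Compact GBLUP** (`gblup.build_compact_system`). Unknowns are the n
own-population additive values u_a and dominance values u_d directly,
2n random equations, with prior precisions G_A⁻¹ and G_D⁻¹ and I σ_e⁻²
data and cross blocks. Marker effects are recovered afterwards by the
selection-index identity â_k = Σ_j σ_{a,kj} Z_j'(G_A⁻¹ û_a)_j — valid only
when G_A is the exact covariance, so backsolving from a blended system is
refused rather than approximated.

**GLS + selection index** (`gls_si`). V is assembled once (a plain sum of
matrices, order n) and Cholesky-factorized; β̂ = (X'V⁻¹X)⁻¹X'V⁻¹y; then
y^c = V⁻¹(y − Xβ̂), v_i = Z_i'y^c_i per population, and
â_k = Σ_j σ_{a,kj} v_j (dominance analogous). The covariance matrix
C_a = Cov(y, a') is never materialized. V is positive definite whenever
residual variances are positive, so this route needs no blending even when
G_A or G_D is rank deficient — the robustness contrast the clone fixture
exercises.

**Matrix-free variant** (`gls_si.solve_matrix_free`). V is applied as an
operator (per flavor: t_j = Z_j'x_j, then Z_i Σ_j σ_{ij} t_j, plus Rx;
O(nm) per product) inside conjugate gradients, solving VΘ = y and VM = X
column by column; then (X'M)β̂ = X'Θ and y^c = Θ − Mβ̂ feed the same
backsolve. CG is used because V is symmetric PD; relative-residual
tolerance defaults to 1e-10 with an iteration cap of 10n, after which a
residual-norm error is raised.

### Prediction-error variances

From SNP-BLUP, marker PEVs are diagonals of the inverse LHS. From GLS+SI,
PEV(t) = PriorVar(t) − c_t' P c_t with
P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹ — the standard GLS-BLUP projection
including fixed-effect uncertainty. The binding contract is cross-method:
both routes must agree (they do, to ~1e-15 on the small fixture), and
0 ≤ PEV ≤ prior variance. Reliability = 1 − PEV/prior, clipped to [0, 1];
a zero-prior target reports reliability 0.

### Blending

`blend(M, ε)` returns M + ε·s·I with s the mean diagonal (s = 1 for a zero
matrix), making ε dimensionless across datasets. Rank is assessed by an
eigenvalue check (smallest eigenvalue < 1e-10 × mean diagonal) rather than
Cholesky failure alone, because Cholesky can numerically succeed on a
singular matrix; the error message suggests a concrete ridge (1e-6).

### Numerical choices

* Cholesky (`scipy.linalg.cho_factor`) everywhere a symmetric PD solve is
  needed; explicit inverses only for PEV queries.
* Cross-method equivalence tolerance is rtol 1e-6 on scale max(|x|, 1),
  accommodating conditioning differences between formulations; observed
  discrepancies are orders of magnitude smaller (~1e-11 on the main
  fixture).
* Fixed effects are solved jointly with random effects (no absorption).
* Optional per-population column centering of Z/W exists but is off by
  default: centering breaks the integer coding and makes the
  individual-level covariances singular. With per-population intercepts
  fitted, solutions are invariant to column shifts anyway (tested).
* Degenerate inputs: non-PD G0a/G0d, non-positive residual variances,
  rank-deficient designs (with the collinear columns named), dosages
  outside {0,1,2} (with row/column named), and SNP-panel mismatches are all
  rejected with specific errors; `validate_dataset` collects failures
  non-fatally for reporting.

## Simulator

`simulate` generates exactly the structure the solvers assume: base allele
frequencies Beta(2,2); population divergence via Balding–Nichols
Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst) — chosen as a standard one-knob
divergence model; binomial(2, p) dosages; optional crossbred populations
built from one Bernoulli gamete per parental frequency pool (frequency
level only, no explicit parents); per-SNP MVN(0, G0a) and MVN(0, G0d)
effects; Gaussian residuals. SNPs monomorphic within every population are
redrawn (bounded retries). A master seed spawns independent substreams for
frequencies, dosages, effects and noise, so changing m does not reshuffle
phenotype noise. The truth bundle (a_true, d_true, beta_true) is always
returned for recovery tests.

What it does **not** emulate: linkage disequilibrium, pedigree structure,
selection, minor-allele-frequency ascertainment, genotyping error. Passing
tests therefore certify the linear-algebraic and statistical correctness of
the solvers under the assumed covariance model, not predictive performance
on real livestock or crop data.

### Preset fixtures and problem sizes

* `tiny-2pop` — P=2, n=(8,8), m=12: hand-checkable block structure.
* `equiv-3pop` — P=3, n=(60,60,60), m=400: m > n with full-rank G*
  matrices, the equivalence workhorse. Marker-effect variances (0.008
  additive, 0.003 dominance per SNP, correlations 0.8/0.5, σ²_e = 1) give
  total genetic variances of realistic magnitude relative to the residual
  at these panel sizes.
* `crossbred-3pop` — third population from gametes of the first two.
* `singular-clones` — one duplicated genotype row, forcing G_A rank
  deficiency while V stays PD.
* The effect-recovery calibration uses the `equiv-3pop` design scaled to
  n=(300,300,300), m=300, averaging the regression of true on estimated
  genetic value over 20 seeds; BLUP unbiasedness puts it near 1. These
  sizes keep the whole suite and the reproduction script in the seconds
  range while leaving all rank and conditioning properties intact.

## Design decisions

* Estimator-class surface (sklearn-style `fit`/`predict`) over the
  module-level assembly functions: the solvers are configuration + fit +
  indirect-prediction objects, and this shape composes with sklearn
  tooling; the assembly functions remain public for element-level testing
  and scripting.
* Marker backsolving is provided from the compact GBLUP and GLS+SI routes
  only; the standard multiple-trait formulation returns genetic values
  only, and the equivalence checker flags (rather than fails) comparisons
  it cannot make.
* Fixed-effect blocks of the SNP-BLUP LHS use the standard Henderson
  couplings X'R⁻¹[X | Z | W]; the displayed random-part structure pins the
  rest.
* All fixed effects are population-specific (block-diagonal X across
  populations); per-population intercepts are mandatory, which underwrites
  the coding-shift invariance property.
* Equivalence is checked in solution space (β, â, d̂, u_a, u_d), not matrix
  space, since the formulations differ in layout by design; system-size
  metadata carries the cost comparison (2Pm vs 2Pn vs 2n vs n).

## Known limitations

* Dense O(k³) factorizations throughout: intended for medium-sized
  problems (up to ~10⁴–10⁵ equations), matching the exact-methods setting;
  only the matrix-free GLS variant avoids forming its system.
* No REML: variance components are inputs.
* No pedigree/single-step extensions, no epistasis, no
  genotype-by-environment interaction terms, no imputation.
* The standard-GBLUP blended path changes the model slightly (as blending
  always does); its solutions then differ from the exact ones at order ε.
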