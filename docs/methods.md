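# Methods

This note documents the models implemented in `selindex`, the numerical
choices behind them, and what the synthetic data generator does and does
not emulate.

## Trait model and covariance estimation

Each trait record is modelled as `Y_ij = μ_j + C_ij + ε_ij`: a trait
mean, a genotypic value and an independent residual. The genotypic
values of a line are generated by markers, `g_j = X u_j`, where `X` is
the centered dosage matrix (`2−2p`, `1−2p`, `−2p` for AA/Aa/aa at allele
frequency `p`) and `u_j` are marker effects. The genomic relationship
matrix is `G = XX'/π` with `π = Σ 2p(1−p)` for an F2-type population and
twice that for doubled haploids; F2 scaling is the default, with DH
available by flag (the formula choice is user-facing; inbred material
sits between the two). Monomorphic markers are dropped and missing
dosages mean-imputed per marker, both with logged counts — imputation
before centering keeps `G` positive semidefinite and is the field
default.

Per-year covariance matrices `C` (genotypic) and `P = C + Ξ`
(phenotypic) are estimated by REML with `G` supplying the relationship
structure:

* **Univariate:** a single eigendecomposition of `G` rotates the model
  into independent coordinates; the restricted likelihood is then a 1-D
  function of the heritability `h² = σ²_g/(σ²_g+σ²_e)`, maximized by
  bounded scalar optimization (tolerance 1e−8 on `h²`). Boundary
  estimates are flagged, not raised.
* **Bivariate:** EM-REML in the same rotated coordinates, where
  observations are independent 2-vectors with covariance
  `λ_i Σ_g + Σ_e`. The E-step uses the REML projection (fixed-effect
  uncertainty included), so each iteration costs O(n) 2×2 operations
  and the restricted log-likelihood never decreases. Convergence:
  relative parameter change < 1e−6 and log-likelihood change < 1e−8,
  max 500 iterations; non-convergence returns the best iterate with a
  flag. Starting values split the phenotypic variance evenly. A tiny
  relative eigenvalue floor (1e−9 of the trace) on the 2×2 iterates
  guards degenerate inputs such as duplicated traits; it is inactive on
  regular data.

Full trait covariance matrices are assembled from univariate diagonals
and pairwise bivariate off-diagonals rather than a joint t-trait REML.
At yearly sample sizes of one to a few hundred lines with whole traits
unmeasured in some years, the pairwise assembly targets the same
quantities while being far more robust; each pair uses its complete-case
intersection (minimum 30 lines). The patchwork can be indefinite, so an
eigenvalue-bending pass floors eigenvalues at 1e−6 of the largest
(with a warning) whenever `P` is not positive definite or `C` not PSD.
Heritabilities are reported raw (`C_jj/P_jj`) and flagged — never
silently clipped — when outside [0, 1]. Because the fits use both
phenotypes and markers, the genomic covariance matrix is identified
with `C`.

Fixed effects are intercept-only within year. Field-design and spatial
adjustments are out of scope; the generator produces no such structure.

## Index algebra

With `P` and `C` in hand (or supplied directly), the three indices are
closed-form linear algebra; all solves use Cholesky factorization, never
explicit inverses, and a condition number above 1e10 raises a
conditioning error naming the offending matrix.

* Smith: solve `P b = C w`.
* Eigen index: the eigenproblem `P⁻¹C b = λ b` is solved in its
  symmetric generalized form `C b = λ P b` (real eigenpairs guaranteed
  for symmetric `C`, PD `P`), and the eigen-residual is verified against
  a 1e−8 relative tolerance. Eigenvectors are sign/scale ambiguous; the
  convention here scales the leading eigenvector so its maximum-
  magnitude element is +1 before applying the transforming matrix `F`.
  A note on `F`: with entries of mixed sign, `β = F b_E` changes the
  direction (and hence the response `k√(β'Pβ)`) of the index, while the
  eigenvalue — and with it the merit correlation — is invariant, since
  `FP⁻¹CF⁻¹` is similar to `P⁻¹C`. The shipped worked example uses
  `F = I`, which reproduces the reference values of all four ESIM
  quantities (coefficients, response, correlation, gains)
  simultaneously; mixed-sign choices of `F` reported alongside those
  same values are not mutually consistent, so the identity convention
  is treated as canonical for reproduction purposes.
* Desired gains: `b = P⁻¹C(CP⁻¹C)⁻¹d`, validated post-hoc against the
  constraint `Cb = d` (1e−8 relative). This is the minimum-variance
  solution of the constraint, which maximizes the gain vector
  `E = k d/σ_I`; its variance can legitimately be tiny, and no merit
  correlation is defined.

Derived parameters: `σ_I = √(b'Pb)`, response `R = kσ_I`, correlation
`ρ_HI = √(b'Pb / w'Cw)` (reported as an absolute value — the defining
ratio of standard deviations is nonnegative), per-trait gains
`E = kCb/σ_I`. The selection intensity is the infinite-population
truncation value `k = φ(z)/p`; finite-population corrections are out of
scope. When a year measures only a subset of traits, weights and the
corresponding rows/columns of `P` and `C` are subset before any index
computation, keeping each year's index well defined.

Lines with a missing trait get a missing index value — no imputation.

## Cross-year prediction of index values

Per-line index values from training years form the response of

`I = μ (+ β_Y·year) + s + g_YC + e`,

`s ~ N(0, σ²_s G)`, `g_YC ~ N(0, σ²_YC Z K Z')` with `K` a year kernel
expanded to observations by year incidence, `e ~ N(0, σ²_e I)`. The five
families: (1) genomic only; (2) + linear EC kernel; (3) genomic + year
trend; (4) trend + linear EC kernel; (5) trend + Gaussian EC kernel.
Crossed with the training-set choices (all four historical years, each
single year, last three, last two) and the EC policies, the registry
enumerates 41 sub-models for the four-years-predict-the-fifth layout;
shorter histories keep only the tasks whose training sets exist.

Estimation is deterministic multi-kernel EM-REML with the classical
update `σ²_c ← σ²_c + σ⁴_c (y'PK_cPy − tr(PK_c))/rank(K_c)`, which
guarantees restricted-likelihood ascent; variance floors at 1e−12 of
the response variance keep iterates valid, and boundary estimates (an
EC component on a single training year is structurally confounded with
the intercept) converge to zero rather than erroring. A Bayesian MCMC
treatment would deliver the same point predictions at these scales at
the cost of reproducibility in tests, so it was not pursued.

Prediction of target-year lines: the genomic part is the BLUP
projection `ŝ_new = G_{new,train} G⁻¹_{tt} ŝ_train` (a ridge of
1e−6·mean(diag) is added and logged if `G_tt` is singular); the EC part
predicts the target year's effect from the kernel row of a synthesized
target EC vector — the average of the training years' vectors, or a
copy of the designated year's vector, per policy. Covariate
standardization is learned on the training years only and applied
unchanged to the synthesized row; with a single training year or no
varying covariate the kernel degenerates to all ones (identical EC
information means identical environments). The year covariate is the
calendar year as an integer, centered on the training-year mean.

Index values estimated in different years live on different scales
(year-specific `P`, `C`), so by default they are centered — not scaled —
within training year before pooling; Pearson correlation, the evaluation
metric, is unaffected by this but the fit is stabilized. Groupwise
summaries report min/mean/max per training set, optionally after
dropping non-positive correlations; a group emptied by the filter is
marked absent rather than zero.

## Synthetic data generator

Defaults emulate the structure of a five-year rice breeding trial:
yearly line counts {134, 332, 307, 348, 300} for 2018–2022, 435
markers, four traits (Chalk %, Whole milling %, Ratoon yield t/ha,
Yield grain t/ha), target heritabilities near {0.46, 0.58, 0.44, 0.54},
year-specific missingness (2019 lacks Ratoon; 2020 keeps only Chalk and
Yield; 2021 lacks Whole), near-disjoint line sets with three shared
check lines between consecutive years, and 20 environmental covariates
per year drawn from a two-factor latent year structure.

Genetic values are simulated through marker effects — per-marker effect
vectors across traits are MVN(0, `target_C/π`) — rather than drawn
directly from `G`, so the GREML model is correctly specified and
prediction across years through `G` is meaningful. Residuals are MVN
with the target residual covariance; optional injected components: a
per-year trait shift, and a year-level effect with variance σ²_YC
structured by the linear EC kernel (zero by default) for recovery
tests. Lines come in families (default size 5) whose members copy each
founder allele with probability 1/2, giving `G` off-diagonal structure.
All draws flow from the single config seed.

Not emulated: trait unit bounds (no % truncation — the analysis is
covariance-level), field-trial design and spatial error, selection
across cycles, linkage disequilibrium beyond family structure, and any
real weather process behind the ECs. Passing tests therefore establish
internal consistency of the machinery under its own assumptions, not
performance on real breeding data.

## Test and validation problem sizes

Stochastic checks use sizes chosen to give stable Monte-Carlo behaviour
at desk scale: closed-form index parameters are validated against
truncation selection on 10⁵ simulated individuals (three-standard-error
bands); optimality against 10⁵-draw random-search oracles; GREML
recovery at n = 400 lines × 435 markers over 30 replicates; mixed-model
reduction, trend-recovery and prediction-sanity checks on five
simulated years of 60–80 lines with 250 markers over 20 replicates.
The full-pipeline sanity check (REML covariances → Smith indices → 
genomic prediction of the held-out year) verifies a positive mean
observed-vs-predicted correlation and that accuracy rises with the
simulated index heritability; real-data correlation levels are not a
target of the synthetic suite.

## Known limitations

* The pairwise covariance assembly can require bending; bending
  perturbs the targeted covariances slightly and is always logged.
* The desired-gains index inherits its known fragilities: an
  ill-conditioned `C` produces extreme coefficients, and its index
  variance is not bounded away from zero.
* EM-REML converges slowly near variance boundaries; fits report
  iteration counts and convergence flags, and non-converged fits are
  still usable best iterates.
* VCF ingest handles biallelic SNPs only; multi-allelic records are
  skipped with a count.
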