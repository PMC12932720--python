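# Methods

This note records the statistical models the package implements, the
assumptions behind the closed forms, the numerical conventions, and the
design choices made where the design was genuinely open.

## Merit and index models

All indices predict the quadratic net genetic merit `H_q = w'g + g'Wg` of a
candidate with true genetic values `g` (t traits). `w` carries merit units
per trait unit; `W` is symmetric (symmetrized on input as `(W + W')/2`) and
carries merit units per squared trait unit. With `W = 0`, `H_q` is the
classical linear net merit.

Under joint multivariate normality of `(g, y)` with `Cov(y) = P`,
`Cov(g) = G = Cov(g, y)`, the minimum-MSPE predictor of `H_q` from
phenotypes is the conditional expectation

    E[H_q | y] = (P⁻¹Gw)'y + y'(P⁻¹GWGP⁻¹)y + tr(W(G − GP⁻¹G)),

which is the QPSI; its linear part is the Smith–Hazel LPSI. On the genomic
side the classical assumption `Cov(γ̂) = Cov(γ̂, g) = Γ` makes the economic
weights themselves MSPE-optimal: the QGSI is `w'γ̂ + γ̂'Wγ̂` and the LGSI its
linear part. Both nestings (`W = 0` collapses quadratic onto linear) are
exact and tested coefficientwise.

**Centering convention.** All scored inputs (entry means or GEBVs) are
mean-centered before evaluation, and the constant part of the conditional
expectation lives in the model's `offset`. The closed-form moments —
`E[I] = tr(QΣ) + offset`, `Var(I) = l'Σl + 2tr(QΣQΣ)` — assume zero-mean
normal inputs; centering makes the reported moments consistent. A published
variant of the QGSI variance writes its first term with a realized GEBV
vector in place of `w'Γw`; a realized vector cannot enter a variance, so the
package uses the standard quadratic-form identity above and validates it
against one-million-draw Monte-Carlo in the test suite.

## Response to truncation selection

Selecting the top proportion `p` by index score gives selection intensity
`k = φ(z_p)/p` (1.755 at p = 0.10). For a **linear** index the classical
results hold exactly under normality:

    R = k · Cov(H_q, I) / σ_I ,   per-trait gains = k · C l / σ_I ,

with `C` the cross-covariance of traits with the scored variable (G for
phenotypic, Γ for genomic indices). For a **quadratic** index the score is a
quadratic form in normals — not itself normal — and the truncation response
has no elementary closed form. The module's hybrid contract:

- `method="closed"` applies the bivariate-normal approximation
  `R = k·Cov(H_q, I)/σ_I`, with all variances and covariances from exact
  quadratic-form identities (`Cov(g'Wg, x'Qx) = 2tr(WCQC')` etc.);
- the default (`"auto"`) path computes quadratic R and realized gains with a
  seeded Monte-Carlo truncation oracle (draw from the assumed joint MVN,
  score, truncate, average), reporting the Monte-Carlo standard error;
- every summary records which path produced it.

**Per-trait gains of quadratic indices equal those of their matched linear
index** on the closed-form path: under joint normality the quadratic
component of the score is uncorrelated with every individual trait's genetic
value (third moments vanish), so the trait-wise correlated response is
driven entirely by the linear component. Accuracy (`SCor`, squared Pearson
correlation — inherently a linear measure, used by convention even for
quadratic merit) and `SR-MSPE = √(Var(H_q) − Cov(H_q,I)²/Var(I))` come from
the exact identities on every path. In the perfect-information limit
(`γ̂ ≡ g`, `Γ = G`) the genomic MSPE is exactly zero.

## Covariance estimation

Replicated trials are analysed on the genotype entry-mean basis. For the
two-way layout the multivariate method-of-moments (MANOVA cross-product)
estimators are `G = (MS_g − MS_e)/r` and `P = MS_g/r`; for balanced data
these coincide with the Gaussian ML solution, and unbalanced replicate
counts use the harmonic mean of `r` (the exact ML for arbitrary incidence
structures is out of scope). Broad-sense heritability is reported on the
entry-mean basis, `h² = σ²_g/(σ²_g + σ²_e/r)`. Missing cells are dropped
pairwise per trait pair with a warning; estimates are clamped to the nearest
PSD matrix by eigenvalue truncation at zero (idempotent; symmetry tolerance
1e-10). `Γ` is the PSD-clamped sample covariance of the GEBV matrix.

Note one deliberate asymmetry: the simulator's `phenotype` step defines its
heritability on the plot (single-replicate) basis — per-rep error variance
`σ²_g(1−h²)/h²` — so a plot-basis h² of 0.5 at r = 4 appears as an
entry-mean h² of `hr/(hr+1−h) = 0.8` when re-estimated. Both definitions
are standard; the tests assert the exact transformation.

## GEBV engines

Markers are biallelic allele counts in {0,1,2}, standardized columnwise to
`2−2p, 1−2p, −2p` with allele-A frequency `p` computed on the **training
cycle and frozen** for all later cycles (frequencies drift under recurrent
selection; predictions must stay on the training scale). Missing codes are
imputed to the column mean (standardized value 0); monomorphic columns are
excluded with a warning.

**GBLUP.** The stacked multi-trait system is block-diagonal across traits
with a shared marker matrix, so per-trait ridge is exact:
`β_t = (M'M + λ_t I)⁻¹M'ȳ_t`, identical to the GRM
(`Φ = MM'/(2Σp(1−p))`) mixed-model solution — the equivalence is asserted
to 1e-8 in tests. The default shrinkage derives from heritability,
`λ_t = c(1−h²_t)/h²_t` with `c = 2Σp(1−p)`, and is overridable.
Cross-trait information enters through `Γ` estimated from the GEBV matrix,
which is how the indices consume it.

**RKHS.** The Gaussian kernel is `K_ij = exp(−d²_ij/(h·q))` with `q` the
median of the nonzero squared Euclidean distances between standardized
marker rows (median heuristic; `h` a multiplier, default 1). The Bayesian
multi-trait model `Y = μ + U + E`, `U ~ MN(0, K, Σ_u)`,
`E ~ MN(0, I, Σ_e)` is fitted by a Gibbs sampler in the eigenbasis of `K`,
where the full conditional of `U` factorises into scalar updates (one n×t
vectorised sweep per iteration). Conjugate inverse-Wishart priors on both
covariance components use df `t+2` and prior mean `prior_scale` × the
observed trait variances. The default `prior_scale = 0.5` splits the
variance evenly between signal and noise a priori — with it, 95% credible
intervals for `Σ_u` cover fixed true values in 18–19 of 20 simulation
replicates at n = 60. Near-noiseless data call for a much weaker error
prior (e.g. 0.002), under which the posterior mean reproduces centered
observations to <1% at 2000 iterations; both regimes are exercised in the
tests. Chain defaults: 4000 iterations, 1000 burn-in, thin 5; a seed is
required (chains are bit-identical under a fixed seed) and non-finite draws
abort with the iteration index. `μ` is fixed at the sample trait means.

## Simulator

The simulator emulates a maize-style recurrent-selection experiment. The
default design: 10 chromosomes of 100 cM, 2806 uniformly spaced markers,
315 randomly placed QTLs, four traits affected by 300/100/60/40 QTLs with
target genotypic correlations (T1,T2) = −0.5, (T1,T3) = 0.4, (T1,T4) = 0.3,
(T2,T3) = −0.3, (T2,T4) = −0.2, (T3,T4) = 0.1, selection of the top 10% per
cycle, 500 genotypes × 4 replicates.

**Calibration.** Founders are drawn with independent loci at frequency 0.5
(no ancestral LD — LD then accrues through selection and drift; the indices
consume covariances, not LD structure). Independence makes the founder
genetic covariance available in closed form, `Σ = 2f(1−f)·E'E` for the QTL
effect matrix `E`, so the allocator solves the targets exactly rather than
iterating: a core block of `min(counts)` QTLs shared by all traits carries
the cross-trait covariance through an orthonormalised effect basis
(`E_core ∝ QA'`, `Q'Q = I`, `A = chol` of the required covariance); pair
blocks with exactly orthogonal effect vectors absorb the remaining sharing
budget without disturbing covariances; trait-specific QTLs fill the
per-trait counts with diagonal variance only. Achieved founder correlations
match targets up to the sampling error of the founder draw (SE ≈
`(1−r²)/√n`, about 0.02 at 2000 founders). Infeasible targets (e.g. fewer
QTLs on some trait than there are traits, with nonzero correlation targets)
raise with the achieved matrix.

**Meiosis.** Gametes take Poisson(`L/100`) crossovers per chromosome with
uniform positions (Haldane map, no interference) and a random start strand;
allele conservation through meiosis is asserted in tests. Generations
advance by random pairing of distinct selected parents at constant
population size.

**Recurrent selection.** Cycle 0 trains everything: P, G, h² from
replicated phenotypes; the GEBV engine on entry means; marker frequencies
frozen. Genomic indices then run phenotype-free (GBLUP effects frozen, or
kernel interpolation `K_new,train K_train⁻¹ U` for RKHS); phenotypic
indices re-phenotype each cycle with the cycle-0 environmental variance and
re-estimate P and G. True genetic values are centered within each cycle
before computing `H_q`, matching the zero-mean convention of the theory.
Per-cycle rows report the *realized* response (selected-minus-population
mean of `H_q`), squared correlation, offset-aligned root-MSPE and realized
per-trait selection differentials, with the nominal intensity recorded and
the realized intensity logged.

**Choices where the design was open** (fixed once, configurable): founder
allele frequency 0.5; chromosome length 100 cM; per-trait plot-basis
heritability 0.5; unit founder genetic variances (merit units are
arbitrary); quadratic weights `W` default to zero, with `rank1`
(`W = ½ww'`) and explicit-matrix constructors — every report records which
`W` was used, and the package's quadratic demonstrations use `rank1`
because with `W = 0` the quadratic and linear indices coincide.

**What the simulator does not emulate:** ancestral LD, mutation,
non-random mating, epistatic QTL action (nonlinearity enters through the
quadratic merit and the kernel, not the QTL truth model), spatial field
structure. Passing tests therefore demonstrate correctness of the
estimators and index theory under the stated generative model, not
robustness to real-data violations of it.

## Normality diagnostics

Shapiro–Wilk delegates to scipy. Mardia's skewness (`n·b₁/6` against χ² on
`d(d+1)(d+2)/6` df, one-sided) and kurtosis (asymptotic normal, two-sided)
and the Henze–Zirkler statistic (standard bandwidth `β(n,d)`, log-normal
p-value approximation) are implemented from the standard formulas on the ML
covariance; Henze–Zirkler agrees with an independent implementation to
1e-9 and all multivariate statistics are exactly affine invariant. Type-I
error at α = 0.05 is within [0.03, 0.07] for every implemented test at
n = 500 over 1000 replicates. Royston and Henze–Wagner names are reserved
in the report schema but not implemented (layered, poorly documented
constants; no reliable oracle). The bivariate merit check runs Mardia and
Henze–Zirkler on the `(H_q, I)` pairs and reports p-values only.

## Numerical conventions and problem sizes

- PSD repair: eigenvalue truncation at 0, symmetric re-assembly, symmetry
  tolerance 1e-10; rank-deficient `Γ` is handled by the PSD clamp and
  validation rather than silent pseudo-inversion.
- Singular `P` raises with the condition number (threshold 1e12).
- Ties in truncation selection break by ascending candidate id,
  deterministically.
- Monte-Carlo oracles default to 10⁶ draws with reported standard errors;
  test-suite oracle comparisons use 4×10⁵ draws per instance and 3-SE
  tolerances, and the recovery/calibration simulations use 500×4 panels and
  2000-founder probes — sizes at which the assertions' standard errors are
  an order of magnitude below the tested tolerances.
- Display rounding in tables: 1 decimal for R and gains, 3 for
  correlations, with full-precision companion files always written.

## Known limitations

- The QPSI/QGSI conditional-expectation optimality is exact only under
  joint normality; heavy-tailed or skewed traits degrade it (the normality
  suite exists to check this assumption).
- Quadratic-index truncation response on the closed path is a
  bivariate-normal approximation; the oracle path is the contract.
- Heritability of quadratic indices is not defined here (no accepted
  definition exists); `index_heritability` covers linear indices only.
- REML for arbitrary incidence structures, G×E modeling, multi-stage
  selection and economic-weight optimization are out of scope.
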