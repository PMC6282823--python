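# Methods

## Model and estimation

The trait is modelled as `y = Wb + Xg + e` with independent Gaussian
residuals. `X` holds standardized genotype codes; standardization serves a
single purpose: under Hardy–Weinberg proportions at minor allele frequency
`f`, every main-effect column has mean 0 and variance 1, so one prior
`(γ, λ)` is exchangeable across loci. This forces the scaling convention:
the additive codes are divided by `s = sqrt(2f(1−f))` and the Falconer
dominance codes by `s² = 2f(1−f)`. (Writing the shared symbol `s_j =
2f_j(1−f_j)` for both denominators, as compact notations sometimes do,
would leave the additive column with HWE variance ≠ 1; the square-root
reading is the one consistent with exchangeability, and the unit-variance
identity is asserted to 1e−12 in the test suite.) Dominance codes are
HWE-orthogonal to additive codes at the same locus, so the two effects are
separable in expectation. Epistatic codes are elementwise products of the
two main-effect columns involved; the four kinds (a×a, a×d, d×a, d×d) over
unordered pairs give `2p(p−1)` coordinates.

Each effect has the prior `γ Laplace(λ) + (1−γ) δ₀`. The one-locus
posterior mean, posterior CDF and the continuous density branches are
closed-form Gaussian expressions in `Y = x'y/x'x` and `σ² = σe²/x'x`.
All mixture weights (T1, T2, T3; f1, f2, f3; p(y)) are handled on the log
scale with `log_ndtr`-based tail probabilities and log-sum-exp: the
textbook products such as `exp(λY)·Φ(·)` overflow for routine inputs
(the contract is: no overflow for |Y|/σ ≤ 40 and λσ ≤ 1e3). Truncated
normal means use the Mills ratio `exp(logpdf − logcdf)`; for |μ|/σ ≥ 25
the direct form `μ + σ·ratio` cancels catastrophically (two ~|μ| terms
leaving a result of order σ²/|μ|), so the asymptotic Mills series is used
there instead. Equivalence with adaptive-quadrature normalization of the
posterior kernel is tested to 1e−6 relative error over 200 parameter draws
spanning `|Y| ∈ [0.05, 20]`, `σ² ∈ [1e−4, 1]`, `γ ∈ {1e−6, 0.005, 0.5}`,
`λ ∈ [0.1, 1e4]`.

The joint fit visits coordinates Gauss–Seidel style (additive, then
dominance, then epistatic kinds, pairs lexicographic), maintaining the
residual incrementally (`y_j = r + x_j ĝ_j`, then `r ← r − x_j Δĝ`).
Convergence is declared when the 2-norm relative change of the *stacked*
effect vector over all kinds falls below `tol` (default 1e−4): a
per-coordinate ratio would be undefined at the many exact zeros produced
by the spike prior. `x'x` uses the realized sample columns, not the HWE
expectation `n`. Non-convergence within `max_sweeps` (default 500) is
reported on the result, never silent.

## Hyperparameters

- `γ` (per kind): prior probability of a nonzero effect. Defaults: 0.005
  for main effects, 1e−6 for epistasis — at ~5,000 analyzed SNPs this
  expects ~25 main effects and ~50 interactions genome-wide.
- `λ` (per kind): Laplace rate; defaults derived as `λ = 2pγ` (main) and
  `λ = p(p−1)γ` (epistasis) with `p` the number of SNPs after MAF
  filtering. Note the coupling: at strongly reduced `p` these rules give a
  much weaker penalty than at full scale, which visibly raises sensitivity
  in scaled-down experiments (see *Scaled experiments* below).
- `σe²`: with covariates, re-estimated each sweep as `e'e/(n−q)` together
  with `b̂ = (W'W)⁻¹W'(y − Xĝ)`. Without covariates the update rule is
  only defined by analogy; the default here is `e'e/n` each sweep,
  initialized at the centred-trait variance, with a fixed known value
  supported via `ModelSpec(sigma_e2=...)`. The choice is consequential:
  `e'e/n` overestimates `σe²` by the uncaptured genetic variance, which
  inflates the shrinkage shift `λσ²` most at low heritability.
- `α` grid for the MOE decision: {0.01, 0.05, 0.10, 0.20}; Bayes factor
  threshold 3. No multiplicity correction is applied across loci — the
  decision is deliberately per-effect, and specificity is evaluated
  empirically instead.

## HPD credibility (measure of evidence)

κ is the posterior mass of the HPD interval tangent to zero on the side of
ĝ; its complement MOE = 1 − κ is the decision statistic. The spike at zero
creates a jump of height `f2(0)/p(y)` in the posterior CDF, but the
tangent interval is open at 0, so only the continuous branches enter the
density comparison `p(g|y) ≥ p(0|y)`. The border search is a grid search
over `[10·min(ĝ), 10·max(ĝ)]` (min/max over the current kind's effect
vector) with 2000 steps — deliberately the same coarse device as the
reference implementation, so near-zero effects whose border falls inside
one grid step get κ = 0 (MOE = 1), which is exactly the behaviour that
keeps the null quiet. A per-locus fallback grid `±10(|ĝ|+σ)` covers kinds
whose shared bounds do not straddle zero, and a closed-form border
(`2(Y ∓ λσ²)`, the reflection point of the Gaussian branch) is available
behind `HpdGridSpec(exact=True)` for verification. ĝ = 0 exactly yields
MOE = 1 by convention (the defining interval is empty).

## Simulator

The generator emulates a dairy-cattle evaluation design: `n_snps` biallelic
SNPs at jittered-uniform genetic positions on `n_chromosomes` equal
chromosomes (defaults 52,773 SNPs, 30 × 1 Morgan); 400 burn-in generations
of random mating among 100 individuals; then 4 generations of 50 sires × 20
dams (1,000 offspring each), generations 1–2 forming the training and 3–4
the validation set. Meiosis is a Markov chain over SNP intervals with
Haldane switch probabilities `(1 − e^{−2d})/2` (no interference);
chromosome starts segregate independently. Physical positions use a fixed
1 cM = 1 Mbp map, so the 100-kbp evaluation window is defined; after 10×
thinning the window usually contains only the causative SNP itself.

Two parameters are not dictated by the study design and were fixed as
follows:

- **Mutation rate** 2e−3 per SNP per meiosis. This is not a biological
  per-base rate; it is the symmetric-mutation/drift equilibrium
  (θ = 4Nμ ≈ 0.8 at N = 100) that reproduces the documented panel
  polymorphism — ~85% of thinned SNPs surviving the MAF > 0.05 filter.
  At a biologically literal 1e−5, four hundred generations of drift at
  N = 100 fix most loci and only ~23% survive, contradicting the design's
  own panel counts. The rate stands in for the larger historical
  population the real panel ascertained.
- **Effect-size law**: standard normal draws per causative coordinate
  (23 additive, 23 dominance, 6 pairs × 4 epistatic kinds), with the
  dominance and epistasis blocks rescaled by a fixed-point iteration so
  their realized shares of the training genetic variance hit the
  configured fractions (defaults 0.10 and 0.29) per replicate. Residual
  noise is rescaled so the realized broad-sense heritability matches the
  target up to the genetic–residual sample covariance.

Causative variants are drawn among SNPs whose training MAF already exceeds
the filter threshold, so thinning (which always keeps causatives) and
filtering cannot remove them. Permutation-null datasets shuffle genotype
rows against the trait; each permutation is reproducible from
`(seed, index)`.

**What the simulator does not emulate:** coalescent-exact LD, selection,
non-equilibrium demography, MAF-dependent effect sizes, genotyping error
or missingness. Passing tests therefore demonstrate the method's operating
characteristics under idealized family-structured LD, not performance on
any particular real panel.

## Evaluation conventions

A significant main-effect SNP is a true positive for kind k if it lies
within 100 kbp (same chromosome) of a causative variant carrying kind-k
truth; an epistatic pair must match a truly interacting pair of the *same*
kind (the stricter of the two possible readings; configurable in
principle). Overall sensitivity counts a causative as found if any
significant coordinate of any kind covers it. Specificity pools all tested
coordinates outside windows — for the full model this denominator is
enormous, which is why specificities sit near 1. Explained variance
(σ²_sign) is the training variance of the significant effects' fitted
values over the simulated genetic variance (no cap; overestimation can
push it above 1). Prediction accuracy correlates `X·ĝ` over *all* fitted
coordinates with the simulated genetic values of the validation set.
γ-tuning splits individuals in half at random, fits per grid value with λ
re-derived, and keeps the γ with the best held-out accuracy.

## Scaled experiments and their biases

The full design (≈4,400 analyzed SNPs, model M3 with ~39M interaction
coordinates) is cluster-scale. The test suite and the acceptance script
run a density-preserving reduction: 5,000 simulated SNPs on 3 Morgan
(≈450 analyzed after thinning and filtering), full n = 2,000 training and
validation sets, 10 replicates (5 in the suite), M1/M2 fits, and a
20-permutation null; the suite adds a small-p directional check that
overall sensitivity orders M3 ≥ M2 ≥ M1. One systematic consequence is
documented rather than hidden: because `λ = 2pγ` scales with `p`, the
reduced panel is penalized an order of magnitude more weakly than the full
one, and measured sensitivities at H² = 0.5 sit above the full-scale
values (specificity, the permutation null, and prediction accuracy are
essentially unaffected). Enlarging the panel toward the full `p` moves the
sensitivities down to the full-scale range but steepens the sensitivity
response to heritability beyond what the full-scale study shows under this
generator's equal-variance Gaussian effect law; no desk-scale setting
removes both distortions at once, so the configuration is pinned to the
stated one and the residual bias is reported as-is.

## Known limitations

- No kinship/population-structure correction; stratification biases the
  MAF estimates that define the standardization.
- The marginal tests condition on the converged fit; they are not joint
  posterior probabilities, and no FDR layer is applied.
- The Gauss–Seidel scheme has no convergence guarantee for heavily
  collinear designs; non-convergence is flagged, and sweep order is
  configurable for sensitivity checks.
- Missing genotypes are rejected at import (impute upstream); VCF parsing
  and phasing are out of scope.
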