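# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, what the synthetic generators do and do
not emulate, and the known limitations.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Superimposition

Generalized Procrustes analysis removes translation, scale and rotation:
each configuration is centered on its (available-landmark) centroid,
scaled to unit centroid size (`CS = sqrt(Σ‖xᵢ − x̄‖²)`, the standard
definition), and rotated to an evolving consensus until the consensus
moves by less than `tol` (default 1e-8, max 100 iterations).  This is
full Procrustes — specimens are rescaled to unit size — and Procrustes
coordinates are used directly as shape variables without a further
tangent-space projection; at the within-radiation scales the pipeline
targets, the curvature correction is far below the noise level, and the
assumption is flagged here.

Two choices deserve emphasis:

* **Rotations are always proper.**  The Kabsch solver constrains the
  determinant to +1; side correction is a separate, recorded `reflect`
  step applied while assembling a uniformly right-sided dataset.  A
  mirrored specimen therefore cannot be silently absorbed by the
  rotation step.
* **Canonical orientation.**  After convergence the consensus is rotated
  onto its principal axes (signs fixed deterministically), which makes
  the result invariant to specimen input order.  The reported consensus
  is the arithmetic mean of the final aligned configurations.

**Missing landmarks.**  Fossils lose landmarks to damage.  The package
first superimposes the complete specimens, aligns each incomplete
specimen to that consensus using only its available landmarks (matching
the scale of the corresponding consensus subset, so no scale leaks from
missing regions), then predicts each missing landmark by linear
regression of its three coordinates on all other landmark coordinates
across the aligned complete specimens.  Because a 30-landmark
configuration has 87 predictor coordinates and reference samples are
often smaller, predictors are reduced to the principal components
holding 99% of their variance before the regression.  A fresh GPA over
all specimens (imputed included) produces the final dataset, with
per-landmark imputation flags and original-scale centroid sizes
preserved.  Whether imputation should precede or follow the first
superimposition is genuinely open; the order above avoids biasing the
consensus with imputed values and is recorded as this package's choice.

## Ordination and classification

PCA is the eigendecomposition of the covariance matrix (correlation
matrix optionally, used for locomotor-mode percentages).  The
broken-stick rule retains the leading run of components whose variance
proportions exceed `b_k = (1/p) Σ_{i=k..p} 1/i`.

CVA maximizes the between/within variance ratio via the generalized
symmetric eigenproblem on PC scores retaining 95% of the variance — raw
shape variables (3 × 30 coordinates) would make the pooled within-group
covariance singular; the paper trail for this regularization is this
note.  Canonical axes are scaled so the pooled within-group covariance
is the identity, making canonical-space Euclidean distance a Mahalanobis
distance.  Classification uses equal priors; posteriors are
`exp(−d²/2)` normalized, with argmax ties broken by lexicographic group
name for determinism.  Accuracy is leave-one-out: the CVA is refit
without each specimen before classifying it.  Mahalanobis distances
between group means get permutation p-values (default 10,000 label
permutations).

Ward clustering is SciPy's Ward.D2 on Euclidean distances, with heights
on the distance scale and a Newick export.

## Phylogenetic comparative statistics

All methods consume the Brownian tip covariance `C` (`C[i,j]` = shared
root-to-MRCA path length).

* **Kmult** — the multivariate K statistic: the observed-to-expected
  ratio of tip deviations from the GLS (phylogenetic) mean,
  `K = (tr E'E / tr E'C⁻¹E) / ((tr C − n/(1'C⁻¹1)) / (n − 1))`.
  On one trait it reduces exactly to the univariate K (asserted to 1e-9
  against a direct implementation of that formula).  K = 1 is the
  Brownian expectation; the permutation test shuffles species-to-tip
  assignments, and p-values are `(b + 1)/(n_perm + 1)` throughout the
  package (default 10,000 permutations, seed mandatory).
* **Two-block PLS** — SVD of the between-block cross-covariance;
  `r_PLS` is the correlation of first-dimension block scores; the
  permutation shuffles rows of one block.  Note that `r_PLS = 1`
  requires the linear relation between blocks to be angle-preserving on
  the leading covariance direction; a general invertible map yields
  `r_PLS` slightly below 1.
* **Phylogenetic PLS** — both blocks are GLS-centered and whitened by
  `C^{-1/2}`.  The whitened, centered blocks live in the subspace
  orthogonal to `u = C^{-1/2}·1`, and both blocks share that constraint,
  so naive row permutation in the whitened space is slightly liberal.
  The package therefore re-expresses the blocks in an orthonormal basis
  of that (n−1)-dimensional subspace — an independent-contrasts
  representation that leaves the observed statistic unchanged while
  making rows exactly iid under Brownian motion.  Measured size at
  α = 0.05 over 500 null simulations is within ±0.02 of nominal
  (asserted in the test suite).
* **Multivariate PGLS** — design and response are premultiplied by
  `C^{-1/2}`; R² and a Goodall-style F come from trace sums of squares
  in that space; significance is by permutation of the reduced-model
  residuals (RRPP), matching the permutation-based p-values the
  surrounding literature reports.  On a star phylogeny it reproduces
  OLS exactly.
* **Ancestral states** — best linear unbiased prediction under Brownian
  motion with a GLS root, computed by conditioning the joint normal of
  nodes and tips.  This coincides with maximum likelihood and with
  weighted squared-change parsimony (minimizing `Σ Δ²/branch length`),
  which the tests verify against a general-purpose optimizer.  95%
  intervals use the conditional (universal-kriging) variance, inflated
  for root-mean estimation, with per-trait ML rates
  `σ² = (y−â)'C⁻¹(y−â)/n`.  Along-branch profiles are piecewise-linear
  interpolations between node states; no along-branch uncertainty is
  re-estimated (a simplification relative to character-map shading).

## Evolutionary models

Fitted by maximum likelihood on species-by-trait matrices (typically
retained PC scores), species-major vec layout, requiring binary trees
(polytomies must be resolved upstream; OU additionally requires
ultrametry).

* **BM** — closed form: GLS root, rate matrix `R = E'C⁻¹E/n`,
  `logL = −½(np·log 2π + p·log|C| + n·log|R| + np)`.  Verified to 1e-8
  against a dense `C ⊗ R` oracle on small trees.
* **EB** — Brownian motion with rate `exp(a t)`, `a ∈ [−10/T, 0]`,
  implemented as the elementwise branch-time transform
  `(exp(a·C) − 1)/a` and profiled over `a` by bounded scalar search.
  `a = 0` reproduces BM exactly.
* **OU** — symmetric positive-definite attraction matrix `A` shared
  across regimes, symmetric PD diffusion `Σ`, one optimum vector per
  regime painted along lineages.  With `A = QΛQ'`, tip means are linear
  in the optima with eigenbasis weights
  `exp(−λ(T−t₁)) − exp(−λ(T−t₀))` per lineage segment (plus
  `exp(−λT)` for the root term), and tip covariance blocks are
  `S_kl·exp(−(λ_k+λ_l)(T−s))·(1−exp(−(λ_k+λ_l)s))/(λ_k+λ_l)` with
  `s` the MRCA depth and `S = Q'ΣQ`.
  The **root state equals the root regime's optimum** (the process
  starts there).  A stationary root was considered and rejected: its
  profiled likelihood differs from BM's by `−½·log(1 + c·1'C⁻¹1)` with
  `c ≈ 1/(2α)`, so the single-peak OU would *not* tend to BM as
  attraction vanishes, breaking the nesting that makes the AICc ledger
  interpretable.  The started-at-optimum root has the identical
  parameter count (no separate root parameter) and nests into BM
  exactly; the test suite asserts agreement within 0.5 log-units at
  α-eigenvalues of 1e-6.
  Optimization is L-BFGS-B over Cholesky factors of `A` and `Σ`
  (log-scale diagonals, bounds ±12), with the optima profiled out by
  GLS at every evaluation and seeded random restarts (default 5; the
  calibration suites use 2 with a moment-based start at a half-life of
  half the tree height).  Multi-peak OU surfaces are multimodal; restart
  counts are recorded on the fit object.
* **Parameter counts** — BM `p(p+1)/2 + p`; EB one more; OU
  `p(p+1) + p·m` for m regimes.  For p = 5 this gives the ledger
  20 / 21 / 35 / 30+5m.
* **AICc** — `−2 logL + 2k + 2k(k+1)/(n_eff − k − 1)` with
  `n_eff = n_species × p`.  This effective-sample-size convention is the
  one that makes the published ledger's arithmetic internally consistent
  and is asserted against seven of its printed rows at ±0.01 (three
  further rows are arithmetically inconsistent under any convention and
  are excluded as typesetting artifacts).  Akaike weights are
  `exp(−Δᵢ/2)/Σ exp(−Δⱼ/2)`.

**Regime paintings.**  Ecological hypotheses are painted by Fitch
parsimony on tip categories with a deterministic ACCTRAN-style top-down
pass (a node keeps its parent's state when possible, otherwise the
lexicographically smallest candidate); each edge takes its child's
state, so monophyletic categories shift on stem edges.  Clade hypotheses
paint the crown group plus its stem edge over a background regime.

**A caution on PC truncation.**  Likelihoods are invariant under
full-rank rotations such as a complete PCA, but fitting models to a few
*leading* PCs is not neutral: truncation keeps the highest-variance
directions, which under Brownian motion are dominated by deep
divergences, and the retained scores then mimic a decaying rate.  On
Brownian-generated data the EB model can decisively beat BM once scores
are truncated (the README example shows this on real output), while on
untruncated traits EB collapses onto BM exactly.  Model preferences
obtained from truncated scores should be read comparatively, not as
absolute evidence for early bursts.

## Adaptive-peak search

The stepwise search fits each trait independently with a scalar-α,
scalar-σ² OU sharing one shift configuration (per-trait
`k = 2 + m`), summing AICc over traits.  α is profiled by bounded
search on a log scale over `[1e-4/T, 50/T]`; θ and σ² are profiled
in closed form.  Shifts sit at branch origins and propagate to all
descendant edges until overridden.  The forward phase accepts the best
candidate shift while it improves the summed AICc by at least 2 units
(the configurable stopping rule; the original formulation accepts any
improvement, and the 2-unit threshold is the stricter published
variant).  The backward phase collapses the best regime pair while any
improvement remains (strict improvement by default, configurable), and
regimes with two or more independent origins (root or shift) are
reported convergent.  Ties are broken deterministically (larger regime,
then lexicographic edge id).  The final painting exports directly into
the multivariate OU machinery, defining the "search-derived" hypothesis
of the model ledger; the round trip is asserted in the tests.

Two operating characteristics matter when reading its output:

* A shift on a root-child edge is unidentifiable from one on its
  sibling (both induce the same two-regime tip partition), so shift
  locations are meaningful only below the root.
* Because each accepted step maximizes improvement over every candidate
  edge, the best spurious gain under a no-peak (Brownian) generating
  process regularly exceeds the nominal threshold — the selection
  inflation familiar from stepwise regression.  Brownian data therefore
  yields a few spurious shifts per dataset rather than none; the test
  suite pins this down relative to the true-peak condition rather than
  asserting a near-zero false-positive count.  Recovery of real,
  strongly attracting peaks and detection of genuinely convergent
  regimes both exceed 80% in the calibration suites.

## Disparity through time

Disparity is `D = Σ_{pairs} dᵢⱼ/(n − 1)` (sum over unordered pairs of
Euclidean distances) — implemented verbatim as printed in the source
formulation, although the classic DTT literature uses the mean squared
pairwise distance.  Both conventions are available behind the `metric`
flag; since relative disparity is a ratio and the simulated envelope
uses the same formula as the observed curve, the MDI behaves the same
way under either (its Brownian centering is asserted in the tests).
Singleton subclades contribute zero.

The curve is evaluated on the relative node-time grid (root 0, tips 1):
at each internal divergence time the lineages crossing the instant just
before it contribute their subclade's disparity divided by the
whole-clade disparity, so the curve starts at 1 and ends at 0 at the
present (all-singleton endpoint, included by convention in both observed
and simulated curves).  The envelope is the pointwise 2.5%/97.5% band
of (default) 1000 Brownian simulations with the rate matrix estimated
from the data; the MDI is the signed trapezoidal area between the
observed curve and the simulated median, positive where observed
disparity exceeds the Brownian expectation.  Relative time makes the
whole analysis invariant to uniform branch-length rescaling.

## Body mass

Calibration individuals collapse to species points unless reported
sexual dimorphism exceeds 20%, in which case male and female points
enter separately.  Each facet's regression is OLS of log₁₀(mass, g) on
log₁₀(area) — OLS rather than reduced major axis because the use-case
is prediction.  `SEE` is the residual standard error (n − 2 df),
`%SEE = 100·(10^SEE − 1)`, and back-transformation applies the
log-normal (quasi-maximum-likelihood) smearing correction
`QMLE = exp(½·SEE²·ln²10)`; this formula reproduces the published QMLE
values from the published %SEE for all four facets at 3-decimal
rounding.  Per-specimen intervals back-transform the t-based log-scale
prediction interval at the new area; the QMLE applies to the point
estimate only, so the interval brackets the uncorrected prediction.
Fossil estimates average the intact facets' point estimates, rounded
half away from zero to integer grams (the published tables round one
borderline case the other way; tests use ±1 g).

## Synthetic data

The generators mirror the empirical design so test magnitudes are
comparable: ~40 species, ~5 specimens per species, 30 3D landmarks,
five locomotor categories, four facets, a 123-point mass-area
calibration.  Specifically:

* `sim_tree` — pure-birth (Yule) trees, exactly ultrametric, with the
  waiting-time construction giving `E[T_k] = Σ 1/(jλ)` (checked in the
  tests).
* `sim_traits` — exact multivariate-normal draws whose mean and
  covariance are the same matrices the likelihoods integrate over, so
  recovery tests draw from the fitted model itself.
* `sim_landmarks` — species mean shapes are a fixed template plus
  Brownian deviations in tangent (coordinate) space; specimens add iid
  digitizing noise, optional random rigid pose, left-mirroring and
  missing-landmark masking.  Default evolutionary and noise scales
  (3% and 1% of template size) put within-species noise well below
  between-species signal, as in real talar data.
* `sim_lmp` — softmax of a linear map of latent shape factors, scaled
  to percentages (rows sum to 100 exactly).
* `sim_mass_area` — `log₁₀ mass = m·log₁₀ area + b + N(0, SEE²)` with
  log-uniform areas; defaults m = 1.25, b = 3.0, SEE = 0.10, inside the
  published per-facet ranges.

What the generators do **not** emulate: real talar anatomy (the
template is an anisotropic point cloud, not a bone), mesh-level
artifacts, digitizer-specific error covariance, allometric shape
change beyond a simple size factor, and non-Brownian within-species
structure.  Green tests therefore certify the statistical machinery
under its stated models, not the biology of any particular dataset.

## Problem sizes and calibration settings

Simulation-based checks run at sizes chosen to give stable operating
characteristics on a single CPU: Kmult centering at 64 tips × 200
replicates; permutation-test sizes at 32 tips × 500 null datasets × 199
permutations; multi-peak OU recovery at 128 tips × 100 replicates
(2 traits, 3 regimes, attraction half-life a tenth of tree height, 2
restarts); peak-search recovery and convergence at 16 tips × 100
replicates (single trait); MDI centering at 24 tips × 200 replicates
with 100-simulation envelopes; mass-regression recovery at the
40-point published design × 100 replicates.  The acceptance script runs
reduced-replicate versions of the same checks (its `n` field records
each size).  Default analysis settings (10,000 permutations,
1000-simulation envelopes) remain the package defaults.

## Known limitations

* OU fitting assumes ultrametric trees and symmetric PD attraction;
  no measurement-error term, trends, or asymmetric attraction.
* Polytomies are accepted by the data layer but rejected by the model
  layer; resolve them upstream.
* The imputation regression assumes damage is unrelated to shape
  (missing-at-random); heavily damaged specimens (< 4 landmarks) are
  rejected rather than guessed.
* CVA posterior probabilities use equal priors and a shared
  within-group covariance; strongly unbalanced or heteroscedastic
  groups will miscalibrate them.
* The stepwise peak search inherits the overfitting behavior discussed
  above; its output is a hypothesis generator, to be re-tested in the
  multivariate ledger, not a hypothesis test.
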