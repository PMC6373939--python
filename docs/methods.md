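# Methods

This note documents the statistical models, the estimation algorithms, the
numerical choices, and what the synthetic-data generators do and do not
emulate.  The README states the models; here the emphasis is on how they are
fitted and why the defaults are what they are.

## Null models

**Independence model.** `log E(X_ij) = u_i + v_j` with NB errors.  Both
effect vectors are free parameters estimated by maximum likelihood with
alternating per-sample / per-taxon Newton updates and step halving, started
from the Poisson closed form (`exp(u_i)` = library size).  `u` is *not*
fixed at the log library size: the effective depth under an NB model weights
taxa by precision, and estimating it is what makes the ordination robust to
depth artefacts.  Identifiability: `Σ_j exp(v_j) = 1`, so `exp(v_j)` is the
mean relative abundance and `u` absorbs the scale.  Convergence: relative
deviance change < 1e-6, at most 100 outer iterations; non-convergence raises
an error carrying the deviance trace.

**Extended null model.** Adds `Σ_l ζ_jl g_il` with the confounder block
**G** mean-centred, so the confounder terms average out per taxon.  The
`ζ_j` are per-taxon Newton updates (batched across taxa), alternated with
`u` and `v`.  Because `u` absorbs each sample's total-count shift, `ζ` is
identified up to a per-sample constant; contrasts between taxa (e.g.
shifted vs unshifted under a batch) are what the model pins down.
Categorical confounders use reference (drop-first) dummy coding: with full
coding the centred block is exactly collinear and the per-taxon regressions
are singular.  Exact collinearity in **G** is an error naming the dependent
columns.

**Dispersions.** Per-taxon Cox–Reid adjusted profile likelihood: maximise
`Σ_i ℓ(x_ij; μ_ij, φ) − ½ log Σ_i w_ij(φ)` over `log φ ∈ [log 1e-8, log 1e3]`
by bounded scalar optimisation (`w = μ/(1+φμ)` are the working weights; the
adjustment accounts for the taxon's mean-model parameter).  Optional
empirical-Bayes shrinkage pulls `log φ_j` toward a linear trend in log mean
abundance with weight `prior_df` (default 10) against the n observed
samples; `prior_df = 0` disables it.  Dispersions are estimated after the
null fit and refreshed once after each ordination dimension converges — not
inside the iteration loop, because the deviance is only comparable at a
fixed dispersion vector, and refreshing per dimension keeps every
within-dimension deviance trace exactly monotone while still letting φ adapt
as interaction structure is absorbed.  Means are floored at 1e-10
throughout; below φ = 1e-10 all NB quantities evaluate their Poisson limits.

## Unconstrained ordination

Dimensions are fitted sequentially (greedily), lower dimensions frozen, so
each `ψ_m` retains its per-dimension interpretation.  Within a dimension the
interaction is parametrised as `a bᵀ` (scale unsplit) and the algorithm
alternates two batched joint Newton blocks:

* per sample: `(u_i, a_i)` jointly, given `b` — a 2×2 system per sample;
* per taxon: `(v_j, b_j)` jointly, given `a`.

Solving intercept and score *pairs* jointly matters: one-at-a-time updates
zigzag on the ridge between them and can take thousands of sweeps.  Each
block step passes through a line search (halve on deviance increase, double
while it helps), and each sweep ends with an extrapolation along the total
displacement — all score constraints are linear, so over-stepping the
combined direction stays feasible.  Centring is an exact reparametrisation
(the mean of `a` moves into `v`, the mean of `b` into `u`), hence free;
orthogonality to earlier dimensions is kept by projecting the Newton step of
each score vector onto the orthogonal complement.  The deviance trace is
recorded once per sweep and is non-increasing by construction.

Initialisation is deterministic: the leading singular pair of the
deviance-residual matrix of the current null/partial model, projected to the
feasible subspace; the seed only controls a jitter fallback when that pair
is degenerate.  At convergence `ψ_m = ‖a‖·‖b‖`, the scores are unit-normed,
and the sign is fixed by making the taxon with the largest |score| positive
(ties to the last such taxon).  Dimensions are reported sorted by `ψ`.
Defaults: tolerance 1e-5 (relative deviance change), 200 iterations per
dimension — sweeps are O(np) and cheap, and weak diffuse dimensions can need
over 50 of them.

**Divergence guard.** With zero-heavy tables the interaction likelihood can
have its supremum at infinite parameters: a block of zero cells rewards
pushing its means toward 0 without bound (a separation-type degeneracy of
interaction MLEs).  The score direction stabilises while the scale creeps
upward, so when `‖a‖·‖b‖` exceeds `30·√(np)` — far above any biologically
plausible interaction, which sits near `√(np)` for log-scale effects of
order one — the dimension is terminated with a warning and the current
finite parameters are kept.  On strictly positive tables the optimum is
interior and the fitted deviance matches an independent quasi-Newton
optimiser to ~1e-11 relative.

## Constrained ordination

The null intercepts and dispersions stay fixed.  Per dimension the fit
alternates:

1. given `α_m`: batched per-taxon NB Newton fits of the response
   coefficients on the design `[1, h]` (`[1, h, h²]` for the quadratic
   family), plus one pooled fit of a *common* response shared by all taxa;
2. a projected gradient-ascent step on the criterion
   `ℓ(taxon-specific) − ℓ(common)` with step halving (the envelope theorem
   makes the inner optima's derivatives vanish, so the criterion gradient is
   the explicit `α` derivative);
3. renormalisation: `α_m` unit-norm, orthogonal (Euclidean) to earlier
   gradients, and restricted to the row space of the centred constraining
   block **C**.

The row-space restriction is what makes full dummy coding workable: a
factor's centred dummies sum to zero, so **C** is structurally
rank-deficient and the component of `α` in its null space never affects
`h = Cα`.  Exactly duplicated columns *across* variables are still an error.
The criterion trace is non-decreasing by construction; identifiability puts
`Σ_j β_1jm² = 1` with the magnitude in `ψ_m`, and the sign convention
mirrors the unconstrained one (largest |slope| positive).  On a tiny d = 2
instance the converged criterion matches an exhaustive angle search with
independent inner fits to ~1e-11 relative.

**Quadratic responses** add a curvature coefficient; the vertex
`−β_1/(2β_2)` is the taxon's optimum along the gradient and convex fits
(β_2 > 0) are flagged as suspicious.  Note that any response component
shared by all taxa is absorbed by the sample intercepts, so the fitted
response functions describe *departures* from the community-average
response — recovery of an absolute niche optimum requires that most taxa do
not share it.

**Spline responses** are fitted post hoc with the gradient frozen at the
linear-fit estimate (alternating spline fits with gradient updates is out of
scope and documented as a limitation): per taxon, a cubic B-spline basis in
`h_1` (8 interior knots by default, reduced with a warning when there are
fewer distinct scores), a second-difference penalty, penalty chosen per
taxon by AIC over the grid {0.01, 0.1, 1, 10, 100, 1e3, 1e4}, offsets from
the null model.  The penalty's null space keeps a constant-plus-linear
component unpenalised, so a flat response bottoms out near 2 effective df.

## Diagnostics

**Deviance residuals** `sign(x−μ̂)·√(unit deviance)` at the fitted means and
dispersions; per-sample and per-taxon sums of squares add up exactly to the
total deviance.  For constrained fits the report carries the sample order
along the first gradient, the natural axis for spotting response-function
misspecification.  Non-converged fits are refused.

**Influence.** The gradient, the per-taxon response coefficients and the
common response jointly solve an estimating-equation system.  The influence
of sample i on a chosen gradient entry is the first-order change from
deleting that sample's score contributions, computed with the
*case-deleted* curvature `J − J_i` (the GLM DFBETA leverage correction; the
full-data curvature underestimates high-leverage samples), observed rather
than expected information, and a Schur reduction of the taxon/common
response blocks onto the gradient block.  Exact leave-one-out refits (full
refit per deleted sample, dispersions held at the full-data estimates, the
classical case-deletion convention) are available for validation; across
synthetic fits with n = 20 the one-step values rank-correlate with exact
deletion at a median Spearman ≈ 0.95.

## Synthetic data

The generators define the study conditions used by the tests and the
acceptance script.  Scenario defaults: 60 samples in four groups of 15,
1000 taxa (tests and the acceptance script scale p to 300 and use 20
replicates to stay desk-sized), 10% of taxa made differentially abundant
per group at fold change 5.  One base composition is drawn, group
compositions multiply the DA taxa without renormalising (the counts are not
compositional: total reads respond to the planted effects).  Scenarios: NB
(gamma-Poisson), NBcor (NB marginals through a block-equicorrelated Gaussian
copula, blocks of 5–20 taxa, within-block ρ ~ U(0.3, 0.7)), NBphy (a random
coalescent tree cut into 20 height clusters; each group's DA taxa are one
cluster, so they are phylogenetically related), DM (Dirichlet-multinomial),
ZINB (NB counts with per-taxon structural zeros; DA only in the count
part), and two no-signal scenarios that multiply per-group library sizes by
0.2/1/5/10 or per-group dispersions by 0.2/1/2/5.

Parameters come from built-in parametric pools rather than pools estimated
from large reference surveys — the one intentional divergence from a
data-driven setup: log-normal library sizes (meanlog 9, sdlog 0.7 — median
≈ 8100 reads), log-normal mean abundances (sdlog 2, heavy-tailed as real
communities are), gamma dispersions (shape 2, scale 0.25, mean φ = 0.5),
Beta(2, 8) zero-inflation fractions (mean 0.2), log-normal Dirichlet
concentration (meanlog log 50, sdlog 0.5).  Consequently the simulations
emulate realistic marginal behaviour (depth variation, abundance skew,
taxon-wise overdispersion, zero excess) but not the correlation networks,
phylogenetic signal strength or covariate structure of any particular real
survey — passing tests demonstrate correct estimation under the stated
generative models, not performance guarantees on arbitrary real data.

Model-based generators (`generate_rcm_dataset`,
`generate_constrained_dataset`) draw counts from the fitted models
themselves with known scores/gradients for recovery checks; unit-norm score
products scale as `1/√(np)` per cell, so the default interaction strength is
`ψ_m = 0.7 · 0.7^m · √(np)`, i.e. log-mean perturbations with standard
deviation ≈ 0.7 in the leading dimension — the order of a four-to-five-fold
abundance shift.  `generate_batch_dataset` plants a two-level batch
(crossed with the biology by default, optionally correlated) shifting a
taxon subset, for conditioning experiments.

## Evaluation metrics

Average silhouette width and pseudo-F (between/within variance ratio of
score rows) measure group separation on importance-scaled scores; the taxon
ratio compares mean absolute inner products `|⟨ψ∘r_i, s_j⟩|` of DA taxa
(paired with their own group's samples) against non-DA taxa (paired with
every group) — absolute values make it invariant to the ordination's sign
freedom, and pairing non-DA taxa with all groups uses all available
background.  Library-size correlations are Pearson correlations of each
score dimension with *log* library size.  All four match naive enumeration
implementations to 1e-10.

## Known limitations

* Exploration only: no permutation tests or confidence statements.
* Sequential (greedy) dimensions: `ψ_m` from a joint fit could differ.
* The spline mode fixes the gradient at the linear estimate.
* The influence approximation is first-order; samples with small influence
  can swap ranks relative to exact deletion.
* Zero-cell separation makes the interaction supremum non-attained on
  sparse tables; the divergence guard reports a finite surrogate with a
  warning rather than an error.
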