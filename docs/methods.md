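# Methods

This note documents the models implemented in `ecosens`, the defaults and
why they were chosen, what the synthetic study system does and does not
emulate, and the numerical decisions that matter.

## Sensitivity estimation

Per grid cell, ordinary least squares of the vegetation index on
temperature and precipitation with an intercept. All series enter
z-transformed (mean 0, unit sample sd, ddof = 1), so slopes are
standardized coefficients comparable across cells and variables. 95 %
confidence intervals use the t distribution on n − 3 degrees of freedom —
the normal approximation would be too tight at the interannual scale,
where n equals the number of years (~10–20).

**Seasonal scale.** Monthly series are detrended with a centred 12-month
moving average before standardization. The even window uses the standard
half-weight endpoint convention (a 2×12 MA), the canonical choice for
monthly data: it passes any 12-month-periodic signal through unchanged and
reproduces a linear trend exactly. The `window/2` positions lost at each
end are dropped, never imputed; `n_obs` records the loss (240 months →
228). Order of operations is detrend first, then z-transform: the final
standardization is what gives the coefficients their standardized
interpretation.

**Interannual scale.** Annual mean EVI, annual mean temperature, cumulative
annual precipitation; no detrending, since deterministic change *is* the
signal of interest at this scale.

**Masking and classification.** Cells with mean EVI below 0.1 are removed
(sparse or absent vegetation makes the index noise-dominated); the
boundary is inclusive — exactly 0.1 is retained. Limiting-factor
classification compares |β_T| with |β_P| per scale; ties (measure zero on
real data) go deterministically to temperature-limited. A signed
comparison is available as an option but absolute values are the default,
consistent with modelling sensitivity magnitudes downstream.

## Biodiversity dimensions

**Richness** is the per-cell column sum of the binary presence matrix.

**Faith's PD** is the total branch length of the union of root-to-tip
paths of an assemblage (root path included), computed on a flat edge
representation (edge length + descendant-tip mask), which makes the
null-model inner loop a single matrix product. PD is evaluated on the
maximum-clade-credibility member of a tree set: each tree is scored by the
sum of log clade frequencies across the set (log-sum rather than a raw
product, to avoid underflow); ties break by input order.

**Functional richness** is the convex-hull volume of an assemblage in a
shared reduced trait space. Traits are centred and unit-scaled before the
eigen-decomposition (correlation PCA) because traits carry incommensurate
units; all species are projected once into a single common space so that
the same species has the same coordinates in every assemblage. The
smallest axis count whose cumulative variance reaches 80 % is retained,
floored at 2 (with the default correlated-trait generator this is 3).
Assemblages with fewer than d + 1 points, or affinely degenerate ones,
return volume 0 with a `degenerate_fric` flag rather than an error.

**SES null model.** Raw PD and FRic scale with richness, so both are
standardized against a null that fixes each cell's richness and redraws
composition uniformly (without replacement) from the species pool:
`SES = (obs − mean(null)) / sd(null)` with the sample sd. The pool is all
species in the analysis extent by default; a per-biome pool is available
as an option. Sampling is unweighted — occupancy frequencies are not
preserved; a fixed-row-sum (occupancy-preserving) randomization would be a
stricter alternative but is not the default. Cells whose null has zero
variance (richness equal to pool size; richness too small for a hull) are
reported as missing with a reason code, never silently dropped. Default
1000 replicates; the pipeline default is 199 at desk scale, a precision
choice (SES Monte-Carlo error ~7 %) that keeps full runs in seconds.

## Trait imputation

Missing trait values are filled from two sources of information: trait–
trait correlation and phylogenetic relatedness. Relatedness enters as
phylogenetic eigenvectors — principal coordinates of the patristic
distance matrix (Gower double-centring of −D²/2), retaining positive-
eigenvalue axes that explain at least 3 % of variance (a fixed-count
option is exposed; desk-scale trees make species-level eigenvectors exact,
so no genus aggregation is needed). The imputer initializes missing
entries at trait means, then iterates ridge regressions of each trait on
[all other traits + eigenvectors], refreshing that trait's missing entries,
until the largest change is below `tol = 1e-6` or 100 iterations
(non-convergence returns a flagged result). The ridge penalty is scaled to
the problem, `α = 1e-6 · trace(XᵀX)/p`, purely for numerical stability.
Finally, imputed values are clamped to the observed per-trait min/max and
every clamp is logged; observed entries are never touched.

This imputer is a deterministic, fully specified procedure on the same
information set that hierarchical Bayesian matrix-factorization gap-fillers
use; it is not a reimplementation of any of them.

## Spatial error models

The biodiversity–sensitivity regression is
`y = Xβ + u`, `u = λWu + ε`, `ε_i ~ N(0, σ²/w_i)`, with

- `y` = |β_climate| for one climate variable at one temporal scale (kept on
  its natural non-negative scale; predictors are z-scored, so only the
  response units differ from a fully standardized fit — an option flips
  this);
- `X` = z-scored richness, SES-PD, SES-FRic; biome dummies (reference =
  first level alphabetically; levels under 10 cells are dropped with their
  cells and logged); a water-limited dummy (omitted and logged if a level
  has < 3 cells — a near-empty level cannot support its interaction
  block); and biodiversity × biome plus biodiversity × limiting-factor
  interactions;
- `W` = row-standardized 1/d weights on a distance band chosen by scanning
  candidates {1.5, 2.5, 3.5, 5, 7.5, 10} cell units for the strongest
  |Moran's I| of the response (scan table reported; candidates isolating
  > 5 % of cells are skipped);
- `w_i` = 1/(CI range) of the cell's sensitivity estimate, entering as
  inverse error variances — the natural likelihood reading of
  uncertainty weights.

Estimation maximizes the concentrated log-likelihood over λ with
`log|I − λW| = Σ log(1 − λe_i)` from the exact eigenvalues of W (W is
similar to a symmetric matrix, so the spectrum is real); β and σ² follow by
weighted GLS on the filtered system. The implementation refuses n > 10 000
rather than switching to determinant approximations. β standard errors are
the conditional-on-λ GLS covariance; λ's standard error comes from the
numerical curvature of the profile likelihood. λ estimates within 1e-4 of
the feasible boundary are flagged. If the design is rank-deficient despite
the level checks, aliased columns are dropped by pivoted QR with a warning
and recorded on the fit. One model is fitted per climate variable ×
temporal scale (four in a full run).

## The synthetic study system

The generator produces every pipeline input with known truth, under a
single seed fanned out to fixed per-stage streams
(`SeedSequence(seed, spawn_key)`), so stages are reproducible in isolation.

- **Climate**: temperature = latitudinal baseline (24 °C at the warm edge,
  −1.2 °C/row) + 8 °C seasonal sinusoid + 0.3 °C/decade trend + per-year
  anomalies (sd 0.4 °C) + monthly noise (sd 1 °C); precipitation = 80
  mm/month + 40 mm seasonal cycle phase-shifted by π/3 (so the two cycles
  are not collinear) + year effects (sd 8 mm) + noise (sd 15 mm), truncated
  at zero. The explicit year-effect terms matter: interannual sensitivity
  is only identifiable if climate actually varies between years, as it
  does in observational records.
- **Vegetation index**: `evi = 0.5 + 0.15·(β_T z(T) + β_P z(P) + noise)`,
  clamped to [0, 1]. The default β fields are spatially smoothed Gaussian
  fields (β_T ~ 0.45 ± 0.15, β_P ~ 0.25 ± 0.10); iid fields and
  fully user-specified fields are available, as is a mode coupling β_T
  linearly to realized richness for directionality experiments. Because
  the z-transform absorbs any affine map, the raw β are identified only up
  to a scale; the generator therefore also reports the exact standardized
  estimand, obtained by pushing the noise-free (linear) construction
  through the estimator on the same climate realization — closed-form
  evaluation, not a fit.
- **Scale-restricted injection**: `seasonal_only` applies the βs to
  within-year anomalies (whose annual means vanish identically);
  `interannual_only` applies them to year means rendered as a smooth
  interpolation through year midpoints — a piecewise-constant rendering
  would put year-boundary steps into the seasonal band that the
  moving-average detrend cannot remove.
- **Ranges**: each species occupies a disc (Gamma-distributed radius,
  mean 6 cells) on the integer lattice, centre biased toward the warm edge
  to create a richness gradient; every species keeps at least its centre
  cell. No projection geodesy: the grid is an abstract equal-area lattice.
- **Phylogeny**: pure-birth (Yule) tree rescaled to root height 100
  ("millions of years"; the absolute scale cancels in SES because null and
  observed share the tree), plus a set of trees perturbed by Poisson-many
  random NNI moves, standing in for a posterior tree sample.
- **Traits**: Brownian motion along the tree; per-edge innovations for the
  8 traits are drawn with a low-rank factor correlation so each trait is
  marginally BM at `bm_rate` while traits correlate (real trait suites
  do; this keeps the retained PCA axis count small). Observational noise
  is iid; missingness is completely at random — the weakest testable
  assumption, since real trait databases' missingness mechanism is
  uncharacterized.
- **Biomes**: latitudinal bands (3 by default).

What the generator does **not** emulate: spatially autocorrelated EVI
noise, phenology and lagged vegetation memory, range-map error structure,
non-random trait missingness, and biome boundaries that do not follow
latitude. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to these
real-data features.

## Problem sizes and calibration checks

The test and acceptance workloads use desk-scale sizes chosen to make
Monte-Carlo checks sharp while keeping full runs in seconds: 20×20 cells ×
20 years for coefficient recovery; 225 cells for scale separation; 500
cells × 199 replicates for SES calibration; 50 paired simulations at the
default 60-species pool for the imputation study (smaller pools leave the
per-trait regressions too few observed rows per predictor for a stable
comparison); 50 replicates at λ = 0.7 on a 20×20 grid for SAR recovery;
and 20 full-pipeline runs for the richness-directionality rate. The λ = 0
collapse check uses a small residual scale so that the comparison isolates
the algebraic collapse to weighted least squares rather than sampling
noise in λ̂.

## Known limitations

- The SES null treats cells independently; shared null draws across
  equal-richness cells would be faster but correlate errors.
- Eigenvalue-based log-determinants cap the SAR at ~10⁴ observations by
  design; hemispheric grids would need sparse-determinant approximations.
- λ standard errors come from the profile curvature, not the full
  information matrix; β standard errors are conditional on λ̂.
- The moving-average detrend leaks a small amount of very-low-frequency
  signal near record edges; edge months are dropped, which bounds but does
  not eliminate the effect.
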