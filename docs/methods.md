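# Methods

## Model

Let `y` be the n×S matrix of per-tow, per-species responses and `X` the
n×Q design matrix. Both response families share one latent Gaussian
structure: each tow's length-S latent vector is

    w_i ~ MVN(B' x_i, Σ),

and the observation rule maps `w` to the data scale. Continuous
abundance (CA, tobit): `y = max(w, 0)`, so exact zeros arise whenever
the latent value is nonpositive. Presence/absence (PA, probit):
`y = 1[w > 0]`. The product of per-entry indicator constraints ties the
latent state to the data; positive CA observations pin their latent
entry exactly (`w = y`), which is the tobit reading of the censoring
rule (re-sampling positive latents would be a different model).

`B` (Q×S) carries species-environment responses. `Σ` (S×S) is the
residual covariance: co-dependence between species that the mean
structure does not explain (missing covariates, biotic interactions,
shared sampling effects). Its correlation form
`R_ss' = Σ_ss'/√(Σ_ss Σ_s's')` is the object usually interpreted.

### Priors

The package uses non-informative conjugate priors: flat on B and
inverse-Wishart(ν₀ = S+2, Ψ₀ = I_S) on Σ. ν₀ = S+2 is the smallest
integer degrees of freedom for which the prior mean exists (it equals
I), so the prior is proper but adds the weight of only ~2
pseudo-observations. Both hyperparameters are arguments of `fit`.

### Gibbs sampler

Three exact conjugate blocks per iteration:

1. **Latent states.** For each species in fixed declared order, the
   univariate conditional of column s given all other current latent
   columns is Gaussian with row-wise mean
   `μ_s + Σ_{s,-s} Σ_{-s,-s}⁻¹ (w_{-s} − μ_{-s})`; censored entries are
   redrawn from this conditional truncated to their region (CA zeros:
   `(-∞, 0]`; PA: sign-constrained), vectorized over tows. Positive CA
   entries are never touched. Truncated draws use the inverse-CDF
   method (`Φ⁻¹(u·Φ(α))`) with a far-tail fallback via the asymptotic
   tail law `z = −√(m² − 2·log(1−u))` when `Φ(α)` underflows; draws are
   therefore reproducible from the seed and finite everywhere.
2. **Coefficients.** Matrix-normal full conditional: mean
   `(X'X)⁻¹X'W`, row covariance `(X'X)⁻¹`, column covariance Σ.
3. **Residual covariance.** Inverse-Wishart with shape ν₀ + n and scale
   `Ψ₀ + (W − XB)'(W − XB)`.

Initialization: `w = y` at positive CA entries, −0.5 in the censored
region, ±0.5 by label for PA — a feasible point of the truncation
region. A single run seed drives one `numpy` Generator for the whole
chain; identical (data, spec, lengths, seed) reproduce draws bitwise.

**PA identification.** The probit likelihood only identifies Σ up to
scale, so the chain runs on an unrestricted Σ (parameter expansion) and
every *stored* draw is rescaled: Σ → correlation matrix,
`B_qs → B_qs/√Σ_ss`. This is the standard marginal-rescaling treatment
of the multivariate probit.

Default run lengths mirror a production analysis — 20,000 iterations
with 8,000 burn-in for a final fit, 5,000/800 for the pruning
selection stage, 1,000/400 for grid screening — and are plain arguments
everywhere.

### Derived quantities

- Sensitivity `f = diag(B Σ⁻¹ B')`, length Q, entries ≥ 0: the
  community-level importance of each design column. Computed per draw,
  so it has a posterior.
- Environmental covariance `E = B'VB` with V the sample covariance of
  the design columns (intercept row/column zeroed): species similarity
  induced by shared responses, amplified for predictors that actually
  vary.
- Variance partition per species: `Var_i(μ_is) + Σ_ss` and the fraction
  contributed by the mean, averaged over draws. The partition formula
  is this package's interpretation of "fraction of variance from the
  mean"; other decompositions exist.
- Complete-data (conditional) DIC: the deviance
  `−2 log MVN(W | XB, Σ)` is accumulated online at every retained draw,
  and the effective-parameter count is `p_D = D̄ − D(θ̄)` at the
  posterior means of (W, B, Σ). Storing running means instead of latent
  trajectories keeps memory flat in chain length. Conditional DIC is
  one of several latent-variable DIC variants; comparisons should use
  the same variant on both sides, which the grid workflow does.

### Prediction

`predict` samples `w̃ ~ MVN(B'x̃, Σ)` per retained draw and censors,
pooling draws for means and central intervals. `predictive_mean` uses
the closed form of the censored-normal mean per draw
(CA: `μΦ(μ/σ) + σφ(μ/σ)`; PA: `Φ(μ/σ)`), removing Monte-Carlo noise
from point predictions — model selection scores out-of-sample fit with
this exact form. `conditional_predict` partitions the MVN over species:
latent values for conditioned species are fixed at observed positive
CPUE and sampled from the censored region otherwise (a short Gibbs scan
within the conditioned block), then targets are drawn from
`MVN(μ_T + Σ_TC Σ_CC⁻¹(w_C − μ_C), Σ_TT − Σ_TC Σ_CC⁻¹ Σ_CT)` and
censored. With nothing conditioned this reduces exactly to marginal
prediction (same code path).

## Inverse prediction

To score how much a covariate matters to the whole community, the model
is inverted: per posterior draw, find the covariate value that
maximizes the MVN log-likelihood of the tow's latent vector, holding
all other covariates at their observed values and recomputing
interaction columns as functions of the free covariate (treating them
as free columns would permit infeasible designs). Because interactions
are products of two *distinct* covariates, the mean is linear in any
single free covariate — every column involving it equals
`x_free × (partner value or 1)` — so the log-likelihood is exactly
quadratic and the maximizer has the GLS closed form

    x̂ = (b'Σ⁻¹b)⁻¹ b'Σ⁻¹ (w − μ₀),

with `b` the row-specific effective coefficient vector and `μ₀` the
mean at `x_free = 0`. The package computes this closed form (a bounded
numeric optimizer is kept as an independent cross-check and agrees to
1e-6 in tests). Estimates are clipped to ±4 standardized units; rows
with negligible curvature (`b'Σ⁻¹b < 1e-10`, a covariate the community
does not respond to) are drawn uniformly over that range, so their
intervals span the search range and the score collapses toward zero —
the correct "no information" answer. Censored observations contribute
through a sampled latent row per draw (three Gibbs sweeps from the
feasible start). Factors are inverted by evaluating the latent
likelihood at each level and normalizing.

Scores: continuous covariates — R² of inverse-predicted vs observed
values; factors — classification accuracy. On large surveys scoring
uses an evenly spaced subset of tows (default cap 400) because the
per-draw latent sampling dominates cost; the cap is an argument.

## Variable selection

**Pruning workflow.** Fit the saturated model, compute term-level
sensitivity posteriors (summing f over the columns a term spans) and
inverse-prediction scores, then drop every term that is *both*
insensitive (median below 10% of the largest term's median) and not
predictable from the community (continuous R² < 0.1; factor accuracy
below chance + 0.05). Interactions are dropped before their main
effects: a main effect survives while any retained interaction
references it. Refit and repeat until a round drops nothing. The
thresholds formalize a judgment call that is otherwise made by eye on
sensitivity/inverse-prediction plots; they are arguments, not
constants.

**Grid workflow.** All 2^k subsets of k optional terms on top of a
forced core (a subset including an interaction without its optional
main effect is completed to a valid hierarchical spec when
materialized). Every candidate is fitted with a short chain on a 70/30
train split (train size = half-up `round(0.7·n)`, which reproduces
3,652/1,565 at n = 5,217 and 4,155/1,780 at n = 5,935), screened by
in-sample DIC, and the shortlist is decided by pooled out-of-sample R²
of the analytic predictive mean. Choosing the *highest* out-of-sample
R² is deliberate; selecting the lowest would pick the worst predictor.
Splits are simple random by seed; a stratified hook would be the
natural extension for strongly clustered surveys.

## Synthetic surveys

The generator emulates the structure of a Northeast-US-shelf bottom
trawl survey rather than any particular data set: five correlated
environmental covariates (bottom/surface temperature and salinity,
depth; depth–bottom-temperature correlation −0.5), a two-level
subregion factor (even proportions) that shifts covariate means
(northern region colder and deeper) and places coordinates in
region-specific bounding boxes, tow ids, years 1998–2020 and stratum
labels. Units are realistic (depth clipped at 10 m, temperatures in °C,
salinities in psu) but cosmetic — the model consumes standardized
values.

Communities are generated by running the observation model forward from
a stored truth (B, Σ, spec, seed). Intercepts are drawn over a range
that produces heavy zero inflation (roughly 10–70% nonzero rows at unit
residual variance); the full-scale scenario (5,217 tows × 30 species,
9 design columns) builds two species clusters with opposite-sign
temperature responses, a block-structured true R (within-cluster 0.4,
between −0.1) and one rare species whose intercept of −1.2816 puts
~10% of rows nonzero (its slopes are damped so covariate variance does
not spread the presence probability back out). Species that come out
all-zero are redrawn up to 100 times, since the model rejects them.

What the generator does **not** emulate: spatial and temporal residual
autocorrelation, gear/vessel effects, stratified station allocation,
measurement error in covariates, and non-Gaussian residual tails.
Passing recovery tests therefore demonstrates correctness of the
estimator under its own assumptions, not robustness to these real-data
features; the semivariogram and PACF diagnostics exist precisely to
check the independence assumptions on real residuals.

## Validation experiment sizes

The experiments behind `scripts/acceptance.py` and
`tests/test_acceptance.py` use moderate problem sizes chosen once:
least-squares oracle agreement at n = 1,000, S = 5 (uncensored by
construction); parameter recovery at n = 2,000, S = 10, Q = 5 with
4,000-iteration chains and 5 replicate surveys (pooled coverage of 250
coefficient intervals and 225 correlation intervals); selection power
at n = 600, S = 10 with screening-length chains and 20 replicates per
workflow. For the grid workflow the generating model is the full
candidate, so both stages (DIC screen, out-of-sample R²) must
discriminate; the pruning workflow faces a saturated model containing a
covariate with exactly zero effect and must remove exactly that one.
Recovery of a *nested* null-term comparison by out-of-sample R² alone
is close to a coin flip at these sizes (the expected R² penalty of one
spurious term is of the same order as its sampling noise), which is the
statistical reality of that comparison, not an implementation artifact;
the DIC stage and the pruning workflow are the levers that reject
spurious terms, and the dedicated DIC test checks exactly that
property.

## Numerical notes and edge cases

- Design construction refuses zero-variance covariates under
  standardization, unseen factor levels at prediction time, and
  factor×factor interactions (not needed; would require cell-mean
  conventions).
- `fit` refuses all-zero species columns (no information for B or Σ;
  the species filter exists to remove them), rank-deficient designs
  (naming the collinear columns), and non-finite states (naming the
  iteration).
- Mean precision skips thresholds with zero predicted presences
  (0/0 undefined) rather than imputing 0 or 1; the grid is the 101
  points {0, 0.01, …, 1}.
- Semivariogram distances are great-circle (haversine); default bins
  are 10 equal widths up to the median pairwise distance. PACF uses
  Durbin–Levinson on sample autocorrelations (Yule-Walker), lag 0 ≡ 1.
- k-means aggregation standardizes predictor columns, retries empty
  clusters with re-seeded runs, and is mean-preserving by construction
  (size-weighted cluster means).
- The species inclusion filter applies "present in ≥ min_presence_tows
  tows" inclusively and "more than min_biomass_tows tows at
  ≥ min_biomass" strictly, matching the asymmetric wording of the rule
  it implements.

## Known limitations

- Full S×S covariance sampling only; no latent-factor dimension
  reduction, so S beyond ~40 becomes expensive.
- No spatial or temporal random effects; diagnostics quantify, but do
  not correct, residual autocorrelation.
- Inverse prediction inverts one covariate at a time post hoc; it does
  not jointly sample covariates inside the MCMC, so scores are
  comparable across covariates within a fit rather than absolute
  measures.
- Conditional DIC values are comparable across models fitted to the
  same data with the same machinery, not across DIC variants or
  packages.
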