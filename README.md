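# tobitjsdm

Joint species distribution modelling for zero-inflated survey data:
a Bayesian **multivariate tobit** (continuous abundance, e.g. CPUE in
kg/tow) and **multivariate probit** (presence/absence) model fitted by
Gibbs sampling, with inverse-prediction variable selection, conditional
prediction, and the standard evaluation metrics and residual
diagnostics.

## Who this is for

Fisheries and community ecologists modelling many species caught in the
same tows (bottom-trawl surveys and similar designs). Single-species
models fitted independently ignore that species are observed jointly and
co-depend; this package models the whole community at once, so
environmental effects come with valid uncertainty and the residual
co-dependence between species becomes a usable object — for grouping
species and for predicting one species from the observed abundances of
others.

## The model

For tow *i* and species *s*, observed CPUE `y_is` is the positive part
of a latent Gaussian:

```
w_i | x_i ~ MVN(B' x_i, Σ)          (length-S latent vector per tow)
y_is = w_is   if w_is > 0           (continuous abundance)
y_is = 0      if w_is ≤ 0           (discrete zero)
```

For presence/absence, `y_is = 1[w_is > 0]` and Σ is identified as a
correlation matrix (multivariate probit). `B` (Q×S) holds the responses
of each species to the design columns; Σ (S×S) is the residual
covariance across species. Priors are non-informative: flat on B,
inverse-Wishart(S+2, I) on Σ. Fitting is by a three-block Gibbs sampler
(truncated-normal latent updates, matrix-normal coefficient draws,
inverse-Wishart covariance draws).

Derived quantities:

- **R** — residual correlation, `R_ss' = Σ_ss'/√(Σ_ss Σ_s's')`:
  co-dependence left after the environmental mean structure.
- **f = diag(B Σ⁻¹ B')** — community sensitivity: one nonnegative
  number per design column measuring whole-community response.
- **E = B' V B** — environmental covariance: species similarity induced
  by shared environmental responses, weighted by predictor variability V.
- **Conditional prediction** — MVN partitioning on the latent scale:
  targets given observed abundances of conditioned species.
- **Inverse prediction** — per posterior draw, the covariate value that
  maximizes the latent likelihood; a covariate the community cannot
  "predict back" explains little community-level variation, which drives
  the pruning variable-selection workflow.

## Worked example

```python
from tobitjsdm import JointSpeciesModel
from tobitjsdm.synthetic import default_neus_scenario

truth, survey = default_neus_scenario(seed=1, n=1000, S=8)
model = JointSpeciesModel.from_dataframe(survey, truth.spec, truth.species)
results = model.fit(n_iter=2000, burnin=800, seed=1, log_every=0)

print(results.summary().head(3).to_string(index=False))
print("residual correlation sp00-sp01: %.3f" % results.R_mean[0, 1])
print(results.sensitivity_summary().to_string(index=False))
```

Output (abridged):

```
     term species    mean     sd      lo      hi  significant
intercept    sp00  0.1933 0.0637  0.0700  0.3213         True
intercept    sp01 -0.3064 0.0760 -0.4676 -0.1640         True
intercept    sp02  0.0950 0.0652 -0.0381  0.2226        False
residual correlation sp00-sp01: 0.449
          term  median   lo90   hi90
     intercept  3.5757 2.8973 4.5900
            BT  1.4917 1.2052 1.8407
         depth  1.8248 1.5098 2.1753
          BSAL  0.5740 0.4485 0.7235
           SST  0.7513 0.5947 0.9152
subregion[SNE]  1.2682 0.9419 1.6548
      depth:BT  0.3173 0.2090 0.4547
    depth:BSAL  0.7481 0.6130 0.9115
     depth:SST  1.9639 1.5593 2.4077
```

The coefficient table gives the posterior mean, spread and 95% credible
interval of each species' response to each design column, flagged
significant when the interval excludes zero. The sensitivity table
ranks predictors by their whole-community importance (posterior median
of f with a 90% interval) — here temperature, depth and their
interaction carry the signal, as built into the generating truth (the
two species clusters respond to temperature with opposite signs). The
positive residual correlation between the first two species (0.449,
true block value 0.4) reflects the block structure of the generating Σ.

The same pipeline is scriptable from the shell:

```bash
tobitjsdm simulate --seed 1 --out runs/sim
tobitjsdm fit --data runs/sim/survey.csv --n-iter 2000 --burnin 800 --out runs/fit
tobitjsdm predict --posterior runs/fit/posterior --data runs/sim/survey.csv --out runs/pred
```

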