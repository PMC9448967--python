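# Methods

This note documents the models implemented in `moltevo`, the choices made
where conventions differ between packages, and what the synthetic-data
generators do and do not emulate.

## Binary phylogenetic mixed model (`moltevo.pmm`)

The response is a per-species 0/1 trait (in the motivating application,
the presence or the extent of the pre-alternate molt in European
passerines). The model is a latent-liability animal model:

    eta_i = x_i' beta + a_i + e_i
    a ~ N(0, sigma2_a * C),   e_i ~ N(0, 1)   (residual fixed, never sampled)
    y_i ~ Bernoulli(logit^-1(eta_i))           (probit available)

`C` is the phylogenetic correlation matrix: the shared root-to-node path
length of each species pair divided by tree depth, the standardized
Brownian covariance of an ultrametric tree. Ultrametricity is accepted up
to a relative root-to-tip depth spread of 1e-3 (text-file truncation of
dated trees introduces jitter at that scale) and depths are averaged.

**Prior on the phylogenetic variance.** The variance is parameter-expanded,
`sigma2_a = alpha^2 * v`, with `alpha ~ N(0, 1)` and `v` scalar
inverse-Wishart with `V = 1, nu = 100`. At these values `v` concentrates
tightly around 1, so the implied prior on `sigma2_a` is essentially
`alpha^2`, i.e. a chi-square with one degree of freedom — a standard
weakly-informative prior for binary responses where the residual variance
is not identifiable and must be fixed. `nu` is configurable.

**Fixed effects.** Flat (improper) by default. When any predictor stratum
perfectly predicts the response ("separation" — e.g. every non-migratory
species sharing one molt state), the flat-prior posterior is improper along
a direction, so fitting raises an error unless the independent
`N(0, 9)`-per-coefficient prior is enabled; the multi-tree driver enables
it automatically when separation is detected. Separation detection is
deliberately conservative (any constant-outcome stratum of a discrete
predictor, or sign stratum of a centered continuous one, triggers it),
because the remedy is a proper prior that is harmless when not needed.

**Sampler.** Metropolis-within-Gibbs. Liabilities get vectorized per-site
random-walk Metropolis under the logistic link (step size adapted toward
44% acceptance during burn-in only), or exact truncated-normal Gibbs under
probit. Working random effects are updated in the eigenbasis of `C`,
where their full conditional is diagonal; `beta`, `alpha` and `v` have
conjugate Gaussian / scaled-inverse-chi-square conditionals. The retained
sample is `(iterations - burn_in) / thinning` draws — 950 at the default
2,000,000 / 100,000 / 2,000 schedule.

**Reporting.** Per coefficient: posterior mean, 95% interval (highest
posterior density by default; equal-tailed optional), effective sample
size (autocorrelation-time estimate, via arviz), lag-1 autocorrelation,
Geweke z (first 10% vs last 50%, spectral variance of each window from the
initial positive part of the autocovariance sequence), and pMCMC — twice
the smaller posterior sign probability, floored at 2/n when one sign is
unobserved and capped at 1. Phylogenetic signal is heritability

    h2 = sigma2_a / (sigma2_a + 1 + c)

with `c` the link variance (pi^2/3 for logistic, configurable to 0, which
changes the scale but not the ordering of h2).

## Correlated evolution of two binary traits (`moltevo.coevo`)

Joint states are 1=(0,0), 2=(0,1), 3=(1,0), 4=(1,1); eight single-change
rates q12...q43 parameterize the generator, dual changes being
structurally zero. The independent model ties the eight rates to four
(each trait's gain and loss do not depend on the other trait); the
dependent model frees all eight. The likelihood is Felsenstein pruning
over the 4-state chain with propagators `expm(Q t)` computed by
eigendecomposition (scipy `expm` fallback when the eigenbasis is
ill-conditioned); polytomies are handled natively; the root is integrated
over uniform 1/4 weights by default (stationary weights optional). Branch
lengths are used untransformed; an optional global scale factor is
available for numerical conditioning.

**Prior.** Every free rate is `Exponential(mean m)` with the single
hyper-mean `m ~ Uniform(0, 10)`, resampled within the chain. The implied
prior mean of each rate is 5 (law of total expectation), which prior-only
runs of the sampler reproduce.

**Reversible jump.** A partition sampler: each of the eight dependent-model
rates carries a label in {zero class} ∪ {shared-value bins}; bin values
take the exponential prior, the partition prior is uniform, and
reassignment moves propose new bin values from the prior, so the
acceptance ratio is the likelihood ratio times a candidate-count
correction. The Z-value of a rate is the percentage of retained samples
in which it sits in the zero class. Posterior mean rates are reported
including zero-class visits (the mean over all retained draws); the mean
over nonzero visits is also computed, since either convention is found in
the literature.

**Marginal likelihoods and Bayes factors.** Stepping-stone sampling along
the power-posterior path `L^beta`, with powers at quantiles of
Beta(0.4, 1) (beta_k = (k/K)^{1/0.4}), run from the posterior toward the
prior, 100 stones x 10,000 iterations each at full scale; each stone
contributes `logmeanexp((beta_k - beta_{k-1}) loglik)` over samples drawn
at the lower power. Marginal likelihoods are computed on fixed-dimension
models (reversible jump off). A model with no free parameter has
`logML = logL` exactly. `BF = 2 (logML_1 - logML_2)`; with each model run
10 times, the 10 x 10 pairings give 100 BF estimates whose mean and 95%
CI are reported; evidence categories are < 2 none, 2-5 positive, > 5
strong (the boundary 2 and 5 values count as positive). When the lag-1
autocorrelation of the dependent model's log-likelihood trace is >= 0.1,
the schedule is escalated — thinning doubled and iterations rescaled so
the retained count is unchanged — up to a configured cap.

**Directional tests.** A restricted dependent model pins two named rates
equal; `BF = 2 (logML_unrestricted - logML_restricted)` with the same
multi-run pairing. The standard battery is four contingent-change tests
(q12 vs q34, q21 vs q43, q13 vs q24, q31 vs q42) and two temporal-order
tests (q12 vs q13, q42 vs q43); when state 0 of one trait is associated
with state 1 of the other, the temporal-order pair swaps to q31 vs q34
and q21 vs q24. Direction is read from the unrestricted posterior means.

## Synthetic data (`moltevo.simulate`)

Trees are pure-birth with unit height — ultrametric, like dated avian
supertrees, but without their rate heterogeneity, imbalance or calibration
error. Trait pairs evolve by exact event-driven CTMC simulation; binary
responses come from the same liability model the PMM fits (including the
logistic latent), with generating parameters stored. The 188-row synthetic
study table reproduces the *schema* and plausible dependencies (migratory
species molt more often and more completely; a fraction of molts confined
to November-December so the two timing rules differ) but none of the real
covariance structure between ecology, phylogeny and molt — so passing
end-to-end tests demonstrates correctness of the machinery, not
reproduction of any real-data estimate.

## Calibration settings used by tests and the acceptance script

Desk-scale problem sizes, chosen once as the package's own calibration
conditions:

- Likelihood oracles: 4-6-tip trees (enumeration over all internal-state
  assignments is exact there); stepping stone vs numeric quadrature on a
  6-tip tree with one free rate, 24 stones x 600 iterations.
- BF calibration: independent-model simulations on 100-tip trees
  (moderate rates 0.7), 10 replicates, 14 stones x 250 iterations;
  strong-dependence simulations multiply one off-state rate by 20
  (q34 = 5.0 vs q12 = 0.25, other rates 1) on 250-tip trees rooted at
  joint absence — acquisition-oriented simulations start from the
  all-absent state, which is also where the contingency signal lives.
- Directional tests: q12 = 0.05 vs q34 = 1.0 (power) and q12 = q34 = 0.5
  (null), other rates 0.5, trees rooted at joint absence, 2 stepping-stone
  runs per model.
- PMM: type-I error of pMCMC over 200 null replicates (100-tip trees);
  interval coverage of a true effect beta = 1 over 40 replicates at the
  full 188-species size; h2 recovery targeting h2 = 0.5 over 20
  replicates on 250-tip trees — at substantially smaller sizes the
  variance posterior is prior-dominated and h2 recovery degrades (see
  Known limitations). Chains of ~10,000 iterations with burn-in
  2,000 are long past convergence for these sizes (checked against 4x
  longer chains).

## Known limitations

- The liability sampler's single-site Metropolis mixes slowly for very
  large phylogenetic variance; the escalation rule (or longer thinning)
  is the remedy, as in the motivating workflow.
- Reversible-jump output is reported for posterior summaries only;
  marginal likelihoods always integrate fixed-dimension models.
- No ambiguity codes in tip states; missing data must be resolved or
  pruned before fitting.
- h2 estimates for binary traits carry noticeable finite-sample prior
  shrinkage below ~200 species; this is a property of the model, visible
  in the calibration runs, not a sampler artifact.
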