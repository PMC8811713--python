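# Methods

## Model

`rlddm` estimates the reinforcement learning drift diffusion model (RLDDM)
for two-alternative instrumental learning tasks. Expected values of the two
options evolve by the delta rule,

    Q_{o,i} = Q_{o,i-1} + α (R_{o,i-1} − Q_{o,i-1}),

updating only the chosen option within each subject × condition block (blocks
are processed in row order; learning is order-dependent). The choice/RT
likelihood of trial *i* is the Wiener first-passage-time (wfpt) distribution
of a unit-variance diffusion between absorbing boundaries 0 and *a*, started
at *z·a*, shifted by the non-decision time *t*, with trial drift

    v_i = (Q_upper,i − Q_lower,i) · v,

where *v* is a free scaling parameter playing the role of the softmax inverse
temperature: a DDM that ignores RT with z = 0.5 reduces exactly to a softmax
with β = a·v (this identity is exercised in the test suite). An RT-free
softmax variant (`likelihood="softmax"`) estimates α and β only.

Optionally the "full" DDM's between-trial variabilities enter: drift
variability `s_v` (normal, handled by the closed-form Gaussian-mixture
density), and uniform non-decision-time (`s_t`) and starting-point (`s_z`)
variability, handled by 11-node Gauss–Legendre quadrature. They are
group-only parameters, since subject-level variabilities are notoriously
poorly identified.

### Numerics of the wfpt density

The density uses the Navarro–Fuss series approximation: for each evaluation
the small-time and large-time expansions' required term counts are compared
and the cheaper branch is used, at absolute tolerance 1e-4 by default
(configurable). A truncation undershoot in the far tails is clipped at 0.
`rt ≤ t` has density 0 (the boundary case `rt = t` included). Invalid
parameter regions (a ≤ 0, z outside (0,1), z ± s_z/2 leaving (0,1),
t − s_t/2 < 0) yield −∞ log-likelihood so the sampler treats them as
rejections rather than errors. The within-trial diffusion coefficient is
fixed at 1; all parameter values in this package assume that scaling
convention.

## Hierarchical structure and priors

Group mean and SD hyperparameters generate subject parameters
(see `rlddm.model` for the full list):

| family | group mean | group SD | subject level |
|---|---|---|---|
| a | Gamma(mean 1.5, rate 0.75) | HalfNormal(0.1) | Gamma(mean μ_a, var σ_a²) |
| v | Normal(2, 3) | HalfNormal(2) | Normal(μ_v, σ_v²) |
| z | Normal(0.5, 0.5) | HalfNormal(0.5) | invlogit(Normal(μ_z, σ_z²)) |
| α | Normal(0, 3) | HalfNormal(2) | invlogit(Normal(μ_α, σ_α²)) |
| t | Gamma(mean 0.4, rate 0.2) | HalfNormal(1) | Normal(μ_t, σ_t²) |

plus s_v ~ HalfNormal(2), s_t ~ HalfNormal(0.3), s_z ~ Beta(1, 3). Gamma
distributions are parameterized by mean and rate at the group level and by
(mean, SD) at the subject level. The DDM priors are informative (drawn from
the meta-analytic tradition of hierarchical DDM software); the learning-rate
prior is wide and centred at 0.5 after the inverse-logit transform. Learning
rates and starting points are sampled on the unconstrained (logit) scale and
reported on both scales (`alpha` and `alpha_trans` in summaries). Subject
non-decision times get Normal densities truncated at 0 by support checks (a
negligible clip of prior mass given the data scales involved).

Condition splits (`depends_on={"v": "split_by"}`) create one full
mean/SD/subject family per condition. With dual learning rates
(`dual=True`), positive and negative prediction errors get separate α
families, each transformed independently through the inverse logit; a zero
prediction error takes the positive branch (a measure-zero tie under
continuous rewards, fixed deterministically).

### Trial-wise regressions

Formulas like `"a ~ neural"` attach linear models to a parameter.
`x*y` expands to main effects plus interaction, `x:y` is the product only,
`0 +` removes the intercept. Links: identity for *a* and *t* (*a* floored at
1e-3 when the unconstrained predictor goes non-positive, so such draws score
near-zero likelihood instead of crashing); inverse logit for *z* and *α*;
for *v* the linear predictor multiplies QΔ, so a zero slope reduces exactly
to the plain scaled-drift rule. The reserved term `conflict` is the
standardized (within subject; zero-variance series map to zeros) reciprocal
1/(|QΔ| + ε), ε = 0.01 by default; "inverse of the value difference" is
genuinely ambiguous between a reciprocal and a negation, so
`conflict_mode="negation"` (−|QΔ|, standardized) is available as a switch. Conflict may not enter a learning-rate regression (it depends on α
itself).

Regression coefficients — intercept and slopes — are group-level parameters
without subject spread: the regression-recovery generating process fixes one
baseline threshold for all subjects, the printed reference posteriors are
consistent with pooled coefficients, and pooling keeps the extra nodes per
formula constant rather than linear in subjects. The intercept takes the
target family's group prior; slopes take Normal(0, 3). In regression models
the learning rate must be included explicitly (`include=("a","v","t","alpha")`);
a formula-only spec otherwise fixes α at 0.

## Sampler

Metropolis-within-Gibbs with univariate slice sampling per node
(stepping-out + shrinkage, initial width 1.0, at most 10 expansions split
randomly between the two sides, shrinkage capped at 200 iterations as a
numerical safeguard). Group nodes condition on subject-node densities only;
subject nodes add that subject's likelihood; group-level likelihood nodes
(variabilities, regression coefficients) add the full likelihood.
Per-subject likelihoods are cached and recomputed only when a node that can
change them is updated. No width adaptation or thinning is applied; defaults
are 1500 draws, 500 burn-in, one chain (three chains for Gelman–Rubin
workflows). Chains are seeded as independent substreams of the configured
seed, so runs are bit-reproducible.

Purely univariate centered updates mix slowly through the hierarchical
funnel when a subject-level spread is weakly identified (small σ pins the
subject values to the mean, which keeps σ small; in practice the drift-scale
spread σ_v is the slowest node, with lag-1 autocorrelation near 0.9).
Every second iteration (`interweave_every`) the sampler therefore adds a
non-centered update of each normal family's group SD: holding the
standardized deviations u_j = (x_j − μ)/σ fixed — their N(0,1) density does
not depend on σ — σ is slice-sampled against prior × likelihood and the
subject values are remapped as μ + σ′u_j. This interweaving move cuts the
worst-node potential scale reduction from ≈1.12 to ≈1.01 at the default
three-chain settings for about 25% extra runtime. The gamma-distributed
threshold family is excluded (the rescaling identity is linear-Gaussian);
its tight HalfNormal(0.1) spread prior limits the funnel there.

Initial states draw group nodes from priors and subject nodes from their
group distributions, resampling subject non-decision times (bounded) until
below the subject's minimum RT, and retrying the whole draw (up to 50 times)
until the joint log density is finite. Slope coefficients start at 0.

The sampler was validated against a conjugate normal–normal oracle, against
prior means under a flat likelihood, and by simulate-and-refit recovery; the
wfpt kernel against numerical integration and against Euler–Maruyama
simulation (Kolmogorov–Smirnov on 1e5 signed RTs, 1% criterion).

## Diagnostics

`summarize` pools chains and reports mean, SD and the 2.5/25/50/75/97.5
percentiles (numpy linear-interpolation quantiles, for reproducibility).
`gelman_rubin` is the classic (non-rank-normalized, non-split) potential
scale reduction factor, floored at 1 so identical chains report exactly 1;
the 1.1 heuristic is reported, never enforced. DIC uses
D̄ + p_D with p_D = D̄ − D(θ̄), the plug-in point θ̄ being the posterior mean
on the sampled (unconstrained) scale for transformed parameters — the scale
choice is a documented convention, not an estimate of anything.

Posterior predictive checks draw retained MCMC states, take their
subject-level parameters, and simulate complete datasets on the task
schedule — observed responses are never used for simulation, only overlaid.
Reported: choice proportion of the upper option in 4-trial bins with a 90%
HDI band across replicate means; RT densities with lower-boundary RTs
negated; and quantile-probability data (10/30/50/70/90% RT quantiles and
choice proportions) across difficulty terciles of |QΔ|, with tercile edges
from posterior-mean learning-rate trajectories on the observed data when
available. PPC simulation is defined for non-regression models (simulating
a regression model would require a covariate-generating model, out of scope).

## Synthetic data

The simulator is the package's generative mirror. First passages are drawn
by Euler–Maruyama integration at dt = 1e-4 s with a Brownian-bridge
crossing correction each step (crossing probability
exp(−2 d₀ d₁ / dt), evaluated only within 5√dt of a boundary, where it is
non-negligible), which removes the leading O(√dt) discretization bias; walks
exceeding a 20 s horizon are redrawn, a truncation that is negligible for
the parameter ranges used (guarded by the normalization and KS tests).
Between-trial variabilities perturb v (normal), t and z (uniform) before
each walk.

The default task is the probabilistic selection task learning phase: three
condition pairs rewarded 80/20, 70/30 and 60/40 percent, binary 0/1
feedback, q_init = 0.5, 60 trials per condition. Subject parameters are
drawn from normals around the group means; the recovery design's grid is
a ∈ {1.5, 2.0, 2.5}, t ∈ {0.3, 0.4, 0.5}, α ∈ {0.15, 0.3, 0.45},
v ∈ {1.5, 2.25, 3.0} with subject SDs 0.1/0.02/0.1/0.25 and 40 subjects.
The learning-rate subject SD is stated on the probability scale; by default
it is applied on the logit scale via the delta-method conversion
sd_logit = sd / (p(1−p)) (so that draws respect (0,1) exactly), with
`alpha_scale="probability"` drawing directly on the probability scale with
clipping as the alternative, since the convention is not fixed by the
recovery design itself.

What the simulator does *not* emulate about real data: contaminant/outlier
RTs (no outlier-mixture component exists in the likelihood either — extreme
observations are the user's preprocessing concern), lapses of attention,
non-stationary learning rates, session/block effects, and any generative
model of neural covariates (regression covariates are abstract Normal(0,1)
series). Passing recovery tests therefore shows the estimator is correct
and well-calibrated *under the model*, not that the model fits any given
empirical dataset.

## Problem sizes used in the shipped checks

The regression-recovery check uses 30 subjects × 180 trials with 1000
draws/250 burn-in; the group-recovery and convergence checks share one
dataset of 20 subjects × 180 trials fit with three chains of 1500/500 —
one grid cell of the full design, at half the subject count, which keeps
the posterior-mean tolerances of the original grid meaningful. The
distributional (KS) checks use five fixed parameter sets spanning both
drift signs and biased/unbiased starting points at 1e5 samples each.

## Known limitations

* Two response options, at most two tracked values per condition.
* No gradient-based samplers; slice sampling mixes well here but scales
  linearly in nodes × likelihood cost.
* No WAIC/LOO; model comparison is by DIC only.
* No sigmoid drift transform or uncertainty-scaled learning rates.
* The conflict latent term is the only latent regressor supported.
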