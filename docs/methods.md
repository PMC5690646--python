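# Methods

`crowdprior` turns quantile-probability judgments elicited from naive
respondents into Gaussian "consensus" priors for two-group study designs,
and uses the implied effect sizes for retrospective design analysis and
sample-size planning.  This note records the models, the numerical choices,
and what the synthetic-data checks do and do not establish.

## Elicitation data model

For each question and condition a participant states a best guess, a
minimum L and a maximum H, and then cumulative probability estimates
p1 <= p2 <= p3 at three quantile prompts placed inside [L, H]:

    c1 = L + (H - L)/6,    c2 = L + (H - L)/2,    c3 = H - (H - L)/6.

The middle prompt is the interval midpoint.  (A commonly printed variant of
this placement rule writes the middle prompt as (H - L)/2 without the L
offset; for L > 0 that value falls below c1 and contradicts the
monotonicity the elicitation itself enforces, so the midpoint convention is
the only self-consistent reading and is what this package implements.)
Validation enforces L <= best <= H, monotone probabilities, probabilities
in [0, 1], and prompt consistency with (L, H) to a relative tolerance of
1e-6 (prompts may be stored rounded).  Zero-width intervals are accepted
with a warning and skipped by the model-fitting stages; the elicitation
procedure gives no information in that case.

## Per-participant fits and median aggregation (MLE route)

Each participant's belief is modeled as N(mu, sigma^2).  The point estimate
minimizes

    SSE(mu, sigma) = sum_i ( p_i - Phi((c_i - mu)/sigma) )^2

by deterministic multi-start Nelder-Mead on (mu, log sigma): a 5 x 5 grid
of starts spanning the prompt range (mu) and 0.1x-10x the prompt spread
(sigma), plus a quantile-inversion start obtained by regressing prompts on
the normal scores of interior probabilities (exact for consistent
responses).  Lowest SSE wins; ties break toward the smaller sigma.  Flat
probability triples are non-identifiable (any mu with sigma -> infinity
fits equally well); they are flagged, assigned the sigma ceiling
100 x (c3 - c1), and excluded from aggregation rather than imputed — median
aggregation needs no imputation to stay robust.  The consensus prior per
condition takes the medians of the participant mu's and sigma's
independently (even counts: mean of the middle two).

## Hierarchical Bayesian consensus (HBM route)

One model per question, on prompts standardized by the pooled mean and
population SD of all the question's prompt values (both conditions; the
transformation is recorded and inverted exactly when reporting).  For
participant i in condition c with standardized prompt q and response p:

    m_ic ~ Normal(mu_c, tau)        s_ic ~ Normal(sigma_c, gamma), s > 0
    p = 0            with probability phi_0
    p = 1            with probability phi_1
    p ~ Beta(mean = Phi((q - m_ic)/s_ic), precision = kappa)   otherwise

with priors mu_c ~ N(0, 1), sigma_c, tau, gamma ~ half-N(0, 1),
kappa ~ half-N(0, 10), phi ~ Dirichlet(1, 1, 8).  The Beta is
mean-precision parameterized (a = mean * kappa, b = (1 - mean) * kappa);
kappa is shared within a question and absorbs response noise.  The
zero/one point masses are the contamination component: a continuous belief
cannot produce exact boundary responses, and without the mixture any
dataset containing them has zero likelihood.  rho, the share of
contaminants that are ones, is derived as phi_1 / (phi_0 + phi_1) — the
boundary-response counts are fixed by the data, so phi (and hence rho) has
a conjugate Dirichlet posterior independent of everything else.  The
consensus prior per condition is the posterior median of (mu_c, sigma_c),
inverse-transformed to outcome units.

### Sampling

The posterior is explored by seeded Metropolis-within-Gibbs with
independent chains (default 5):

* phi: exact conjugate Dirichlet draw each sweep;
* mu_c: exact conjugate normal draw;
* (m, log s) per participant: joint random-walk Metropolis, vectorized
  across participants, three refreshes per sweep;
* tau, gamma, sigma_c, kappa: scalar random-walk on the log scale.  The
  positive-truncation normalizer Phi(sigma_c/gamma) of the s-hierarchy is
  carried in the sigma_c and gamma conditionals;
* interweaved non-centered refreshes of tau, sigma_c and gamma: with only
  three responses per participant the centered conditionals form a funnel
  (a small gamma pins the s_i, which in turn pin gamma), so each sweep also
  proposes the scale while holding the standardized residuals fixed,
  moving the participant values jointly.  In these moves the
  participant-prior terms are constant and the 1/scale densities cancel
  against the reparameterization Jacobian, leaving the response
  likelihood, the truncation normalizers, and the half-normal prior.
  gamma and kappa — the slowest-mixing pair, coupled along a
  noise-attribution ridge — additionally get a joint non-centered move and
  extra refreshes per sweep.

Proposal scales adapt every 50 warmup sweeps toward acceptance 0.30
(bivariate) / 0.44 (scalar) and are frozen before sampling, so retained
draws come from a fixed kernel.  Defaults: 1000 warmup sweeps, then
600 draws per chain at thinning 5.  All randomness derives from the single
config seed; identical configs give bitwise-identical draws.

Initialization: the consensus-layer parameters start at prior draws
(overdispersed across chains).  The participant layer and kappa start at
data-informed values — each (m, s) at its single-subject least-squares fit
and kappa at a moment-matched residual estimate, both jittered per chain.
The reason is a genuine feature of this posterior: it can carry a second,
low-precision mode in which responses are read as heavy Beta noise around
near-homogeneous beliefs (small kappa, small tau/gamma, inflated sigma_c).
Chains whose participant layer starts at unrelated prior draws fall into
whichever mode is nearest and random-walk kernels do not cross between the
modes, which the split-R-hat diagnostic then correctly flags.  Seeding the
participant layer from the data places every chain in the data-supported
basin; the consensus layer remains overdispersed so between-chain agreement
is still informative.  When the competing mode retains non-trivial mass for
a particular dataset a chain can still migrate into it — this surfaces as
R-hat >= 1.1 and is reported as a convergence warning rather than hidden.

Diagnostics use split R-hat and bulk effective sample size (via arviz); the
summary convergence flag requires all R-hat < 1.1 and hyperparameter
ESS >= 200, echoing standard practice of judging fits on five independent
chains.

### Pooling coefficients

For each participant parameter the pooling coefficient is

    (unpooled MLE - posterior median) / (unpooled MLE - hyperparameter median)

clipped to [0, 1]: 0 = the hierarchical estimate sits at the individual
fit, 1 = at the grand mean.  Note the two routes are different estimators —
least squares on CDF values versus the Beta response likelihood — so even
with pooling switched off their centers differ by a fraction of the
posterior SD.  The shrinkage-direction test therefore allows half a
posterior SD of slack; exact betweenness is not a theorem of this pair of
estimators.

## Retrospective design analysis

Given an assumed true standardized effect d and total sample n, with
lambda = |d| sqrt(n), df = n - 1 and t* the two-sided critical value at
alpha (default 0.05), the estimate is modeled as lambda plus central-t
noise in standard-error units:

    power  = 1 - F(t* - lambda; df) + F(-t* - lambda; df)
    Type S = F(-t* - lambda; df) / power
    Type M = E[ |lambda + T| given |lambda + T| > t* ] / lambda

Type M uses seeded Monte Carlo (default 10^6 draws); the tests check it
against direct numerical integration of the truncated shifted-t
expectation.  The one-sample convention (lambda = |d| sqrt(n),
df = n - 1) is deliberate: it is the convention under which the published
power values this package reproduces were computed; a two-sample per-group
convention does not reproduce them.  At d = 0: power = alpha exactly,
Type S = 1/2, Type M is flagged infinite.

Sample-size planning inverts the normal approximation,
n = ((z_{1-alpha/2} + z_{power}) / |d|)^2, rounded to the nearest integer.
The rule's known small-sample behavior is kept as-is: for large effects the
planned n is small and the exact t-test power of that n falls a few points
short of the target (e.g. 0.76 at d = 0.65), while for moderate effects the
planned sample lands within about two points of the target.

The prior-weighted t statistic mixes a consensus prior into each
condition's empirical summary with the weight of one observation:
mean_k = (n_k xbar_k + mu_k)/(n_k + 1), sd_k = (n_k sd_k + sigma_k)/(n_k + 1)
(SDs averaged linearly, following the verbal description of the procedure
literally), then the Welch unequal-variances t of the weighted summaries
with counts n_k + 1 and Welch-Satterthwaite degrees of freedom.

Effect sizes from a pair of condition priors use
pooled_sd = sqrt((sigma_c^2 + sigma_t^2)/2), the equal-n pooled-SD
analogue; this is an assumption, as the source procedure never defines how
two prior spreads pool.

## Synthetic data generator

The generator emulates the elicitation with the same hierarchy the HBM
assumes.  Defaults (chosen once, as the study conditions for all checks):
mu_c = -0.5 / +0.5 (control/treatment), sigma_c = 1.0, tau = 0.5,
gamma = 0.3, phi = (0.05, 0.05, 0.90), kappa = 30, 20 subjects, 2
conditions, 3 responses each — a modest standardized treatment effect with
realistic disagreement between respondents, ~10% boundary contamination,
and response noise of SD ~0.08 on the probability scale, at the scale of
the recovery simulation reported for this method.  Guess fields are
synthesized as m -/+ 2s with Normal(0, 0.1 s) jitter, purely so records
carry plausible (best, lo, hi) values; the models consume prompts and
probabilities only.

By default each probability triple is sorted ascending after contamination,
mirroring the survey instrument's forced monotone entry.  This is
instrument-faithful but not model-faithful: sorting re-pairs contaminant
and valid responses with the wrong prompts (an exact-1 response always
lands on c3), and fits to sorted data inflate the belief-heterogeneity
parameter tau substantially (about +70% at these settings, persisting at
large n) while leaving the consensus means essentially unaffected.  The
recovery harness therefore generates with sorting disabled: it checks the
sampler against the exact generative model, which is what a
parameter-recovery claim is about.  What passing recovery shows is that
the inference machinery is correct on model-distributed data; it does not
show that instrument artifacts (forced monotonicity) or violations of the
Gaussian-belief assumption are harmless — the sorted-versus-unsorted gap in
tau is itself the measure of the first artifact.

## Recovery behavior

The recovery harness simulates at the 20-subject scale (20 replicates, 90%
intervals) at the generator's default hierarchy and refits with the default
sampler budget.  Observed behavior, recomputed fresh by the test suite and
`scripts/acceptance.py`: consensus means mu_c are covered at near-nominal
rates, tau and gamma are recovered with negligible bias, and the sampler's
own diagnostics (split R-hat < 1.1, hyperparameter ESS >= 200) pass on
every replicate.  A ``draw_hyper_from_priors`` mode draws each replicate's
consensus-layer truth from the model priors instead — the full Bayesian
calibration design — but prior-drawn truths include weakly identified
corners (near-zero spreads with large heterogeneity) where the default
budget does not converge, so that mode is reserved for larger budgets.

One widely expected small-sample property does **not** appear at these
conditions: sigma_c posterior medians are not pulled below the true value
by the half-normal prior; they sit very slightly above it.  The reason is
identifiability: because the quantile prompts adapt to each participant's
own stated [min, max] interval, they straddle the belief distribution and
make the spreads unusually well identified, so the prior's boundary pull
(measured directly by refitting with a 10x flatter spread prior, which
moves the posterior median by at most a few hundredths) is smaller than the
small-sample upward skew of the spread likelihood.  Less informative
prompt placements, or truths in the prior's upper tail where its density
falls steeply, would shift that balance back toward attenuation; this
package does not explore those regimes.  The corresponding directional
test is kept in its expected-direction form and documents this finding.

## Known limitations

* Gaussian beliefs are an assumption of convenience; kernel-density or
  Gaussian-process belief models are out of scope.
* The Beta construction ties the response mean to the belief CDF with a
  single shared precision; richer noise models (per-participant precision,
  systematic miscalibration) are not implemented.
* The posterior can be genuinely multimodal (noise-versus-heterogeneity
  trade-off); the sampler reports rather than resolves residual
  multimodality, and stuck-mode chains surface as R-hat warnings.
* Published t values of the eight example studies cannot be recomputed
  with prior weighting here because that requires condition-level means and
  SDs the printed summaries do not include; the operation is implemented
  and property-tested instead.
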