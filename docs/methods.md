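# Methods

## The ordinal disease-course model

The package models the progression of a multi-item ordinal rating scale
(the SARA, total 0–40, or the four-item f-SARA, total 0–16) as a nonlinear
mixed-effects process on a latent population disease clock.

**Individual time reparameterization.** A subject with log acceleration
ξ ~ N(0, σ_ξ²) and start-of-progression age τ ~ N(τ_pop, σ_τ²) observed at
age t sits at ψ = exp(ξ)(t − τ) on the population clock.  τ is anchored to
the reference (first) item: its first threshold is fixed at ψ = 0, so τ is
the age at which that item's score typically moves from 0 to 1.  exp(ξ) is
a multiplicative speed: calendar time spent at level l is δ_l·exp(−ξ).

**Ordinal observation model.** Item k with maximum level L_k has
thresholds c_{k,1} = θ_k (onset offset, ≥ 0, zero for the reference item)
and c_{k,l+1} = c_{k,l} + δ_{k,l}, with every level duration δ_{k,l} > 0.
Exceedance probabilities are logistic in ψ with per-item steepness s_k
(years): P(Y ≥ l | ψ) = logistic((ψ − c_{k,l})/s_k); level probabilities
are successive differences.  This makes the δ's interpretable directly as
average years spent per level while defining a proper ordinal likelihood
that handles missing items by omission.  Observations across visits and
items are conditionally independent given (ξ, τ).

Assumptions worth stating: no item-specific individual effects beyond the
shared (ξ, τ) (two individual parameters only); cofactors (genotype, sex,
CAG, cohort) act on the analysis of the individual parameters, not inside
the generative model; visit ages are treated as fixed covariates.

## Inference: MCMC-SAEM

`fit()` runs, per chain:

* **Individual blocks.** Joint random-walk Metropolis per subject for ξ
  and for τ (vectorized across subjects), targeting the conditional
  posterior given the current population parameters.
* **Identifiability.** After each individual update the ξ vector is
  recentred to mean 0 and the time-scale parameters (δ, θ, s) are rescaled
  by exp(−mean ξ); the likelihood is exactly invariant under this
  transformation, which removes the scale ridge (δ, s, ξ) → (cδ, cs,
  ξ + ln c).
* **Structural parameters.** Single-site random-walk Metropolis on the
  *thresholds* c_{k,l} (with the ordering constraint and the exact
  log-delta prior including its Jacobian), plus a log-scale move for s_k.
  Threshold-space moves were chosen over cumulative-delta moves because a
  single delta move shifts every higher threshold and mixes roughly an
  order of magnitude worse; in threshold coordinates each site is pinned
  locally by the observations near that level, restoring nominal credible
  interval coverage at desk-scale budgets.
* **Hyperparameters.** During burn-in, closed-form stochastic-approximation
  (SAEM) updates of (τ_pop, σ_τ, σ_ξ) from the current individual draws,
  with step 1 for the first half of burn-in and k^(−0.65) thereafter.
  After burn-in, conjugate Gibbs draws (flat prior on τ_pop, Jeffreys on
  the variances) so the retained draws form a genuine joint posterior
  sample; the structural parameters carry near-flat Normal(0, 10⁶) priors
  on their unconstrained transforms.
* **Adaptation.** Proposal scales adapt toward 0.3 acceptance in windows
  during burn-in only; sampling-phase acceptance rates are recorded and
  are expected in [0.1, 0.6].

Defaults are 5500 burn-in + 3500 retained iterations and 2 chains (the
`full` profile); a `test` profile (1000 + 500) is used throughout the test
suite and CLI smoke runs.  All draws are deterministic given the seed;
chain seeds are spawned from a single `SeedSequence`.

**Convergence.** `geweke()` compares the first 10% and last 50% of a
chain; segment-mean variances use a Bartlett-window (Newey–West) long-run
variance estimator with lag ⌊4(n/100)^{2/9}⌋.  |z| < 2 is read as
consistent with convergence.

**Personalization.** For a new subject, the (ξ, τ) posterior mode is found
by Nelder–Mead on the observation log-likelihood plus the Gaussian priors
(multi-start over τ), followed by random-walk Metropolis draws.

**Univariate mode.** The total score is treated as one pseudo-item with
one delta per total-score level (39 for the SARA), mirroring the analysis
of global scale progression; the multivariate mode models the eight items
jointly with shared (ξ, τ).

### Identifiability limits

Level durations of severity levels never visited in a cohort are prior-
dominated: under the near-flat prior their draws random-walk and their
summaries are meaningless.  This is intrinsic, not a sampler defect;
analyses should read per-level summaries only over the severity range the
cohort covers.  Item mean deltas that include such levels inherit the
problem, which is why the end-to-end generator test asserts the fast
(items 1–2) versus slow (items 5–8) ordering rather than per-level values
for slow items.

## Posterior analyses

* **Delta summaries**: equal-tailed percentile medians and 95% credible
  intervals per level duration (requires ≥ 100 retained draws).
* **Linearity**: for each item, per-draw differences between every pair of
  level durations; progression is flagged nonlinear when at least one
  pairwise 95% interval excludes zero.  The max − min per-draw difference
  is reported as the item's maximum difference in progression.  No
  multiplicity correction is applied across pairs (raw 95% intervals);
  with k levels the familywise flag rate under an exact null is about
  1 − 0.95^{k(k−1)/2}, which the calibration test bounds at 20% for
  three-level items.
* **Item speeds**: per-draw mean delta per item (average years per
  one-point increase), summarized by median, 95% CI and the IQR of the
  posterior as the variability measure.  The IQR-of-the-posterior reading
  was chosen over pooling per-level deltas because it measures uncertainty
  in the speed itself.
* **Group dynamics**: per retained iteration, group means of exp(ξ) and τ
  under a subject→category map; summarized by median and 95% CI.
* **CAG correlation**: Pearson r between per-subject τ (posterior medians)
  and log CAG, with Fisher-z CI.  Correlations are computed within
  genotype: across genotypes the CAG–onset relationship is confounded by
  between-genotype differences (SCA3 has later onset *and* longer repeats
  than SCA1).

## Trial design

The design primitive is the change score over the trial duration, compared
between two equal arms with a two-sided z-test.  The sample size uses the
normal-approximation formula n/arm = ⌈(z_{1−α/2} + z_{power})²·2σ²/d²⌉
with d = effect_fraction × placebo mean change; for the reference scenario
(1.08, SD 1.27, 50% effect, α 0.05, power 0.90) this gives 117 per arm,
234 total.  `empirical_power` verifies any design by simulating normal
change scores (via their sufficient statistics, with the pooled-variance
estimate studentizing the test) and is deterministic given the seed.
Scenario grids accept per-(group × scale variant × inclusion window)
change statistics; inclusion windows are closed intervals on the baseline
total score, and pre-ataxic (RISCA-like) subjects are excluded from change
statistics by default since they do not progress over a short window.

## Synthetic data generator

The generator emulates the structure of pooled SCA natural-history
cohorts so every stage of the pipeline is testable without any external
data; scores are simulated from the course model itself, so cohorts are
self-consistent with the likelihood and ground truth is retained.

Defaults (per-genotype onset means 32.7/33.0/37.2/51.0 y; σ_τ = 8 y;
σ_ξ = 0.4; item mean-delta bands 2.5–5 y for gait/stance, 5–7.5 y for
sitting/speech, 9–12.5 y for the four limb items; onset offsets
Uniform(0, 3) y for non-reference items; steepness 0.3 × the item's
smallest delta; 1–6 visits at 1 ± 0.15 y intervals; 3% per-item
missingness; disease duration at entry Uniform(0, 15) y; 10% pre-ataxic
subjects entering up to 10 y before onset, labelled RISCA; CAG marginals
centred on medians 46.5/39/70/22 with log-scale SD 0.08) were fixed once
to match the cohort shapes the analysis is meant for.  Each level duration
is drawn uniformly from its item's band, so item mean deltas necessarily
fall in the band and a degenerate band yields exactly equal deltas.  CAG
is generated from the inverse linear model on τ with noise set so the
within-genotype τ–log CAG correlation is −0.7 before integer rounding
(rounding attenuates it by well under 0.01).

**What the generator does not emulate**: centre and rater effects,
severity-dependent dropout, measurement error beyond the ordinal
likelihood, and any real-data deviation from the logistic exceedance
form.  Passing recovery tests therefore demonstrates the correctness of
the inference machinery under the model's own assumptions, not the
adequacy of the model for any particular real cohort.

**Informative entry and the recovery fixture.** In the main generator,
baseline age is onset plus a disease-duration draw — as in real cohorts,
where enrolment age and onset age are correlated.  Because the model
conditions on visit ages as fixed covariates, such latent-dependent entry
makes p(τ | ages) differ from the prior and biases population-parameter
estimates upward by roughly 20% under these conditions (verified by
Monte-Carlo marginal-likelihood profiling).  The dedicated univariate
recovery fixture (`generate_univariate_cohort`: 10-level pseudo-item,
equal 1-year durations, 4 annual visits) therefore draws baseline ages
from a fixed window *independent* of onset, making parameter recovery a
well-posed consistency check.  The same informative-entry caveat applies
to real-data analyses with this class of models and is listed under
limitations.

## Numerical choices

* Interior level log-probabilities are computed as
  log σ(a) + log1p(−exp(log σ(b) − log σ(a))) with the difference clamped
  at −10⁻¹², and all observation log-probabilities floored at −700, so the
  likelihood is finite everywhere and the sampler can recover from poor
  regions.
* `most_likely_level` breaks ties toward the lower level (first argmax),
  making the average trajectory a non-decreasing step function.
* Initialization: a crude years-per-point d₀ from median first-to-last
  total-score slopes; τᵢ from the first visit age minus d₀ × baseline
  total; each item's initial level durations spread its course over the
  full total-score course.
* Cronbach's α uses the unbiased (n−1) variance convention, resamples
  subjects (rows), and is computed on complete rows only (count reported);
  the bootstrap CI is the 2.5/97.5 percentile interval of 1000 resamples.
  By default reliability is computed on baseline visits (one row per
  subject) to avoid within-subject dependence.
* The SARA→f-SARA mapping ships as a proportional collapse fixing both
  endpoints (gait 0/1–2/3–4/5–6/7–8 → 0..4; stance and speech
  0/1–2/3–4/5/6 → 0..4; sitting identity) and can be replaced by any
  monotone table via JSON; monotonicity and endpoint preservation are
  validated on load.
* Duplicate (subject, age) rows are an error, not a merge; ordinal visits
  must be distinct.

## Problem sizes

The test suite and acceptance checks run reduced-budget configurations
chosen as desk-scale defaults: recovery studies use 300-subject univariate
cohorts at 1000 + 500 iterations (single chain, ~3 s each; 20 seeded
replicates), multivariate smoke runs use 60–100 subjects, and Monte-Carlo
power uses 20,000 simulated trials.  The `full` profile (5500 + 3500, two
chains) is the recommended setting for real analyses.

## Known limitations

* Population parameters for unvisited severity levels are unidentified
  (see above).
* The unimodal Gaussian assumption on τ over a genotype mixture shrinks
  group differences slightly (a few percent of the gap at desk scale).
* Informative entry ages bias population-level time-scale estimates; the
  model shares this property with other latent-time progression models.
* The sample-size routine supports 1:1 allocation and normal-approximation
  sizing only; no dropout inflation.
* The linearity flag inherits the raw-interval multiplicity behaviour of
  its definition.
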