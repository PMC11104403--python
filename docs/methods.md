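# Methods

## The task and its data model

The modified Balloon Analogue Risk Task (BART) presents two blocks of 30
balloons. Each pump earns 10 points; the balloon bursts once a hidden,
per-balloon threshold is reached, forfeiting the balloon's points. In the
low-cost (LC) block a burst costs only the balloon's points; in the
high-cost (HC) block it additionally deducts a fixed penalty from the
running total (1000 points in the main design, 200 in the pilot preset).
Thresholds come from a fixed master array, re-shuffled independently per
participant, so every participant faces the same multiset of risks in a
different order.

The published design reports only summary statistics of the master arrays
(mean 12.23, SD 4.72, range 1–19 for all blocks except the pilot LC block's
12.37, SD 3.49, range 6–18). `make_burst_array` therefore generates integer
arrays pinned exactly to the range endpoints with mean and SD within ±0.5
of the targets, by seeded greedy adjustment from a rounded-normal start;
`TaskConfig` accepts exact arrays whenever they are available.

## The four-parameter model

The agent tracks a per-pump burst belief. Before balloon *t* it holds

    p_belief = 1 − (priorBelief + learningRate · n_successes)
                   / (1 + learningRate · n_pumps),

where `n_pumps` / `n_successes` count past pump evidence (a burst's final
pump is the one failure). The belief is clamped to [1e−6, 1−1e−6]: the
exponential transform bounds `priorBelief` only below, so raw beliefs can
leave the unit interval, and the clamp keeps the likelihood defined
everywhere. From the belief and a risk-taking propensity the agent forms a
target pump count `number_t = −riskTaking / ln(1 − p_belief)` and pumps at
the l-th opportunity with probability `sigmoid(−β (l − number_t))`, β the
inverse temperature.

A balloon observed with *n* pumps and no burst contributes *n* pump terms
and one stop term to the likelihood; a burst balloon contributes only the
*n* pump terms, because the explosion censors the stop decision. Outcome
probabilities over "stop after 0..K−1 pumps or burst at K" telescope to
exactly 1, which the test suite verifies by brute-force enumeration.

Two readings of the evidence window exist: the description of the update
speaks of the previous trial, while the classic implementation of this
model accumulates evidence over all previous trials. The package defaults
to cumulative accumulation and exposes `evidence_window="last_trial"` for
the literal single-trial reading. The single-trial window produces much
stronger trial-to-trial carryover and is used in the post-hoc carryover
tests for exactly that reason.

The variant family assigns each of the four parameters either
participant-level (random: group mean, group SD and per-participant error)
or group-level (fixed: one shared value) status; excluding the all-fixed
assignment leaves 15 models.

## Synthetic cohorts

The generator draws participant parameters with the same non-centered
scheme the fitting pipeline assumes — raw = mean + SD · error on the
sampling scale, then the learning rate through a logistic ("approximate
Phi") transform `inv_logit(0.07056 x³ + 1.5976 x)` (exact Phi available via
config) and the other parameters through `exp`.

Default group-level values (sampling scale) are

| parameter            | mean  | SD   | natural-scale centre |
|----------------------|-------|------|----------------------|
| prior belief         | −0.16 | 0.12 | ≈ 0.85               |
| learning rate        | −0.9  | 0.6  | ≈ 0.18               |
| risk taking          | −0.6  | 0.4  | ≈ 0.55               |
| inverse temperature  | 0.7   | 0.3  | ≈ 2.0                |

with a default HC shift of −0.2 on the raw risk-taking mean. These were
calibrated once against the published behavioural summaries of the main
study — LC non-burst mean pumps ≈ 8.4 with between-participant SD ≈ 2.3 and
a lower HC mean ≈ 7.1 — and then frozen; under them the simulated LC block
reproduces those statistics with a burst rate near 0.4.

Questionnaire totals are generated through a Gaussian copula: the CQ latent
correlates with the standardized raw target parameter (default: risk
taking, r = −0.3, the direction hypothesised for catastrophizing), the
other instruments correlate 0.5 with the CQ latent, and totals are
rescaled, rounded and clipped to instrument ranges (GAD-7 0–21, STAI-T
20–80, PSWQ 16–80, PHQ-8 0–24; the CQ total range is configurable and
defaults to 0–96, i.e. 24 items scored 0–4). Item-level structure, floor
effects and demographic covariates of real questionnaires are not
emulated, so passing tests show pipeline correctness under the model's own
assumptions, not robustness to real-data violations.

## Hierarchical inference

Priors follow the study pipeline: standard-normal group means and
participant errors, group SDs half-normal with scale 0.2 (the positivity
constraint is the standard reading of a Normal(0, 0.2) SD prior), blocks
fitted separately. Two backends satisfy the same prior/transform/likelihood
contract:

* **map_laplace** (default): joint posterior mode by L-BFGS over (group
  means, log group SDs, participant errors). Optimizing log-SD with its
  Jacobian keeps the mode off the sd = 0 funnel degeneracy. Gradients use
  structured central differences: participants are conditionally
  independent, so all per-participant error derivatives come from a handful
  of batched likelihood evaluations. The Gaussian (Laplace) approximation
  exploits the same structure — the precision matrix is assembled from a
  group block, participant blocks and their couplings, and the group
  marginal covariance comes from a Schur complement, at O(participants)
  cost. Precision spectra are floored at 0.25 (no direction's posterior SD
  above 2): finite-difference Hessians can carry tiny negative eigenvalues
  in nearly flat directions (typically weakly identified log group SDs),
  and the order-one prior curvature justifies the floor. Draws are sampled
  from the resulting Gaussian; the backend is deterministic given its seed.
* **emcee**: affine-invariant ensemble MCMC on the identical posterior,
  initialized near the mode; used as a cross-check at small scale.

Defaults mirror the study configuration (4 chains × 3000 iterations, 2000
warm-up; the Laplace backend reads chains × kept iterations as its draw
count). Convergence is summarised by split-R̂ on the group draws with a
1.05 flag threshold; flagged fits are excluded from model rankings, never
silently accepted.

The scaled-down designs used by the test suite are 8–12 participants for
unit-level fits, 20 fits of 12 participants for the calibration check
(where 95% intervals cover the generating group means in ≥ 90% of cases),
and 3 cohorts × 30 participants for the recovery gate. A single cohort of
30 gives Pearson-r sampling noise of ±0.15–0.19, which would make the gate
outcome a seed lottery; pooling three cohorts (90 generating/recovered
pairs) makes the decision stable while staying well inside desk-scale
runtimes.

## Model comparison

Models are scored by the integrated BIC,
`iBIC = −2 log p̂(D|M) + k log n`, with participant-level parameters
integrated against the *fitted* group distribution, `k` counting
group-level free parameters (two per random parameter, one per fixed), and
`n` counting atomic pump/stop decisions (trials or participants are
selectable conventions; absolute iBIC values are only comparable within
one convention). The marginal likelihood uses defensive importance
sampling: naive draws from the group distribution almost never land where
a 30-trial likelihood is non-negligible, so half the proposal mass sits on
a Gaussian moment-matched to each participant's posterior (inflated 1.5×)
and the weights estimate the same integral with bounded variance. The
estimator is seeded and reported with a delta-method Monte-Carlo standard
error; a degenerate group SD collapses the integral to the plug-in
likelihood. Bayes factors use the conventional `exp(ΔiBIC/2)` mapping.

A winning model is only reported as best when it also passes the recovery
gate: generating-vs-recovered Pearson r above 0.6 for every random
parameter and no cross-parameter trade-off above 0.4 in magnitude
(operationalized as |r| regardless of p-value, for reproducibility).
Recovery correlations are computed on the sampling scale, where the
hierarchy is linear and boundary pile-up cannot saturate the statistic;
Spearman correlations are reported alongside as a robustness line.

## Model-free pipeline

The behavioural summary is each participant's mean pumps over non-burst
trials per block. Variables with |sample skewness| > 0.5 (a conventional
cutoff; the trigger is configurable) are square-root transformed —
`sqrt(max(x) − x)` for negative skew, which reverses order and is so
labelled in every report, and `sqrt(x + c)` for positive skew with the
smallest non-negativity shift `c`. Correlations are Pearson with df = n−2;
a Shapiro–Wilk check (α = 0.05) on the regression residuals decides the
rank-based fallback, a reproducible proxy for visual residual inspection.
The cost-moderation contract is a linear mixed model of block-mean pumps
on centred CQ × cost with a participant random intercept; the trial-level
post-hoc model regresses pumps on previous-burst × centred CQ per block,
excluding each block's first trial. Both delegate to statsmodels MixedLM
and report Wald F statistics with a residual-df approximation
(Satterthwaite df are not available there; the label records the method).
Mediation/SEM is out of scope — the pipeline instead emits a tidy
per-participant table usable by external SEM tools.

## Numerical choices and limitations

* Belief clamp 1e−6; stable log-sigmoid throughout; raw parameters clipped
  at ±300 before exponentiation.
* L-BFGS stops at ftol 1e−8 / gtol 1e−4 (the finite-difference gradient
  noise floor), with up to 2000 iterations.
* Zero-pump balloons are valid observations contributing one stop term;
  participants absent from one block are handled by masking, and
  participants with zero non-burst trials are flagged rather than dropped.
* Penalty size never enters the likelihood (the model has no point terms);
  block differences are modelled, when desired, as group-mean shifts.
* The Laplace backend approximates the posterior by a Gaussian around the
  joint mode; its calibration is verified empirically at desk scale but
  heavy-tailed or multimodal posteriors (e.g. very few trials per
  participant) would be better served by the emcee backend.
* Absolute iBIC values depend on the observation-count convention and the
  MC estimator; only differences within a comparison table are meaningful.
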