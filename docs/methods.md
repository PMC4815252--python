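# Methods

## The data-generating model

Each subject carries a latent normal vector (X_U, X_B, X_C[, X_B′, X_C′])
with unit variances and covariance parameters σ_{U,B} (= σ_{U,B′}), σ_{U,C}
(= σ_{U,C′}) and σ_{B,C} (= σ_{B′,C′}); the two confounder pairs are mutually
independent (all cross-covariances between the pairs are zero — the model
names no others, and the causal graph has no edge between them). Measured
covariates are B = 1{X_B > 0} (Bernoulli(0.5)), C = X_C (standard normal),
and the latent health score is U = Φ(X_U), uniform on (0,1) by the
probability integral transform.

Exposure is Bernoulli with logit P(E=1) = δ₀ + δ_B B + δ_C C
(+ δ_B B′ + δ_C C′ with four confounders). The event time is

    T = −log(U) / (λ · exp(γ E)),     λ = 0.1 by default,

so that marginally T | E is exponential with rate λ·e^{γE}: γ is by
construction the *marginal* (ATE) log hazard ratio, with no conditional
model and hence no non-collapsibility detour. Confounding arises solely
because the same U appears in the copula (correlated with B, C) and in the
event time; replacing it with a fresh uniform would silently remove all
confounding, so the implementation reuses the copula's U verbatim. Only
baseline confounding is generated — no time-varying exposure or confounders.
Censoring is Uniform(0, c), independent of everything; ties T = T_c count
as events (the rule is T ≤ T_c).

Degenerate covariance corners (e.g. four confounders with σ_{U,·} = 0.5,
where the smallest eigenvalue is exactly 0) are legal: sampling goes through
an eigendecomposition with negative eigenvalues in [−1e−10, 0] clamped to
zero and a warning raised; anything below −1e−10 is a configuration error.

## Calibration

Two constants are calibrated rather than specified:

* **δ₀** — the mean of logit⁻¹(δ₀ + δ_B B + δ_C C [...]) over the covariate
  distribution is strictly increasing in δ₀, so δ₀ is found by Brent root
  search on [−30, 10] over a fixed simulated covariate draw, averaged over 5
  independent draws of 200,000 subjects (≈ one million covariate vectors in
  total). With δ_B = δ_C = 0 the answer is logit(p) and is returned
  analytically. A minimiser over repeated draws (as one might write with a
  generic optimiser) targets the identical estimand; the monotone root
  search is simply cheaper and exactly reproducible.
* **c** — event times are simulated from the full generative chain
  (covariates → exposure → T) for 200,000 subjects, because T and E are
  dependent through U and no exact closed form exists. The uniform censoring
  draw is then integrated out analytically, P(censored | T) = min(T/c, 1),
  leaving a smooth strictly decreasing function of c solved by Brent's
  method with geometric bracket expansion. This removes the Monte Carlo
  noise of drawing T_c while estimating exactly the same censoring rate.
  A zero censoring target returns c = ∞ (no censoring).

Both calibrations are bit-for-bit reproducible given the scenario seed, and
round-trip checks (re-simulated prevalence within ±0.002, censoring rate
within ±0.01 on large fresh cohorts) are part of the test suite. No
published values exist for these constants, so round-trip validation is the
only possible check.

## Sampling and estimation

**Event-anchored samples.** The analysis sample for a target y is the
minimal prefix of the cohort, in generation order, containing exactly y
events among exposed subjects. Generation order is exchangeable, so any
deterministic prefix rule yields representative samples; the prefix is the
simplest reproducible choice. If a cohort cannot supply y exposed events the
replicate is recorded as excluded (and the exclusion count reported), never
silently regenerated.

**Propensity model.** Logistic regression of E on exactly the confounders
that generate exposure (correctly specified by construction), fitted by
Newton/IRLS (statsmodels, max 100 iterations, tolerance 1e−8). Separation —
endemic under rare exposure — is declared when the fit raises a perfect-
separation error, diverges, or any |coefficient| exceeds 15; such replicates
count as convergence failures for every downstream method in that cell.
Fitted probabilities are clipped to [1e−9, 1 − 1e−9] before weights and
logits: this prevents infinite weights from numerically saturated fits while
leaving honest extremes (ATE weights above 15 do legitimately occur) intact.
Weights are never truncated or trimmed — truncation would change the
estimand.

**Weights.** ATT: exposed 1, unexposed PS/(1−PS). ATE (always stabilized):
exposed p̄/PS, unexposed (1−p̄)/(1−PS), with p̄ the exposed fraction of the
analysis sample.

**Matching.** Greedy nearest-neighbour 1:1 on the logit PS, without
replacement, caliper 0.2 × SD of the logit PS pooled over both groups.
Exposed subjects are processed in random order under the replicate's seed
(greedy matching is order-dependent and no canonical order exists; random
order avoids sorted-PS pathologies and stays reproducible). Equidistant
controls go to the lowest subject index. Unmatched exposed subjects are
dropped and the matched percentage reported.

**Cox fit.** The marginal model λ(t) = λ₀(t)·exp(γE) has a single binary
covariate, so the (weighted) partial likelihood reduces to two suffix sums
and is maximised by Newton iteration with step halving (tolerance 1e−10 on
the step). Event times are continuous, so ties have probability zero; risk
sets use the Breslow convention, which coincides with Efron's correction in
the absence of ties. Standard errors are the Lin–Wei robust sandwich from
per-subject score residuals — independence working model for weighting,
score contributions summed within pair for matching. The implementation
agrees with lifelines' `CoxPHFitter` (robust and cluster-robust) to its
convergence tolerance and with a brute-force grid search of the partial
likelihood to 1e−6; both cross-checks are in the test suite. Confidence
intervals are Wald on the log-HR scale. Monotone likelihoods (no events in
one exposure group, |γ̂| > 15) and other degeneracies are reported as failed
replicates, not exceptions.

## The theoretical ATT

The generator fixes the marginal ATE at e^γ, but ATT-targeting methods must
be judged against the average effect *in the treated*, which differs under
confounding because hazard ratios are non-collapsible. Per replicate the
oracle simulates covariates, U and realized exposure for 100,000 subjects,
forms both potential uncensored times T(0) = −log(U)/λ and
T(1) = T(0)·e^{−γ} from the shared U, restricts to realized-exposed
subjects, stacks each twice labelled by potential treatment, and fits the
exposure-only Cox model. Averaging is done on the log-HR scale (the
estimation scale; the alternative differs only at the order of the Monte
Carlo variance). γ = 0 short-circuits to ATT = 0 exactly, since the two
potential times coincide subject-by-subject. The stacked design involves no
censoring and no confounding of the label, so the result is invariant to
the censoring parameters (asserted in tests). The two rows of a subject are
treated as independent; only the point estimate is consumed, so the variance
model is irrelevant. Default 20 replicates (log-scale Monte Carlo SE
≈ 0.001–0.003); more are available via the `reps` argument.

## Performance criteria

Per (scenario, method, y) cell over converged replicates: bias
mean(γ̂) − γ_ref; RMSE; variability ratio mean(ŜE)/SD(γ̂) (SD with the
1/(R−1) divisor); 1 − coverage of the 95% Wald interval; mean analyzed n;
mean matched percentage. γ_ref is γ for PSW-ATE and the oracle ATT for
PSW-ATT and matching. Failed replicates are excluded from the four criteria
but their count is always reported — at 1–2% prevalence matching fails
often, and hiding that would misrepresent the method. Each metric carries a
Monte Carlo SE (bias: SD/√R; coverage: binomial; RMSE: delta method), so
runs at reduced replication compare honestly against large-replication
benchmarks: the acceptance tests use 3 combined SEs (this run ⊕ benchmark ⊕
print rounding).

Weight-distribution summaries (mean/variance/min/max by weight type and
exposure group) are statistics of the distribution pooled over all subjects
across replicates: the min/max are extreme-value statistics that only exist
at the pooled level (a per-replicate average of minima would be a different,
larger number).

## Seeding and problem sizes

Every replicate's cohort seed is SeedSequence(root, scenario-key, replicate
index), where the scenario key hashes only the generative parameters; within
a cohort, covariates, exposure and censoring use independent spawned
streams, and matching order gets a stream keyed additionally by y. Serial
and parallel execution therefore agree bit-for-bit, and extending a run
never changes existing replicates. Within one replicate the same cohort
serves all y values and methods (nested prefixes).

Default problem sizes are chosen as desk-scale analogues of the published
study conditions: cohorts of N = 10,000 as specified; the reference-
configuration evaluation at 1000 replications (the published tables used
5000); the ATT oracle at 20 × 100,000 (published: 1000 × 100,000); the
full scenario grid (hundreds of cells) is expressible and any single cell
runs on demand, but grid-wide reproduction is intentionally out of scope.

## What the generator does and does not emulate

It reproduces the structural features that matter for the question — rare
exposure, confounding of tunable strength routed through an unmeasured
health score, exponential baseline hazards, uninformative uniform censoring,
correctly specifiable propensity models. Real cohorts add features it lacks:
non-proportional or time-varying effects, covariate-dependent censoring,
measurement error, many weak confounders, and misspecified propensity
models. Passing tests therefore certify the estimators' behaviour under the
stated design, not under arbitrary observational data.

## Known limitations

* Estimators cover exposure-only marginal Cox models; no PS stratification,
  covariate adjustment on the PS, disease risk scores, 1:k or with-
  replacement matching.
* The 4-confounder strong-confounding corner sits on a singular covariance;
  it samples correctly but is flagged, and covariances outside the PSD cone
  fail loudly.
* The Cox solver handles a single binary covariate only — by design; use a
  general package for anything richer.
* Replicate loops are serial; the seeding scheme is parallel-safe, but no
  executor is bundled.
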