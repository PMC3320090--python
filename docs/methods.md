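# Methods

## Model

`mcistates` models panel-observed cognitive trajectories as a discrete-time
multistate Markov chain over six states: three transient (normal cognition,
test-based amnestic MCI `AMCI_TB`, test-based mixed MCI `MMCI_TB`), one
quasi-absorbing (clinical-consensus MCI `MCI_CC`, which may progress to
dementia or death but never reverts to a transient state), and two absorbing
(`DEMENTIA`, `DEATH`).  The state at an assessment depends only on the state at
the prior assessment and on covariates (first-order Markov); transitions among
transient states *between* scheduled assessments are ignored, and dementia,
clinical MCI, and death are dated to the assessment slot at which they are
observed — interval-censored timing is deliberately out of scope, as is any
continuous-time intensity formulation.

Conditional on a subject-level random effect `u ~ N(0, σ_u²)`, the transition
from a prior state with base state *b* (normal cognition before `MCI_CC`
entry, `MCI_CC` afterwards) follows a multinomial logit:

    log P(k | x, u) / P(b | x, u) = α_k^{(b)} + x' β_k^{(b)} + u.

Two parameter blocks exist.  The normal-base block has five competing outcomes
(`AMCI_TB`, `MMCI_TB`, `MCI_CC`, `DEMENTIA`, `DEATH`) and nine design terms
(intercept; age at the prior assessment minus 78 years; female; family history
of dementia; any APOE-4 allele; ≤12 years of education; baseline hypertension;
indicators for an `AMCI_TB` or `MMCI_TB` prior state).  The clinical-MCI-base
block has two competing outcomes (`DEMENTIA`, `DEATH`) and drops the
prior-state indicators.  Additivity — no interaction between covariates and the
prior state — means a single normal-base block with prior-state indicator
covariates subsumes separate per-prior-state regressions, and a joint
likelihood over both blocks is what makes a *shared* random effect meaningful;
the package therefore fits one joint likelihood rather than a series of
separate models.  Death is a competing outcome category in both blocks, not a
censoring event.

The random effect is a single scalar entering every non-reference logit of
both blocks with loading 1.  This is the minimal structure consistent with a
"shared" effect and is identifiable at a few hundred subjects; richer
per-outcome loadings would demand far more events than typical cohorts carry.
A single σ_u is estimated across both base states.

The reported "relative risks" are exponentiated coefficients `exp(β)` with
Wald intervals `exp(β ± 1.959964·SE)` — odds-ratio-type quantities from a
logistic model, labelled RR to mirror conventional reporting in this
literature; they approximate risk ratios only while per-interval transition
probabilities are small.

## State classification

A *poor* score is at least `threshold` (default 1.5, inclusive, configurable)
residual SDs on the impaired side of an age-adjusted normative mean, with
per-test direction flags so error-count and completion-time scores (more
errors, more seconds = worse) flip the inequality.  Norms are fitted once on
the baseline visits of the normal cohort and frozen.  The age adjustment is a
per-test ordinary least-squares regression of score on age whose residual SD
serves as the normative SD — the simplest mechanism consistent with an
"age-adjusted mean"; banded or nonlinear adjustments can be substituted by
supplying a custom norms table.  A test with zero residual variance cannot
define a 1.5-SD cut-off and is rejected with an error naming the test; if all
contributing ages coincide, the fit degenerates gracefully to the sample mean
and SD.

Classification precedence is death > dementia > clinical MCI > test-based
states; among test-based states, any poor language/executive score yields
`MMCI_TB` regardless of memory performance, otherwise any poor memory score
yields `AMCI_TB`, otherwise `NORMAL`.  Missing scores never trigger "poor" —
absence of evidence must not create impairment — and classification proceeds on
whatever scores are available; a visit with no score and no clinical flag is an
error rather than silently `NORMAL`, which would bias transition counts toward
stability.  The default battery covers episodic-memory measures (logical
memory, visual retention correct/errors, word-list learning, delayed recall,
savings, and forgetting scores) and language/executive measures (phonemic and
category fluency, short-form naming, trail-making A/B seconds); arbitrary
batteries are registered through configuration.

## Trajectory cleaning

Apparent reversions from `MCI_CC` to a transient state are resolved by two
deterministic patterns replacing human chart review, with a full audit trail
and a manual per-visit override hook for record-level adjudication:

* **Pattern A** — a later `MCI_CC` or dementia follows the reversion: every
  transient visit after the first `MCI_CC` is reclassified as `MCI_CC`.  When
  the intervening visits include test-based MCI states (not only normals) they
  are overwritten too; the audit records each such visit.
* **Pattern B** — the `MCI_CC` visits are followed only by transient states to
  the end of follow-up (terminal death allowed): the unsupported diagnoses are
  demoted to the visit's *test-based* classification when scores are available
  (such subjects may legitimately remain `AMCI_TB`/`MMCI_TB`), else to
  `NORMAL`.  `B_initial` labels the sub-case where the demoted diagnosis sits
  at the first visit, `B_mid` the isolated-diagnosis case.

Cleaning is idempotent, never alters dementia or death visits, visit counts or
times, and its output always satisfies the quasi-absorbing invariant, which a
separate non-mutating validator counts violations of.

## Estimation

The marginal likelihood integrates `u` per subject by Gauss–Hermite
quadrature.  The default rule is **adaptive with one node**: nodes are
recentred and rescaled at the per-subject posterior mode of `u` (found by a
vectorised damped Newton iteration on a strictly concave objective), and with
a single node the rule coincides with the Laplace approximation.  Non-adaptive
rules centred at zero and adaptive rules with any node count are available;
with σ_u = 0 every rule collapses exactly to the fixed-effects likelihood.  On
simulated cohorts at σ_u = 0.5 the one-node rule differs from a 20-node
adaptive rule by well under 0.5% of the log-likelihood (about 0.03% at the
default scenario), an error the test suite quantifies.

Maximisation is quasi-Newton (BFGS), warm-started at the fixed-effects MLE,
with σ_u estimated as log σ_u to enforce positivity (start value 0.3) and
optional seeded multi-start jitter as a guard against local optima.  Exact
analytic gradients are supplied for the fixed-effects likelihood, for the
one-node adaptive (Laplace) objective — differentiating through the
per-subject mode via the implicit-function theorem — and for non-adaptive
rules; adaptive rules with more than one node fall back on finite differences.
The analytic scores are verified against central finite differences in the
test suite; they make a full random-effects fit at 554 subjects take a few
seconds, so the 50-replicate recovery study runs in minutes on one CPU.
Convergence is declared at gradient norm 1e-6 (configurable) within 500
iterations; non-convergence flags the result rather than silently returning
it, and any |β| above 15 raises a separation warning.  Standard errors come
from the inverse observed information (central-difference Hessian of the
analytic score), with the σ_u standard error mapped from the log scale by the
delta method.  Pairs with missing baseline covariates are excluded complete
case with a logged count — the simplest auditable policy.

Degenerate inputs: an outcome category with no observed transition raises an
error naming the category (its coefficients are inestimable); a dataset with
no clinical-MCI-base pairs at all leaves that block at its (zero) starting
values rather than erroring, since the normal-base block remains well posed.

## Synthetic cohorts

The generator emulates a volunteer ageing cohort: age at entry 72.7 ± 7.8
years, 64.3% female, 41.3% family history, 30.0% APOE-4, 11.9% with ≤12 years
of education, 36.6% baseline hypertension; about 10.8 ± 4.5 assessments per
subject (minimum 2) at truncated-normal intervals of 1.1 ± 0.4 years (minimum
0.5, so the realised mean interval is ≈1.16 y); each subject draws `u`, starts
in normal cognition, and steps through the chain using the model's own
transition probabilities until absorption or end of follow-up.  Default effect
sizes are literature-informed relative risks for these transitions; default
σ_u is 0.5.

Baseline intercepts are not knowable from published summaries, so they are
**calibrated**: `calibrate_intercepts` simulates a large cohort, compares
empirical outcome-versus-base log-odds per prior row with target row
percentages, shifts each intercept by the average discrepancy, and iterates to
a (noise-free, fixed-seed) fixed point.  Because the three transient prior
rows share the normal-base intercepts while their differences are pinned by
the fixed prior-state coefficients, the targets over-determine the intercepts;
averaging the three rows' discrepancies with equal weight yields a
least-squares compromise in log-odds.  The frozen defaults were produced at
20,000 subjects per iteration (seed 20260927) and leave every structural cell
of the simulated one-step matrix within about 1.5 percentage points of its
target; the regression test checks ±2 points at 20,000 subjects, where
binomial noise in the sparse clinical-MCI row (SE above 1 point per cell at
5,000 subjects) no longer masks the systematic agreement being verified.
These calibrated intercepts are approximations, not published quantities.

Raw-score emission lets the classification stage round-trip: scores are drawn
in z-space with poor scores planted at least 0.1 SD beyond the cut-off in the
state's defining domain and non-poor scores at least 0.1 SD inside it, so
classification against the emission norms recovers the simulated state
(≥99% agreement; memory scores at mixed-MCI visits are left unconstrained,
mirroring the precedence rule).  Dementia and death visits carry flags and no
scores.  The generator does **not** emulate realistic between-test correlation
structure, practice effects, missing-visit processes, or time-varying
covariates — so passing tests certify the statistical machinery, not the
behaviour of any particular real cohort.

All randomness flows from one mandatory seed through four named
`SeedSequence` children (covariates, visit process, state process, raw
scores); identical seeds give byte-identical output.

## Verification scales and scenarios

The published regression tables of the motivating study cannot be reproduced —
the underlying cohort is not deposited — so the suite substitutes
property-based checks, run at sizes chosen to finish in minutes on one CPU:

* **σ=0 oracle** — the fixed-effects fit must match an independent
  multinomial-logit MLE (statsmodels `MNLogit`) to 1e-4 on both blocks, on a
  200-subject cohort simulated from a deliberately well-conditioned scenario
  (modest effects, balanced covariates, elevated clinical-MCI occupancy): under
  the study's own sparse event rates the clinical-MCI block's MLE is not
  interior at that size, and no finite optimum exists to compare.
* **Quadrature** — 20-node Gauss–Hermite agrees with 10,001-node trapezoid
  integration to 1e-6 on a 3-subject toy; the node sequence is Cauchy with
  increments below 1e-6 by 30 nodes.
* **Parameter recovery** — 50 replicates at 554 subjects with σ_u = 0.5 and
  true coefficients equal to the default log relative risks: the two large
  monitored effects (mixed-MCI indicator on clinical MCI, RR 4.80; age on
  clinical MCI, RR 1.12) show |bias| below twice the Monte-Carlo SE and Wald
  95% coverage within [0.85, 1.0].

## Numerical conventions

Row percentages are reported to one decimal with half-up rounding.  Quadrature
nodes/weights come from `scipy.special.roots_hermite`; posterior modes iterate
Newton with steps clipped at ±4 to tolerance 1e-11.  Wald intervals use
z = 1.959964.  Probabilities are computed via log-sum-exp throughout, so
−∞ logits (structurally excluded outcomes, degenerate scenarios) are exact
zeros rather than numerical noise.

## Limitations

Discrete-time only: subjects assessed at strongly irregular intervals violate
the equal-step Markov interpretation (interval length is carried on each pair
but not used by the default model).  The single shared random effect cannot
represent outcome-specific frailty.  Hypertension enters as a baseline
indicator; time-varying risk factors are not modelled.  The Laplace default
slightly biases σ_u at small cluster sizes — users needing unbiased variance
components should raise the adaptive node count at the cost of
finite-difference gradients.
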