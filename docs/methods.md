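# Methods

## The model

`iwspkpd` implements a mechanism-based pharmacokinetic–pharmacodynamic
(PKPD) model of iatrogenic withdrawal syndrome (IWS) in children who
receive prolonged infusions of opioids and sedatives in intensive care.
The model has four layers:

**1. Pharmacokinetics.** Each drug's dosing history (boluses, zero-order
infusions, extravascular doses with first-order absorption and
bioavailability `F`) drives a linear 1–3-compartment disposition model.
Clearance-like constants scale allometrically with body weight,
`CL ∝ (WT/ref)^0.75`, volumes linearly, `V ∝ (WT/ref)^1.0`, relative to a
70-kg reference. The system `x' = Ax + u` is solved *piecewise-exactly*:
`A` is diagonalized once and every constant-rate segment is propagated in
closed modal form — the matrix exponential of the linear system written in
its eigenbasis. There is no step-size or tolerance tuning; profiles are
bit-stable and linear in dose (superposition holds exactly). A dense
`scipy.linalg.expm` fallback covers near-defective eigensystems and the
mass-balance diagnostic (`simulate_state`).

**2. Dependence compartment.** For each drug a hypothetical concentration
`C_dep` tracks plasma with first-order kinetics,

    dC_dep/dt = k_dep (C_plasma − C_dep),

representing the exposure level the patient has adapted to. Because the
modal plasma representation is a piecewise sum of exponentials, `C_dep`
also has a closed form on every segment (modes with rate ≈ −k_dep
degenerate to a `t·e^{−k_dep t}` term, handled explicitly). The
*concentration shortage* `max(0, C_dep − C_plasma)` drives severity
linearly with a per-drug `slope`; a drug whose plasma level still covers
its dependence level contributes exactly zero. Per-drug contributions add
to a lognormal individual baseline:

    λ_i(t) = baseline · e^{η_i} + Σ_j slope_j · shortage_j(t),   η_i ~ N(0, ω²).

The dependence compartment starts empty at admission (patients enter
naïve; an explicit initial level can be supplied for pre-exposed
patients). The shortage→severity link is linear; a saturating link could
be substituted at the `drug_effect` seam but none is shipped.

**3. Observation model.** The integer withdrawal score Y ∈ {0..10} follows
a *truncated generalized Poisson* distribution,

    p(y) ∝ λ (λ + δy)^{y−1} e^{−λ−δy} / y!,   y = 0..10,

renormalized over the 11 supported scores (renormalization, not
tail-lumping, is the truncation convention). δ ∈ [0,1) inflates the
variance; δ = 0 recovers the truncated Poisson. Serial correlation between
consecutive scores is a Markov probability inflation: point mass π0|0 (or
π0|x) on repeating the previous score of zero (or nonzero), and a shared
π± on scores one or two points away; targets outside 0..10 are dropped,
shrinking the retained mass Π, and the base distribution is scaled by
1 − Π. The first observation of a patient has no predecessor and is
uninflated. How other implementations of score-inflation models rescale
boundary-truncated inflation varies; the drop-then-mix convention here is
the documented choice and is applied identically in the generator and the
likelihood, so estimation is internally consistent.

**4. Risk read-out.** Scores above 3 indicate IWS requiring intervention;
`P(Y > 3)` (strict) is the clinical risk reported by the weaning
simulations. Risk curves describe a *typical* patient: η = 0 and the
uninflated (memoryless) score distribution. Marginalizing over η or over
Markov histories would be straightforward but is deliberately not the
default, matching the typical-patient convention of the simulation
figures.

## Reference parameters

The shipped reference vector (`published_params()` /
`data/iws_reference.yaml`) is the final estimate from a pediatric ICU
cohort: baseline 0.564 (IIV 114 CV%), δ 0.428, π0|0 0.401, π0|x 0.216,
π±1 = π±2 0.0698, and three drugs with quantifiable dynamics — fentanyl
k_dep 0.242 h⁻¹ (half-time ≈ 2.9 h), slope 5.93 ml/ng; morphine
0.00848 h⁻¹ (≈ 82 h), 0.0687 ml/ng; ketamine 0.0180 h⁻¹ (≈ 39 h),
1.59 ml/mcg. Concentration units are per-drug declarations (ng/mL for
morphine and fentanyl, mcg/mL for ketamine) because the slopes are in the
matching reciprocal units. The IIV convention is the exact lognormal one,
CV% = 100·√(exp(ω²) − 1), so 114% ↔ ω ≈ 0.9126.

The pediatric PK parameter sets shipped in `data/pk_defaults.yaml` are
*illustrative* stand-ins in the range of published pediatric population
models, not fitted quantities; every analysis that depends on them states
them explicitly, and figure-shape tests assert orderings and ratios of
risks rather than absolute curves.

## Estimation

The marginal likelihood integrates each patient's conditional score
likelihood over η. The integral is approximated by a Laplace expansion
around the per-patient mode, found by a vectorized safeguarded Newton
search with *analytic* first and second derivatives of the log-probability
with respect to λ (propagated through the generalized-Poisson mass, the
renormalization and the inflation mixture), convergence |Δη| < 1e−8 in at
most 50 iterations with step-halving and a bracketed-grid fallback.
Adaptive Gauss–Hermite quadrature (default 15 nodes, centered and scaled
at the same mode) serves as the independent oracle; on test cohorts the
two agree to better than 0.1% relative. ω = 0 degenerates exactly to the
conditional likelihood at η = 0.

Free parameters are optimized on an unconstrained scale: logs for
baseline, ω, k_dep and slopes; a logistic for δ; and a nested logistic for
the inflation probabilities — π± = expit(·)/4, π0|0 = expit(·)(1 − 2π±),
π0|x = expit(·)(1 − 4π±) — which guarantees Π < 1 for every possible
previous score (π± is thereby bounded by 0.25, far above any plausible
value). L-BFGS-B with finite-difference gradients does the outer
maximization; plasma profiles are θ-independent and are precomputed once,
and shortage profiles are cached per (drug, k_dep) so gradient
perturbations of the non-PK parameters cost almost nothing. Multi-start:
the first start uses the supplied initial vector, further starts perturb
the transformed vector by N(0, 0.35²) and run under a reduced function
budget; the best start is polished at full budget. Ties break by lowest
OFV (−2 log L), then smallest parameter norm. AIC = OFV + 2·k.

Standard errors use a central-difference Hessian of the negative marginal
log-likelihood on the transformed scale (step 1e−4); its inverse is the
covariance, mapped to the natural scale by a numerical delta method. CIs
are estimate ± 1.96 SE on the transformed scale, back-transformed; for the
coupled inflation parameters the other coordinates are held at their
estimates during back-transformation. A non-positive-definite Hessian
flags the result and suppresses CIs. Model comparison uses ΔOFV ~ χ²
for nested fits and ΔAIC otherwise; the package reports raw p-values and
leaves inclusion thresholds to the analyst.

Diagnostics compute, at the empirical-Bayes (post hoc) η of each patient,
the full conditional score distribution of every observation (conditioned
on the observed previous score), the expected score Σ j·p(j), residuals
observed − expected, and mirror frequencies — observed vs mean-predicted
counts per score and per transition (current − previous).

## Synthetic cohorts

`synthetic.generate_cohort` draws fully reproducible cohorts from the
generating law itself: lognormal weights (median 11 kg, log-SD 0.89,
clipped to 2.4–70 kg), per-drug randomized treatment templates (constant
infusion at a lognormal per-kg rate, uniform treatment duration, stepwise
10%-per-24-h weaning with a configurable probability of an abrupt stop),
observations every 8 h by default, η ~ N(0, ω²), and scores sampled
sequentially through PK → dependence → λ(t) → Markov-inflated distribution
conditioned on the previously *sampled* score. Seeding uses
`numpy.random.SeedSequence.spawn`, so cohorts are identical across runs
and platforms.

Two template families are shipped. `default_templates()` emulates the
reference cohort descriptively: drug prevalences 93% (morphine), 94%
(fentanyl), 60% (ketamine), median rates 8 mcg/kg/h, 1.0 mcg/kg/h and
0.5 mg/kg/h with geometric SD 2, treatments of 5–21 days. Under the
reference parameters even a drug-free patient population has an
η-averaged P(Y > 3) of ≈ 13%, so realized cohorts carry roughly 15–20% of
scores above 3 — of the same order as the ~11% a comparable clinical
cohort reports. `recovery_template(drug)` is the estimation-study design:
every patient treated, 14–28-day treatments at the simulation-scenario
rates, 20% abrupt stops, follow-up long enough for the dependence
compartment to resolve (4–10 days depending on k_dep).

What passing tests on these cohorts show — and do not show: they verify
that the estimator recovers the generating law under the model's own
assumptions at realistic size and sampling density. They cannot speak to
score-responsive dose titration (real bedside dosing reacts to the scores;
the templates are fixed), informative observation times, rater effects, or
co-medication outside the templated drugs.

## Numerical choices and problem sizes

* Time unit hours everywhere; weaning risk curves use a 0.5-h grid
  (resolves fentanyl's ≈ 2.9-h dependence half-time).
* A weaning schedule's first reduction occurs at the end of the treatment
  phase, so fraction-f / interval-Δ weaning lasts (⌈1/f⌉ − 1)·Δ hours
  (10%/24 h ⇒ a 9-day wean; 20%/48 h ⇒ 8 days).
* Eigendecompositions are accepted when the eigenvalues are real and the
  eigenvector condition number is below 1e10; otherwise the dense
  matrix-exponential path is used.
* λ is floored at 1e−12 and observation probabilities at 1e−300 inside the
  likelihood; infeasible parameter proposals return a large penalty.
* The parameter-recovery experiments in `scripts/acceptance.py` use 5
  replicate cohorts of 100 patients per drug with 3 multi-starts
  (≈ 5 minutes on one CPU); the scaled-down recovery test in the suite
  uses 3 replicates of 50 patients with identical acceptance bands
  (±40% for k_dep and slope, ±20% for baseline, δ, the π's and CV%).

## Known limitations

* The dependence→severity link is linear only; tolerance compartments and
  cross-drug interactions (one drug suppressing another's withdrawal) are
  out of scope.
* Only the baseline carries inter-individual variability; k_dep and slope
  are population constants.
* Ketamine's k_dep is the least identifiable quantity under the shipped
  study design (slow dynamics sampled every 8 h); replicate medians
  scatter within, but use most of, the ±40% recovery band.
* The shipped PK parameter files are illustrative; analyses of real data
  should substitute drug- and population-appropriate PK models.
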