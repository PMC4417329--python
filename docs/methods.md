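# Methods

## Measurement model

Polypharmacy is measured as the number of *distinct* drug classes
dispensed to a patient in the 84 days ending on (and including) the
index date. The convention is fixed as follows: a record dated `d` is in
the window iff `index − 83 days ≤ d ≤ index`, so the window spans
exactly 84 calendar days. Whether the index day itself counts is a
convention with no right answer; we include it ("on or before" the
index date) and apply the same rule to every period, which is what
matters for between-period comparisons.

Classes are the numbered subsections of a BNF-style hierarchy, expanded
so that distinct, commonly co-prescribed agents sit in distinct codes.
Combination products count once per constituent class. Classes flagged
`excluded` (devices that deliver no drug, dressings, stoma and catheter
products, vaccines) stay in the ontology — so reports can audit what was
excluded — but never contribute to counts. Repeat dispensings of one
class count once; counts are therefore invariant to record duplication
and ordering (property-tested).

A potentially serious DDI is defined as *co-dispensing within the same
window* of both members of a listed class pair. No overlap of supply is
required: a patient may have stopped one drug before starting the other,
so the screen overestimates simultaneous exposure. Conversely it ignores
over-the-counter drugs, so it underestimates true exposure. Both biases
are constant across periods by construction (one knowledge base, one
window rule), which is why the two-period *comparison* is meaningful
even though the level in either period is approximate. One consequence
of the class-level definition is accepted deliberately: if a single
combination product supplies both interacting constituents, the pair
counts as present, since both classes were dispensed.

## Standardised comparison

Stratum grid: sex × 10-year age band (20–29 … 70–79, 80+), 14 strata.
The directly standardised prevalence of the later period uses the
earlier period's stratum sizes as weights; its variance is
`Σ w_s² p_s(1−p_s)/n_s`. The standardised relative risk divides the
later period's standardised percentage by the earlier period's crude
percentage; its 95% CI is computed on the log scale with
`var(log sRR) = var_std/p_std² + var_crude/p_crude²`, treating the two
cross-sections as independent. Prevalence differences use Wald
intervals. These are standard large-sample choices; at the denominators
the pipeline targets (10⁴–10⁵ per period) the normal approximations are
excellent, and a Monte-Carlo test confirms ≈95% coverage of the sRR
interval over 500 replicated stratified datasets. Exact small-count
intervals are out of scope.

Degenerate inputs: an empty study stratum contributes rate 0 with a
logged warning (its reference weight is kept); zero events in the early
period make the sRR undefined and the report prints no ratio for that
row; proportions of exactly 0 or 1 in both groups give a zero-width
Wald interval with a logged warning.

## Random-intercept logistic regression

The model is `logit P(y_ij = 1) = x_ijᵀβ + u_j`, `u_j ~ N(0, σ_u²)`,
patients `i` nested in practices `j`. The marginal likelihood integrates
each practice's Bernoulli likelihood over its intercept; the integral is
approximated by adaptive Gauss–Hermite quadrature: per practice, a
damped Newton iteration finds the posterior mode of `u_j`, the
integrand is rescaled by the curvature there, and a 15-node Hermite rule
(configurable; 51 nodes changes the log-likelihood by < 1e-9 in tests)
is applied on the transformed axis with log-sum-exp accumulation.
`σ_u < 1e-8` switches to the exact ordinary-logistic branch, so the
model collapses continuously to a GLM at the boundary.

Optimisation is L-BFGS-B over `(β, σ_u)` with `σ_u ≥ 0`, initialised
from an internal Newton/IRLS logistic fit (kept independent of the
statsmodels oracle used in tests). Gradients are numerical; the
**convergence criterion** reported in `converged_` is that the
central-difference gradient of the *mean* (per-observation) negative
log-likelihood has max-norm < `tol` (default 1e-5) — at the σ = 0
boundary the σ component only counts if it points into the feasible
region. Standard errors come from inverting the central-difference
Hessian of the total negative log-likelihood at the optimum (the σ row
is skipped at the boundary, where the Wald SE for σ is meaningless).
Fitted σ below 1e-4 is reported as exactly 0. A `sigma_fixed` option
constrains σ (useful for likelihood-ratio checks and for the collapse
tests). Quasi-separation — a binary design column whose active rows
have constant outcome — is detected before fitting; the fit proceeds
but the affected coefficient is reported as ±∞ with an infinite SE and
a warning, never silently.

The empty model's intraclass correlation is reported on the latent
threshold scale, `ICC = σ_u²/(σ_u² + π²/3)`, the conventional choice
for logistic multilevel models (`π²/3` is the standard logistic
residual variance). Odds ratios are `exp(β)` with Wald intervals;
reference levels (age 20–29, male, SIMD quintile 1, primary city, own
home, drug band 2–4) are fixed by the table layout. The DDI models are
restricted to patients dispensed ≥ 2 classes — patients below that
cannot have the outcome, and including them would only manufacture
separation.

Two identifiability facts surfaced by testing are worth recording.
First, data simulated *without* practice variation still yield small
positive σ̂ in a free fit (the MLE of a variance component overshoots
zero with noise); exact agreement with a GLM is therefore asserted for
the σ-constrained fit, while the free fit is only required to land near
the boundary. Second, with one observation per cluster σ_u is weakly
identified: the profile likelihood is a near-flat ridge, and the fitted
σ̂ may sit anywhere on it without materially changing the likelihood.
Such designs should be modelled as ordinary logistic regressions.

## Synthetic-data generator

The generator produces, per period, a practice-clustered adult
population and dispensing records in the ingest formats. For patient
`i` in practice `j`, class `c` is dispensed with probability

`logit⁻¹( α_c + period + age(band_i) + 0.10·(SIMD_i − 3) + 0.18·[female]
 + 0.8·[care home] + f_i + u_j )`,

with patient frailty `f_i ~ N(0, 1.3²)` shared across classes and
practice effect `u_j ~ N(0, 0.22²)`. Designated interacting pairs get a
logit boost to the second member when the first is present (sequential
sampling in canonical class order). Dispensed classes emit 1–3 records
at uniform dates inside the window. The earlier period subtracts 0.5
from every baseline and uses a younger age structure with no care-home
flag (mirroring the data situation where residence was recorded only at
the later time point).

The defaults were calibrated once against the published marginal
structure of a two-period regional dispensing study of ~310,000 adults
(the dataset this pipeline's table layout follows) and then frozen:
class baselines by chapter plus per-class adjustments, an age gradient
rising ~2.3 logits from the 20s to the 80+ band, and the SDs above.
Under these defaults the later period gives roughly 40/44/11/3/2% of
adults in the 0/1–4/5–9/10–14/15+ bands, ~11% with ≥1 DDI (≈29% of
those on ≥2 classes), an empty-model ICC for the ≥10-classes outcome of
~0.01–0.03, and DDI prevalence rising steeply with drug count — the
qualitative structure the analysis depends on. A single shared Gaussian
frailty cannot reproduce every published band fraction simultaneously
(the published tables have more mass at 5–9 and less at 15+ than the
lognormal-like count tail this mechanism implies), so passing tests
demonstrate that the *pipeline measures simulated populations
correctly*, not that the simulator is a substitute for real prescribing
data. Other knowingly absent features: over-the-counter exposure,
within-window start/stop dynamics, dose and duration, realistic product
vocabularies, and practice-level covariates. Conditioning on ≥2 classes
also drains most practice-level variation from the DDI outcome, so its
empty-model ICC in simulations is often near 0 — smaller than published
values for comparable real outcomes.

`expected_summary` provides the independent oracle for end-to-end
tests: with no random effects and ≤ 12 classes it enumerates all class
subsets exactly (reducing to a Poisson-binomial when no co-occurrence
boosts apply); otherwise it Monte-Carlo samples covariate cells and
random effects without going through records, dates, or files.

## Problem sizes

The test suite and acceptance script size their simulations to run
comfortably on one CPU: the default two-period pipeline uses 60
practices averaging 250 patients (~15,000 adults per period); the
end-to-end oracle comparison uses 200 practices (~50,000 adults)
against a 100,000-draw Monte-Carlo oracle; GLMM parameter recovery uses
the 100-cluster × 200-patient reference design; interval-coverage
checks use 500 replicates. The whole suite completes in well under two
minutes; the acceptance script in under one.
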