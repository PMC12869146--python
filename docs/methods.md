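# Methods

## The model

`telemap` analyses small-area telehealth adoption with the
Besag–York–Mollié (BYM) convolution model. For area *i* with population
*E<sub>i</sub>* and outcome count *Y<sub>i</sub>* (by default the number of
unique patients with at least one telehealth visit in the study year):

```
Y_i ~ Poisson(E_i · exp(η_i)),    η_i = β0 + x_i'β + u_i + v_i
```

* `x_i` — standardized area covariates (per-1-SD coefficients), so
  `exp(β_j)` is a relative risk (RR) per standard deviation.
* `u` — spatially structured random effect with an intrinsic conditional
  autoregressive (ICAR) prior on the queen-contiguity graph:
  `p(u | τ_u) ∝ τ_u^{(n−c)/2} exp(−τ_u/2 · Σ_{i~j} (u_i − u_j)²)`, with
  *n* areas and *c* graph components. The prior is improper; we impose the
  standard sum-to-zero constraint within every connected component.
* `v` — unstructured iid `N(0, 1/τ_v)` effect capturing overdispersion.
* Priors: independent `N(0, 1/β_prec)` on `β0, β` with `β_prec = 1e-4`
  (vague on standardized covariates); `Gamma(1, 0.0005)` on each precision,
  a common convolution-model default. All are configurable.

We use the classic additive `u + v` parameterisation (not the rescaled
BYM2): it is the form the contiguity-covariance literature this package
follows states directly, and the conjugate precision updates stay exact.

Models are fitted separately per study year; the candidate ladder used in
model comparison is: Model 1 — primary covariate + unstructured effect;
Model 2 — primary covariate + both effects; Model 3 — all covariates +
both effects.

## Inference: Metropolis-within-Gibbs

Posteriors are computed by MCMC rather than an approximate integration
scheme: a from-scratch sampler is fully auditable and can be validated
against a brute-force oracle (below). One sweep consists of:

1. **(β0, β) block** — normal random-walk Metropolis.
2. **Interweaving (ASIS-style) translation moves** — for each coefficient,
   propose `β_j → β_j + δ` together with `v → v − δ·x_j` (and, when the
   structured effect is present, the analogous move against `u` using the
   component-centred covariate). These moves leave `η` — and hence the
   likelihood — invariant, so only the priors vote. They are essential:
   with informative per-area counts, the conditional posterior of `β`
   given `(u, v)` is far narrower than its marginal, and a plain random
   walk explores the marginal at an effective sample size of single digits
   per 20,000 iterations. With the interweaving moves the same chain
   reaches ESS in the hundreds, and its credible intervals match a 6×
   longer gold-standard chain.
3. **u sites** — single-site random-walk updates, vectorised over colour
   classes of the contiguity graph (greedy colouring; sites in one class
   share no edge, hence are conditionally independent under the ICAR
   prior, so their accept/reject steps can run simultaneously).
4. **u scale move** — a multiplicative proposal `u → a·u` with Jacobian
   `(n−c)·log a`. Single-site moves change the field's overall roughness
   only diffusively, which otherwise makes `τ_u` take >10k iterations to
   equilibrate from a cold start.
5. **v sites** — vectorised single-site updates (conditionally independent
   given everything else).
6. **Precisions** — conjugate Gibbs draws:
   `τ_u ~ Gamma(a + (n−c)/2, b + Σ_{i~j}(u_i−u_j)²/2)`,
   `τ_v ~ Gamma(a + n/2, b + Σ v_i²/2)`.
7. **Recentring** — `u` is recentred to sum to zero per component; the
   overall mean shift is absorbed into `β0`.

Proposal scales adapt during burn-in (Robbins–Monro on the log scale)
toward 0.44 acceptance for scalar updates and 0.234 for the multivariate
block, then freeze, preserving detailed balance for all retained draws.
Fixed seeds give bit-identical output. Areas with no neighbours keep
`u_i = 0` (their singleton component forces it under the constraint) and
rely on the unstructured effect — islands are retained, not dropped,
though a caller can exclude them upstream.

Split-chain R-hat and bulk ESS are available via
`bym_model.convergence_diagnostics` for logging; thresholds are advisory,
not hard failures.

## The grid-integration oracle

`grid_posterior_oracle` integrates the unnormalised posterior on a regular
grid (trapezoid rule) over at most 4 free parameters — `β0`, coefficients,
the sum-to-zero basis coordinates of `u`, and a precision — and reports
means/variances. A boundary-density check warns if more than 1e-6 of the
posterior mass sits in a grid's outermost slabs. Oracle toys use an
informative `Gamma(2, 1)` precision prior (in both the oracle and the MCMC
run it validates) so the precision posterior has finite-grid support; the
pipeline default stays the vague `Gamma(1, 0.0005)`. On a 3-area path
graph the sampler reproduces the oracle's `β0` and `u` means to ~1e-3,
well inside the 0.05 validation tolerance.

## Posterior products

* **RR tables** — point estimate `exp(mean β_j)`; 95% interval as `exp` of
  the 2.5%/97.5% coefficient quantiles. Because quantiles commute with
  monotone maps, these equal the quantiles of the exponentiated draws;
  note `exp(mean β)` is not the mean of `exp(β)` (we follow the
  exponentiated-mean convention).
* **DIC** — `DIC = D̄ + p_D`, `p_D = D̄ − D(θ̄)`, with the *conditional*
  focus: the deviance is evaluated given the random effects, and `D(θ̄)`
  plugs in posterior means of `β0, β, u, v`. Negative `p_D` warns rather
  than fails.
* **Exceedance maps** — for threshold fraction *f* (0.1 pre-pandemic, 0.5
  for pandemic years by default), the probability that an area's fitted
  per-person rate `exp(η_i)` falls below `f ×` reference. The reference is
  the population-weighted mean fitted rate *within the same draw*, keeping
  the comparison coherent draw by draw; a fixed-value reference is also
  available. Probabilities are exact draw counts and are monotone in *f*
  by construction.

## Descriptive layer

* Cohort filters run in a fixed order — missing fields, study-year range,
  area validity — with a conservation-checked ledger (`in − dropped = out`
  at every stage, stages compose).
* Use rates divide unique telehealth patients per area-year by area
  population. A patient appearing in two areas in one year counts in both
  numerators: area-level rates are the estimand, so no cross-area
  deduplication is attempted.
* Rurality shares divide telehealth visits per class by total telehealth
  visits that year (visits, not patients), reported to one decimal with
  half-up rounding to match published-table conventions. A year with zero
  telehealth visits yields no share (0/0 is flagged, not reported as 0).
  `shares_from_counts` accepts an explicit denominator so published tables
  can be reproduced against their printed totals.
* The monotone-trend test on annual proportions is Cochran–Armitage with
  equally spaced year scores and a two-sided normal p-value — the standard
  test for this design; a permutation variant (multivariate hypergeometric
  reallocation under fixed margins) is provided for very small counts.
* Covariate screening: VIF `= 1/(1−R²)` with iterative worst-first removal
  above 5.0, recomputing after each removal. Ties (always present for an
  exactly collinear pair) are resolved by a user-supplied retention
  priority, defaulting to column order — "construct validity" is a
  judgment the code must not invent.

## Synthetic data: what it emulates and what it does not

The generator stands in for a claims database crossed with census-style
area tables. It produces: a rectangular lattice of unit squares (area ids,
uniform populations, rurality assigned by row banding into three
horizontal bands so all classes occur whenever there are ≥3 rows);
equicorrelated standardized covariates; an exact ICAR draw for `u`
(Laplacian eigenbasis with null directions removed — no propriety fudge
factor); iid `v`; Poisson counts with the log-population offset; and
visit-level records whose unique telehealth patients reproduce the panel
counts exactly, with year-rotating diagnosis-code weights, in-person
visits padding telehealth to a target share of all visits, deterministic
patient ids, and an iid-corrupted fraction of area ids to exercise the
cohort filters.

Default conditions (one simulated study year): 20×20 lattice, β0 =
log(0.05) (a 5% baseline annual use rate), β = (0.3, −0.2) per SD,
τ_u = τ_v = 4 (effect sd ≈ 0.5), populations uniform on [500, 20000],
telehealth ≈ 30% of visits, ~2 visits per telehealth patient. Multi-year
studies are produced by repeated runs with year-indexed seeds; the panel
outcome defaults to unique patients (visit counts are available from the
record level for the share/ranking figures).

Not emulated: payer mix, real deprivation-index construction, survey
sampling error in covariates, irregular polygon geometry, within-year
seasonality. Passing tests therefore demonstrate correctness of the
algorithms under the stated generating process, not robustness to the
messiness of real claims data.

## Validation experiments and their design

* **Oracle agreement** (3-area toy, ≤ 4 free parameters): sampler vs grid
  integration, tolerance 0.05.
* **Parameter recovery**: 20 replicate simulations at the default
  conditions, 20,000 iterations each; the mean posterior-mean error per
  coefficient must stay within ±0.05 and 95% intervals must cover the
  truth in ≥17/20 replicates.
* **DIC ordering**: both ordering experiments run on 10×10 lattices with
  *small* populations (50–500). This is deliberate: with per-area counts
  in the hundreds both candidate models fit nearly saturated and
  conditional-focus DIC differences sink into Monte-Carlo noise; spatial
  borrowing of strength (and the cost of omitting a covariate) only
  registers when the per-area likelihood is weak. For the crude-vs-
  adjusted comparison the omitted covariate's effect (−0.5 per SD) must
  dominate the unstructured noise (sd 0.2): a small omitted effect is
  absorbed by the iid effect at negligible deviance cost — which is also
  why adjusted-vs-crude DIC gaps are characteristically small in
  convolution models.
* **Trend calibration**: p < 0.001 under a strong simulated rise
  (0.10→0.40 over 5 years, 10,000 trials/year); approximately uniform
  p-values under a constant-proportion null (KS test over 200 replicates).

Problem sizes (lattice sizes, replicate counts, iteration counts) are the
package's standard validation settings; they were chosen so the full
battery runs in minutes on one CPU while leaving comfortable statistical
margins.

## Numerical choices

* Queen contiguity uses a `dwithin` predicate with tolerance 1e-9
  coordinate units, absorbing GeoJSON round-trip jitter.
* Sum-to-zero is enforced to 1e-10 in generated effects; the prior
  evaluator rejects violations beyond 1e-6.
* VIF treats `R² ≥ 1 − 1e-12` as exact collinearity (infinite VIF).
* Shares round half-up (not banker's) to one decimal.
* The pipeline expands one global seed into per-stage seeds via
  `SeedSequence([global_seed, stage_counter])` with fixed stage counters,
  so adding stages never perturbs earlier ones; every artifact is hashed
  (SHA-256) into the run manifest.

## Known limitations

* The sampler is tuned for lattices up to a few thousand areas; it is not
  a replacement for specialised software on very large graphs.
* Conditional-focus DIC is reported because it matches common practice for
  this model family, but it discriminates weakly between models that
  differ only in how flexible random effects absorb structure (see the
  experiment-design note above).
* Exceedance maps use fitted rates; smoothed relative-risk exceedance is a
  flag away (`fixed_value` reference) but not the default.
* Permutation invariance of the sampler holds statistically, not
  bit-for-bit: the colour-blocked updates consume random numbers in
  colour order, which relabeling reorders.
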