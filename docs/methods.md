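# Methods

## Model

For study i = 1..N and arm k ∈ {0 control, 1 experimental}, event counts
are binomial, X_ik ~ Bin(n_ik, π_ik), and the logit-transformed event
probabilities carry a bivariate normal random effect

(logit π_i0, logit π_i1) ~ N((μ0, μ1), Σ),  Σ = [[σ0², ρσ0σ1], [ρσ0σ1, σ1²]].

The exchangeability assumption is on *absolute* arm effects, not on
within-study contrasts.  ρ is the between-arm correlation; it both
respects within-study randomization and is the conduit through which a
single-arm study informs the opposite arm.  A study missing an arm simply
contributes no binomial factor for that arm: its latent pair keeps the
full bivariate-normal prior, so borrowing happens exactly when ρ ≠ 0.
Double-zero studies contribute their x = 0 likelihood terms and need no
continuity correction.

Two variance structures are supported: equal (σ0 = σ1 = σ) and unequal.
With `variance_structure="auto"`, both are fitted and the equal-SD model
is kept unless DIC_equal − DIC_unequal > 3 (the absolute-difference rule;
`dic_threshold` parameter, default 3).

### Priors (defaults, with units on the logit scale)

| parameter | prior | default hyperparameter | why |
|---|---|---|---|
| μ0, μ1 | N(0, mu_sd²) | mu_sd = 100 | effectively flat on the logit scale |
| σ0, σ1 | U(0, sigma_upper) | sigma_upper = 10 | spans negligible-to-extreme heterogeneity |
| ρ | U(rho_lower, rho_upper) | (−1, 1) | uninformative over the full correlation domain |

In fixed-ρ mode the correlation is a constant in Σ (a point-mass prior);
all other priors are unchanged.

## Sampler

An adaptive Metropolis-within-Gibbs scheme, numba-compiled:

1. each latent logit θ_ik: scalar random-walk Metropolis against its
   binomial likelihood times the normal conditional prior given θ_i(1−k);
2. (μ0, μ1): exact conjugate bivariate-normal draw given the latents and Σ;
3. σ (or σ0, σ1): scalar random walk, proposals outside (10⁻⁶,
   sigma_upper) rejected;
4. ρ: scalar random walk within the prior bounds (and |ρ| < 0.9999 for
   numerical safety), skipped in fixed-ρ mode.

Step sizes are tuned toward 0.44 acceptance by a decaying Robbins-Monro
rule **only during the adaptation phase**; the retained draws come from a
fixed transition kernel, so detailed balance holds for everything that is
kept.  The headline schedule mirrors standard practice for this model
class: 3 chains × 100,000 iterations with 10,000 adaptation iterations,
10,000 burn-in and thinning 2, retaining 3 × 45,000 = 135,000 draws.
Chains are seeded from a base seed through `numpy.random.SeedSequence`
(per-chain spawns; each fixed-ρ refit derives its seed from the base seed
and its grid index), with overdispersed initial values (empirical logits
plus noise; σ uniform in [0.3, 2]; ρ uniform in [−0.5, 0.5]).

Convergence is monitored by the split-chain potential scale reduction
factor (arviz); any R-hat ≥ 1.05 sets `converged_ = False` and raises a
warning — flagged fits are reported, never silently discarded or re-run.
The sampler was validated against an independent Gibbs implementation of
the identical model (JAGS via rjags) on the packaged five-study dataset;
the cross-check lives in the test suite and agrees on all posterior
medians to well within Monte-Carlo error.

## Effect measures

All measures are computed **per retained draw** and then summarized by the
posterior median and equal-tailed 95% CrI (2.5%/97.5% quantiles, not HPD),
so the reported intervals propagate the joint posterior uncertainty of
(μ0, μ1, σ0, σ1).  The conditional OR is exp(μ1 − μ0).  Marginal
probabilities use the logistic-normal mean approximation
π_k ≈ expit(μ_k/√(1 + C²σ_k²)) with C = 16√3/(15π) stored at full double
precision; its absolute error against adaptive quadrature of
E[expit(N(μ, σ²))] stays below 0.02 for μ ∈ [−3, 3], σ ∈ [0, 2] (checked
in the tests).  Under unequal SDs each arm uses its own σ_k in the
shrinkage factor — a convention this package adopts (and documents here)
because the closed-form expressions are usually printed only for the
equal-SD case; it reduces to them when σ0 = σ1.  Heterogeneity shrinks
marginal contrasts toward the null: |log marginal OR| ≤ |log conditional
OR| with equality iff σ0 = σ1 = 0.

## DIC

The deviance is conditioned on the study-level latents:
D(θ) = −2 Σ log Bin(x_ik; n_ik, expit(θ_ik)) over observed arms.
DIC = D̄ + p_D with p_D = D̄ − D(θ̄), the plug-in taken at the posterior
mean of the latent linear predictors (the "focused" penalty).  Other
software may compute the penalty differently; since model selection uses
only the DIC *difference* against a margin of 3, small definitional
differences are absorbed.  DIC values are therefore comparable within this
package, not across packages.

## Tipping-point analysis

Grid: equally spaced values strictly inside R_ρ (default R_ρ = (−1, 1)
with step 0.01 → 199 points −0.99..0.99, or a point count B), capped at
±0.99 to keep Σ well-conditioned.  At each grid value the model is refitted
with ρ fixed, same variance structure and priors as the selected free-ρ
fit.

*Interval tipping*: a grid value is a tipping point when its interval
conclusion (95% CrI excludes/covers the null; an interval touching the
null counts as covering) differs from the original free-ρ conclusion.  The
tipping range T = [min, max] of the tipping set deliberately may contain
interior non-flipped values when the conclusion oscillates under
Monte-Carlo error; the per-point flip mask is retained so oscillation is
visible.  The posterior mass of ρ over T is computed from the original
fit's draws; when the tipping set reaches the grid's upper (lower)
boundary the region is extended one-sidedly to +1 (−1), i.e. the mass
reads Pr(ρ ≥ min tipping point) — the natural reading when tipping is
observed "at ρ ≥ r*".  Verdict: *not robust* iff T is nonempty and
intersects the original 95% CrI of ρ.

*Magnitude tipping*: relative change (new − original)/original of each
point estimate along the grid, thresholds ±15% and ±30% by default
(clinical context may override).  If the original RD is within 10⁻³ of 0
the relative change is ill-conditioned; the trajectory switches to
absolute change with a warning.  OR, RR and RD are analyzed independently
with no multiplicity adjustment.

Per-grid-point MCMC defaults to a reduced schedule (2 chains × 20,000
iterations, 2,000 adaptation, 5,000 burn-in, thin 2): 199 full-schedule
refits are needlessly heavy for routine use, and the reduced schedule
reproduces full-schedule conclusions in the suite's spot checks.  Full
replication mode is one parameter away (`--full-schedule` on the CLI).
Non-converged grid points are flagged in the result, never dropped.

## Visualization

Tipping plot: one panel per measure (AR0, AR1, OR, RR, RD) with the point
estimate and CrI at each grid ρ, plus a panel with the kernel density
(Gaussian KDE, Scott bandwidth, draws thinned to ≤ 20,000 for determinism)
of ρ's posterior on the shared axis.  Point colors are a pure function of
(inside ρ's 95% CrI, at its posterior median, flipped): flip inside the
CrI → dark red, flip outside → red, the grid point nearest the median →
blue, unflipped inside → black.  Unflipped points *outside* the CrI have
no conventional color; light gray was chosen so the CrI boundary stays
visible.  Trajectory plot: relative-change curves, red inside ρ's CrI and
black outside, a blue dashed vertical at the ρ median, horizontal guides
at ± each threshold.  The `PlotSpec` behind both figures serializes to
JSON and re-renders deterministically.

## Synthetic data

`simulate_meta` draws latent logit pairs from the bivariate normal and
counts from the binomial — exactly the model's data-generating process.
Reference conditions (the generator defaults): μ0 = 0, μ1 = 0.5,
σ0 = σ1 = 1, ρ = 0.7, N = 50 studies, 50 subjects per arm; under them the
true marginal OR/RR/RD are 1.54/1.21/0.11.  The five-study
`table1_fixture` is a frozen draw from these conditions, shipped verbatim
so the small-N analysis is exactly reproducible.  The generator emulates
between-study heterogeneity and arm correlation but **not** features of
real data such as unequal or informative arm sizes, missingness
mechanisms behind single-arm studies, publication bias, or non-exchangeable
studies — passing tests show correct behavior under the model's own
assumptions, not robustness to their violation.  Single-arm and
double-zero structures are exercised through hand-written CSV fixtures
instead.

## Numerical choices

- Binomial log-likelihood in the logit parameter uses a softplus guard
  (|θ| > 35 short-circuits) against overflow.
- Continuity correction for *descriptive* logits: (x + c)/(n + 2c),
  default c = 0.5, applied only when plotting/describing; the likelihood
  never uses it.  The denominator convention is this package's documented
  choice among the common variants.
- Grid construction uses integer step counts and rounding to 12 decimals
  so the default grid hits −0.99..0.99 exactly.
- Quantile summaries use linear interpolation (numpy default).
- Ties/degenerate inputs: constant draw vectors summarize to (c, c, c);
  an empty draw vector, an empty trajectory, or a zero-variance arm in the
  empirical correlation are rejected with explicit errors.

## Problem sizes in the test suite

The suite fits the headline schedule once on the five-study data; all
other fits use reduced schedules (typically 2 chains × 8,000–20,000
iterations), a coarse 5-point tipping grid, and 20 replicates for the
coverage calibration — sizes chosen to keep the checks sharp at a few
minutes of total runtime while preserving the Monte-Carlo tolerances they
assert.

## Limitations

Logit link only (no probit/cloglog); pairwise meta-analysis only (no
network extension); Bayesian fitting only; the separation-strategy prior
on Σ (no inverse-Wishart alternative); tipping analysis targets ρ alone,
not σ or the priors.  DIC values are engine-specific (see above).  The
marginal approximation degrades for |μ| ≫ 3 or σ ≫ 2; beyond that range
quadrature should replace the closed form.
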