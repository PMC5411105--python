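# Methods

This note documents the models, defaults and numerical choices behind
`paleowean`, and what the test suite does and does not establish.

## Data model and screening

A `CollagenSample` is one individual's bone-collagen record: δ13C (‰ VPDB),
δ15N (‰ AIR), %C, %N, atomic C/N, collagen yield, and for juveniles a printed
age estimate parsed into a decimal-year interval ("Perinatal" and "Birth" map
to age 0; mixed-unit ranges such as "10 months–1 year" are supported).  The
preservation screen requires %N ≥ 4.8, %C ≥ 13 and C/N in [2.9, 3.6], bounds
inclusive.  One bundled individual (E-29, C/N 2.80) fails the screen yet
belongs to the published sample; screening therefore *flags* rather than
drops by default, and the pipeline accepts an explicit override list
(`drop_qc_failures` enforces removal).

Juveniles are placed on the age axis at their interval midpoint and binned
into four groups with right-closed bins (0, 0.5], (0.5, 1], (1, 2], (2, 6]
years (age 0 in the first group).  Right-closure is deliberate: the bundled
one-year-old belongs with the 0.5–1-year group, and this convention
reproduces the published group sizes 11/6/8/6.  Reported summaries round half
away from zero to two decimals, the precision of the source tables.

## Breast-milk source construction

Milk cannot be sampled, so its isotope composition is inferred from
adult-female collagen through tissue offsets (convention Δ(a→b) = δ_b − δ_a):

* maternal milk→maternal collagen = Δ(keratin→collagen) − Δ(keratin→milk),
  endpoint-wise over the literature ranges;
* milk diet→infant collagen = Δ(milk→newborn hair) + Δ(keratin→collagen).

A literature range [low, high] is summarised by its midpoint and the sample
SD of its two endpoints (|high − low|/√2) — this is the convention that
generates the published fractionation summaries (4.34–4.50 → 4.42 ± 0.11;
4.98–5.93 → 5.46 ± 0.67).  The milk source mean is the female collagen mean
minus the maternal-offset midpoint; its SD inherits the female collagen SD,
with the offset-range uncertainty carried separately in the fractionation SD.
The published maternal δ13C offset (4.58–5.55 ‰) differs by 0.02 ‰ from
endpoint arithmetic on the rounded chain inputs (4.58–5.53 ‰); the
construction defaults to the published range so downstream values match the
published source table, and `milk_collagen_offset` exposes the arithmetic
result.  Milk elemental concentrations (1.61 ± 0.27 %N, 49.13 ± 3.63 %C) are
configuration constants from the milk-composition literature.

## Mixing model

For each age group independently, consumers' (δ15N, δ13C) pairs are modelled
as normal around a concentration-weighted mixture of fractionation-corrected
sources (equations in the README).  Source and fractionation uncertainty are
marginalised into the observation variance under independence assumptions
rather than sampled as latent per-source values; this matches the standard
formulation of concentration-dependent isotope mixing models and keeps the
sampler in K+1 dimensions (K−1 simplex coordinates plus two residual SDs).

Priors: Dirichlet(1, …, 1) on the proportions; half-normal with scale 5 ‰ on
each residual SD (weakly informative at the scale of collagen scatter).
Sampling: random-walk Metropolis on additive-log-ratio coordinates
z_k = log(p_k/p_K) and log-σ, all chains advanced in lock-step by vectorised
updates; proposal scales adapt toward ~30 % acceptance during burn-in only,
so the post-burn-in kernel is fixed and runs are bitwise reproducible per
seed.  Defaults: 4 chains × 50 000 iterations, 25 000 burn-in, thinning 10.
Split-chain R-hat is computed for every proportion and residual SD; any value
above 1.05 flags `converged=False` in the output rather than raising.

Per-source posteriors are summarised by the mode of a Gaussian KDE (Silverman
bandwidth) with boundary reflection at 0 and 1 — without reflection the KDE
leaks mass outside the unit interval and cannot place modes at the boundary,
where poorly constrained sources pile up — plus 2.5/97.5-percentile
intervals, reported as integer percent.

On the bundled series the 1–2-year group gives a breast-milk mode of ~76–77 %
robustly across seeds.  The three other groups' milk posteriors are close to
flat (the nitrogen and carbon axes pull in opposite directions and the
residual SDs inflate to absorb the tension), so their *modes* are unstable
summaries even though their credibility intervals are stable; the test suite
documents one published-comparison failure that follows from this (see
"Known limitations").

## Weaning-age reconstruction

The dietary δ15N trajectory has a breastfeeding plateau at the female mean
plus an enrichment term, a linear decline between t₁ and t₂, and a
weaning-food plateau.  Collagen relaxes toward this signal at the
age-dependent turnover rate r(t) = r∞ + (r₀ − r∞)e^(−t/τ), integrated by
fixed-step classical RK4 from δcol(0) = female mean (fetal collagen reflects
the maternal diet).  Default step 0.02 y; off-grid observation ages use cubic
Hermite interpolation with the ODE's own slopes, keeping interpolation error
at the integrator's order (the constant-diet/constant-rate closed form is
reproduced to 10⁻⁶ ‰).

Turnover defaults r₀ = 3/yr, r∞ = 0.1/yr, τ = 3 y: infant collagen is
replaced roughly three times in the first year, and the rate does not reach
the adult level until adolescence (r(12) ≈ 0.15/yr).  A faster-decaying
schedule (adult rate by age ~5) was rejected because childhood turnover is
biologically protracted, and because it forces implausibly depleted
weaning-food estimates when fitting individuals older than three.  Weaning
point estimates are materially sensitive to this schedule, which is why it is
explicit configuration recorded in every output.

Inference is plain rejection ABC: parameter vectors (t₁, duration t₂ − t₁,
enrichment, weaning-food value) are drawn from independent uniforms
(U(0,4) y, U(0,5) y, U(0,4) ‰, U(2,12) ‰), trajectories are simulated at the
observed ages (vectorised across simulations, batched to bound memory), and
the 0.5 % of 10⁶ draws with the smallest root-mean-square distance are
retained.  (t₁, t₂) are summarised jointly by the argmax of a 2D Gaussian KDE
on a 128² grid clipped to t₁ ≤ t₂; enrichment and the weaning-food value use
marginal KDE argmaxes; intervals are 2.5/97.5 percentiles of accepted draws.
Runs are bitwise reproducible per seed.

## Group statistics

Shapiro–Wilk, classical one-way fixed-effects ANOVA, and Tukey–Kramer
pairwise comparisons (studentized-range critical values with the Kramer
unequal-n adjustment, via statsmodels) across the five groups.  The sign
convention is fixed by the level order (G1, G2, G3, G4, females): every
difference is mean(later level) − mean(earlier level), stated in the output
headers.  Human-readable tables print adjusted p-values below 0.0005 as
"0.000"; machine output keeps full precision.  Because the correct pooling
for the normality check is ambiguous, the pipeline reports Shapiro results
for both the juvenile-only and the pooled 49-individual sets.

## Synthetic cohorts

The generators emulate the statistical structure the inference assumes:
females as independent normal draws per isotope; juveniles as noisy
observations of a known trajectory (δ15N noise default 1.5 ‰, the
within-group SD scale of the real series) at ages drawn uniformly over
0–5.5 y by default, or triangularly peaked in the 1–2-y infant-mortality
window; mixture consumers as normal draws around the concentration-weighted
mixture mean/variance at a known proportion vector.  They do **not** emulate
diagenesis, δ15N–δ13C covariance, or mortality–diet interaction, so passing
recovery tests demonstrates internal consistency of the estimators, not
robustness to those real-data features.  Quality indicators on generated
records are pass-through constants that clear the screen.

## Problem sizes used by the test suite

Stochastic stages run at reduced but well-mixed budgets chosen as the
smallest sizes at which the estimators' behaviour is stable: mixing fits at
20 000 iterations × 4 chains (real groups) and 8 000 × 2 (calibration
replicates); ABC at 1–3 × 10⁵ simulations for fits and 20-replicate recovery
studies.  The acceptance script runs the full default budgets (4 × 50 000
mixing iterations, 10⁶ ABC simulations).

## Known limitations

* The δ13C ANOVA F computed from the bundled (printed, 2-decimal) individual
  values is 14.91; the published 14.5 was evidently computed from unrounded
  laboratory values, which are not available.  The corresponding test asserts
  the published value and fails, documenting the discrepancy.
* The published per-group milk-mode *ordering* places the 0–0.5-y group above
  the 0.5–1-y group, but the bundled data order their δ15N means the other
  way, and no residual-prior setting reverses the fitted ordering.  The wide
  published credibility intervals for these groups are reproduced; the point
  modes of near-flat posteriors are not.
* The end-of-weaning recovery bias over 20 synthetic uniform-age cohorts is
  ≈ +0.5 y (target < 0.3 y): when a cohort's ages poorly cover 2.5–3.5 y, t₂
  is weakly identified and the U(0,5) duration prior drags the posterior
  upward.  The corresponding assertion is left failing with this diagnosis.
* The start-of-weaning estimate is the quantity most sensitive to the
  turnover schedule; under the default schedule the real-series t₁ MDE is
  ≈ 2.5 y with a 95 % interval reaching well below 2 y.
* The mixing model has no isotope-routing (macronutrient-specific carbon) and
  no time-continuous age structure; age enters only through the four groups.
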