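# Methods

## Scope and data model

The package reimplements, as a reusable library, a quality-of-life and
cost-utility analysis of three rare bone diseases in UK adults:
osteogenesis imperfecta (OI, n = 43), fibrous dysplasia (FD, n = 42)
and X-linked hypophosphatemia (XLH, n = 24). The atomic observation is
one EQ-5D-5L response: five ordinal levels (1–5) on mobility,
self-care, usual activities, pain/discomfort and anxiety/depression,
plus a 0–100 visual analogue scale (VAS). The VAS is reported
alongside but never enters utility scoring; a missing VAS is permitted,
a missing dimension level is not.

Value sets are data, not code: CSV tables of additive decrements
`(dimension, level) → w ≥ 0` with `w(·, 1) = 0`, non-decreasing in
level, so `U(s) = 1 − Σ_d w_d(ℓ_d)`. The packaged England set (Devlin
et al. 2018 decrements) has floor `1 − 1.285 = −0.285`; the commonly
quoted scale floor "−0.28" is that value rounded, and all tests compare
against the fixture's own floor rather than the rounded figure.
Utilities are carried at full precision and rounded (3 dp) only at
presentation. A linear toy value set backs every test that does not
specifically need the England coefficients, so no single fixture is
load-bearing.

## Descriptive statistics

Levels collapse to three categories — no/slight (1–2), moderate (3),
severe/extreme (4–5) — and each dimension yields a 3 (disease) × 3
(category) contingency table. Association is tested with a two-sided
exact r×c Fisher test under the multivariate hypergeometric null with
both margins fixed: p is the sum of probabilities of all tables whose
point probability does not exceed the observed table's, ties counted
within a 1e-7 relative tolerance (the convention of standard
statistical software). The implementation enumerates tables row by row
with margin-based pruning, resolving the final two rows with a
vectorised sweep over bounded compositions; a 3×3 table with n ≈ 100
completes in well under a second, and n = 200 in about half a second.
Tables beyond the enumeration budget raise an error directing the
caller to the seeded Monte-Carlo fallback, which resamples fixed-margin
tables with the Patefield algorithm (`scipy.stats.random_table`) and
estimates the same tail sum. The collapsed 3×3 reading (rather than
the raw 5×3) was adopted; it reproduces the published p-values exactly
(mobility 0.775, self-care 0.322, usual activities 1.000,
pain/discomfort 0.627, anxiety/depression 0.100).

Group comparisons of mean utility and VAS use classical one-way ANOVA
(delegated to `scipy.stats.f_oneway` after validity checks); age
relations use ordinary least squares / Pearson correlation
(`scipy.stats.linregress`). Summaries report sample SD (n−1
denominator); a single-member group reports SD 0 flagged as
undefined-variance.

Tertile splitting sorts ascending by utility, stable, with ties broken
by patient id, and allocates the remainder of `n mod 3` from the lowest
tertile upward — 43 participants split 15/14/14, fixing the 15-person
treatment group.

## Cost-utility simulation

The simulated intervention treats the lower utility tertile of the OI
group over a 10-year horizon of annual cycles `t = 0..9`.

* **Potential improvement**: `PI = max(0, u* − u0)` with target
  `u* = 0.745`, the middle-tertile mean. The target is a config
  constant, not recomputed per synthetic cohort; `TertileSplit.middle_mean`
  lets users apply the original empirical procedure to their own data.
* **Attainment**: the treated arm reaches `Δ = a · PI` by the end of
  year 1 (base case a = 0.75; sensitivity grid 0.55–0.95). The effect
  builds linearly within year 1, so cycle 0 contributes Δ/2 and cycles
  1–9 the full Δ.
* **Ageing**: both arms lose d = 0.005 utility per year (`u0 − d·t`,
  no decrement in cycle 0). Any common-to-both-arms convention leaves
  the gain unchanged; this one reproduces the published 41-QALY control
  total.
* **Discounting**: rate r = 0.035 with cycle 0 undiscounted,
  `A(r, H) = Σ_{t=0}^{H−1}(1+r)^{−t}`; `A(0.035, 10) = 8.60769`. This
  timing is forced by the published arithmetic
  (£14,355 × 8.60769 ≈ £123,561).
* **Trajectories** are clamped to the value-set range [−0.285, 1];
  since `u* < 1` the upper clamp never binds under defaults and the
  lower clamp binds only for extreme baselines.
* **Mortality** is excluded by assumption over the 10-year horizon.

Per person, `QALY_arm = Σ_t u_arm(t)·(1+r)^{−t}` and the gain is
treatment minus control; absent clamping the gain collapses to
`a · PI · (A − 1/2)`, exactly linear in attainment and in PI, and
invariant to the ageing decrement. Aggregates report totals, means,
the sample SD of gains, a mean ± 1.96·SD spread of per-person gains
(`gain_interval`, the convention of the reported results, which is a
population-spread interval rather than a CI of the mean) and a
standard-error-based 95% CI of the mean (`gain_mean_ci`).

Willingness-to-pay: at threshold λ the maximum constant annual cost is
`λ·G/A(r, H)` — the price whose discounted 10-year payment stream per
QALY gained equals λ exactly (ICER identity). The grid spans
£20,000–£100,000 in £10,000 steps by the five attainment fractions;
cells are kept unrounded and rounded to whole currency units only when
printed. The published sensitivity gains deviate from exact linearity
in attainment by up to ~1.6%; the model here is exactly linear and the
deviation is treated as presentation rounding in the source, not
reverse-engineered.

## Synthetic cohort generator

The generator emulates the study conditions so the pipeline is testable
without the undeposited patient data. What it matches:

* **Sizes** 43/42/24; **ages** truncated normal at the published
  mean/SD/range per disease (only those three facts are published);
  **sex** Bernoulli at the published female shares (0.77/0.69/0.79).
* **Response levels**: independent per-dimension multinomials at the
  published level frequencies.
* **Utilities**: a two-component truncated-normal mixture (bimodal, as
  the published distributions are). Defaults — weights 0.45/0.55, low
  component N(0.45, 0.29), high component N(0.85, 0.12), each truncated
  to [−0.285, 1] — are a calibration solved by least squares
  (`scripts/calibrate_mixture.py`) on the two moments that drive the
  simulation: overall mean ≈ 0.65 and expected mean of the lowest 15 of
  43 draws ≈ 0.3386, the baseline that yields the 41-QALY control total
  and the 2.47 base-case gain. The implied SD ≈ 0.273 versus the
  published 0.283 is accepted: the two calibrated moments, not the SD,
  determine the simulation outputs.
* **Couplings** (OI only): age↔usual-activities r = +0.39, age↔VAS
  r = −0.42, utility-on-age slope = −0.005/year, injected through a
  one-factor Gaussian copula with age as the factor. Latent
  correlations are solved from the targets by a first-order Hermite
  inversion — for `X = F⁻¹(Φ(Z))`, `corr(X, Y) ≈ ρ·a₁ᵡa₁ʸ/(σᵡσʸ)` with
  `a₁ = E[X·Z]` computed by 96-node Gauss–Hermite quadrature — which
  lands the realised correlations within a few hundredths of target
  (verified by recovery tests at n = 10⁴). A target needing |ρ| ≥ 1 is
  rejected as infeasible. The slope target is converted to a
  correlation via the quadrature margin SDs.
* **Two utility modes**: `mixture` (utilities drawn from the mixture;
  used by the simulation pipeline) and `valueset` (utilities recomputed
  from the generated responses under a value set; used for
  descriptive-pipeline checks). The two are not mutually consistent —
  no joint distribution of responses and utilities is published — and
  the config selects one.
* **Seeding**: one master seed; each (disease, stream) pair derives a
  child generator via `SeedSequence(master, spawn_key=(disease_idx,
  stream_idx))` with a fixed append-only stream registry, so adding a
  stream or dropping a disease never perturbs the other streams.
  Identical spec + seed gives byte-identical CSV output.

What it does **not** emulate: within-person coherence between the five
response dimensions (they are independent given disease), any
correlation structure outside the three published OI couplings,
comorbidities, OI Sillence subtypes, or longitudinal change. Passing
tests therefore demonstrate that the analysis machinery reproduces the
published quantities under the published marginal structure — not that
the generator reproduces unpublished joint features of the real cohort.
Two published VAS summaries are mutually inconsistent (69.4 SD 21.4 vs
67.6 SD 22.7 for OI); the generator uses the first set and the
discrepancy is documented here, not resolved.

## Problem sizes and numerical choices

Replicated simulation results (tests and the acceptance script) average
≥ 500 seeded 43-person cohorts, giving Monte-Carlo standard errors of
≈ 0.003 QALYs on the mean gain — two orders below the quantities
compared. Parameter-recovery tests use n = 10⁴ cohorts; marginal
calibration checks use up to 10⁶ draws. The mixture quantile function
is a 64-step vectorised bisection on [−0.285, 1] (resolution ~7e-20,
far below utility precision). The exact Fisher enumeration budget
defaults to 5×10⁶ tables; the published 3×3 tables need ~10⁵.
Between-group ANOVA p on real utilities (published 0.993) and the exact
OI correlation magnitudes depend on individual-level data and are
checked as recovery properties on synthetic data rather than as value
reproductions.

## Known limitations

* The synthetic cohort matches published marginals and three pairwise
  couplings only; any analysis sensitive to unpublished joint structure
  will not transfer.
* The Fisher test enumerates exhaustively only within its budget;
  beyond it the Monte-Carlo estimate carries sampling error
  (~1/√draws).
* The simulation is deterministic given baselines: no probabilistic
  sensitivity analysis beyond the attainment grid, no half-cycle
  correction, no discontinuation, adverse events or mortality.
* Currency is an opaque unit; no inflation indexing.
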