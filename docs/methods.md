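# Methods

`stiidil` explains a black-box insulin-titration predictor
`f : R^d -> R` (output: a dose adjustment in U) at a single patient
instance `x` by a second-order game-theoretic attribution with clinical
constraints folded into the estimation objective.  This note records the
model, the numerical choices, and what the synthetic experiments do and do
not establish.

## Coalition semantics

Each feature `i` has an observed value `x_i` and a per-patient reference
(baseline) value `b_i`.  A coalition `S ⊆ N = {0..d-1}` keeps the observed
values on `S` and the baselines elsewhere, defining the set function
`v(S) = f(mask(x, S))` with `v(∅) = f(b)` and `v(N) = f(x)`.  The quantity
attributed is `v(N) − v(∅)`.

Baselines are a modelling choice the explanation is conditional on.  The
cohort generator supports two schemes: `cohort_mean` (population means for
continuous features, 0 for flags — the common Shapley convention) and
`carry_forward` (a recent BG record's reference is the same slot the day
before, so its main effect tracks the day-over-day change — the natural
frame for the wrong-quadrant analyses).  A missing measurement is encoded
as two features: a mean-imputed value (flagged in `missing_mask`) and a
0/1 missing indicator, giving the missing-content constraint an explicit
handle.  Note that under mean imputation the imputed value sits at its
baseline and carries no attribution by construction; spurious "missing
record" mass therefore appears on the indicator, which is why the
suppression rule covers both.

## The order-2 index

Main effects and pairwise interactions are Shapley-Taylor values of
order 2.  For a pair `S = {i, j}`:

    I(f, S) = Σ_{T ⊆ N\S}  w(t) · δ_S f(T),
    δ_S f(T) = Σ_{W ⊆ S} (−1)^{|S|−|W|} v(T ∪ W)

Two weight conventions are implemented (`variant=`):

* `sundararajan` (default): `w(t) = 2 / (n · C(n−1, t))` for pairs and
  `main_i = δ_i f(∅)` for singletons.  This is the order-2 Shapley-Taylor
  index; attributions sum exactly to `v(N) − v(∅)` (efficiency) for
  *every* coalition game.  We verified efficiency symbolically on the
  Möbius basis and numerically on random tabular games.
* `shapley_interaction`: `w(t) = t!(n−t−s)!/(n−s+1)!`, i.e. classical
  Shapley values for singletons and the Grabisch–Roubens interaction index
  for pairs.  This convention does **not** satisfy efficiency when the
  game has third-or-higher-order structure (a pure 3-way interaction game
  receives total attribution 3/2); it is provided for comparison because
  it is the form most often written down.

The two variants coincide on coalition games that are multilinear of
degree ≤ 2 — exactly the class generated by the package's additive +
pairwise surrogates.

Exact computation memoizes `v` over all `2^d` coalitions and is capped at
`d ≤ 12` (4096 model calls); factorial weights are computed in log space.

## Kernel estimator

For larger `d` the coefficients are estimated by Shapley-kernel-weighted
regression: draw `M` coalition masks, evaluate the model once per distinct
mask, and solve

    min_α  Σ_m w_m (⟨α, φ(mask_m)⟩ + v(∅) − y_m)²  +  λ_lasso ‖α‖₁

where `φ` stacks the `d` main columns (the mask) and the `d(d−1)/2` pair
columns (ANDs of mask pairs), and `w_m = (d−1)/(C(d,z)·z·(d−z))`,
`z = |mask|`.  Design points:

* **Symmetric pair columns.**  Ordered-pair duplicates are perfectly
  collinear; the upper-triangular design (`p = d + C(d,2)`) is the
  identifiable canonical form.  Serialization mirrors pairs back to the
  redundant `d² + d` layout.
* **Anchors.**  The empty and full coalitions have infinite kernel weight;
  they are imposed as hard equalities `intercept = v(∅)` and
  `Σα = v(N) − v(∅)`.  Every fit — penalized or not — therefore satisfies
  efficiency to machine precision (the equality is eliminated by an exact
  null-space parameterization and re-projected after solving).
* **Sampling** (`kernel_prop`, default): complete coalition-size levels
  are enumerated exactly, outermost first, while the budget `M` allows
  (for `d = 15`, `M = 2048` this covers `z ∈ {1,2,3,12,13,14}`, ≈70% of
  the kernel mass, variance-free); residual levels are sampled with
  probability proportional to their aggregated kernel mass, each mask
  paired with its complement.  Duplicates are merged with multiplicity.
  A `uniform_z` importance-weighted scheme and full enumeration are also
  available.
* **λ_lasso default**: 0 for exhaustive designs;
  `1e-3 · median|y − mean(y)|` for sampled designs (a light threshold
  against sampling noise; no value is published for this stage).
* On degree-≤2 games the exhaustive unpenalized fit reproduces the exact
  index (theorem, and our oracle-equivalence test); on general games the
  regression projects onto a different interaction index, so exact/kernel
  agreement is only claimed for the surrogate class.

The solver: when the problem is purely quadratic the anchored normal
equations are solved in closed form (KKT).  With L1 or clinical penalties,
an active-set Newton warm start over the quadratic penalty pieces is
polished by L-BFGS on the smooth objective (|α| smoothed with half-width
1e-9).  A rank check raises an explicit ill-posed-fit error for
underdetermined unpenalized designs.

A random-forest variant of the regression stage (masks → coalition
values, impurity importances per design column) is included for robustness
comparisons only; its importances are unsigned.

## Clinical constraints (doctor-in-the-loop layer)

Expert rules enter as penalty terms `Σ_k λ_k g_k(α)` added to the same
objective.  Shapes:

| kind | g(α) | used by |
|---|---|---|
| sign (main or pair) | `max(0, −s·α_t)²` | BG change, medication change, BG-insulin interaction |
| suppress (main or pair) | `α_t²` | missing content |
| emphasize group | `(max(0, τ − Σ_G \|α_g\|))²`, `τ = 0.25·\|v(N)−v(∅)\|` | prescribed BG |

Sign and suppression penalties are convex; group emphasis is convex on
each sign orthant only (it rewards attribution mass) and is solved from
the unconstrained warm start.  A squared hinge drives violations to
`O(1/λ)` but never exactly zero, so after convergence residual violations
below a snap tolerance (1e-3 U) are clamped to the boundary and the
anchor deficit is redistributed over unconstrained coordinates — the
numerical realization of the large-λ limit.  Hard-λ behaviour
(`λ = 10⁶`) therefore yields exactly-zero wrong-signed terms.

The five rule families read the feature metadata (kind, day, slot,
regimen linkage, prescribed-BG flag):

* **BG change** — an action-window BG record that rose (fell) more than a
  deadband (default 0.5 mmol/L) versus the same slot the prior day must
  not contribute negatively (positively) to the dose.
* **Antidiabetic medications** — a newly added oral agent must not push
  the dose up; a stopped one must not pull it down (flag pairs at days
  −1/0).
* **Missing content** — suppress imputed records, their indicators, and
  every pair touching them.
* **Prescribed BG** — emphasize the BG records in the explained regimen's
  action window (regimen → slot table shipped as editable config; e.g.
  pre-lunch short-acting → post-lunch/pre-dinner, bedtime long-acting →
  next-morning fasting).
* **BG-insulin interaction** — when the prior dose was cut by more than a
  deadband (0.5 U) and the subsequent action-window BG rose (or the
  mirrored case), the (insulin, BG) pair term must be nonnegative.

Default strengths: 10× a base scale for sign rules, 100× for missing
suppression (suppression must dominate); all per-family strengths,
deadbands, the emphasis share τ and the regimen table are configurable
(YAML), because the deployed rule statements are institution-specific.

## Synthetic cohorts and surrogates

The generator emulates the inpatient data shape: a 3-day × 7-slot BG grid
(AR(1) within day, persistence 0.6, post-meal bumps of 1.4–1.8 mmol/L,
values truncated to [2, 30] mmol/L), per-day insulin history at the
regimen's injection slot (0.5 U resolution), oral-medication flags,
demographics (age 58.5 ± 14.3 y, weight 70 ± 15 kg, HbA1c 9.3 ± 2.2 %),
and missing BG entries at a configurable rate.  Default layout: 21 BG + 3
insulin + 2 med flags + 3 demographics (d = 29; indicators added when
missingness is enabled).  Default cohort BG level 10 ± 2.5 mmol/L,
doses 2–20 U.

Surrogate models are additive + pairwise polynomials, optionally specified
in centered form around a reference vector so the designed weights are the
effective attribution weights.  The clinical surrogate pushes the dose up
with action-window BG (+0.35/record), down with recent insulin (−0.20)
and added oral agents, with small negative-feedback (insulin, BG) pair
terms.  The adversarial surrogate flips half the BG weights negative and
gives missing indicators spurious weight — the knowledge-inconsistent
structure the constraint layer is tested against.  The worked interaction
case embeds the dose-cut (6 U → 3 U) / BG-rise (11.7 → 14.8 mmol/L)
history with a pairwise term that scores the interaction −0.93 U.

What passing these experiments shows: the estimator recovers known
attribution structure and the constraint layer removes engineered
inconsistencies under ideal conditions (deterministic surrogates, correct
feature encoding, no label noise).  What they do not show: behaviour on
real EHR distributions, encoder drift, or models whose interaction
structure exceeds order 2 (where the order-2 index aggregates higher-order
effects into pairs).

## Evaluation metrics

Implemented as printed-formula transcriptions: top-N alignment
(overlap / expert picks × 100, panel pooled as the union of top-3 sets,
per-expert mean available), nested correctness tiers by per-item majority
vote (partial ⊇ moderate ⊇ absolute by construction), Pearson r with
two-sided p for value-vs-contribution checks, (ΔBG, contribution)
quadrant tables (axis tolerance 1e-6; II and IV are the inconsistent
quadrants), top-item mass shares on prescribed and missing features, dose
MAE, clinical agreement (same adjustment direction and |clinician −
expert|/expert ≤ 20%, inclusive; expert dose 0 requires clinician dose 0),
a 3×3 benefit matrix over (accuracy change × confidence change) with a
0.25 U accuracy deadband — the shipped default
`((2,1,1),(1,0,−1),(−1,−1,−2))` is antisymmetric and penalizes misleading
assistance; the published table is not public, so the matrix is
config-overridable — and faulty-explanation generation as a seeded
Sattolo cycle (a uniform single-cycle permutation: guaranteed
derangement, payload multiset preserved, ranks recomputed).

Item ranking ties break by (magnitude desc, mains before pairs, lower
feature index).  Only the top 10 items are reported by default, matching
deployment practice.

## Problem sizes

The verification studies use sizes chosen so the whole suite runs in a few
minutes on one core: oracle equivalence on 100 random surrogates at
d ≤ 6; axiom checks on 25; recovery at d = 15 with M = 2048 over 20
seeds (dense ground truth, so the |α| ranking is fully identified);
constraint efficacy on exhaustive d = 7–10 cohorts of 4–8 patients;
1000-seed derangement checks.

## Known limitations

* Order 2 only; higher-order structure is aggregated, not resolved.
* The kernel/exact equivalence is exact only for degree-≤2 games.
* Group emphasis is non-convex globally; the solver commits to the warm
  start's orthant.
* Integrated gradients with the finite-difference fallback costs 2·d
  model calls per step.
* The generator reproduces data *shape*, not glucose-insulin physiology.
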