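# Methods

## Model

Each questionnaire dimension is treated as unidimensional and calibrated
separately with the Rating Scale Model (RSM), the polytomous Rasch model in
which all items share one set of category thresholds.  For person *n*, item
*i* and category *k* ∈ {0..K},

    P(X_ni = k) = exp(k(θ_n − β_i) − ct_k) / Σ_m exp(m(θ_n − β_i) − ct_m),
    ct_k = τ_1 + … + τ_k,  ct_0 = 0.

External Likert codes 1..K+1 are shifted to 0..K on load, because the
category index enters the model directly.  The logit scale is identified by
mean(β) = 0 and Στ = 0; person measures are therefore expressed relative to
the item mean, with no rescaling of their spread.  Model expectation
E = Σ k·P(k) and score variance W = Σ k²·P(k) − E² drive everything
downstream: residuals, fit statistics, standard errors and information.

## Estimation

Joint maximum likelihood (JMLE), the estimation method of the established
Rasch calibration programs, chosen so that measures, standard errors and
fit statistics carry the semantics practitioners expect from such output.
The implementation alternates damped Newton updates for θ (per person),
β (per item) and τ (diagonal Newton on the category-passing margins), with:

- starting values from the log-odds of normalized raw scores (PROX-style)
  and log category-frequency ratios for τ;
- per-cycle step cap of 1.0 logit and backtracking halving until the joint
  log-likelihood does not decrease, making the recorded likelihood path
  monotone;
- probability-preserving gauge fixing each cycle (re-centring τ shifts β,
  re-centring β shifts θ);
- convergence when the maximum absolute parameter change falls below the
  tolerance (default 0.001 logits, max 100 cycles).  Because the updates
  are block-diagonal, very small datasets can settle into a limit cycle of
  a few 1e-5 logits around the optimum; a stalled likelihood (relative
  change < 1e-10 over three cycles) with sub-0.001-logit oscillation is
  accepted as converged.  Non-convergence is returned flagged with a
  warning, never silently.

**Extreme and degenerate units.**  Persons and items with all-minimum or
all-maximum observed scores have no finite MLE.  They are excluded from the
joint estimation; their measures are then obtained by solving the score
equation with the raw score pulled 0.3 score points toward the interior
(configurable), and flagged.  Items answered in a single *interior*
category carry no difficulty information at all and are dropped with a
warning, as are all-missing rows.  Unobserved categories are retained as
structural categories of the shared rating scale — thresholds are common
across items, so other items identify them.

**Standard errors.**  SE(θ_n) = 1/√(Σ_i W_ni) over the person's observed
items, and symmetrically for items.

**JMLE bias.**  JMLE inflates the item-difficulty spread by roughly
L/(L−1) for a test of L items; the optional `bias_correction` flag applies
the standard (L−1)/L shrinkage to β and τ and re-scores persons.  The
default is off, matching conventional calibration-program output; the
known-truth recovery checks in the test suite use the corrected estimator,
since they measure distance to the generating values rather than agreement
with conventional output (uncorrected recovery on a 10-item test leaves a
~0.1–0.2-logit spread artefact that is a property of the estimator, not of
the implementation).

## Diagnostics

Standardized residuals z = (x − E)/√W.  Per unit (item or person),
OUTFIT = mean(z²) over observed cells and INFIT = Σ(x−E)²/ΣW
(information-weighted).  Interpretation bands: > 2.0 degrading;
(1.5, 2.0] unproductive; [0.5, 1.5] productive; < 0.5
overfit-deterministic.  The prose convention leaves the boundaries
ambiguous; here 1.5 belongs to "productive" and 2.0 to "unproductive",
and the bands exactly partition [0, ∞).

Separation per margin: observed SD of measures (sample SD, ddof = 1, over
non-extreme units), RMSE = √mean(SE²), adjusted SD = √max(SD² − RMSE², 0),
reliability = adjusted²/observed², separation G = adjusted/RMSE, strata
= (4G + 1)/3 (the standard Rasch formula).  Verdicts: person separation
< 2 and item separation < 3 are inadequate.

Item–total correlations use the rest-score (person's mean of the other
items of the dimension) to avoid self-inflation; whether published tables
of this kind use total or rest-score is typically unstated, so this choice
is documented rather than assumed.

Test information I(θ) = Σ_i W_i(θ) on a default grid of −6..6 logits in
0.1 steps; SE(θ) = 1/√I(θ).  Item maps sort by β (ties broken by item id)
and report adjacent gaps; gaps > 0.5 logits are flagged as substantial,
and gaps > 0.3 are flagged when both items lie in the central region,
defaulting to [−1, 1] logits since "central" has no published bounds.

## Concordance

Both versions are calibrated independently (an anchored mode — scoring the
short form at the full-form item anchors — is available but not the
default, matching the design in which each instrument is fitted
separately).  Persons extreme in either fit are dropped pairwise with a
logged count.  Measures are z-scored with the sample SD (n−1; the
estimator behind published z-score figures is usually unstated) and the
full-version measure is regressed on the short-version measure by OLS;
with z-scored inputs slope = r and intercept = 0, so the slope doubles as
the "diagonal correlation" between versions.

RiU = 1 − √(1 − r²), with ≥ 0.5 counting as concordant.  Efficiency
= (n_short/n_full)/r with ≤ 0.80 counting as efficient: the source
formulation's typography is ambiguous between dividing and multiplying by
the correlation; division is adopted because lower values are read as more
efficient and the ≤ 0.80 pass criterion only makes sense when the
item-count saving dominates, with the multiplicative reading available via
`form="ratio-times-r"`.  Item-order preservation is Kendall's τ on the
shared items' difficulties from the two calibrations.

## Synthetic data

The generator emulates the study design the analysis expects: by default
455 persons, θ ~ Normal(0, 1), five-category items with difficulties
evenly spaced on [−2, 2] logits (matching the ±2-logit range typical of
published calibrations of this instrument) and symmetric thresholds
τ = (−1.5, −0.5, 0.5, 1.5).  Two-version studies are a column subset of
one simulated matrix, so both versions share the true trait by
construction; an independent-trait variant provides a negative control.
Missingness is injected MCAR only, and misfit as uniform random
responders.  All generators are pure functions of (config, seed).

What passing tests therefore show: the estimator recovers known RSM
parameters, the fit statistics detect the injected misfit, and the
concordance indices behave correctly when the short form truly measures
the same trait.  What they cannot show: robustness to multidimensionality,
local item dependence, informative missingness, reverse-keying errors or
category-use styles — none of which the generator produces.

## Problem sizes and tolerances

Known-truth checks use 500 persons × 10 items (K = 4) for calibration
recovery (r(β̂, β) ≥ 0.98, RMSE ≤ 0.15 logits, mean item INFIT/OUTFIT in
[0.9, 1.1]), 50 seeded replicates for misfit detection (OUTFIT > 1.5 for
≥ 90% of injected random responders), 400 scoring replicates for the
empirical-SE vs 1/√I agreement (within 15%), and 455-person two-version
studies for the concordance envelope — sizes chosen to match the emulated
study design while keeping the full suite fast.  Tiny-instance oracles: a
2×2 three-category toy checked against direct Nelder–Mead maximization of
the joint likelihood, and the dichotomous reduction checked against
logistic regression on person/item indicators (an exact equivalence of
Rasch JMLE).

## Known limitations

- JMLE estimates are inconsistent in the number of items (incidental
  parameters); the provided correction is the standard first-order fix.
- No Partial Credit Model (item-specific thresholds), 2PL/graded-response
  models, MML/CML estimation, DIF analysis or formal equating.
- Person measures are step functions of the raw score given the item set;
  missing-data patterns change the mapping per person.
- The packaged UPPS-P scale definition leaves the reverse-keyed item set
  empty (the Spanish-form keying is not enumerated publicly); users supply
  their own when loading raw keyed data.
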