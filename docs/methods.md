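# Methods

This note documents the models, the numerical choices, and the synthetic
data the package is tested on — including what passing tests do and do not
establish about real field data.

## Colony maps and metrics

A map is one colony at one timepoint: nests (worker population, mound
volume, canopy cover, planar coordinates in metres) and trees as nodes,
internest and foraging trails as edges.  A polydomous colony proper is two
or more nests joined by internest trails; maps below that definition are
kept but flagged degenerate.

**Traffic and weight.**  Traffic is distance-based (trail length to find
10 workers) rather than rate-based, so it does not depend on walking speed
(temperature-sensitive).  `ants_per_cm = 10/gap`, `total = ants_per_cm ×
length`.  Weight divides the total by the mean population of the connected
nests (internest) or the foraging nest's population (foraging), measuring
trail importance relative to nest size.

**Resource-flow betweenness.**  Shortest paths are computed on the
undirected graph with edge cost `1/weight`: shortest-path algorithms treat
edge values as costs, so strong trails must be cheap.  Choices the
literature leaves open, fixed here:

- endpoints excluded; each unordered pair counted once; equally short
  paths split contribution fractionally (the standard definition);
- all node pairs contribute, trees included — trees sit terminally on
  their own branch, so their own betweenness is structurally zero (a
  warning is logged if an input map violates this);
- zero-weight trails are unusable for flow and are excluded from the
  shortest-path graph (equivalent to infinite cost), with a log message;
- per map, raw values are normalized to the largest *nest* value; if every
  raw value is zero (e.g. no internest trails) all normalized values are
  defined as zero rather than undefined;
- disconnected maps are computed per component with a logged warning.

Display bands for normalized flow: exact 0, exact 1, low (<0.25), medium
(0.25–0.75 inclusive at both ends), high (>0.75).  The inclusive middle is
a deliberate tie-break for the open boundaries.

**Colony-level metrics.**  Foraging effort sums `ants_per_cm × length`
over foraging trails (an effort measure, not a forager count).  The
worker:forager ratio divides total colony population by that effort; high
values mean low foraging effort per worker.  Nest-to-tree distance is
straight-line, not along trails.  Mound-volume→population calibration is
site-specific and must be supplied by the caller; there is no default.

## Identity, events, records

Remappings are blind, so nest identity is resolved spatially: greedy
mutual-nearest-neighbour matching accepting pairs within 2 m (mound
positions are effectively static between seasons; the threshold is
configurable).  Unmatched old nests are abandonments; unmatched new nests
are foundings; nests in the final map are right-censored.  Nests present
at the first map enter at time 0 with unknown prior age (no left-truncation
correction — a stated limitation).

Time is measured in mapping intervals (0–4), not calendar days: intervals
are ecologically comparable (start vs height of the foraging season) and
events are only observed at remapping anyway.  Ties are therefore heavy,
which drives the Efron default below.

Founder inference assumes (i) a newly budded nest stays trail-connected to
its natal nest and (ii) the natal nest is the nearest trail-connected
nest.  If that nearest connected nest is itself new, foundation order is
unknowable and the nearest established nest — Euclidean over all
established nests by default, restrictable to trail-connected — is a
*possible founder*.  A nest that is both founder and possible founder
keeps the founder label.  Trails inherit identity from their linked
endpoint pair.

Survival records are in counting-process form: one `(start, stop]` row per
subject (nest or internest trail) per observed interval, covariates at the
interval start, delayed entry for nests founded mid-study.  Trail rows
carry traffic, weight, trail (edge) betweenness, the lower of the two
endpoint betweenness values, and an indicator that both endpoints survive
the interval.

## Survival: extended Cox + QAP

The partial likelihood over start/stop risk sets is maximized by Newton
iteration with step halving; Efron tie handling by default (Breslow
available) because interval-granularity event times produce heavy ties.
Covariates are centred (coefficients unchanged; baseline hazard estimated
at the covariate means by the Breslow estimator).  Colony enters as a
categorical fixed covariate by default, with stratification as an option.
Errors are explicit: no events, constant covariates (singular
information), and diverging coefficients (monotone likelihood/perfect
separation) each raise a named error.

An optional per-covariate ridge penalty exists for separation-prone
indicators.  The pipeline's trail models use it for the endpoint-survival
indicator: a trail cannot outlive an abandoned endpoint, so that indicator
separates perfectly and its coefficient has no finite maximum.  The
penalty (default 1.0 on that indicator only) keeps refits finite; because
significance comes from the permutation null refitted under the identical
penalty, the test's validity is unaffected.

**QAP.**  The covariate of interest is shuffled uniformly among the
subjects of each colony×timepoint map — never across maps — and the model
refitted; the observed Wald *z* is compared to the null distribution of
*z* (results are conventionally reported as *z*, and *z* is
pivot-like across permutations).  Only the tested covariate is permuted by
default, preserving the observed association structure of co-adjusted
covariates (joint permutation available), matching QAP regression
practice.  The p-value uses the add-one rule `(1 + #extreme)/(1 + B)`,
valid under exchangeability, with floor `1/(B+1)`; the default tail is
two-sided, with directional tails available.  Refits that fail are dropped
and counted; results with >5% failures are flagged unreliable.  A single
seeded generator drives all permutations, so results are exactly
reproducible.

Kaplan–Meier curves use the product-limit estimator with delayed entry;
model-based curves evaluate `S(t|x) = exp(−H0(t))^exp((x−x̄)β)` at a fixed
covariate profile (the package reproduces the low/medium/high flow
profiles 0.1/0.5/0.9).

## Budding: binomial GLMM + analysis of deviance

Founder status is binary, so the three-level status (founder / nonfounder
/ possible founder) needs a coding policy for possible founders, whose
contribution is genuinely unknowable: `exclude` (default), `as_founder`,
`as_nonfounder`.  A harness runs all three and reports whether the
qualitative conclusion is policy-stable.

The model is binomial-logit with random intercepts for colony, nest
identity and season, fitted by Laplace approximation at the joint
penalized mode (the PIRLS scheme lme4 uses at `nAGQ = 0`; verified against
`glmer` to ~1e-3 on fixed effects and log-likelihood).  Season has only
two levels; its variance component is retained and simply estimates to the
boundary when inestimable (boundary fits are flagged, not failed).  All
optimizer settings are pinned constants, so refits are deterministic.
Analysis of deviance compares full vs null fitted on identical rows:
`chisq = 2·Δloglik`, df = fixed-parameter difference, upper-tail
chi-squared p.

**Covariate timing.**  Level covariates are measured at the interval
*start*.  This matters: a newly budded nest is trail-connected to its
founder, so a founder's betweenness measured after the event is
mechanically inflated, and using end-of-interval values makes the null
test anticonservative.  The `d_*` covariates (change over the founding
interval) deliberately include that feedback — they quantify how flow
changed over the period in which the new nest appeared.

## Synthetic colonies

The generator emulates the field design: 13 colonies, five seasonal maps
(summer year 1; spring/summer years 2–3), 2–21 initial nests in a 40 m
arena, trees static across timepoints (honeydew is a spatially and
temporally stable resource), each tree foraged by its nearest nest only
(trees stay terminal), internest structure a Euclidean MST plus
occasional cycle-forming near-neighbour trails.  Populations are lognormal
(`μ = 9.8`, `σ = 1.6` on the log scale, floored at 50), spanning tens of
workers to ~10⁶ as observed across real colonies; populations drift
lognormally (σ = 0.15) and trail sample gaps get seasonal lognormal jitter
(σ = 0.3) between maps.

Dynamics per interval: each nest is abandoned with probability
`logistic(logit(p_a) + b_sb·betweenness + b_ss·z(log pop))`, each survivor
buds with probability `logistic(logit(p_b) + b_bb·betweenness +
b_bd·Δbetweenness)`; the new nest appears 1.5–4 m from its natal nest and
is trail-connected to it, satisfying the founder-inference assumption.
Metrics are recomputed each timepoint, so betweenness feeds back
dynamically as nests appear and disappear.  Defaults: `b_sb = −2`,
`b_bb = +3`, other slopes 0; baselines `p_a = 0.20`, `p_b = 0.025`, chosen
so the *realized* rates (≈0.11 abandonments and ≈0.10 foundings per
nest-interval once the planted effects act on typical betweenness ≈0.4)
and the resulting table size (~500–700 nest records plus a comparable trail
table) match the multi-year field census the defaults emulate.
Covariates are standardized inside the linear predictors (z-scored log
population within colony) so effect sizes are comparable across colony
sizes.  If every nest of a colony draws abandonment in one interval, one
survivor is kept uniformly at random (covariate-independent, so null
calibration is unbiased) and logged.  Colonies may shrink to a single
degenerate nest — extinction-adjacent trajectories occur in the field too.

Every planted event is ledgered (`SimTruth`) with its linear predictor;
identity linkage is exact because nests do not move.

**What the generator does not emulate:** measurement error in populations
and traffic, nest movement between seasons (so identity-linkage accuracy
on real data is untested), shared foraging trees, within-interval timing
of events, spatial habitat heterogeneity, and queen/genetic structure.
Passing tests therefore establish the *statistical machinery* (calibration,
power, bookkeeping, determinism) under the emulated design, not the
robustness of field conclusions to those unmodelled features.

## Problem sizes and tolerances

Null calibration uses 200 replicates of a six-colony design at B = 199
with all planted effects zero, testing p-value uniformity by
Kolmogorov–Smirnov at α = 0.01 — sizes chosen to give a sharp test of
calibration at modest cost.  Power uses 100 replicates at the default
13-colony scale (~500–700 records), requiring detection (p ≤ 0.05) of the
planted −2 survival slope in ≥80% of replicates.  The budding slope is checked against
a colony-level cluster bootstrap percentile interval (60 resamples;
colonies are the exchangeable unit for clustered binary data).  Oracle
comparisons: betweenness vs exhaustive path enumeration (abs 1e-8), Cox
Newton vs grid search at step 0.001 (3 decimals), GLMM vs lme4 (~1e-3),
Kaplan–Meier hand example exact.

## Known limitations

- The Cox fitter reports model-based (Wald) standard errors; no robust
  sandwich variance.  Inference rests on the permutation null instead.
- `nAGQ = 0`-style Laplace slightly attenuates GLMM fixed effects with
  few observations per random-effect level; adequate here because
  conclusions are deviance-based and verified by parameter-recovery
  simulation.
- No frailty/random-effect survival models, no proportional-hazards
  diagnostics beyond event counts, no probabilistic identity model, no
  estimation of within-interval event times.
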