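# Methods

## Model

Scores from a measurement burst are arranged as a fully crossed random
two-facet design: persons *p*, occasions *o*, and items *i*, with

y_poi = μ + a_p + b_o + c_i + (ab)_po + (ac)_pi + (bc)_oi + e_poi,

all effects independent, zero-mean, with variances σ²_p, σ²_o, σ²_i, σ²_po,
σ²_pi, σ²_oi and σ²_e. Two parameterizations of the facets are supported:

- **momentary**: occasion = session; item = trial (single-task analyses) or
  task (composite analyses, trials summed within session first).
- **daily**: occasion = calendar day; the sessions within a day are treated
  as unlabeled replicates of the (person, day, item) cell. The
  session-within-day variation and the three-way interaction are pooled into
  σ²_e. This keeps the daily decomposition on the same seven components as
  the momentary one, which is how the source tables for both timescales are
  laid out.

σ²_po is the *within-person change signal*: it measures how persons differ
in their occasion-to-occasion fluctuations. σ²_e is the noise it must be
detected against.

## Estimators

**Balanced data — expected mean squares.** The seven mean squares of the
crossed layout are equated to their Cornfield–Tukey expectations, e.g.
E[MS_p] = σ²_e + c·r·σ²_po + b·r·σ²_pi + b·c·r·σ²_p for a design with b
occasions, c items and r replicates, and the linear system is solved in
closed form. Negative solutions are truncated to 0, consistent with the
boundary zeros reported for the occasion×item term in the reference tables.
The untruncated solutions are retained (`VarianceComponents.raw`) because
they, not the truncated values, are the unbiased estimates; the unbiasedness
test in the acceptance suite deliberately uses them — truncation biases a
zero-truth component upward by construction.

**Unbalanced data — REML.** Missing sessions (non-compliance) make the
design unbalanced, so the same model is fit by REML on Henderson's
mixed-model equations: a handful of EM warm-up steps, then direct
minimization of the restricted deviance

(n − 1 − q)·log σ²_e + Σ_f q_f log σ²_f + log|M| + y'Py

with analytic gradients, on the log-variance scale (L-BFGS-B). Because the
log-scale gradient vanishes as a component approaches zero, the optimizer
can stall at the boundary even when the optimum is interior; any component
that finishes near the floor is restarted from a clearly interior value and
the lowest-deviance solution is kept. Components below 10⁻⁹ of the total
variance are reported as 0. Missingness is assumed completely at random.

On balanced data the REML solution coincides with the EMS solution whenever
the unconstrained EMS solution is interior (all components nonnegative);
when an EMS component is negative, constrained REML at the boundary
legitimately redistributes the remaining components relative to
truncated-EMS, so estimator-agreement checks are run on instances verified
to be interior. The estimator is cross-checked in the test suite against an
independent REML implementation (lme4, via Rscript) on an unbalanced
instance. The dense linear algebra is intended for burst-sized problems
(hundreds of persons at session level; the MME dimension grows with
persons × occasions, so very large unbalanced designs should be split or
analyzed at the daily level).

## Decision-study coefficients

For a design with m item administrations per occasion and k occasions:

- R_BP = (σ²_p + σ²_pi/m) / (σ²_p + σ²_pi/m + σ²_po/k + σ²_e/(m·k)) —
  consistency of persons' burst means. σ²_pi/m counts as signal because
  stable person×item profiles reproduce across bursts of the same items.
- R_WP = σ²_po / (σ²_po + σ²_e/m) — reliability of within-person change,
  evaluated from the momentary components (m = items per session) or daily
  components (m = items × sessions per day).

Both functional forms were validated against all six published coefficients
(0.17/0.32/0.37/0.48 within-person; 0.96/0.97 between-person) before being
relied on, and those checks are frozen in the acceptance suite.

Properties worth knowing:

- Both coefficients are invariant to rescaling all components by c > 0.
- R_BP is strictly non-decreasing in k. In m it is non-decreasing **iff
  σ²_po·σ²_pi ≤ σ²_e·σ²_p** (differentiating R_BP in m shows the sign of
  dR_BP/dm equals the sign of σ²_e·σ²_p − σ²_po·σ²_pi): adding items dilutes
  the σ²_pi/m signal term, so a design dominated by person×item variance can
  lose between-person reliability as m grows. All published component sets
  satisfy the condition comfortably.
- Incremental R_BP curves re-estimate the components on each person's first
  k sessions (complete-case restricted when the balanced estimator is used)
  and evaluate R_BP at that k; a `fixed_components` mode skips re-estimation
  and gives the pure projection instead.

## Scoring

Partial-credit ("load") scoring credits each recalled item; the default
credit rule requires the correct serial position, the standard convention
for automated complex-span administration. A position-free rule (multiset
intersection of presented and recalled) is available because verbal
descriptions of partial-credit scoring are ambiguous between the two; on
the bundled generators both rules coincide by construction. Composites are
means of per-task z-scores; the standardization pool defaults to all
person-sessions (a person-mean pool is available), and a session yields a
composite only when every configured task is present, to avoid silently
mixing 2- and 3-task composites.

## Synthetic bursts

The generator's defaults are the study conditions themselves: 39 persons,
4 days × 4 sessions, three tasks × two trials (operation span at set sizes
5–6, symmetry and rotation span at 4–5), compliance 15/16 (mean 15 of 16
sessions completed); and 102 persons, 7 days × 5 sessions, one task × three
set-size-5 trials, compliance 29/35. Gaussian-mode truth components are the
published momentary decompositions. Notification schedules anchor the first
session uniformly within 2 h of a wake time drawn uniform 06:00–09:00 (only
the 2-hour anchoring rule is documented, so the wake distribution is a
modeling choice) and space subsequent sessions 3.75 h ± 30 min.

Two modes serve different jobs:

- **gaussian** draws cell scores exactly from the ANOVA model above, so the
  estimators' statistical properties can be verified against known truth.
  Scores are continuous by default (`discretize` rounds and clips them).
  `exact_marginals=True` centers and rescales each effect vector to its
  nominal variance; this matters for parameter-recovery checks because a
  facet with 3 levels identifies its component with only 2 degrees of
  freedom — under unconstrained draws the realized item variance is a
  ~100%-relative-SD draw and no estimator could recover the nominal value
  tightly. Recovery tests use matched draws; unbiasedness tests use plain
  iid draws, since unbiasedness is a statement about the expectation over
  draws.
- **mechanistic** simulates each memorandum as a Bernoulli recall with
  log-odds (intercept + trait + day drift + occasion state − slope·(set
  size − 5)), plus a small guessing floor, and emits presented/recalled
  token sequences whose position-strict score equals the recorded trial
  score (failed positions become out-of-set intruders or are truncated from
  the end of the response). Defaults (trait SD 0.9, occasion SD 0.55, day
  SD 0.25, intercept 1.2, slope 0.35) put accuracy near 75% and the
  session-score ICC near 0.5, the mid-range of values reported for such
  tasks.

What the generators do **not** emulate: practice/fatigue trends, secondary-
task performance and response times, non-random missingness (compliance is
MCAR), floor/ceiling discreteness of real span scores (gaussian mode), and
serial correlation of occasion states. Passing recovery tests therefore
show the estimators are correct under the model's own assumptions, not that
real burst data satisfy those assumptions.

## Numerical and design choices

- Monte-Carlo test sizes are chosen to keep each check's sampling error
  well inside its asserted tolerance: recovery at 1000 persons × 15
  occasions × 3 items; unbiasedness over 200 replicates at 100 persons;
  missing-data REML recovery at 80 persons with a tolerance set from the
  large-sample sampling SD of σ̂²_p at that size (~20%, so a 2-SD band of
  40%) rather than from the large-n figure.
- Published coefficients are compared after round-half-up to the printed
  precision (2 decimals; the doubled-items projection to 1).
- Criterion scores are generated as r·z(trait) + √(1−r²)·noise, so
  configured population correlations are exact; the incremental criterion
  correlation is checked against the Spearman attenuation law
  r(k) ≈ ρ·√R_BP(k) (exact up to the small σ²_pi/m signal share).
- Sessions are ordered by timestamp when present, else by (day, slot);
  "first k sessions" counts any session with at least one completed trial.
  All indices are 1-based on disk.
- Degenerate inputs: constant data yield all-zero components with a
  warning; a zero-variance task raises rather than emitting infinite
  z-scores; blocks with a single set size pass through the lowest-set-size
  filter unchanged with a warning.

## Known limitations

- The REML estimator's dense linear algebra limits unbalanced session-level
  fits to roughly a few hundred persons; daily-level fits scale further.
- Confidence intervals for components and reliability coefficients are out
  of scope, as are multi-facet designs beyond p × o × i and latent-variable
  (factor) models of the task battery.
- The daily parameterization discards session labels within a day; designs
  where session-of-day effects are systematic would need a third facet.
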