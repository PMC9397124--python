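# Methods

`painflow` implements a time-resolved analysis of brain-network integration
and segregation around evoked painful pressure, together with a synthetic
study generator that makes every stage of the analysis verifiable without
access to real fMRI data.  This note documents the models, the parameters
that matter, the numerical choices, and the limits of what the synthetic
validation shows.

## The analysis chain

The pipeline consumes parcellated BOLD time series (node x TR matrices, one
per run), fMRIPrep-dialect confound tables, BIDS-style event tables, a
static node-to-community partition, and a study manifest.  Stages:

1. **QC run exclusion.**  A run whose mean framewise displacement (FD)
   strictly exceeds 0.5 is discarded.  FD follows the Power convention: the
   sum of absolute backward differences of the six rigid-body motion
   parameters, rotations converted to arc length on a 50 mm sphere.

2. **Confound regression.**  Each node series is OLS-residualized on the
   full confound set — six motion parameters, their backward-difference
   derivatives, six anatomical-noise components, white matter, CSF, FD —
   plus an intercept.  The intercept is always included so residuals are
   mean-zero, a prerequisite for correlation-based connectivity.  Exact
   duplicate and constant confound columns are dropped; any remaining rank
   deficiency is an error naming the collinear columns.  No temporal
   filtering, despiking, or scrubbing is applied.

3. **Jackknife-correlation connectivity.**  For each node pair (i, j) and
   time point t, the estimate is the Pearson correlation of the two series
   over all time points *except* t, multiplied by -1:

       JC_t(i, j) = -corr( {x_s}_{s != t}, {y_s}_{s != t} )

   Removing a time point at which the two series co-fluctuate strongly
   lowers the leave-one-out correlation, so after negation a strongly
   coupled time point maps to a relatively high value; the sign flip
   restores "positive association at t -> positive estimate at t".
   Implementation: per-node centering and unit-norm scaling (to which
   correlation is invariant) reduce the leave-one-out correlation to a
   rank-one update of the full Gram matrix, computed for all t in one
   vectorized pass; this is exact (it agrees with a literal delete-one-column
   computation to ~1e-15) and makes a 70-node, 160-TR run cost ~10 ms.
   An edge-timepoint whose leave-one-out sub-series has (numerically) zero
   variance is NaN, and NaN propagates as *missing* into all downstream
   metrics — zero-filling would bias the participation coefficient.

4. **Flow standardization.**  Each edge's jackknife series is z-scored
   (sample SD) across its own run's TRs.  Within-run scope is the only one
   that respects run independence; the population/sample SD choice is a
   constant factor absorbed by the standardization.  A constant edge series
   is flagged undefined rather than standardized.

5. **Network metrics per TR.**  Against a static partition (the seven
   canonical communities by default):

   * participation coefficient `PC_i = 1 - sum_s (k_is / k_i)^2`, with
     `k_is` node i's *positive* strength into community s and `k_i` its
     total positive strength.  `k_i = 0` gives PC = 0 (an isolated node
     participates in no community).  Bounds: 0 <= PC <= 1 - 1/M for M
     communities.
   * within-module degree z-score `z_i = (k_i - mean_s(k)) / sd_s(k)`,
     where `k_i` is strength restricted to the node's own community and the
     moments (population SD) are taken over that community's members at the
     same TR.  Each community's z therefore averages to exactly 0 at every
     TR; a community with zero spread (including singletons) gets z = 0.

   The positive-edge rule is applied to both metrics for consistent
   "strength" semantics; a `z_signed` switch retains negative weights in z
   for sensitivity analyses.  Because the metrics consume standardized
   flow, "positive" means above that edge's own temporal mean — roughly
   half of each edge's series at any TR.

   Community-level series are the *medians* of PC or z over each
   community's member nodes (the mean of z is identically zero, the median
   is not); the nodal level extracts a configured list of single nodes.

6. **Event-locked binning.**  Each stimulus onset maps to the TR during
   which stimulation begins (floor of onset / TR; onsets are jittered and
   never align with TR boundaries).  Around each onset TR o the six bins
   {o-2 ... o+3} are extracted, for painful events only.  Trials whose
   window leaves the run are dropped, never padded.  Averaging is nested:
   trials within run, then the site's two runs (a subject left with one
   run after QC still contributes, flagged); a pooled-trials mode exists
   for sensitivity checks.  Pre-onset bins (-2, -1) are computed and
   plotted but excluded from statistics.

7. **Group statistics.**  Per unit (community or node) and per analysed bin
   (0, +1, +2, +3), each treated separately:

   * *Group contrast* (patients vs controls, at the disease-relevant site):
     one-way ANCOVA, metric ~ group + age, with the group effect tested by
     Type II sums of squares — the extra sum of squares of group after age
     over the full-model residual mean square, F(1, n-3).  Type II is the
     appropriate attribution for the unbalanced design.  Age is
     mean-centered (conditioning only).
   * *Site contrast* (joint vs thumb, within patients): linear mixed model
     with site and age as fixed effects, a random intercept per subject and
     an independent intercept per site within subject, fitted by REML with
     the Powell optimizer (L-BFGS fallback when the weakly identified site
     variance component makes the Hessian singular mid-fit); the site
     effect uses the asymptotic Wald test.  Non-converged cells are
     reported but excluded from the FDR family.

   Raw p-values are adjusted by the Benjamini-Hochberg step-up rule.  The
   default family is all units x analysed bins of one
   metric/level/contrast table (7 x 4 = 28 at the community level); the
   family size is configurable because the correction family is a
   declaration, not a derived quantity.

Everything is orchestrated by `run_all`, which writes long-format TSVs, a
provenance record (config hash, seed, version), and stamps every output
table with the configuration hash so outputs of different configurations
cannot be silently mixed.  The whole chain is deterministic given inputs
and configuration.

## The synthetic study generator

The generator emulates the study design the pipeline targets: 28 patients
and 22 controls (ages uniform on 23-72), four runs per subject (two
stimulation sites x two runs), 160 volumes at TR = 3 s, and per run 30
pressure events (15 painful, 15 non-painful, 2.5 s duration) with
inter-onset intervals uniform on 10-20 s (mean 15 s).  Schedules are
rejection-sampled so the last onset leaves a full post-stimulus window,
keeping intervals uniform conditional on fitting the run; an
`allow_edge_events` override permits boundary events to exercise the
trial-dropping rule.

Signals follow a modular factor model: node i in community c at TR t is

    x_i(t) = sqrt(a(t)) g(t) + sqrt(b(t)) f_c(t) + sqrt(w) m(t)
             + sqrt(1 - within_r - w) eps_i(t)

with unit-variance white factors (g global, f_c per community, m a motion
composite with weight w = `confound_loading`, eps node noise), baseline
a = `between_r` and b = `within_r - a`.  Pairs therefore correlate at
`within_r` within and `between_r` between communities.

**Event boost.**  For the closed TR window
[onset + `hemo_lag_trs`, onset + `hemo_lag_trs` + `boost_window_trs`] after
each *painful* onset, a(t) is raised by the group's boost and b(t) lowered
in step.  This is a coupling *reallocation*: between-community correlation
rises to `between_r + boost` while within-community correlation stays at
`within_r`.  The distinction matters: a boost that raised the global factor
without lowering the community factor would elevate within- and
between-community coupling together, and after per-edge standardization the
participation coefficient — which measures the *relative* spread of a
node's strength across communities — would not move.  The reallocation
injects exactly the quantity the analysis is designed to detect: a
transient shift toward integration.  Validity constraint:
`between_r + boost <= within_r`.

Defaults: `within_r` 0.35, `between_r` 0.05, boost 0.15 (patients) and 0.05
(controls), `hemo_lag_trs` 1 and `boost_window_trs` 2, so TRs +1..+3 after
the onset TR are boosted — a crude stand-in for hemodynamic delay chosen to
land the injected effect in the post-onset analysis bins.  The boost
magnitudes are calibration knobs for verifying the pipeline's sensitivity,
not estimates of any real effect size.  Confounds are smooth AR(1) motion
series (plus derivatives, six white-noise component regressors, AR(1)
white-matter/CSF series) with FD computed from the motion; a bad-run flag
inflates motion ~8x so mean FD exceeds 0.5.

**What the generator does not emulate:** hemodynamic response convolution
(the factor model controls connectivity directly, because connectivity is
what the analysis consumes), physiological noise structure, spatial
autocorrelation within parcels, non-painful-specific responses (non-painful
events modulate nothing; they exist to exercise the condition filter), and
any realistic group difference in age or motion.  Passing tests on this
generator therefore certify the *pipeline machinery* — estimators,
contracts, calibration, power against a known injected effect — not claims
about real BOLD data.

## Monte-Carlo calibration and power

`painflow.calibration` runs study-level experiments at a reduced size (12
patients, 12 controls, 70 nodes; full run geometry) so hundreds of
replicates fit on one CPU:

* **Null calibration** (zero boost in both groups): raw ANCOVA rejections
  of the community-PC group contrast occur at the nominal 5% rate, and the
  28-cell BH family produces at least one false discovery in about 5% of
  studies — under a global null, BH's false-discovery rate equals the
  familywise any-rejection rate, so that is the rate the nominal level
  pins down.  (Per-cell BH rejection counts are far below 5% by
  construction; that is the correction working, not miscalibration.)
* **Effect recovery** (patient-only boost 0.15): the community-median PC
  group contrast is FDR-significant at the boosted bins in the large
  majority of replicates, and detections concentrate at bins +1..+3 (the
  lag-shifted boost window) rather than the onset bin — the detected-bin
  pattern tracks the injected hemodynamic lag.

Small-sample caveat: the mixed model's Wald p is mildly anti-conservative
at ~30 subjects (empirically ~0.067 at nominal 0.05); its calibration test
runs at 60 subjects where the asymptotic reference is adequate.  A
degrees-of-freedom correction (e.g. Satterthwaite) would remove this but is
not part of the estimation approach implemented here.

## Numerical choices and degenerate inputs

* Leave-one-out variances below 1e-12 (in unit-norm coordinates), node
  series whose centered norm is below ~1e-14 of their amplitude, and
  constant edge series are flagged undefined (NaN), never silently zero.
* Jackknife values are clipped to [-1, 1] against rounding excursions.
* Symmetry of connectivity slices is enforced to 1e-8 at the public API;
  tensors produced by the package's own standardization skip the recheck.
* ANCOVA returns F = 0 when the group extra sum of squares is itself
  numerically zero (no between-group signal, including all-identical
  input); zero residual variance with nonzero group signal is an error.
* An all-identical mixed-model cell short-circuits to a flagged degenerate
  result (estimate 0, variance components 0) without fitting.
* BH adjustment with a declared family larger than the observed vector
  treats the unobserved members as non-discoveries (they only enter
  through the family size m).

## Problem sizes

Default test and acceptance runs use reduced studies (12+12 subjects x 4
runs x 160 TRs x 70 nodes for the Monte-Carlo experiments; a few hundred
replicates), chosen so the full verification battery completes in minutes
on a single CPU while keeping the run geometry of the emulated design.
The estimators themselves are exercised at full 400-node scale in the
shape tests.

## Known limitations

* The jackknife estimate at time t is a global quantity perturbed by one
  time point; per-edge standardization is what turns its small temporal
  fluctuations into usable effect sizes.  Consequently flow has no
  absolute scale and levels are not comparable across edges — only
  event-locked *changes* are interpretable, which is how the pipeline uses
  them.
* Static partition: integration/segregation are measured against fixed
  communities; dynamic community reassignment is out of scope.
* The FDR family is a configuration choice; published analyses may have
  used a different (larger) family, so adjusted p-values are comparable
  only within a declared family.
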