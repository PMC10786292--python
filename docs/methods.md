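# Methods

## Connectome model and edge set

Nodes are the regions of a bilateral parcellation: cortical language
regions (inferior frontal gyrus, temporal lobe, inferior parietal lobe)
plus anterior/posterior corpus-callosum (CC) waypoints, 33 cortical + 5 CC
per hemisphere in the default table. The packaged region list is a
synthetic stand-in with the correct per-system structure; any table with
equal left/right counts is accepted.

Candidate edges are (i) intra-hemispheric cortical–cortical pairs in each
hemisphere and (ii) every cortical-to-CC pair. Direct interhemispheric
cortical–cortical pairs are excluded because tractography cannot estimate
them reliably; CC–CC pairs are excluded as anatomically meaningless.
Cortical regions may pair with all 10 CC regions — thresholding prunes
implausible combinations. For the default table this yields
2·C(33,2) + 66·10 = 1,716 candidates.

Directed duplicate entries in input tables are symmetrized by their mean
(tractography is direction-asymmetric; the network is modeled undirected).
Unlisted pairs are zero. Weights are arbitrary nonnegative values; no
normalization is applied.

**Thresholding.** One group-level mask: candidate edges ranked by mean
weight over *all* (participant, timepoint) matrices, the top
`round(f·n_candidates)` retained (default f = 0.30, half-up rounding).
Rank ties are broken toward the lexicographically smaller region pair so
the mask is reproducible. A group-level (rather than per-subject or
per-timepoint) mask is required for comparing the same edges across
timepoints; applying it after pooling timepoints avoids selection bias
toward any one session.

**Summaries.** Left/right strength = sum of retained intra-hemispheric
cortical–cortical weights; interhemispheric strength = sum of retained
cortical-to-CC weights; LI = (L − R)/(L + R) (0 when both are 0), the
standard laterality quotient.

## Mixed-effects models

All longitudinal tests use a participant random intercept, REML
estimation, and treatment coding of time against the earliest level:

* `y ~ time + (1|participant)` — time categorical over the measured months;
* `y ~ score + (1|participant)` — proficiency as a continuous fixed effect
  over months 3 and 6 (scores exist only there).

Participants missing a timepoint contribute their available observations.
Period contrasts (0→3, 3→6, 0→6) are releveled two-timepoint refits, so
each reported t is the later-timepoint coefficient of a model restricted
to that pair. Reported p-values use a t reference with residual degrees of
freedom `n_obs − rank(X)`; mixed-model software differs in this convention
(Satterthwaite, containment, z), so t statistics are the primary
quantities and the convention is configurable.

Single-response fits (hemispheric strengths, behavior) go through
statsmodels `MixedLM`. Edge-wise and permutation fits use an internal
vectorized engine that profiles the variance ratio θ = τ²/σ²: for fixed θ
the GLS solution is a closed form over per-subject sufficient statistics,
and the REML criterion is minimized per edge by a coarse log grid
(θ ∈ {0} ∪ [10⁻⁶, 10⁵], 34 points) plus ~16–28 golden-section refinements.
The engine agrees with statsmodels to ≈4 significant digits (tested) and
makes K-permutation NBS runs over hundreds of edges desk-fast.

**Balanced fast path.** When every participant is observed exactly once at
every level, REML is closed-form: treatment contrasts are level-mean
differences with variance 2σ̂²/n, where σ̂² is the subject×time interaction
mean square when the subject-variance estimate is interior, and the pooled
OLS residual variance when it is truncated at zero. With two levels and an
interior estimate this *equals* the paired t statistic exactly — the
oracle equivalence the test suite asserts to 10⁻⁶. Degenerate responses
(zero variance) are flagged and reported with t = 0, p = 1 rather than
aborting a batch.

## Network-based statistic

Edges with model p below the primary threshold (default 0.01) and a common
sign form a graph; connected components are the candidate subnetworks,
scored by extent (edge count; intensity = Σ|t| is available). For the
three-timepoint omnibus model an edge enters if *either* baseline contrast
passes the threshold, and its sign is that of the strongest contrast —
post-hoc two-timepoint contrasts (p < 0.05) then localize each component
edge to the learning period(s) in which it changed.

The permutation null records, per permutation, the maximal component
statistic pooled over both signs, giving two-sided FWE control;
`p_fwe = (1 + #{null ≥ observed})/(K + 1)`, which can never fall below
1/(K+1). Defaults: K = 5,000, α = 0.05; analyses in the examples and
acceptance script use K = 500, which resolves p_fwe down to 0.002 and
keeps a full run in the low minutes on one core.

Permutation schemes (exchangeability under H0):

* **Time model** — timepoint labels are permuted within each participant,
  respecting that participant's observed sessions. Given the random
  intercept, a participant's observations are exchangeable across time
  under H0; the scheme also preserves balance, so the fast path applies to
  every permutation.
* **Score model** — whole score trajectories are swapped between
  participants with identical timepoint availability. This preserves each
  participant's within-person score ordering (everyone improves) while
  breaking brain–behavior coupling.

A consequence of the score scheme worth stating: a *group-mean* trend on an
edge (everyone's connectivity rises while everyone's score rises) produces
the same edge statistic under every permutation, so it cannot generate
extent-based score-NBS significance — only between-participant coupling
(participants who change more improve more) can. This is the intended
inferential target; it also means subnetworks carrying a strong common
learning trend can be significant in the time-NBS yet null in the
score-NBS, as happens for the packaged study-style cohort.

## Synthetic cohort generator

Weight of edge e, participant p, month t:

    w = max(0, base_e + a_p·[e left-cortical] + b_p + Σ planted shifts + ε)

with `base_e ~ N(μ₀, σ₀²)` drawn once per cohort (defaults 1.0, 0.25),
`b_p ~ N(0, 0.15²)` a participant intercept, `ε ~ N(0, 0.10²)` residual
noise, and `a_p ~ N(0.08, 0.075²)` each participant's left-hemisphere
offset. Making the asymmetry participant-varying keeps the group paired t
at a realistic magnitude; a purely deterministic offset would be detected
with implausibly extreme statistics. A log-normal weight option exists;
the truncated-normal default keeps planted effects interpretable as
standardized mean shifts (truncation is negligible at the default weight
scale).

Planted effects are connected edge sets with a per-period standardized
shift: `(magnitude + u_p)·noise_sd·sign`, active from month 3 (first
period, persistent), month 6 (second period), or accumulating (both);
`u_p ~ N(0, subject_sd²)` is shared across the effect's edges and models
individual differences in plasticity. Effects are planted on robustly
retained edges (chosen from a thresholded null cohort with a margin above
the cutoff) — otherwise most planted edges would fall outside the analyzed
network. The default study configuration plants a 20-edge second-period
interhemispheric decrease (magnitude 1.2), an 8-edge right-hemispheric
increase (1.0) and a 4-edge first-period decrease (0.6).

Dropout is missing-at-random: a seeded random subset of participants is
removed from later timepoints (default 59 → 59 → 51).

**Scores.** Month-3 scores are `N(50, 8²)` on an arbitrary scale; the 3→6
gain is `gain_mean + κ·z_p + N(0, gain_sd)` clipped at a small positive
floor, so *every* participant improves. `z_p` is the participant's
standardized realized change on the coupling edges, giving expected
gain–change correlation `κ/√(κ² + gain_sd²)`; `coupling_for_target_r`
inverts this. A vocabulary measure at month 6 is calibrated to correlate
r ≈ 0.5 with the month-6 score and drives the above/below-mean subgroup
split. The score-NBS power benchmark uses a cohort where individual
differences dominate (planted magnitude 0.2, subject_sd 3.0, month-3 score
sd 2.0 — beginners starting from a common level — coupling target 0.85);
these conditions were calibrated once so that recovery is well-posed under
the trajectory-permutation null, and then frozen.

Everything is deterministic given the config seed (independent SeedSequence
streams for weights, dropout, scores, vocabulary); the pipeline fans a
single global seed out to per-stage seeds the same way.

## What the simulations do and do not show

The generator reproduces the *statistical* structure the analysis assumes:
random intercepts, unbalanced dropout, planted connected effects,
monotone behavioral gains with tunable coupling. It does not emulate
tractography's weight distributions (streamline-count skew,
distance-dependence), spatial autocorrelation of edges, or scanner/session
effects. Passing tests therefore validate the inference machinery — FWE
calibration, power against planted truths, oracle equivalences — not the
biological claims one could draw from real cohorts.

Problem sizes used in the packaged experiments: the FWE study runs 200
null cohorts (20 regions, n = 20, K = 200); power studies use n = 40 with
K = 500 and 20–50 replicates; the acceptance script analyzes the full
76-region, 59-participant cohort with K = 500. These sizes make the whole
suite reproducible in minutes on a single core while leaving the binomial
Monte-Carlo intervals tight enough to be informative.

## Known limitations

* Only random intercepts: no random slopes, crossed effects, or nonlinear
  learning-curve models.
* The residual-df t convention can differ slightly from Satterthwaite
  approximations in heavily unbalanced designs.
* Extent-based score-NBS is blind to purely common-trend associations by
  construction (see above); use the intensity statistic when the excess
  strength of a trend matters.
* The permutation null assumes within-participant exchangeability of
  timepoints under H0 (compound symmetry); serially correlated residuals
  would make it approximate.
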