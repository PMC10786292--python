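# plastconn

Statistics for longitudinal plasticity of the structural language
connectome: hemispheric strength and lateralization summaries, edge-wise
linear mixed-effects models, network-based statistics (NBS) with
permutation family-wise-error control, post-hoc learning-period contrasts,
behavior–connectivity subnetworks, and a synthetic longitudinal cohort
generator that makes every stage testable without imaging data.

## The scientific problem

Learning a second language in adulthood reorganizes the white-matter
language network. A typical longitudinal design measures each participant's
structural connectome (region-pair connectivity from diffusion
tractography) at baseline and after two successive learning periods
(months 0, 3, 6), together with proficiency scores. The questions are:

1. Is the language network left-lateralized, and does lateralization change?
2. Does interhemispheric (transcallosal) connectivity change with learning,
   and in which period?
3. Which connected subnetworks change over time, and are those changes
   coupled to behavioral improvement?

`plastconn` implements the statistical machinery for all three on a
bilateral parcellation of 33 cortical + 5 corpus-callosum (CC) regions per
hemisphere (76 regions). Because tractography cannot robustly estimate
direct cortico-cortical connections across hemispheres, cortical-to-CC
edges serve as the interhemispheric approximation; CC–CC and direct
cross-hemisphere cortical pairs are excluded, giving 1,716 candidate edges.
A single group-level threshold retains the strongest 30% of candidate edges
(by mean weight over all participants and timepoints) so the same edge set
is compared longitudinally.

## Models and statistics

**Edge-wise mixed model.** For each retained edge, connectivity is modeled
with a participant random intercept:

    y ~ time + (1 | participant)        (time categorical, baseline-coded)
    y ~ score + (1 | participant)       (proficiency at months 3 and 6)

fitted by REML. Dropout (participants missing later timepoints) is handled
as unbalanced data. Reported t statistics use residual degrees of freedom
`n_obs − rank(X)` (configurable).

**Network-based statistic.** Edges with model p < 0.01 form signed graphs
(increase/decrease, or positive/negative score association); connected
components are scored by extent (edge count). The null distribution of the
maximal component (pooled over both signs) comes from K permutations —
timepoint labels shuffled within participants for the time model, whole
score trajectories swapped between participants for the score model — and
each observed component receives `p_fwe = (1 + #{null ≥ obs}) / (K + 1)`.

**Summaries.** Hemispheric strength is the sum of retained intra-hemispheric
cortical–cortical weights; interhemispheric strength sums retained
cortical-to-CC weights; the lateralization index is LI = (L − R)/(L + R).
Lateralization is tested by paired t per timepoint; strength trajectories
by the time LME with 0→3, 3→6 and 0→6 contrasts.

## Worked example

```bash
cd examples
python 01_simulate_cohort.py      # writes cohort_demo/
python 02_lateralization_summary.py
python 03_time_nbs.py
```

The simulated cohort has 59 participants (51 completing month 6) with a
planted second-period interhemispheric decrease and right-hemispheric
increase. The summary prints:

```
left-vs-right paired t (positive = left-lateralized):
  month 0: t =  27.79  (n = 59, p = 3.3e-35)
  month 3: t =  27.21  (n = 59, p = 1e-34)
  month 6: t =  24.79  (n = 51, p = 9.5e-30)

interhemispheric strength over time (LME contrasts):
   0->3 months: t =   1.30  (p = 0.19)
   0->6 months: t =  -9.36  (p = 1.3e-15)
   3->6 months: t =  -9.43  (p = 9.4e-16)
```

i.e. a stably left-lateralized network whose transcallosal connectivity is
unchanged in the first period and drops sharply in the second. The NBS
stage then localizes the change to subnetworks:

```
omnibus subnetworks (direction, extent, p_fwe):
 * decrease extent= 24  p_fwe=0.0020
 * increase extent=  8  p_fwe=0.0020

post-hoc period localization:
  months 3->6: decrease  21 edges  (mean t = -6.56)
  months 3->6: increase   8 edges  (mean t =  4.97)
```

— both planted subnetworks recovered, with the effects correctly assigned
to the second learning period. `04_score_nbs.py` shows the score model
recovering a behavior-coupled subnetwork (8/8 planted edges,
p_fwe = 0.002), and `05_full_pipeline.py` runs everything from files into a
deterministic JSON report.

A thin CLI wraps the same functions: `plastconn simulate`, `plastconn
summarize`, `plastconn nbs`, `plastconn report` (see `--help`).

## Documentation

`docs/methods.md` describes the generative model of the synthetic cohort,
the REML engine and permutation schemes, numerical conventions, and known
limitations.
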