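"""Omnibus NBS over time plus post-hoc period localization.

Edge-wise random-intercept models (connectivity ~ time) feed a
network-based statistic: connected components of edges with p < 0.01 are
scored by extent and compared against a permutation null (timepoint labels
shuffled within participants) for family-wise error control.  Post-hoc
two-timepoint contrasts assign each surviving edge to the learning period
in which it changed.
"""

import plastconn as pc

regions = pc.language_parcellation()
config = pc.study_config(regions, seed=1)
data = pc.simulate_connectomes(config, regions)
mask = pc.group_threshold(data, 0.30)

nets = pc.nbs_test(data, mask, pc.ModelSpec("time"),
                   pc.NBSConfig(p_threshold=0.01, n_permutations=500,
                                alpha=0.05, seed=2))
print("omnibus subnetworks (direction, extent, p_fwe):")
for s in nets[:5]:
    flag = "*" if s.significant else " "
    print(f" {flag} {s.direction:8s} extent={s.extent:3d}  "
          f"p_fwe={s.p_fwe:.4f}")

sig = [s for s in nets if s.significant]
period = pc.posthoc_adjacent(data, mask, sig, alpha=0.05)
print("\npost-hoc period localization:")
for s in period:
    print(f"  months {s.period[0]}->{s.period[1]}: {s.direction:8s} "
          f"{s.extent:3d} edges  (mean t = {s.mean_t:5.2f})")
# Significant decreases concentrated in months 3->6 reproduce the planted
# second-period interhemispheric drop; the increase is the planted
# right-hemispheric subnetwork.
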