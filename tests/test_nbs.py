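import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import plastconn as pc
from plastconn.nbs import (
    NBSError,
    _edge_endpoint_codes,
    _uf_max_stat,
    suprathreshold_components,
)

from conftest import random_cohort


def stat_map(edges, tvals, pvals, kind="time"):
    E = len(edges)
    return pc.EdgeStatMap(
        edges=tuple(edges),
        contrasts=("time[3]",) if kind == "time" else ("score",),
        estimate=np.asarray(tvals, float).reshape(E, 1),
        tstat=np.asarray(tvals, float).reshape(E, 1),
        pval=np.asarray(pvals, float).reshape(E, 1),
        ok=np.ones(E, bool),
        df=20.0,
        spec=pc.ModelSpec(kind),
    )


class TestSuprathresholdComponents:
    def test_path_graph(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
        stats = stat_map(edges, [3.0] * 4, [0.001] * 4)
        comps = suprathreshold_components(stats, 0.01, "increase")
        assert len(comps) == 1
        assert comps[0]["extent"] == 4

    def test_two_disjoint_triangles(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"),
                 ("x", "y"), ("y", "z"), ("x", "z")]
        stats = stat_map(edges, [-2.9] * 6, [0.004] * 6)
        comps = suprathreshold_components(stats, 0.01, "decrease")
        assert [c["extent"] for c in comps] == [3, 3]
        assert suprathreshold_components(stats, 0.01, "increase") == []

    def test_oracle_equivalence_random_graphs(self):
        """Components match a brute-force union-find over <=12-node graphs."""
        rng = np.random.default_rng(40)
        for _ in range(25):
            nodes = [f"n{k}" for k in range(rng.integers(4, 13))]
            pairs = [tuple(sorted(p)) for p in
                     {tuple(sorted(rng.choice(nodes, 2, replace=False)))
                      for _ in range(rng.integers(3, 20))}]
            pairs = sorted(pairs)
            t = rng.normal(0, 3, len(pairs))
            p = rng.random(len(pairs)) * 0.2
            stats = stat_map(pairs, t, p)
            for direction, sign in (("increase", 1), ("decrease", -1)):
                comps = suprathreshold_components(stats, 0.05, direction)
                sel = [e for e, tv, pv in zip(pairs, t, p)
                       if pv < 0.05 and np.sign(tv) == sign]
                g = nx.Graph(sel)
                expected = sorted(
                    (len(g.subgraph(c).edges) for c in
                     nx.connected_components(g)), reverse=True)
                assert [c["extent"] for c in comps] == expected
                # and the union-find max-stat agrees with networkx
                if sel:
                    u, v = _edge_endpoint_codes(sel)
                    assert _uf_max_stat(u, v, np.ones(len(sel))) == expected[0]


@pytest.fixture(scope="module")
def planted(toy_regions):
    cfg, edges = pc.recovery_benchmark_config(toy_regions, seed=55)
    data = pc.simulate_connectomes(cfg, toy_regions)
    mask = pc.group_threshold(data, 0.30)
    return data, mask, edges


class TestNBSTest:
    def test_planted_edges_have_extreme_t(self, planted):
        data, mask, edges = planted
        stats = pc.edgewise_stats(data, mask, pc.ModelSpec("time"))
        t, _ = stats.primary()
        sel = np.array([e in set(edges) for e in stats.edges])
        assert np.median(np.abs(t[sel])) > np.median(np.abs(t[~sel]))

    def test_recovery_and_determinism(self, planted):
        data, mask, edges = planted
        cfg = pc.NBSConfig(n_permutations=200, seed=9)
        a = pc.nbs_test(data, mask, pc.ModelSpec("time"), cfg)
        b = pc.nbs_test(data, mask, pc.ModelSpec("time"), cfg)
        assert [(s.edges, s.p_fwe) for s in a] == [(s.edges, s.p_fwe)
                                                   for s in b]
        sig = [s for s in a if s.significant and s.direction == "decrease"]
        assert sig and set(edges) <= set(sig[0].edges) | set(edges)
        assert len(set(sig[0].edges) & set(edges)) >= 6

    def test_p_fwe_floor(self, planted):
        data, mask, _ = planted
        res = pc.nbs_test(data, mask, pc.ModelSpec("time"),
                          pc.NBSConfig(n_permutations=50, seed=1))
        assert all(s.p_fwe >= 1 / 51 for s in res)

    def test_k1_pvalues(self, planted):
        data, mask, _ = planted
        with pytest.warns(UserWarning, match="cannot reach"):
            res = pc.nbs_test(data, mask, pc.ModelSpec("time"),
                              pc.NBSConfig(n_permutations=1, seed=2))
        assert res and all(s.p_fwe in (0.5, 1.0) for s in res)

    def test_threshold_monotonicity(self, planted):
        """Lowering p_threshold never grows any component."""
        data, mask, _ = planted
        stats = pc.edgewise_stats(data, mask, pc.ModelSpec("time"))
        for direction in ("increase", "decrease"):
            loose = suprathreshold_components(stats, 0.05, direction)
            strict = suprathreshold_components(stats, 0.005, direction)
            loose_edges = {e for c in loose for e in c["edges"]}
            strict_edges = {e for c in strict for e in c["edges"]}
            assert strict_edges <= loose_edges
            if strict and loose:
                assert strict[0]["extent"] <= loose[0]["extent"]

    def test_empty_mask_rejected(self, toy_regions, small_cohort):
        _, data = small_cohort
        mask = pc.group_threshold(data, 0.3)
        empty = dataclasses.replace(mask, edges=())
        with pytest.raises(NBSError, match="empty"):
            pc.edgewise_stats(data, empty, pc.ModelSpec("time"))

    def test_constant_edge_flagged(self, toy_regions):
        data = random_cohort(toy_regions, 8, (0, 3, 6), seed=60)
        mask = pc.group_threshold(data, 0.3)
        i, j = (toy_regions.position(mask.edges[0][0]),
                toy_regions.position(mask.edges[0][1]))
        for m in data.matrices.values():
            m[i, j] = m[j, i] = 5.0  # saturate one retained edge
        stats = pc.edgewise_stats(data, mask, pc.ModelSpec("time"))
        assert not stats.ok[0]
        _, p = stats.primary()
        assert p[0] == 1.0


class TestPosthoc:
    def test_period_localization(self, toy_regions):
        cfg, edges = pc.recovery_benchmark_config(toy_regions, seed=70)
        data = pc.simulate_connectomes(cfg, toy_regions)
        mask = pc.group_threshold(data, 0.30)
        nets = pc.nbs_test(data, mask, pc.ModelSpec("time"),
                           pc.NBSConfig(n_permutations=100, seed=3))
        sig = [s for s in nets if s.significant]
        period = pc.posthoc_adjacent(data, mask, sig)
        hits = {(s.period, s.direction): s.extent for s in period}
        # effect planted in the second period only
        second = hits.get(((3, 6), "decrease"), 0)
        first = hits.get(((0, 3), "decrease"), 0)
        assert second >= 0.5 * len(edges)
        assert first <= 2

    def test_no_change_data_empty(self, toy_regions):
        cfg = pc.SimulationConfig(n_participants=10,
                                  dropout_per_period=(0, 0),
                                  subject_sd=0.3, noise_sd=0.0,
                                  asymmetry_subject_sd=0.0, seed=71)
        data = pc.simulate_connectomes(cfg, toy_regions)
        mask = pc.group_threshold(data, 0.3)
        comp = pc.SubnetworkResult(edges=mask.edges[:5], direction="increase",
                                   statistic_value=5, p_fwe=0.01,
                                   component_statistic="extent", mean_t=1.0)
        assert pc.posthoc_adjacent(data, mask, [comp]) == []

    def test_two_opposite_effects(self, toy_regions):
        from plastconn.connectome import connected_retained_edges
        from plastconn.simulate import PlantedEffect
        base = pc.SimulationConfig(n_participants=40,
                                   dropout_per_period=(0, 0), seed=72)
        mask0 = pc.group_threshold(pc.simulate_connectomes(base, toy_regions),
                                   0.30)
        up = connected_retained_edges(mask0, toy_regions, 4, "left",
                                      min_margin=0.02)
        down = connected_retained_edges(mask0, toy_regions, 4, "right",
                                        min_margin=0.02)
        cfg = dataclasses.replace(base, planted_effects=(
            PlantedEffect(up, period="second", direction="increase",
                          magnitude=1.2),
            PlantedEffect(down, period="second", direction="decrease",
                          magnitude=1.2),
        ))
        data = pc.simulate_connectomes(cfg, toy_regions)
        mask = pc.group_threshold(data, 0.30)
        nets = pc.nbs_test(data, mask, pc.ModelSpec("time"),
                           pc.NBSConfig(n_permutations=100, seed=4))
        sig = [s for s in nets if s.significant]
        period = pc.posthoc_adjacent(data, mask, sig)
        rec_up = {e for s in period
                  if s.period == (3, 6) and s.direction == "increase"
                  for e in s.edges}
        rec_down = {e for s in period
                    if s.period == (3, 6) and s.direction == "decrease"
                    for e in s.edges}
        assert len(rec_up & set(up)) >= 3
        assert len(rec_down & set(down)) >= 3


class TestNBSScore:
    def test_zero_variance_scores_rejected(self, toy_regions, small_cohort):
        _, data = small_cohort
        mask = pc.group_threshold(data, 0.3)
        scores = pd.DataFrame({
            "participant": np.repeat(data.participants(), 2),
            "timepoint": [3, 6] * len(data.participants()),
            "score": 1.0,
        })
        with pytest.raises(NBSError, match="zero variance"):
            pc.nbs_score(data, scores, mask,
                         pc.NBSConfig(n_permutations=20, seed=0))

    def test_mostly_missing_scores_rejected(self, toy_regions, small_cohort):
        _, data = small_cohort
        mask = pc.group_threshold(data, 0.3)
        pids = data.participants()[:3]  # 3 of 12
        scores = pd.DataFrame({
            "participant": np.repeat(pids, 2),
            "timepoint": [3, 6] * len(pids),
            "score": np.arange(6, dtype=float),
        })
        with pytest.raises(NBSError, match="missing"):
            pc.nbs_score(data, scores, mask,
                         pc.NBSConfig(n_permutations=20, seed=0))

    def test_coupled_set_recovered(self, toy_regions):
        cfg, edges = pc.coupling_benchmark_config(toy_regions, seed=1)
        data = pc.simulate_connectomes(cfg, toy_regions)
        mask = pc.group_threshold(data, 0.30)
        scores = pc.simulate_scores(cfg, data)
        nets = pc.nbs_score(data, scores, mask,
                            pc.NBSConfig(n_permutations=200, seed=5))
        sig = [s for s in nets if s.significant and s.direction == "positive"]
        assert sig
        best = max(sig, key=lambda s: len(set(s.edges) & set(edges)))
        assert len(set(best.edges) & set(edges)) >= 3


class TestSubgroupSplit:
    def test_mean_split_by_hand(self):
        with pytest.warns(UserWarning, match="underpowered"):
            above, below = pc.subgroup_split(
                {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        assert (above, below) == (["c", "d"], ["a", "b"])

    def test_all_equal_warns_empty_group(self):
        with pytest.warns(UserWarning, match="subgroup"):
            above, below = pc.subgroup_split({"a": 2.0, "b": 2.0, "c": 2.0})
        assert above == [] and len(below) == 3

    def test_partition(self):
        rng = np.random.default_rng(80)
        vals = {f"P{k}": float(v) for k, v in enumerate(rng.normal(size=40))}
        above, below = pc.subgroup_split(vals)
        assert len(above) + len(below) == 40
        assert not set(above) & set(below)
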