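import itertools

import numpy as np
import pandas as pd
import pytest

import plastconn as pc
from plastconn.connectome import (
    ConnectomeError,
    classify_edge,
    connected_retained_edges,
    connectomes_from_frame,
)

from conftest import random_cohort


def brute_candidates(regions):
    """Independent enumeration of analyzable pairs."""
    out = set()
    for a, b in itertools.combinations(regions.region_ids, 2):
        cc_a, cc_b = regions.is_cc(a), regions.is_cc(b)
        if cc_a and cc_b:
            continue
        if not cc_a and not cc_b and regions.hemisphere(a) != regions.hemisphere(b):
            continue
        out.add(tuple(sorted((a, b))))
    return out


class TestCandidateEdges:
    def test_paper_parcellation_count(self, paper_regions):
        edges = pc.candidate_edges(paper_regions)
        # 2 * C(33,2) intra-hemispheric + 66 cortical x 10 CC
        assert len(edges) == 2 * (33 * 32 // 2) + 66 * 10 == 1716
        assert set(edges) == brute_candidates(paper_regions)

    def test_toy_count(self):
        regions = pc.toy_parcellation(2, 1)
        edges = pc.candidate_edges(regions)
        assert len(edges) == 1 + 1 + 4 * 2 == 10
        assert set(edges) == brute_candidates(regions)

    def test_no_cc_regions(self):
        frame = pd.DataFrame(
            [("L_a", "L", "IFG"), ("L_b", "L", "TL"),
             ("R_a", "R", "IFG"), ("R_b", "R", "TL")],
            columns=["region_id", "hemisphere", "system"],
        )
        edges = pc.candidate_edges(pc.RegionTable(frame))
        assert edges == [("L_a", "L_b"), ("R_a", "R_b")]


class TestReadConnectomes:
    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=["participant", "timepoint", "region_a",
                           "region_b", "weight"])

    def test_single_listing_mirrored(self, toy_regions):
        ids = toy_regions.region_ids
        frame = self.frame([("P1", 0, ids[0], ids[1], 2.5),
                            ("P1", 0, ids[0], ids[2], 1.0),
                            ("P1", 0, ids[1], ids[2], 0.5)])
        data = connectomes_from_frame(frame, toy_regions)
        m = data.matrix("P1", 0)
        assert m[0, 1] == m[1, 0] == 2.5
        assert m[0, 2] == m[2, 0] == 1.0

    def test_directed_pair_averaged(self, toy_regions):
        ids = toy_regions.region_ids
        frame = self.frame([("P1", 0, ids[0], ids[1], 2.0),
                            ("P1", 0, ids[1], ids[0], 4.0)])
        data = connectomes_from_frame(frame, toy_regions)
        assert data.matrix("P1", 0)[0, 1] == 3.0

    def test_negative_weight_rejected(self, toy_regions):
        ids = toy_regions.region_ids
        frame = self.frame([("P1", 0, ids[0], ids[1], -0.2)])
        with pytest.raises(ConnectomeError, match="negative"):
            connectomes_from_frame(frame, toy_regions)

    def test_unknown_region_rejected(self, toy_regions):
        frame = self.frame([("P1", 0, "nope", toy_regions.region_ids[0], 1.0)])
        with pytest.raises(ConnectomeError, match="unknown region"):
            connectomes_from_frame(frame, toy_regions)

    def test_missing_baseline_rejected(self, toy_regions):
        ids = toy_regions.region_ids
        frame = self.frame([("P1", 3, ids[0], ids[1], 1.0)])
        with pytest.raises(ConnectomeError, match="baseline"):
            connectomes_from_frame(frame, toy_regions)

    def test_file_roundtrip_exact(self, tmp_path, toy_regions, small_cohort):
        _, data = small_cohort
        path = tmp_path / "conn.tsv"
        data.write(path)
        again = pc.read_connectomes(path, toy_regions)
        assert sorted(again.matrices) == sorted(data.matrices)
        for key in data.matrices:
            np.testing.assert_array_equal(again.matrices[key],
                                          data.matrices[key])


class TestGroupThreshold:
    def test_exact_retention_counts(self, toy_regions):
        n_cand = len(pc.candidate_edges(toy_regions))
        for seed in range(3):
            data = random_cohort(toy_regions, 4, (0, 3), seed=seed)
            for frac in (0.1, 0.3, 0.5, 1.0):
                mask = pc.group_threshold(data, frac)
                assert mask.n_edges == int(np.floor(frac * n_cand + 0.5))

    def test_top_means_retained(self, toy_regions):
        data = random_cohort(toy_regions, 5, (0, 3, 6), seed=1)
        mask = pc.group_threshold(data, 0.30)
        means = mask.mean_weights.sort_values(ascending=False)
        assert set(mask.edges) == set(means.index[:mask.n_edges])

    def test_tie_break_lexicographic(self, toy_regions):
        # all candidate edges share one weight -> ties at every rank
        n = toy_regions.n_regions
        m = np.ones((n, n)) - np.eye(n)
        data = pc.LongitudinalConnectomes(toy_regions, {("P1", 0): m})
        mask = pc.group_threshold(data, 0.25)
        cands = pc.candidate_edges(toy_regions)
        assert list(mask.edges) == sorted(cands)[: mask.n_edges]

    def test_insertion_order_invariance(self, toy_regions):
        data = random_cohort(toy_regions, 4, (0, 3), seed=3)
        reordered = pc.LongitudinalConnectomes(
            toy_regions, dict(reversed(list(data.matrices.items()))))
        assert (pc.group_threshold(data, 0.3).edges
                == pc.group_threshold(reordered, 0.3).edges)

    def test_fraction_validation(self, toy_regions, small_cohort):
        _, data = small_cohort
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                pc.group_threshold(data, bad)


class TestHemisphericSummary:
    def test_hand_computed_sums(self):
        regions = pc.toy_parcellation(2, 1)
        n = regions.n_regions
        ids = regions.region_ids
        pos = {r: i for i, r in enumerate(ids)}
        m = np.zeros((n, n))

        def put(a, b, w):
            m[pos[a], pos[b]] = m[pos[b], pos[a]] = w

        put("L_C00", "L_C01", 2.0)           # left
        put("R_C00", "R_C01", 0.5)           # right
        put("L_C00", "L_CC00", 1.5)          # interhemispheric
        put("R_C01", "R_CC00", 0.25)         # interhemispheric
        data = pc.LongitudinalConnectomes(regions, {("P1", 0): m})
        mask = pc.group_threshold(data, 1.0)
        s = pc.hemispheric_summary(m, mask, regions)
        assert s.left_strength == 2.0
        assert s.right_strength == 0.5
        assert s.interhemispheric_strength == 1.75
        assert s.lateralization_index == pytest.approx((2.0 - 0.5) / 2.5)

    def test_symmetric_blocks_zero_li(self, toy_regions):
        data = random_cohort(toy_regions, 1, (0,), seed=5)
        m = data.matrix("S00", 0).copy()
        # mirror the left block onto the right block
        left = [toy_regions.position(r) for r in toy_regions.cortical_ids("L")]
        right = [toy_regions.position(r) for r in toy_regions.cortical_ids("R")]
        m[np.ix_(right, right)] = m[np.ix_(left, left)]
        mask = pc.group_threshold(
            pc.LongitudinalConnectomes(toy_regions, {("P1", 0): m}), 1.0)
        s = pc.hemispheric_summary(m, mask, toy_regions)
        assert s.lateralization_index == pytest.approx(0.0)

    def test_all_zero_matrix(self, toy_regions):
        n = toy_regions.n_regions
        z = np.zeros((n, n))
        ones = np.ones((n, n)) - np.eye(n)
        mask = pc.group_threshold(
            pc.LongitudinalConnectomes(toy_regions, {("P1", 0): ones}), 0.5)
        s = pc.hemispheric_summary(z, mask, toy_regions)
        assert (s.left_strength, s.right_strength,
                s.interhemispheric_strength, s.lateralization_index) == (0, 0, 0, 0)

    def test_additivity_over_edge_disjoint_masks(self, toy_regions):
        import dataclasses
        data = random_cohort(toy_regions, 2, (0,), seed=6)
        full = pc.group_threshold(data, 1.0)
        half = len(full.edges) // 2
        m_a = dataclasses.replace(full, edges=full.edges[:half])
        m_b = dataclasses.replace(full, edges=full.edges[half:])
        mat = data.matrix("S00", 0)
        s_a = pc.hemispheric_summary(mat, m_a, toy_regions)
        s_b = pc.hemispheric_summary(mat, m_b, toy_regions)
        s_full = pc.hemispheric_summary(mat, full, toy_regions)
        assert s_a.left_strength + s_b.left_strength == pytest.approx(
            s_full.left_strength)
        assert s_a.interhemispheric_strength + s_b.interhemispheric_strength \
            == pytest.approx(s_full.interhemispheric_strength)


def test_connected_retained_edges(toy_regions):
    data = random_cohort(toy_regions, 3, (0, 3), seed=9)
    mask = pc.group_threshold(data, 0.5)
    for kind in ("any", "interhemispheric", "right"):
        edges = connected_retained_edges(mask, toy_regions, 5, kind)
        assert len(edges) == 5
        assert set(edges) <= set(mask.edges)
        if kind != "any":
            assert all(classify_edge(e, toy_regions) == kind for e in edges)
        # connectivity: union-find over the chosen edges
        import networkx as nx
        g = nx.Graph(list(edges))
        assert nx.is_connected(g)
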