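"""Gated one-to-one Hungarian matching vs exhaustive enumeration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesselquant import (
    InputError,
    MatchCriteria,
    build_cost_matrix,
    gate_pair,
    hungarian_assign,
    match_instances,
)
from conftest import make_instance


def brute_force_assignment(cost, admissible):
    """Enumerate every one-to-one assignment; return (max cardinality,
    min total cost among max-cardinality assignments)."""
    n_p, n_g = cost.shape
    best_card, best_cost = 0, 0.0
    rows = range(n_p)
    k = min(n_p, n_g)
    for size in range(k, -1, -1):
        found = False
        for row_subset in itertools.combinations(rows, size):
            for col_perm in itertools.permutations(range(n_g), size):
                if all(admissible[i, j] for i, j in zip(row_subset, col_perm)):
                    total = sum(cost[i, j] for i, j in zip(row_subset, col_perm))
                    if not found or total < best_cost:
                        best_cost = total
                        found = True
        if found:
            best_card = size
            break
    return best_card, best_cost


def random_instance_sets(rng, n_p, n_g, spread=10.0):
    preds = [
        make_instance(i + 1, rng.uniform(0, spread), rng.uniform(0, spread),
                      rng.uniform(20, 120))
        for i in range(n_p)
    ]
    refs = [
        make_instance(100 + i, rng.uniform(0, spread), rng.uniform(0, spread),
                      rng.uniform(20, 120))
        for i in range(n_g)
    ]
    return preds, refs


class TestGatePair:
    def test_admissible_within_both_gates(self):
        p = make_instance(1, 0, 0, math.pi * 25)  # r = 5
        g = make_instance(2, 4, 0, math.pi * 25)
        assert gate_pair(p, g, MatchCriteria())

    def test_centroid_gate_strict(self):
        p = make_instance(1, 0, 0, math.pi * 25)
        g = make_instance(2, 6, 0, math.pi * 25)  # d = 6 ≥ 5
        assert not gate_pair(p, g, MatchCriteria())
        g_at_r = make_instance(3, 5, 0, math.pi * 25)  # d = 5, not < 5
        assert not gate_pair(p, g_at_r, MatchCriteria())

    def test_area_gate_strict_at_boundary(self):
        p = make_instance(1, 0, 0, 130.0)
        g = make_instance(2, 0, 0, 100.0)  # |130-100|/100 = 0.30, not < 0.30
        assert not gate_pair(p, g, MatchCriteria(tau=0.30))
        assert gate_pair(p, g, MatchCriteria(tau=0.301))

    def test_area_gate_uses_reference_denominator(self):
        p = make_instance(1, 0, 0, 100.0)
        g = make_instance(2, 0, 0, 130.0)  # |100-130|/130 = 0.23 < 0.3
        assert gate_pair(p, g, MatchCriteria())

    def test_circle_iou_mode_threshold_comparator(self):
        p = make_instance(1, 0, 0, math.pi)
        g = make_instance(2, 0, 0, math.pi)
        crit_ge = MatchCriteria(mode="circle_iou", iou_threshold=1.0)
        assert gate_pair(p, g, crit_ge)  # IoU exactly 1.0, ≥ comparator
        crit_gt = MatchCriteria(mode="circle_iou", iou_threshold=1.0,
                                iou_comparator="gt")
        assert not gate_pair(p, g, crit_gt)

    def test_circle_iou_mode_has_no_area_gate(self):
        # concentric but very different areas: geometric mode rejects,
        # circle-IoU mode decides purely on overlap
        p = make_instance(1, 0, 0, 400.0)
        g = make_instance(2, 0, 0, 100.0)
        assert not gate_pair(p, g, MatchCriteria())
        assert gate_pair(p, g, MatchCriteria(mode="circle_iou", iou_threshold=0.25))


class TestCostMatrix:
    def test_flags_equal_direct_gate_evaluation(self, rng):
        preds, refs = random_instance_sets(rng, 3, 3)
        crit = MatchCriteria()
        cost, adm = build_cost_matrix(preds, refs, crit)
        for i, p in enumerate(preds):
            for j, g in enumerate(refs):
                assert adm[i, j] == gate_pair(p, g, crit)
                assert cost[i, j] >= 0

    def test_all_forbidden_and_empty(self):
        assert hungarian_assign(np.zeros((2, 2)), np.zeros((2, 2), bool)) == []
        assert hungarian_assign(np.zeros((0, 3)), np.zeros((0, 3), bool)) == []


class TestHungarian:
    def test_two_by_two_worked_example(self):
        # brute force over both permutations: 1+2=3 beats 2+2=4
        cost = np.array([[1.0, 2.0], [2.0, 2.0]])
        adm = np.ones((2, 2), bool)
        assert hungarian_assign(cost, adm) == [(0, 0), (1, 1)]

    def test_sacrifices_greedy_pair_for_cardinality(self):
        # pred 0 admissible to both refs, pred 1 only to ref 0: taking the
        # cheap (0,0) pair greedily would strand pred 1
        cost = np.array([[0.1, 5.0], [0.2, 9.9]])
        adm = np.array([[True, True], [True, False]])
        pairs = hungarian_assign(cost, adm)
        assert sorted(pairs) == [(0, 1), (1, 0)]

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 6), st.integers(1, 6))
    def test_matches_exhaustive_enumeration(self, seed, n_p, n_g):
        rng = np.random.default_rng(seed)
        preds, refs = random_instance_sets(rng, n_p, n_g)
        crit = MatchCriteria(alpha=1.0, tau=0.5)
        cost, adm = build_cost_matrix(preds, refs, crit)
        pairs = hungarian_assign(cost, adm)
        card, total = brute_force_assignment(cost, adm)
        assert len(pairs) == card
        assert sum(cost[i, j] for i, j in pairs) == pytest.approx(total, rel=1e-9, abs=1e-12)


class TestMatchInstances:
    def test_identical_sets_all_tp(self, rng):
        preds, _ = random_instance_sets(rng, 8, 0)
        refs = [make_instance(100 + i, r.centroid_x_um, r.centroid_y_um, r.area_um2)
                for i, r in enumerate(preds)]
        m = match_instances(preds, refs)
        assert (m.tp, m.fp, m.fn) == (8, 0, 0)
        assert all(p.distance_um == 0 for p in m.pairs)

    def test_empty_predictions(self, rng):
        _, refs = random_instance_sets(rng, 0, 5)
        m = match_instances([], refs)
        assert (m.tp, m.fp, m.fn) == (0, 0, 5)

    def test_planted_tp_fp_fn_scenario(self):
        refs = [make_instance(100 + i, 20.0 * i, 0.0, 100.0) for i in range(8)]
        preds = []
        for i in range(6):  # detections with sub-gate jitter on 6 of 8 refs
            preds.append(make_instance(i, 20.0 * i + 0.5, 0.3, 110.0))
        preds.append(make_instance(50, 500.0, 500.0, 100.0))  # far spurious
        preds.append(make_instance(51, 600.0, 600.0, 100.0))
        m = match_instances(preds, refs)
        assert (m.tp, m.fp, m.fn) == (6, 2, 2)
        assert sorted(m.false_positives) == [50, 51]
        assert sorted(m.false_negatives) == [106, 107]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 6), st.integers(0, 6))
    def test_bookkeeping_identities(self, seed, n_p, n_g):
        rng = np.random.default_rng(seed)
        preds, refs = random_instance_sets(rng, n_p, n_g)
        m = match_instances(preds, refs)
        assert m.tp + m.fp == n_p
        assert m.tp + m.fn == n_g
        pred_ids = [p.pred_id for p in m.pairs] + m.false_positives
        ref_ids = [p.ref_id for p in m.pairs] + m.false_negatives
        assert sorted(pred_ids) == sorted(r.id for r in preds)
        assert sorted(ref_ids) == sorted(r.id for r in refs)

    def test_relabeling_invariance(self, rng):
        preds, refs = random_instance_sets(rng, 6, 6, spread=6.0)
        base = match_instances(preds, refs)
        shuffled_p = [make_instance(1000 - r.id, r.centroid_x_um, r.centroid_y_um,
                                    r.area_um2) for r in preds]
        shuffled_g = [make_instance(2000 - r.id, r.centroid_x_um, r.centroid_y_um,
                                    r.area_um2) for r in refs]
        out = match_instances(shuffled_p, shuffled_g)
        assert (out.tp, out.fp, out.fn) == (base.tp, base.fp, base.fn)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_relaxing_gates_never_loses_tp(self, seed):
        rng = np.random.default_rng(seed)
        preds, refs = random_instance_sets(rng, 6, 6, spread=8.0)
        tps = [
            match_instances(preds, refs, MatchCriteria(alpha=a, tau=t)).tp
            for a, t in [(0.5, 0.15), (0.5, 0.30), (1.0, 0.30), (2.0, 0.60)]
        ]
        assert all(a <= b for a, b in zip(tps, tps[1:]))

    def test_geometric_and_iou_modes_agree_on_deep_overlap(self, rng):
        """When d < min(r) the equivalent circles necessarily overlap, so a
        near-zero IoU threshold admits every geometrically-admissible pair."""
        for _ in range(50):
            p = make_instance(1, rng.uniform(0, 5), rng.uniform(0, 5),
                              rng.uniform(20, 200))
            g = make_instance(2, rng.uniform(0, 5), rng.uniform(0, 5),
                              rng.uniform(20, 200))
            geo = gate_pair(p, g, MatchCriteria(alpha=1.0, tau=1e9))
            if geo:
                assert gate_pair(
                    p, g, MatchCriteria(mode="circle_iou", iou_threshold=1e-9)
                )
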