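"""Two-point estimation, LOD grouping and stepwise refinement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radmap import (NoDataError, RHGroup, TwoPointEstimate,
                    UninformativeMarkerError, all_pairs, build_groups,
                    estimate_from_counts, estimate_two_point, refine_group,
                    theta_to_cr)
from radmap.evaluate import partition_errors
from radmap.linkage import _loglik, pair_counts
from radmap.matrix import RHCallMatrix

from conftest import NOISE_FREE


def grid_argmax(n11, n10, n01, n00, step=1e-3):
    """Exhaustive (theta, r) lattice oracle for the linked model."""
    thetas = np.arange(0.0, 1.0 + step / 2, step)
    rs = np.arange(step, 1.0, step)
    T, R = np.meshgrid(thetas, rs, indexing="ij")
    eps = 1e-300
    p11 = R * (1 - T * (1 - R))
    p10 = R * T * (1 - R)
    p00 = (1 - R) * (1 - T * R)
    ll = (n11 * np.log(np.maximum(p11, eps))
          + (n10 + n01) * np.log(np.maximum(p10, eps))
          + n00 * np.log(np.maximum(p00, eps)))
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(thetas[i]), float(rs[j]), float(ll[i, j])


class TestTwoPoint:
    def test_identical_vectors_are_fully_linked(self):
        vec = np.zeros(190, dtype=np.int8)
        vec[:22] = 1
        est = estimate_two_point(vec, vec)
        assert est.theta == 0.0
        assert est.distance_cr == 0.0
        assert est.lod > 0
        assert est.retention == pytest.approx(22 / 190, abs=1e-6)

    def test_exact_independence_gives_lod_zero(self):
        est = estimate_from_counts("A", "B", 50, 50, 50, 50)
        assert est.lod == pytest.approx(0.0, abs=1e-9)
        assert est.retention == pytest.approx(0.5, abs=1e-6)

    def test_mle_matches_grid_oracle_on_example(self):
        n = (30, 5, 5, 150)
        t_g, r_g, ll_g = grid_argmax(*n)
        est = estimate_from_counts("A", "B", *n)
        assert est.theta == pytest.approx(t_g, abs=1e-3)
        assert est.retention == pytest.approx(r_g, abs=1e-3)
        assert _loglik(est.theta, est.retention, n[0], n[1] + n[2],
                       n[3]) >= ll_g - 1e-9

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 25), st.integers(0, 25),
                     st.integers(0, 25), st.integers(0, 25)))
    def test_mle_never_below_grid(self, counts):
        n11, n10, n01, n00 = counts
        N = sum(counts)
        if N == 0 or n11 + n10 in (0, N) or n11 + n01 in (0, N):
            return
        t_g, r_g, ll_g = grid_argmax(n11, n10, n01, n00, step=0.01)
        est = estimate_from_counts("A", "B", n11, n10, n01, n00)
        ll = _loglik(est.theta, est.retention, n11, n10 + n01, n00)
        # 1e-4 slack covers the intentional theta <= 1 - 1e-6 cap
        assert ll >= ll_g - 1e-4

    def test_constant_vector_is_uninformative(self):
        ones = np.ones(50, dtype=np.int8)
        mixed = np.zeros(50, dtype=np.int8)
        mixed[:10] = 1
        with pytest.raises(UninformativeMarkerError):
            estimate_two_point(ones, mixed)

    def test_no_shared_informative_clones(self):
        a = np.array([1, 0, 2, 2], dtype=np.int8)
        b = np.array([2, 2, 1, 0], dtype=np.int8)
        with pytest.raises(NoDataError):
            estimate_two_point(a, b)

    def test_ambiguous_calls_dropped_pairwise(self):
        a = np.array([1, 1, 0, 0, 2], dtype=np.int8)
        b = np.array([1, 2, 0, 1, 0], dtype=np.int8)
        assert pair_counts(a, b) == (1, 0, 1, 1)


class TestDistance:
    def test_distance_zero_at_theta_zero(self):
        assert theta_to_cr(0.0) == 0.0

    def test_distance_strictly_increasing(self):
        thetas = np.linspace(0.0, 0.95, 50)
        d = [theta_to_cr(t) for t in thetas]
        assert np.all(np.diff(d) > 0)

    def test_small_theta_linear_approximation(self):
        for theta in (0.001, 0.005, 0.01):
            d = theta_to_cr(theta)
            assert abs(d - 100 * theta) / (100 * theta) < 0.01

    def test_cap_applies_near_one(self):
        assert theta_to_cr(1.0) == 300.0
        assert theta_to_cr(0.999999, max_distance_cr=150.0) == 150.0


class TestAllPairs:
    def test_three_markers_three_estimates(self):
        rng = np.random.default_rng(0)
        calls = (rng.random((60, 3)) < 0.4).astype(np.int8)
        m = RHCallMatrix([f"c{i}" for i in range(60)], ["A", "B", "C"],
                         calls)
        ests, flagged = all_pairs(m, min_informative=10)
        assert len(ests) == 3

    def test_symmetric_in_marker_order(self, clean_dataset):
        m = clean_dataset.call_matrix
        a, b = m.markers[0], m.markers[1]
        e1 = estimate_two_point(m.vector(a), m.vector(b))
        e2 = estimate_two_point(m.vector(b), m.vector(a))
        assert e1.theta == pytest.approx(e2.theta, abs=1e-6)
        assert e1.lod == pytest.approx(e2.lod, abs=1e-6)

    def test_all_ambiguous_marker_flagged_everywhere(self):
        rng = np.random.default_rng(1)
        calls = (rng.random((60, 3)) < 0.4).astype(np.int8)
        calls[:, 2] = 2
        m = RHCallMatrix([f"c{i}" for i in range(60)], ["A", "B", "C"],
                         calls)
        ests, flagged = all_pairs(m, min_informative=10)
        assert len(ests) == 1
        assert all("C" in (fa, fb) for fa, fb, _ in flagged)


class TestGroups:
    def _ests(self, triples):
        return [TwoPointEstimate(a, b, 0.3, 0.1, lod, 100, 35.0)
                for a, b, lod in triples]

    def test_threshold_above_max_lod_unlinks_everything(self):
        ests = self._ests([("A", "B", 6.0), ("B", "C", 5.0)])
        groups, unlinked = build_groups(ests, ["A", "B", "C"], 10.0)
        assert not groups
        assert unlinked == ["A", "B", "C"]

    def test_single_linkage_chains(self):
        ests = self._ests([("A", "B", 6.0), ("B", "C", 5.0),
                           ("A", "C", 1.0)])
        groups, unlinked = build_groups(ests, ["A", "B", "C"], 4.0)
        assert len(groups) == 1
        assert groups[0].markers == ["A", "B", "C"]
        assert not unlinked

    def test_simulated_two_chromosomes_recovered(self, clean_dataset):
        m = clean_dataset.call_matrix
        ests, _ = all_pairs(m)
        groups, unlinked = build_groups(ests, m.markers, 4.0)
        assert not unlinked
        assert partition_errors([g.markers for g in groups],
                                clean_dataset.truth_order) == (0, 0)

    def test_raising_threshold_never_merges(self, clean_dataset):
        m = clean_dataset.call_matrix
        ests, _ = all_pairs(m)
        prev = None
        for lod in (4.0, 5.0, 6.0, 7.0):
            groups, unlinked = build_groups(ests, m.markers, lod)
            part = {mk: g.group_id for g in groups for mk in g.markers}
            if prev is not None:
                for g in groups:
                    # every new group fits inside one previous group
                    assert len({prev.get(mk) for mk in g.markers}) == 1
            prev = part


class TestRefine:
    def _bridged(self):
        # two tight cliques bridged by one moderate edge
        markers = ["A1", "A2", "A3", "B1", "B2", "B3"]
        triples = [("A1", "A2", 9.0), ("A2", "A3", 8.0), ("A1", "A3", 8.5),
                   ("B1", "B2", 9.0), ("B2", "B3", 8.0), ("B1", "B3", 8.5),
                   ("A3", "B1", 4.5)]
        ests = [TwoPointEstimate(a, b, 0.3, 0.1, lod, 100, 35.0)
                for a, b, lod in triples]
        groups, _ = build_groups(ests, markers, 4.0)
        assert len(groups) == 1
        return groups[0], ests

    def test_clean_group_returned_unchanged(self, clean_dataset):
        m = clean_dataset.call_matrix
        ests, _ = all_pairs(m)
        groups, _ = build_groups(ests, m.markers, 4.0)
        out, unlinked, history = refine_group(
            groups[0], ests, m, aberration_test=lambda g: False)
        assert [g.markers for g in out] == [groups[0].markers]
        assert not unlinked and not history

    def test_bridge_broken_at_higher_lod(self, clean_dataset):
        group, ests = self._bridged()
        aberrant = lambda g: {m[0] for m in g.markers} == {"A", "B"}
        out, unlinked, history = refine_group(
            group, ests, clean_dataset.call_matrix,
            lod_schedule=(4.5, 5.0), aberration_test=aberrant)
        parts = sorted(tuple(sorted(g.markers)) for g in out)
        assert parts == [("A1", "A2", "A3"), ("B1", "B2", "B3")]
        assert any(h["action"] == "split" and h["threshold"] == 5.0
                   for h in history)

    def test_schedule_exhausted_flags_persistent(self, clean_dataset):
        group, ests = self._bridged()
        out, unlinked, history = refine_group(
            group, ests, clean_dataset.call_matrix, lod_schedule=(4.2,),
            aberration_test=lambda g: True)
        flags = [f for g in out for f in g.flags]
        assert "persistent-aberration" in flags
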