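"""Minimal-event trees, transit nodes, WGD edges and the exact oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mifish import (
    SignalPattern,
    build_tree,
    build_tree_from_records,
    event_distance,
    steiner_oracle,
    tree_metrics,
)

from conftest import make_records


def _patterns(*vecs):
    return [SignalPattern(tuple(v), 1) for v in vecs]


class TestEventDistance:
    def test_plain_l1(self):
        cost, k, _ = event_distance((2, 2, 2), (3, 1, 2))
        assert (cost, k) == (2, 0)

    def test_wgd_shortcut(self):
        cost, k, ways = event_distance((2, 2, 2, 2), (4, 4, 4, 4))
        assert (cost, k) == (1, 1)
        assert ways == ((2, 2, 2, 2),)

    def test_wgd_with_pre_and_post_steps(self):
        # (2,2) -> (2,3) -> WGD (4,6) -> (5,6): 3 events
        cost, k, _ = event_distance((2, 2), (5, 6))
        assert (cost, k) == (3, 1)

    def test_absorbing_zero_blocks_regain(self):
        cost, _, _ = event_distance((0, 2), (1, 2))
        assert cost == float("inf")
        cost, _, _ = event_distance((0, 2), (1, 2), absorbing_zero=False)
        assert cost == 1


class TestBuildTree:
    def test_single_gain_pattern(self):
        tree = build_tree(_patterns((3, 2, 2, 2, 2, 2, 2, 2)))
        assert (tree.tree_depth, tree.total_events) == (1, 1)
        assert not any(not n.observed and n.pattern != (2,) * 8 for n in tree.nodes)

    def test_three_step_pattern_inserts_two_transit_nodes(self):
        tree = build_tree(_patterns((2, 1, 3, 2, 1, 2, 2, 2)))
        assert (tree.tree_depth, tree.total_events) == (3, 3)
        transit = [n for n in tree.nodes if not n.observed and n.pattern != (2,) * 8]
        assert len(transit) == 2
        assert all(n.multiplicity == 0 for n in transit)

    def test_wgd_semantics_four_probes(self):
        with_wgd = build_tree(_patterns((4, 4, 4, 4)), allow_wgd=True)
        without = build_tree(_patterns((4, 4, 4, 4)), allow_wgd=False)
        assert with_wgd.total_events == 1
        assert without.total_events == 8

    def test_every_observed_pattern_is_a_node(self):
        vecs = [(2, 1, 3, 2), (2, 1, 4, 2), (4, 4, 4, 4)]
        tree = build_tree(_patterns(*vecs))
        assert tree.observed_patterns == set(vecs)

    def test_edges_respect_move_model(self):
        tree = build_tree(_patterns((2, 1, 3, 2), (4, 2, 6, 4), (0, 1, 3, 2)))
        for e in tree.edges:
            parent = tree.nodes[e.parent].pattern
            child = tree.nodes[e.child].pattern
            if e.event[0] == "wgd":
                assert child == tuple(2 * c for c in parent)
            else:
                diff = [c - p for p, c in zip(parent, child)]
                assert sorted(map(abs, diff)) == [0] * (len(diff) - 1) + [1]
                # absorbing zero: no coordinate rises from 0
                _, i, step = e.event
                assert not (parent[i] == 0 and step == 1)

    def test_deterministic(self):
        vecs = [(3, 1, 2, 4), (2, 2, 5, 1), (4, 4, 4, 4)]
        t1 = build_tree(_patterns(*vecs))
        t2 = build_tree(_patterns(*list(reversed(vecs))))
        assert [n.pattern for n in t1.nodes] == [n.pattern for n in t2.nodes]
        assert [(e.parent, e.child, e.event) for e in t1.edges] == [
            (e.parent, e.child, e.event) for e in t2.edges
        ]

    def test_records_entry_point_uses_gene_probes(self, panel):
        records = make_records([((2, 1, 3, 2, 1, 2, 2, 2), 10)])
        tree = build_tree_from_records(records, panel)
        assert tree.observed_patterns == {(2, 1, 3, 2, 1, 2, 2, 2)}

    @settings(max_examples=40, deadline=None)
    @given(
        st.sets(
            st.tuples(*[st.integers(0, 6)] * 3), min_size=1, max_size=5
        )
    )
    def test_heuristic_bounds(self, vecs):
        """Total events sit between the max single-pattern distance and
        the sum of all root distances."""
        vecs = list(vecs)
        root = (2,) * 3
        dists = [event_distance(root, v)[0] for v in vecs]
        if any(d == float("inf") for d in dists):
            return  # unroutable isolated coordinates
        tree = build_tree(_patterns(*vecs))
        lower = max(dists, default=0)
        upper = sum(event_distance(root, v, allow_wgd=False)[0] for v in vecs
                    if v != root)
        if np.isfinite(upper):
            assert tree.total_events <= upper
        assert tree.total_events >= lower


class TestTreeMetrics:
    def test_root_only(self):
        tree = build_tree(_patterns((2, 2, 2)))
        assert tree_metrics(tree) == (0, 0)

    def test_chain_and_star(self):
        chain = build_tree(_patterns((5, 2, 2)))  # 3 unit steps
        assert tree_metrics(chain) == (3, 3)
        star = build_tree(_patterns((3, 2, 2), (1, 2, 2), (2, 3, 2)))
        assert tree_metrics(star) == (1, 3)


class TestSteinerOracle:
    def test_two_patterns_share_nothing(self):
        assert steiner_oracle([(2, 1), (2, 3)]) == 2

    def test_single_pattern_equals_distance(self):
        assert steiner_oracle([(5, 1, 3)]) == event_distance((2, 2, 2), (5, 1, 3))[0]

    def test_wgd_single_event(self):
        assert steiner_oracle([(4, 4)], allow_wgd=True) == 1
        assert steiner_oracle([(4, 4)], allow_wgd=False) == 4

    def test_bounds_enforced(self):
        with pytest.raises(ValueError, match="at most 3"):
            steiner_oracle([(2, 1), (2, 3), (3, 3), (1, 1)])
        with pytest.raises(ValueError, match="counts up to"):
            steiner_oracle([(9, 2)])

    def test_heuristic_never_beats_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            d = int(rng.integers(2, 5))
            k = int(rng.integers(1, 4))
            vecs = set()
            while len(vecs) < k:
                vecs.add(tuple(int(x) for x in rng.integers(0, 7, size=d)))
            heuristic = build_tree(_patterns(*vecs)).total_events
            assert heuristic >= steiner_oracle(list(vecs))
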