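"""Dual-cutoff kinetics, co-binding graph, site detection and metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import lipidsites as ls
from lipidsites.sites import _runs, occupancy_from_events

from conftest import dual_cutoff_oracle, make_bound_series


class TestDualCutoff:
    def test_stated_hysteresis_sequence(self):
        d = [0.50, 0.70, 0.95, 1.05, 0.60]
        out = ls.dual_cutoff_states(d)
        # 0.60 does not re-bind: it is above the 0.55 entry cutoff
        assert out.tolist() == [True, True, True, False, False]

    def test_equal_cutoffs_reduce_to_thresholding(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.2, 1.5, size=500)
        out = ls.dual_cutoff_states(d, lower=0.55, upper=0.55)
        np.testing.assert_array_equal(out, d < 0.55)

    def test_empty_series_and_bad_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ls.dual_cutoff_states([])
        with pytest.raises(ValueError, match="lower"):
            ls.dual_cutoff_states([0.5], lower=1.0, upper=0.5)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_automaton_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.2, 1.4, size=200)
        np.testing.assert_array_equal(
            ls.dual_cutoff_states(d), dual_cutoff_oracle(d, 0.55, 1.0)
        )

    @given(st.integers(0, 2**31 - 1), st.floats(1.0, 1.6))
    def test_raising_upper_cutoff_never_shortens_runs(self, seed, upper2):
        """Hysteresis monotonicity: a larger release cutoff can only extend
        bound runs."""
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.2, 1.8, size=300)
        s1 = ls.dual_cutoff_states(d, upper=1.0)
        s2 = ls.dual_cutoff_states(d, upper=upper2)
        assert np.all(s2 | ~s1)  # s1 implies s2

    def test_vectorized_over_trailing_axes(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.2, 1.4, size=(50, 4, 3))
        out = ls.dual_cutoff_states(d)
        for i in range(4):
            for j in range(3):
                np.testing.assert_array_equal(
                    out[:, i, j], dual_cutoff_oracle(d[:, i, j], 0.55, 1.0)
                )


class TestCobindingGraph:
    def test_perfect_cobinding_edge_weight_one(self):
        states = np.zeros((10, 1, 2), dtype=bool)
        states[2:8, 0, :] = True
        g = ls.build_cobinding_graph(make_bound_series(states))
        assert g[0][1]["weight"] == pytest.approx(1.0)

    def test_disjoint_lipids_no_edge(self):
        states = np.zeros((10, 2, 2), dtype=bool)
        states[:5, 0, 0] = True  # residue 0 binds lipid 0 only
        states[5:, 1, 1] = True  # residue 1 binds lipid 1 only
        g = ls.build_cobinding_graph(make_bound_series(states))
        assert g.number_of_edges() == 0

    def test_two_disjoint_triplets_give_two_components(self):
        import networkx as nx

        states = np.zeros((20, 2, 6), dtype=bool)
        states[3:12, 0, 0:3] = True
        states[6:18, 1, 3:6] = True
        g = ls.build_cobinding_graph(make_bound_series(states))
        comps = [frozenset(c) for c in nx.connected_components(g)]
        assert sorted(comps, key=min) == [frozenset({0, 1, 2}), frozenset({3, 4, 5})]

    def test_no_bound_frames_gives_empty_graph(self):
        g = ls.build_cobinding_graph(make_bound_series(np.zeros((5, 1, 3), bool)))
        assert g.number_of_nodes() == 0
        assert ls.detect_sites(g) == []


class TestDetectSites:
    def test_two_disconnected_cliques_detected(self):
        states = np.zeros((20, 2, 6), dtype=bool)
        states[3:12, 0, 0:3] = True
        states[6:18, 1, 3:6] = True
        sites = ls.detect_sites(ls.build_cobinding_graph(make_bound_series(states)))
        assert sites == [frozenset({0, 1, 2}), frozenset({3, 4, 5})]

    def test_uniform_clique_not_split(self):
        states = np.zeros((30, 1, 6), dtype=bool)
        states[5:20, 0, :] = True
        sites = ls.detect_sites(ls.build_cobinding_graph(make_bound_series(states)))
        assert sites == [frozenset(range(6))]

    def test_fixed_seed_reproducible(self, two_site_system):
        topo, traj, _ = two_site_system
        bound = ls.compute_bound_series(traj, topo)
        g = ls.build_cobinding_graph(bound)
        assert ls.detect_sites(g, seed=4) == ls.detect_sites(g, seed=4)


class TestSiteMetrics:
    def test_occupancy_is_bound_fraction(self):
        states = np.zeros((100, 1, 2), dtype=bool)
        states[10:40, 0, 0] = True
        occ, _, _ = ls.site_metrics({0, 1}, make_bound_series(states))
        assert occ == pytest.approx(0.30)

    def test_mean_residence_is_event_mean(self):
        states = np.zeros((20, 1, 1), dtype=bool)
        states[2:4, 0, 0] = True  # 2 frames
        states[10:14, 0, 0] = True  # 4 frames
        occ, res, events = ls.site_metrics({0}, make_bound_series(states, dt=1.0))
        assert res == pytest.approx(3.0)
        assert events == [(0, 2, 3), (0, 10, 13)]

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError, match="empty site"):
            ls.site_metrics(set(), make_bound_series(np.zeros((5, 1, 1), bool)))

    def test_union_occupancy_dominates_parts(self):
        rng = np.random.default_rng(8)
        states = rng.random((200, 2, 4)) < 0.2
        bs = make_bound_series(states)
        occ_a = ls.site_metrics({0, 1}, bs)[0]
        occ_b = ls.site_metrics({2, 3}, bs)[0]
        occ_ab = ls.site_metrics({0, 1, 2, 3}, bs)[0]
        assert 0 <= occ_a <= 1 and 0 <= occ_b <= 1
        assert occ_ab >= max(occ_a, occ_b)

    def test_occupancy_recomputable_from_serialized_events(self):
        rng = np.random.default_rng(5)
        states = rng.random((300, 3, 4)) < 0.15
        bs = make_bound_series(states)
        occ, _, events = ls.site_metrics({0, 2}, bs)
        site = ls.BindingSite(0, frozenset({0, 2}), occ, 0.0, events)
        round_tripped = ls.BindingSite.from_dict(site.to_dict())
        assert occupancy_from_events(round_tripped.events, 300) == pytest.approx(occ)

    def test_geometric_dwell_matches_inverse_p_off(self):
        """Events drawn from a two-state chain have mean dwell 1/p_off."""
        rng = np.random.default_rng(12)
        p_on, p_off = 0.3, 0.1
        s, cur = [], False
        for _ in range(5000):
            cur = (rng.random() < p_on) if not cur else (rng.random() >= p_off)
            s.append(cur)
        states = np.array(s, bool).reshape(-1, 1, 1)
        _, res, events = ls.site_metrics({0}, make_bound_series(states))
        assert len(events) >= 200
        assert res == pytest.approx(1 / p_off, rel=0.2)

    def test_survival_fit_close_to_mean_for_geometric_events(self):
        rng = np.random.default_rng(2)
        durations = rng.geometric(0.1, size=400)
        states = np.zeros((int(durations.sum() + 2 * len(durations) + 1), 1, 1), bool)
        t = 1
        for d in durations:
            states[t : t + d, 0, 0] = True
            t += d + 2
        bs = make_bound_series(states)
        _, res_fit, _ = ls.site_metrics({0}, bs, residence_estimator="survival-fit")
        _, res_mean, _ = ls.site_metrics({0}, bs, residence_estimator="mean")
        assert res_fit == pytest.approx(res_mean, rel=0.25)


class TestFilters:
    def _site(self, occ, res, residues=frozenset({0})):
        return ls.BindingSite(0, residues, occ, res, [(0, 0, 1)])

    def test_short_residence_site_removed(self):
        states = np.zeros((50, 1, 1), bool)
        states[0:8, 0, 0] = True
        bs = make_bound_series(states)
        kept = ls.filter_sites([self._site(0.16, 8.0)], bs, min_residence=10.0)
        assert kept == []

    def test_residence_exactly_at_threshold_removed(self):
        states = np.zeros((50, 1, 1), bool)
        states[0:10, 0, 0] = True
        bs = make_bound_series(states)
        assert ls.filter_sites([self._site(0.2, 10.0)], bs) == []

    def test_low_occupancy_residue_pruned(self):
        states = np.zeros((100, 1, 2), dtype=bool)
        states[0:50, 0, 0] = True  # residue 0: occupancy 0.50
        states[0:3, 0, 1] = True  # residue 1: occupancy 0.03 < 0.05
        bs = make_bound_series(states)
        occ, res, events = ls.site_metrics({0, 1}, bs)
        kept = ls.filter_sites(
            [ls.BindingSite(0, frozenset({0, 1}), occ, res, events)], bs
        )
        assert len(kept) == 1
        assert kept[0].residue_ids == frozenset({0})

    def test_all_sites_above_threshold_pass_unchanged(self):
        states = np.zeros((100, 1, 2), dtype=bool)
        states[0:60, 0, :] = True
        bs = make_bound_series(states)
        occ, res, events = ls.site_metrics({0, 1}, bs)
        sites = [ls.BindingSite(0, frozenset({0, 1}), occ, res, events)]
        kept = ls.filter_sites(sites, bs)
        assert len(kept) == 1
        assert kept[0].residue_ids == sites[0].residue_ids
        assert kept[0].occupancy == sites[0].occupancy


class TestRepresentativePose:
    def test_single_event_returns_it(self, planted_system):
        topo, traj, gt = planted_system
        sites, bound = ls.find_binding_sites(traj, topo)
        assert len(sites) == 1
        frame, lipid = sites[0].representative_pose
        assert lipid == gt[0].lipid_id
        assert gt[0].states[frame]

    def test_equal_length_events_earlier_wins(self):
        states = np.zeros((30, 2, 1), dtype=bool)
        states[2:6, 0, 0] = True
        states[10:14, 1, 0] = True
        bs = make_bound_series(states)
        occ, res, events = ls.site_metrics({0}, bs)
        site = ls.BindingSite(0, frozenset({0}), occ, res, events)
        # build a matching fake system: one residue, two CDL lipids
        from lipidsites.core import Lipid, Residue, SystemTopology, Trajectory

        res0 = Residue(0, "ARG", "A", {"BB": 0})
        lips = [
            Lipid(
                k,
                "CDL",
                "inner",
                {r: 1 + 7 * k + i for i, r in enumerate(["GL0", "PO1", "PO2", "C1A", "C2A", "C1B", "C2B"])},
            )
            for k in range(2)
        ]
        topo = SystemTopology([res0], lips)
        coords = np.full((30, 15, 3), 5.0)
        traj = Trajectory(np.arange(30.0), coords, np.array([10.0, 10, 10]))
        frame, lipid = ls.representative_pose(site, traj, topo, bs)
        assert (frame, lipid) == (2, 0)

    def test_no_events_rejected(self):
        site = ls.BindingSite(0, frozenset({0}), 0.0, 0.0, [])
        with pytest.raises(ValueError, match="no binding events"):
            ls.representative_pose(site, None, None, None)


class TestRunsHelper:
    @given(st.lists(st.booleans(), min_size=1, max_size=60))
    def test_runs_reconstruct_mask(self, bits):
        mask = np.array(bits, dtype=bool)
        rebuilt = np.zeros_like(mask)
        for start, end in _runs(mask):
            assert mask[start : end + 1].all()
            rebuilt[start : end + 1] = True
        np.testing.assert_array_equal(rebuilt, mask)


class TestEndToEnd:
    def test_two_planted_sites_recovered_exactly(self, two_site_system):
        topo, traj, gt = two_site_system
        sites, _ = ls.find_binding_sites(traj, topo)
        recovered = {s.residue_ids for s in sites}
        assert recovered == {frozenset({1, 2, 3}), frozenset({7, 8, 9})}

    def test_recovered_occupancy_matches_ground_truth(self, two_site_system):
        topo, traj, gt = two_site_system
        sites, _ = ls.find_binding_sites(traj, topo)
        by_res = {s.residue_ids: s for s in sites}
        for g in gt:
            s = by_res[frozenset(g.site.residue_ids)]
            assert s.occupancy == pytest.approx(g.realized_occupancy, abs=1e-9)
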