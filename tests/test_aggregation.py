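"""Aggregate clustering, size statistics, transition networks, events, CAP."""

import numpy as np
import pytest

from pepagg.synth.spheres import StickySphereConfig, simulate_sticky_spheres
from pepagg.traj.aggregation import (AggregateState, EventLog,
                                     aggregate_states, assign_aggregates,
                                     build_transition_network,
                                     collision_acceptance_probability,
                                     detect_events, nonaggregated_fraction)
from pepagg.traj.model import molecule_contact_matrix

from conftest import (brute_force_components, chain_topology, frame_of,
                      point_topology, traj_of)


class TestAssignAggregates:
    def test_all_far_apart_gives_singletons(self):
        topo = point_topology(4)
        f = frame_of([[0, 0, 0], [3, 0, 0], [0, 3, 0], [3, 3, 0]], box=10.0)
        st = assign_aggregates(f, topo, cutoff=0.5)
        assert st.aggregates == [(0,), (1,), (2,), (3,)]

    def test_chain_transitivity(self):
        # A-B and B-C within cutoff, A-C not: single-linkage joins all three
        topo = point_topology(3)
        f = frame_of([[0, 0, 0], [0.4, 0, 0], [0.8, 0, 0]], box=10.0)
        st = assign_aggregates(f, topo, cutoff=0.5)
        assert st.aggregates == [(0, 1, 2)]
        contact = molecule_contact_matrix(f, topo, 0.5)
        assert not contact[0, 2]  # A-C itself is beyond the cutoff
        assert brute_force_components(contact) == [(0, 1, 2)]

    def test_contact_across_periodic_boundary(self):
        topo = point_topology(2)
        f = frame_of([[0.1, 5, 5], [14.9, 5, 5]], box=15.0)
        st = assign_aggregates(f, topo, cutoff=0.5)
        assert st.aggregates == [(0, 1)]

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(2024)
        for trial in range(25):
            n = int(rng.integers(2, 31))
            topo = point_topology(n)
            box = float(rng.uniform(3.0, 8.0))
            f = frame_of(rng.uniform(0, box, (n, 3)), box=box)
            cutoff = float(rng.uniform(0.3, 1.5))
            st = assign_aggregates(f, topo, cutoff)
            contact = molecule_contact_matrix(f, topo, cutoff)
            assert st.aggregates == brute_force_components(contact)

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        topo = point_topology(12)
        f = frame_of(rng.uniform(0, 4, (12, 3)), box=4.0)
        st = assign_aggregates(f, topo, cutoff=0.8)
        members = sorted(m for agg in st.aggregates for m in agg)
        assert members == list(range(12))
        assert sum(st.sizes) == 12

    def test_invalid_cutoff(self):
        topo = point_topology(2)
        with pytest.raises(ValueError):
            assign_aggregates(frame_of(np.zeros((2, 3))), topo, cutoff=0.0)


class TestNonaggregatedFraction:
    def _traj_with_sizes_3_1_1(self):
        # molecules 0,1,2 clustered; 3 and 4 free
        pts = [[0, 0, 0], [0.3, 0, 0], [0.6, 0, 0], [5, 5, 5], [8, 8, 8]]
        return traj_of([pts, pts], point_topology(5), box=10.0)

    def test_sizes_311_at_n2_is_40_percent(self):
        traj = self._traj_with_sizes_3_1_1()
        f = nonaggregated_fraction(traj, 2)
        assert np.allclose(f["percent"], 40.0)

    def test_sizes_311_at_n4_is_100_percent(self):
        traj = self._traj_with_sizes_3_1_1()
        f = nonaggregated_fraction(traj, 4)
        assert np.allclose(f["percent"], 100.0)

    def test_single_full_aggregate_at_n10_is_zero(self):
        pts = [[0.35 * i, 0, 0] for i in range(20)]
        traj = traj_of([pts, pts], point_topology(20), box=30.0)
        f = nonaggregated_fraction(traj, 10)
        assert np.allclose(f["percent"], 0.0)

    def test_monotone_in_cutoff_size_and_contact_cutoff(self):
        rng = np.random.default_rng(5)
        traj = traj_of([rng.uniform(0, 5, (10, 3))], point_topology(10),
                       box=5.0)
        vals = [nonaggregated_fraction(traj, n)["percent"].iloc[0]
                for n in (2, 4, 6, 10)]
        assert vals == sorted(vals)  # non-decreasing in n
        by_cutoff = [nonaggregated_fraction(traj, 4, contact_cutoff=c)
                     ["percent"].iloc[0] for c in (0.3, 0.6, 1.2)]
        assert by_cutoff == sorted(by_cutoff, reverse=True)


class TestTransitionNetwork:
    def test_two_monomers_dimerize_edge_counted_twice(self):
        states = [AggregateState(0.0, [(0,), (1,)]),
                  AggregateState(1.0, [(0, 1)])]
        net = build_transition_network(states)
        assert net.edges == {(1, 2): 2}
        assert net.nodes == {1: 2, 2: 1}

    def test_stationary_partitions_add_no_edges(self):
        st = [AggregateState(t, [(0, 1), (2,)]) for t in (0.0, 1.0, 2.0)]
        net = build_transition_network(st)
        assert net.edges == {}
        assert net.nodes == {2: 3, 1: 3}

    def test_scripted_full_coalescence_reaches_node_20(self):
        # doubling coalescence 20x1 -> 10x2 -> 5x4 -> ... -> 1x20
        mols = list(range(20))
        partitions = [[(m,) for m in mols]]
        sizes = [2, 4, 10, 20]
        for s in sizes:
            partitions.append([tuple(mols[i:i + s])
                               for i in range(0, 20, s)])
        states = [AggregateState(float(t), p)
                  for t, p in enumerate(partitions)]
        net = build_transition_network(states)
        assert net.max_size == 20
        assert net.growth_path_connected()

    def test_breakup_recorded_as_downward_edge(self):
        states = [AggregateState(0.0, [(0, 1, 2)]),
                  AggregateState(1.0, [(0, 1), (2,)])]
        net = build_transition_network(states)
        assert (3, 2) in net.edges


class TestDetectEvents:
    def _traj_from_contact_pattern(self, pattern, box=10.0):
        """Two single-atom molecules; 1 = in contact (0.4 nm), 0 = far."""
        frames = [[[0, 0, 0], [0.4 if c else 5.0, 0, 0]] for c in pattern]
        return traj_of(frames, point_topology(2), box=box)

    def test_contact_from_frame_k_gives_one_bind(self):
        traj = self._traj_from_contact_pattern([0, 0, 1, 1, 1])
        log = detect_events(traj)
        assert (log.n_bind, log.n_unbind) == (1, 0)

    def test_flicker_suppressed_by_debounce(self):
        traj = self._traj_from_contact_pattern([0, 1, 0])
        log = detect_events(traj, debounce=2)
        assert (log.n_bind, log.n_unbind) == (0, 0)

    def test_persistent_bind_then_unbind_with_debounce(self):
        traj = self._traj_from_contact_pattern([0, 1, 1, 0, 0])
        log = detect_events(traj, debounce=2)
        assert (log.n_bind, log.n_unbind) == (1, 1)

    def test_raw_transitions_at_debounce_one(self):
        traj = self._traj_from_contact_pattern([0, 1, 0, 1, 0])
        log = detect_events(traj, debounce=1)
        assert (log.n_bind, log.n_unbind) == (2, 2)

    def test_alternation_per_pair_on_simulator_run(self):
        cfg = StickySphereConfig(n_molecules=8, n_steps=150, p_unbind=0.05,
                                 seed=42)
        traj, _ = simulate_sticky_spheres(cfg)
        log = detect_events(traj)
        by_pair: dict = {}
        for pair, _, kind in log.events:
            by_pair.setdefault(pair, []).append(kind)
        for pair, kinds in by_pair.items():
            expected_first = ("unbind" if pair in log.initial_bound
                              else "bind")
            assert kinds[0] == expected_first
            for a, b in zip(kinds[:-1], kinds[1:]):
                assert a != b  # strict alternation

    def test_event_conservation_on_simulator_runs(self):
        for seed in (0, 1, 2):
            cfg = StickySphereConfig(n_molecules=10, n_steps=150,
                                     p_unbind=0.03, seed=seed)
            traj, _ = simulate_sticky_spheres(cfg)
            log = detect_events(traj)
            assert log.n_bind - log.n_unbind == \
                len(log.final_bound) - len(log.initial_bound)


class TestCap:
    def _log(self, n_bind, n_unbind):
        log = EventLog()
        t = 0.0
        for _ in range(n_bind):
            log.events.append(((0, 1), t, "bind")); t += 1
        for _ in range(n_unbind):
            log.events.append(((0, 1), t, "unbind")); t += 1
        return log

    def test_irreversible_binding_gives_one(self):
        assert collision_acceptance_probability(self._log(10, 0)) == 1.0

    def test_balanced_events_give_zero(self):
        assert collision_acceptance_probability(self._log(10, 10)) == 0.0

    def test_no_bind_events_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            collision_acceptance_probability(EventLog())

    def test_clipped_into_unit_interval(self):
        assert collision_acceptance_probability(self._log(5, 9)) == 0.0

    def test_alternative_ratio_formula(self):
        cap = collision_acceptance_probability(self._log(6, 2),
                                               formula="ratio")
        assert cap == pytest.approx(0.75)

    def test_cap_rank_follows_stickiness_rank(self):
        """Less reversible binding must rank higher, matching the use of
        CAP as an aggregation-propensity score."""
        means = []
        for p_unbind in (0.0, 0.01, 0.1):
            caps = []
            for seed in range(4):
                cfg = StickySphereConfig(n_molecules=20, n_steps=200,
                                         p_unbind=p_unbind, seed=seed)
                traj, _ = simulate_sticky_spheres(cfg)
                caps.append(collision_acceptance_probability(
                    detect_events(traj)))
            means.append(np.mean(caps))
        assert means[0] > means[1] > means[2]
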