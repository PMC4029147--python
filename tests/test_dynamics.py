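"""Synchronous update rule, trajectories, attractor enumeration, STG."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boolcycle import (
    NetworkState,
    ThresholdNetwork,
    enumerate_attractors,
    export_state_transition_graph,
    label_phase,
    simulate_trajectory,
    successor_map,
    successor_state,
)
from conftest import oracle_attractors, oracle_successor, random_small_net

# Temporal evolution of one full cell cycle: S entry back to the rest state.
CELL_CYCLE_TRAJECTORY = [
    ("10010111", "S"),
    ("00100101", "S/M"),
    ("00010001", "S/M"),
    ("00010000", "S/M"),
    ("00011000", "M"),
    ("00011010", "M"),
    ("00011111", "M"),
    ("00010111", "M/S"),
]

# Fixed points of the cell-cycle network with their basin sizes.
CELL_CYCLE_ATTRACTORS = [
    ("00010111", 219),
    ("01010111", 16),
    ("00000111", 12),
    ("01000111", 5),
    ("00000000", 4),
]


class TestNetworkState:
    @given(st.integers(min_value=0, max_value=255))
    def test_index_bits_round_trip(self, index):
        s = NetworkState.from_index(index, 8)
        assert s.index == index
        assert NetworkState.from_string(str(s)) == s

    def test_node_zero_is_most_significant_bit(self):
        assert NetworkState.from_string("10000000").index == 128

    def test_rejects_bad_bits(self):
        with pytest.raises(ValueError):
            NetworkState.from_string("10x0")
        with pytest.raises(ValueError):
            NetworkState.from_index(256, 8)


class TestSuccessor:
    def test_cell_cycle_single_step(self, celegans):
        s = NetworkState.from_string("10010111")
        assert str(successor_state(celegans, s)) == "00100101"

    def test_all_zero_state_is_held_by_tie_rule(self, celegans):
        zero = NetworkState.from_string("00000000")
        assert successor_state(celegans, zero) == zero

    def test_rest_state_is_fixed(self, celegans):
        rest = NetworkState.from_string("00010111")
        assert successor_state(celegans, rest) == rest

    def test_toy_network_full_truth_table(self, toy_net):
        expected = {"00": "00", "01": "00", "10": "11", "11": "11"}
        for start, nxt in expected.items():
            got = successor_state(toy_net, NetworkState.from_string(start))
            assert str(got) == nxt

    def test_length_mismatch_raises(self, celegans):
        with pytest.raises(ValueError, match="bits"):
            successor_state(celegans, NetworkState.from_string("101"))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_on_random_nets(self, seed):
        rng = np.random.default_rng(seed)
        net = random_small_net(rng, int(rng.integers(1, 5)))
        for idx in range(1 << net.n_nodes):
            s = NetworkState.from_index(idx, net.n_nodes)
            assert successor_state(net, s).bits == oracle_successor(net, s.bits)

    @pytest.mark.parametrize("seed", range(5))
    def test_successor_map_agrees_with_single_steps(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_small_net(rng, 4)
        succ = successor_map(net)
        for idx in range(16):
            s = NetworkState.from_index(idx, 4)
            assert succ[idx] == successor_state(net, s).index


class TestTrajectory:
    def test_cell_cycle_pathway_is_reproduced_bit_exactly(self, celegans):
        traj = simulate_trajectory(celegans, NetworkState.from_string("10010111"))
        assert [str(s) for s in traj.states] == [s for s, _ in CELL_CYCLE_TRAJECTORY]
        assert traj.phases == [p for _, p in CELL_CYCLE_TRAJECTORY]
        assert traj.absorbed
        assert len(traj) == 8

    def test_start_at_fixed_point_gives_length_one(self, celegans):
        traj = simulate_trajectory(celegans, NetworkState.from_string("00010111"))
        assert len(traj) == 1 and traj.absorbed

    def test_toy_trajectory(self, toy_net):
        traj = simulate_trajectory(toy_net, NetworkState.from_string("01"))
        assert [str(s) for s in traj.states] == ["01", "00"]
        assert traj.absorbed

    def test_unabsorbed_flagged_when_steps_exhausted(self, celegans):
        traj = simulate_trajectory(
            celegans, NetworkState.from_string("10010111"), max_steps=2
        )
        assert not traj.absorbed and len(traj) == 3

    def test_limit_cycle_is_not_absorbed(self):
        # self-repressor with threshold -1/2 flips every tick: 0 -> 1 -> 0
        net = ThresholdNetwork.from_weight_matrix(
            np.array([[-1]]), thresholds=np.array([-0.5])
        )
        traj = simulate_trajectory(net, NetworkState.from_string("1"), max_steps=50)
        assert not traj.absorbed
        assert [str(s) for s in traj.states] == ["1", "0"]

    def test_max_steps_validated(self, celegans):
        with pytest.raises(ValueError):
            simulate_trajectory(celegans, NetworkState.from_string("00000000"), 0)


class TestEnumerateAttractors:
    def test_cell_cycle_attractor_table(self, celegans):
        report = enumerate_attractors(celegans)
        assert report.cycles == []
        got = [(str(s), b) for s, b in report.fixed_points]
        assert got == CELL_CYCLE_ATTRACTORS
        assert sum(report.basin_sizes) == 256

    def test_edgeless_network_holds_every_state(self, edgeless_net):
        report = enumerate_attractors(edgeless_net)
        assert report.n_fixed_points == 4
        assert all(b == 1 for b in report.basin_sizes)

    def test_toy_network_two_basins(self, toy_net):
        report = enumerate_attractors(toy_net)
        got = {(str(s), b) for s, b in report.fixed_points}
        assert got == {("00", 2), ("11", 2)}

    def test_ordering_descending_basin_then_index(self, celegans):
        report = enumerate_attractors(celegans)
        keys = [(-b, s.index) for s, b in report.fixed_points]
        assert keys == sorted(keys)

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_on_small_networks(self, seed):
        """Exhaustive enumeration agrees with naive orbit-following, N <= 4."""
        rng = np.random.default_rng(1000 + seed)
        net = random_small_net(rng, int(rng.integers(1, 5)))
        report = enumerate_attractors(net)
        oracle = oracle_attractors(net)
        mine = {
            frozenset([s.bits]): b for s, b in report.fixed_points
        } | {
            frozenset(s.bits for s in cyc): b for cyc, b in report.cycles
        }
        assert mine == oracle

    @pytest.mark.parametrize("seed", range(10))
    def test_basin_conservation_on_random_nets(self, seed):
        rng = np.random.default_rng(2000 + seed)
        n = int(rng.integers(2, 7))
        net = random_small_net(rng, n)
        report = enumerate_attractors(net)
        total = sum(report.basin_sizes) + sum(b for _, b in report.cycles)
        assert total == 2**n

    def test_pure_oscillator_reported_as_cycle(self):
        net = ThresholdNetwork.from_weight_matrix(
            np.array([[-1]]), thresholds=np.array([-0.5])
        )
        report = enumerate_attractors(net)
        assert report.fixed_points == []
        assert len(report.cycles) == 1
        cycle, basin = report.cycles[0]
        assert {str(s) for s in cycle} == {"0", "1"}
        assert basin == 2  # cycle states count toward their own basin

    def test_node_limit_enforced(self):
        net = ThresholdNetwork.from_weight_matrix(np.zeros((21, 21), dtype=int))
        with pytest.raises(ValueError, match="capped"):
            enumerate_attractors(net)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_fixed_point_iff_self_successor(self, seed):
        rng = np.random.default_rng(seed)
        net = random_small_net(rng, 3)
        report = enumerate_attractors(net)
        fixed = {s.index for s, _ in report.fixed_points}
        succ = successor_map(net)
        assert fixed == {i for i in range(8) if succ[i] == i}


class TestPhaseLabels:
    @pytest.mark.parametrize(
        "state, fixed, phase",
        [
            ("10010111", False, "S"),
            ("00011000", False, "M"),
            ("00010111", True, "M/S"),
            ("00100101", False, "S/M"),
        ],
    )
    def test_cell_cycle_phases(self, celegans, state, fixed, phase):
        s = NetworkState.from_string(state)
        assert label_phase(celegans, s, is_fixed=fixed) == phase

    def test_network_without_drivers_is_unlabeled(self, toy_net):
        assert label_phase(toy_net, NetworkState.from_string("10")) == "-"


class TestStateTransitionGraph:
    def test_full_graph_shape(self, celegans, tmp_path):
        g = export_state_transition_graph(celegans, tmp_path / "stg.graphml")
        assert g.number_of_nodes() == 256
        assert g.number_of_edges() == 256  # one out-edge per state
        assert all(g.out_degree(n) == 1 for n in g.nodes)

    def test_attractor_flags(self, celegans, tmp_path):
        g = export_state_transition_graph(celegans, tmp_path / "stg.graphml")
        attractors = [n for n, d in g.nodes(data=True) if d["is_attractor"]]
        assert sorted(attractors) == sorted(s for s, _ in CELL_CYCLE_ATTRACTORS)
        largest = [n for n, d in g.nodes(data=True) if d["is_largest_attractor"]]
        assert largest == ["00010111"]

    def test_basin_ids_partition_the_state_space(self, celegans, tmp_path):
        g = export_state_transition_graph(celegans, tmp_path / "stg.graphml")
        from collections import Counter

        basin_counts = Counter(d["basin_id"] for _, d in g.nodes(data=True))
        assert basin_counts == dict(CELL_CYCLE_ATTRACTORS)

    def test_single_node_network(self, tmp_path):
        net = ThresholdNetwork.from_weight_matrix(np.zeros((1, 1), dtype=int))
        g = export_state_transition_graph(net, tmp_path / "stg.dot", format="dot")
        assert g.number_of_nodes() == 2
        assert all(g.has_edge(n, n) for n in g.nodes)

    def test_unknown_format_rejected(self, celegans, tmp_path):
        with pytest.raises(ValueError):
            export_state_transition_graph(celegans, tmp_path / "x", format="gexf")
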