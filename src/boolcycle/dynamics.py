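"""Synchronous threshold dynamics: successors, trajectories, attractors.

Every node carries a binary state (1 = active).  At each tick all nodes
update simultaneously from the weighted sum of their inputs:

    S_i(t+1) = 1            if sum_j w_ij S_j(t) > theta_i
             = 0            if sum_j w_ij S_j(t) < theta_i
             = S_i(t)       if sum_j w_ij S_j(t) = theta_i

The tie branch holds the previous state, so self-degradation acts purely
through the -1 self-loop summand.  The state space of an N-node network has
2^N configurations; the successor function is total and deterministic, so
the state-transition graph (STG) is a functional graph whose terminal
components are fixed points or limit cycles.  Exhaustive enumeration
decomposes it into attractors and their basins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import ThresholdNetwork

__all__ = [
    "NetworkState",
    "Trajectory",
    "AttractorReport",
    "PHASE_S",
    "PHASE_M",
    "PHASE_SM",
    "PHASE_MS",
    "PHASE_UNLABELED",
    "successor_state",
    "successor_map",
    "simulate_trajectory",
    "enumerate_attractors",
    "label_phase",
    "export_state_transition_graph",
    "EXHAUSTIVE_NODE_LIMIT",
]

#: Hard cap on exhaustive 2^N enumeration; raise explicitly for bigger nets.
EXHAUSTIVE_NODE_LIMIT = 20

PHASE_S = "S"
PHASE_M = "M"
PHASE_SM = "S/M"
PHASE_MS = "M/S"
PHASE_UNLABELED = "-"

# Node slugs the phase labeller keys on (S-phase and M-phase drivers).
S_DRIVER = "cdk2_cyclinE"
M_DRIVER = "cdk1_cyclinB"


@dataclass(frozen=True)
class NetworkState:
    """An ordered bit-vector over the canonical node order.

    The integer encoding treats node 0 as the most significant bit, so the
    printed bit-string reads left-to-right in canonical node order.
    """

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"state bits must be 0/1, got {self.bits}")

    @property
    def index(self) -> int:
        idx = 0
        for b in self.bits:
            idx = (idx << 1) | b
        return idx

    @classmethod
    def from_index(cls, index: int, n_nodes: int) -> "NetworkState":
        if not 0 <= index < (1 << n_nodes):
            raise ValueError(f"index {index} out of range for {n_nodes} nodes")
        bits = tuple((index >> (n_nodes - 1 - i)) & 1 for i in range(n_nodes))
        return cls(bits)

    @classmethod
    def from_string(cls, s: str) -> "NetworkState":
        s = s.strip()
        if not s or set(s) - {"0", "1"}:
            raise ValueError(f"bit-string must be non-empty over 0/1, got {s!r}")
        return cls(tuple(int(c) for c in s))

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __len__(self) -> int:
        return len(self.bits)

    def with_bit(self, position: int, value: int) -> "NetworkState":
        bits = list(self.bits)
        bits[position] = value
        return NetworkState(tuple(bits))


@dataclass
class Trajectory:
    """An orbit of the synchronous dynamics, with per-state phase labels."""

    states: list[NetworkState]
    absorbed: bool
    phases: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def final_state(self) -> NetworkState:
        return self.states[-1]


@dataclass
class AttractorReport:
    """Fixed points and limit cycles with their basin sizes.

    ``fixed_points`` is sorted by descending basin size, ties broken by
    ascending state index; ``cycles`` likewise by basin then smallest
    member index.  Basins partition the state space: states on a limit
    cycle count toward that cycle's own basin.
    """

    fixed_points: list[tuple[NetworkState, int]]
    cycles: list[tuple[list[NetworkState], int]]
    total_states: int

    @property
    def n_fixed_points(self) -> int:
        return len(self.fixed_points)

    @property
    def largest_fixed_point(self) -> tuple[NetworkState, int] | None:
        return self.fixed_points[0] if self.fixed_points else None

    @property
    def basin_sizes(self) -> list[int]:
        return [b for _, b in self.fixed_points]

    def basin_of(self, state: NetworkState) -> int:
        """Basin size of a given fixed-point state, 0 if not a fixed point."""
        for s, b in self.fixed_points:
            if s == state:
                return b
        return 0


def _check_state(net: ThresholdNetwork, s: NetworkState) -> None:
    if len(s) != net.n_nodes:
        raise ValueError(
            f"state has {len(s)} bits but network has {net.n_nodes} nodes"
        )


def successor_state(net: ThresholdNetwork, s: NetworkState) -> NetworkState:
    """Apply the synchronous threshold update rule once."""
    _check_state(net, s)
    bits = np.array(s.bits, dtype=np.int64)
    sums = net.weight_matrix @ bits
    nxt = np.where(sums > net.thresholds, 1, np.where(sums < net.thresholds, 0, bits))
    return NetworkState(tuple(int(b) for b in nxt))


def successor_map(net: ThresholdNetwork) -> np.ndarray:
    """Successor index of every state: array ``succ`` with succ[i] = index
    of the successor of the state with encoding ``i``.

    Vectorised over the full 2^N state space (node 0 = MSB).
    """
    n = net.n_nodes
    if n > EXHAUSTIVE_NODE_LIMIT:
        raise ValueError(
            f"network has {n} nodes; exhaustive enumeration is capped at "
            f"{EXHAUSTIVE_NODE_LIMIT} (raise boolcycle.dynamics.EXHAUSTIVE_NODE_LIMIT "
            "explicitly for larger state spaces)"
        )
    total = 1 << n
    idx = np.arange(total, dtype=np.int64)
    shifts = n - 1 - np.arange(n)
    states = (idx[:, None] >> shifts[None, :]) & 1          # (2^N, N) bit matrix
    sums = states @ net.weight_matrix.T                     # input sum per node
    nxt = np.where(
        sums > net.thresholds, 1, np.where(sums < net.thresholds, 0, states)
    )
    return (nxt << shifts[None, :]).sum(axis=1)


def simulate_trajectory(
    net: ThresholdNetwork, start: NetworkState, max_steps: int = 1000
) -> Trajectory:
    """Iterate the update rule from ``start`` until absorption or repetition.

    Stops when a fixed point is reached (``absorbed=True``; the fixed point
    is the final state and appears exactly once), when a previously seen
    state recurs (limit cycle; ``absorbed=False``), or after ``max_steps``
    transitions.
    """
    _check_state(net, start)
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    states = [start]
    seen = {start.index}
    absorbed = False
    current = start
    for _ in range(max_steps):
        nxt = successor_state(net, current)
        if nxt == current:
            absorbed = True
            break
        if nxt.index in seen:
            break
        states.append(nxt)
        seen.add(nxt.index)
        current = nxt
    traj = Trajectory(states=states, absorbed=absorbed)
    fixed_idx = states[-1].index if absorbed else None
    traj.phases = [
        label_phase(net, s, is_fixed=(s.index == fixed_idx)) for s in states
    ]
    return traj


def enumerate_attractors(net: ThresholdNetwork) -> AttractorReport:
    """Exhaustively decompose the state space into attractors and basins.

    Visits all 2^N states, finds every fixed point and limit cycle of the
    functional successor graph, and counts for each attractor the number of
    initial states whose orbit it absorbs.  Basin sizes always sum to 2^N.
    """
    n = net.n_nodes
    succ = successor_map(net)
    total = 1 << n

    # Iterated doubling sends every state to a state on its terminal cycle.
    f = succ
    for _ in range(max(1, n)):
        f = f[f]

    # Identify cycles by walking succ from each terminal representative;
    # canonical cycle id = smallest state index on the cycle.
    cycle_id = np.full(total, -1, dtype=np.int64)
    cycles: dict[int, list[int]] = {}
    for rep in np.unique(f):
        if cycle_id[rep] != -1:
            continue
        cyc = [int(rep)]
        cur = int(succ[rep])
        while cur != rep:
            cyc.append(cur)
            cur = int(succ[cur])
        cid = min(cyc)
        # rotate so the cycle starts at its canonical member
        k = cyc.index(cid)
        cyc = cyc[k:] + cyc[:k]
        for s in cyc:
            cycle_id[s] = cid
        cycles[cid] = cyc

    basin_of_state = cycle_id[f]                       # attractor id per state
    ids, counts = np.unique(basin_of_state, return_counts=True)
    basin = dict(zip(ids.tolist(), counts.tolist()))

    fixed_points: list[tuple[NetworkState, int]] = []
    limit_cycles: list[tuple[list[NetworkState], int]] = []
    for cid, members in cycles.items():
        b = basin.get(cid, 0)
        if len(members) == 1:
            fixed_points.append((NetworkState.from_index(cid, n), b))
        else:
            limit_cycles.append(
                ([NetworkState.from_index(s, n) for s in members], b)
            )

    fixed_points.sort(key=lambda fb: (-fb[1], fb[0].index))
    limit_cycles.sort(key=lambda cb: (-cb[1], cb[0][0].index))
    return AttractorReport(
        fixed_points=fixed_points, cycles=limit_cycles, total_states=total
    )


def label_phase(net: ThresholdNetwork, s: NetworkState, is_fixed: bool = False) -> str:
    """Cell-cycle phase of a state.

    S while the S-phase driver (cdk-2/cyclinE) is active; otherwise M while
    the M-phase driver (cdk-1/cyclinB) is active; otherwise the stationary
    M/S rest state if the state is a fixed point, else the S/M transition.
    Networks lacking the driver nodes get the unlabeled marker.
    """
    _check_state(net, s)
    names = net.node_names
    if S_DRIVER not in names or M_DRIVER not in names:
        return PHASE_UNLABELED
    if s.bits[net.node_index(S_DRIVER)]:
        return PHASE_S
    if s.bits[net.node_index(M_DRIVER)]:
        return PHASE_M
    return PHASE_MS if is_fixed else PHASE_SM


def export_state_transition_graph(
    net: ThresholdNetwork, path, format: str = "graphml"
) -> nx.DiGraph:
    """Write the full STG (2^N nodes, one out-edge per state).

    Node attributes: ``is_attractor`` (state lies on a fixed point or limit
    cycle), ``basin_id`` (canonical index of its attractor), and
    ``is_largest_attractor`` for states of the largest-basin attractor.
    Returns the graph for further use.
    """
    if format not in ("graphml", "dot"):
        raise ValueError(f"format must be 'graphml' or 'dot', got {format!r}")
    n = net.n_nodes
    succ = successor_map(net)
    report = enumerate_attractors(net)

    attractor_states: set[int] = {s.index for s, _ in report.fixed_points}
    for cyc, _ in report.cycles:
        attractor_states.update(s.index for s in cyc)

    all_attractors = [(s.index, b) for s, b in report.fixed_points] + [
        (cyc[0].index, b) for cyc, b in report.cycles
    ]
    largest_id = max(all_attractors, key=lambda ib: (ib[1], -ib[0]))[0] if all_attractors else -1
    largest_members: set[int] = set()
    for s, _ in report.fixed_points:
        if s.index == largest_id:
            largest_members.add(s.index)
    for cyc, _ in report.cycles:
        if cyc[0].index == largest_id:
            largest_members.update(s.index for s in cyc)

    f = succ
    for _ in range(max(1, n)):
        f = f[f]

    # canonical attractor index for every attractor-member state
    canon: dict[int, int] = {s.index: s.index for s, _ in report.fixed_points}
    for cyc, _ in report.cycles:
        for member in cyc:
            canon[member.index] = cyc[0].index

    g = nx.DiGraph()
    for i in range(1 << n):
        label = str(NetworkState.from_index(i, n))
        basin_id = canon[int(f[i])]
        g.add_node(
            label,
            is_attractor=bool(i in attractor_states),
            basin_id=str(NetworkState.from_index(basin_id, n)),
            is_largest_attractor=bool(i in largest_members),
        )
    for i in range(1 << n):
        g.add_edge(
            str(NetworkState.from_index(i, n)),
            str(NetworkState.from_index(int(succ[i]), n)),
        )
    if format == "graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("digraph stg {\n")
            for node, data in g.nodes(data=True):
                attrs = ",".join(f'{k}="{v}"' for k, v in data.items())
                fh.write(f'  "{node}" [{attrs}];\n')
            for u, v in g.edges():
                fh.write(f'  "{u}" -> "{v}";\n')
            fh.write("}\n")
    return g
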