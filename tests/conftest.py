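"""Shared fixtures and the independent brute-force oracle.

The oracle deliberately avoids the package's vectorised successor map: it
re-derives the update rule per node in pure Python and follows each orbit
with explicit cycle detection, so enumeration results can be cross-checked
on small networks.
"""

from __future__ import annotations

import numpy as np
import pytest

from boolcycle import (
    Interaction,
    RegulatorNode,
    ThresholdNetwork,
    build_celegans_network,
)


@pytest.fixture(scope="session")
def celegans():
    return build_celegans_network()


@pytest.fixture()
def toy_net():
    """2-node net from the worked examples: A activates B, B self-degrades."""
    nodes = [RegulatorNode("A", "A", 0), RegulatorNode("B", "B", 1)]
    inter = [Interaction("A", "B", +1), Interaction("B", "B", -1)]
    return ThresholdNetwork(nodes=nodes, interactions=inter)


@pytest.fixture()
def edgeless_net():
    nodes = [RegulatorNode("A", "A", 0), RegulatorNode("B", "B", 1)]
    return ThresholdNetwork(nodes=nodes, interactions=[])


def oracle_successor(net: ThresholdNetwork, bits: tuple[int, ...]) -> tuple[int, ...]:
    """Per-node threshold update, written longhand."""
    w = net.weight_matrix
    theta = net.thresholds
    out = []
    for i in range(net.n_nodes):
        total = 0
        for j in range(net.n_nodes):
            total += int(w[i, j]) * bits[j]
        if total > theta[i]:
            out.append(1)
        elif total < theta[i]:
            out.append(0)
        else:
            out.append(bits[i])
    return tuple(out)


def oracle_attractors(net: ThresholdNetwork):
    """Follow every orbit with cycle detection; return (attractors, basins).

    Attractors are frozensets of member state-tuples; basins map each
    attractor to the number of initial states absorbed by it.
    """
    n = net.n_nodes
    all_states = [
        tuple((s >> (n - 1 - i)) & 1 for i in range(n)) for s in range(1 << n)
    ]
    attractor_of: dict[tuple[int, ...], frozenset] = {}
    basins: dict[frozenset, int] = {}
    for start in all_states:
        path = []
        seen = {}
        cur = start
        while cur not in seen:
            if cur in attractor_of:
                break
            seen[cur] = len(path)
            path.append(cur)
            cur = oracle_successor(net, cur)
        if cur in attractor_of:
            att = attractor_of[cur]
        else:
            att = frozenset(path[seen[cur]:])
        for s in path:
            attractor_of[s] = att
        basins[att] = basins.get(att, 0) + len(path)
    return basins


def random_small_net(rng: np.random.Generator, n_nodes: int) -> ThresholdNetwork:
    """A random signed network on <= 4 nodes for oracle cross-checks."""
    w = rng.integers(-1, 2, size=(n_nodes, n_nodes))
    return ThresholdNetwork.from_weight_matrix(w)
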