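"""Signed threshold networks and the built-in *C. elegans* cell-cycle model.

A :class:`ThresholdNetwork` is a directed network of named regulators with
signed integer edge weights (+1 activation, -1 repression/degradation) and a
real activation threshold per node (0 by default).  The built-in network
models the two-phase (S/M) cell cycle of the early *C. elegans* embryo with
eight merged regulator nodes and 21 literature-curated interactions,
including -1 self-degradation loops on the three nodes that lack an explicit
repressor (cul-1/lin-23, fzr-1, cki-1).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "RegulatorNode",
    "Interaction",
    "ThresholdNetwork",
    "NetworkFormatError",
    "build_celegans_network",
    "read_edge_list",
    "write_edge_list",
    "export_sif",
    "export_graphml",
]


class NetworkFormatError(ValueError):
    """Raised for malformed or inconsistent network definitions."""


@dataclass(frozen=True)
class RegulatorNode:
    """A regulator (gene/protein or merged complex) in the network.

    ``name`` is a short file-safe slug; ``label`` is the display name
    (e.g. ``"cdk-2/cyclinE"``); ``index`` is the position in the canonical
    node order used for all bit-strings and reports.
    """

    name: str
    label: str
    index: int


@dataclass(frozen=True)
class Interaction:
    """A signed directed edge: +1 activation, -1 repression/degradation."""

    source: str
    target: str
    weight: int

    def __post_init__(self) -> None:
        if self.weight not in (1, -1):
            raise NetworkFormatError(
                f"interaction weight must be +1 or -1, got {self.weight!r}"
            )


@dataclass
class ThresholdNetwork:
    """A signed, weighted directed network with per-node thresholds.

    The dynamics treat ``weight_matrix[i, j]`` as the weight of the edge
    from node *j* onto node *i* (row = target, column = source), so the
    weighted input to node *i* in state ``s`` is ``weight_matrix[i] @ s``.
    """

    nodes: list[RegulatorNode]
    interactions: list[Interaction] = field(default_factory=list)
    thresholds: np.ndarray | None = None

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise NetworkFormatError("node names must be unique")
        if [n.index for n in self.nodes] != list(range(len(self.nodes))):
            raise NetworkFormatError("node indices must be 0..N-1 in order")
        if self.thresholds is None:
            self.thresholds = np.zeros(len(self.nodes))
        else:
            self.thresholds = np.asarray(self.thresholds, dtype=float)
            if self.thresholds.shape != (len(self.nodes),):
                raise NetworkFormatError("one threshold per node required")
        self._index = {n.name: n.index for n in self.nodes}
        seen: set[tuple[str, str]] = set()
        for it in self.interactions:
            if it.source not in self._index or it.target not in self._index:
                raise NetworkFormatError(
                    f"interaction {it.source}->{it.target} references unknown node"
                )
            pair = (it.source, it.target)
            if pair in seen:
                raise NetworkFormatError(f"duplicate interaction {pair}")
            seen.add(pair)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def node_labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    def node_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"no node named {name!r}; known: {self.node_names}") from None

    @property
    def weight_matrix(self) -> np.ndarray:
        """N x N signed integer matrix; ``W[target, source]`` layout."""
        w = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int64)
        for it in self.interactions:
            w[self._index[it.target], self._index[it.source]] = it.weight
        return w

    def weight(self, source: str, target: str) -> int:
        """Weight of the edge source -> target, 0 if absent."""
        return int(self.weight_matrix[self.node_index(target), self.node_index(source)])

    def has_interaction(self, source: str, target: str) -> bool:
        return any(it.source == source and it.target == target for it in self.interactions)

    def copy(self) -> "ThresholdNetwork":
        return ThresholdNetwork(
            nodes=list(self.nodes),
            interactions=list(self.interactions),
            thresholds=self.thresholds.copy(),
        )

    @classmethod
    def from_weight_matrix(
        cls,
        w: np.ndarray,
        names: list[str] | None = None,
        labels: list[str] | None = None,
        thresholds: np.ndarray | None = None,
    ) -> "ThresholdNetwork":
        """Build a network from a (target, source) signed weight matrix."""
        w = np.asarray(w)
        n = w.shape[0]
        if w.shape != (n, n):
            raise NetworkFormatError("weight matrix must be square")
        if names is None:
            names = [f"n{i}" for i in range(n)]
        if labels is None:
            labels = list(names)
        nodes = [RegulatorNode(nm, lb, i) for i, (nm, lb) in enumerate(zip(names, labels))]
        interactions = [
            Interaction(names[j], names[i], int(w[i, j]))
            for i in range(n)
            for j in range(n)
            if w[i, j] != 0
        ]
        return cls(nodes=nodes, interactions=interactions, thresholds=thresholds)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node.name, label=node.label, index=node.index)
        for it in self.interactions:
            g.add_edge(it.source, it.target, weight=it.weight)
        return g


# Canonical node order follows the attractor-table layout; slugs keep file
# formats happy while labels preserve the biological names.
_CELEGANS_NODES: list[tuple[str, str]] = [
    ("cdk2_cyclinE", "cdk-2/cyclinE"),
    ("cdc251", "cdc-25.1"),
    ("cul1_lin23", "cul-1/lin-23"),
    ("lin35_efl1_dpl1", "lin-35/efl-1/dpl-1"),
    ("cdk1_cyclinB", "cdk-1/cyclinB"),
    ("fzr1", "fzr-1"),
    ("cdc14_fzy1", "cdc-14/fzy-1"),
    ("cki1", "cki-1"),
]

# The 21 curated interactions: 9 activating, 12 repressing (three of them
# self-degradation loops on the nodes without an explicit repressor).
_CELEGANS_EDGES: list[tuple[str, str, int]] = [
    ("cdc14_fzy1", "cdk1_cyclinB", -1),  # fzy-1 activates APC -> cyclin B degraded
    ("cdc14_fzy1", "fzr1", +1),
    ("cdc14_fzy1", "cki1", +1),
    ("cdc251", "cdk2_cyclinE", +1),      # dephosphorylation activates CDK-2
    ("cdc251", "cdk1_cyclinB", +1),
    ("cdk1_cyclinB", "cdc14_fzy1", +1),
    ("cdk2_cyclinE", "cul1_lin23", +1),  # SCF turned on for cyclin E degradation
    ("cdk2_cyclinE", "lin35_efl1_dpl1", -1),
    ("cdk2_cyclinE", "cdc14_fzy1", -1),
    ("cki1", "cdk2_cyclinE", -1),        # CKI is rate-limiting for S entry
    ("cki1", "cdk1_cyclinB", -1),
    ("cki1", "cki1", -1),                # self-degradation
    ("cul1_lin23", "cdk2_cyclinE", -1),  # SCF degrades cyclin E
    ("cul1_lin23", "cdc251", -1),
    ("cul1_lin23", "cul1_lin23", -1),    # self-degradation
    ("cul1_lin23", "lin35_efl1_dpl1", +1),
    ("fzr1", "cdk1_cyclinB", -1),        # APC route for cyclin B degradation
    ("fzr1", "fzr1", -1),                # self-degradation
    ("fzr1", "cki1", +1),
    ("lin35_efl1_dpl1", "cdk2_cyclinE", -1),  # Rb/E2F represses cyclin E
    ("lin35_efl1_dpl1", "cdk1_cyclinB", +1),  # efl-1/dpl-1 promotes cyclin B
]


def build_celegans_network() -> ThresholdNetwork:
    """The built-in 8-node, 21-edge early embryonic cell-cycle network.

    All thresholds are 0; nodes are in canonical order (cdk-2/cyclinE,
    cdc-25.1, cul-1/lin-23, lin-35/efl-1/dpl-1, cdk-1/cyclinB, fzr-1,
    cdc-14/fzy-1, cki-1).
    """
    nodes = [RegulatorNode(nm, lb, i) for i, (nm, lb) in enumerate(_CELEGANS_NODES)]
    interactions = [Interaction(s, t, w) for s, t, w in _CELEGANS_EDGES]
    return ThresholdNetwork(nodes=nodes, interactions=interactions)


# ---------------------------------------------------------------------------
# Edge-list TSV dialect:
#   # comment lines anywhere
#   #nodes: name1 name2 ...      (optional; fixes canonical node order)
#   #labels: lbl1|lbl2|...       (optional; display labels, same order)
#   source <TAB> target <TAB> +1|-1
# Without a #nodes: header, nodes appear in first-occurrence order.
# ---------------------------------------------------------------------------

def read_edge_list(path) -> ThresholdNetwork:
    """Read a network from the tab-separated edge-list dialect."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()

    declared: list[str] | None = None
    labels: list[str] | None = None
    edges: list[tuple[str, str, int]] = []
    order: list[str] = []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#nodes:"):
            declared = line[len("#nodes:"):].split()
            continue
        if line.startswith("#labels:"):
            labels = [s.strip() for s in line[len("#labels:"):].strip().split("|")]
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 'source<TAB>target<TAB>weight', got {line!r}"
            )
        src, tgt, wtok = (p.strip() for p in parts)
        if wtok not in ("+1", "-1", "1"):
            raise NetworkFormatError(
                f"{path}:{lineno}: weight must be '+1' or '-1', got {wtok!r}"
            )
        w = 1 if wtok in ("+1", "1") else -1
        edges.append((src, tgt, w))
        for nm in (src, tgt):
            if nm not in order:
                order.append(nm)

    names = declared if declared is not None else order
    if declared is not None:
        missing = [nm for nm in order if nm not in declared]
        if missing:
            raise NetworkFormatError(
                f"{path}: interaction references nodes missing from #nodes: header: {missing}"
            )
    if labels is None:
        labels = list(names)
    elif len(labels) != len(names):
        raise NetworkFormatError(f"{path}: #labels: count does not match node count")

    nodes = [RegulatorNode(nm, lb, i) for i, (nm, lb) in enumerate(zip(names, labels))]
    seen: set[tuple[str, str]] = set()
    interactions = []
    for src, tgt, w in edges:
        if (src, tgt) in seen:
            raise NetworkFormatError(f"{path}: duplicate interaction {src}->{tgt}")
        seen.add((src, tgt))
        interactions.append(Interaction(src, tgt, w))
    return ThresholdNetwork(nodes=nodes, interactions=interactions)


def write_edge_list(net: ThresholdNetwork, path) -> None:
    """Write the TSV edge-list dialect; :func:`read_edge_list` inverts it."""
    buf = io.StringIO()
    buf.write("#nodes: " + " ".join(net.node_names) + "\n")
    buf.write("#labels: " + "|".join(net.node_labels) + "\n")
    buf.write("#source\ttarget\tweight\n")
    for it in net.interactions:
        buf.write(f"{it.source}\t{it.target}\t{'+1' if it.weight > 0 else '-1'}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def export_sif(net: ThresholdNetwork, path) -> None:
    """Write a Cytoscape SIF file: ``source activates|represses target``.

    Isolated nodes are written as bare node lines so they survive import.
    """
    touched = {it.source for it in net.interactions} | {it.target for it in net.interactions}
    with open(path, "w", encoding="utf-8") as fh:
        for it in net.interactions:
            rel = "activates" if it.weight > 0 else "represses"
            fh.write(f"{it.source} {rel} {it.target}\n")
        for nm in net.node_names:
            if nm not in touched:
                fh.write(nm + "\n")


def export_graphml(net: ThresholdNetwork, path) -> None:
    """Write GraphML with a ``weight`` attribute per edge (Cytoscape-loadable)."""
    nx.write_graphml(net.to_networkx(), path)
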