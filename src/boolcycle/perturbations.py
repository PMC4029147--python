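"""Structural robustness tests and in-silico gene knockdown.

Robustness is probed one edge at a time: delete an existing interaction,
add a signed interaction on an empty ordered pair, or switch the sign of an
existing interaction.  The observable is the relative change dB/B of the
largest attractor's basin.  By default B_perturbed is the basin of the
*original* largest-attractor state in the perturbed network (0 if that
state is no longer a fixed point); ``track="largest"`` switches to the
perturbed network's own largest basin.

Knockdown mimics RNAi: the knocked gene stops affecting its targets, so all
its outgoing weights (including any self-loop) are zeroed while its
incoming edges stay intact and the node keeps updating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dynamics import (
    AttractorReport,
    NetworkState,
    Trajectory,
    enumerate_attractors,
    simulate_trajectory,
)
from .network import Interaction, ThresholdNetwork

__all__ = [
    "Perturbation",
    "PerturbationResult",
    "KnockdownSpec",
    "apply_perturbation",
    "enumerate_perturbations",
    "perturbation_scan",
    "ensemble_perturbation_comparison",
    "knockdown_network",
    "knockdown_analysis",
    "remove_node",
    "delta_histogram",
]

KINDS = ("delete", "add", "switch")


@dataclass(frozen=True)
class Perturbation:
    """A single-edge structural change."""

    kind: str
    source: str
    target: str
    weight: int | None = None  # required sign for 'add'

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "add" and self.weight not in (1, -1):
            raise ValueError("'add' perturbation requires weight +1 or -1")


@dataclass
class PerturbationResult:
    perturbation: Perturbation
    b_original: int
    b_perturbed: int

    @property
    def delta_rel(self) -> float:
        """(B_perturbed - B_original) / B_original."""
        return (self.b_perturbed - self.b_original) / self.b_original


@dataclass(frozen=True)
class KnockdownSpec:
    """Genes to silence; the rule zeroes each gene's outgoing weights."""

    knocked_nodes: tuple[str, ...]

    def __init__(self, knocked_nodes: Iterable[str]):
        object.__setattr__(self, "knocked_nodes", tuple(knocked_nodes))


def apply_perturbation(net: ThresholdNetwork, p: Perturbation) -> ThresholdNetwork:
    """Return a new network with the perturbation applied; input untouched."""
    net.node_index(p.source)
    net.node_index(p.target)
    exists = net.has_interaction(p.source, p.target)
    if p.kind in ("delete", "switch") and not exists:
        raise ValueError(f"no interaction {p.source}->{p.target} to {p.kind}")
    if p.kind == "add" and exists:
        raise ValueError(f"interaction {p.source}->{p.target} already present")

    interactions = []
    for it in net.interactions:
        if it.source == p.source and it.target == p.target:
            if p.kind == "delete":
                continue
            interactions.append(Interaction(it.source, it.target, -it.weight))
        else:
            interactions.append(it)
    if p.kind == "add":
        interactions.append(Interaction(p.source, p.target, int(p.weight)))
    return ThresholdNetwork(
        nodes=list(net.nodes), interactions=interactions, thresholds=net.thresholds.copy()
    )


def enumerate_perturbations(
    net: ThresholdNetwork, kinds: Sequence[str]
) -> list[Perturbation]:
    """Every applicable single perturbation of the requested kinds:
    each existing edge for delete/switch, each empty ordered pair with both
    signs for add."""
    for k in kinds:
        if k not in KINDS:
            raise ValueError(f"unknown perturbation kind {k!r}")
    perts: list[Perturbation] = []
    occupied = {(it.source, it.target) for it in net.interactions}
    if "delete" in kinds:
        perts += [Perturbation("delete", it.source, it.target) for it in net.interactions]
    if "add" in kinds:
        for src in net.node_names:
            for tgt in net.node_names:
                if (src, tgt) not in occupied:
                    perts.append(Perturbation("add", src, tgt, +1))
                    perts.append(Perturbation("add", src, tgt, -1))
    if "switch" in kinds:
        perts += [Perturbation("switch", it.source, it.target) for it in net.interactions]
    return perts


def _basin_after(
    perturbed: ThresholdNetwork, original_largest: NetworkState, track: str
) -> int:
    report = enumerate_attractors(perturbed)
    if track == "largest":
        basins = report.basin_sizes
        return max(basins) if basins else 0
    return report.basin_of(original_largest)


def perturbation_scan(
    net: ThresholdNetwork,
    kinds: Sequence[str] = KINDS,
    track: str = "original",
) -> list[PerturbationResult]:
    """dB/B for every applicable single perturbation of the given kinds.

    ``track="original"`` (default) follows the unperturbed network's
    largest-attractor state through each perturbation; ``track="largest"``
    reports the perturbed network's own largest basin.
    """
    if track not in ("original", "largest"):
        raise ValueError("track must be 'original' or 'largest'")
    base = enumerate_attractors(net)
    if not base.fixed_points:
        raise ValueError("network has no fixed point; dB/B undefined")
    largest_state, b0 = base.largest_fixed_point
    results = []
    for p in enumerate_perturbations(net, kinds):
        b1 = _basin_after(apply_perturbation(net, p), largest_state, track)
        results.append(PerturbationResult(perturbation=p, b_original=b0, b_perturbed=b1))
    return results


def delta_histogram(results: Sequence[PerturbationResult]) -> dict[float, float]:
    """Empirical probability of each observed dB/B value (probabilities sum to 1)."""
    if not results:
        return {}
    vals, counts = np.unique(
        np.round([r.delta_rel for r in results], 12), return_counts=True
    )
    total = counts.sum()
    return {float(v): float(c) / total for v, c in zip(vals, counts)}


def ensemble_perturbation_comparison(
    reference: ThresholdNetwork,
    spec,
    kinds: Sequence[str] = KINDS,
    track: str = "original",
) -> dict:
    """Pooled dB/B comparison: reference network vs a random ensemble.

    Runs a full single-perturbation scan on the reference network and on
    every ensemble member (members without a fixed point are skipped, as
    dB/B is undefined there), and reports the probability mass at
    dB/B = 0 for each, plus the pooled histograms.
    """
    from .ensembles import generate_random_network  # local to avoid cycle

    ref_results = perturbation_scan(reference, kinds, track=track)
    ref_hist = delta_histogram(ref_results)
    ref_p0 = ref_hist.get(0.0, 0.0)

    pooled: list[float] = []
    per_network_p0: list[float] = []
    skipped = 0
    for k in range(spec.n_networks):
        net = generate_random_network(spec, k)
        try:
            results = perturbation_scan(net, kinds, track=track)
        except ValueError:
            skipped += 1
            continue
        deltas = [r.delta_rel for r in results]
        pooled.extend(deltas)
        per_network_p0.append(float(np.mean(np.isclose(deltas, 0.0))))

    ens = np.array(pooled)
    ens_hist: dict[float, float] = {}
    if len(ens):
        vals, counts = np.unique(np.round(ens, 12), return_counts=True)
        ens_hist = {float(v): float(c) / counts.sum() for v, c in zip(vals, counts)}
    return {
        "reference_p0": ref_p0,
        "reference_histogram": ref_hist,
        "ensemble_p0": ens_hist.get(0.0, 0.0),
        "ensemble_p0_per_network_mean": float(np.mean(per_network_p0)) if per_network_p0 else 0.0,
        "ensemble_histogram": ens_hist,
        "n_ensemble_networks": spec.n_networks - skipped,
        "n_skipped_no_fixed_point": skipped,
    }


def knockdown_network(
    net: ThresholdNetwork, spec: KnockdownSpec | Iterable[str]
) -> ThresholdNetwork:
    """Zero all outgoing weights of each knocked node (self-loops included).

    Incoming edges are untouched: the knocked node keeps updating, it just
    no longer affects any target.
    """
    if not isinstance(spec, KnockdownSpec):
        spec = KnockdownSpec(spec)
    for name in spec.knocked_nodes:
        net.node_index(name)  # raises KeyError for unknown nodes
    knocked = set(spec.knocked_nodes)
    interactions = [it for it in net.interactions if it.source not in knocked]
    return ThresholdNetwork(
        nodes=list(net.nodes), interactions=interactions, thresholds=net.thresholds.copy()
    )


def remove_node(net: ThresholdNetwork, node: str) -> ThresholdNetwork:
    """Drop a node and every interaction touching it, reindexing the rest."""
    net.node_index(node)
    from .network import RegulatorNode

    kept = [n for n in net.nodes if n.name != node]
    nodes = [RegulatorNode(n.name, n.label, i) for i, n in enumerate(kept)]
    keep_idx = [n.index for n in kept]
    interactions = [
        it for it in net.interactions if node not in (it.source, it.target)
    ]
    return ThresholdNetwork(
        nodes=nodes,
        interactions=interactions,
        thresholds=net.thresholds[keep_idx].copy(),
    )


def knockdown_analysis(
    net: ThresholdNetwork, node: str, max_steps: int = 1000, project: bool = True
) -> tuple[AttractorReport, Trajectory]:
    """Attractor report of the knocked network plus its cell-cycle pathway.

    With a gene's outgoing weights zeroed, the dynamics of the remaining
    genes no longer depend on it: the knocked node is a read-out that rides
    along, and full-state-space attractors differing only in its bit are
    the same regulatory attractor.  ``project=True`` (default) therefore
    counts attractors of the dynamics restricted to the genes that still
    regulate — equivalently, of the network with the knocked node removed —
    over its 2^(N-1) states.  ``project=False`` enumerates the knocked
    N-node network over all 2^N states, passenger bit included.

    The pathway always runs on the full knocked network.  It starts from
    the S-entry state: the unperturbed network's largest-attractor pattern
    with the S-phase driver (cdk-2/cyclinE) forced on and the knocked gene
    silenced (bit 0), mirroring how the cycle is triggered from the
    stationary state while the gene is knocked down.
    """
    from .dynamics import S_DRIVER

    knocked = knockdown_network(net, [node])
    if project:
        report = enumerate_attractors(remove_node(net, node))
    else:
        report = enumerate_attractors(knocked)

    base = enumerate_attractors(net)
    if base.largest_fixed_point is None:
        raise ValueError("network has no fixed point; no stationary state to start from")
    start = base.largest_fixed_point[0]
    if S_DRIVER in net.node_names:
        start = start.with_bit(net.node_index(S_DRIVER), 1)
    start = start.with_bit(net.node_index(node), 0)
    trajectory = simulate_trajectory(knocked, start, max_steps=max_steps)
    return report, trajectory
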