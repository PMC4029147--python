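"""Random-network null ensembles matched on size and sign counts.

The null model keeps what the reference network fixes — the number of
nodes, the number of activating (+1) edges, and the number of repressing
(-1) edges — and randomises everything else: edges are placed uniformly at
random over distinct ordered node pairs and the two sign classes are
assigned by a uniform random partition.  Self-loops are excluded by
default; the convention is switchable, and the null statistics are mildly
sensitive to it (see the methods note), with the no-self-loop sampler the
one whose largest-basin statistics line up with the published reference
values.  Enumerating
the attractors of each draw yields null distributions for the fixed-point
count, the largest basin, and the pooled basin-size histogram against which
the biological network is compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import enumerate_attractors
from .network import ThresholdNetwork

__all__ = [
    "EnsembleSpec",
    "EnsembleStats",
    "generate_random_network",
    "run_ensemble",
    "basin_size_distribution",
    "DEFAULT_SPEC",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of a matched random ensemble.

    Defaults mirror the reference cell-cycle network: 8 nodes, 9 activating
    and 12 repressing edges, 1000 draws.
    """

    n_networks: int = 1000
    n_nodes: int = 8
    n_activating: int = 9
    n_repressing: int = 12
    allow_self_loops: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 1 or self.n_nodes < 1:
            raise ValueError("n_networks and n_nodes must be positive")
        if self.n_activating < 0 or self.n_repressing < 0:
            raise ValueError("edge counts must be non-negative")
        n_pairs = self.n_nodes**2 if self.allow_self_loops else self.n_nodes * (self.n_nodes - 1)
        if self.n_activating + self.n_repressing > n_pairs:
            raise ValueError(
                f"{self.n_activating + self.n_repressing} edges do not fit in "
                f"{n_pairs} allowed ordered pairs"
            )

    @property
    def n_edges(self) -> int:
        return self.n_activating + self.n_repressing


DEFAULT_SPEC = EnsembleSpec()


@dataclass
class EnsembleStats:
    """Summary of an ensemble run.

    Per-network vectors are kept so that means, standard errors and
    exceedance fractions are recomputable; the basin histogram pools every
    fixed-point attractor across the ensemble.
    """

    spec: EnsembleSpec
    reference_basin: int
    attractor_counts: np.ndarray          # fixed points per network
    largest_basins: np.ndarray            # largest fixed-point basin per network (0 if none)
    all_basins: np.ndarray                # pooled basin sizes of every fixed point
    cycle_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    @property
    def n_networks(self) -> int:
        return len(self.attractor_counts)

    @property
    def mean_attractors(self) -> float:
        return float(np.mean(self.attractor_counts))

    @property
    def mean_largest_basin(self) -> float:
        return float(np.mean(self.largest_basins))

    def sem_attractors(self) -> float:
        return float(np.std(self.attractor_counts, ddof=1) / np.sqrt(self.n_networks))

    def sem_largest_basin(self) -> float:
        return float(np.std(self.largest_basins, ddof=1) / np.sqrt(self.n_networks))

    @property
    def exceedance_fraction(self) -> float:
        """Fraction of all pooled fixed points with basin > reference."""
        if len(self.all_basins) == 0:
            return 0.0
        return float(np.mean(self.all_basins > self.reference_basin))

    @property
    def exceedance_fraction_per_network(self) -> float:
        """Alternative reading: fraction of per-network largest basins > reference."""
        return float(np.mean(self.largest_basins > self.reference_basin))

    def basin_histogram(self) -> dict[int, float]:
        """Empirical probability of each basin size over pooled fixed points."""
        if len(self.all_basins) == 0:
            return {}
        sizes, counts = np.unique(self.all_basins, return_counts=True)
        total = counts.sum()
        return {int(s): float(c) / total for s, c in zip(sizes, counts)}


def _rng_for_draw(seed: int, draw_index: int) -> np.random.Generator:
    # one independent stream per draw so ensembles are order-insensitive
    return np.random.default_rng(np.random.SeedSequence([seed, draw_index]))


def generate_random_network(spec: EnsembleSpec, draw_index: int = 0) -> ThresholdNetwork:
    """Draw one random network: uniform distinct ordered pairs, random sign
    partition, thresholds 0.  Reproducible given (spec.seed, draw_index)."""
    rng = _rng_for_draw(spec.seed, draw_index)
    n = spec.n_nodes
    pairs = [(i, j) for i in range(n) for j in range(n) if spec.allow_self_loops or i != j]
    chosen = rng.choice(len(pairs), size=spec.n_edges, replace=False)
    signs = np.concatenate(
        [np.ones(spec.n_activating, dtype=np.int64), -np.ones(spec.n_repressing, dtype=np.int64)]
    )
    rng.shuffle(signs)
    w = np.zeros((n, n), dtype=np.int64)
    for k, s in zip(chosen, signs):
        src, tgt = pairs[int(k)]
        w[tgt, src] = s
    return ThresholdNetwork.from_weight_matrix(w)


def run_ensemble(spec: EnsembleSpec, reference_basin: int = 219) -> EnsembleStats:
    """Generate and exhaustively analyse every network of the ensemble."""
    counts = np.zeros(spec.n_networks, dtype=np.int64)
    largest = np.zeros(spec.n_networks, dtype=np.int64)
    n_cycles = np.zeros(spec.n_networks, dtype=np.int64)
    pooled: list[int] = []
    for k in range(spec.n_networks):
        net = generate_random_network(spec, k)
        report = enumerate_attractors(net)
        counts[k] = report.n_fixed_points
        n_cycles[k] = len(report.cycles)
        basins = report.basin_sizes
        largest[k] = max(basins) if basins else 0
        pooled.extend(basins)
    return EnsembleStats(
        spec=spec,
        reference_basin=reference_basin,
        attractor_counts=counts,
        largest_basins=largest,
        all_basins=np.array(pooled, dtype=np.int64),
        cycle_counts=n_cycles,
    )


def basin_size_distribution(stats: EnsembleStats, path) -> None:
    """Write the pooled basin-size distribution as a two-column TSV
    (basin_size, probability); suitable for log-log plotting."""
    hist = stats.basin_histogram()
    if not hist:
        raise ValueError("ensemble contains no fixed points; nothing to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#basin_size\tprobability\n")
        for size in sorted(hist):
            fh.write(f"{size}\t{hist[size]:.10g}\n")
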