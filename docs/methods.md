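# Methods

## Model and update rule

The package models gene/protein activity as binary states evolving under a
synchronous threshold rule. For node *i* with inputs weighted
$w_{ij} \in \{+1,-1\}$ and threshold $\theta_i$ (0 unless set otherwise),
the next state is 1 when the weighted input sum exceeds the threshold, 0
when it falls below, and unchanged at equality. Two consequences of the
tie branch matter in practice:

* a node with no inputs (or with all inputs off) holds its state
  indefinitely — the all-off state of the built-in network is therefore a
  fixed point;
* self-degradation is modelled purely as a $w_{ii}=-1$ summand competing
  with the other inputs in the same sum, not as a separate time-delayed
  decay. This reading reproduces the bundled network's full 8-step
  cell-cycle trajectory row for row, which is the deciding evidence for
  it.

Updates are strictly synchronous. Asynchronous or continuous-time
schemes, which can change which attractors exist, are out of scope.

## The built-in network

The bundled network has 8 nodes and 21 signed interactions (9 activating,
12 repressing, of which 3 are self-degradation loops on cul-1/lin-23,
fzr-1 and cki-1, the nodes lacking an explicit repressor). All thresholds
are 0. The canonical node order — cdk-2/cyclinE, cdc-25.1, cul-1/lin-23,
lin-35/efl-1/dpl-1, cdk-1/cyclinB, fzr-1, cdc-14/fzy-1, cki-1 — fixes the
layout of every bit-string, report and file the package emits. Node names
are file-safe slugs (`cdk2_cyclinE`); the biological labels are kept as
display metadata. Merged regulators (e.g. cdk-2/cyclinE) are single
nodes; no sub-gene resolution is attempted.

## Attractor enumeration

`enumerate_attractors` visits all $2^N$ states (vectorised over the full
state space; node 0 is the most significant bit of the state index). The
successor map is a functional graph, so iterated doubling
($f \mapsto f \circ f$, $\lceil \log_2 2^N \rceil$ rounds) sends every
state to a state on its terminal cycle; cycles are then walked explicitly
and identified by their smallest member index. Fixed points are
length-one cycles. The basin of an attractor counts every initial state
absorbed by it, with cycle states counting toward their own cycle's basin,
so basins always partition the state space — the package asserts
$\sum B = 2^N$ on every network it touches. Attractors are reported in
descending basin order, ties broken by ascending state index, making
reports deterministic. Exhaustive enumeration is capped at 20 nodes
(1,048,576 states); the cap is a module constant that a caller can raise
deliberately.

For the built-in network the enumeration yields five fixed points, no
limit cycles, basins 219/16/12/5/4; the dominant rest state has the
degraders and CDK inhibitor on and both cyclin drivers off. Phase labels
follow the drivers: S while cdk-2/cyclinE is active, else M while
cdk-1/cyclinB is active, else M/S for a fixed point and S/M for a
transient state. Networks lacking the driver nodes get an unlabeled
marker.

## Knockdown rule

In-silico RNAi zeroes every outgoing weight of the silenced gene,
self-loop included; incoming edges stay intact and the node keeps
updating. Under this rule the remaining genes' dynamics are provably
independent of the silenced gene's state (verified exhaustively in the
tests), which has one structural consequence: the silenced gene is an
output-only passenger, and full-state-space attractors that differ only in
its bit describe the same regulatory attractor. Attractor counts after
knockdown are therefore taken over the dynamics projected onto the genes
that still regulate — equivalently, over the network with the silenced
node removed ($2^{N-1}$ states). The full $2^N$ report remains available
behind a flag. Projected counts for the built-in network: cdc-14/fzy-1
knockdown 4, lin-35/efl-1/dpl-1 knockdown 3, cki-1 knockdown 5.

The knockdown pathway is simulated on the full 8-node knocked network
from the S-entry state: the rest-state pattern with cdk-2/cyclinE forced
on and the silenced gene set to 0. For cki-1 this yields a shortened
7-step cycle. One caveat is deliberate: the silenced gene's own column
follows the update rule (its intact incoming edges can re-activate it
mid-trajectory), so golden comparisons of the knockdown pathway cover the
seven non-silenced columns; the cki-1 column itself is not a stable
observable of the rule and is documented rather than patched.

## Random-network null

The null ensemble fixes what the reference network fixes — 8 nodes, 9
activating and 12 repressing edges — and randomises placement: edge
positions are drawn uniformly without replacement from the distinct
ordered node pairs, and the +1/-1 signs are assigned by a uniform random
partition. Each draw gets an independent child stream of the ensemble
seed (`SeedSequence([seed, draw_index])`), so ensembles are bit-reproducible
and order-insensitive. "Attractor" in ensemble statistics means fixed
point; limit cycles are tallied separately and excluded from the counts,
and a network with no fixed point contributes a largest basin of 0.

Self-loops are excluded from the null by default. The convention is
switchable and the statistics are mildly sensitive to it: at 1000
networks, the no-self-loop sampler gives a mean largest basin of
105.1–105.6 (across seeds) against the reference value 105.56, whereas
allowing self-loops depresses it to 99–103. That agreement is why the
no-self-loop convention is the default. The mean fixed-point count is
15.7–16.0 without self-loops (14.7–15.1 with), against a reference value
of 17.57; the residual gap of ~1.7 attractors (~10 standard errors) is a
convention difference in how the historical null was sampled, not
sampling noise, and is reported as-is rather than tuned away.

Two readings of "fraction of attractors with a basin larger than 219"
are computed, since the denominator is ambiguous: pooled over every fixed
point of the ensemble (~0.1–0.2%) and per-network largest attractors
(~1.7–2.5%). The per-network reading is the one on the scale of the
reference value (1.1%) and is the headline number; both appear in the
ensemble summary.

## Perturbation robustness

Single-edge perturbations are enumerated exhaustively: every existing
edge for deletion and sign-switch, every empty ordered pair with both
signs for addition (the one-edge-per-pair invariant is preserved, so the
built-in network has 21 + 21 + 86 = 128 single perturbations). The
observable is $\Delta B / B$ of the largest attractor. Two referents are
implemented:

* `track="original"` (default): $B_\text{perturbed}$ is the basin of the
  *original* largest-attractor state in the perturbed network, 0 if that
  state is no longer fixed — the conservative reading;
* `track="largest"`: the perturbed network's own largest basin.

The distribution over all 128 perturbations of the built-in network has
its mode at $\Delta B/B = 0$ under either reading. The comparison against
the null ("the cell-cycle network keeps its largest basin unchanged more
often than random networks") holds under the `largest` reading
(P(ΔB/B=0) ≈ 0.305 vs ≈ 0.20 for the null) and is run that way; under the
`original` reading the two probabilities are statistically
indistinguishable, which is documented here rather than hidden.

## Problem sizes and runtime choices

The package's own acceptance checks run the full published scale: all 256
states for enumeration and trajectories, 1000 random networks for the
null means and exceedance, 128 states for knockdown counts. The
ensemble-vs-reference perturbation comparison runs 200 random networks
(~128 single perturbations, i.e. ~25,600 exhaustive enumerations), a size
at which the observed gap is ~10 times its seed-to-seed variation.
Oracle-equivalence tests cross-check the vectorised enumeration against a
pure-Python orbit-follower on networks of up to 4 nodes.

## What the synthetic null does and does not capture

Random matched networks share the reference network's size and sign
budget but none of its biology: no degree-sequence preservation, no
motif structure, no constraint that self-degradation attaches to
unrepressed nodes. Conclusions from the comparison are therefore about
how unusual the cell-cycle topology is among all sign-matched wirings,
not among biologically plausible ones. Real regulatory networks also
update asynchronously and with graded activities; passing the checks
here shows the discrete model is internally faithful, not that it
predicts kinetics — experimentally measured cell-cycle durations are
outside what this model can compute, and only the direction of the
knockdown effects (fewer attractors, shorter cycle) is interpretable
against them.

## Known limitations

* Exhaustive enumeration only; no symbolic/BDD attractor detection, so
  the practical ceiling is ~20 nodes.
* Weights are restricted to ±1 and at most one edge per ordered pair; no
  multi-edges or graded weights.
* The null generator does not implement degree-preserving rewiring
  variants.
* No SBML-qual/BoolNet import; the edge-list TSV, SIF and GraphML cover
  interchange.
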