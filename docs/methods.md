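# Methods

This note documents the models and procedures implemented in `longax`, the
assumptions behind them, the parameters that matter, and what the synthetic
test data can and cannot establish.

## Projection features

An axon's projection pattern is the pair of vectors t_a (terminal counts)
and l_a (path lengths, μm) over the regions it terminates in. Choices:

- **Termination restriction.** l_a is restricted to regions with
  t_a(b) > 0; cable merely passing through a region carries no targeting
  information and is discarded. `include_passthrough=True` keeps it, in
  which case Σ_b l_a(b) equals the axon's total cable (up to unannotated
  voxels).
- **Midpoint attribution.** A segment belongs to the region of its
  midpoint; segments are not split at voxel boundaries. The attribution
  error is bounded by one voxel per boundary crossing and vanishes as
  morphologies are resampled finer than the voxel size.
- **Hemisphere encoding.** Contralateral targets get their own vocabulary
  entries (suffix `_contra`, relative to the soma's side of the midline
  plane), so ipsi/contra targeting survives clustering unchanged. Points
  exactly on the midline count as right (documented tie-break).
- The soma's own region is included when terminals land there
  (`include_soma_region=False` to drop it).

## Gaussian-mixture clustering

Axons of one source region are clustered on t_a or l_a under a C-component
Gaussian mixture fitted by EM. Defaults and rationale:

- **Spherical covariances** (one scalar variance per component). Projection
  vectors are high-dimensional relative to the handful of axons per source
  region; richer covariances overfit immediately. Diagonal and full are
  available.
- **Initialization**: k-means++ seeding refined by Lloyd iterations, best
  of `n_init=10` runs. The refinement keeps EM out of the classical
  singular maximizers (a component collapsing onto one point with variance
  at the floor), which otherwise corrupt BIC comparisons across C.
- **Convergence**: tolerance 1e-6 on the relative log-likelihood change,
  max 500 iterations; variances floored at 1e-6 of the mean data variance;
  a component that empties is re-seeded from the point with the lowest
  maximum posterior.
- **Model selection**: BIC = κ ln n − 2 ℓ(θ), argmin over C. κ counts
  C−1 weights, C·B means, and C (spherical), C·B (diag) or C·B(B+1)/2
  (full) covariance parameters. The default search range is ⌈N/2⌉..N for N
  axons — in this regime most clusters hold one or two axons, which is
  deliberate: the mixture is used as a generative summary of the observed
  patterns, not as a parsimonious description. An imposed C overrides the
  search (the standard demo imposes C = 5).
- **Virtual axons**: sampling draws a component by weight, a vector from
  N(μ_c, Σ_c), clips negatives to zero, and zeroes regions never observed
  among the component's training members — without the mask, spherical
  variances bleed probability into regions a cluster never targets.

## Tufts

Terminal pairs may merge iff their Euclidean distance ≤ 300 μm AND their
along-tree path distance ≤ 300 μm; single linkage over all such pairs
(parameter-free beyond the two thresholds and verifiable by brute force).
Each multi-terminal cluster becomes a tuft rooted at the lowest common
ancestor of its terminals; if that subtree contains further terminals they
are absorbed and the ancestor recomputed, so tuft subtrees are disjoint.
The ancestor node belongs to the tuft; the trunk ends in a duplicated seam
point, and node counts satisfy |trunk| + Σ|tufts| = |axon| with ancestors
counted once (in the tuft).

Tuft topology is summarized by the persistence barcode of the path-distance
filtration from the tuft root (elder rule: at each bifurcation the child
with the larger maximal descendant path distance survives). Bars equal
leaves; the bar lengths partition the tuft's cable.

Groups are keyed by (cluster, ancestor region); per-axon tuft counts give
the group's mean and *population* (N) variance, matching the maximum
likelihood convention of the mixture fit. Representativity of a tuft in its
group: per scalar feature f (total length, leaf count, maximal path
distance, mean bar length), d_f = |value − group median| / spread_f with
spread half the group's 5th–95th percentile range (a zero-spread feature
contributes 0 on an exact match and saturates the score to 0 otherwise);
score = max(0, 1 − mean_f d_f). Singleton groups score 1. The formula is
deliberately isolated behind one function: it is the simplest instantiation
that is 1 at the group median, decreases monotonically with deviation, and
degrades gracefully.

## Synthesis

Per new soma: cluster ~ p_c; each candidate region included independently
with the fraction of cluster members targeting it (after 10 empty redraws,
the most probable region is taken deterministically); per selected region,
T = round(N(mean, sd)) clamped to ≥ 1 target points placed uniformly inside
the region on the hemisphere its key encodes.

**Trunk.** The routing graph is a regular lattice of in-brain voxel centers
(default spacing 2 voxels, 26-connectivity) plus the soma and target
points snapped to their nearest lattice vertex; edge weight = Euclidean
length × α when both endpoints lie in the fiber-tract mask (α = 0.5 by
default; the lattice, rather than a data-adaptive vertex construction, is
the main structural approximation of the trunk router). The weighted
Steiner tree uses nearest-terminal shortest-path insertion — a classical
2-approximation — polished by re-spanning its vertex set with an MST and
pruning non-terminal leaves, with insertion restarted from every terminal
and the lightest tree kept. An exact Dreyfus–Wagner dynamic program is
included as the reference on small instances; on random geometric graphs
(≤ 60 vertices, ≤ 6 terminals) the heuristic matches the optimum on ~80%
of instances and stays within 7% otherwise.

**Post-processing.** Tree paths are rewalked at a fixed step (50 μm); each
emitted direction blends the pull toward the next waypoint
(weight 1 − n − r), the previous direction (history r = 0.3) and standard
Gaussian noise (n = 0.1). Waypoints, branch points, source and targets are
emitted exactly, so zero noise reproduces the tree polyline and tortuosity
grows monotonically with n.

**Tufts.** At each target, a tuft from the (cluster, region) group is drawn
with probability proportional to its representativity score (the simplest
monotone choice) and regrown from its barcode: one tip starts along the
incoming trunk direction; a tip passing an unassigned bar's birth spawns a
sibling there; a tip stops exactly at its bar's death. Leaf count equals
bar count and the regrown cable equals the bar-length sum. Growth is
softly confined to the target region (a step that would exit is redrawn
with the direction reflected inward, bounded retries) — unconstrained
tufts spill across region borders and distort per-region length
comparisons. A missing (cluster, region) tuft group falls back to the
nearest region with a group in the same cluster, logged.

Determinism: a master seed spawns independent substreams per axon
(`numpy` SeedSequence), so results are independent of execution order.

## Connectivity

Touches are axon/dendrite segment pairs of distinct neurons with minimal
segment–segment distance below the threshold (default: sum of segment radii
plus 1 μm; a fixed distance can be imposed — toy-scale ensembles use tens
of μm to emulate the neuropil densities a 1:1 scale scene cannot provide).
Detection hashes segments into a uniform grid expanded by the maximal
threshold, which is exactly equivalent to the all-pairs computation. The
inter-bouton filter greedily enforces a minimum arc-length spacing per
(axon, branch); density pruning keeps per postsynaptic neuron a uniform
random subset of at most density × dendritic length candidates. Out-degree
counts distinct postsynaptic partners (a synapse-count variant is kept
alongside). The projectome direction is presynaptic soma region →
postsynaptic synapse region.

## Synthetic data: what it emulates and what it does not

The toy atlas is a row of six box regions (100 μm voxels), mirrored across
a midline, over a background filler so the whole volume is routable. The
generator produces axons with: a soma uniform in the source region; one
chained trunk visiting all tuft anchors in order of distance (axons take
near-minimal paths, matching the cable-minimizing model class); anchors
uniform in each target region (inter-tuft path distances ≥ 392 μm
guarantee distinct tufts without any separation constraint); and Y-shaped
two-terminal tufts (branch length 140 μm, safely inside the 300 μm
clustering threshold) kept inside their region. Cluster identity = the set
of targeted regions with per-region tuft counts; at zero noise t_a is
exactly twice the specified tuft count. The demo population has 59 axons
in 5 clusters whose target sets overlap so every region receives ~20
axons — below that, the sampling noise of an MVS between identical
distributions approaches the 0.5 decision line and the comparison stops
measuring the method. No fiber corridors are marked in the demo atlas: the
generated axons run point-to-point, so a corridor mask would not describe
their routes; fiber preference is exercised on a dedicated corridor
fixture where the discounted path demonstrably dives into the tract.

Postsynaptic scenes are stellate neurons (straight rays) with somata
stratified across regions proportionally to voxel volume, so dendrite
density per unit volume is uniform by construction.

What passing tests show: the pipeline recovers known cluster structure,
reproduces per-region targeting fractions and length distributions, and
builds connectomes whose per-region counts scale linearly with cable.
What they do not show: realistic branching statistics, reconstruction
artifacts (cut planes, swapped radii), diameter variation (synthesized
radii are constant, 0.5 μm), within-region topographic structure, or any
claim about real mouse data, which require the original reconstructions
and atlas.

## Problem sizes

Test and acceptance runs use the 59-axon demo (toy atlas 40×16×16 voxels,
lattice ≈ 1300 vertices), 50 Steiner instances of ≤ 60 vertices / ≤ 6
terminals against the exact dynamic program, 100 random trees for the tuft
oracle, 20 mixtures of n = 200 for recovery, and a 100-axon / 250-neuron
scene for connectivity — sizes chosen so the full suite replays in a few
minutes on one CPU while every statistical check retains the power to fail.

## Known limitations

- The trunk router's lattice granularity bounds how tightly trunks can
  hug narrow fiber tracts; a tract thinner than the lattice spacing is
  sampled only patchily.
- Tuft counts are drawn independently per region; joint (region, axon)
  count correlations within a cluster are not modelled.
- The representativity formula and the MVS spread window (5–95
  percentiles) are defensible defaults, not fitted quantities; both are
  isolated behind single functions for replacement.
- EM with the paper-regime search range C ∈ ⌈N/2⌉..N intentionally
  produces many singleton clusters; BIC comparisons there are between
  near-degenerate models and should not be over-interpreted.
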