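# longax

Brain-wide synthesis of long-range axonal morphologies (LRAs) and the
connectomes they induce.

Reconstructing complete axons at single-neuron resolution is slow and
expensive, so whole-brain datasets cover only a sparse sample of neurons.
`longax` turns such a sparse sample into a full population: it learns the
*projection patterns* of reconstructed axons — which brain regions each axon
terminates in, and with how much cable — and then grows new, anatomically
embedded axons for arbitrarily many somata so that the population-level
targeting, lengths and tuft morphology statistically match the input. From
the synthesized population it derives axo-dendritic connectivity: a
single-cell connectome and a region-level projectome. It is intended for
computational neuroanatomists and circuit modellers who need simulation-ready
long-range connectivity from sparse reconstructions.

## Model

**Projection features.** For axon *a* with soma in source region *s_a*, over
a region vocabulary *B*: t_a(b) = number of terminal points in region *b*;
l_a(b) = axonal path length inside *b* (μm), restricted to termination
regions. Contralateral targets are distinct vocabulary entries. The two
features are proportional (one tuft of roughly fixed cable per terminal
cluster) and can be used interchangeably.

**Clustering.** Axons of one source region are modelled as a Gaussian
mixture with C components: f_a ~ Σ_k p_k N(μ_k, Σ_k), fitted by EM
(spherical covariances by default) and selected by the Bayesian Information
Criterion, BIC = κ ln n − 2 ℓ(θ) with κ the free-parameter count (lower is
better). Posterior membership P(c|f) = p_c N(f; μ_c, Σ_c) / Σ_k p_k N(f; μ_k, Σ_k).

**Tufts.** Terminals within a radial *and* a tree path distance (default
300 μm each) agglomerate by single linkage into tufts rooted at their
common ancestor; the remainder is the trunk. Each tuft is summarized by the
persistence barcode of its path-distance filtration (elder rule), grouped
by (cluster, ancestor region), and scored by how morphometrically typical
it is of its group (representativity ∈ [0, 1]).

**Synthesis.** For a new soma: draw a cluster with probability p_c; include
each region *b* with probability (cluster members targeting *b*)/(cluster
size); place T ~ N(mean, sd) tuft target points uniformly in *b*; connect
soma and targets with a weighted Steiner tree on an in-brain voxel lattice
in which fiber-tract edges are discounted by α (trunks prefer white
matter); resample the trunk with direction noise and history to restore
tortuosity; regrow a representativity-sampled tuft from its barcode at each
target.

**Connectivity.** Touches = axon/dendrite segment pairs of distinct neurons
within a touch distance; filtered by a minimum inter-bouton interval along
each axonal branch; pruned to a dendritic synapse density; aggregated into
neuron adjacency, out-degrees and a region projectome.

**Validation.** Feature values are normalized against the reference
population as V_norm(a) = (median(P_r) − V(a)) / σ(P_r). Two samples are
compared with the Maximum Visible Spread score
MVS(P, Q) = |median(P) − median(Q)| / max(spread(P), spread(Q)), spread =
half the 5th–95th percentile range; MVS < 0.1 flags strong similarity
(`**`), MVS < 0.5 non-randomness (`*`).

## Worked example

`examples/03_synthesize_axons.py` runs the whole pipeline on the built-in
demo: a toy atlas (six mirrored regions on a 100 μm grid) and 59 generated
axons in five projection classes. It clusters them, builds the tuft
library, synthesizes 59 new axons and compares the populations:

```
tuft library: 236 tufts in 12 (cluster, region) groups
synthesized 59 axons; median cable 5919 um (input 5090 um)

   region  frac_terminating_bio  frac_terminating_synth  mvs_length flag
       RA                 0.407                   0.458       0.118    *
       RB                 0.441                   0.424       0.009   **
       RC                 0.458                   0.441       0.035   **
RC_contra                 0.288                   0.305       0.040   **
       RD                 0.407                   0.373       0.022   **
       RE                 0.288                   0.305       0.154    *
```

Per region: the fraction of input (bio) and synthesized axons terminating
there agree to a few percent, and the per-axon cable-length distributions
inside each region match at MVS well below 0.5 (mostly below 0.1), i.e. the
synthesized population is statistically indistinguishable from the input by
these criteria, including the contralateral pathway (`RC_contra`).

The other examples isolate single capabilities: `01_project_and_cluster.py`
(projection features, EM/BIC, virtual-axon sampling),
`02_extract_tufts.py` (trunk/tuft decomposition and barcodes),
`04_build_connectome.py` (touch detection through projectome).

A thin CLI wraps the same library for file-based runs:

```bash
longax make-fixtures --out demo --seed 3
longax project --config config.yaml     # then: cluster, synthesize,
longax connect --config config.yaml     # validate
```

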