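"""Synthetic toy atlases and axon populations with known ground truth.

The generator emulates the structure the analysis pipeline consumes: axons
rooted in a source region whose trunks descend into a white-matter corridor,
travel to their target regions and end in Y-shaped terminal tufts placed
well apart inside each region.  Cluster identity is defined by the set of
targeted regions and per-region tuft counts, so projection-based clustering
has a known partition to recover, tuft extraction has known counts, and
zero-noise populations have exactly reproducible terminal counts
(each Y-tuft contributes two terminals).

It does not emulate reconstruction artifacts (cut planes, swapped radii) or
realistic branching statistics of biological arbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from longax.atlas import Atlas, build_toy_atlas
from longax.morpho import Morphology, MorphologyBuilder, SectionType
from longax.projections import base_acronym, is_contra

__all__ = [
    "ClusterSpec",
    "PopulationSpec",
    "demo_atlas_spec",
    "demo_atlas",
    "demo_population_spec",
    "generate_population",
    "generate_scene",
]


# ---------------------------------------------------------------------------
# toy atlas
# ---------------------------------------------------------------------------

def demo_atlas_spec() -> dict:
    """Six cortical-like regions in a row, mirrored hemispheres, a source
    region and a background filler (voxels of 100 μm).

    No fiber corridors are marked: the generated axons run point-to-point,
    so an honest white-matter mask for this population is empty (a corridor
    mask that does not follow the population's routes would only divert
    synthesized trunks).  Fiber-tract preference is exercised on dedicated
    corridor fixtures instead.
    """
    regions = [
        {"acronym": "SRC", "box": [[1, 1, 2], [6, 7, 14]]},
        {"acronym": "RA", "box": [[8, 1, 2], [13, 7, 14]]},
        {"acronym": "RB", "box": [[15, 1, 2], [20, 7, 14]]},
        {"acronym": "RC", "box": [[22, 1, 2], [27, 7, 14]]},
        {"acronym": "RD", "box": [[29, 1, 2], [34, 7, 14]]},
        {"acronym": "RE", "box": [[35, 1, 2], [39, 7, 14]]},
    ]
    return {
        "shape": [40, 16, 16],
        "voxel_size": 100.0,
        "origin": [0.0, 0.0, 0.0],
        "midline_axis": 1,
        "mirror": True,
        "regions": regions,
        "background": "bg",
        "fiber_corridors": [],
        "root_acronym": "root",
    }


def demo_atlas() -> Atlas:
    return build_toy_atlas(demo_atlas_spec())


# ---------------------------------------------------------------------------
# population specification
# ---------------------------------------------------------------------------

@dataclass
class ClusterSpec:
    """One projection pattern: region key → mean tuft count."""

    weight: float
    targets: dict[str, float]  # e.g. {"RA": 2, "RC_contra": 1}
    tuft_size: float = 140.0  # Y-branch length, μm (terminal pair stays
    # safely inside the 300 μm path-distance clustering threshold)
    count_noise: float = 0.0  # SD of the per-region tuft count draw
    length_noise: float = 0.0  # relative SD of the tuft branch length


@dataclass
class PopulationSpec:
    source_region: str
    n_axons: int
    clusters: list[ClusterSpec]
    soma_hemisphere: str = "right"

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.clusters)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cluster weights sum to {total}, expected 1")
        if self.n_axons < 1:
            raise ValueError("n_axons must be >= 1")


def demo_population_spec() -> PopulationSpec:
    """The standard demo: 59 axons in 5 clusters from the source region,
    echoing a presubiculum-like population with five projection classes."""
    return PopulationSpec(
        source_region="SRC",
        n_axons=59,
        clusters=[
            ClusterSpec(weight=0.25, targets={"RA": 3, "RB": 1}),
            ClusterSpec(weight=0.20, targets={"RB": 2, "RC": 2}),
            ClusterSpec(weight=0.20, targets={"RD": 3, "RC": 1}),
            ClusterSpec(weight=0.20, targets={"RE": 2, "RA": 1, "RC_contra": 1}),
            ClusterSpec(weight=0.15, targets={"RC_contra": 2, "RD": 1, "RE": 1}),
        ],
    )


# ---------------------------------------------------------------------------
# axon construction
# ---------------------------------------------------------------------------

def _resolve_hemisphere(region_key: str, soma_hemi: str) -> str:
    if not is_contra(region_key):
        return soma_hemi
    return "left" if soma_hemi == "right" else "right"


def _polyline(builder: MorphologyBuilder, parent: int, points, step: float = 150.0,
              radius: float = 0.8) -> int:
    """Append straight polyline legs resampled at ``step``; returns end id."""
    cur_id = parent
    cur = builder._nodes[parent - 1].xyz.copy()
    for target in points:
        target = np.asarray(target, float)
        leg = target - cur
        dist = float(np.linalg.norm(leg))
        n = max(1, int(np.ceil(dist / step)))
        for i in range(1, n + 1):
            cur_id = builder.add(cur_id, cur + leg * (i / n), SectionType.axon, radius)
        cur = target
    return cur_id


def _grow_y_tuft(
    builder: MorphologyBuilder,
    parent: int,
    anchor: np.ndarray,
    branch_len: float,
    atlas: Atlas,
    region_id: int,
    rng: np.random.Generator,
) -> None:
    """Stem + two branches of ``branch_len`` whose terminals stay inside the
    region (stem biased toward the region interior; directions re-drawn and
    the tuft shrunk until all points land inside)."""
    vox = atlas.region_voxels(region_id)
    centers = atlas.origin + (vox + 0.5) * atlas.voxel_size
    # interior pull: centroid of the region voxels on the anchor's side
    side = centers[:, atlas.midline_axis] >= atlas.midline
    if atlas.hemisphere_of(anchor) == "left":
        side = ~side
    local = centers[side] if side.any() else centers
    inward = local.mean(axis=0) - anchor
    inward_n = float(np.linalg.norm(inward))
    inward = inward / inward_n if inward_n > 0 else np.zeros(3)
    scale = 1.0
    for attempt in range(60):
        u = 0.7 * rng.standard_normal(3) + 1.2 * inward
        u /= max(np.linalg.norm(u), 1e-12)
        stem = anchor + u * (branch_len * 0.4 * scale)
        # two branches splayed around the stem direction
        perp = np.cross(u, rng.standard_normal(3))
        perp /= max(np.linalg.norm(perp), 1e-12)
        d1 = u + 0.9 * perp
        d2 = u - 0.9 * perp
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        t1 = stem + d1 * branch_len * scale
        t2 = stem + d2 * branch_len * scale
        ok = all(
            (r := atlas.region_at(p)) is not None
            and atlas.hierarchy.is_descendant(r, region_id)
            for p in (stem, t1, t2)
        )
        if ok:
            stem_id = builder.add(parent, stem, SectionType.axon, 0.6)
            mid1 = builder.add(stem_id, 0.5 * (stem + t1), SectionType.axon, 0.5)
            builder.add(mid1, t1, SectionType.axon, 0.5)
            mid2 = builder.add(stem_id, 0.5 * (stem + t2), SectionType.axon, 0.5)
            builder.add(mid2, t2, SectionType.axon, 0.5)
            return
        if attempt % 5 == 4:
            scale *= 0.6
    raise RuntimeError("could not fit tuft inside its region")


def _sample_anchors(
    atlas: Atlas, region: str, hemisphere: str, k: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Uniform tuft anchors, as the synthesis model places target points.

    No separation is enforced: terminals of distinct Y-tufts are always
    more than the 300 μm path-distance threshold apart along the tree
    (2 × (stem + branch) ≈ 392 μm), so tuft extraction keeps them distinct
    regardless of their Euclidean proximity.
    """
    return [atlas.sample_point_in_region(region, rng, hemisphere=hemisphere)
            for _ in range(k)]


def generate_population(
    spec: PopulationSpec,
    atlas: Atlas,
    seed: int = 0,
) -> tuple[list[Morphology], np.ndarray, pd.DataFrame]:
    """Generate a labeled axon population on the atlas.

    Per axon: a cluster is drawn by weight; a soma is placed in the source
    region; for each target region of the cluster, ``round(N(mean, sd))``
    (≥1; exactly ``mean`` at zero noise) tuft anchors are placed well apart
    inside the region, each reached by a straight trunk branch from the
    soma (axons take near-minimal paths, matching the cable-minimizing
    model class) and finished with a Y-shaped tuft of two terminals kept
    inside the region.

    Returns (morphologies, cluster labels, ground-truth tuft counts with one
    row per (axon, region)).
    """
    rng = np.random.default_rng(seed)
    weights = np.array([c.weight for c in spec.clusters])
    labels = rng.choice(len(spec.clusters), size=spec.n_axons, p=weights)
    morphs: list[Morphology] = []
    truth_rows: list[dict] = []

    for i, label in enumerate(labels):
        cl = spec.clusters[label]
        neuron_id = f"ax{i:03d}"
        soma = atlas.sample_point_in_region(spec.source_region, rng,
                                            hemisphere=spec.soma_hemisphere)
        builder = MorphologyBuilder(soma, neuron_id=neuron_id)
        axon_root = builder.add(builder.soma_id, soma, SectionType.axon, 1.0)
        jobs: list[tuple[np.ndarray, float, int]] = []  # (anchor, blen, region id)
        for region_key in sorted(cl.targets):
            mean = cl.targets[region_key]
            if cl.count_noise > 0:
                k = max(1, int(round(rng.normal(mean, cl.count_noise))))
            else:
                k = max(1, int(round(mean)))
            hemi = _resolve_hemisphere(region_key, spec.soma_hemisphere)
            region = base_acronym(region_key)
            region_id = atlas.hierarchy.id_of(region)
            anchors = _sample_anchors(atlas, region, hemi, k, rng=rng)
            for anchor in anchors:
                blen = cl.tuft_size
                if cl.length_noise > 0:
                    blen *= max(0.2, 1.0 + rng.normal(0.0, cl.length_noise))
                jobs.append((anchor, blen, region_id))
            truth_rows.append(
                {"neuron_id": neuron_id, "cluster": int(label),
                 "region": region_key, "n_tufts": int(k)}
            )
        # one chained trunk visiting anchors by distance from the soma:
        # axons share cable instead of fanning parallel branches
        jobs.sort(key=lambda j: float(np.linalg.norm(j[0] - soma)))
        trunk_end = axon_root
        for anchor, blen, region_id in jobs:
            trunk_end = _polyline(builder, trunk_end, [anchor])
            _grow_y_tuft(builder, trunk_end, anchor, blen, atlas, region_id, rng)
        morphs.append(builder.build())

    truth = pd.DataFrame(truth_rows,
                         columns=["neuron_id", "cluster", "region", "n_tufts"])
    return morphs, labels, truth


# ---------------------------------------------------------------------------
# postsynaptic scenes
# ---------------------------------------------------------------------------

def generate_scene(
    n_neurons: int,
    total_dendrite_length: float,
    atlas: Atlas,
    seed: int = 0,
    regions: list[str] | None = None,
    n_rays: int = 6,
    resample_step: float = 50.0,
) -> list[Morphology]:
    """Neurons with stellate (ray-like) dendrites as postsynaptic targets.

    Somata are spread uniformly over the brain volume by stratified
    allocation — each leaf region receives a share of neurons proportional
    to its voxel volume (largest-remainder rounding), placed uniformly
    inside it — so the dendrite density per unit volume is constant across
    regions.  Passing ``regions`` restricts and cycles placement instead.
    Each neuron grows ``n_rays`` straight dendritic rays of equal share of
    ``total_dendrite_length``, resampled at ``resample_step`` μm.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    morphs: list[Morphology] = []
    ray_len = total_dendrite_length / n_rays
    if regions:
        placement = [regions[i % len(regions)] for i in range(n_neurons)]
    else:
        leaf_ids = [rid for rid in atlas.hierarchy.all_ids()
                    if not atlas.hierarchy.children(rid)]
        vols = np.array([(atlas.annotation == rid).sum() for rid in leaf_ids], float)
        keep = vols > 0
        leaf_ids = [r for r, k in zip(leaf_ids, keep) if k]
        vols = vols[keep]
        quota = n_neurons * vols / vols.sum()
        counts = np.floor(quota).astype(int)
        for j in np.argsort(-(quota - counts))[: n_neurons - counts.sum()]:
            counts[j] += 1
        placement = [atlas.hierarchy.acronym(rid)
                     for rid, c in zip(leaf_ids, counts) for _ in range(c)]
    for i in range(n_neurons):
        soma = atlas.sample_point_in_region(placement[i], rng)
        builder = MorphologyBuilder(soma, neuron_id=f"post{i:03d}")
        for _ in range(n_rays):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            n_seg = max(1, int(np.ceil(ray_len / resample_step)))
            pid = builder.soma_id
            for s in range(1, n_seg + 1):
                pid = builder.add(pid, soma + u * ray_len * (s / n_seg),
                                  SectionType.basal_dendrite, 0.7)
        morphs.append(builder.build())
    return morphs
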