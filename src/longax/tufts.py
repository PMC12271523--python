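"""Axon decomposition into trunks and tufts, tuft grouping and scoring.

Axon terminals that are close together — within a *radial* (Euclidean) and a
*path* (along-the-tree) distance, both 300 μm by default — are agglomerated
by single linkage up to their lowest common ancestor into a *tuft*.  The
axon with all tufts removed is the *trunk*: the inter-regional cable whose
endpoints (the tuft ancestors) become the target points of synthesis.

Each tuft carries a persistence barcode of the path-distance filtration from
its root (elder rule: at a bifurcation, the child component with the larger
maximal descendant path distance survives), which is the topological recipe
used to regrow it.  Tufts are grouped by (projection cluster, region of the
common ancestor); each group records the mean and variance of per-axon tuft
counts and assigns every member a representativity score in [0, 1]
measuring how morphometrically typical it is of its group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from longax.atlas import Atlas
from longax.morpho import Morphology, MorphNode, SectionType
from longax.projections import CONTRA_SUFFIX

__all__ = [
    "Tuft",
    "TuftGroup",
    "extract_tufts",
    "barcode_of",
    "path_distance_barcode",
    "group_tufts",
    "representativity",
]


@dataclass
class Tuft:
    """A terminal cluster of one axon, rooted at its common ancestor."""

    neuron_id: str
    common_ancestor: np.ndarray  # xyz μm
    region: str | None  # vocabulary key (acronym, "_contra" if across midline)
    subtree: Morphology  # fragment re-rooted at the ancestor
    barcode: list[tuple[float, float]]  # (birth, death) path distances, μm
    terminal_ids: list[int] = field(default_factory=list)  # ids in the parent axon
    n_nodes: int = 0  # nodes owned in the parent axon (ancestor included)

    @property
    def total_length(self) -> float:
        return self.subtree.total_length(SectionType.axon)

    @property
    def n_leaves(self) -> int:
        return len(self.barcode)

    @property
    def max_path_distance(self) -> float:
        return max(d for _, d in self.barcode)

    def scalar_features(self) -> dict[str, float]:
        """Morphometric summary used for representativity scoring."""
        bars = np.asarray(self.barcode, float)
        return {
            "total_length": self.total_length,
            "number_of_leaves": float(self.n_leaves),
            "max_path_distance": self.max_path_distance,
            "mean_bar_length": float(np.mean(bars[:, 1] - bars[:, 0])),
        }


@dataclass
class TuftGroup:
    """Tufts of one (cluster, region) key with count statistics and scores."""

    cluster: int
    region: str
    tufts: list[Tuft]
    mean_count: float = 0.0  # mean per-axon tuft count in the group
    var_count: float = 0.0  # population variance of per-axon tuft counts
    scores: list[float] = field(default_factory=list)

    @property
    def sd_count(self) -> float:
        return float(np.sqrt(self.var_count))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _axon_depths_and_parents(m: Morphology) -> tuple[dict[int, int], dict[int, float]]:
    """Edge depth and arc-length path distance for every axon node."""
    depth: dict[int, int] = {}
    pdist = m.path_distances(SectionType.axon)
    for nid in m.neurite_node_ids(SectionType.axon):
        p = m.parent(nid)
        if p is None or m.node(p).section_type != SectionType.axon:
            depth[nid] = 0
        else:
            depth[nid] = depth[p] + 1
    return depth, pdist


def _lca(m: Morphology, depth: dict[int, int], a: int, b: int) -> int:
    while depth[a] > depth[b]:
        a = m.parent(a)  # type: ignore[arg-type]
    while depth[b] > depth[a]:
        b = m.parent(b)  # type: ignore[arg-type]
    while a != b:
        a = m.parent(a)  # type: ignore[arg-type]
        b = m.parent(b)  # type: ignore[arg-type]
    return a


def _tree_path_distance(m, depth, pdist, a, b) -> float:
    return pdist[a] + pdist[b] - 2.0 * pdist[_lca(m, depth, a, b)]


def _subtree_fragment(m: Morphology, root_id: int, neuron_id: str) -> Morphology:
    """Copy the subtree at ``root_id`` into a standalone morphology whose
    root is a soma point at the ancestor position."""
    ids = m.subtree_ids(root_id)
    remap = {root_id: 1}
    nodes = [MorphNode(1, None, m.node(root_id).xyz.copy(),
                       max(m.node(root_id).radius, 1e-6), SectionType.soma)]
    nxt = 2
    for nid in ids:
        if nid == root_id:
            continue
        remap[nid] = nxt
        src = m.node(nid)
        nodes.append(MorphNode(nxt, remap[src.parent_id], src.xyz.copy(),
                               src.radius, SectionType.axon))
        nxt += 1
    return Morphology(nodes, neuron_id=neuron_id)


def extract_tufts(
    m: Morphology,
    radial_max: float = 300.0,
    path_max: float = 300.0,
    atlas: Atlas | None = None,
    level: int | str = "leaf",
) -> tuple[Morphology, list[Tuft]]:
    """Split one axon into its trunk and tufts.

    Two terminals may merge iff their Euclidean distance ≤ ``radial_max``
    AND their along-tree path distance ≤ ``path_max`` (single linkage over
    all such pairs).  Every multi-terminal cluster becomes a tuft rooted at
    the lowest common ancestor of its terminals; if that ancestor's subtree
    contains further terminals they are absorbed and the ancestor recomputed,
    so tuft subtrees are disjoint.  Singleton terminals stay trunk endpoints.

    The ancestor node belongs to the tuft; the trunk ends in a duplicated
    seam point at the ancestor position, so trunk-plus-tuft node sets
    reconstitute the axon exactly (ancestors counted once, in the tuft).
    When ``atlas`` is given, each tuft's region key is filled (acronym with
    a ``_contra`` suffix when across the midline from the soma).

    Returns (trunk morphology, list of tufts).
    """
    terminals = m.leaves(SectionType.axon)
    if not terminals:
        raise ValueError(f"{m.neuron_id}: axon has no terminals")
    depth, pdist = _axon_depths_and_parents(m)
    pos = {t: m.node(t).xyz for t in terminals}

    uf = _UnionFind(terminals)
    for i, a in enumerate(terminals):
        for b in terminals[i + 1:]:
            if np.linalg.norm(pos[a] - pos[b]) > radial_max:
                continue
            if _tree_path_distance(m, depth, pdist, a, b) > path_max:
                continue
            uf.union(a, b)

    clusters: dict[int, list[int]] = {}
    for t in terminals:
        clusters.setdefault(uf.find(t), []).append(t)

    # multi-terminal clusters become tufts; absorb terminals that fall
    # inside a tuft's subtree so subtrees stay disjoint
    groups = [set(members) for members in clusters.values() if len(members) > 1]
    singles = {t for members in clusters.values() if len(members) == 1
               for t in members}
    tuft_roots: list[tuple[int, set[int]]] = []
    changed = True
    while changed:
        changed = False
        tuft_roots = []
        for members in groups:
            mem = list(members)
            anc = mem[0]
            for t in mem[1:]:
                anc = _lca(m, depth, anc, t)
            inside = set(m.subtree_ids(anc))
            extra = (set(terminals) & inside) - members
            if extra:
                # merge this group with every group or singleton whose
                # terminal lies inside the ancestor's subtree
                absorbing = members | extra
                merged: set[int] = set()
                rest: list[set[int]] = []
                for g in groups:
                    if g & absorbing:
                        merged |= g
                    else:
                        rest.append(g)
                merged |= extra
                groups = rest + [merged]
                singles -= extra
                changed = True
                break
            tuft_roots.append((anc, members))
        # a merge restarts the scan from the new group list

    # deduplicate roots (two clusters can share an ancestor only if merged;
    # by construction they are disjoint here)
    tufts: list[Tuft] = []
    tuft_node_ids: set[int] = set()
    soma_hemi = None
    if atlas is not None:
        soma_hemi = atlas.hemisphere_of(m.soma_center)
    for anc, members in sorted(tuft_roots, key=lambda kv: kv[0]):
        sub_ids = m.subtree_ids(anc)
        tuft_node_ids.update(sub_ids)
        frag = _subtree_fragment(m, anc, m.neuron_id)
        barcode = path_distance_barcode(m, anc)
        region = None
        if atlas is not None:
            rid = atlas.region_at(m.node(anc).xyz, level)
            if rid is not None:
                acro = atlas.hierarchy.acronym(rid)
                hemi = atlas.hemisphere_of(m.node(anc).xyz)
                region = acro if hemi == soma_hemi else acro + CONTRA_SUFFIX
        tufts.append(
            Tuft(
                neuron_id=m.neuron_id,
                common_ancestor=m.node(anc).xyz.copy(),
                region=region,
                subtree=frag,
                barcode=barcode,
                terminal_ids=sorted(members),
                n_nodes=len(sub_ids),
            )
        )

    # trunk: all nodes outside tuft subtrees, plus a seam duplicate at each
    # tuft ancestor so the cable geometry is preserved on re-serialization
    trunk_nodes: list[MorphNode] = []
    keep = [n for n in m.nodes if n.id not in tuft_node_ids]
    kept_ids = {n.id for n in keep}
    trunk_nodes.extend(keep)
    next_id = max(n.id for n in m.nodes) + 1
    for anc, _members in tuft_roots:
        parent = m.parent(anc)
        if parent is not None and parent in kept_ids:
            trunk_nodes.append(
                MorphNode(next_id, parent, m.node(anc).xyz.copy(),
                          m.node(anc).radius, SectionType.axon)
            )
            next_id += 1
    trunk = Morphology(trunk_nodes, neuron_id=m.neuron_id)
    return trunk, tufts


# ---------------------------------------------------------------------------
# barcodes
# ---------------------------------------------------------------------------

def path_distance_barcode(m: Morphology, root_id: int) -> list[tuple[float, float]]:
    """Persistence barcode of the path-distance filtration of the subtree
    rooted at ``root_id``.

    Distances are measured from ``root_id``.  At each bifurcation the child
    component with the larger maximal descendant path distance survives
    (elder rule); the other children die there, contributing bars
    ``(path_distance(bifurcation), component maximum)``.  The surviving
    component yields the final bar ``(0, max path distance)``.  The number
    of bars equals the number of leaves.
    """
    ids = m.subtree_ids(root_id)
    idset = set(ids)
    pd: dict[int, float] = {root_id: 0.0}
    for nid in ids:
        if nid == root_id:
            continue
        p = m.parent(nid)
        pd[nid] = pd[p] + m.segment_length(p, nid)

    bars: list[tuple[float, float]] = []

    # iterative post-order: compute surviving max per node
    surviving: dict[int, float] = {}
    for nid in reversed(ids):  # reverse preorder = children before parents
        kids = [k for k in m.children(nid) if k in idset]
        if not kids:
            surviving[nid] = pd[nid]
            continue
        vals = sorted((surviving[k] for k in kids), reverse=True)
        surviving[nid] = vals[0]
        for v in vals[1:]:
            bars.append((pd[nid], v))
    bars.append((0.0, surviving[root_id]))
    bars.sort(key=lambda bd: (bd[0], -bd[1]))
    return bars


def barcode_of(t: Tuft) -> list[tuple[float, float]]:
    """Barcode of a tuft (path-distance filtration from its root)."""
    return path_distance_barcode(t.subtree, t.subtree.root.id)


# ---------------------------------------------------------------------------
# grouping and representativity
# ---------------------------------------------------------------------------

def group_tufts(
    tufts: list[Tuft], cluster_of: dict[str, int]
) -> dict[tuple[int, str], TuftGroup]:
    """Group tufts by (projection cluster of their axon, ancestor region).

    Per group, the mean and population variance of per-axon tuft counts are
    computed over the axons contributing to the group, and every tuft gets
    its representativity score.  Grouping is invariant to input order.
    """
    groups: dict[tuple[int, str], TuftGroup] = {}
    for t in sorted(tufts, key=lambda t: (t.neuron_id, t.common_ancestor.tolist())):
        if t.neuron_id not in cluster_of:
            raise KeyError(f"no cluster assignment for neuron {t.neuron_id!r}")
        if t.region is None:
            raise ValueError(
                f"tuft of {t.neuron_id!r} has no region; extract with an atlas"
            )
        key = (int(cluster_of[t.neuron_id]), t.region)
        groups.setdefault(key, TuftGroup(key[0], key[1], [])).tufts.append(t)

    for group in groups.values():
        counts: dict[str, int] = {}
        for t in group.tufts:
            counts[t.neuron_id] = counts.get(t.neuron_id, 0) + 1
        vals = np.array(list(counts.values()), float)
        group.mean_count = float(vals.mean())
        group.var_count = float(vals.var())  # population variance
        group.scores = representativity(group)
    return groups


def representativity(group: TuftGroup, percentiles: tuple[float, float] = (5.0, 95.0)
                     ) -> list[float]:
    """Score each tuft in [0, 1] by closeness to its group's morphometrics.

    For every scalar feature f the deviation is
    ``d_f = |value − group median| / spread_f`` with spread half the
    5th–95th percentile range of the group (features with zero spread
    contribute 0 when the value matches the median, and saturate the score
    to 0 otherwise); the score is ``max(0, 1 − mean_f d_f)``.  A tuft at
    the group median of every feature scores 1; singleton groups score 1.
    """
    if not group.tufts:
        raise ValueError("empty tuft group")
    if len(group.tufts) == 1:
        return [1.0]
    feats = [t.scalar_features() for t in group.tufts]
    names = list(feats[0])
    table = np.array([[f[k] for k in names] for f in feats], float)
    med = np.median(table, axis=0)
    lo, hi = np.percentile(table, percentiles, axis=0)
    spread = (hi - lo) / 2.0
    scores = []
    for row in table:
        devs = []
        for v, mv, sp in zip(row, med, spread):
            if sp <= 0:
                devs.append(0.0 if np.isclose(v, mv) else np.inf)
            else:
                devs.append(abs(v - mv) / sp)
        scores.append(float(max(0.0, 1.0 - float(np.mean(devs)))))
    return scores
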