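"""Long-range axon synthesis.

Given fitted projection clusters and a tuft library, a new axon for a soma
in source region *s* is built in five steps:

1. **cluster assignment** — a cluster *c* of *s* is drawn with probability
   ``p_c`` (the fitted mixture weight);
2. **target selection** — each region *b* targeted by cluster members is
   selected independently with probability (members targeting *b*) /
   (cluster size); per selected region, ``T ~ N(mean, sd)`` of the
   (cluster, region) tuft-count statistics target points are placed
   uniformly inside *b* (respecting the ipsi/contra hemisphere encoded in
   the region key);
3. **trunk routing** — a graph over an in-brain lattice of voxel centers
   (26-connectivity) links the soma to all target points; edges inside
   fiber tracts get their Euclidean length discounted by a factor α, and a
   weighted Steiner tree (iterative nearest-terminal shortest-path
   insertion, a 2-approximation) connects the targets with minimal cable;
4. **trunk post-processing** — tree paths are resampled at a fixed step
   with a blend of goal direction, local history and Gaussian noise, which
   restores realistic tortuosity while keeping source, targets and branch
   points exactly;
5. **tuft growth** — at each target a tuft is drawn from the (cluster,
   region) group with probability proportional to its representativity
   score, and regrown from its persistence barcode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from longax.atlas import Atlas, AtlasError
from longax.gmm import GMMModel
from longax.morpho import Morphology, MorphNode, SectionType
from longax.projections import ProjectionMatrix, base_acronym, is_contra
from longax.tufts import Tuft, TuftGroup, group_tufts

logger = logging.getLogger(__name__)

__all__ = [
    "SynthesisConfig",
    "SynthesisTask",
    "SteinerGraph",
    "SourceInputs",
    "assign_cluster",
    "choose_targets",
    "build_lattice",
    "build_graph",
    "steiner_tree",
    "steiner_tree_exact_weight",
    "postprocess_trunk",
    "grow_tuft",
    "synthesize_population",
    "build_source_inputs",
]


@dataclass
class SynthesisConfig:
    """Tunable parameters of the synthesis pipeline (all lengths in μm)."""

    feature: str = "lengths"  # clustering feature used for assignments
    lattice_step_vox: int = 2  # lattice spacing in voxels
    fiber_discount: float = 0.5  # α: edge-weight factor inside fiber tracts
    trunk_step: float = 50.0  # trunk resampling step
    trunk_noise: float = 0.1  # n: Gaussian-noise weight in trunk directions
    trunk_history: float = 0.3  # r: persistence of the previous direction
    tuft_step: float = 20.0  # tuft growth step
    tuft_noise: float = 0.3  # direction noise during tuft growth
    retry_bound: int = 10  # redraws when no target region is selected
    radius: float = 0.5  # constant neurite radius of synthesized cable


@dataclass
class SynthesisTask:
    """One soma to grow an axon for."""

    neuron_id: str
    soma_xyz: np.ndarray
    source_region: str

    def __post_init__(self) -> None:
        self.soma_xyz = np.asarray(self.soma_xyz, float)


@dataclass
class SteinerGraph:
    """Routing graph: terminal nodes snapped onto an in-brain lattice."""

    graph: nx.Graph  # node attrs: xyz, fiber; edge attr: weight, length
    source: object  # node key of the source point
    targets: list  # node keys of the target points


@dataclass
class SourceInputs:
    """Everything synthesis needs for one source region."""

    model: GMMModel
    region_prob: dict[int, dict[str, float]]  # cluster -> region -> member frac
    tuft_groups: dict[tuple[int, str], TuftGroup]


# ---------------------------------------------------------------------------
# cluster assignment and target choice
# ---------------------------------------------------------------------------

def assign_cluster(model: GMMModel, rng: np.random.Generator | int) -> int:
    """Draw a cluster id with probability equal to its mixture weight."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return int(rng.choice(model.C, p=model.weights))


def choose_targets(
    cluster: int,
    inputs: SourceInputs,
    atlas: Atlas,
    soma_hemisphere: str,
    rng: np.random.Generator | int,
    retry_bound: int = 10,
) -> list[tuple[str, np.ndarray]]:
    """Select target regions and place target points for one axon.

    Each candidate region is included independently with the fraction of
    cluster members targeting it; if no region is selected after
    ``retry_bound`` redraws, the highest-probability region is taken.  For
    every selected region, a tuft count ``T`` is drawn from the group's
    Normal(mean, sd) (rounded, clamped to ≥1) and ``T`` points are placed
    uniformly inside the region, on the hemisphere the region key encodes.

    Returns a list of (region key, point) pairs, one entry per target point.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    probs = inputs.region_prob.get(cluster)
    if not probs:
        raise ValueError(f"cluster {cluster} has no member statistics")
    regions = sorted(probs)
    selected: list[str] = []
    for _ in range(max(1, retry_bound)):
        selected = [b for b in regions if rng.random() < probs[b]]
        if selected:
            break
    if not selected:
        selected = [max(regions, key=lambda b: probs[b])]

    out: list[tuple[str, np.ndarray]] = []
    for b in selected:
        group = inputs.tuft_groups.get((cluster, b))
        if group is None:
            fallback = _nearest_group_region(cluster, b, inputs, atlas)
            if fallback is None:
                logger.warning("no tuft group for cluster %d region %s; skipped",
                               cluster, b)
                continue
            logger.info("cluster %d region %s: using tuft stats of %s",
                        cluster, b, fallback)
            group = inputs.tuft_groups[(cluster, fallback)]
        t_count = int(round(rng.normal(group.mean_count, group.sd_count)))
        t_count = max(1, t_count)
        hemi = _region_hemisphere(b, soma_hemisphere)
        for _ in range(t_count):
            point = atlas.sample_point_in_region(base_acronym(b), rng, hemisphere=hemi)
            out.append((b, point))
    return out


def _region_hemisphere(region_key: str, soma_hemisphere: str) -> str:
    if not is_contra(region_key):
        return soma_hemisphere
    return "left" if soma_hemisphere == "right" else "right"


def _nearest_group_region(
    cluster: int, region_key: str, inputs: SourceInputs, atlas: Atlas
) -> str | None:
    """Closest region (by centroid distance) with a tuft group in the cluster."""
    candidates = [r for (c, r) in inputs.tuft_groups if c == cluster]
    if not candidates:
        return None
    try:
        ref = atlas.region_centroid(base_acronym(region_key))
    except AtlasError:
        return candidates[0]

    def dist(r: str) -> float:
        try:
            return float(np.linalg.norm(atlas.region_centroid(base_acronym(r)) - ref))
        except AtlasError:
            return np.inf

    return min(candidates, key=dist)


# ---------------------------------------------------------------------------
# routing graph and Steiner trees
# ---------------------------------------------------------------------------

@dataclass
class Lattice:
    """Cached in-brain lattice shared by all axons of one run."""

    positions: np.ndarray  # (n, 3) world μm of lattice vertices
    fiber: np.ndarray  # (n,) bool
    edges: list[tuple[int, int, float, float]]  # (u, v, length, weight)
    step_um: float
    fiber_discount: float


def build_lattice(atlas: Atlas, step_vox: int = 2, fiber_discount: float = 0.5
                  ) -> Lattice:
    """Regular lattice of in-brain voxel centers with 26-connectivity.

    Vertices are annotation-nonzero voxels sampled every ``step_vox`` along
    each axis; an edge's weight is its Euclidean length times
    ``fiber_discount`` when both endpoints lie in the fiber-tract mask.
    """
    if not (0 < fiber_discount <= 1):
        raise ValueError("fiber discount must be in (0, 1]")
    ann = atlas.annotation
    sub = ann[::step_vox, ::step_vox, ::step_vox]
    idx = np.argwhere(sub != 0)  # subgrid indices
    vox = idx * step_vox
    positions = atlas.origin + (vox + 0.5) * atlas.voxel_size
    fiber = atlas.fiber_mask[tuple(vox.T)]
    key = {tuple(v): i for i, v in enumerate(idx)}
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)  # each undirected pair once
    ]
    edges = []
    for i, v in enumerate(idx):
        for off in offsets:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            j = key.get(w)
            if j is None:
                continue
            length = float(np.linalg.norm(positions[i] - positions[j]))
            disc = fiber_discount if (fiber[i] and fiber[j]) else 1.0
            edges.append((i, j, length, length * disc))
    return Lattice(positions, fiber, edges,
                   step_um=step_vox * atlas.voxel_size,
                   fiber_discount=fiber_discount)


def build_graph(
    atlas: Atlas,
    source: np.ndarray,
    targets: list[np.ndarray],
    lattice_step_vox: int = 2,
    fiber_discount: float = 0.5,
    lattice: Lattice | None = None,
) -> SteinerGraph:
    """Assemble the routing graph for one axon.

    Lattice vertices plus the source and target points; source/targets are
    snapped to their nearest lattice vertex by an extra edge.  Raises if any
    target is disconnected from the source (the unreachable targets are
    listed).
    """
    if lattice is None:
        lattice = build_lattice(atlas, lattice_step_vox, fiber_discount)
    g = nx.Graph()
    for i, p in enumerate(lattice.positions):
        g.add_node(i, xyz=p, fiber=bool(lattice.fiber[i]))
    for u, v, length, weight in lattice.edges:
        g.add_edge(u, v, length=length, weight=weight)

    from scipy.spatial import cKDTree

    tree = cKDTree(lattice.positions)

    def attach(key, p):
        p = np.asarray(p, float)
        d, j = tree.query(p)
        in_fiber = atlas.in_fiber_tract(p)
        g.add_node(key, xyz=p, fiber=in_fiber)
        length = float(d)
        disc = lattice.fiber_discount if (in_fiber and lattice.fiber[j]) else 1.0
        if length == 0.0:
            length = 1e-9  # keep weights strictly positive
        g.add_edge(key, int(j), length=length, weight=length * disc)

    attach("source", source)
    tkeys = []
    for t_i, p in enumerate(targets):
        k = ("target", t_i)
        attach(k, p)
        tkeys.append(k)

    comp = nx.node_connected_component(g, "source")
    unreachable = [k for k in tkeys if k not in comp]
    if unreachable:
        raise ValueError(f"targets disconnected from source: {unreachable}")
    return SteinerGraph(graph=g, source="source", targets=tkeys)


def _insertion_tree(g: nx.Graph, root, terminals) -> nx.Graph:
    """Nearest-terminal shortest-path insertion from ``root``."""
    tree = nx.Graph()
    tree.add_node(root, **g.nodes[root])
    remaining = set(terminals)
    while remaining:
        dist, paths = nx.multi_source_dijkstra(g, sources=set(tree.nodes),
                                               weight="weight")
        best = min(remaining, key=lambda t: dist.get(t, np.inf))
        if dist.get(best, np.inf) == np.inf:
            raise ValueError(f"target {best} unreachable")
        path = paths[best]
        for u, v in zip(path[:-1], path[1:]):
            tree.add_node(u, **g.nodes[u])
            tree.add_node(v, **g.nodes[v])
            tree.add_edge(u, v, **g.edges[u, v])
        remaining.discard(best)
    return tree


def _mst_prune(g: nx.Graph, tree: nx.Graph, terminals: set) -> nx.Graph:
    """Re-span the tree's vertex set by an MST and prune non-terminal leaves."""
    sub = g.subgraph(list(tree.nodes)).copy()
    t2 = nx.minimum_spanning_tree(sub, weight="weight")
    changed = True
    while changed:
        changed = False
        for v in [v for v in t2.nodes if t2.degree[v] <= 1 and v not in terminals]:
            t2.remove_node(v)
            changed = True
    return t2


def steiner_tree(sg: SteinerGraph, restarts: bool = True) -> nx.Graph:
    """Heuristic weighted Steiner tree connecting source and targets.

    Core step: nearest-terminal shortest-path insertion — the terminal
    closest (in weighted shortest-path distance) to the current tree is
    attached via that path, repeatedly; a classic 2-approximation.  The
    result is polished by re-spanning its vertex set with a minimum
    spanning tree and pruning non-terminal leaves; with ``restarts`` the
    insertion is additionally rerun rooted at every terminal and the
    lightest tree kept (still within the 2-approximation guarantee).
    """
    g = sg.graph
    terms = set(sg.targets) | {sg.source}
    roots = [sg.source] + (list(sg.targets) if restarts else [])
    best: nx.Graph | None = None
    best_w = np.inf
    for root in roots:
        t = _insertion_tree(g, root, terms - {root})
        for cand in (t, _mst_prune(g, t, terms)):
            w = tree_weight(cand)
            if w < best_w - 1e-12:
                best, best_w = cand, w
    assert best is not None and nx.is_tree(best), "Steiner heuristic failed"
    assert terms <= set(best.nodes)
    return best


def tree_weight(tree: nx.Graph) -> float:
    return float(sum(d["weight"] for _, _, d in tree.edges(data=True)))


def steiner_tree_exact_weight(sg: SteinerGraph) -> float:
    """Optimal Steiner tree weight by Dreyfus–Wagner dynamic programming.

    Exponential in the number of terminals — intended as an exact reference
    on small instances (≤ ~60 vertices, ≤ ~7 terminals).
    """
    g = sg.graph
    nodes = list(g.nodes)
    node_idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    # all-pairs weighted shortest paths
    dist = np.full((n, n), np.inf)
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="weight"):
        i = node_idx[src]
        for dst, d in lengths.items():
            dist[i, node_idx[dst]] = d

    terminals = [node_idx[t] for t in sg.targets]
    root = node_idx[sg.source]
    if not terminals:
        return 0.0
    k = len(terminals)
    full = (1 << k) - 1
    # dp[S][v]: min weight of a tree connecting terminal subset S and vertex v
    dp = np.full((1 << k, n), np.inf)
    for ti, t in enumerate(terminals):
        dp[1 << ti] = dist[t]
    for S in range(1, full + 1):
        if S & (S - 1) == 0:
            continue  # singleton handled above
        # merge two subtrees at v
        sub = (S - 1) & S
        while sub:
            if sub < (S ^ sub):  # each unordered split once
                cand = dp[sub] + dp[S ^ sub]
                np.minimum(dp[S], cand, out=dp[S])
            sub = (sub - 1) & S
        # re-root via shortest paths (Dijkstra over the dp row; with a full
        # metric closure one relaxation round suffices)
        dp[S] = np.min(dp[S][None, :] + dist, axis=1)
    return float(dp[full][root])


# ---------------------------------------------------------------------------
# trunk post-processing
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else v


@dataclass
class TrunkResult:
    morphology: Morphology
    target_attach: dict  # target key -> (node id in morphology, incoming unit dir)


def postprocess_trunk(
    sg: SteinerGraph,
    tree: nx.Graph,
    step: float,
    noise: float,
    history: float,
    rng: np.random.Generator | int,
    radius: float = 0.5,
) -> TrunkResult:
    """Resample the Steiner tree into a trunk morphology with noisy curvature.

    Each path between structural nodes (source, targets, branch points) is
    walked at ``step`` μm: the emitted direction blends the pull toward the
    next tree waypoint (weight 1−noise−history), the previous emitted
    direction (``history``) and unit Gaussian noise (``noise``).  Structural
    node coordinates are preserved exactly, so with noise = history = 0 the
    output is the tree polyline up to resampling.
    """
    if noise < 0 or history < 0 or noise + history >= 1:
        raise ValueError("require noise, history >= 0 and noise + history < 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    structural = {sg.source} | set(sg.targets)
    structural |= {v for v in tree.nodes if tree.degree[v] >= 3}

    soma_xyz = tree.nodes[sg.source]["xyz"]
    nodes: list[MorphNode] = [MorphNode(1, None, soma_xyz, 5.0, SectionType.soma)]
    next_id = 2
    attach: dict = {}

    def emit_path(waypoints: list[np.ndarray], parent_id: int, prev_dir):
        """Append a noisy polyline through the waypoints; returns
        (end node id, end direction).  Every waypoint is emitted exactly, so
        with zero noise and history the output is the tree polyline
        resampled at the step."""
        nonlocal next_id
        cur = waypoints[0].copy()
        d = prev_dir if prev_dir is not None else _unit(waypoints[-1] - cur)
        pid = parent_id
        for wp in waypoints[1:]:
            guard = int(10 * np.linalg.norm(wp - cur) / step) + 10
            for _ in range(guard):
                to_wp = wp - cur
                gap = float(np.linalg.norm(to_wp))
                if gap <= step:
                    break
                direction = _unit(
                    (1.0 - noise - history) * _unit(to_wp)
                    + history * d
                    + noise * rng.standard_normal(3)
                )
                if not np.any(direction):
                    direction = _unit(to_wp)
                cur = cur + step * direction
                d = direction
                nodes.append(MorphNode(next_id, pid, cur.copy(), radius,
                                       SectionType.axon))
                pid = next_id
                next_id += 1
            if np.linalg.norm(wp - cur) > 0:
                d = _unit(wp - cur)
            cur = wp.copy()
            nodes.append(MorphNode(next_id, pid, cur.copy(), radius,
                                   SectionType.axon))
            pid = next_id
            next_id += 1
        return pid, d

    # walk the tree from the source, splitting paths at structural nodes
    morph_id_of = {sg.source: 1}
    dir_at = {sg.source: None}
    stack = [sg.source]
    visited_edges = set()
    while stack:
        start = stack.pop()
        for nb in tree.neighbors(start):
            if (start, nb) in visited_edges or (nb, start) in visited_edges:
                continue
            # follow the chain of degree-2 intermediate vertices
            waypoints = [tree.nodes[start]["xyz"]]
            prev, cur = start, nb
            visited_edges.add((start, nb))
            while cur not in structural and tree.degree[cur] == 2:
                waypoints.append(tree.nodes[cur]["xyz"])
                nxt = [v for v in tree.neighbors(cur) if v != prev][0]
                visited_edges.add((cur, nxt))
                prev, cur = cur, nxt
            waypoints.append(tree.nodes[cur]["xyz"])
            end_id, end_dir = emit_path(waypoints, morph_id_of[start], dir_at[start])
            morph_id_of[cur] = end_id
            dir_at[cur] = end_dir
            if cur in sg.targets:
                attach[cur] = (end_id, end_dir)
            stack.append(cur)

    morph = Morphology(nodes)
    return TrunkResult(morphology=morph, target_attach=attach)


# ---------------------------------------------------------------------------
# tuft growth
# ---------------------------------------------------------------------------

def grow_tuft(
    barcode: list[tuple[float, float]],
    root_xyz: np.ndarray,
    initial_direction: np.ndarray,
    step: float = 20.0,
    noise: float = 0.3,
    rng: np.random.Generator | int = 0,
    inside=None,
) -> Morphology:
    """Regrow a tuft from its persistence barcode.

    A single tip starts at the root walking along ``initial_direction``;
    whenever a tip's path distance passes the birth of an unassigned bar, a
    sibling tip spawns there (taking the bar); a tip terminates exactly when
    its path distance reaches its bar's death.  Directions persist with
    added Gaussian noise.  The grown tuft has one leaf per bar and terminal
    path distances within one step of the bar deaths.

    ``inside`` (optional predicate on a position) constrains growth, e.g.
    to the target region: a step that would leave it is redrawn with the
    direction reflected toward the allowed volume (bounded retries, after
    which the step is accepted so growth always terminates).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    bars = sorted((tuple(map(float, b)) for b in barcode), key=lambda bd: (bd[0], -bd[1]))
    if not bars:
        raise ValueError("empty barcode")
    for birth, death in bars:
        if not (death > birth >= 0):
            raise ValueError(f"malformed bar ({birth}, {death})")
    root_bar = bars[0]
    if root_bar[0] != 0:
        raise ValueError("barcode has no bar born at 0")
    unassigned = list(bars[1:])

    root_xyz = np.asarray(root_xyz, float)
    # soma point plus an axon root at the same position, so path distances
    # along the grown axon are measured from the tuft origin itself
    nodes: list[MorphNode] = [
        MorphNode(1, None, root_xyz, 1.0, SectionType.soma),
        MorphNode(2, 1, root_xyz.copy(), 0.5, SectionType.axon),
    ]
    next_id = 3

    # tip: [pos, dir, path_distance, death, parent_node_id]
    tips = [
        {"pos": root_xyz.copy(), "dir": _unit(np.asarray(initial_direction, float)),
         "pd": 0.0, "death": root_bar[1], "parent": 2}
    ]
    if not np.any(tips[0]["dir"]):
        tips[0]["dir"] = np.array([1.0, 0.0, 0.0])

    while tips:
        new_tips = []
        # spawn siblings for bars whose birth has been reached
        for bar in list(unassigned):
            birth, death = bar
            candidates = [t for t in tips if t["pd"] >= birth - 1e-9]
            if not candidates:
                continue
            host = min(candidates, key=lambda t: abs(t["pd"] - birth))
            sib_dir = _unit(host["dir"] + 0.8 * rng.standard_normal(3))
            new_tips.append(
                {"pos": host["pos"].copy(), "dir": sib_dir, "pd": host["pd"],
                 "death": death, "parent": host["parent"]}
            )
            unassigned.remove(bar)
        tips.extend(new_tips)
        survivors = []
        for tip in tips:
            remaining = tip["death"] - tip["pd"]
            advance = min(step, remaining)
            direction = _unit(tip["dir"] + noise * rng.standard_normal(3))
            if not np.any(direction):
                direction = tip["dir"]
            if inside is not None:
                for _retry in range(10):
                    if inside(tip["pos"] + advance * direction):
                        break
                    # turn back toward the allowed volume and jitter
                    direction = _unit(-0.5 * direction + rng.standard_normal(3))
            tip["pos"] = tip["pos"] + advance * direction
            tip["dir"] = direction
            tip["pd"] += advance
            nodes.append(MorphNode(next_id, tip["parent"], tip["pos"].copy(), 0.5,
                                   SectionType.axon))
            tip["parent"] = next_id
            next_id += 1
            if tip["pd"] < tip["death"] - 1e-9:
                survivors.append(tip)
        tips = survivors
        if not tips and unassigned:
            # bars born beyond every death (malformed input tolerated by
            # hanging them off the root)
            birth, death = unassigned.pop(0)
            tips.append({"pos": root_xyz.copy(),
                         "dir": _unit(rng.standard_normal(3)),
                         "pd": 0.0, "death": death, "parent": 2})
    return Morphology(nodes)


# ---------------------------------------------------------------------------
# population synthesis
# ---------------------------------------------------------------------------

def build_source_inputs(
    matrix: ProjectionMatrix,
    model: GMMModel,
    tufts: list[Tuft],
    feature: str = "lengths",
) -> SourceInputs:
    """Derive per-cluster targeting statistics and the grouped tuft library.

    Cluster membership is the model's hard assignment of the training
    features; the probability of targeting region *b* is the fraction of
    cluster members with at least one terminal in *b*.
    """
    labels = model.predict(matrix.feature(feature))
    region_prob: dict[int, dict[str, float]] = {}
    for c in range(model.C):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue
        probs = {}
        for j, b in enumerate(matrix.region_vocab):
            frac = float((matrix.terminals[members, j] > 0).mean())
            if frac > 0:
                probs[b] = frac
        region_prob[int(c)] = probs
    cluster_of = {nid: int(c) for nid, c in zip(matrix.neuron_ids, labels)}
    groups = group_tufts([t for t in tufts if t.neuron_id in cluster_of], cluster_of)
    return SourceInputs(model=model, region_prob=region_prob, tuft_groups=groups)


def _select_tuft(group: TuftGroup, rng: np.random.Generator) -> Tuft:
    scores = np.asarray(group.scores, float)
    if scores.sum() <= 0:
        probs = np.full(len(group.tufts), 1.0 / len(group.tufts))
    else:
        probs = scores / scores.sum()
    return group.tufts[int(rng.choice(len(group.tufts), p=probs))]


def synthesize_axon(
    task: SynthesisTask,
    inputs: SourceInputs,
    atlas: Atlas,
    config: SynthesisConfig,
    rng: np.random.Generator,
    lattice: Lattice | None = None,
) -> tuple[Morphology, dict]:
    """Synthesize one long-range axon; returns (morphology, manifest)."""
    cluster = assign_cluster(inputs.model, rng)
    soma_hemi = atlas.hemisphere_of(task.soma_xyz)
    targets = choose_targets(cluster, inputs, atlas, soma_hemi, rng,
                             retry_bound=config.retry_bound)
    if not targets:
        raise ValueError(f"{task.neuron_id}: no target points selected")
    sg = build_graph(
        atlas, task.soma_xyz, [p for _, p in targets],
        lattice_step_vox=config.lattice_step_vox,
        fiber_discount=config.fiber_discount,
        lattice=lattice,
    )
    tree = steiner_tree(sg)
    trunk = postprocess_trunk(sg, tree, step=config.trunk_step,
                              noise=config.trunk_noise,
                              history=config.trunk_history,
                              rng=rng, radius=config.radius)

    # graft a tuft at every target point
    nodes = list(trunk.morphology.nodes)
    next_id = max(n.id for n in nodes) + 1
    for t_i, (region, point) in enumerate(targets):
        key = ("target", t_i)
        attach_id, incoming = trunk.target_attach[key]
        group = inputs.tuft_groups.get((cluster, region))
        if group is None:
            fallback = _nearest_group_region(cluster, region, inputs, atlas)
            if fallback is None:
                continue
            group = inputs.tuft_groups[(cluster, fallback)]
        tuft = _select_tuft(group, rng)
        region_id = atlas.hierarchy.id_of(base_acronym(region))

        def inside(p, _rid=region_id):
            rid = atlas.region_at(p)
            return rid is not None and atlas.hierarchy.is_descendant(rid, _rid)

        grown = grow_tuft(tuft.barcode, point, incoming,
                          step=config.tuft_step, noise=config.tuft_noise, rng=rng,
                          inside=inside)
        remap = {grown.root.id: attach_id}
        for n in grown.nodes:
            if n.parent_id is None:
                continue
            remap[n.id] = next_id
            nodes.append(MorphNode(next_id, remap[n.parent_id], n.xyz.copy(),
                                   config.radius, SectionType.axon))
            next_id += 1

    morph = Morphology(nodes, neuron_id=task.neuron_id)
    manifest = {
        "neuron_id": task.neuron_id,
        "source_region": task.source_region,
        "cluster": int(cluster),
        "targets": [
            {"region": r, "xyz": [float(v) for v in p]} for r, p in targets
        ],
    }
    return morph, manifest


def synthesize_population(
    tasks: list[SynthesisTask],
    inputs_by_source: dict[str, SourceInputs],
    atlas: Atlas,
    config: SynthesisConfig | None = None,
    seed: int = 0,
) -> tuple[list[Morphology], list[dict]]:
    """Synthesize axons for all tasks; deterministic under the master seed.

    Each task gets an independent substream spawned from the master seed, so
    results do not depend on task execution order.
    """
    config = config or SynthesisConfig()
    lattice_cache: dict[int, Lattice] = {}
    base = np.random.SeedSequence(seed)
    streams = base.spawn(len(tasks))
    morphs: list[Morphology] = []
    manifests: list[dict] = []
    step = config.lattice_step_vox
    if step not in lattice_cache:
        lattice_cache[step] = build_lattice(atlas, step, config.fiber_discount)
    for task, ss in zip(tasks, streams):
        if task.source_region not in inputs_by_source:
            raise KeyError(f"no fitted inputs for source region {task.source_region!r}")
        rng = np.random.default_rng(ss)
        morph, manifest = synthesize_axon(
            task, inputs_by_source[task.source_region], atlas, config, rng,
            lattice=lattice_cache[step],
        )
        morphs.append(morph)
        manifests.append(manifest)
    return morphs, manifests
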