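"""Proximity-based axo-dendritic connectivity.

Synapse candidates ("touches") are detected wherever an axon segment of one
neuron passes within a touch distance of a dendrite segment of another
neuron.  Touches are then filtered by a minimum inter-bouton interval along
each axonal branch, pruned to a physiological synapse density per μm of
postsynaptic dendrite, and aggregated into a neuron-level adjacency and a
region-level projectome.

Detection uses a uniform spatial hash over segment bounding boxes for
speed, but the result is exactly the all-pairs computation: any pair within
the touch distance shares at least one hash cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from longax.atlas import Atlas
from longax.morpho import Morphology, SectionType

__all__ = [
    "Touch",
    "Synapse",
    "Connectome",
    "detect_touches",
    "filter_interbouton",
    "prune_to_density",
    "aggregate",
    "segment_segment_distance",
]


@dataclass(frozen=True)
class Touch:
    """A candidate contact between an axon and a dendrite segment."""

    pre: str
    post: str
    xyz: tuple[float, float, float]
    pre_branch: int  # axon section index on the presynaptic neuron
    pre_arclen: float  # arc length along the axon at the touch, μm
    distance: float  # closest approach, μm


@dataclass(frozen=True)
class Synapse:
    pre: str
    post: str
    xyz: tuple[float, float, float]
    pre_arclen: float
    post_region: str | None = None


@dataclass
class Connectome:
    """Synapse list with neuron- and region-level aggregations."""

    synapses: list[Synapse]
    adjacency: dict[tuple[str, str], int]  # (pre, post) -> synapse count
    projectome: dict[tuple[str, str], int]  # (pre region, post region) -> count
    out_degree: dict[str, int]  # pre -> distinct postsynaptic partners
    out_synapses: dict[str, int]  # pre -> synapse count variant
    region_counts: dict[str, int]  # post region -> synapse count

    @property
    def n_synapses(self) -> int:
        return len(self.synapses)

    def synapse_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"pre": s.pre, "post": s.post, "x": s.xyz[0], "y": s.xyz[1],
                 "z": s.xyz[2], "pre_arclen": s.pre_arclen,
                 "post_region": s.post_region}
                for s in self.synapses
            ]
        )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def segment_segment_distance(p0, p1, q0, q1) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimal distance between segments [p0, p1] and [q0, q1].

    Returns (distance, closest point on P, closest point on Q); the standard
    clamped closed-form solution.
    """
    p0, p1, q0, q1 = (np.asarray(v, float) for v in (p0, p1, q0, q1))
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    eps = 1e-12
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r)), p0, q0
    if a <= eps:
        s = 0.0
        t = np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= eps:
            t = 0.0
            s = np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t = 1.0
                s = np.clip((b - c) / a, 0.0, 1.0)
    cp = p0 + s * d1
    cq = q0 + t * d2
    return float(np.linalg.norm(cp - cq)), cp, cq


@dataclass
class _Seg:
    neuron: str
    p0: np.ndarray
    p1: np.ndarray
    radius: float
    branch: int
    arc_start: float


def _axon_segments(m: Morphology) -> list[_Seg]:
    segs: list[_Seg] = []
    pdist = m.path_distances(SectionType.axon)
    sections = m.sections(SectionType.axon)
    for b_idx, sec in enumerate(sections):
        for a, b in zip(sec[:-1], sec[1:]):
            na, nb = m.node(a), m.node(b)
            seg_len = float(np.linalg.norm(nb.xyz - na.xyz))
            # the soma-seam segment sits just before the neurite root
            arc = pdist[a] if a in pdist else pdist[b] - seg_len
            segs.append(_Seg(m.neuron_id, na.xyz, nb.xyz,
                             0.5 * (na.radius + nb.radius), b_idx, arc))
    return segs


def _dendrite_segments(m: Morphology) -> list[_Seg]:
    segs: list[_Seg] = []
    for st in (SectionType.basal_dendrite, SectionType.apical_dendrite):
        for b_idx, sec in enumerate(m.sections(st)):
            for a, b in zip(sec[:-1], sec[1:]):
                na, nb = m.node(a), m.node(b)
                segs.append(_Seg(m.neuron_id, na.xyz, nb.xyz,
                                 0.5 * (na.radius + nb.radius), b_idx, 0.0))
    return segs


def dendrite_length(m: Morphology) -> float:
    return (m.total_length(SectionType.basal_dendrite)
            + m.total_length(SectionType.apical_dendrite))


# ---------------------------------------------------------------------------
# touch detection
# ---------------------------------------------------------------------------

def detect_touches(
    pre_morphs: list[Morphology],
    post_morphs: list[Morphology],
    touch_distance: float | None = None,
    touch_margin: float = 1.0,
) -> list[Touch]:
    """All axon-dendrite segment pairs of distinct neurons within reach.

    The per-pair threshold is ``touch_distance`` when given, otherwise the
    sum of the two segment radii plus ``touch_margin`` μm.  The touch point
    is the midpoint of the closest-approach segment; its axonal arc-length
    position and branch index are recorded for inter-bouton filtering.
    """
    pre_segs = [s for m in pre_morphs for s in _axon_segments(m)]
    post_segs = [s for m in post_morphs for s in _dendrite_segments(m)]
    if not pre_segs or not post_segs:
        return []

    max_r_pre = max(s.radius for s in pre_segs)
    max_r_post = max(s.radius for s in post_segs)
    max_thresh = (touch_distance if touch_distance is not None
                  else max_r_pre + max_r_post + touch_margin)
    cell = max(
        max_thresh,
        float(np.median([np.linalg.norm(s.p1 - s.p0) for s in post_segs])) + 1e-9,
    ) * 2.0

    # hash post segments into all cells their (threshold-expanded) bbox hits
    grid: dict[tuple[int, int, int], list[int]] = {}
    for j, s in enumerate(post_segs):
        lo = np.minimum(s.p0, s.p1) - max_thresh
        hi = np.maximum(s.p0, s.p1) + max_thresh
        lo_c = np.floor(lo / cell).astype(int)
        hi_c = np.floor(hi / cell).astype(int)
        for ix in range(lo_c[0], hi_c[0] + 1):
            for iy in range(lo_c[1], hi_c[1] + 1):
                for iz in range(lo_c[2], hi_c[2] + 1):
                    grid.setdefault((ix, iy, iz), []).append(j)

    touches: list[Touch] = []
    for s in pre_segs:
        lo = np.minimum(s.p0, s.p1)
        hi = np.maximum(s.p0, s.p1)
        lo_c = np.floor(lo / cell).astype(int)
        hi_c = np.floor(hi / cell).astype(int)
        seen: set[int] = set()
        for ix in range(lo_c[0], hi_c[0] + 1):
            for iy in range(lo_c[1], hi_c[1] + 1):
                for iz in range(lo_c[2], hi_c[2] + 1):
                    seen.update(grid.get((ix, iy, iz), ()))
        for j in sorted(seen):
            t = post_segs[j]
            if t.neuron == s.neuron:
                continue
            thresh = (touch_distance if touch_distance is not None
                      else s.radius + t.radius + touch_margin)
            d, cp, cq = segment_segment_distance(s.p0, s.p1, t.p0, t.p1)
            if d <= thresh:
                mid = 0.5 * (cp + cq)
                seg_len = float(np.linalg.norm(s.p1 - s.p0))
                along = float(np.linalg.norm(cp - s.p0))
                touches.append(
                    Touch(
                        pre=s.neuron, post=t.neuron, xyz=tuple(mid),
                        pre_branch=s.branch,
                        pre_arclen=s.arc_start + min(along, seg_len),
                        distance=d,
                    )
                )
    touches.sort(key=lambda t: (t.pre, t.post, t.pre_branch, t.pre_arclen))
    return touches


def filter_interbouton(touches: list[Touch], min_interval: float) -> list[Touch]:
    """Greedy minimum-spacing filter along each axonal branch.

    Per (presynaptic neuron, branch), touches are scanned in increasing
    arc length; one is kept iff it lies at least ``min_interval`` μm past
    the last kept touch.
    """
    if min_interval <= 0:
        return list(touches)
    by_branch: dict[tuple[str, int], list[Touch]] = {}
    for t in touches:
        by_branch.setdefault((t.pre, t.pre_branch), []).append(t)
    kept: list[Touch] = []
    for key in sorted(by_branch):
        last = -np.inf
        for t in sorted(by_branch[key], key=lambda t: t.pre_arclen):
            if t.pre_arclen - last >= min_interval:
                kept.append(t)
                last = t.pre_arclen
    kept.sort(key=lambda t: (t.pre, t.post, t.pre_branch, t.pre_arclen))
    return kept


def prune_to_density(
    touches: list[Touch],
    density: float,
    post_morphs: list[Morphology],
    rng: np.random.Generator | int = 0,
) -> list[Synapse]:
    """Cap touches per postsynaptic neuron at density × dendritic length.

    When a neuron receives more candidates than its budget, a uniform random
    subset of exactly the budget size is kept (reproducible per seed); the
    survivors become synapses.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lengths = {m.neuron_id: dendrite_length(m) for m in post_morphs}
    by_post: dict[str, list[Touch]] = {}
    for t in touches:
        by_post.setdefault(t.post, []).append(t)
    synapses: list[Synapse] = []
    for post in sorted(by_post):
        cands = by_post[post]
        budget = int(np.floor(density * lengths.get(post, 0.0)))
        if len(cands) > budget:
            keep_idx = sorted(rng.choice(len(cands), size=budget, replace=False))
            cands = [cands[i] for i in keep_idx]
        synapses.extend(
            Synapse(pre=t.pre, post=t.post, xyz=t.xyz, pre_arclen=t.pre_arclen)
            for t in cands
        )
    return synapses


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate(
    synapses: list[Synapse],
    atlas: Atlas,
    level: int | str = "leaf",
    pre_region: dict[str, str] | None = None,
) -> Connectome:
    """Neuron adjacency, region projectome and out-degrees from a synapse list.

    Each synapse's postsynaptic region is the atlas region of its position
    at the requested hierarchy level; the projectome direction is
    pre-region → post-region with the presynaptic region taken from
    ``pre_region`` (e.g. soma regions) when provided.
    """
    pre_region = pre_region or {}
    located: list[Synapse] = []
    adjacency: dict[tuple[str, str], int] = {}
    projectome: dict[tuple[str, str], int] = {}
    region_counts: dict[str, int] = {}
    partners: dict[str, set[str]] = {}
    out_synapses: dict[str, int] = {}
    for s in synapses:
        region = atlas.acronym_at(s.xyz, level)
        s = Synapse(s.pre, s.post, s.xyz, s.pre_arclen, post_region=region)
        located.append(s)
        adjacency[(s.pre, s.post)] = adjacency.get((s.pre, s.post), 0) + 1
        partners.setdefault(s.pre, set()).add(s.post)
        out_synapses[s.pre] = out_synapses.get(s.pre, 0) + 1
        if region is not None:
            region_counts[region] = region_counts.get(region, 0) + 1
            src = pre_region.get(s.pre)
            if src is not None:
                projectome[(src, region)] = projectome.get((src, region), 0) + 1
    return Connectome(
        synapses=located,
        adjacency=adjacency,
        projectome=projectome,
        out_degree={k: len(v) for k, v in partners.items()},
        out_synapses=out_synapses,
        region_counts=region_counts,
    )


def connections_vs_border_distance(
    conn: Connectome, atlas: Atlas, source_region: str
) -> pd.DataFrame:
    """Per post region: synapse count and border distance to the source."""
    rows = []
    for region, count in sorted(conn.region_counts.items()):
        rows.append(
            {
                "region": region,
                "connections": count,
                "border_distance_um": atlas.border_distance(source_region, region),
            }
        )
    return pd.DataFrame(rows, columns=["region", "connections", "border_distance_um"])


def connections_vs_axon_length(
    conn: Connectome, pre_morphs: list[Morphology], atlas: Atlas,
    level: int | str = "leaf",
) -> pd.DataFrame:
    """Per region: synapse count vs total presynaptic axon length inside it.

    Length is attributed by segment midpoint over all traversed regions (the
    relation between cable and connection count is about presence, not
    termination).
    """
    lengths: dict[str, float] = {}
    for m in pre_morphs:
        for pid, cid in m.segments(SectionType.axon):
            mid = 0.5 * (m.node(pid).xyz + m.node(cid).xyz)
            acro = atlas.acronym_at(mid, level)
            if acro is not None:
                lengths[acro] = lengths.get(acro, 0.0) + m.segment_length(pid, cid)
    regions = sorted(set(lengths) | set(conn.region_counts))
    return pd.DataFrame(
        [
            {
                "region": r,
                "axon_length_um": lengths.get(r, 0.0),
                "connections": conn.region_counts.get(r, 0),
            }
            for r in regions
        ]
    )


def export_matrices(conn: Connectome, directory) -> None:
    """Write adjacency and projectome as MatrixMarket files + index JSON."""
    import json
    from pathlib import Path

    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def write(counts: dict[tuple[str, str], int], stem: str) -> None:
        rows = sorted({k[0] for k in counts})
        cols = sorted({k[1] for k in counts})
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: i for i, c in enumerate(cols)}
        if counts:
            mat = coo_matrix(
                (
                    [v for v in counts.values()],
                    (
                        [ri[k[0]] for k in counts],
                        [ci[k[1]] for k in counts],
                    ),
                ),
                shape=(len(rows), len(cols)),
            )
        else:
            mat = coo_matrix((0, 0))
        mmwrite(directory / f"{stem}.mtx", mat)
        with open(directory / f"{stem}.index.json", "w") as fh:
            json.dump({"rows": rows, "cols": cols}, fh, indent=1)

    write(conn.adjacency, "adjacency")
    write(conn.projectome, "projectome")
    conn.synapse_frame().to_csv(directory / "synapses.csv", index=False)
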