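"""Morphology data model, SWC I/O and tree morphometrics.

A :class:`Morphology` is a rooted tree of 3D points with radii and section
types (soma / axon / dendrites), stored in topological order (every parent
precedes its children).  Single-child nodes are polyline points inside a
*section*; sections break only at the root, at bifurcations and at leaves,
so the section graph never contains unifurcations.

Coordinates are in micrometers throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SectionType",
    "MorphNode",
    "Morphology",
    "MorphologyBuilder",
    "Morphometrics",
    "read_swc",
    "write_swc",
    "compute_morphometrics",
]


class SectionType(IntEnum):
    """SWC structure identifiers."""

    soma = 1
    axon = 2
    basal_dendrite = 3
    apical_dendrite = 4


@dataclass(frozen=True)
class MorphNode:
    """One SWC record: a 3D point with radius and structure type."""

    id: int
    parent_id: int | None
    xyz: np.ndarray  # shape (3,), μm
    radius: float  # μm
    section_type: SectionType

    def __post_init__(self) -> None:
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))


class MorphologyError(ValueError):
    """Raised on malformed or structurally invalid morphologies."""


class Morphology:
    """Rooted tree of :class:`MorphNode` with a single soma root.

    Parameters
    ----------
    nodes:
        Nodes with unique ids; exactly one node has ``parent_id is None``
        and it must be of type soma.
    neuron_id:
        Identifier carried through projections, clustering and synthesis.
    """

    def __init__(self, nodes: Sequence[MorphNode], neuron_id: str = "") -> None:
        if not nodes:
            raise MorphologyError("morphology has no nodes")
        ids = [n.id for n in nodes]
        if len(set(ids)) != len(ids):
            raise MorphologyError("duplicate node ids")
        by_id = {n.id: n for n in nodes}
        roots = [n for n in nodes if n.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        root = roots[0]
        if root.section_type != SectionType.soma:
            raise MorphologyError("root node must be of soma type")
        for n in nodes:
            if n.parent_id is not None and n.parent_id not in by_id:
                raise MorphologyError(f"node {n.id} references missing parent {n.parent_id}")
            if not np.all(np.isfinite(n.xyz)):
                raise MorphologyError(f"node {n.id} has non-finite coordinates")
            if n.radius <= 0:
                raise MorphologyError(f"node {n.id} has non-positive radius")
        self.nodes = self._toposort(nodes, by_id, root)
        self.neuron_id = neuron_id
        self._by_id = {n.id: n for n in self.nodes}
        self._children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id is not None:
                self._children[n.parent_id].append(n.id)

    @staticmethod
    def _toposort(
        nodes: Sequence[MorphNode], by_id: dict[int, MorphNode], root: MorphNode
    ) -> list[MorphNode]:
        children: dict[int, list[int]] = {n.id: [] for n in nodes}
        for n in nodes:
            if n.parent_id is not None:
                children[n.parent_id].append(n.id)
        order: list[MorphNode] = []
        stack = [root.id]
        seen = set()
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise MorphologyError("cyclic parent links")
            seen.add(nid)
            order.append(by_id[nid])
            stack.extend(reversed(children[nid]))
        if len(order) != len(nodes):
            raise MorphologyError("cyclic or disconnected parent links")
        return order

    # -- basic accessors ---------------------------------------------------

    @property
    def root(self) -> MorphNode:
        return self.nodes[0]

    @property
    def soma_center(self) -> np.ndarray:
        return self.root.xyz

    def node(self, nid: int) -> MorphNode:
        return self._by_id[nid]

    def children(self, nid: int) -> list[int]:
        return self._children[nid]

    def parent(self, nid: int) -> int | None:
        return self._by_id[nid].parent_id

    def __len__(self) -> int:
        return len(self.nodes)

    # -- neurite views -----------------------------------------------------

    def neurite_node_ids(self, section_type: SectionType) -> list[int]:
        """Ids of nodes of the given type, in topological order."""
        return [n.id for n in self.nodes if n.section_type == section_type]

    def leaves(self, section_type: SectionType | None = None) -> list[int]:
        """Ids of terminal nodes, optionally restricted to one neurite type."""
        out = []
        for n in self.nodes:
            if section_type is not None and n.section_type != section_type:
                continue
            kids = self._children[n.id]
            if section_type is None:
                if not kids:
                    out.append(n.id)
            elif not any(self._by_id[k].section_type == section_type for k in kids):
                out.append(n.id)
        return out

    def segments(
        self, section_type: SectionType | None = None
    ) -> list[tuple[int, int]]:
        """(parent_id, child_id) pairs of neurite cable.

        The seam from the soma point to each neurite root is included (a
        neurite starts at the soma), so summed segment lengths equal the
        neurite's total cable length.
        """
        segs = []
        for n in self.nodes:
            if n.parent_id is None or n.section_type == SectionType.soma:
                continue
            if section_type is not None and n.section_type != section_type:
                continue
            segs.append((n.parent_id, n.id))
        return segs

    def segment_length(self, parent_id: int, child_id: int) -> float:
        return float(
            np.linalg.norm(self._by_id[child_id].xyz - self._by_id[parent_id].xyz)
        )

    def path_distances(self, section_type: SectionType) -> dict[int, float]:
        """Arc length from each node of the neurite to the neurite root.

        The neurite root is the first node of the given type on each
        root-ward path (its own path distance is 0); the virtual segment
        from the soma point to the neurite root is not counted.
        """
        dist: dict[int, float] = {}
        for n in self.nodes:
            if n.section_type != section_type:
                continue
            p = n.parent_id
            if p is None or self._by_id[p].section_type != section_type:
                dist[n.id] = 0.0
            else:
                dist[n.id] = dist[p] + self.segment_length(p, n.id)
        return dist

    def sections(self, section_type: SectionType) -> list[list[int]]:
        """Maximal unbranched chains of the neurite, root-ward node first.

        A section starts at the soma seam (for the neurite root) or at a
        bifurcation, and runs through single-child polyline points to a leaf
        or the next bifurcation.  The branch-point node is shared: it
        terminates the parent section and starts each child section; the
        root section includes the soma point as its first polyline point.
        """
        type_children = {
            n.id: [
                k for k in self._children[n.id]
                if self._by_id[k].section_type == section_type
            ]
            for n in self.nodes
        }
        starts = []
        for n in self.nodes:
            if n.section_type != section_type:
                continue
            p = n.parent_id
            if p is None or self._by_id[p].section_type != section_type:
                starts.append((n.id, p))  # neurite root, anchored at the soma
        sections = []
        stack = list(reversed(starts))
        while stack:
            start, anchor = stack.pop()
            sec = [anchor] if anchor is not None else []
            cur = start
            sec.append(cur)
            while len(type_children[cur]) == 1:
                cur = type_children[cur][0]
                sec.append(cur)
            sections.append(sec)
            for k in reversed(type_children[cur]):
                stack.append((k, cur))
        return sections

    def total_length(self, section_type: SectionType | None = None) -> float:
        return float(
            sum(self.segment_length(p, c) for p, c in self.segments(section_type))
        )

    def subtree_ids(self, nid: int) -> list[int]:
        """Ids of the subtree rooted at ``nid`` (inclusive), preorder."""
        out = []
        stack = [nid]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(reversed(self._children[cur]))
        return out


class MorphologyBuilder:
    """Incremental construction of a morphology, used by fixtures and synthesis."""

    def __init__(self, soma_xyz: Iterable[float], soma_radius: float = 5.0,
                 neuron_id: str = "") -> None:
        self.neuron_id = neuron_id
        self._nodes: list[MorphNode] = [
            MorphNode(1, None, np.asarray(list(soma_xyz), float), soma_radius,
                      SectionType.soma)
        ]

    @property
    def soma_id(self) -> int:
        return 1

    def add(self, parent_id: int, xyz: Iterable[float],
            section_type: SectionType = SectionType.axon,
            radius: float = 0.5) -> int:
        nid = len(self._nodes) + 1
        self._nodes.append(
            MorphNode(nid, parent_id, np.asarray(list(xyz), float), radius,
                      section_type)
        )
        return nid

    def build(self) -> Morphology:
        return Morphology(self._nodes, neuron_id=self.neuron_id)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path: str | Path, neuron_id: str | None = None) -> Morphology:
    """Read a standard 7-column SWC file.

    The dialect is: 1-based ids, parent ``-1`` for the root, ``#`` comments.
    Multi-point somata are collapsed to their centroid (mean of soma points,
    mean radius); children of any soma point are re-parented to the single
    soma node.  Coordinates are taken verbatim (μm).

    Raises
    ------
    MorphologyError
        On malformed lines (named by line number) or cyclic parent links.
    """
    path = Path(path)
    raw: list[tuple[int, int, float, float, float, float, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MorphologyError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                stype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise MorphologyError(f"{path.name}:{lineno}: {exc}") from None
            raw.append((nid, stype, x, y, z, r, pid))

    soma_rows = [row for row in raw if row[1] == SectionType.soma]
    if not soma_rows:
        raise MorphologyError(f"{path.name}: no soma record")
    soma_ids = {row[0] for row in soma_rows}
    centroid = np.mean([[r[2], r[3], r[4]] for r in soma_rows], axis=0)
    soma_radius = float(np.mean([r[5] for r in soma_rows]))
    soma_id = min(soma_ids)

    nodes = [MorphNode(soma_id, None, centroid, soma_radius, SectionType.soma)]
    for nid, stype, x, y, z, r, pid in raw:
        if nid in soma_ids:
            continue
        if pid in soma_ids:
            pid = soma_id
        try:
            st = SectionType(stype)
        except ValueError:
            st = SectionType.axon  # unknown custom types folded into axon
        nodes.append(MorphNode(nid, None if pid == -1 else pid, (x, y, z), r, st))
    return Morphology(nodes, neuron_id=neuron_id if neuron_id is not None else path.stem)


def write_swc(m: Morphology, path: str | Path) -> None:
    """Write a 7-column SWC file; ids renumbered 1..n in topological order."""
    renum = {n.id: i + 1 for i, n in enumerate(m.nodes)}
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in m.nodes:
            pid = -1 if n.parent_id is None else renum[n.parent_id]
            fh.write(
                f"{renum[n.id]} {int(n.section_type)} "
                f"{n.xyz[0]:.9f} {n.xyz[1]:.9f} {n.xyz[2]:.9f} "
                f"{n.radius:.9f} {pid}\n"
            )


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

@dataclass
class Morphometrics:
    """Scalar and distributional features of one neurite tree."""

    neuron_id: str
    neurite: SectionType
    number_of_leaves: int
    section_lengths: list[float]
    path_distances_to_root: list[float]  # per leaf, μm
    remote_bifurcation_angles: list[float]  # rad
    branch_orders: list[int]
    total_length: float
    empty: bool = False

    def as_records(self) -> list[dict]:
        """Long-format records (neuron_id, neurite, feature, value)."""
        rows = []

        def emit(feature: str, values) -> None:
            for v in np.atleast_1d(values):
                rows.append(
                    {"neuron_id": self.neuron_id, "neurite": self.neurite.name,
                     "feature": feature, "value": float(v)}
                )

        emit("number_of_leaves", self.number_of_leaves)
        emit("section_lengths", self.section_lengths)
        emit("path_distances_to_root", self.path_distances_to_root)
        emit("remote_bifurcation_angles", self.remote_bifurcation_angles)
        emit("branch_orders", self.branch_orders)
        emit("total_length", self.total_length)
        return rows


def _angle(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = float(np.dot(u, v) / (nu * nv))
    return math.acos(min(1.0, max(-1.0, c)))


def compute_morphometrics(m: Morphology, neurite: SectionType) -> Morphometrics:
    """Compute the feature set of one neurite tree.

    Path distance of a leaf is the arc length along parents to the neurite
    root; the remote bifurcation angle at a branch point is the angle
    between the vectors from it to the far endpoints of its child sections
    (all child pairs for multifurcations); branch order of a section counts
    the bifurcations on the path from the neurite root.
    """
    node_ids = m.neurite_node_ids(neurite)
    if not node_ids:
        return Morphometrics(m.neuron_id, neurite, 0, [], [], [], [], 0.0, empty=True)

    sections = m.sections(neurite)
    sec_lengths = [
        sum(m.segment_length(a, b) for a, b in zip(sec[:-1], sec[1:]))
        for sec in sections
    ]
    pdist = m.path_distances(neurite)
    leaves = m.leaves(neurite)
    leaf_pd = [pdist[l] for l in leaves]

    # child sections per branch node: section list whose first node is the branch
    angles: list[float] = []
    by_start: dict[int, list[list[int]]] = {}
    for sec in sections:
        by_start.setdefault(sec[0], []).append(sec)
    for start, secs in by_start.items():
        if len(secs) < 2:
            continue
        origin = m.node(start).xyz
        tips = [m.node(sec[-1]).xyz for sec in secs]
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                angles.append(_angle(tips[i] - origin, tips[j] - origin))

    # branch order of a section = number of bifurcations on the path from
    # the neurite root down to (and including) the section's anchor node
    def is_bifurcation(nid: int) -> bool:
        return (
            m.node(nid).section_type == neurite
            and len([k for k in m.children(nid)
                     if m.node(k).section_type == neurite]) >= 2
        )

    orders: list[int] = []
    for sec in sections:
        count = 1 if is_bifurcation(sec[0]) else 0
        cur = m.parent(sec[0])
        while cur is not None and m.node(cur).section_type == neurite:
            if is_bifurcation(cur):
                count += 1
            cur = m.parent(cur)
        orders.append(count)

    return Morphometrics(
        neuron_id=m.neuron_id,
        neurite=neurite,
        number_of_leaves=len(leaves),
        section_lengths=sec_lengths,
        path_distances_to_root=leaf_pd,
        remote_bifurcation_angles=angles,
        branch_orders=orders,
        total_length=float(sum(sec_lengths)),
    )


def morphometrics_frame(metrics: Iterable[Morphometrics]):
    """Long-format DataFrame (neuron_id, neurite, feature, value)."""
    import pandas as pd

    rows: list[dict] = []
    for mm in metrics:
        rows.extend(mm.as_records())
    return pd.DataFrame(rows, columns=["neuron_id", "neurite", "feature", "value"])
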