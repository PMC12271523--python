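"""Voxelized annotated brain volume and region hierarchy.

The :class:`Atlas` couples a 3D integer annotation raster (one region id per
voxel, 0 = outside the brain) with an Allen-style region hierarchy, a boolean
fiber-tract mask and a midline definition.  It answers position→region
queries at any hierarchy level, assigns hemispheres, samples points inside
regions and measures inter-region border distances.

Conventions: world coordinates in μm; 0-based voxel indices; a point belongs
to voxel ``floor((xyz - origin) / voxel_size)`` (half-open ownership
``[v, v + voxel_size)``).  Rasters are stored on disk as raw little-endian
arrays next to a JSON header; the hierarchy as Allen-structure-graph-style
JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["RegionHierarchy", "Atlas", "build_toy_atlas", "AtlasError"]


class AtlasError(ValueError):
    pass


class RegionHierarchy:
    """Single-rooted region tree with unique integer ids and acronyms."""

    def __init__(self, root: dict) -> None:
        # root: nested dicts {"id", "acronym", "children": [...]}
        self._parent: dict[int, int | None] = {}
        self._children: dict[int, list[int]] = {}
        self._acronym: dict[int, str] = {}
        self._id_of: dict[str, int] = {}
        self._depth: dict[int, int] = {}
        self.root_id = int(root["id"])

        def walk(node: dict, parent: int | None, depth: int) -> None:
            nid = int(node["id"])
            acro = str(node["acronym"])
            if nid in self._acronym:
                raise AtlasError(f"duplicate region id {nid}")
            if acro in self._id_of:
                raise AtlasError(f"duplicate acronym {acro!r}")
            self._parent[nid] = parent
            self._acronym[nid] = acro
            self._id_of[acro] = nid
            self._depth[nid] = depth
            self._children[nid] = []
            for child in node.get("children", []):
                self._children[nid].append(int(child["id"]))
                walk(child, nid, depth + 1)

        walk(root, None, 0)

    # -- queries -----------------------------------------------------------

    def __contains__(self, region_id: int) -> bool:
        return region_id in self._acronym

    def acronym(self, region_id: int) -> str:
        return self._acronym[region_id]

    def id_of(self, acronym: str) -> int:
        try:
            return self._id_of[acronym]
        except KeyError:
            raise AtlasError(f"unknown region acronym {acronym!r}") from None

    def parent(self, region_id: int) -> int | None:
        return self._parent[region_id]

    def children(self, region_id: int) -> list[int]:
        return self._children[region_id]

    def depth(self, region_id: int) -> int:
        return self._depth[region_id]

    def descendants(self, region_id: int) -> list[int]:
        """Subtree ids, inclusive, preorder."""
        out, stack = [], [region_id]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(reversed(self._children[cur]))
        return out

    def ancestor_at_depth(self, region_id: int, level: int) -> int:
        """Lift ``region_id`` to the ancestor at ``level``; identity if already
        at or above that depth."""
        cur = region_id
        while self._depth[cur] > level:
            cur = self._parent[cur]  # type: ignore[assignment]
        return cur

    def is_descendant(self, region_id: int, ancestor_id: int) -> bool:
        cur: int | None = region_id
        while cur is not None:
            if cur == ancestor_id:
                return True
            cur = self._parent[cur]
        return False

    def all_ids(self) -> list[int]:
        return list(self._acronym)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def build(nid: int) -> dict:
            return {
                "id": nid,
                "acronym": self._acronym[nid],
                "children": [build(c) for c in self._children[nid]],
            }

        return build(self.root_id)

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionHierarchy":
        with open(path) as fh:
            doc = json.load(fh)
        # accept either the bare tree or an Allen structure-graph envelope
        if "msg" in doc:
            doc = doc["msg"][0]
        return cls(doc)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class Atlas:
    """Annotation raster + hierarchy + fiber mask + midline.

    ``annotation[i, j, k]`` is the region id owning voxel (i, j, k); 0 marks
    voxels outside the brain.  ``fiber_mask`` flags white-matter corridors on
    the same grid.  The midline is a plane perpendicular to ``midline_axis``
    at world coordinate ``midline`` μm; points exactly on it count as right.
    """

    annotation: np.ndarray
    voxel_size: float
    origin: np.ndarray
    hierarchy: RegionHierarchy
    fiber_mask: np.ndarray
    midline_axis: int = 0
    midline: float | None = None

    def __post_init__(self) -> None:
        self.annotation = np.asarray(self.annotation, dtype=np.int32)
        self.fiber_mask = np.asarray(self.fiber_mask, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.annotation.shape != self.fiber_mask.shape:
            raise AtlasError("annotation and fiber_mask shapes differ")
        if self.voxel_size <= 0:
            raise AtlasError("voxel_size must be positive")
        present = np.unique(self.annotation)
        for rid in present:
            if rid != 0 and int(rid) not in self.hierarchy:
                raise AtlasError(f"annotation id {rid} missing from hierarchy")
        if self.midline is None:
            self.midline = float(
                self.origin[self.midline_axis]
                + self.annotation.shape[self.midline_axis] * self.voxel_size / 2.0
            )

    # -- coordinate mapping ------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.annotation.shape

    def world_to_index(self, xyz: Iterable[float]) -> tuple[int, int, int] | None:
        idx = np.floor((np.asarray(xyz, float) - self.origin) / self.voxel_size)
        if np.any(idx < 0) or np.any(idx >= self.shape):
            return None
        return tuple(int(v) for v in idx)

    def voxel_center(self, ijk: Iterable[int]) -> np.ndarray:
        return self.origin + (np.asarray(ijk, float) + 0.5) * self.voxel_size

    def in_brain(self, xyz: Iterable[float]) -> bool:
        idx = self.world_to_index(xyz)
        return idx is not None and self.annotation[idx] != 0

    def in_fiber_tract(self, xyz: Iterable[float]) -> bool:
        idx = self.world_to_index(xyz)
        return idx is not None and bool(self.fiber_mask[idx])

    # -- region queries ----------------------------------------------------

    def region_at(self, xyz: Iterable[float], level: int | str = "leaf") -> int | None:
        """Region id at ``xyz``, lifted to hierarchy depth ``level``.

        Returns None outside the raster or on unannotated (id 0) voxels.
        """
        idx = self.world_to_index(xyz)
        if idx is None:
            return None
        rid = int(self.annotation[idx])
        if rid == 0:
            return None
        if level == "leaf":
            return rid
        return self.hierarchy.ancestor_at_depth(rid, int(level))

    def acronym_at(self, xyz: Iterable[float], level: int | str = "leaf") -> str | None:
        rid = self.region_at(xyz, level)
        return None if rid is None else self.hierarchy.acronym(rid)

    def hemisphere_of(self, xyz: Iterable[float]) -> str:
        """'left' or 'right' of the midline plane; on-plane ties go right."""
        if self.world_to_index(xyz) is None:
            raise AtlasError(f"point {tuple(xyz)} outside the atlas raster")
        coord = float(np.asarray(xyz, float)[self.midline_axis])
        return "right" if coord >= self.midline else "left"

    def _resolve(self, region: int | str) -> int:
        return region if isinstance(region, int) else self.hierarchy.id_of(region)

    def region_voxels(self, region: int | str) -> np.ndarray:
        """(n, 3) voxel indices of the region subtree (descendants included)."""
        rid = self._resolve(region)
        ids = set(self.hierarchy.descendants(rid))
        mask = np.isin(self.annotation, list(ids))
        return np.argwhere(mask)

    def region_centroid(self, region: int | str,
                        hemisphere: str | None = None) -> np.ndarray:
        """Mean voxel-center position of the region, optionally one hemisphere."""
        vox = self.region_voxels(region)
        if vox.size == 0:
            raise AtlasError(f"region {region!r} has no voxels")
        centers = self.origin + (vox + 0.5) * self.voxel_size
        if hemisphere is not None:
            side = centers[:, self.midline_axis] >= self.midline
            keep = side if hemisphere == "right" else ~side
            if not keep.any():
                raise AtlasError(f"region {region!r} empty in {hemisphere} hemisphere")
            centers = centers[keep]
        return centers.mean(axis=0)

    def sample_point_in_region(
        self, region: int | str, rng: np.random.Generator | int,
        hemisphere: str | None = None,
    ) -> np.ndarray:
        """Uniform point inside the region subtree: uniform voxel, then
        uniform within the voxel cube.  Reproducible per seed.  With
        ``hemisphere`` the draw is restricted to voxels whose centers lie on
        that side of the midline."""
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        vox = self.region_voxels(region)
        if hemisphere is not None and vox.shape[0]:
            centers = self.origin[self.midline_axis] + (
                vox[:, self.midline_axis] + 0.5) * self.voxel_size
            side = centers >= self.midline
            vox = vox[side if hemisphere == "right" else ~side]
        if vox.shape[0] == 0:
            acro = region if isinstance(region, str) else self.hierarchy.acronym(
                self._resolve(region))
            raise AtlasError(f"region {acro!r} has no voxels to sample")
        pick = vox[rng.integers(vox.shape[0])]
        return self.origin + (pick + rng.random(3)) * self.voxel_size

    def border_distance(self, region_a: int | str, region_b: int | str) -> float:
        """Closest distance between region borders, μm.

        Measured between voxel centers minus one voxel size, so regions whose
        voxels touch (face, edge or corner gap of one step) report 0 and a
        k-voxel axis-aligned gap reports k·voxel_size.
        """
        va = self.region_voxels(region_a)
        vb = self.region_voxels(region_b)
        if va.shape[0] == 0 or vb.shape[0] == 0:
            raise AtlasError("border_distance on empty region")
        ca = (va + 0.5) * self.voxel_size
        cb = (vb + 0.5) * self.voxel_size
        tree = cKDTree(ca)
        d, _ = tree.query(cb, k=1)
        return max(0.0, float(d.min()) - self.voxel_size)

    # -- serialization -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write annotation.raw, fiber_mask.raw, header.json, hierarchy.json."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.annotation.astype("<i4").tofile(directory / "annotation.raw")
        self.fiber_mask.astype("<u1").tofile(directory / "fiber_mask.raw")
        header = {
            "shape": list(self.annotation.shape),
            "dtype": "<i4",
            "voxel_size_um": self.voxel_size,
            "origin_um": self.origin.tolist(),
            "midline_axis": self.midline_axis,
            "midline_um": self.midline,
        }
        with open(directory / "header.json", "w") as fh:
            json.dump(header, fh, indent=1)
        self.hierarchy.to_json(directory / "hierarchy.json")

    @classmethod
    def load(cls, directory: str | Path) -> "Atlas":
        directory = Path(directory)
        with open(directory / "header.json") as fh:
            header = json.load(fh)
        shape = tuple(header["shape"])
        ann = np.fromfile(directory / "annotation.raw", dtype="<i4").reshape(shape)
        fib = np.fromfile(directory / "fiber_mask.raw", dtype="<u1").reshape(shape)
        return cls(
            annotation=ann,
            voxel_size=float(header["voxel_size_um"]),
            origin=np.asarray(header["origin_um"], float),
            hierarchy=RegionHierarchy.from_json(directory / "hierarchy.json"),
            fiber_mask=fib.astype(bool),
            midline_axis=int(header["midline_axis"]),
            midline=float(header["midline_um"]),
        )


# ---------------------------------------------------------------------------
# Toy atlas builder
# ---------------------------------------------------------------------------

def build_toy_atlas(spec: Mapping, rng: np.random.Generator | int | None = None) -> Atlas:
    """Build a deterministic toy atlas from a box-list specification.

    ``spec`` keys (YAML friendly):

    - ``shape``: raster shape in voxels ``[nx, ny, nz]``
    - ``voxel_size``: μm (isotropic, default 100)
    - ``origin``: world μm of voxel (0,0,0) corner (default 0)
    - ``midline_axis``: axis index of the left/right split (default 0)
    - ``mirror``: if true, regions are specified in the left half and
      mirrored across the midline with the same region id
    - ``regions``: list of ``{acronym, box: [[lo...],[hi...]], parent,
      layers}``; boxes are half-open voxel index ranges.  ``layers: k``
      splits the box along the last axis into k leaf children
      ``<acronym>1..k``.  ``parent`` names another listed region or the root.
    - ``fiber_corridors``: list of ``[acronym_a, acronym_b]``; straight
      corridors (1-voxel radius) between per-hemisphere region centroids are
      marked in the fiber mask.
    - ``background``: optional acronym; every voxel not covered by a region
      box is annotated with this region (child of the root), so the whole
      raster is in-brain and inter-region cable can be routed anywhere.
    - ``root_acronym``: default ``"root"``.

    Overlapping region boxes raise :class:`AtlasError`.  The result is
    mirror-symmetric when ``mirror`` is set, and independent of ``rng``
    (accepted for interface uniformity only).
    """
    shape = tuple(int(v) for v in spec["shape"])
    voxel_size = float(spec.get("voxel_size", 100.0))
    origin = np.asarray(spec.get("origin", [0.0, 0.0, 0.0]), float)
    maxis = int(spec.get("midline_axis", 0))
    mirror = bool(spec.get("mirror", False))
    root_acro = spec.get("root_acronym", "root")

    # assign ids: root=1, then listed regions (and their layer children)
    next_id = 1
    nodes: dict[str, dict] = {root_acro: {"id": next_id, "acronym": root_acro,
                                          "children": []}}
    annotation = np.zeros(shape, dtype=np.int32)
    fiber = np.zeros(shape, dtype=bool)

    def paint(box_lo, box_hi, rid: int) -> None:
        sl = tuple(slice(int(l), int(h)) for l, h in zip(box_lo, box_hi))
        if np.any(annotation[sl] != 0):
            raise AtlasError("overlapping region boxes in toy-atlas spec")
        annotation[sl] = rid

    def mirrored_slices(box_lo, box_hi):
        lo, hi = list(box_lo), list(box_hi)
        n = shape[maxis]
        lo2, hi2 = lo.copy(), hi.copy()
        lo2[maxis], hi2[maxis] = n - hi[maxis], n - lo[maxis]
        return lo2, hi2

    for reg in spec["regions"]:
        acro = reg["acronym"]
        if acro in nodes:
            raise AtlasError(f"duplicate acronym {acro!r}")
        parent = reg.get("parent", root_acro)
        if parent not in nodes:
            raise AtlasError(f"parent {parent!r} of {acro!r} not defined before use")
        next_id += 1
        node = {"id": next_id, "acronym": acro, "children": []}
        nodes[acro] = node
        nodes[parent]["children"].append(node)
        box = reg.get("box")
        layers = int(reg.get("layers", 0))
        if box is None:
            continue  # pure grouping node
        lo, hi = box
        if layers >= 2:
            # split along the last axis into equal-depth leaf layers
            axis = len(shape) - 1
            edges = np.linspace(lo[axis], hi[axis], layers + 1).astype(int)
            for li in range(layers):
                next_id += 1
                child = {"id": next_id, "acronym": f"{acro}{li + 1}", "children": []}
                nodes[child["acronym"]] = child
                node["children"].append(child)
                llo, lhi = list(lo), list(hi)
                llo[axis], lhi[axis] = int(edges[li]), int(edges[li + 1])
                paint(llo, lhi, child["id"])
                if mirror:
                    mlo, mhi = mirrored_slices(llo, lhi)
                    paint(mlo, mhi, child["id"])
        else:
            paint(lo, hi, node["id"])
            if mirror:
                mlo, mhi = mirrored_slices(lo, hi)
                paint(mlo, mhi, node["id"])

    bg_acro = spec.get("background")
    if bg_acro is not None:
        if bg_acro in nodes:
            raise AtlasError(f"duplicate acronym {bg_acro!r}")
        next_id += 1
        node = {"id": next_id, "acronym": bg_acro, "children": []}
        nodes[bg_acro] = node
        nodes[root_acro]["children"].append(node)
        annotation[annotation == 0] = next_id

    hierarchy = RegionHierarchy(nodes[root_acro])
    atlas = Atlas(
        annotation=annotation,
        voxel_size=voxel_size,
        origin=origin,
        hierarchy=hierarchy,
        fiber_mask=fiber,
        midline_axis=maxis,
    )

    # fiber corridors between per-hemisphere centroids
    for pair in spec.get("fiber_corridors", []):
        a, b = pair
        for hemi in (["left", "right"] if mirror else [None]):
            try:
                ca = atlas.region_centroid(a, hemisphere=hemi)
                cb = atlas.region_centroid(b, hemisphere=hemi)
            except AtlasError:
                continue
            _mark_corridor(atlas, ca, cb)
    return atlas


def _mark_corridor(atlas: Atlas, a: np.ndarray, b: np.ndarray,
                   radius_vox: float = 1.0) -> None:
    """Mark voxels within ``radius_vox`` voxels of segment a-b in the mask."""
    length = float(np.linalg.norm(b - a))
    n = max(2, int(length / (atlas.voxel_size / 2)) + 1)
    pts = a[None, :] + np.linspace(0, 1, n)[:, None] * (b - a)[None, :]
    r = int(np.ceil(radius_vox))
    for p in pts:
        idx = atlas.world_to_index(p)
        if idx is None:
            continue
        lo = [max(0, idx[d] - r) for d in range(3)]
        hi = [min(atlas.shape[d], idx[d] + r + 1) for d in range(3)]
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        atlas.fiber_mask[sl] = True
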