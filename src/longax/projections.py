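"""Per-axon inter-regional projection features.

For an axon *a* with soma in source region *s_a*, the projection pattern is
described by two vectors over a region vocabulary *B*:

- ``t_a(b)``: number of axon terminal points inside region *b*;
- ``l_a(b)``: axonal path length inside region *b* (μm), restricted by
  default to *termination* regions (those with ``t_a(b) > 0``) — cable
  merely passing through a region is discarded.

Hemispheres are encoded in the vocabulary itself: a terminal landing in
region X on the opposite side of the midline from the soma contributes to
``"X_contra"``, an ipsilateral one to ``"X"``.  Either vector can serve as
the clustering feature; on real axons the two are proportional
(one tuft of roughly fixed cable per terminal), which makes them
interchangeable for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from longax.atlas import Atlas
from longax.morpho import Morphology, SectionType

__all__ = [
    "ProjectionFeatures",
    "ProjectionMatrix",
    "ProjectionError",
    "compute_projection_features",
    "stack_population",
]

CONTRA_SUFFIX = "_contra"


class ProjectionError(ValueError):
    """Raised when an axon cannot enter the projection analysis
    (e.g. soma outside the annotated volume)."""


@dataclass
class ProjectionFeatures:
    """Projection pattern of one axon over its termination regions."""

    neuron_id: str
    source_region: str
    region_vocab: list[str]
    terminals: np.ndarray  # int, per vocab entry
    lengths: np.ndarray  # μm, per vocab entry
    soma_hemisphere: str = "right"

    def terminal_count(self, region: str) -> int:
        try:
            return int(self.terminals[self.region_vocab.index(region)])
        except ValueError:
            return 0

    def length_in(self, region: str) -> float:
        try:
            return float(self.lengths[self.region_vocab.index(region)])
        except ValueError:
            return 0.0


def base_acronym(vocab_entry: str) -> str:
    """Strip the contralateral suffix from a vocabulary entry."""
    if vocab_entry.endswith(CONTRA_SUFFIX):
        return vocab_entry[: -len(CONTRA_SUFFIX)]
    return vocab_entry


def is_contra(vocab_entry: str) -> bool:
    return vocab_entry.endswith(CONTRA_SUFFIX)


def compute_projection_features(
    m: Morphology,
    atlas: Atlas,
    level: int | str = "leaf",
    include_passthrough: bool = False,
    include_soma_region: bool = True,
) -> ProjectionFeatures:
    """Compute ``t_a`` and ``l_a`` for one axon.

    Terminal counting maps each axon leaf to its region at the requested
    hierarchy ``level``.  Segment length is attributed to the region of the
    segment midpoint (no splitting at voxel boundaries; the error is bounded
    by the voxel size).  Unless ``include_passthrough``, lengths are kept
    only for termination regions.  ``include_soma_region=False`` drops the
    soma's own (ipsilateral) region from the vocabulary.

    Raises
    ------
    ProjectionError
        If the soma lies outside the annotated volume or the morphology has
        no axon.
    """
    soma = m.soma_center
    src_id = atlas.region_at(soma, level)
    if src_id is None:
        raise ProjectionError(
            f"{m.neuron_id}: soma at {tuple(soma)} outside the annotated volume"
        )
    source = atlas.hierarchy.acronym(src_id)
    soma_hemi = atlas.hemisphere_of(soma)
    axon_nodes = m.neurite_node_ids(SectionType.axon)
    if not axon_nodes:
        raise ProjectionError(f"{m.neuron_id}: no axon")

    def vocab_key(xyz) -> str | None:
        rid = atlas.region_at(xyz, level)
        if rid is None:
            return None
        acro = atlas.hierarchy.acronym(rid)
        hemi = atlas.hemisphere_of(xyz)
        return acro if hemi == soma_hemi else acro + CONTRA_SUFFIX

    t: dict[str, int] = {}
    for leaf in m.leaves(SectionType.axon):
        key = vocab_key(m.node(leaf).xyz)
        if key is None:
            continue
        t[key] = t.get(key, 0) + 1

    l: dict[str, float] = {}
    for pid, cid in m.segments(SectionType.axon):
        mid = 0.5 * (m.node(pid).xyz + m.node(cid).xyz)
        idx = atlas.world_to_index(mid)
        if idx is None:
            continue
        key = vocab_key(mid)
        if key is None:
            continue
        l[key] = l.get(key, 0.0) + m.segment_length(pid, cid)

    if not include_soma_region:
        t.pop(source, None)
        l.pop(source, None)

    if include_passthrough:
        vocab = sorted(set(t) | set(l))
    else:
        vocab = sorted(t)
    terminals = np.array([t.get(b, 0) for b in vocab], dtype=int)
    lengths = np.array([l.get(b, 0.0) for b in vocab], dtype=float)
    return ProjectionFeatures(
        neuron_id=m.neuron_id,
        source_region=source,
        region_vocab=vocab,
        terminals=terminals,
        lengths=lengths,
        soma_hemisphere=soma_hemi,
    )


@dataclass
class ProjectionMatrix:
    """A population of projection features on a shared region vocabulary.

    In the conventional heat-map display (one axon per column, one region
    per row) the columns correspond to rows here: ``terminals[i]`` and
    ``lengths[i]`` belong to ``neuron_ids[i]``.
    """

    source_region: str
    neuron_ids: list[str]
    region_vocab: list[str]
    terminals: np.ndarray  # (n, B) int
    lengths: np.ndarray  # (n, B) float

    @property
    def n_axons(self) -> int:
        return len(self.neuron_ids)

    def feature(self, which: str) -> np.ndarray:
        """'terminals' or 'lengths' matrix, float."""
        if which == "terminals":
            return self.terminals.astype(float)
        if which == "lengths":
            return self.lengths
        raise ValueError(f"unknown feature {which!r}")

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Wide CSV, one row per axon, with a JSON vocabulary sidecar."""
        import json
        from pathlib import Path

        df = pd.DataFrame(
            {
                "neuron_id": self.neuron_ids,
                "source_region": self.source_region,
                **{f"t:{b}": self.terminals[:, j] for j, b in enumerate(self.region_vocab)},
                **{f"l:{b}": self.lengths[:, j] for j, b in enumerate(self.region_vocab)},
            }
        )
        path = Path(path)
        df.to_csv(path, index=False)
        with open(path.with_suffix(".vocab.json"), "w") as fh:
            json.dump(
                {"source_region": self.source_region, "region_vocab": self.region_vocab},
                fh,
                indent=1,
            )

    @classmethod
    def from_csv(cls, path) -> "ProjectionMatrix":
        df = pd.read_csv(path)
        vocab = [c[2:] for c in df.columns if c.startswith("t:")]
        return cls(
            source_region=str(df["source_region"].iloc[0]),
            neuron_ids=[str(v) for v in df["neuron_id"]],
            region_vocab=vocab,
            terminals=df[[f"t:{b}" for b in vocab]].to_numpy(dtype=int),
            lengths=df[[f"l:{b}" for b in vocab]].to_numpy(dtype=float),
        )


def stack_population(
    features: list[ProjectionFeatures], source: str | None = None
) -> ProjectionMatrix:
    """Stack per-axon features of one source region on the union vocabulary.

    The vocabulary is the sorted union of regions observed across the
    population; entries an axon does not target are 0.  Mixing source
    regions is an error (each source is clustered separately).
    """
    if not features:
        raise ProjectionError("empty population")
    sources = {f.source_region for f in features}
    if source is None:
        if len(sources) > 1:
            raise ProjectionError(f"mixed source regions: {sorted(sources)}")
        source = next(iter(sources))
    elif sources != {source}:
        raise ProjectionError(
            f"features from sources {sorted(sources)}, expected {source!r}"
        )
    vocab = sorted(set().union(*(f.region_vocab for f in features)))
    col = {b: j for j, b in enumerate(vocab)}
    n = len(features)
    T = np.zeros((n, len(vocab)), dtype=int)
    L = np.zeros((n, len(vocab)), dtype=float)
    for i, f in enumerate(features):
        for b, t, length in zip(f.region_vocab, f.terminals, f.lengths):
            T[i, col[b]] = t
            L[i, col[b]] = length
    return ProjectionMatrix(
        source_region=source,
        neuron_ids=[f.neuron_id for f in features],
        region_vocab=vocab,
        terminals=T,
        lengths=L,
    )
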