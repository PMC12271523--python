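import numpy as np
import pytest

from longax.connectome import (
    Touch,
    aggregate,
    connections_vs_axon_length,
    detect_touches,
    filter_interbouton,
    prune_to_density,
    segment_segment_distance,
    _axon_segments,
    _dendrite_segments,
)
from longax.morpho import Morphology, MorphNode, SectionType


def line_neuron(neuron_id, start, end, stype=SectionType.axon, n_seg=1,
                radius=0.5):
    start, end = np.asarray(start, float), np.asarray(end, float)
    nodes = [MorphNode(1, None, start, 1.0, SectionType.soma)]
    for i in range(1, n_seg + 1):
        nodes.append(
            MorphNode(i + 1, i, start + (end - start) * i / n_seg, radius, stype)
        )
    return Morphology(nodes, neuron_id=neuron_id)


class TestSegmentDistance:
    def test_parallel_segments(self):
        d, _, _ = segment_segment_distance((0, 0, 0), (10, 0, 0),
                                           (0, 1, 0), (10, 1, 0))
        assert d == pytest.approx(1.0)

    def test_crossing_segments(self):
        d, _, _ = segment_segment_distance((0, 0, 0), (10, 0, 0),
                                           (5, -5, 2), (5, 5, 2))
        assert d == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_sampling_lower_bound(self, seed):
        rng = np.random.default_rng(seed)
        p0, p1, q0, q1 = rng.normal(size=(4, 3)) * 10
        d, _, _ = segment_segment_distance(p0, p1, q0, q1)
        ts = np.linspace(0, 1, 200)
        pts_p = p0 + ts[:, None] * (p1 - p0)
        pts_q = q0 + ts[:, None] * (q1 - q0)
        sampled = np.min(
            np.linalg.norm(pts_p[:, None, :] - pts_q[None, :, :], axis=2)
        )
        assert d <= sampled + 1e-9
        assert d == pytest.approx(sampled, abs=0.1)


class TestDetectTouches:
    def test_parallel_within_threshold_is_one_touch(self):
        pre = line_neuron("a", (0, 0, 0), (10, 0, 0))
        post = line_neuron("b", (0, 1, 0), (10, 1, 0),
                           stype=SectionType.basal_dendrite)
        touches = detect_touches([pre], [post], touch_distance=2.0)
        assert len(touches) == 1
        assert touches[0].pre == "a" and touches[0].post == "b"

    def test_same_neuron_never_touches_itself(self):
        m_nodes = [
            MorphNode(1, None, (0, 0, 0), 1.0, SectionType.soma),
            MorphNode(2, 1, (10, 0, 0), 0.5, SectionType.axon),
            MorphNode(3, 1, (10, 0.5, 0), 0.5, SectionType.basal_dendrite),
        ]
        m = Morphology(m_nodes, neuron_id="self")
        assert detect_touches([m], [m], touch_distance=5.0) == []

    def test_default_threshold_uses_radii_plus_margin(self):
        pre = line_neuron("a", (0, 0, 0), (10, 0, 0), radius=1.0)
        post = line_neuron("b", (0, 2.5, 0), (10, 2.5, 0),
                           stype=SectionType.basal_dendrite, radius=1.0)
        # gap 2.5 <= r1 + r2 + 1 = 3 -> touch; with margin 0 -> none
        assert len(detect_touches([pre], [post])) == 1
        assert detect_touches([pre], [post], touch_margin=0.0) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_spatial_hash_matches_allpairs_bruteforce(self, atlas, seed):
        from longax.fixtures import (demo_population_spec, generate_population,
                                     generate_scene)

        spec = demo_population_spec()
        spec.n_axons = 5
        pre, _, _ = generate_population(spec, atlas, seed=seed)
        post = generate_scene(10, 6000.0, atlas, seed=seed + 50)
        fast = detect_touches(pre, post, touch_distance=40.0)
        pre_segs = [s for m in pre for s in _axon_segments(m)]
        post_segs = [s for m in post for s in _dendrite_segments(m)]
        brute = []
        for s in pre_segs:
            for t in post_segs:
                if s.neuron == t.neuron:
                    continue
                d, _, _ = segment_segment_distance(s.p0, s.p1, t.p0, t.p1)
                if d <= 40.0:
                    brute.append((s.neuron, t.neuron, s.branch,
                                  round(s.arc_start, 6)))
        assert len(fast) == len(brute)
        fast_keys = sorted((t.pre, t.post, t.pre_branch) for t in fast)
        brute_keys = sorted((b[0], b[1], b[2]) for b in brute)
        assert fast_keys == brute_keys


def make_touch(pre, arclen, post="p", branch=0):
    return Touch(pre=pre, post=post, xyz=(0.0, 0.0, 0.0), pre_branch=branch,
                 pre_arclen=arclen, distance=0.5)


class TestInterbouton:
    def test_close_pair_keeps_first(self):
        kept = filter_interbouton([make_touch("a", 0.0), make_touch("a", 3.0)],
                                  min_interval=5.0)
        assert [t.pre_arclen for t in kept] == [0.0]

    def test_zero_interval_keeps_all(self):
        touches = [make_touch("a", x) for x in (0.0, 1.0, 2.0)]
        assert filter_interbouton(touches, 0.0) == touches

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_matches_bruteforce_maximal_spacing(self, seed):
        rng = np.random.default_rng(seed)
        arclens = np.sort(rng.uniform(0, 100, 30))
        touches = [make_touch("a", float(x)) for x in arclens]
        kept = filter_interbouton(touches, 7.0)
        # independent greedy re-implementation
        expect, last = [], -np.inf
        for x in arclens:
            if x - last >= 7.0:
                expect.append(x)
                last = x
        assert [t.pre_arclen for t in kept] == pytest.approx(expect)

    def test_branches_filtered_independently(self):
        touches = [make_touch("a", 0.0, branch=0), make_touch("a", 1.0, branch=1)]
        assert len(filter_interbouton(touches, 5.0)) == 2


class TestPruning:
    def post_neuron(self, length=100.0):
        return line_neuron("p", (0, 0, 0), (length, 0, 0),
                           stype=SectionType.basal_dendrite, n_seg=2)

    def test_huge_density_keeps_all(self):
        touches = [make_touch("a", float(i)) for i in range(10)]
        syn = prune_to_density(touches, 1e6, [self.post_neuron()], rng=0)
        assert len(syn) == 10

    def test_zero_density_keeps_none(self):
        touches = [make_touch("a", float(i)) for i in range(10)]
        assert prune_to_density(touches, 0.0, [self.post_neuron()], rng=0) == []

    @pytest.mark.parametrize("density", [0.01, 0.05, 0.2])
    def test_kept_count_is_min_of_candidates_and_budget(self, density):
        touches = [make_touch("a", float(i)) for i in range(17)]
        post = self.post_neuron(length=100.0)
        syn = prune_to_density(touches, density, [post], rng=1)
        assert len(syn) == min(17, int(np.floor(density * 100.0)))

    def test_reproducible_per_seed(self):
        touches = [make_touch("a", float(i)) for i in range(30)]
        s1 = prune_to_density(touches, 0.1, [self.post_neuron()], rng=9)
        s2 = prune_to_density(touches, 0.1, [self.post_neuron()], rng=9)
        assert s1 == s2


class TestAggregate:
    def test_single_synapse_unit_projectome(self, atlas):
        from longax.connectome import Synapse

        xyz = tuple(atlas.region_centroid("RA", hemisphere="right"))
        conn = aggregate([Synapse("a", "b", xyz, 0.0)], atlas,
                         pre_region={"a": "SRC"})
        assert conn.projectome == {("SRC", "RA"): 1}
        assert conn.adjacency == {("a", "b"): 1}
        assert conn.out_degree == {"a": 1}

    def test_totals_conserved_and_outdegree_matches_recount(self, atlas):
        from longax.fixtures import (demo_population_spec, generate_population,
                                     generate_scene)

        spec = demo_population_spec()
        spec.n_axons = 8
        pre, _, _ = generate_population(spec, atlas, seed=2)
        post = generate_scene(20, 8000.0, atlas, seed=3)
        touches = filter_interbouton(
            detect_touches(pre, post, touch_distance=40.0), 10.0
        )
        syn = prune_to_density(touches, 0.05, post, rng=4)
        conn = aggregate(syn, atlas,
                         pre_region={m.neuron_id: "SRC" for m in pre})
        assert sum(conn.adjacency.values()) == len(syn)
        located = sum(1 for s in conn.synapses if s.post_region is not None)
        assert sum(conn.projectome.values()) == located
        assert sum(conn.region_counts.values()) == located
        # brute recount of out-degree
        for pre_id in {s.pre for s in syn}:
            partners = {s.post for s in syn if s.pre == pre_id}
            assert conn.out_degree[pre_id] == len(partners)

    def test_conservation_through_pipeline(self, atlas):
        from longax.fixtures import (demo_population_spec, generate_population,
                                     generate_scene)

        spec = demo_population_spec()
        spec.n_axons = 5
        pre, _, _ = generate_population(spec, atlas, seed=6)
        post = generate_scene(10, 8000.0, atlas, seed=7)
        raw = detect_touches(pre, post, touch_distance=40.0)
        filtered = filter_interbouton(raw, 10.0)
        syn = prune_to_density(filtered, 0.02, post, rng=8)
        assert set(filtered) <= set(raw)
        syn_keys = {(s.pre, s.post, s.xyz) for s in syn}
        filt_keys = {(t.pre, t.post, t.xyz) for t in filtered}
        assert syn_keys <= filt_keys


class TestLocalVsLongRange:
    def test_local_axons_connect_only_at_zero_border_distance(self, atlas):
        """Axons confined to the source region connect only to regions at
        border distance 0, while long-range axons reach distant ones."""
        from longax.connectome import connections_vs_border_distance
        from longax.fixtures import (ClusterSpec, PopulationSpec,
                                     demo_population_spec,
                                     generate_population, generate_scene)

        local_spec = PopulationSpec(
            source_region="SRC", n_axons=6,
            clusters=[ClusterSpec(weight=1.0, targets={"SRC": 3})],
        )
        local, _, _ = generate_population(local_spec, atlas, seed=1)
        lra_spec = demo_population_spec()
        lra_spec.n_axons = 6
        lras, _, _ = generate_population(lra_spec, atlas, seed=1)
        post = generate_scene(40, 8000.0, atlas, seed=2)

        def table(pre):
            touches = detect_touches(pre, post, touch_distance=40.0)
            syn = prune_to_density(filter_interbouton(touches, 10.0), 0.1,
                                   post, rng=3)
            conn = aggregate(syn, atlas)
            return connections_vs_border_distance(conn, atlas, "SRC")

        t_local = table(local)
        t_lra = table(lras)
        far_local = t_local[t_local.border_distance_um > 0]
        assert far_local.connections.sum() == 0
        far_lra = t_lra[t_lra.border_distance_um > 200]
        assert far_lra.connections.sum() > 0
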