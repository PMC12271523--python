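import networkx as nx
import numpy as np
import pytest
from scipy.spatial import cKDTree

from longax.atlas import build_toy_atlas
from longax.morpho import SectionType, write_swc
from longax.synthesis import (
    SteinerGraph,
    SynthesisConfig,
    SynthesisTask,
    assign_cluster,
    build_graph,
    build_lattice,
    build_source_inputs,
    choose_targets,
    grow_tuft,
    postprocess_trunk,
    steiner_tree,
    steiner_tree_exact_weight,
    synthesize_population,
    tree_weight,
)
from longax.gmm import GMMModel


def random_geometric_graph(rng, n, k_terminals):
    pts = rng.random((n, 3)) * 100
    g = nx.Graph()
    for i in range(n):
        g.add_node(i, xyz=pts[i])
    kd = cKDTree(pts)
    for i in range(n):
        _, js = kd.query(pts[i], k=5)
        for j in js[1:]:
            w = float(np.linalg.norm(pts[i] - pts[int(j)]))
            g.add_edge(i, int(j), weight=w, length=w)
    if not nx.is_connected(g):
        comps = list(nx.connected_components(g))
        for a, b in zip(comps, comps[1:]):
            i, j = next(iter(a)), next(iter(b))
            w = float(np.linalg.norm(pts[i] - pts[j]))
            g.add_edge(i, j, weight=w, length=w)
    terms = [int(t) for t in rng.choice(n, size=k_terminals + 1, replace=False)]
    return SteinerGraph(graph=g, source=terms[0], targets=terms[1:])


class TestAssignCluster:
    def test_degenerate_weight_always_picked(self):
        m = GMMModel("s", [], 1, [1.0], [[0.0]], [1.0])
        assert all(assign_cluster(m, rng=i) == 0 for i in range(5))

    def test_frequencies_match_weights(self):
        m = GMMModel("s", [], 2, [0.5, 0.5], [[0.0], [5.0]], [1.0, 1.0])
        rng = np.random.default_rng(0)
        draws = np.array([assign_cluster(m, rng) for _ in range(10_000)])
        sigma = np.sqrt(10_000 * 0.25)
        assert abs((draws == 0).sum() - 5000) <= 3 * sigma

    def test_fixed_seed_reproducible(self):
        m = GMMModel("s", [], 3, [0.3, 0.3, 0.4], np.zeros((3, 1)), [1, 1, 1])
        seq1 = [assign_cluster(m, np.random.default_rng(7)) for _ in range(5)]
        seq2 = [assign_cluster(m, np.random.default_rng(7)) for _ in range(5)]
        assert seq1 == seq2


class TestChooseTargets:
    @pytest.fixture()
    def inputs(self, atlas, demo_population):
        from longax.gmm import select_model
        from longax.projections import compute_projection_features, stack_population
        from longax.tufts import extract_tufts

        morphs, _, _ = demo_population
        mat = stack_population(
            [compute_projection_features(m, atlas) for m in morphs]
        )
        model = select_model(mat.feature("lengths"), imposed_c=5, rng=0,
                             region_vocab=mat.region_vocab)
        tufts = []
        for m in morphs:
            _, tt = extract_tufts(m, 300.0, 300.0, atlas=atlas)
            tufts.extend(tt)
        return build_source_inputs(mat, model, tufts)

    def test_always_targeted_region_always_selected(self, atlas, inputs):
        cluster = next(
            c for c, probs in inputs.region_prob.items()
            if any(p == 1.0 for p in probs.values())
        )
        region = next(b for b, p in inputs.region_prob[cluster].items() if p == 1.0)
        rng = np.random.default_rng(1)
        for _ in range(10):
            targets = choose_targets(cluster, inputs, atlas, "right", rng)
            assert any(r == region for r, _ in targets)

    def test_zero_sd_group_gives_exact_count(self, atlas, inputs):
        for (c, region), group in inputs.tuft_groups.items():
            if group.sd_count == 0:
                rng = np.random.default_rng(2)
                targets = choose_targets(c, inputs, atlas, "right", rng)
                counts = sum(1 for r, _ in targets if r == region)
                if counts:
                    assert counts == int(round(group.mean_count))
                break

    def test_selection_frequency_matches_member_fraction(self, atlas, inputs):
        cluster = 0
        probs = inputs.region_prob[cluster]
        rng = np.random.default_rng(3)
        n = 2000
        hits = {b: 0 for b in probs}
        for _ in range(n):
            regions = {r for r, _ in choose_targets(cluster, inputs, atlas,
                                                    "right", rng)}
            for b in regions:
                hits[b] = hits.get(b, 0) + 1
        for b, p in probs.items():
            if p in (0.0, 1.0):
                assert hits[b] == (n if p == 1.0 else 0)
            else:
                sigma = np.sqrt(n * p * (1 - p))
                # conditioning on non-empty selections biases upward a bit
                assert abs(hits[b] - n * p) <= 3 * sigma + 0.05 * n


class TestRoutingGraph:
    def test_unit_discount_weights_equal_lengths(self, atlas):
        lat = build_lattice(atlas, step_vox=4, fiber_discount=1.0)
        for _, _, length, weight in lat.edges[:200]:
            assert weight == length

    def test_weights_positive_and_symmetric(self, atlas):
        rng = np.random.default_rng(4)
        src = atlas.sample_point_in_region("SRC", rng)
        tgt = atlas.sample_point_in_region("RC", rng)
        sg = build_graph(atlas, src, [tgt], lattice_step_vox=4)
        for u, v, d in sg.graph.edges(data=True):
            assert d["weight"] > 0
            assert sg.graph.edges[v, u]["weight"] == d["weight"]

    def test_fiber_corridor_attracts_weighted_shortest_path(self):
        # a straight fiber corridor at the bottom of a tall box: with a
        # strong discount the weighted path dives into the corridor even
        # though the Euclidean straight line is shorter
        atlas = build_toy_atlas(
            {"shape": [30, 5, 10], "voxel_size": 100.0,
             "regions": [{"acronym": "A", "box": [[0, 0, 0], [30, 5, 10]]}]}
        )
        atlas.fiber_mask[:, :, 0:2] = True
        src = np.array([150.0, 250.0, 850.0])
        tgt = np.array([2850.0, 250.0, 850.0])
        sg = build_graph(atlas, src, [tgt], lattice_step_vox=1,
                         fiber_discount=0.3)
        tree = steiner_tree(sg, restarts=False)
        zs = [sg.graph.nodes[v]["xyz"][2] for v in tree.nodes]
        assert min(zs) < 300.0  # the path dove into the corridor

    def test_disconnected_target_reported(self, atlas):
        sg_atlas = build_toy_atlas(
            {"shape": [7, 3, 3], "voxel_size": 100.0,
             "regions": [
                 {"acronym": "A", "box": [[0, 0, 0], [3, 3, 3]]},
                 {"acronym": "B", "box": [[4, 0, 0], [7, 3, 3]]},
             ]}
        )  # gap at x index 3: A and B are disconnected islands
        with pytest.raises(ValueError, match="disconnected"):
            build_graph(sg_atlas, np.array([150.0, 150.0, 150.0]),
                        [np.array([650.0, 150.0, 150.0])], lattice_step_vox=1)


class TestSteiner:
    def test_single_target_reduces_to_shortest_path(self):
        rng = np.random.default_rng(5)
        sg = random_geometric_graph(rng, 40, 1)
        tree = steiner_tree(sg)
        expect = nx.shortest_path_length(sg.graph, sg.source, sg.targets[0],
                                         weight="weight")
        assert tree_weight(tree) == pytest.approx(expect)

    @pytest.mark.parametrize("seed", range(15))
    def test_within_factor_two_of_exact_optimum(self, seed):
        rng = np.random.default_rng(seed)
        sg = random_geometric_graph(rng, int(rng.integers(20, 61)),
                                    int(rng.integers(2, 7)))
        tree = steiner_tree(sg)
        assert nx.is_tree(tree)
        assert set([sg.source] + sg.targets) <= set(tree.nodes)
        opt = steiner_tree_exact_weight(sg)
        w = tree_weight(tree)
        assert opt - 1e-6 <= w <= 2 * opt + 1e-6


class TestTrunkPostprocessing:
    def build_tree(self, atlas, rng):
        src = atlas.sample_point_in_region("SRC", rng)
        tgts = [atlas.sample_point_in_region(r, rng) for r in ("RA", "RC")]
        sg = build_graph(atlas, src, tgts, lattice_step_vox=2)
        return sg, steiner_tree(sg)

    def test_zero_noise_follows_tree_polyline(self, atlas):
        rng = np.random.default_rng(6)
        sg, tree = self.build_tree(atlas, rng)
        trunk = postprocess_trunk(sg, tree, step=50.0, noise=0.0, history=0.0,
                                  rng=rng)
        # every emitted point lies on some tree edge (distance ~ 0)
        pts = np.array([n.xyz for n in trunk.morphology.nodes])
        segs = [
            (tree.nodes[u]["xyz"], tree.nodes[v]["xyz"]) for u, v in tree.edges
        ]
        from longax.connectome import segment_segment_distance

        for p in pts:
            d = min(segment_segment_distance(p, p, a, b)[0] for a, b in segs)
            assert d < 1.0

    def test_endpoints_and_branch_points_exact(self, atlas):
        rng = np.random.default_rng(7)
        sg, tree = self.build_tree(atlas, rng)
        trunk = postprocess_trunk(sg, tree, step=50.0, noise=0.2, history=0.3,
                                  rng=rng)
        pts = {tuple(np.round(n.xyz, 6)) for n in trunk.morphology.nodes}
        for key in [sg.source] + sg.targets:
            assert tuple(np.round(tree.nodes[key]["xyz"], 6)) in pts
        for v in tree.nodes:
            if tree.degree[v] >= 3:
                assert tuple(np.round(tree.nodes[v]["xyz"], 6)) in pts

    def test_tortuosity_increases_with_noise(self, atlas):
        # straight two-point fixture: source and one far target
        rng = np.random.default_rng(8)
        src = np.array([200.0, 1000.0, 800.0])
        tgt = np.array([3700.0, 1000.0, 800.0])
        sg = build_graph(atlas, src, [tgt], lattice_step_vox=2)
        tree = steiner_tree(sg)

        def mean_tortuosity(noise):
            vals = []
            for s in range(50):
                trunk = postprocess_trunk(sg, tree, step=50.0, noise=noise,
                                          history=0.0,
                                          rng=np.random.default_rng(1000 + s))
                m = trunk.morphology
                path = m.total_length(SectionType.axon)
                vals.append(path / np.linalg.norm(tgt - src))
            return float(np.mean(vals))

        t_small, t_big = mean_tortuosity(0.05), mean_tortuosity(0.3)
        assert t_small >= 1.0 - 1e-9
        assert t_big > t_small


class TestGrowTuft:
    def test_single_bar_gives_unbranched_path_of_length(self):
        m = grow_tuft([(0.0, 200.0)], np.zeros(3), [1.0, 0, 0], step=20.0,
                      noise=0.2, rng=0)
        leaves = m.leaves(SectionType.axon)
        assert len(leaves) == 1
        assert m.total_length(SectionType.axon) == pytest.approx(200.0, abs=20.0)

    def test_y_barcode_bifurcates_near_birth(self):
        m = grow_tuft([(0.0, 30.0), (10.0, 30.0)], np.zeros(3), [0, 0, 1.0],
                      step=5.0, noise=0.1, rng=1)
        assert len(m.leaves(SectionType.axon)) == 2
        pdist = m.path_distances(SectionType.axon)
        branch = [n.id for n in m.nodes
                  if len([c for c in m.children(n.id)
                          if m.node(c).section_type == SectionType.axon]) >= 2
                  and n.section_type == SectionType.axon]
        assert branch
        assert min(abs(pdist[b] - 10.0) for b in branch) <= 5.0 + 1e-9

    @pytest.mark.parametrize("seed", range(6))
    def test_random_barcode_leaf_count_and_depths(self, seed):
        rng = np.random.default_rng(400 + seed)
        n_bars = int(rng.integers(2, 7))
        deaths = np.sort(rng.uniform(50, 300, n_bars))[::-1]
        bars = [(0.0, float(deaths[0]))]
        for d in deaths[1:]:
            bars.append((float(rng.uniform(0, d * 0.8)), float(d)))
        step = 20.0
        m = grow_tuft(bars, np.zeros(3), [1.0, 0, 0], step=step, noise=0.3,
                      rng=rng)
        assert len(m.leaves(SectionType.axon)) == len(bars)
        pdist = m.path_distances(SectionType.axon)
        max_term = max(pdist[l] for l in m.leaves(SectionType.axon))
        assert max_term == pytest.approx(max(d for _, d in bars), abs=step)

    def test_malformed_barcode_rejected(self):
        with pytest.raises(ValueError):
            grow_tuft([(30.0, 10.0)], np.zeros(3), [1, 0, 0])
        with pytest.raises(ValueError):
            grow_tuft([], np.zeros(3), [1, 0, 0])


@pytest.fixture(scope="module")
def pipeline(atlas, demo_population):
    from longax.gmm import select_model
    from longax.projections import compute_projection_features, stack_population
    from longax.tufts import extract_tufts

    morphs, _, _ = demo_population
    mat = stack_population(
        [compute_projection_features(m, atlas) for m in morphs]
    )
    model = select_model(mat.feature("lengths"), imposed_c=5, rng=0,
                         region_vocab=mat.region_vocab)
    tufts = []
    for m in morphs:
        _, tt = extract_tufts(m, 300.0, 300.0, atlas=atlas)
        tufts.extend(tt)
    return mat, build_source_inputs(mat, model, tufts)


class TestPopulationSynthesis:
    def make_tasks(self, atlas, n):
        rng = np.random.default_rng(13)
        return [
            SynthesisTask(f"s{i:03d}",
                          atlas.sample_point_in_region("SRC", rng,
                                                       hemisphere="right"),
                          "SRC")
            for i in range(n)
        ]

    def test_every_axon_reaches_its_target_regions(self, atlas, pipeline):
        from longax.projections import base_acronym

        _, inputs = pipeline
        tasks = self.make_tasks(atlas, 10)
        morphs, manifests = synthesize_population(
            tasks, {"SRC": inputs}, atlas, SynthesisConfig(), seed=5
        )
        for m, man in zip(morphs, manifests):
            leaf_regions = set()
            for leaf in m.leaves(SectionType.axon):
                rid = atlas.region_at(m.node(leaf).xyz)
                if rid is not None:
                    leaf_regions.add(atlas.hierarchy.acronym(rid))
            for t in man["targets"]:
                assert base_acronym(t["region"]) in leaf_regions

    def test_fixed_master_seed_gives_identical_swc(self, atlas, pipeline,
                                                   tmp_path):
        _, inputs = pipeline
        tasks = self.make_tasks(atlas, 4)
        blobs = []
        for run in range(2):
            morphs, _ = synthesize_population(
                tasks, {"SRC": inputs}, atlas, SynthesisConfig(), seed=5
            )
            out = tmp_path / f"run{run}"
            out.mkdir()
            content = b""
            for m in morphs:
                write_swc(m, out / f"{m.neuron_id}.swc")
                content += (out / f"{m.neuron_id}.swc").read_bytes()
            blobs.append(content)
        assert blobs[0] == blobs[1]

    def test_missing_source_region_raises(self, atlas, pipeline):
        _, inputs = pipeline
        task = SynthesisTask("x", atlas.region_centroid("RA"), "RA")
        with pytest.raises(KeyError):
            synthesize_population([task], {"SRC": inputs}, atlas,
                                  SynthesisConfig(), seed=0)
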