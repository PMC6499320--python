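"""Cross-sample clustering: grouping, similarity graph, complete-linkage cut,
oracle equivalence and planted-partition recovery."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from svmosaic.cluster import (
    ClusterParams,
    build_similarity_graph,
    cluster_all,
    cluster_component,
    cluster_insertions,
    group_by_overlap,
    pair_distance,
    split_components,
)
from svmosaic.core import breakpoint_error, reciprocal_overlap
from svmosaic.simulate import SimConfig, simulate_panel
from tests.conftest import make_call, random_callset


class TestGroupByOverlap:
    def test_one_bp_overlap_groups(self):
        a, b = make_call(0, 100), make_call(99, 200)
        assert len(group_by_overlap([a, b])) == 1

    def test_abutting_half_open_intervals_do_not_group(self):
        a, b = make_call(0, 100), make_call(100, 200)
        assert len(group_by_overlap([a, b])) == 2

    def test_transitive_chain_groups_even_without_direct_overlap(self):
        a = make_call(0, 100)
        b = make_call(90, 250)
        c = make_call(240, 400)  # c does not touch a
        groups = group_by_overlap([a, b, c])
        assert len(groups) == 1 and len(groups[0]) == 3

    def test_different_chromosomes_never_group(self):
        a = make_call(0, 100, chrom="chr1")
        b = make_call(0, 100, chrom="chr2")
        assert len(group_by_overlap([a, b])) == 2


class TestSimilarityGraph:
    def test_strong_ro_edge(self):
        g = build_similarity_graph(
            [make_call(100, 200), make_call(105, 205)], ClusterParams()
        )  # RO 0.95
        assert g.has_edge(0, 1)

    def test_weak_ro_with_large_error_gets_no_edge(self):
        g = build_similarity_graph(
            [make_call(100, 200), make_call(95, 220)], ClusterParams()
        )  # RO 0.8, e 25
        assert not g.has_edge(0, 1)

    def test_moderate_ro_edge(self):
        g = build_similarity_graph(
            [make_call(100, 200), make_call(103, 205)], ClusterParams()
        )  # RO ~0.924 >= 0.9
        assert g.has_edge(0, 1)

    def test_weak_ro_with_small_error_gets_edge(self):
        # small events: RO 45/53 ~ 0.85 < 0.9 but e = 8 <= 10
        g = build_similarity_graph(
            [make_call(100, 150), make_call(97, 150)], ClusterParams()
        )
        assert g.has_edge(0, 1)

    def test_split_components_matches_bfs_oracle(self, rng):
        import networkx as nx

        for _ in range(20):
            g = nx.gnp_random_graph(12, 0.15, seed=int(rng.integers(1 << 30)))
            ours = {frozenset(c) for c in split_components(g)}
            bfs = {frozenset(nx.node_connected_component(g, n)) for n in g}
            assert ours == bfs


class TestClusterComponent:
    def test_close_pair_forms_one_cluster(self):
        cells = cluster_component(
            [make_call(1000, 2000, sample="S0"), make_call(1005, 2005, sample="S1")],
            ClusterParams(),
        )  # d = 10/2000 = 0.005
        assert len(cells) == 1

    def test_distant_pair_splits_at_height_cutoff(self):
        a, b = make_call(1000, 2000, sample="S0"), make_call(1150, 2150, sample="S1")
        assert pair_distance(a, b, ClusterParams()) == pytest.approx(0.15)
        assert len(cluster_component([a, b], ClusterParams())) == 2

    def test_identical_calls_give_tightness_zero(self):
        calls = [make_call(500, 800, sample=f"S{i}") for i in range(4)]
        catalog = cluster_all(calls)
        (cl,) = catalog.clusters
        assert cl.n_samples == 4 and cl.tightness == 0.0
        assert (cl.rep_start, cl.rep_end) == (500, 800)

    def test_cut_is_inclusive_at_the_cutoff(self):
        # d = exactly 0.1: stays one cluster
        a = make_call(1000, 2000, sample="S0")
        b = make_call(1100, 2100, sample="S1")
        assert pair_distance(a, b, ClusterParams()) == pytest.approx(0.1)
        assert len(cluster_component([a, b], ClusterParams())) == 1


class TestClusterInsertions:
    def test_chain_within_gap(self):
        calls = [make_call(p, p, svtype="INS", length=50, sample=f"S{i}")
                 for i, p in enumerate((100, 108, 117))]
        assert len(cluster_insertions(calls, ClusterParams())) == 1

    def test_gap_beyond_radius_splits(self):
        calls = [make_call(100, 100, svtype="INS", length=50, sample="S0"),
                 make_call(111, 111, svtype="INS", length=50, sample="S1")]
        assert len(cluster_insertions(calls, ClusterParams())) == 2

    def test_empty_input(self):
        assert cluster_insertions([], ClusterParams()) == []


def naive_cluster(calls, params=None):
    """Independent re-implementation: exhaustive pairwise rules + naive
    agglomeration, used as the oracle for the pipeline."""
    params = params or ClusterParams()
    non_ins = [c for c in calls if c.svtype != "INS"]
    labels = {}
    next_label = 0
    # transitive 1-bp overlap grouping by exhaustive closure
    parent = list(range(len(non_ins)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(non_ins)), 2):
        a, b = non_ins[i], non_ins[j]
        if a.svtype != b.svtype or a.chrom != b.chrom:
            continue
        if min(a.end, b.end) - max(a.start, b.start) >= 1:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(len(non_ins)):
        groups.setdefault(find(i), []).append(i)

    for members in groups.values():
        # similarity edges, exhaustively
        comp_parent = {i: i for i in members}

        def cfind(i):
            while comp_parent[i] != i:
                comp_parent[i] = comp_parent[comp_parent[i]]
                i = comp_parent[i]
            return i

        for i, j in itertools.combinations(members, 2):
            a, b = non_ins[i], non_ins[j]
            ro = reciprocal_overlap(a, b)
            if ro >= params.ro_strong or (
                ro >= params.ro_weak
                and breakpoint_error(a, b) <= params.bp_error_cap
            ):
                comp_parent[cfind(i)] = cfind(j)
        comps = {}
        for i in members:
            comps.setdefault(cfind(i), []).append(i)
        for comp in comps.values():
            # naive complete-linkage agglomeration with inclusive cut
            clusters = [[i] for i in comp]

            def complete_d(c1, c2):
                return max(
                    pair_distance(non_ins[i], non_ins[j], params)
                    for i in c1 for j in c2
                )

            while len(clusters) > 1:
                best = None
                for x, y in itertools.combinations(range(len(clusters)), 2):
                    d = complete_d(clusters[x], clusters[y])
                    if best is None or d < best[0]:
                        best = (d, x, y)
                if best[0] > params.height_cutoff:
                    break
                d, x, y = best
                clusters[x] = clusters[x] + clusters[y]
                del clusters[y]
            for cell in clusters:
                for i in cell:
                    labels[id(non_ins[i])] = next_label
                next_label += 1
    return [labels[id(c)] for c in non_ins]


class TestPipelineEquivalence:
    def test_matches_naive_oracle_on_random_instances(self, rng):
        """cluster_all agrees with the brute-force implementation (ARI 1.0)
        on random small instances."""
        params = ClusterParams()
        for trial in range(60):
            n = int(rng.integers(2, 31))
            calls = random_callset(rng, n, span=20_000)
            catalog = cluster_all(calls, params)
            ours = catalog.labels_for(calls)
            naive = naive_cluster(calls, params)
            assert adjusted_rand_score(ours, naive) == 1.0

    def test_permutation_invariance(self, rng):
        calls = random_callset(rng, 40, span=30_000)
        base = cluster_all(calls).labels_for(calls)
        perm = list(calls)
        rng.shuffle(perm)
        shuffled_catalog = cluster_all(perm)
        shuffled = shuffled_catalog.labels_for(calls)
        pairing = {}
        ok = True
        for a, b in zip(base, shuffled):
            pairing.setdefault(a, b)
            ok &= pairing[a] == b
        assert ok and adjusted_rand_score(base, shuffled) == 1.0

    def test_every_call_in_exactly_one_cluster(self, rng):
        calls = random_callset(rng, 60, span=50_000)
        catalog = cluster_all(calls)
        assert sum(len(c.members) for c in catalog.clusters) == len(calls)
        labels = catalog.labels_for(calls)  # raises KeyError if any missing
        assert len(labels) == len(calls)

    def test_nesting_of_partitions(self, rng):
        """Final clusters refine graph components, which refine 1-bp groups."""
        calls = random_callset(rng, 50, span=30_000)
        params = ClusterParams()
        groups = group_by_overlap(calls)
        for group in groups:
            graph = build_similarity_graph(group, params)
            comps = split_components(graph)
            group_set = {c.interval + (c.sample_id, c.caller_id) for c in group}
            for comp in comps:
                comp_calls = [group[i] for i in comp]
                cells = cluster_component(comp_calls, params)
                comp_set = {c.interval + (c.sample_id, c.caller_id)
                            for c in comp_calls}
                assert comp_set <= group_set
                cell_union = set()
                for cell in cells:
                    cell_union |= {c.interval + (c.sample_id, c.caller_id)
                                   for c in cell}
                assert cell_union == comp_set

    def test_complete_linkage_diameter_guarantee(self, rng):
        """Within any final cluster, max pairwise distance <= cutoff."""
        params = ClusterParams()
        calls = random_callset(rng, 60, span=30_000)
        catalog = cluster_all(calls, params)
        for cl in catalog.clusters:
            for a, b in itertools.combinations(cl.members, 2):
                assert pair_distance(a, b, params) <= params.height_cutoff + 1e-12


class TestPlantedPartition:
    def test_recovery_with_two_percent_jitter(self):
        """Planted events with breakpoint jitter at 2% of SV length are
        recovered exactly across a 20-sample panel."""
        cfg = SimConfig(seed=42, panel_size=20, panel_jitter_rel=0.02)
        panel = simulate_panel(cfg, n_clusters=50)
        catalog = cluster_all(panel.all_calls, panel_size=cfg.panel_size)
        labels = catalog.labels_for(panel.all_calls)
        assert adjusted_rand_score(panel.true_labels, labels) == 1.0

    def test_single_sample_calls_stay_singletons_unless_duplicated(self):
        calls = [make_call(i * 10_000, i * 10_000 + 500, sample="S0")
                 for i in range(5)]
        catalog = cluster_all(calls)
        assert len(catalog.clusters) == 5

    def test_membership_matrix_shape_and_content(self):
        cfg = SimConfig(seed=7, panel_size=6)
        panel = simulate_panel(cfg, n_clusters=10)
        catalog = cluster_all(panel.all_calls, panel_size=cfg.panel_size,
                              sample_panel=sorted(panel.calls_by_sample))
        m = catalog.membership
        assert m.shape == (6, len(catalog.clusters))
        for cl in catalog.clusters:
            for s in cl.samples:
                assert m.loc[s, cl.cluster_id]

    def test_mean_tightness_tracks_jitter_scale(self):
        """With per-side jitter at 2% of length, mean cluster tightness lands
        near the half-normal expectation (~1.6% of the SV length)."""
        cfg = SimConfig(seed=13, panel_size=20, panel_jitter_rel=0.02)
        panel = simulate_panel(cfg, n_clusters=60)
        catalog = cluster_all(panel.all_calls, panel_size=cfg.panel_size)
        mt = catalog.summary()["mean_tightness"]
        assert 0.008 < mt < 0.03
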