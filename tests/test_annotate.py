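"""TE classification, genic-feature assignment, TSS profiles, deleted genes,
density windows."""

import numpy as np
import pytest

from svmosaic.annotate import (
    FEATURE_PRECEDENCE,
    GeneIndex,
    assign_feature,
    classify_te_overlap,
    deleted_genes,
    density_windows,
    tss_profile,
)
from svmosaic.cluster import cluster_all
from svmosaic.io_formats import AnnotationTrack, BedRecord, GeneModel
from svmosaic.simulate import SimConfig, simulate_annotations
from tests.conftest import make_call


def te(start, end, label="DTT", chrom="chr1", name="TE"):
    return BedRecord(chrom, start, end, name, label)


def gene(gene_id="g1", chrom="chr1", strand="+", lo=10_000, cds=None, utr5=None,
         utr3=None, introns=None):
    span = 2000
    tss = lo if strand == "+" else lo + span - 1
    tes = lo + span - 1 if strand == "+" else lo
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
        transcription_end=tes,
        cds_intervals=cds or [(lo + 200, lo + 1800)],
        utr5_intervals=utr5 if utr5 is not None else
            ([(lo, lo + 200)] if strand == "+" else [(lo + 1800, lo + 2000)]),
        utr3_intervals=utr3 if utr3 is not None else
            ([(lo + 1800, lo + 2000)] if strand == "+" else [(lo, lo + 200)]),
        intron_intervals=introns or [],
    )


class TestTeClassification:
    def test_strict_te_at_80_percent_reciprocal(self):
        track = AnnotationTrack([te(50, 950, "DTH")])
        cat, label = classify_te_overlap(make_call(0, 1000), track)
        assert cat == "strict_te" and label == "DTH"

    def test_union_coverage_half_length_is_repeat_associated(self):
        track = AnnotationTrack([te(0, 300), te(250, 600)])  # union covers 600
        cat, _ = classify_te_overlap(make_call(0, 1000), track)
        assert cat == "repeat_associated"

    def test_no_overlap_is_none(self):
        track = AnnotationTrack([te(5000, 6000)])
        assert classify_te_overlap(make_call(0, 1000), track) == ("none", None)

    def test_empty_track_is_none(self):
        assert classify_te_overlap(make_call(0, 1000), AnnotationTrack([])) == (
            "none", None
        )

    def test_best_label_is_max_ro_te(self):
        track = AnnotationTrack([te(0, 400, "RLG"), te(100, 950, "DTM")])
        cat, label = classify_te_overlap(make_call(0, 1000), track)
        assert label == "DTM"

    def test_strict_implies_repeat_associated_criterion(self, rng):
        """Nesting: any strict_te cluster also passes the 50% coverage rule."""
        for _ in range(50):
            start = int(rng.integers(0, 5000))
            length = int(rng.integers(100, 2000))
            cluster = make_call(start, start + length)
            n_te = int(rng.integers(0, 4))
            records = []
            for _ in range(n_te):
                ts = int(rng.integers(max(start - 500, 0), start + length + 500))
                records.append(te(ts, ts + int(rng.integers(80, 2200))))
            track = AnnotationTrack(records)
            cat, _ = classify_te_overlap(cluster, track)
            if cat == "strict_te":
                from svmosaic.annotate import _union_coverage

                cov = _union_coverage(start, start + length, records)
                assert cov >= 0.5 * length

    def test_ins_without_sequence_is_none(self):
        track = AnnotationTrack([te(0, 400)])
        ins = make_call(100, 100, svtype="INS", length=400)
        assert classify_te_overlap(ins, track) == ("none", None)

    def test_ins_with_sequence_matches_te_by_length(self):
        track = AnnotationTrack([te(0, 400, "DTT")])
        ins = make_call(100, 100, svtype="INS", seq="A" * 390)
        cat, label = classify_te_overlap(ins, track)
        assert cat == "strict_te" and label == "DTT"


class TestFeatureAssignment:
    def test_cds_wins(self):
        g = gene()
        a = assign_feature(make_call(10_500, 10_600), [g])
        assert a.feature == "CDS" and a.gene_id == "g1"

    def test_spanning_cds_and_intron_is_cds(self):
        g = gene(cds=[(10_200, 10_800), (11_000, 11_800)],
                 introns=[(10_800, 11_000)])
        a = assign_feature(make_call(10_700, 11_100), [g])
        assert a.feature == "CDS"

    def test_minus_strand_promoter_is_at_higher_coordinates(self):
        g = gene(strand="-")  # TSS at 11_999
        a = assign_feature(make_call(12_250, 12_350), [g])  # 300 bp upstream
        assert a.feature == "promoter"

    def test_plus_strand_promoter(self):
        g = gene()  # TSS at 10_000
        a = assign_feature(make_call(9600, 9700), [g])
        assert a.feature == "promoter"

    def test_intergenic_far_from_genes(self):
        a = assign_feature(make_call(50_000, 50_100), [gene()])
        assert a.feature == "intergenic" and a.gene_id is None

    def test_every_cluster_gets_exactly_one_label(self, rng):
        genes = [gene(f"g{i}", lo=20_000 * (i + 1), strand="+-"[i % 2])
                 for i in range(5)]
        index = GeneIndex(genes)
        for _ in range(100):
            start = int(rng.integers(0, 120_000))
            a = assign_feature(make_call(start, start + 200), index)
            assert a.feature in FEATURE_PRECEDENCE


class TestTssProfile:
    def test_single_deletion_covers_its_relative_window(self):
        g = gene()  # + strand, TSS 10_000
        profile = tss_profile([make_call(10_005, 10_015)], [g], half_window=50)
        short = profile.short_fraction
        covered = (profile.positions >= 5) & (profile.positions < 15)
        assert np.all(short[covered] == 1.0)
        assert np.all(short[~covered] == 0.0)
        assert np.all(profile.long_fraction == 0.0)

    def test_minus_strand_coverage_is_flipped(self):
        g = gene(strand="-")  # TSS 11_999; genomic 12_100..12_110 = upstream
        profile = tss_profile([make_call(12_100, 12_110)], [g], half_window=200)
        covered = profile.positions[profile.short_fraction == 1.0]
        assert covered.min() == -110 and covered.max() == -101

    def test_long_events_go_to_long_track(self):
        g = gene()
        profile = tss_profile([make_call(10_000, 10_100)], [g], half_window=50)
        assert np.all(profile.short_fraction == 0.0)
        assert profile.long_fraction[profile.positions >= 0].min() == 1.0

    def test_no_svs_gives_zero_profile(self):
        profile = tss_profile([], [gene()], half_window=20)
        assert np.all(profile.short_counts == 0) and np.all(profile.long_counts == 0)

    def test_contig_edge_truncates_denominator(self):
        g = gene(lo=100)  # TSS at 100, window extends past the contig start
        profile = tss_profile([], [g], half_window=500,
                              contig_lengths={"chr1": 10_000})
        assert profile.denominators[0] == 0  # position -500 does not exist
        assert profile.denominators[-1] == 1

    def test_uniform_placement_gives_flat_profile(self, rng):
        """SVs placed uniformly around the TSS produce a flat coverage profile
        (within binomial noise)."""
        genes = [gene(f"g{i}", lo=10_000 + 30_000 * i) for i in range(40)]
        svs = []
        for g in genes:
            for _ in range(5):
                offset = int(rng.integers(-480, 480))
                svs.append(make_call(g.tss + offset, g.tss + offset + 20))
        profile = tss_profile(svs, genes, half_window=400)
        frac = profile.short_fraction
        p = frac.mean()
        se = np.sqrt(p * (1 - p) / len(genes))
        assert np.all(np.abs(frac - p) < 5 * se)


class TestDeletedGenes:
    def _gene(self):
        return gene(cds=[(10_100, 10_400)])

    def _cluster_for(self, calls):
        return cluster_all(calls).clusters

    def test_single_spanning_deletion_deletes_gene(self):
        clusters = self._cluster_for([make_call(10_050, 10_500, sample="S0")])
        res = deleted_genes(clusters, [self._gene()])
        assert res.per_sample["S0"] == {"g1"}

    def test_union_of_two_abutting_deletions_deletes_gene(self):
        clusters = self._cluster_for([
            make_call(10_050, 10_250, sample="S0"),
            make_call(10_240, 10_500, sample="S0"),
        ])
        res = deleted_genes(clusters, [self._gene()])
        assert res.per_sample["S0"] == {"g1"}

    def test_99_percent_coverage_is_not_deleted(self):
        clusters = self._cluster_for([make_call(10_100, 10_397, sample="S0")])
        res = deleted_genes(clusters, [self._gene()])
        assert res.per_sample["S0"] == set()

    def test_monotone_in_added_deletions(self):
        base = [make_call(10_050, 10_250, sample="S0")]
        extra = base + [make_call(10_240, 10_500, sample="S0")]
        res_base = deleted_genes(self._cluster_for(base), [self._gene()])
        res_extra = deleted_genes(self._cluster_for(extra), [self._gene()])
        assert res_base.per_sample["S0"] <= res_extra.per_sample["S0"]

    def test_gene_without_cds_excluded_with_warning(self):
        g = gene(cds=[])
        g.cds_intervals = []
        clusters = self._cluster_for([make_call(10_000, 12_500, sample="S0")])
        with pytest.warns(UserWarning, match="no CDS"):
            res = deleted_genes(clusters, [g])
        assert res.per_sample["S0"] == set()

    def test_group_sharing_table(self):
        calls = [make_call(10_050, 10_500, sample=f"S{i}") for i in range(6)]
        clusters = self._cluster_for(calls)
        groups = {f"S{i}": ("indica" if i < 4 else "japonica") for i in range(6)}
        res = deleted_genes(clusters, [self._gene()], group_assignments=groups,
                            min_group_freq=5)
        assert res.per_group["indica"] == {"g1"}
        assert res.sharing["indica+japonica"] == 1


class TestDensityWindows:
    def test_identical_tracks_correlate_perfectly(self):
        variants = [make_call(i * 37_000, i * 37_000 + 100) for i in range(20)]
        res = density_windows(variants, variants,
                              chrom_lengths={"chr1": 800_000})
        assert res.correlation == pytest.approx(1.0)

    def test_uniform_counts_have_no_flags(self):
        # one variant at the centre of every 50-kb step: all windows equal
        variants = [make_call(25_000 + i * 50_000, 25_100 + i * 50_000)
                    for i in range(8)]
        res = density_windows(variants, chrom_lengths={"chr1": 400_000})
        inner = res.track_a.windows.iloc[:-1]  # last window is truncated
        assert not inner["flagged"].any()

    def test_hand_built_example_flags_only_the_spike(self):
        """Counts [1,1,1,1,1,7] over six windows: mean 2, only the last
        window reaches 2 x mean."""
        positions = [10_000 + i * 100_000 for i in range(5)]
        positions += [510_000 + j for j in range(7)]
        variants = [make_call(p, p + 50) for p in positions]
        res = density_windows(variants, window=100_000, step=100_000,
                              chrom_lengths={"chr1": 600_000})
        counts = res.track_a.windows["count"].tolist()
        assert counts == [1, 1, 1, 1, 1, 7]
        assert res.track_a.windows["flagged"].tolist() == [False] * 5 + [True]

    def test_sliding_windows_count_start_position_in_both(self):
        variants = [make_call(60_000, 60_100)]
        res = density_windows(variants, window=100_000, step=50_000,
                              chrom_lengths={"chr1": 200_000})
        w = res.track_a.windows
        counted = w[w["count"] > 0]
        assert list(counted["start"]) == [0, 50_000]

    def test_chromosome_shorter_than_window(self):
        res = density_windows([make_call(100, 200)], window=100_000, step=50_000,
                              chrom_lengths={"chr1": 30_000})
        assert len(res.track_a.windows) == 1
        assert res.track_a.windows.iloc[0]["end"] == 30_000


class TestSimulatedAnnotationsIntegration:
    def test_promoter_enrichment_of_simulated_deletions(self):
        sim = simulate_annotations(SimConfig(seed=21), n_genes=40, sv_per_gene=2.0)
        index = GeneIndex(sim.genes)
        features = [assign_feature(c, index).feature for c in sim.sv_calls]
        # deletions are planted in [TSS-500, TSS+500]: none should be intergenic
        assert features.count("intergenic") / len(features) < 0.2
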