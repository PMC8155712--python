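"""TSS calling: clustering rules, TAP filter, consensus, categorization."""
import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endmap._peaks import Peak
from endmap.genome_io import (
    AnnotationSet,
    EndCountTrack,
    Gene,
    GenomeRecord,
    GenomeSet,
)
from endmap.tss_caller import (
    TSSRecord,
    categorize_tss,
    cluster_candidates,
    consensus_and_curate,
    filter_by_tap,
    tss_sequence_stats,
)


def _track(counts_fwd, counts_rev=None, library="TAP_PLUS", rep="rep1",
           normalized=True):
    return EndCountTrack("chr", library, rep,
                         counts_fwd=dict(counts_fwd),
                         counts_rev=dict(counts_rev or {}),
                         total_reads=1e6, size_factor=1.0, normalized=normalized)


def brute_force_representatives(depths, max_gap, sd_threshold):
    """Independent re-derivation of the clustering + sub-clustering rules
    (plain Python, statistics.pstdev)."""
    positions = sorted(depths)
    clusters, current = [], []
    for p in positions:
        if current and p - current[-1] >= max_gap:
            clusters.append(current)
            current = []
        current.append(p)
    if current:
        clusters.append(current)
    reps = []
    for cluster in clusters:
        sub = []
        for p in cluster:
            if sub and statistics.pstdev(sub + [p]) >= sd_threshold:
                reps.append(max(sub, key=lambda q: (depths[q], -q)))
                sub = []
            sub.append(p)
        reps.append(max(sub, key=lambda q: (depths[q], -q)))
    return sorted(reps)


class TestClustering:
    def test_subcluster_collapses_nearby_peaks(self):
        track = _track({100: 50.0, 103: 30.0, 300: 20.0})
        peaks = cluster_candidates(track)
        assert [(p.position, p.depth) for p in peaks] == [(100, 50.0), (300, 20.0)]

    def test_wide_cluster_splits_into_subclusters(self):
        # gap 90 < 100 joins the cluster; SD 45 >= 10 splits it again
        track = _track({100: 50.0, 190: 40.0})
        peaks = cluster_candidates(track)
        assert [p.position for p in peaks] == [100, 190]

    def test_isolated_peak_unchanged(self):
        peaks = cluster_candidates(_track({500: 3.0}))
        assert [(p.position, p.depth) for p in peaks] == [(500, 3.0)]

    def test_tie_broken_toward_smaller_coordinate(self):
        peaks = cluster_candidates(_track({100: 5.0, 101: 5.0}))
        assert [p.position for p in peaks] == [100]

    def test_requires_normalized_track(self):
        with pytest.raises(ValueError, match="normalized"):
            cluster_candidates(_track({1: 1.0}, normalized=False))

    @given(
        depths=st.dictionaries(st.integers(0, 3000), st.floats(0.5, 100),
                               min_size=1, max_size=50)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, depths):
        track = _track(depths)
        got = [p.position for p in cluster_candidates(track)]
        assert got == brute_force_representatives(depths, 100, 10.0)

    @given(
        depths=st.dictionaries(st.integers(0, 2000), st.floats(0.5, 50),
                               min_size=1, max_size=30),
        seed=st.integers(0, 10),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_order_independent(self, depths, seed):
        rng = np.random.default_rng(seed)
        items = list(depths.items())
        rng.shuffle(items)
        a = cluster_candidates(_track(depths))
        b = cluster_candidates(_track(dict(items)))
        assert [(p.position, p.depth) for p in a] == [(p.position, p.depth) for p in b]


class TestTapFilter:
    def _peak(self, pos=100, depth=20.0):
        return Peak("chr", pos, "+", depth, "rep1")

    def test_enriched_peak_kept_with_ratio(self):
        kept = filter_by_tap([self._peak()], _track({100: 8.0}, library="TAP_MINUS"))
        assert len(kept) == 1 and kept[0].tap_ratio == pytest.approx(2.5)

    def test_absent_in_tap_minus_kept_with_inf(self):
        kept = filter_by_tap([self._peak()], _track({}, library="TAP_MINUS"))
        assert len(kept) == 1 and math.isinf(kept[0].tap_ratio)

    def test_unenriched_peak_removed(self):
        kept = filter_by_tap([self._peak()], _track({100: 15.0}, library="TAP_MINUS"))
        assert kept == []


class TestConsensus:
    def _rna(self, counts=None):
        return _track(counts or {}, library="RNA")

    def test_one_nt_offset_restored_at_deeper_position(self):
        a = [Peak("chr", 100, "+", 30.0, "rep1")]
        b = [Peak("chr", 101, "+", 50.0, "rep2")]
        kept = consensus_and_curate([a, b], [self._rna()], tolerance=2,
                                    rna_support_threshold=1.0)
        assert len(kept) == 1
        assert kept[0].position == 101
        assert kept[0].depth == pytest.approx(40.0)
        assert kept[0].replicate_support == 2

    def test_lone_peak_without_rna_removed(self):
        a = [Peak("chr", 100, "+", 30.0, "rep1")]
        kept = consensus_and_curate([a, []], [self._rna()], tolerance=2,
                                    rna_support_threshold=1.0)
        assert kept == []

    def test_lone_peak_with_clear_rna_kept(self):
        a = [Peak("chr", 100, "+", 30.0, "rep1")]
        rna = self._rna({p: 5.0 for p in range(100, 150)})
        kept = consensus_and_curate([a, []], [rna], tolerance=2,
                                    rna_support_threshold=1.0)
        assert len(kept) == 1 and kept[0].replicate_support == 1

    def test_distant_peaks_not_matched(self):
        a = [Peak("chr", 100, "+", 30.0, "rep1")]
        b = [Peak("chr", 110, "+", 30.0, "rep2")]
        kept = consensus_and_curate([a, b], [self._rna()], tolerance=2,
                                    rna_support_threshold=1.0)
        assert kept == []

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="2 replicate"):
            consensus_and_curate([[]], [self._rna()])


class TestCategorize:
    @pytest.fixture
    def setup(self):
        genome = GenomeSet([GenomeRecord("chr", "ACGT" * 1000)])
        annotation = AnnotationSet([Gene("g1", "chr", 1000, 2000, "+")])
        return genome, annotation

    def _peak(self, pos, strand="+", depth=10.0):
        return Peak("chr", pos, strand, depth, "rep1")

    def test_primary_secondary_and_utr_length(self, setup):
        genome, annotation = setup
        records = categorize_tss(
            [self._peak(958, depth=80.0), self._peak(700, depth=20.0)],
            annotation, genome)
        by_pos = {r.position: r for r in records}
        assert by_pos[958].category == "P" and by_pos[958].utr5_length == 42
        assert by_pos[700].category == "S" and by_pos[700].utr5_length == 300

    def test_internal_antisense_intergenic(self, setup):
        genome, annotation = setup
        records = categorize_tss(
            [self._peak(1500), self._peak(1500, strand="-"), self._peak(50)],
            annotation, genome)
        cats = {(r.position, r.strand): r.category for r in records}
        assert cats[(1500, "+")] == "I"
        assert cats[(1500, "-")] == "A"
        assert cats[(50, "+")] == "N"

    def test_p_unique_per_gene_and_window_contains_site(self, sim_dataset,
                                                        sim_drna, sim_term):
        from endmap.tss_caller import call_tss

        genome, annotation, _ = sim_dataset
        tap_plus, tap_minus = sim_drna
        _, rna = sim_term
        records = call_tss(tap_plus, tap_minus, rna, annotation, genome)
        seen_p = set()
        for r in records:
            if r.category == "P":
                assert r.associated_gene not in seen_p
                seen_p.add(r.associated_gene)
            if r.category in ("P", "S"):
                gene = annotation.get(r.associated_gene)
                off = (r.position - gene.start if gene.strand == "+"
                       else gene.end - 1 - r.position)
                assert -500 <= off < 100

    def test_minus_strand_window_mirrored(self):
        genome = GenomeSet([GenomeRecord("chr", "ACGT" * 1000)])
        annotation = AnnotationSet([Gene("g1", "chr", 1000, 2000, "-")])
        records = categorize_tss([self._peak(2041, strand="-", depth=9.0)],
                                 annotation, genome)
        assert records[0].category == "P" and records[0].utr5_length == 42

    def test_weak_internal_peak_dropped(self, setup):
        genome, annotation = setup
        records = categorize_tss(
            [self._peak(958, depth=1000.0), self._peak(1500, depth=5.0)],
            annotation, genome)
        assert {r.category for r in records} == {"P"}


class TestSequenceStats:
    def test_planted_ca_context(self):
        genome = GenomeSet([GenomeRecord("chr", "GGCAGG")])
        recs = [TSSRecord("chr", 3, "+", 1.0, "P", "g", None, 2, None)]
        stats = tss_sequence_stats(recs, genome)
        assert stats["purine_plus1"] == pytest.approx(1.0)
        assert stats["pyrimidine_minus1"] == pytest.approx(1.0)

    def test_uniform_genome_gives_half(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200_000))
        genome = GenomeSet([GenomeRecord("chr", seq)])
        positions = rng.integers(1, len(seq) - 1, size=10_000)
        recs = [TSSRecord("chr", int(p), "+", 1.0, "N", None, None, 2, None)
                for p in positions]
        stats = tss_sequence_stats(recs, genome)
        se3 = 3 * math.sqrt(0.25 / 10_000)
        assert abs(stats["purine_plus1"] - 0.5) < se3
        assert abs(stats["pyrimidine_minus1"] - 0.5) < se3

    def test_empty_list_rejected(self):
        genome = GenomeSet([GenomeRecord("chr", "ACGT")])
        with pytest.raises(ValueError, match="no TSS"):
            tss_sequence_stats([], genome)

    def test_edge_site_skipped(self):
        genome = GenomeSet([GenomeRecord("chr", "ACGT")])
        recs = [TSSRecord("chr", 0, "+", 1.0, "N", None, None, 2, None),
                TSSRecord("chr", 2, "+", 1.0, "N", None, None, 2, None)]
        stats = tss_sequence_stats(recs, genome)
        assert stats["n_skipped"] == 1 and stats["n_sites"] == 1
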