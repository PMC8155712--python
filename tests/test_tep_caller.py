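"""TEP calling: Z-scores, training sets, KNN votes, consensus, shapes, dG."""
import itertools
import math

import numpy as np
import pytest

from endmap.genome_io import (
    AnnotationSet,
    EndCountTrack,
    Gene,
    GenomeRecord,
    GenomeSet,
)
from endmap.tep_caller import (
    TEPCandidate,
    TEPRecord,
    build_training_sets,
    candidate_teps,
    categorize_tep,
    classify_shape,
    consensus_teps,
    fold_energy,
    hairpin_delta_g,
    knn_call,
    nucleotide_enrichment,
)


def _track(counts_fwd, counts_rev=None, library="TERM", rep="rep1"):
    return EndCountTrack("chr", library, rep,
                         counts_fwd=dict(counts_fwd),
                         counts_rev=dict(counts_rev or {}),
                         total_reads=1e6, size_factor=1.0, normalized=True)


def _cand(pos, strand="+", depth=10.0, z=10.0, vec=None, rep="rep1"):
    if vec is None:
        vec = np.zeros(21)
        vec[10] = depth
    return TEPCandidate("chr", pos, strand, depth, z, np.asarray(vec, float), rep)


class TestZScore:
    def test_hand_computed_neighbourhood(self):
        # peak 20 vs neighbours {2, 4, 6, 8}: z = (20 - 5) / 2.582 ~= 5.81
        counts = {100: 20.0, 90: 2.0, 95: 4.0, 105: 6.0, 110: 8.0}
        cands = candidate_teps(_track(counts), sd_threshold=0.1)
        peak = [c for c in cands if c.position == 100][0]
        assert peak.z_score == pytest.approx(15 / np.std([2, 4, 6, 8], ddof=1), abs=1e-6)
        assert peak.z_score == pytest.approx(5.8095, abs=1e-3)

    def test_zero_sd_neighbourhood_falls_back_to_track(self):
        counts = {100: 10.0, 95: 1.0, 105: 1.0, 500: 2.0, 600: 4.0}
        cands = candidate_teps(_track(counts), sd_threshold=0.1)
        peak = [c for c in cands if c.position == 100][0]
        pop = [1.0, 1.0, 2.0, 4.0]
        expect = (10.0 - np.mean(pop)) / np.std(pop, ddof=1)
        assert peak.z_score == pytest.approx(expect)

    def test_isolated_peak_uses_fallback(self):
        counts = {100: 10.0, 500: 2.0, 700: 3.0}
        cands = candidate_teps(_track(counts), sd_threshold=0.1)
        peak = [c for c in cands if c.position == 100][0]
        assert math.isfinite(peak.z_score)

    def test_feature_vector_orientation(self):
        counts = {100: 9.0, 103: 4.0}
        plus = [c for c in candidate_teps(_track(counts), sd_threshold=0.1)
                if c.position == 100][0]
        assert plus.feature_vector[10] == 9.0 and plus.feature_vector[13] == 4.0
        minus = [c for c in candidate_teps(_track({}, counts), sd_threshold=0.1)
                 if c.position == 100][0]
        # downstream on the minus strand means smaller coordinates
        assert minus.feature_vector[10] == 9.0 and minus.feature_vector[7] == 4.0


class TestTrainingSets:
    def _rna(self, counts):
        return _track(counts, library="RNA")

    def test_z_and_rna_drop_select_positives(self):
        term = _track({500: 50.0, 495: 2.0, 505: 1.0,
                       460: 1.0, 470: 1.0, 480: 1.0})
        rna = self._rna({p: 10.0 for p in range(450, 501)})  # falls after 500
        cands = candidate_teps(term, sd_threshold=0.1)
        pos, neg = build_training_sets(cands, [rna], term, z_min=6.0)
        assert [p.position for p in pos] == [500]
        assert sorted(n.position for n in neg) == [495, 505]

    def test_flat_rna_profile_excluded(self):
        term = _track({500: 50.0, 495: 2.0, 460: 1.0, 470: 1.0, 480: 1.0})
        rna = self._rna({p: 10.0 for p in range(400, 600)})  # no drop
        cands = candidate_teps(term, sd_threshold=0.1)
        with pytest.raises(ValueError, match="no positive"):
            build_training_sets(cands, [rna], term, z_min=6.0)

    def test_no_positives_is_error(self):
        term = _track({500: 2.0, 495: 2.0})
        with pytest.raises(ValueError, match="z_min"):
            build_training_sets(
                candidate_teps(term, sd_threshold=0.1), [self._rna({})], term,
                z_min=6.0)


class TestKnn:
    def test_identical_to_positive_accepted(self):
        pos = [_cand(500, vec=[0] * 10 + [10] + [0] * 10)]
        neg = [_cand(495, vec=[0] * 5 + [10] + [0] * 15)]
        query = _cand(800, vec=[0] * 10 + [7] + [0] * 10)  # same shape as positive
        assert knn_call([query], pos, neg, k=1) == [query]

    def test_identical_to_negative_rejected(self):
        pos = [_cand(500, vec=[0] * 10 + [10] + [0] * 10)]
        neg = [_cand(495, vec=[0] * 5 + [10] + [0] * 15)]
        query = _cand(800, vec=[0] * 5 + [7] + [0] * 15)
        assert knn_call([query], pos, neg, k=1) == []

    def test_majority_vote_with_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        pos = [_cand(i, vec=rng.random(21)) for i in range(5)]
        neg = [_cand(100 + i, vec=rng.random(21)) for i in range(7)]
        queries = [_cand(1000 + i, vec=rng.random(21)) for i in range(20)]
        accepted = {c.position for c in knn_call(queries, pos, neg, k=3)}

        def scale(v):
            m = v.max()
            return v / m if m > 0 else v

        train = [(scale(c.feature_vector), 1) for c in pos] + \
                [(scale(c.feature_vector), 0) for c in neg]
        for q in queries:
            dists = sorted(
                (float(np.linalg.norm(scale(q.feature_vector) - v)), label)
                for v, label in train
            )
            votes = sum(label for _, label in dists[:3])
            assert (q.position in accepted) == (votes >= 2)

    def test_training_set_separates_itself(self):
        rng = np.random.default_rng(4)
        pos = [_cand(i, vec=rng.random(21)) for i in range(6)]
        neg = [_cand(100 + i, vec=rng.random(21)) for i in range(6)]
        accepted = {c.position for c in knn_call(pos + neg, pos, neg, k=1)}
        assert accepted == {c.position for c in pos}

    def test_k_reduced_when_training_small(self):
        pos = [_cand(1, vec=[1] * 21), _cand(2, vec=[1] * 20 + [0])]
        neg = [_cand(3, vec=[0] * 20 + [1])]
        # k collapses to the training size (3); 2 of 3 neighbours are positive
        assert knn_call([_cand(9, vec=[1] * 21)], pos, neg, k=50)

    def test_even_k_tie_breaks_negative(self):
        pos = [_cand(1, vec=[1] * 21)]
        neg = [_cand(2, vec=[0] * 20 + [1])]
        assert knn_call([_cand(9, vec=[1] * 21)], pos, neg, k=2) == []

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            knn_call([], [], [_cand(1)], k=1)


class TestConsensus:
    def test_two_of_three_within_one_nt_kept(self):
        sets = [[_cand(500, rep="rep1")], [_cand(501, rep="rep2")], []]
        merged = consensus_teps(sets)
        assert len(merged) == 1 and merged[0].replicate_support == 2

    def test_single_replicate_removed(self):
        merged = consensus_teps([[_cand(500)], [], []])
        assert merged == []

    def test_three_nt_apart_not_matched(self):
        sets = [[_cand(500, rep="rep1")], [_cand(503, rep="rep2")], []]
        assert consensus_teps(sets) == []

    def test_symmetric_under_replicate_permutation(self):
        sets = [
            [_cand(500, depth=5.0, rep="rep1"), _cand(900, depth=2.0, rep="rep1")],
            [_cand(501, depth=9.0, rep="rep2")],
            [_cand(499, depth=7.0, rep="rep3"), _cand(901, depth=1.0, rep="rep3")],
        ]
        base = {(c.position, c.depth, c.replicate_support)
                for c in consensus_teps(sets)}
        for perm in itertools.permutations(sets):
            assert {(c.position, c.depth, c.replicate_support)
                    for c in consensus_teps(list(perm))} == base

    def test_requires_three_sets(self):
        with pytest.raises(ValueError, match="3 replicate"):
            consensus_teps([[], []])


class TestCategorize:
    @pytest.fixture
    def annotation(self):
        return AnnotationSet([Gene("g1", "chr", 1000, 2000, "+")])

    def test_primary_secondary_downstream(self, annotation):
        records = categorize_tep(
            [_cand(2100, depth=9.0), _cand(2300, depth=4.0)], annotation, {})
        cats = {r.position: r.category for r in records}
        assert cats == {2100: "P", 2300: "S"}

    def test_five_prime_utr_tep(self, annotation):
        records = categorize_tep([_cand(980)], annotation, {"g1": 958})
        assert records[0].category == "U" and records[0].associated_gene == "g1"

    def test_internal_antisense_intergenic(self, annotation):
        records = categorize_tep(
            [_cand(1500), _cand(1500, strand="-"), _cand(10)], annotation, {})
        cats = {(r.position, r.strand): r.category for r in records}
        assert cats[(1500, "+")] == "I"
        assert cats[(1500, "-")] == "A"
        assert cats[(10, "+")] == "N"

    def test_minus_strand_gene_mirrored(self):
        annotation = AnnotationSet([Gene("g1", "chr", 1000, 2000, "-")])
        records = categorize_tep([_cand(900, strand="-")], annotation, {})
        assert records[0].category == "P"


class TestShape:
    def _genome(self, seq):
        return GenomeSet([GenomeRecord("chr", seq)])

    def test_u_tract_is_l_shaped(self):
        # window -10..+2 around the TEP contains the TTTT run
        seq = "G" * 40 + "GGCGCCTTTT" + "AGG" + "G" * 40
        genome = self._genome(seq)
        tep = 49  # last T of the tract
        shape, u_count, run = classify_shape(tep, "+", genome, "chr")
        assert shape == "L" and u_count >= 4 and run >= 4

    def test_scattered_t_is_i_shaped(self):
        seq = "G" * 40 + "GTCGTCGATG" + "CGG" + "G" * 40
        shape, u_count, _ = classify_shape(49, "+", self._genome(seq), "chr")
        assert shape == "I" and u_count < 4

    def test_u_min_zero_everything_l(self):
        shape, _, _ = classify_shape(50, "+", self._genome("G" * 100), "chr", u_min=0)
        assert shape == "L"

    def test_minus_strand_counts_template_a(self):
        # coding-strand T on '-' appears as A on the forward strand
        seq = "C" * 40 + "AAAA" + "C" * 40
        shape, u_count, _ = classify_shape(40, "-", self._genome(seq), "chr")
        assert shape == "L" and u_count == 4


class TestFoldEnergy:
    def test_perfect_gc_stem(self):
        assert hairpin_delta_g("GGGGGG" + "AAAA" + "CCCCCC") == -14.0

    def test_poly_a_no_stem(self):
        assert hairpin_delta_g("A" * 40) == 0.0

    def test_au_and_gu_pairs_scored(self):
        # 4 AU pairs, 4-nt loop: -8 + 4 = -4
        assert hairpin_delta_g("AAAA" + "CCCC" + "TTTT") == -4.0

    def test_short_sequence_returns_zero(self):
        genome = GenomeSet([GenomeRecord("chr", "ACGTACGTAC")])
        assert fold_energy(5, "+", genome, "chr") == 0.0

    def test_planted_terminators_more_stable_than_random(self, sim_dataset):
        genome, _, truth = sim_dataset
        rng = np.random.default_rng(0)
        dg_term = [fold_energy(t.position, t.strand, genome, truth.seq_id)
                   for t in truth.teps if t.klass == "L"]
        seq = genome.sequence(truth.seq_id)
        dg_rand = [hairpin_delta_g(seq[p: p + 40])
                   for p in rng.integers(0, len(seq) - 40, size=100)]
        assert np.mean(dg_term) < np.mean(dg_rand)

    def test_external_engine_matches_sign(self):
        import shutil

        if shutil.which("RNAfold") is None:
            pytest.xfail("RNAfold not on PATH")
        genome = GenomeSet([GenomeRecord(
            "chr", "A" * 5 + "GCGCGCGCGC" + "TTCG" + "GCGCGCGCGC" + "TTTTT" + "A" * 6)])
        dg = fold_energy(40, "+", genome, "chr", engine="external")
        assert dg < -5.0


class TestEnrichment:
    def test_null_sites_give_unit_ratios(self, sim_dataset):
        genome, annotation, truth = sim_dataset
        rng = np.random.default_rng(1)
        seq_len = truth.genome_length
        sites = []
        covered = set()
        for g in annotation:
            covered.update(range(g.start, g.end))
        free = [p for p in range(20, seq_len - 20) if p not in covered]
        for p in rng.choice(free, size=300, replace=False):
            sites.append(TEPRecord(truth.seq_id, int(p), "+", 1.0, "N", "I", None, 3))
        mat = nucleotide_enrichment(sites, genome, annotation, flank=10,
                                    n_random=4000, seed=5)
        assert np.nanmean(np.abs(mat.to_numpy() - 1.0)) < 0.25

    def test_planted_l_teps_show_t_enrichment(self, sim_dataset):
        genome, annotation, truth = sim_dataset
        teps = [TEPRecord(truth.seq_id, t.position, t.strand, 1.0, "P", t.klass,
                          t.gene_id, 3)
                for t in truth.teps if t.klass == "L"]
        mat = nucleotide_enrichment(teps, genome, annotation, flank=10,
                                    n_random=4000, seed=5)
        assert (mat.loc["T", range(-10, 1)] > 1.0).any()

    def test_deterministic_given_seed(self, sim_dataset):
        genome, annotation, truth = sim_dataset
        teps = [TEPRecord(truth.seq_id, t.position, t.strand, 1.0, "P", t.klass,
                          t.gene_id, 3) for t in truth.teps]
        a = nucleotide_enrichment(teps, genome, annotation, flank=5,
                                  n_random=500, seed=9)
        b = nucleotide_enrichment(teps, genome, annotation, flank=5,
                                  n_random=500, seed=9)
        assert a.equals(b)
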