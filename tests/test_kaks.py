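import math

import numpy as np
import pytest

from _oracles import GENETIC_CODE, SENSE, brute_pathways, brute_sites
from genefam.core_io import GeneModel, SeqRecord
from genefam.kaks import (KaKsResult, call_paralog_pairs, classify_duplication,
                          divergence_time, nearest_edge_distance, ng86_kaks,
                          ng86_sites, pathway_differences,
                          reciprocal_best_hits, thread_codon_alignment)


class TestSites:
    def test_all_sense_codons_match_brute_force(self):
        for codon in SENSE:
            s, n = ng86_sites(codon)
            bs, bn = brute_sites(codon)
            assert s == pytest.approx(bs) and n == pytest.approx(bn), codon
            assert s + n == pytest.approx(3.0)

    def test_phenylalanine_and_methionine(self):
        assert ng86_sites("TTT") == pytest.approx((1 / 3, 8 / 3))
        assert ng86_sites("ATG") == pytest.approx((0.0, 3.0))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")


class TestPathways:
    def test_single_synonymous_difference(self):
        assert pathway_differences("TTT", "TTC") == (1.0, 0.0)

    def test_two_position_average(self):
        # TTT -> GTA: via GTT (nonsyn, then syn) or via TTA (nonsyn, nonsyn)
        assert pathway_differences("TTT", "GTA") == pytest.approx((0.5, 1.5))

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = rng.choice(SENSE, 2)
            assert pathway_differences(a, b) == pytest.approx(brute_pathways(a, b))

    def test_stop_blocked_pathway_excluded_from_average(self):
        # TGG (W) -> TCA (S): the route via TGA passes a stop and is
        # dropped, leaving only TGG -> TCG (nonsyn) -> TCA (syn).
        assert pathway_differences("TGG", "TCA") == pytest.approx((1.0, 1.0))
        assert brute_pathways("TGG", "TCA") == pytest.approx((1.0, 1.0))


class TestKaKs:
    def test_identical_pair_is_zero(self):
        aln = [("TTT", "TTT"), ("GGA", "GGA")]
        res = ng86_kaks(aln)
        assert (res.Ka, res.Ks, res.omega) == (0.0, 0.0, 0.0)

    def test_single_synonymous_difference_hand_count(self):
        codons = ["TTT"] * 99
        aln = [(c, c) for c in codons] + [("TTT", "TTC")]
        res = ng86_kaks(aln)
        S = sum(ng86_sites(c)[0] for c in codons + ["TTT"])  # per-seq sites
        # averaged S equals per-sequence S here (TTC has the same s)
        assert res.S == pytest.approx(S)
        assert res.Ka == 0.0
        pS = 1.0 / res.S
        assert res.Ks == pytest.approx(-0.75 * math.log(1 - 4 * pS / 3))
        assert res.omega == 0.0  # Ka = 0 with Ks > 0

    def test_omega_undefined_when_only_nonsynonymous(self):
        aln = [("ATG", "ATG")] * 50 + [("ATG", "ATT")]  # M -> I, nonsyn
        res = ng86_kaks(aln)
        assert res.Ks == 0.0 and res.Ka > 0
        assert res.omega is None

    def test_site_conservation_invariant(self):
        # mostly identical columns plus a few single-nucleotide changes
        rng = np.random.default_rng(1)
        aln = [(c, c) for c in rng.choice(SENSE, 30)]
        aln += [("TTT", "TTC"), ("ATG", "ATT"), ("GGA", "GGC")]
        res = ng86_kaks(aln)
        assert res.S + res.N == pytest.approx(3 * res.n_codons)

    def test_saturation_is_error(self):
        # a lone TTA/CTG pair: 2 synonymous differences over S = 1 site
        # on average, so pS = 2 >= 3/4 and the JC correction is undefined
        with pytest.raises(ValueError, match="Jukes-Cantor"):
            ng86_kaks([("TTA", "CTG")])


class TestThreading:
    def test_gapless_pair_expands_in_order(self):
        pairs = thread_codon_alignment("MKV", "MKV",
                                       "ATGAAAGTT", "ATGAAAGTA")
        assert pairs == [("ATG", "ATG"), ("AAA", "AAA"), ("GTT", "GTA")]

    def test_gap_column_excluded(self):
        pairs = thread_codon_alignment("M-V", "MKV", "ATGGTT", "ATGAAAGTT")
        assert pairs == [("ATG", "ATG"), ("GTT", "GTT")]

    def test_bad_cds_length_is_error(self):
        with pytest.raises(ValueError, match="3x"):
            thread_codon_alignment("MKV", "MKV", "ATGAAAGTTA", "ATGAAAGTT")

    def test_translation_mismatch_names_codon(self):
        with pytest.raises(ValueError, match="codon 1"):
            thread_codon_alignment("MKV", "MKV", "ATGCCCGTT", "ATGAAAGTT")

    def test_ambiguous_base_column_excluded(self):
        pairs = thread_codon_alignment("MKV", "MKV", "ATGAANGTT", "ATGAAAGTT")
        assert pairs == [("ATG", "ATG"), ("GTT", "GTT")]


class TestDivergenceTime:
    def test_zero(self):
        assert divergence_time(0.0) == (0.0, 0.0)

    def test_printed_rate_example(self):
        t_years, t_mya = divergence_time(0.013, 6.5e-9)
        assert t_years == pytest.approx(1.0e6)
        assert t_mya == pytest.approx(1.0)

    def test_linear_in_ks_and_inverse_in_lambda(self):
        t1, _ = divergence_time(0.1)
        t2, _ = divergence_time(0.2)
        assert t2 == pytest.approx(2 * t1)
        t3, _ = divergence_time(0.1, 1.3e-8)
        assert t3 == pytest.approx(t1 / 2)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)


def gene(gid, chrom, start, end):
    return GeneModel(gene_id=gid, chromosome=chrom, start=start, end=end,
                     strand="+")


class TestClassification:
    def test_close_same_chromosome_is_tandem(self):
        a, b = gene("a", "1", 0, 1000), gene("b", "1", 1_001_000, 1_002_000)
        assert classify_duplication(a, b) == "tandem"

    def test_distant_same_chromosome_is_segmental(self):
        a, b = gene("a", "1", 0, 1000), gene("b", "1", 6_001_000, 6_002_000)
        assert classify_duplication(a, b) == "segmental"

    def test_different_chromosomes_are_segmental(self):
        a, b = gene("a", "2", 0, 1000), gene("b", "7", 100, 1100)
        assert classify_duplication(a, b) == "segmental"

    def test_unknown_chromosome_is_segmental(self):
        a, b = gene("a", "0", 0, 1000), gene("b", "0", 100, 1100)
        assert classify_duplication(a, b) == "segmental"

    def test_nearest_edge_distance(self):
        a, b = gene("a", "1", 0, 1000), gene("b", "1", 1500, 2500)
        assert nearest_edge_distance(a, b) == 500
        assert nearest_edge_distance(b, a) == 500
        overlapping = gene("c", "1", 500, 1200)
        assert nearest_edge_distance(a, overlapping) == 0


class TestPairCalling:
    AA20 = "ACDEFGHIKLMNPQRSTVWY"

    def make_pair(self, n_mismatch):
        base = (self.AA20 * 50)[:1000]
        other = list(base)
        # substitutions spread evenly so the optimal alignment stays gapless
        positions = list(range(0, 1000, 5)) + list(range(1, 1000, 5))
        for pos in positions[:n_mismatch]:
            other[pos] = "A" if other[pos] != "A" else "G"
        return base, "".join(other)

    def test_identical_duplicates_called(self):
        seq = (self.AA20 * 3)[:50]
        pairs = call_paralog_pairs([SeqRecord("a", "a", seq),
                                    SeqRecord("b", "b", seq)])
        assert len(pairs) == 1 and pairs[0].identity == 1.0

    def test_borderline_identity_threshold(self):
        base, at_80 = self.make_pair(200)
        pairs = call_paralog_pairs([SeqRecord("a", "a", base),
                                    SeqRecord("b", "b", at_80)])
        assert len(pairs) == 1 and pairs[0].identity == pytest.approx(0.8)
        base, below = self.make_pair(201)
        pairs = call_paralog_pairs([SeqRecord("a", "a", base),
                                    SeqRecord("b", "b", below)])
        assert pairs == []

    def test_unrelated_proteins_not_called(self):
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list(self.AA20), 200))
        b = "".join(rng.choice(list(self.AA20), 200))
        assert call_paralog_pairs([SeqRecord("a", "a", a),
                                   SeqRecord("b", "b", b)]) == []


class TestReciprocalBestHits:
    def test_identical_proteomes_pair_up(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40))
                for _ in range(4)]
        pa = [SeqRecord(f"a{i}", f"a{i}", s) for i, s in enumerate(seqs)]
        pb = [SeqRecord(f"b{i}", f"b{i}", s) for i, s in enumerate(seqs)]
        hits = reciprocal_best_hits(pa, pb)
        assert hits == [(f"a{i}", f"b{i}") for i in range(4)]

    def test_known_mapping_recovered_with_decoys(self):
        rng = np.random.default_rng(4)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        ancestors = ["".join(rng.choice(aa, 60)) for _ in range(5)]

        def mutate(seq, k):
            s = list(seq)
            for pos in rng.choice(len(s), k, replace=False):
                s[pos] = rng.choice(aa)
            return "".join(s)

        pa = [SeqRecord(f"a{i}", f"a{i}", mutate(anc, 3))
              for i, anc in enumerate(ancestors)]
        pb = [SeqRecord(f"b{i}", f"b{i}", mutate(anc, 3))
              for i, anc in enumerate(ancestors)]
        hits = reciprocal_best_hits(pa, pb)
        assert hits == [(f"a{i}", f"b{i}") for i in range(5)]
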