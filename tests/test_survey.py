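import numpy as np
import pytest
from hypothesis import given, strategies as st

from genefam.core_io import GeneModel, SeqRecord
from genefam.survey import (AVERAGE_RESIDUE_MASS, PKA_EMBOSS, WATER_MASS,
                            DomainProfile, chromosome_distribution,
                            intron_count, isoelectric_point, molecular_weight,
                            reduce_redundancy, scan_domains, _net_charge)

AA = "ACDEFGHIKLMNPQRSTVWY"
aa_seq = st.text(alphabet=AA, min_size=1, max_size=30)


class TestMolecularWeight:
    def test_glycine(self):
        assert molecular_weight("G") == pytest.approx(0.0750672, abs=1e-6)

    def test_diglycine(self):
        assert molecular_weight("GG") == pytest.approx(0.1321191, abs=1e-6)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            molecular_weight("")

    def test_x_is_error(self):
        with pytest.raises(ValueError, match="X"):
            molecular_weight("GXG")

    @given(a=aa_seq, b=aa_seq)
    def test_additivity(self, a, b):
        lhs = molecular_weight(a + b)
        rhs = molecular_weight(a) + molecular_weight(b) - WATER_MASS / 1000
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_agrees_with_biopython(self):
        # independent implementation of the same average-mass convention
        from Bio.SeqUtils import molecular_weight as bio_mw
        seq = "MKVLINGKTLKGEITVEGAKNAALPIL"
        ours = molecular_weight(seq) * 1000
        theirs = bio_mw(seq, seq_type="protein")
        assert ours == pytest.approx(theirs, rel=1e-4)


class TestIsoelectricPoint:
    def test_residual_charge_below_tolerance(self):
        seq = "MKDEYRHACK"
        pi = isoelectric_point(seq)
        from collections import Counter
        assert abs(_net_charge(Counter(seq), pi, PKA_EMBOSS)) < 1e-4

    def test_basic_above_acidic(self):
        assert isoelectric_point("KKKKKK") > isoelectric_point("DDDDDD")

    def test_termini_only_matches_fine_grid_root(self):
        # GG has no ionisable side chains: root of the 2-term equation.
        # The solver stops on |charge| < 1e-4; the flat charge curve of a
        # 2-term peptide maps that to ~0.01 pH units of slack.
        grid = np.linspace(0, 14, 2_000_001)
        charge = (1 / (1 + 10 ** (grid - PKA_EMBOSS["Nterm"]))
                  - 1 / (1 + 10 ** (PKA_EMBOSS["Cterm"] - grid)))
        root = grid[np.argmin(np.abs(charge))]
        assert isoelectric_point("GG") == pytest.approx(root, abs=0.02)

    @given(seq=st.text(alphabet=AA, min_size=2, max_size=20))
    def test_permutation_invariance(self, seq):
        shuffled = "".join(sorted(seq))
        assert isoelectric_point(seq) == pytest.approx(
            isoelectric_point(shuffled), abs=1e-6)


class TestReduceRedundancy:
    def rec(self, id_, seq):
        return SeqRecord(id_, id_, seq)

    def test_identical_pair_collapses_at_cutoff_one(self):
        seq = "MKVLINGKTLKGEITVEGAK"
        kept, clusters = reduce_redundancy(
            [self.rec("a", seq), self.rec("b", seq)], 1.0)
        assert len(kept) == 1
        assert sorted(clusters[kept[0].id]) == ["a", "b"]

    def test_distant_pair_kept_at_high_cutoff(self):
        kept, _ = reduce_redundancy(
            [self.rec("a", "MKVLINGKTLKGEITVEGAK"),
             self.rec("b", "GHWDEPCRSTYFQNAMVLIK")], 0.9)
        assert len(kept) == 2

    def test_similar_pair_plus_outlier_gives_two_representatives(self):
        a = "MKVLINGKTLKGEITVEGAK"
        b = a[:-1] + "R"  # 19/20 identical
        c = "GHWDEPCRSTYFQNAMVLIK"
        kept, clusters = reduce_redundancy(
            [self.rec("a", a), self.rec("b", b), self.rec("c", c)], 0.9)
        assert len(kept) == 2
        rep = [k for k in clusters if len(clusters[k]) == 2][0]
        assert sorted(clusters[rep]) == ["a", "b"]

    def test_empty_input_is_empty_output(self):
        kept, clusters = reduce_redundancy([], 0.9)
        assert kept == [] and clusters == {}

    def test_order_independent(self):
        recs = [self.rec("a", "MKVLINGKTLKGEITVEGAK"),
                self.rec("b", "MKVLINGKTLKGEITVEGAR"),
                self.rec("c", "GHWDEPCRSTYFQNAMVLIK")]
        kept1, cl1 = reduce_redundancy(recs, 0.9)
        kept2, cl2 = reduce_redundancy(recs[::-1], 0.9)
        assert [r.id for r in kept1] == [r.id for r in kept2]
        assert cl1 == cl2


class TestScanDomains:
    CONS = "VLDEADRMLDMGF"

    def prof(self, min_score=None):
        return DomainProfile("DEXDC", self.CONS,
                             len(self.CONS) if min_score is None else min_score)

    def test_exact_consensus_scores_full_length(self):
        protein = SeqRecord("p", "p", "AAAA" + self.CONS + "WWWW")
        (hit,) = scan_domains(protein, [self.prof()])
        assert (hit.start, hit.end, hit.matches) == (4, 4 + len(self.CONS), len(self.CONS))

    def test_two_mismatches_found_with_relaxed_min_score(self):
        mutated = "IW" + self.CONS[2:]  # V->I and L->W: 2 mismatches
        protein = SeqRecord("p", "p", "GGGG" + mutated + "GGGG")
        hits = scan_domains(protein, [self.prof(len(self.CONS) - 2)])
        assert len(hits) == 1
        assert hits[0].matches == len(self.CONS) - 2

    def test_profile_longer_than_protein_gives_no_hit(self):
        protein = SeqRecord("p", "p", "MKV")
        assert scan_domains(protein, [self.prof()]) == []

    def test_unrelated_protein_has_no_hit(self):
        protein = SeqRecord("p", "p", "KKKKKKKKKKKKKKKKKKKKKKKK")
        assert scan_domains(protein, [self.prof(len(self.CONS) - 2)]) == []

    def test_x_in_consensus_matches_anything(self):
        profile = DomainProfile("P", "AXAXA", 5)
        protein = SeqRecord("p", "p", "GGAWACAGG")
        (hit,) = scan_domains(protein, [profile])
        assert hit.start == 2


class TestDistributionAndIntrons:
    def gene(self, gid, chrom, n_exons=1):
        exons = [(i * 200, i * 200 + 100) for i in range(n_exons)]
        return GeneModel(gene_id=gid, chromosome=chrom, start=0,
                         end=max(e for _, e in exons), strand="+", exons=exons)

    def test_even_split_is_fifty_fifty(self):
        genes = [self.gene(f"a{i}", "A") for i in range(4)] + \
                [self.gene(f"b{i}", "B") for i in range(4)]
        dist = chromosome_distribution(genes)
        assert dist.percents == {"A": 50, "B": 50}

    def test_percentages_sum_to_about_hundred(self):
        genes = [self.gene(f"g{i}", str(i % 3 + 1)) for i in range(7)]
        dist = chromosome_distribution(genes)
        assert abs(sum(dist.percents.values()) - 100) <= 1

    def test_unassigned_reported_separately(self):
        genes = [self.gene("g1", "1"), self.gene("g2", "0")]
        dist = chromosome_distribution(genes)
        assert dist.unassigned == 1
        assert dist.counts == {"1": 1}
        assert dist.percents == {"1": 100}

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            chromosome_distribution([])

    @pytest.mark.parametrize("n_exons,expected", [(1, 0), (3, 2), (34, 33)])
    def test_intron_count(self, n_exons, expected):
        assert intron_count(self.gene("g", "1", n_exons)) == expected

    def test_no_exons_is_error(self):
        g = GeneModel(gene_id="g", chromosome="1", start=0, end=10, strand="+")
        with pytest.raises(ValueError):
            intron_count(g)
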