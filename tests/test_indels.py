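"""Tests of indel normalisation, aging, and flank characterisation."""

import math

import numpy as np
import pandas as pd
import pytest

from mutspect.indels import (
    IndelRecord,
    age_indels,
    build_indel_records,
    coding_fraction_by_age,
    flank_base_composition,
    from_variant,
    left_normalize,
    str_adjacency,
)
from mutspect.pipeline import RunConfig, aged_indels, analyze_cohort
from mutspect.simulate import SimulationConfig
from mutspect.spectrum import EffectClassifier

from conftest import make_record


class TestLeftNormalize:
    def test_deletion_shifts_through_homopolymer(self):
        assert left_normalize("GAAAAC", 4, "AA", "A") == (1, "GA", "G")

    def test_insertion_shifts_through_homopolymer(self):
        assert left_normalize("GTTC", 3, "T", "TT") == (1, "G", "GT")

    def test_already_leftmost_unchanged(self):
        assert left_normalize("GATTC", 2, "AT", "A") == (2, "AT", "A")

    def test_common_suffix_trimmed(self):
        # GAT -> GT written as pos1 GAT>GT: trailing T shared
        assert left_normalize("GATC", 1, "GAT", "GT") == (1, "GA", "G")


class TestIndelRecords:
    def _genome(self):
        return {"chr1": "ACGTGATTACAGATTACAGT" + "A" * 20 + "CGTACGTACG"}

    def test_flanks_and_anchor_deletion(self):
        g = {"chr1": "TTTTTTTTTTGCATCGATCGA" + "CCCCCCCCCC"}
        # delete "CA" at positions 12-13: record pos 11, ref GCA, alt G
        rec = make_record(pos=11, ref="GCA", alt="G")
        ind = from_variant(rec, "s0", g)
        assert ind.length == -2
        assert ind.anchor == 12
        assert ind.flank_5p == g["chr1"][1:11]    # ten bases ending at pos 11
        assert ind.flank_3p == g["chr1"][13:23]   # ten bases after the run

    def test_flanks_insertion(self):
        g = {"chr1": "ACGTACGTACGTACGTACGTACGT"}
        rec = make_record(pos=12, ref="T", alt="TGG")
        ind = from_variant(rec, "s0", g)
        assert ind.length == 2
        assert ind.flank_5p == g["chr1"][2:12]
        assert ind.flank_3p == g["chr1"][12:22]

    def test_near_edge_dropped(self):
        g = {"chr1": "ACGTACGTACGTACGTACGT"}
        rec = make_record(pos=3, ref="GT", alt="G")
        recs, n_dropped = build_indel_records([rec], g)
        assert recs == [] and n_dropped == 1

    def test_only_singletons_kept(self):
        g = self._genome()
        shared = make_record(pos=12, ref="GA", alt="G", carriers=(0, 1))
        single = make_record(pos=12, ref="GA", alt="G", carriers=(2,))
        recs, _ = build_indel_records([shared, single], g)
        assert len(recs) == 1 and recs[0].carrier == "s2"


def _indel(age=None, flank_5p="GCATCGATCG", flank_3p="CGATCGATGC", **kw):
    defaults = dict(chrom="chr1", pos=100, ref="GA", alt="G", carrier="s0",
                    length=-1, anchor=101)
    defaults.update(kw)
    return IndelRecord(flank_5p=flank_5p, flank_3p=flank_3p, age=age,
                       **defaults)


class TestAging:
    def test_density_examples(self):
        two = [_indel(pos=100 + i, anchor=101 + i) for i in range(2)]
        aged = age_indels(two, {"chr1": 1_000_000})
        assert all(r.age == pytest.approx(0.002) for r in aged)
        one = age_indels([_indel()], {"chr1": 200_000})
        assert one[0].age == pytest.approx(0.005)

    def test_empty(self):
        assert age_indels([], {"chr1": 100_000}) == []

    def test_separate_ledger_from_snps(self, neutral_cohort):
        """Indel ages are densities of indel singletons alone."""
        ind = aged_indels(neutral_cohort)
        groups = {}
        for r in ind:
            groups.setdefault((r.carrier, r.chrom), []).append(r)
        for (_, chrom), members in groups.items():
            expected = len(members) / (
                neutral_cohort.chromosome_lengths[chrom] / 1000
            )
            assert all(r.age == pytest.approx(expected) for r in members)


class TestFlankComposition:
    def test_all_a_flanks(self):
        rec = _indel(flank_5p="A" * 10, flank_3p="A" * 10)
        comp = flank_base_composition([rec])
        assert (comp["A"] == 1.0).all()
        assert (comp[["C", "G", "T"]].to_numpy() == 0).all()

    def test_rows_sum_to_one(self, neutral_cohort):
        ind = aged_indels(neutral_cohort)
        comp = flank_base_composition(ind)
        assert np.allclose(comp.sum(axis=1), 1.0)
        assert list(comp.index) == list(range(-10, 0)) + list(range(1, 11))


class TestStrAdjacency:
    def test_run_touching_boundary(self):
        rec = _indel(flank_3p="AAAAAATCGG", flank_5p="GCATCGATCG")
        table = str_adjacency([rec])
        # the 6-A run touches the boundary: counted for every m <= 6
        assert (table.loc[1:6, "A"] == 1.0).all()
        assert (table.loc[7:, "A"] == 0.0).all()

    def test_alternating_flank_only_m1(self):
        rec = _indel(flank_5p="ACGTACGTAC", flank_3p="ACGTACGTAC")
        table = str_adjacency([rec])
        assert (table.loc[2:].to_numpy() == 0.0).all()
        # the bases actually touching the boundary count at m = 1
        assert table.loc[1, "A"] == 1.0 and table.loc[1, "C"] == 1.0

    def test_window_mode_sees_interior_runs(self):
        rec = _indel(flank_5p="GCATCGATCG", flank_3p="CGTTTTTTAC")
        touching = str_adjacency([rec])
        window = str_adjacency([rec], mode="window")
        assert touching.loc[6, "T"] == 0.0
        assert window.loc[6, "T"] == 1.0

    def test_nonincreasing_in_m(self, neutral_cohort):
        ind = aged_indels(neutral_cohort)
        table = str_adjacency(ind)
        arr = table.to_numpy()
        assert ((arr >= 0) & (arr <= 1)).all()
        assert (np.diff(arr, axis=0) <= 1e-12).all()

    def test_uniform_genome_matches_geometric_baseline(self):
        """On an iid uniform genome the chance that a flank starts with a
        run of >= m copies of one base is (1/4)^m per side."""
        sim = SimulationConfig(
            chromosome_lengths=(120_000,), gc_content=0.5, coding_fraction=0.0,
            mutations_per_kb_total_depth=4.0, indel_rate_relative=1.2,
            selection_halflife=math.inf, indel_selection_halflife=math.inf,
            seed=19,
        )
        cohort = analyze_cohort(RunConfig(simulation=sim, n_boot=0))
        ind = aged_indels(cohort)
        n = len(ind)
        assert n >= 150
        table = str_adjacency(ind)
        for m in (1, 2, 3):
            q = 0.25 ** m
            p = 1 - (1 - q) ** 2  # either flank
            sd = math.sqrt(p * (1 - p) / n)
            for base in "ACGT":
                assert abs(table.loc[m, base] - p) <= 4 * sd + 0.01


class TestCodingFraction:
    def _classifier(self):
        genome = {"chr1": "A" * 30 + "ATGAAATTTCCCGGGTAA" + "A" * 52}
        ann = pd.DataFrame(
            [{"chrom": "chr1", "start": 31, "end": 48, "strand": "+"}]
        )
        return EffectClassifier(genome, ann)

    def test_fraction_arithmetic(self):
        clf = self._classifier()
        coding = [_indel(anchor=35 + i, age=0.001) for i in range(2)]
        noncoding = [_indel(anchor=60 + i, age=0.001) for i in range(8)]
        out = coding_fraction_by_age(coding + noncoding, clf,
                                     age_edges=[0.002])
        assert out.coding_fraction.iloc[0] == pytest.approx(0.20)
        assert out.n.iloc[0] == 10 and out.n.iloc[1] == 0
        assert np.isnan(out.coding_fraction.iloc[1])

    def test_all_noncoding(self):
        clf = self._classifier()
        recs = [_indel(anchor=60 + i, age=0.01) for i in range(5)]
        out = coding_fraction_by_age(recs, clf, age_edges=[0.002])
        assert out.coding_fraction.iloc[1] == 0.0

    def test_no_selection_recovers_coding_fraction(self, neutral_cohort):
        """Without selection the coding fraction of indels tracks the
        genomic coding fraction (~0.70) in every age class."""
        ind = aged_indels(neutral_cohort)
        out = coding_fraction_by_age(ind, neutral_cohort.classifier, n_bins=3)
        target = 0.70
        for _, row in out.iterrows():
            sd = math.sqrt(target * (1 - target) / row.n)
            assert abs(row.coding_fraction - target) <= 4 * sd

    def test_unaged_indels_rejected(self):
        with pytest.raises(ValueError):
            coding_fraction_by_age([_indel()], self._classifier())


class TestReverseComplementConsistency:
    def test_flanks_swap_and_complement(self):
        """Analysing the reverse-complemented genome swaps 5'/3' flanks and
        complements bases (indel placed away from homopolymers so the
        normalised anchor is unambiguous)."""
        from mutspect.spectrum import revcomp

        seq = "GCATCGATCGTAGCTAGCATGCATCGACTG"
        g = {"chr1": seq}
        rec = make_record(pos=13, ref="GC", alt="G")  # delete C at 14
        fwd = from_variant(rec, "s0", g)
        L = len(seq)
        g_rc = {"chr1": revcomp(seq)}
        # the same physical deletion in the flipped coordinate system
        pos_rc = L - 14  # base left of the deleted run in new coordinates
        ref_rc = g_rc["chr1"][pos_rc - 1:pos_rc + 1]
        rec_rc = make_record(pos=pos_rc, ref=ref_rc, alt=ref_rc[0])
        rev = from_variant(rec_rc, "s0", g_rc)
        assert rev.flank_5p == revcomp(fwd.flank_3p)
        assert rev.flank_3p == revcomp(fwd.flank_5p)
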