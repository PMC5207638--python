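"""Tests of effect classification, selection signatures, and rate tables."""

import math

import numpy as np
import pandas as pd
import pytest

from mutspect.pipeline import RunConfig, analyze_cohort
from mutspect.simulate import MutationSpectrum, SimulationConfig
from mutspect.spectrum import (
    CLASSES6,
    CONTEXTS32,
    AnnotationError,
    EffectClassifier,
    UndefinedStatisticError,
    annotate_snp_frame,
    at_gc_site_counts,
    bootstrap_se,
    collapse_change,
    compare_rates,
    context_rates_32,
    context_site_counts,
    gc_equilibrium,
    neutral_pn_expectation,
    percent_nonsynonymous,
    relative_rates_6class,
    revcomp,
    signatures_by_bin,
    ts_tv_ratio,
)

# a plus-strand gene ATG AAA TGG TAA at positions 5..16
PLUS_GENOME = {"chr1": "CCCC" + "ATGAAATGGTAA" + "GGGG"}
PLUS_ANN = pd.DataFrame(
    [{"chrom": "chr1", "start": 5, "end": 16, "strand": "+"}]
)
# a minus-strand gene whose mRNA is ATG AAA TAA, at positions 3..11
MINUS_GENOME = {"chr2": "AA" + "TTATTTCAT" + "CC"}
MINUS_ANN = pd.DataFrame(
    [{"chrom": "chr2", "start": 3, "end": 11, "strand": "-"}]
)


class TestEffectClassification:
    @pytest.mark.parametrize("pos,ref,alt,expected", [
        (10, "A", "G", "synonymous"),     # AAA -> AAG, Lys -> Lys
        (10, "A", "T", "nonsynonymous"),  # AAA -> AAT, Lys -> Asn
        (13, "G", "A", "nonsense"),       # TGG -> TGA, Trp -> stop
        (2, "C", "T", "noncoding"),
    ])
    def test_plus_strand(self, pos, ref, alt, expected):
        clf = EffectClassifier(PLUS_GENOME, PLUS_ANN)
        assert clf.classify("chr1", pos, ref, alt) == expected

    def test_minus_strand_codon_read_on_coding_strand(self):
        clf = EffectClassifier(MINUS_GENOME, MINUS_ANN)
        # genomic T>C at pos 6 is AAA -> AAG on the coding strand
        assert clf.classify("chr2", 6, "T", "C") == "synonymous"
        # genomic T>A at pos 8 is first base of codon 2: AAA -> TAA (stop)
        assert clf.classify("chr2", 8, "T", "A") == "nonsense"

    def test_bad_interval_length_raises(self):
        ann = pd.DataFrame(
            [{"chrom": "chr1", "start": 5, "end": 14, "strand": "+"}]
        )
        with pytest.raises(AnnotationError):
            EffectClassifier(PLUS_GENOME, ann)

    def test_reference_mismatch_raises(self):
        clf = EffectClassifier(PLUS_GENOME, PLUS_ANN)
        with pytest.raises(AnnotationError):
            clf.classify("chr1", 10, "C", "G")


class TestNeutralPn:
    def test_exclude_nonsense_convention(self):
        value = neutral_pn_expectation("exclude_nonsense")
        assert value == pytest.approx(392 / 526)
        assert round(value, 2) == 0.75

    def test_nonsense_as_nonsyn_convention(self):
        value = neutral_pn_expectation("nonsense_as_nonsyn")
        assert value == pytest.approx(415 / 549)
        assert round(value, 2) == 0.76

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            neutral_pn_expectation("bogus")


def _frame(effects=None, classes=None):
    """Annotated frame from lists of effects and/or (ref, alt) pairs."""
    n = len(effects) if effects is not None else len(classes)
    pairs = classes or [("A", "G")] * n
    df = pd.DataFrame({
        "chrom": ["chr1"] * n,
        "pos": np.arange(1, n + 1) * 10,
        "ref": [p[0] for p in pairs],
        "alt": [p[1] for p in pairs],
    })
    df = annotate_snp_frame(df)
    if effects is not None:
        df["effect"] = effects
    return df


class TestSignatureStatistics:
    def test_percent_nonsynonymous(self):
        df = _frame(["nonsynonymous"] * 75 + ["synonymous"] * 25)
        assert percent_nonsynonymous(df) == pytest.approx(0.75)
        assert percent_nonsynonymous(_frame(["synonymous"] * 10)) == 0.0
        assert percent_nonsynonymous(_frame(["nonsynonymous"] * 10)) == 1.0

    def test_pn_nonsense_conventions(self):
        df = _frame(["nonsynonymous"] * 6 + ["synonymous"] * 3 + ["nonsense"])
        assert percent_nonsynonymous(df) == pytest.approx(6 / 9)
        assert percent_nonsynonymous(
            df, convention="nonsense_as_nonsyn"
        ) == pytest.approx(7 / 10)

    def test_pn_undefined_without_coding_variants(self):
        with pytest.raises(UndefinedStatisticError):
            percent_nonsynonymous(_frame(["noncoding"] * 5))

    def test_ts_tv_examples(self):
        ts, tv = ("A", "G"), ("A", "T")
        assert ts_tv_ratio(_frame(classes=[ts] * 10 + [tv] * 10)) == 1.0
        assert ts_tv_ratio(_frame(classes=[ts] * 25 + [tv] * 10)) == 2.5
        assert ts_tv_ratio(_frame(classes=[tv] * 10)) == 0.0
        with pytest.raises(UndefinedStatisticError):
            ts_tv_ratio(_frame(classes=[ts] * 10))

    def test_gc_equilibrium(self):
        to_gc, to_at = ("T", "C"), ("C", "T")
        sym = _frame(classes=[to_gc] * 20 + [to_at] * 20)
        assert gc_equilibrium(sym, 100, 100) == pytest.approx(50.0)
        df = _frame(classes=[to_gc] * 32 + [to_at] * 68)
        assert gc_equilibrium(df, 100, 100) == pytest.approx(32.0)
        assert gc_equilibrium(_frame(classes=[to_at] * 5), 100, 100) == 0.0
        with pytest.raises(UndefinedStatisticError):
            gc_equilibrium(_frame(classes=[("C", "G")] * 5), 100, 100)

    def test_gc_equilibrium_fixed_point(self):
        """At mutational equilibrium the fluxes balance (v*AT = u*GC), so
        equal opposing counts on a 32% GC genome estimate GCeqm = 32%."""
        to_gc, to_at = ("A", "G"), ("G", "A")
        df = _frame(classes=[to_gc] * 40 + [to_at] * 40)
        assert gc_equilibrium(df, at_sites=680, gc_sites=320) == pytest.approx(32.0)


class TestBootstrap:
    def test_identical_data_zero_se(self):
        df = _frame(["nonsynonymous"] * 30)
        assert bootstrap_se(df, percent_nonsynonymous, seed=1) == 0.0

    def test_seeded_reproducibility(self):
        df = _frame(["nonsynonymous"] * 30 + ["synonymous"] * 20)
        a = bootstrap_se(df, percent_nonsynonymous, seed=5)
        b = bootstrap_se(df, percent_nonsynonymous, seed=5)
        assert a == b and a > 0

    def test_pn_se_close_to_binomial(self):
        df = _frame(["nonsynonymous"] * 50 + ["synonymous"] * 50)
        se = bootstrap_se(df, percent_nonsynonymous, n_boot=500, seed=0)
        binomial = math.sqrt(0.5 * 0.5 / 100)
        assert abs(se - binomial) / binomial < 0.20


class TestRateTables:
    def test_six_class_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 2_000))}
        seq = genome["chr1"]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rows = []
        for _ in range(300):
            pos = int(rng.integers(1, 2_001))
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append({"chrom": "chr1", "pos": pos, "ref": ref, "alt": alt})
        df = pd.DataFrame(rows)
        table = relative_rates_6class(df, genome, n_boot=0)
        # independent site-by-site tally
        counts = dict.fromkeys(CLASSES6, 0)
        for r in rows:
            ref, alt = r["ref"], r["alt"]
            if ref in "AG":
                ref, alt = comp[ref], comp[alt]
            counts[f"{ref}>{alt}"] += 1
        n_gc = sum(seq.count(b) for b in "CG")
        n_at = sum(seq.count(b) for b in "AT")
        per_site = {
            k: counts[k] / (n_gc if k[0] == "C" else n_at) for k in CLASSES6
        }
        total = sum(per_site.values())
        for k in CLASSES6:
            assert table.loc[k, "count"] == counts[k]
            assert table.loc[k, "rate"] == pytest.approx(per_site[k] / total)
        assert table["rate"].sum() == pytest.approx(1.0)

    def test_removing_a_class_renormalizes(self):
        genome = {"chr1": "ACGT" * 500}
        classes = [("C", "T")] * 30 + [("T", "G")] * 50 + [("C", "G")] * 20
        df = _frame(classes=classes)
        full = relative_rates_6class(df, genome, n_boot=0)
        reduced = relative_rates_6class(
            df[df["mut_class"] != "C>G"], genome, n_boot=0
        )
        assert reduced.loc["C>G", "rate"] == 0.0
        kept = [k for k in CLASSES6 if k != "C>G"]
        expected = full.loc[kept, "rate"] / full.loc[kept, "rate"].sum()
        assert np.allclose(reduced.loc[kept, "rate"], expected)

    def test_strand_collapse_involution(self):
        """Reverse-complementing the genome and flipping alleles leaves every
        rate table unchanged."""
        rng = np.random.default_rng(8)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 3_000))}
        seq = genome["chr1"]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rows = []
        for _ in range(400):
            pos = int(rng.integers(2, 3_000))
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append({"chrom": "chr1", "pos": pos, "ref": ref, "alt": alt})
        df = pd.DataFrame(rows)
        genome_rc = {"chr1": revcomp(seq)}
        df_rc = pd.DataFrame([
            {"chrom": "chr1", "pos": 3_000 - r["pos"] + 1,
             "ref": comp[r["ref"]], "alt": comp[r["alt"]]}
            for r in rows
        ])
        t6 = relative_rates_6class(df, genome, n_boot=0)
        t6_rc = relative_rates_6class(df_rc, genome_rc, n_boot=0)
        pd.testing.assert_frame_equal(t6, t6_rc)
        t32 = context_rates_32(df, genome, n_boot=0)
        t32_rc = context_rates_32(df_rc, genome_rc, n_boot=0)
        pd.testing.assert_frame_equal(t32, t32_rc)

    def test_context_counts_cover_genome(self):
        genome = {"chr1": "ACGTACGTAC"}
        counts = context_site_counts(genome)
        assert sum(counts.values()) == 8  # all interior sites
        assert set(counts) == set(CONTEXTS32)

    def test_uniform_simulation_contexts_binomial(self, neutral_cohort):
        """With no context modifiers, per-context counts are binomial draws
        proportional to context occurrences within each source base."""
        df = annotate_snp_frame(
            pd.DataFrame(
                [{"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt}
                 for r in neutral_cohort.snps]
            ),
            genome=neutral_cohort.genome,
        )
        table = context_rates_32(df, neutral_cohort.genome, n_boot=0)
        occ = table["sites"]
        for focal in "CT":
            keys = [k for k in CONTEXTS32 if k[1] == focal]
            n_src = int(table.loc[keys, "count"].sum())
            occ_total = int(occ[keys].sum())
            for k in keys:
                p = occ[k] / occ_total
                expected = n_src * p
                sd = math.sqrt(n_src * p * (1 - p))
                assert abs(table.loc[k, "count"] - expected) <= 4 * sd

    def test_context_modifier_recovery(self):
        """A 5x site weight at CCG elevates that environment's relative rate
        about fivefold over the other C-focal environments."""
        spectrum = MutationSpectrum(
            {k: 1 / 6 for k in CLASSES6}, context_modifiers={"CCG": 5.0}
        )
        sim = SimulationConfig(
            chromosome_lengths=(150_000,), gc_content=0.5, coding_fraction=0.0,
            mutations_per_kb_total_depth=80.0, spectrum=spectrum,
            indel_rate_relative=0.0, selection_halflife=math.inf, seed=13,
        )
        cohort = analyze_cohort(RunConfig(simulation=sim, n_boot=0))
        df = annotate_snp_frame(
            pd.DataFrame(
                [{"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt}
                 for r in cohort.snps]
            ),
            genome=cohort.genome,
        )
        table = context_rates_32(df, cohort.genome, n_boot=0)
        others = [k for k in CONTEXTS32 if k[1] == "C" and k != "CCG"]
        per_site = table["count"] / table["sites"]
        ratio = per_site["CCG"] / per_site[others].mean()
        assert 3.5 < ratio < 6.5


class TestCompareRates:
    def _table(self, counts):
        return pd.DataFrame(
            {"count": counts, "sites": [1_000] * len(counts),
             "rate": np.asarray(counts) / sum(counts),
             "se": [0.0] * len(counts)},
            index=pd.Index([f"c{i}" for i in range(len(counts))], name="class"),
        )

    def test_identical_tables(self):
        t = self._table([10, 20, 30])
        out = compare_rates(t, t)
        assert np.allclose(out["z"], 0.0)
        assert np.allclose(out["p"], 1.0)

    def test_hand_computed_two_proportion_z(self):
        a = self._table([30, 70])
        b = self._table([10, 90])
        out = compare_rates(a, b)
        p1, p2, pp = 0.30, 0.10, 0.20
        z = (p1 - p2) / math.sqrt(pp * (1 - pp) * (1 / 100 + 1 / 100))
        assert out.loc["c0", "z"] == pytest.approx(z)
        assert out.loc["c0", "p_adj"] == pytest.approx(
            min(1.0, 2 * out.loc["c0", "p"])
        )

    def test_bonferroni_arithmetic(self):
        a = self._table([10, 10, 10, 10, 10, 10])
        b = self._table([20, 10, 10, 10, 5, 5])
        out = compare_rates(a, b)
        assert np.allclose(out["p_adj"], np.minimum(1.0, 6 * out["p"]))

    def test_mismatched_keys_raise(self):
        with pytest.raises(ValueError):
            compare_rates(self._table([1, 2]), self._table([1, 2, 3]))


class TestSignaturesByBin:
    def test_single_bin_table(self):
        df = _frame(["nonsynonymous"] * 10 + ["synonymous"] * 5)
        out = signatures_by_bin([("all", df)], 100, 100, n_boot=20)
        assert len(out) == 1
        assert out.loc[0, "pn"] == pytest.approx(10 / 15)

    def test_undefined_cells_are_nan_not_dropped(self):
        coding = _frame(["nonsynonymous"] * 5)
        noncoding = _frame(["noncoding"] * 5)
        out = signatures_by_bin(
            [("a", coding), ("b", noncoding)], 100, 100, n_boot=20
        )
        assert len(out) == 2
        assert np.isnan(out.loc[1, "pn"])

    def test_site_counts_from_genome(self):
        at, gc = at_gc_site_counts({"chr1": "AACCGGTT"})
        assert (at, gc) == (4, 4)
        at, gc = at_gc_site_counts(
            {"chr1": "AACCGGTT"}, mask_intervals=[("chr1", 0, 4)]
        )
        assert (at, gc) == (2, 2)


def test_collapse_change_examples():
    assert collapse_change("G", "A") == "C>T"
    assert collapse_change("C", "T") == "C>T"
    assert collapse_change("A", "C") == "T>G"
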