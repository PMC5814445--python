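"""Lesion-integration tests: genotypes, GOF/LOF, prevalence, categories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lesionscope.integrate import (
    CATEGORY_NAMES,
    CaseLesionProfile,
    GenotypeClass,
    Mutation,
    call_gof_lof,
    cellular_prevalence,
    classify_genotype,
    cohort_frequency,
    gene_landscape,
    lesional_categories,
)


class TestGenotype:
    def test_loh(self):
        cls = classify_genotype(1.3, [Mutation(vaf=0.6)])
        assert cls is GenotypeClass.LOH

    def test_vaf_threshold_strict(self):
        cls = classify_genotype(2.0, [Mutation(vaf=0.15)])
        assert cls is GenotypeClass.BIALLELIC_UNMUTATED
        assert classify_genotype(2.0, [Mutation(vaf=0.2)]) \
            is GenotypeClass.BIALLELIC_UNMUTATED     # exactly 20% not above
        assert classify_genotype(2.0, [Mutation(vaf=0.21)]) \
            is GenotypeClass.BIALLELIC_MUTATED

    def test_unmutated_classes(self):
        assert classify_genotype(2.0, []) is GenotypeClass.BIALLELIC_UNMUTATED
        assert classify_genotype(1.2, []) \
            is GenotypeClass.MONOALLELIC_UNMUTATED

    def test_upd_mutated(self):
        assert classify_genotype(2.0, [Mutation(vaf=0.5)], upd=True) \
            is GenotypeClass.UPD_MUTATED
        assert classify_genotype(2.0, [Mutation(vaf=0.5)], upd=False) \
            is GenotypeClass.BIALLELIC_MUTATED

    def test_gap_assignment_nearest_boundary(self):
        # (1.5, 1.7) goes to the monoallelic side, [1.7, 1.9) biallelic
        assert classify_genotype(1.6, [Mutation(vaf=0.5)]) \
            is GenotypeClass.LOH
        assert classify_genotype(1.8, [Mutation(vaf=0.5)]) \
            is GenotypeClass.BIALLELIC_MUTATED

    def test_partition_property(self, rng):
        """Every fully observed gene/case pair gets exactly one class."""
        for _ in range(200):
            cn = float(rng.uniform(0.5, 4.0))
            muts = [Mutation(vaf=float(rng.uniform(0, 1)))
                    for _ in range(rng.integers(0, 3))]
            cls = classify_genotype(cn, muts, upd=bool(rng.random() < 0.2))
            assert isinstance(cls, GenotypeClass)

    def test_missing_cn_is_error(self):
        with pytest.raises(ValueError):
            classify_genotype(float("nan"), [])


class TestGofLof:
    @pytest.mark.parametrize("cn,vaf,expected", [
        (2.5, 0.6, "GOF"),
        (1.6, 0.6, "LOF"),
        (2.0, 0.9, "none"),    # neutral CN
        (2.5, 0.5, "none"),    # VAF not strictly above 0.5
        (2.5, 0.0, "none"),
    ])
    def test_calls(self, cn, vaf, expected):
        muts = [Mutation(vaf=vaf)] if vaf > 0 else []
        assert call_gof_lof(cn, muts) == expected

    def test_mutual_exclusivity(self, rng):
        for _ in range(200):
            cn = float(rng.uniform(0.5, 4))
            muts = [Mutation(vaf=float(rng.uniform(0, 1)))]
            assert call_gof_lof(cn, muts) in ("GOF", "LOF", "none")


class TestPrevalence:
    @pytest.mark.parametrize("vaf,cn,purity,expected", [
        (0.5, 2.0, 1.0, 1.0),
        (0.25, 2.0, 1.0, 0.5),
        (0.5, 2.0, 0.98, 1.0),    # 1.0204 clipped to 1
    ])
    def test_formula(self, vaf, cn, purity, expected):
        assert cellular_prevalence(vaf, cn, purity) == pytest.approx(expected)

    def test_reduces_to_twice_vaf_when_diploid_pure(self, rng):
        for _ in range(50):
            vaf = float(rng.uniform(0, 0.5))
            assert cellular_prevalence(vaf, 2.0, 1.0) == pytest.approx(
                2 * vaf)

    def test_zero_purity_error(self):
        with pytest.raises(ValueError):
            cellular_prevalence(0.3, 2.0, 0.0)


class TestCooccurrence:
    def test_hand_computed_or(self):
        from lesionscope.integrate import cooccurrence_test
        a = [True] * 24 + [True] * 13 + [False] * 7 + [False] * 10
        b = [True] * 24 + [False] * 13 + [True] * 7 + [False] * 10
        oddsr, p = cooccurrence_test(a, b)
        assert oddsr == pytest.approx(24 * 10 / (13 * 7))
        # cross-check p against scipy directly
        assert p == pytest.approx(
            stats.fisher_exact([[24, 13], [7, 10]])[1])

    def test_identical_flags_significant(self):
        from lesionscope.integrate import cooccurrence_test
        flags = [True] * 10 + [False] * 10
        _, p = cooccurrence_test(flags, flags)
        assert p < 0.001

    def test_symmetry_and_inversion(self, rng):
        from lesionscope.integrate import cooccurrence_test
        a = rng.random(40) < 0.5
        b = rng.random(40) < 0.5
        or1, p1 = cooccurrence_test(a, b)
        or2, p2 = cooccurrence_test(b, a)
        assert p1 == pytest.approx(p2)
        assert or1 == pytest.approx(or2)
        or_neg, _ = cooccurrence_test(a, ~b)
        if np.isfinite(or1) and np.isfinite(or_neg) and \
                min(or1, or_neg) > 0:
            # without zero-cell correction these would be exact inverses
            pass

    def test_null_calibration(self, rng):
        from lesionscope.integrate import cooccurrence_test
        n_sig = 0
        reps = 1000
        for _ in range(reps):
            a = rng.random(30) < 0.4
            b = rng.random(30) < 0.4
            _, p = cooccurrence_test(a, b)
            n_sig += p < 0.05
        assert n_sig / reps <= 0.07

    def test_constant_flag_or_undefined(self):
        from lesionscope.integrate import cooccurrence_test
        oddsr, p = cooccurrence_test([True] * 5, [True, False] * 2 + [True])
        assert np.isnan(oddsr)


def make_profile(case_id, **kw):
    return CaseLesionProfile(case_id=case_id, **kw)


GENE_SETS = {"epigenetic": {"EZH2", "KAT6B"}, "ddr": {"ATM", "TP53"}}


class TestCategories:
    def test_all_platforms_missing_is_masked(self):
        p = make_profile("T1", platforms={"cn": False, "mutation": False,
                                          "expression": False})
        mat, ordering, freqs = lesional_categories([p], GENE_SETS)
        assert mat.loc["T1"].isna().all()
        assert all(np.isnan(f) for f in freqs)

    def test_unanimous_category(self):
        profiles = [
            make_profile(f"T{i}", cn={"ATM": 1.2}, mutations={})
            for i in range(5)]
        mat, _, freqs = lesional_categories(profiles, GENE_SETS)
        assert mat["ATM"].all()
        assert freqs["ATM"] == 100.0

    def test_ordering_by_call_count(self):
        p1 = make_profile("T1", cn={"ATM": 1.2, "AGO2": 3.0, "MYC": 3.0})
        p2 = make_profile("T2", cn={"ATM": 1.2})
        p3 = make_profile("T3", cn={})
        mat, ordering, _ = lesional_categories([p3, p1, p2], GENE_SETS)
        counts = (mat == True).sum(axis=1)  # noqa: E712
        assert ordering == sorted(
            mat.index, key=lambda c: (-counts[c], c))
        assert ordering[0] == "T1"

    def test_category_semantics(self):
        p = make_profile(
            "T1", cn={"AGO2": 3.1, "MYC": 2.0},
            mutations={"JAK3": [Mutation(vaf=0.4)]},
            upd={"AGO1": True},
            expression_fc={"TCL1A": 5.0, "EZH2": 2.0})
        mat, _, _ = lesional_categories([p], GENE_SETS)
        row = mat.loc["T1"]
        assert row["TCL1_MTCP1"] and row["AGO2_sCNA"]
        assert row["AGO134_UPD"] and row["JAK_STAT_mut"]
        assert row["epigenetic_DE"]
        assert not row["MYC"]
        assert list(mat.columns) == list(CATEGORY_NAMES)

    def test_missing_gene_set_error(self):
        with pytest.raises(ValueError):
            lesional_categories([make_profile("T1")], {"epigenetic": set()})


class TestLandscape:
    def test_row_oracle(self):
        profiles = [
            make_profile("T1", cn={"ATM": 1.5},
                         mutations={"ATM": [Mutation(vaf=0.7)]}),
            make_profile("T2", cn={"ATM": 2.0}),
            make_profile("T3", cn={"ATM": 2.5},
                         mutations={"ATM": [Mutation(vaf=0.3)]}),
        ]
        out = gene_landscape(profiles)
        row = out.loc["ATM"]
        assert row["cn_mean"] == pytest.approx(2.0)
        assert row["mean_vaf"] == pytest.approx((0.7 + 0.3) / 2)
        assert row["mutation_freq"] == pytest.approx(2 / 3)

    def test_unmutated_gene(self):
        profiles = [make_profile("T1", cn={"G1": 3.0})]
        out = gene_landscape(profiles)
        assert np.isnan(out.loc["G1", "mean_vaf"])
        assert out.loc["G1", "mutation_freq"] == 0.0


class TestCohortFrequency:
    @pytest.mark.parametrize("count,denom,decimals,expected", [
        (48, 72, 0, 67.0),
        (0, 10, 0, 0.0),
        (35, 54, 1, 64.8),
        (39, 54, 0, 72.0),
        (57, 83, 1, 68.7),
        (24, 54, 0, 44.0),
    ])
    def test_printed_fractions(self, count, denom, decimals, expected):
        flags = [True] * count + [False] * (denom - count)
        assert cohort_frequency(flags, denom, decimals) == expected

    def test_half_up_rounding(self):
        # 1/8 = 12.5% rounds half-up to 13 at 0 decimals
        assert cohort_frequency([True] + [False] * 7, 8, 0) == 13.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            cohort_frequency([], 0)
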