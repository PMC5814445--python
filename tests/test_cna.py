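"""Copy-number profiling tests: gene mapping, MDR scan, UPD, bins."""

import numpy as np
import pandas as pd
import pytest

from lesionscope.cna import (
    GeneCNProfile,
    GeneTable,
    Segment,
    complexity_score,
    detect_upd,
    find_minimal_region,
    map_segments_to_genes,
    size_bin_spectrum,
)


def table(rows):
    return GeneTable(pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end"]))


GENES = table([
    ("A", "chr1", 100, 199), ("B", "chr1", 300, 399),
    ("C", "chr1", 500, 599), ("D", "chr1", 700, 799),
])


def profile_from_cn(cn_dict):
    """cn_dict: gene -> list of per-case CN values."""
    cn = pd.DataFrame(cn_dict).T
    cn.columns = [f"S{i + 1}" for i in range(cn.shape[1])]
    return GeneCNProfile(cn=cn, genes=GENES)


class TestMapping:
    def test_gene_inside_single_segment(self):
        segs = [Segment("S1", "chr1", 1, 1000, 1.4)]
        prof = map_segments_to_genes(segs, GENES)
        assert prof.cn.loc["A", "S1"] == pytest.approx(1.4)
        assert prof.loss.loc["A", "S1"]
        assert not prof.gain.loc["A", "S1"]

    def test_split_gene_weighted_mean(self):
        # gene A (100-199) split 50/50 between cn 1.0 and cn 3.0
        segs = [Segment("S1", "chr1", 1, 149, 1.0),
                Segment("S1", "chr1", 150, 1000, 3.0)]
        prof = map_segments_to_genes(segs, GENES)
        assert prof.cn.loc["A", "S1"] == pytest.approx(2.0)
        assert not prof.loss.loc["A", "S1"]
        assert not prof.gain.loc["A", "S1"]

    def test_empty_segments_all_neutral(self):
        prof = map_segments_to_genes([], GENES, cases=["S1"])
        assert (prof.cn == 2.0).all().all()

    def test_weighted_mean_bounded_by_overlaps(self, rng):
        # random tilings: gene CN always within [min, max] of overlapping CN
        for _ in range(20):
            cuts = np.sort(rng.choice(np.arange(2, 1000), 4, replace=False))
            bounds = [1, *cuts, 1000]
            segs = [Segment("S1", "chr1", int(bounds[i]) + (i > 0),
                            int(bounds[i + 1]), float(rng.uniform(0.5, 4)))
                    for i in range(len(bounds) - 1)]
            prof = map_segments_to_genes(segs, GENES)
            for g, row in GENES.frame.iterrows():
                over = [s.cn for s in segs
                        if s.start <= row["end"] and s.end >= row["start"]]
                v = prof.cn.loc[row["gene"], "S1"]
                assert min(over) - 1e-9 <= v <= max(over) + 1e-9

    def test_unknown_contig_warns_neutral(self):
        genes = table([("X", "chrZ", 10, 20)])
        with pytest.warns(UserWarning):
            prof = map_segments_to_genes(
                [Segment("S1", "chr1", 1, 100, 1.0)], genes)
        assert prof.cn.loc["X", "S1"] == 2.0


class TestMinimalRegion:
    def test_unanimous_region(self):
        prof = profile_from_cn({
            "A": [2, 2, 2], "B": [1.2, 1.3, 1.1],
            "C": [1.2, 1.3, 1.1], "D": [2, 2, 2]})
        mr = find_minimal_region(prof, "chr1", "MDR")
        assert mr.genes == ["B", "C"]
        assert (mr.start, mr.end) == (300, 599)
        assert mr.frequency == 1.0
        assert set(mr.affected_cases) == {"S1", "S2", "S3"}

    def test_max_frequency_run(self):
        # per-gene loss frequencies A:0.2 B:0.5 C:0.5 D:0.1 over 10 cases
        def col(loss_cases, n=10):
            return [1.0 if i < loss_cases else 2.0 for i in range(n)]
        prof = profile_from_cn({
            "A": col(2), "B": col(5), "C": col(5), "D": col(1)})
        mr = find_minimal_region(prof, "chr1", "MDR")
        assert mr.genes == ["B", "C"]

    def test_tie_break_smallest_span(self):
        genes = table([
            ("A", "chr1", 100, 199), ("B", "chr1", 300, 50_000),
            ("C", "chr1", 60_000, 60_099)])
        cn = pd.DataFrame({"S1": [2.0, 1.0, 1.0], "S2": [2.0, 1.0, 1.0]},
                          index=["A", "B", "C"])
        # B and C are separate max-frequency runs only if not adjacent;
        # make them non-contiguous by a neutral gene between
        genes2 = table([
            ("A", "chr1", 100, 199), ("B", "chr1", 300, 50_000),
            ("N", "chr1", 55_000, 55_099), ("C", "chr1", 60_000, 60_099)])
        cn2 = pd.DataFrame(
            {"S1": [2.0, 1.0, 2.0, 1.0], "S2": [2.0, 1.0, 2.0, 1.0]},
            index=["A", "B", "N", "C"])
        prof = GeneCNProfile(cn=cn2, genes=genes2)
        mr = find_minimal_region(prof, "chr1", "MDR")
        assert mr.genes == ["C"]     # 100 bp beats ~50 kb at equal frequency

    def test_no_flagged_case_returns_none(self):
        prof = profile_from_cn({g: [2.0, 2.0] for g in "ABCD"})
        assert find_minimal_region(prof, "chr1", "MDR") is None

    def test_mar_uses_gains(self):
        prof = profile_from_cn({
            "A": [2, 2], "B": [3.0, 3.1], "C": [2, 2], "D": [2, 2]})
        mr = find_minimal_region(prof, "chr1", "MAR")
        assert mr.genes == ["B"] and mr.kind == "MAR"

    def test_frequency_maximality_exhaustive(self, rng):
        # no contiguous run has strictly higher all-case-shared frequency
        for _ in range(10):
            cn = pd.DataFrame(
                rng.choice([1.0, 2.0], size=(4, 6), p=[0.4, 0.6]),
                index=list("ABCD"),
                columns=[f"S{i}" for i in range(6)])
            prof = GeneCNProfile(cn=cn, genes=GENES)
            mr = find_minimal_region(prof, "chr1", "MDR")
            if mr is None:
                assert not (cn < 1.5).any().any()
                continue
            loss = (cn < 1.5)
            per_gene = loss.mean(axis=1).to_numpy()
            best = per_gene.max()
            run_freqs = per_gene[[list("ABCD").index(g) for g in mr.genes]]
            assert np.allclose(run_freqs, best)


class TestComplexity:
    def test_zero_flags(self):
        prof = profile_from_cn({g: [2.0] for g in "ABCD"})
        out = complexity_score(prof)
        assert out.loc["S1", "n_affected"] == 0
        assert out.loc["S1", "tier"] == "moderate"

    def test_exclusion_set_difference(self):
        prof = profile_from_cn({
            "A": [1.0], "B": [1.0], "C": [3.0], "D": [2.0]})
        out = complexity_score(prof, exclude=[("chr1", 250, 450)])  # drops B
        assert out.loc["S1", "n_lost"] == 1
        assert out.loc["S1", "n_gained"] == 1

    @pytest.mark.parametrize("n,tier", [
        (1999, "moderate"), (2000, "intermediate"),
        (5000, "intermediate"), (5001, "high")])
    def test_tiers(self, n, tier):
        genes = table([(f"G{i}", "chr1", 10 * i + 1, 10 * i + 5)
                       for i in range(6000)])
        cn = pd.DataFrame(
            {"S1": [1.0] * n + [2.0] * (6000 - n)}, index=genes.frame["gene"])
        out = complexity_score(GeneCNProfile(cn=cn, genes=genes))
        assert out.loc["S1", "tier"] == tier


class TestSizeBins:
    @pytest.mark.parametrize("size,label", [
        (1000, "1-1000"), (1001, "1001-10000"),
        (10_000, "1001-10000"), (10_001, "10001-100000")])
    def test_decade_scheme(self, size, label):
        seg = Segment("S1", "chr1", 1, size, 1.0)
        out = size_bin_spectrum([seg])
        assert out.loc["S1", label] == 1
        assert out.loc["S1"].sum() == 1

    def test_neutral_not_counted(self):
        out = size_bin_spectrum([Segment("S1", "chr1", 1, 500, 2.0)])
        assert out.loc["S1"].sum() == 0

    def test_partition_property(self, rng):
        segs = [Segment("S1", "chr1", 1, int(rng.integers(1, 10 ** 6)),
                        float(rng.choice([1.0, 2.0, 3.0])))
                for _ in range(100)]
        out = size_bin_spectrum(segs)
        non_neutral = sum(1 for s in segs if s.cn < 1.5 or s.cn > 2.5)
        assert out.to_numpy().sum() == non_neutral


class TestUPD:
    def test_rules(self):
        prof = profile_from_cn({
            "A": [2.0], "B": [1.4], "C": [2.0], "D": [2.05]})
        loh = pd.DataFrame(
            {"S1": [True, True, False, True]}, index=list("ABCD"))
        upd = detect_upd(prof, loh)
        assert upd.loc["A", "S1"]          # LOH + biallelic -> UPD
        assert not upd.loc["B", "S1"]      # deletion LOH, not UPD
        assert not upd.loc["C", "S1"]      # no LOH
        assert upd.loc["D", "S1"]          # 2.05 inside [1.9, 2.1]

    def test_misaligned_flags_rejected(self):
        prof = profile_from_cn({g: [2.0] for g in "ABCD"})
        bad = pd.DataFrame({"S1": [True]}, index=["A"])
        with pytest.raises(ValueError):
            detect_upd(prof, bad)


def test_planted_deletion_recovered(small_cohort):
    b = small_cohort
    prof = map_segments_to_genes(
        b.segments, b.gene_table,
        cases=sorted({s.sample for s in b.segments}))
    mr = find_minimal_region(prof, "chr1", "MDR")
    gf = b.gene_table.frame
    chr1 = gf[gf["chrom"] == "chr1"].reset_index(drop=True)
    i0, i1 = b.config.planted_mdr
    assert mr.start == chr1.loc[i0, "start"]
    assert mr.end == chr1.loc[i1, "end"]
    assert set(mr.affected_cases) == set(b.truth["planted_mdr"]["cases"])
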