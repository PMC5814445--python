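"""Integrate CN, mutation and expression into per-case lesion profiles.

Derives ATM allelic genotype classes and their cohort fractions,
gain-/loss-of-function calls, the ATM mutation/sCNA co-occurrence test,
the eight-category lesional matrix, and the gene-centric landscape.
"""

import argparse
import json
from collections import Counter
from pathlib import Path

import pandas as pd

from lesionscope import io as lio
from lesionscope.cna import detect_upd, map_segments_to_genes
from lesionscope.integrate import (
    CaseLesionProfile,
    Mutation,
    call_gof_lof,
    classify_genotype,
    cohort_frequency,
    cooccurrence_test,
    gene_landscape,
    lesional_categories,
)

GENE_SETS = {"epigenetic": {"EZH2", "KAT6B"}, "ddr": {"ATM", "TP53"}}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--filtered", type=Path,
                    default=Path("results/filtering/filtered.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/integration"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    segments = lio.read_seg(args.cohort / "segments.seg")
    genes = lio.read_gene_table(args.cohort / "genes.tsv")
    cases = sorted({s.sample for s in segments})
    profile = map_segments_to_genes(segments, genes, cases=cases)
    loh = pd.read_csv(args.cohort / "loh_flags.tsv", sep="\t",
                      index_col=0).astype(bool)[profile.cn.columns]
    upd = detect_upd(profile, loh)
    calls, samples = lio.read_variants_tsv(args.filtered)
    truth = json.loads((args.cohort / "truth.json").read_text())
    wes_cases = sorted(set(samples))

    muts: dict[str, dict[str, list[Mutation]]] = {c: {} for c in cases}
    for call, case in zip(calls, samples):
        muts[case].setdefault(call.gene, []).append(
            Mutation(vaf=call.vaf, gene=call.gene))

    expr = pd.read_csv(args.cohort / "expression.tsv", sep="\t",
                       index_col=0)
    tcl1a = expr.iloc[0]                      # the TCL1A tracking probe
    tcl1a_fc = tcl1a / tcl1a.median()

    profiles = []
    for case in cases:
        has_wes = case in set(wes_cases)
        has_gep = case in set(expr.columns)
        profiles.append(CaseLesionProfile(
            case_id=case,
            cn=profile.cn[case].to_dict(),
            mutations=muts[case] if has_wes else {},
            expression_fc={"TCL1A": float(tcl1a_fc.get(case, float("nan")))}
            if has_gep else {},
            upd=upd[case].to_dict(),
            platforms={"cn": True, "mutation": has_wes,
                       "expression": has_gep}))

    # ATM allelic genotypes over cases with full CN + mutation data
    atm_classes = Counter()
    atm_loh_flags, atm_mut_flags, atm_cna_flags = [], [], []
    for case in wes_cases:
        cls = classify_genotype(
            profile.cn.loc["ATM", case], muts[case].get("ATM", []),
            upd=bool(upd.loc["ATM", case]))
        atm_classes[cls.value] += 1
        atm_loh_flags.append(cls.value == "LOH")
        atm_mut_flags.append(bool(muts[case].get("ATM")))
        atm_cna_flags.append(profile.cn.loc["ATM", case] < 1.5)
    print("ATM genotype classes over WES cases:", dict(atm_classes))
    print(f"ATM LOH frequency: "
          f"{cohort_frequency(atm_loh_flags, len(wes_cases), 0):.0f}% "
          f"of {len(wes_cases)}")
    oddsr, p = cooccurrence_test(atm_mut_flags, atm_cna_flags)
    print(f"ATM mutation x ATM sCNA co-occurrence: OR {oddsr:.2f}, "
          f"Fisher p {p:.4f}")

    gof_cases = [
        any(call_gof_lof(profile.cn.loc[g, case], ms) != "none"
            for g, ms in muts[case].items() if g in profile.cn.index)
        for case in wes_cases]
    print(f"cases with any GOF/LOF call: "
          f"{cohort_frequency(gof_cases, len(wes_cases), 0):.0f}%")

    mat, ordering, freqs = lesional_categories(profiles, GENE_SETS)
    mat.reindex(ordering).to_csv(args.out / "lesional_matrix.tsv", sep="\t")
    freqs.rename("percent").to_csv(args.out / "category_freqs.tsv",
                                   sep="\t")
    print("lesional category frequencies (%):",
          {k: v for k, v in freqs.round(1).items()})

    landscape = gene_landscape(profiles)
    landscape.round(4).to_csv(args.out / "gene_landscape.tsv", sep="\t")
    print(f"gene landscape rows: {len(landscape)}")
    _ = truth


if __name__ == "__main__":
    main()
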