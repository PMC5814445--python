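"""Readers and writers for the pipeline's tabular formats.

Formats: IGV SEG (tab-separated, 1-based inclusive; linear CN or log2
ratio), gene tables (TSV 1-based or BED 0-based half-open), MAF-like
variant TSV, a minimal VCF 4.2 writer/reader (FOXOG/TLOD/VAF INFO keys,
F1R2/F2R1 per-sample counts), expression/survival TSV, and the long-form
plate CSV used by the drug screen.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cna import GeneTable, Segment
from .filtering import VariantCall
from .synergy import DoseResponsePlate

__all__ = [
    "read_seg", "write_seg", "read_gene_table",
    "read_variants_tsv", "write_variants_tsv",
    "write_vcf", "read_vcf",
    "read_plates_csv", "write_plates_csv",
]

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
_POP_SOURCES = ("1000G", "ESP6500", "ExAC")


def write_seg(segments: list[Segment], path: str | Path) -> None:
    rows = [[s.sample, s.chrom, s.start, s.end, s.n_markers, round(s.cn, 6)]
            for s in segments]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path, log2: bool = False) -> list[Segment]:
    """Read IGV SEG; ``log2=True`` converts ratios as cn = 2 * 2**ratio."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip() for c in df.columns]
    out = []
    for _, r in df.iterrows():
        cn = float(r["seg.mean"])
        if log2:
            cn = 2.0 * 2.0 ** cn
        out.append(Segment(
            sample=str(r["ID"]), chrom=str(r["chrom"]),
            start=int(r["loc.start"]), end=int(r["loc.end"]),
            cn=cn, n_markers=int(r.get("num.mark", 0))))
    return out


def read_gene_table(path: str | Path, bed: bool = False) -> GeneTable:
    if bed:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "gene"])
        return GeneTable.from_bed(df)
    return GeneTable(pd.read_csv(path, sep="\t"))


_VAR_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "category", "sample",
    "vaf", "depth", "qual", "alt_f1r2", "alt_f2r1", "tumor_load",
    "maf_1000G", "maf_ESP6500", "maf_ExAC",
    "sift", "polyphen2", "provean_damaging", "cosmic",
    "confirmed_by_second_caller",
]


def write_variants_tsv(
    calls: list[VariantCall], path: str | Path,
    samples: list[str] | None = None,
) -> None:
    rows = []
    for i, c in enumerate(calls):
        rows.append({
            "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "gene": c.gene, "category": c.category,
            "sample": samples[i] if samples else "",
            "vaf": round(c.vaf, 6), "depth": c.depth, "qual": c.qual,
            "alt_f1r2": c.alt_f1r2, "alt_f2r1": c.alt_f2r1,
            "tumor_load": round(c.tumor_load, 6),
            "maf_1000G": c.pop_freqs.get("1000G", ""),
            "maf_ESP6500": c.pop_freqs.get("ESP6500", ""),
            "maf_ExAC": c.pop_freqs.get("ExAC", ""),
            "sift": "" if c.sift is None else c.sift,
            "polyphen2": "" if c.polyphen2 is None else c.polyphen2,
            "provean_damaging": ("" if c.provean_damaging is None
                                 else int(c.provean_damaging)),
            "cosmic": int(c.cosmic),
            "confirmed_by_second_caller": (
                "" if c.confirmed_by_second_caller is None
                else int(c.confirmed_by_second_caller)),
        })
    pd.DataFrame(rows, columns=_VAR_COLUMNS).to_csv(
        path, sep="\t", index=False)


def _opt_float(v):
    return None if (pd.isna(v) or v == "") else float(v)


def _opt_bool(v):
    return None if (pd.isna(v) or v == "") else bool(int(v))


def read_variants_tsv(
    path: str | Path,
) -> tuple[list[VariantCall], list[str]]:
    df = pd.read_csv(path, sep="\t")
    calls, samples = [], []
    for _, r in df.iterrows():
        pop = {}
        for src in _POP_SOURCES:
            v = _opt_float(r.get(f"maf_{src}"))
            if v is not None:
                pop[src] = v
        samples.append(str(r.get("sample", "")))
        calls.append(VariantCall(
            chrom=str(r["chrom"]), pos=int(r["pos"]),
            ref=str(r["ref"]), alt=str(r["alt"]),
            gene=str(r.get("gene", "")),
            category=str(r.get("category", "nonsynonymous")),
            vaf=float(r["vaf"]), depth=int(r["depth"]),
            qual=float(r.get("qual", 0.0)),
            alt_f1r2=int(r["alt_f1r2"]), alt_f2r1=int(r["alt_f2r1"]),
            tumor_load=float(r.get("tumor_load", 0.0)),
            pop_freqs=pop,
            sift=_opt_float(r.get("sift")),
            polyphen2=_opt_float(r.get("polyphen2")),
            provean_damaging=_opt_bool(r.get("provean_damaging")),
            cosmic=bool(int(r.get("cosmic", 0))),
            confirmed_by_second_caller=_opt_bool(
                r.get("confirmed_by_second_caller")),
            call_id=f"{r.get('sample', '')}:{r['chrom']}:{r['pos']}:"
                    f"{r['ref']}>{r['alt']}",
        ))
    return calls, samples


def write_vcf(
    calls: list[VariantCall], path: str | Path,
    samples: list[str] | None = None,
    contigs: dict[str, int] | None = None,
) -> None:
    """Minimal single-column VCF 4.2 with FOXOG/TLOD/VAF INFO keys."""
    from .filtering import compute_foxog, is_cga_class

    lines = ["##fileformat=VCFv4.2"]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=TLOD,Number=1,Type=Float,Description="Tumor log odds">',
        '##INFO=<ID=FOXOG,Number=1,Type=Float,'
        'Description="Oxidation orientation-bias fraction">',
        '##INFO=<ID=VAF,Number=1,Type=Float,'
        'Description="Variant allele fraction">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Case id">',
        '##FORMAT=<ID=F1R2,Number=1,Type=Integer,'
        'Description="Alt reads in F1R2 orientation">',
        '##FORMAT=<ID=F2R1,Number=1,Type=Integer,'
        'Description="Alt reads in F2R1 orientation">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR",
    ]
    for i, c in enumerate(calls):
        info = [f"TLOD={c.tumor_load:.4f}", f"VAF={c.vaf:.4f}"]
        if (is_cga_class(c.ref, c.alt) and not c.is_indel
                and c.alt_f1r2 + c.alt_f2r1 > 0):
            info.append(f"FOXOG={compute_foxog(c):.4f}")
        if samples:
            info.append(f"SAMPLE={samples[i]}")
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{c.qual:.0f}\t.\t"
            f"{';'.join(info)}\tF1R2:F2R1\t{c.alt_f1r2}:{c.alt_f2r1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read the minimal VCF back as a frame (cyvcf2-backed)."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        f1r2 = v.format("F1R2")
        f2r1 = v.format("F2R1")
        rows.append({
            "chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0],
            "qual": v.QUAL,
            "tlod": v.INFO.get("TLOD"), "vaf": v.INFO.get("VAF"),
            "foxog": v.INFO.get("FOXOG"),
            "sample": v.INFO.get("SAMPLE"),
            "alt_f1r2": int(f1r2[0][0]) if f1r2 is not None else None,
            "alt_f2r1": int(f2r1[0][0]) if f2r1 is not None else None,
        })
    return pd.DataFrame(rows)


PLATE_COLUMNS = ["plate_id", "row_conc_nM", "col_conc_nM",
                 "drug_a", "drug_b", "value", "control"]


def write_plates_csv(plates: list[DoseResponsePlate], path: str | Path) -> None:
    rows = []
    for p in plates:
        for ra in p.grid.index:
            for cb in p.grid.columns:
                rows.append([p.plate_id, float(ra), float(cb),
                             p.drug_a, p.drug_b,
                             round(float(p.grid.loc[ra, cb]), 4), "none"])
        for d, v in p.mono_a.items():
            rows.append([p.plate_id, float(d), 0.0, p.drug_a, p.drug_b,
                         round(float(v), 4), "none"])
        for d, v in p.mono_b.items():
            rows.append([p.plate_id, 0.0, float(d), p.drug_a, p.drug_b,
                         round(float(v), 4), "none"])
        for v in p.pos:
            rows.append([p.plate_id, 0.0, 0.0, p.drug_a, p.drug_b,
                         round(float(v), 4), "pos"])
        for v in p.neg:
            rows.append([p.plate_id, 0.0, 0.0, p.drug_a, p.drug_b,
                         round(float(v), 4), "neg"])
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_plates_csv(path: str | Path) -> list[DoseResponsePlate]:
    df = pd.read_csv(path)
    plates = []
    for pid, sub in df.groupby("plate_id", sort=True):
        combo = sub[(sub["control"] == "none")
                    & (sub["row_conc_nM"] > 0) & (sub["col_conc_nM"] > 0)]
        grid = combo.pivot_table(index="row_conc_nM", columns="col_conc_nM",
                                 values="value").sort_index()
        ma = sub[(sub["control"] == "none") & (sub["col_conc_nM"] == 0)
                 & (sub["row_conc_nM"] > 0)].set_index("row_conc_nM")[
            "value"].sort_index()
        mb = sub[(sub["control"] == "none") & (sub["row_conc_nM"] == 0)
                 & (sub["col_conc_nM"] > 0)].set_index("col_conc_nM")[
            "value"].sort_index()
        plates.append(DoseResponsePlate(
            drug_a=str(sub["drug_a"].iloc[0]),
            drug_b=str(sub["drug_b"].iloc[0]),
            grid=grid, mono_a=ma, mono_b=mb,
            pos=sub.loc[sub["control"] == "pos", "value"].tolist(),
            neg=sub.loc[sub["control"] == "neg", "value"].tolist(),
            plate_id=str(pid)))
    return plates


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=default) + "\n")
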