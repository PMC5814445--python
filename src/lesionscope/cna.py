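"""Gene-level somatic copy-number profiling from array segments.

Consumes CBS-style segments (IGV SEG, 1-based inclusive, linear copy
number with diploid = 2), maps them onto gene intervals, and derives the
cohort-level summaries: loss/gain calls (CN < 1.5 / CN > 2.5), minimal
deleted/amplified regions, copy-neutral LOH (uniparental disomy: LOH
genotype with CN in [1.9, 2.1]), per-case genomic-complexity counts, and
decade size-bin spectra of non-neutral segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "GeneTable",
    "GeneCNProfile",
    "MinimalRegion",
    "LOSS_CN",
    "GAIN_CN",
    "UPD_CN_LOW",
    "UPD_CN_HIGH",
    "map_segments_to_genes",
    "find_minimal_region",
    "complexity_score",
    "size_bin_spectrum",
    "detect_upd",
]

LOSS_CN = 1.5
GAIN_CN = 2.5
UPD_CN_LOW = 1.9
UPD_CN_HIGH = 2.1
NEUTRAL_CN = 2.0


@dataclass(frozen=True)
class Segment:
    """One copy-number segment, 1-based inclusive, linear CN scale."""

    sample: str
    chrom: str
    start: int
    end: int
    cn: float
    n_markers: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start > end: {self}")
        if self.cn < 0:
            raise ValueError(f"negative copy number: {self.cn}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneTable:
    """Gene coordinates, 1-based inclusive, sorted within chromosome."""

    frame: pd.DataFrame  # columns: gene, chrom, start, end

    def __post_init__(self) -> None:
        need = {"gene", "chrom", "start", "end"}
        if not need.issubset(self.frame.columns):
            raise ValueError(f"gene table needs columns {sorted(need)}")
        self.frame = (
            self.frame.sort_values(["chrom", "start", "end"])
            .reset_index(drop=True)
        )

    @classmethod
    def from_bed(cls, frame: pd.DataFrame) -> "GeneTable":
        """Convert a BED-style (0-based half-open) table on read."""
        f = frame.copy()
        f["start"] = f["start"].astype(int) + 1
        f["end"] = f["end"].astype(int)
        return cls(f)

    def genes_on(self, chrom: str) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]


@dataclass
class GeneCNProfile:
    """Gene x case copy-number matrix with threshold-derived flags."""

    cn: pd.DataFrame            # genes x cases, linear CN
    genes: GeneTable

    @property
    def loss(self) -> pd.DataFrame:
        return self.cn < LOSS_CN

    @property
    def gain(self) -> pd.DataFrame:
        return self.cn > GAIN_CN

    @property
    def biallelic(self) -> pd.DataFrame:
        return (self.cn >= UPD_CN_LOW) & (self.cn <= UPD_CN_HIGH)

    @property
    def cases(self) -> list[str]:
        return list(self.cn.columns)


@dataclass
class MinimalRegion:
    chrom: str
    start: int
    end: int
    kind: str                   # "MDR" or "MAR"
    genes: list[str] = field(default_factory=list)
    affected_cases: list[str] = field(default_factory=list)
    frequency: float = 0.0
    mean_cn_in_affected: float = float("nan")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def map_segments_to_genes(
    segments: list[Segment], genes: GeneTable, cases: list[str] | None = None
) -> GeneCNProfile:
    """Length-weighted mean segment CN per gene per case.

    Genes with no overlapping segment default to neutral CN = 2 (array
    exports may omit unaltered regions).  A gene on a contig absent from
    the segments is neutral with a warning.
    """
    if cases is None:
        cases = sorted({s.sample for s in segments})
    gene_names = genes.frame["gene"].tolist()
    cn = pd.DataFrame(NEUTRAL_CN, index=gene_names, columns=list(cases),
                      dtype=float)
    by_case_chrom: dict[tuple[str, str], list[Segment]] = {}
    for seg in segments:
        by_case_chrom.setdefault((seg.sample, seg.chrom), []).append(seg)
    seg_chroms = {c for (_, c) in by_case_chrom}
    missing = set(genes.frame["chrom"]) - seg_chroms
    if missing and segments:
        warnings.warn(
            f"genes on contigs with no segments treated as neutral: "
            f"{sorted(missing)}", stacklevel=2)
    for (case, chrom), segs in by_case_chrom.items():
        if case not in cn.columns:
            continue
        gsub = genes.genes_on(chrom)
        if gsub.empty:
            continue
        gstart = gsub["start"].to_numpy()
        gend = gsub["end"].to_numpy()
        acc = np.zeros(len(gsub))
        cov = np.zeros(len(gsub))
        for seg in segs:
            ov = (np.minimum(gend, seg.end)
                  - np.maximum(gstart, seg.start) + 1).clip(min=0)
            acc += ov * seg.cn
            cov += ov
        got = cov > 0
        vals = np.full(len(gsub), NEUTRAL_CN)
        vals[got] = acc[got] / cov[got]
        cn.loc[gsub["gene"].to_numpy(), case] = vals
    return GeneCNProfile(cn=cn, genes=genes)


def _flag_matrix(profile: GeneCNProfile, kind: str) -> pd.DataFrame:
    if kind == "MDR":
        return profile.loss
    if kind == "MAR":
        return profile.gain
    raise ValueError(f"kind must be MDR or MAR, got {kind!r}")


def find_minimal_region(
    profile: GeneCNProfile, chrom: str, kind: str = "MDR"
) -> MinimalRegion | None:
    """Minimal common deleted/amplified region on one chromosome.

    The per-gene affected frequency (fraction of cases beyond the CN
    threshold) is scanned along the chromosome; the region is the
    contiguous run of genes at the maximal frequency, ties broken by
    smallest genomic span then leftmost start.  Affected cases are those
    flagged on every gene of the run.  Returns None if no case is flagged
    anywhere on the chromosome.
    """
    flags = _flag_matrix(profile, kind)
    gsub = profile.genes.genes_on(chrom)
    if gsub.empty:
        return None
    names = gsub["gene"].tolist()
    sub = flags.loc[names]
    freq = sub.mean(axis=1).to_numpy()
    if freq.max() <= 0:
        return None
    fmax = freq.max()
    # enumerate maximal runs of genes at the max frequency
    runs: list[tuple[int, int]] = []
    i = 0
    at_max = freq >= fmax - 1e-12
    while i < len(names):
        if at_max[i]:
            j = i
            while j + 1 < len(names) and at_max[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    starts = gsub["start"].to_numpy()
    ends = gsub["end"].to_numpy()
    runs.sort(key=lambda r: (ends[r[1]] - starts[r[0]], starts[r[0]]))
    i0, i1 = runs[0]
    run_genes = names[i0:i1 + 1]
    run_flags = sub.loc[run_genes]
    affected = run_flags.all(axis=0)
    affected_cases = [c for c in profile.cases if affected.get(c, False)]
    if affected_cases:
        mean_cn = float(
            profile.cn.loc[run_genes, affected_cases].to_numpy().mean())
    else:
        mean_cn = float("nan")
    return MinimalRegion(
        chrom=chrom,
        start=int(starts[i0]),
        end=int(ends[i1]),
        kind=kind,
        genes=run_genes,
        affected_cases=affected_cases,
        frequency=len(affected_cases) / len(profile.cases),
        mean_cn_in_affected=mean_cn,
    )


def complexity_score(
    profile: GeneCNProfile,
    exclude: list[tuple[str, int, int]] | None = None,
    moderate_max: int = 2000,
    high_min: int = 5000,
) -> pd.DataFrame:
    """Per-case counts of gained and lost genes, with tier labels.

    Genes overlapping any excluded region (e.g. the recurrent 11q/8q
    targets themselves) are removed before counting.  Tiers: moderate for
    < 2000 affected genes, high for > 5000, intermediate between.
    """
    keep = np.ones(len(profile.genes.frame), dtype=bool)
    for chrom, start, end in exclude or []:
        if start > end:
            raise ValueError(f"invalid exclusion region {chrom}:{start}-{end}")
        g = profile.genes.frame
        hit = (g["chrom"] == chrom) & (g["start"] <= end) & (g["end"] >= start)
        keep &= ~hit.to_numpy()
    kept_genes = profile.genes.frame.loc[keep, "gene"].tolist()
    lost = profile.loss.loc[kept_genes].sum(axis=0)
    gained = profile.gain.loc[kept_genes].sum(axis=0)
    total = lost + gained
    tier = pd.Series(
        np.where(total < moderate_max, "moderate",
                 np.where(total > high_min, "high", "intermediate")),
        index=total.index)
    return pd.DataFrame(
        {"n_lost": lost, "n_gained": gained, "n_affected": total,
         "tier": tier})


def size_bin_spectrum(
    segments: list[Segment],
    cn_low: float = LOSS_CN,
    cn_high: float = GAIN_CN,
    max_decade: int = 9,
) -> pd.DataFrame:
    """Per-sample counts of non-neutral segments in decade size bins.

    Bin 0 holds sizes 1..1000 bp, bin 1 holds 1001..10^4, bin 2 holds
    10^4+1..10^5, and so on; size = end - start + 1.  Neutral segments
    (cn_low <= cn <= cn_high) are not counted.
    """
    edges = [10 ** k for k in range(3, max_decade + 1)]
    labels = ["1-1000"] + [
        f"{edges[i] + 1}-{edges[i + 1]}" for i in range(len(edges) - 1)]
    samples = sorted({s.sample for s in segments})
    out = pd.DataFrame(0, index=samples, columns=labels, dtype=int)
    for seg in segments:
        if cn_low <= seg.cn <= cn_high:
            continue
        k = int(np.searchsorted(edges, seg.size, side="left"))
        if k >= len(labels):
            raise ValueError(f"segment size {seg.size} exceeds last bin")
        out.loc[seg.sample, labels[k]] += 1
    return out


def detect_upd(profile: GeneCNProfile, loh_flags: pd.DataFrame) -> pd.DataFrame:
    """Copy-neutral LOH (UPD): LOH genotype with CN in [1.9, 2.1].

    ``loh_flags`` is a boolean gene x case frame aligned to the profile.
    """
    if (list(loh_flags.index) != list(profile.cn.index)
            or list(loh_flags.columns) != list(profile.cn.columns)):
        raise ValueError("loh_flags not aligned to profile (genes x cases)")
    return loh_flags.astype(bool) & profile.biallelic
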