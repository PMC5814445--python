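"""Per-case, per-gene integration of copy number, mutation and expression.

Combines the platform layers into allelic genotype classes (LOH,
biallelic-mutated, UPD-mutated, ...), gain-/loss-of-function calls,
deterministic cellular-prevalence correction of VAFs, pairwise
co-occurrence statistics, the eight-category lesional matrix, and the
gene-centric landscape summary.  Category denominators are always
mask-aware: a case contributes to a frequency only where the relevant
platform was analyzed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .cna import UPD_CN_HIGH, UPD_CN_LOW

__all__ = [
    "GenotypeClass",
    "Mutation",
    "CaseLesionProfile",
    "CATEGORY_NAMES",
    "classify_genotype",
    "call_gof_lof",
    "cellular_prevalence",
    "cooccurrence_test",
    "lesional_categories",
    "gene_landscape",
    "cohort_frequency",
]


class GenotypeClass(enum.Enum):
    LOH = "LOH"
    BIALLELIC_MUTATED = "biallelic_mutated"
    UPD_MUTATED = "UPD_mutated"
    MONOALLELIC_UNMUTATED = "monoallelic_unmutated"
    BIALLELIC_UNMUTATED = "biallelic_unmutated"


@dataclass(frozen=True)
class Mutation:
    vaf: float
    damaging: bool = True
    gene: str = ""


@dataclass
class CaseLesionProfile:
    """Integrated per-case view across platforms.

    ``platforms`` records availability ("cn", "mutation", "expression");
    flags are only meaningful where the platform is available.
    """

    case_id: str
    cn: dict[str, float] = field(default_factory=dict)          # gene -> CN
    mutations: dict[str, list[Mutation]] = field(default_factory=dict)
    expression_fc: dict[str, float] = field(default_factory=dict)
    upd: dict[str, bool] = field(default_factory=dict)
    rearrangement: dict[str, bool] = field(default_factory=dict)
    platforms: dict[str, bool] = field(
        default_factory=lambda: {"cn": True, "mutation": True,
                                 "expression": True})


# The allelic-genotype gap rule: CN between the canonical loss (<1.5) and
# biallelic (1.9-2.1) bands is assigned to the nearer side, split at 1.7.
_MONOALLELIC_MAX = 1.7


def classify_genotype(
    cn: float,
    mutations: list[Mutation],
    upd: bool = False,
    vaf_min: float = 0.2,
) -> GenotypeClass:
    """Allelic genotype of one gene in one case.

    A gene counts as mutated when any mutation exceeds ``vaf_min``
    (strictly; the canonical rule is VAF > 20%).  LOH = CN loss plus a
    mutation; UPD-mutated = biallelic CN with an LOH genotype plus a
    mutation; the remaining combinations fall out as listed in
    :class:`GenotypeClass`.
    """
    if cn is None or not np.isfinite(cn):
        raise ValueError("copy number required for genotype classification")
    mutated = any(mu.vaf > vaf_min for mu in mutations)
    monoallelic = cn < _MONOALLELIC_MAX
    biallelic = UPD_CN_LOW <= cn <= UPD_CN_HIGH
    if mutated:
        if monoallelic:
            return GenotypeClass.LOH
        if biallelic and upd:
            return GenotypeClass.UPD_MUTATED
        return GenotypeClass.BIALLELIC_MUTATED
    if monoallelic:
        return GenotypeClass.MONOALLELIC_UNMUTATED
    return GenotypeClass.BIALLELIC_UNMUTATED


def call_gof_lof(
    cn: float,
    mutations: list[Mutation],
    gain_cn: float = 2.2,
    loss_cn: float = 1.7,
    vaf_min: float = 0.5,
) -> str:
    """Gain-/loss-of-function from co-occurring sCNA and clonal mutation.

    GOF: CN > 2.2 with a mutation of VAF > 0.5; LOF: CN < 1.7 with a
    mutation of VAF > 0.5; otherwise "none".  The two are mutually
    exclusive since no CN is both above 2.2 and below 1.7.
    """
    if not mutations:
        return "none"
    max_vaf = max(mu.vaf for mu in mutations)
    if max_vaf <= vaf_min:
        return "none"
    if cn > gain_cn:
        return "GOF"
    if cn < loss_cn:
        return "LOF"
    return "none"


def cellular_prevalence(vaf: float, cn: float, purity: float) -> float:
    """Copy-number- and purity-corrected mutation prevalence.

    Under the single-copy-mutation assumption, the fraction of tumor
    cells carrying the mutation is

        prevalence = vaf * (purity * cn + 2 * (1 - purity)) / purity

    clipped to [0, 1].
    """
    if purity <= 0 or purity > 1:
        raise ValueError("purity must lie in (0, 1]")
    if cn <= 0:
        raise ValueError("copy number must be positive")
    if not 0 <= vaf <= 1:
        raise ValueError("vaf must lie in [0, 1]")
    prev = vaf * (purity * cn + 2.0 * (1.0 - purity)) / purity
    return float(np.clip(prev, 0.0, 1.0))


def cooccurrence_test(
    flags_a: np.ndarray | list[bool], flags_b: np.ndarray | list[bool]
) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p for two lesion flags.

    The OR is ad/bc with Haldane-Anscombe 0.5 on zero cells (NaN when a
    flag vector is constant); the p-value is the exact hypergeometric
    two-sided test.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("flag vectors must be equal-length and non-empty")
    t11 = int((a & b).sum())
    t10 = int((a & ~b).sum())
    t01 = int((~a & b).sum())
    t00 = int((~a & ~b).sum())
    table = np.array([[t11, t10], [t01, t00]])
    p = float(stats.fisher_exact(table)[1])
    if a.all() or (~a).all() or b.all() or (~b).all():
        return float("nan"), p
    if 0 in (t11, t10, t01, t00):
        oddsr = ((t11 + 0.5) * (t00 + 0.5)) / ((t10 + 0.5) * (t01 + 0.5))
    else:
        oddsr = (t11 * t00) / (t10 * t01)
    return float(oddsr), p


CATEGORY_NAMES = (
    "TCL1_MTCP1",          # expression high or rearrangement
    "ATM",                 # sCNA loss or mutation
    "AGO2_sCNA",
    "AGO134_UPD",
    "MYC",                 # sCNA or mRNA up
    "JAK_STAT_mut",        # IL2RG/JAK1/JAK3/STAT5B mutated
    "epigenetic_DE",       # differentially expressed epigenetic regulators
    "DDR",                 # DNA-damage-response gene set hit
)

_DEFAULT_GENES = {
    "tcl1": ("TCL1A", "TCL1B", "MTCP1"),
    "atm": ("ATM",),
    "ago2": ("AGO2",),
    "ago134": ("AGO1", "AGO3", "AGO4"),
    "myc": ("MYC",),
    "jak_stat": ("IL2RG", "JAK1", "JAK3", "STAT5B"),
}


def _case_categories(
    p: CaseLesionProfile,
    gene_sets: dict[str, set[str]],
    genes: dict[str, tuple[str, ...]],
    loss_cn: float = 1.5,
    gain_cn: float = 2.5,
    fc_min: float = 1.5,
) -> dict[str, object]:
    """Category flags for one case; NaN where the platform is missing."""
    has_cn = p.platforms.get("cn", False)
    has_mut = p.platforms.get("mutation", False)
    has_expr = p.platforms.get("expression", False)

    def scna(gene):
        cn = p.cn.get(gene)
        return cn is not None and (cn < loss_cn or cn > gain_cn)

    def scna_gain(gene):
        cn = p.cn.get(gene)
        return cn is not None and cn > gain_cn

    def mutated(gene):
        return bool(p.mutations.get(gene))

    def expr_up(gene):
        fc = p.expression_fc.get(gene)
        return fc is not None and fc > fc_min

    out: dict[str, object] = {}
    out["TCL1_MTCP1"] = (
        any(expr_up(g) or p.rearrangement.get(g, False)
            for g in genes["tcl1"])
        if (has_expr or any(p.rearrangement.values())) else np.nan)
    out["ATM"] = (
        any((has_cn and p.cn.get(g) is not None and p.cn[g] < loss_cn)
            or (has_mut and mutated(g)) for g in genes["atm"])
        if (has_cn or has_mut) else np.nan)
    out["AGO2_sCNA"] = (
        any(scna_gain(g) for g in genes["ago2"]) if has_cn else np.nan)
    out["AGO134_UPD"] = (
        any(p.upd.get(g, False) for g in genes["ago134"])
        if has_cn else np.nan)
    out["MYC"] = (
        any(scna(g) or expr_up(g) for g in genes["myc"])
        if (has_cn or has_expr) else np.nan)
    out["JAK_STAT_mut"] = (
        any(mutated(g) for g in genes["jak_stat"]) if has_mut else np.nan)
    out["epigenetic_DE"] = (
        any(expr_up(g) for g in gene_sets["epigenetic"])
        if has_expr else np.nan)
    out["DDR"] = (
        any(mutated(g) or scna(g) for g in gene_sets["ddr"])
        if (has_mut or has_cn) else np.nan)
    return out


def lesional_categories(
    profiles: list[CaseLesionProfile],
    gene_sets: dict[str, set[str]],
    genes: dict[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, list[str], pd.Series]:
    """The eight-category lesional matrix over a cohort.

    Returns (matrix, ordering, frequencies): a case x category frame of
    True/False/NaN (NaN = platform not analyzed), the case ordering by
    descending call count (ties by case id), and per-category cohort
    frequencies in percent over cases with data.
    """
    for key in ("epigenetic", "ddr"):
        if key not in gene_sets:
            raise ValueError(f"missing gene set {key!r}")
    genes = {**_DEFAULT_GENES, **(genes or {})}
    rows = {p.case_id: _case_categories(p, gene_sets, genes)
            for p in profiles}
    mat = pd.DataFrame.from_dict(rows, orient="index")[list(CATEGORY_NAMES)]
    counts = (mat == True).sum(axis=1)  # noqa: E712  (NaN-safe count)
    ordering = sorted(mat.index, key=lambda c: (-counts[c], c))
    freqs = {}
    for cat in CATEGORY_NAMES:
        col = mat[cat]
        observed = col.notna()
        denom = int(observed.sum())
        freqs[cat] = (
            cohort_frequency(col[observed].astype(bool).to_numpy(),
                             denom, decimals=1)
            if denom else float("nan"))
    return mat, ordering, pd.Series(freqs)


def gene_landscape(
    profiles: list[CaseLesionProfile],
    de_table: pd.DataFrame | None = None,
    cn_gain_min: float = 2.2,
    cn_loss_max: float = 1.8,
    vaf_min: float = 0.5,
    fdr_max: float = 0.1,
) -> pd.DataFrame:
    """Gene-centric landscape: mean CN, mean VAF, mutation frequency, fc.

    Rows are emitted for genes that are CN-shifted on cohort average,
    carry a clonal mutation, or are significant in the differential-
    expression table (q < ``fdr_max``).
    """
    genes: set[str] = set()
    for p in profiles:
        genes |= set(p.cn) | set(p.mutations)
    if de_table is not None:
        genes |= set(de_table.index)
    rows = []
    n_cases = len(profiles)
    for gene in sorted(genes):
        cns = [p.cn[gene] for p in profiles if gene in p.cn]
        cn_mean = float(np.mean(cns)) if cns else float("nan")
        vafs = [max(mu.vaf for mu in p.mutations[gene])
                for p in profiles if p.mutations.get(gene)]
        mean_vaf = float(np.mean(vafs)) if vafs else float("nan")
        mut_freq = len(vafs) / n_cases if n_cases else 0.0
        fc = q = float("nan")
        if de_table is not None and gene in de_table.index:
            fc = float(de_table.loc[gene, "fc"])
            q = float(de_table.loc[gene, "q"])
        significant = np.isfinite(q) and q < fdr_max
        keep = (
            (np.isfinite(cn_mean)
             and (cn_mean > cn_gain_min or cn_mean < cn_loss_max))
            or (vafs and max(vafs) > vaf_min)
            or significant)
        if keep:
            rows.append({"gene": gene, "cn_mean": cn_mean,
                         "mean_vaf": mean_vaf, "mutation_freq": mut_freq,
                         "fc": fc, "q": q, "significant": significant})
    return pd.DataFrame(
        rows, columns=["gene", "cn_mean", "mean_vaf", "mutation_freq",
                       "fc", "q", "significant"]).set_index("gene")


def cohort_frequency(
    flags: np.ndarray | list[bool], denominator: int, decimals: int = 0
) -> float:
    """Percentage of flagged cases, half-up rounded to ``decimals``.

    Half-up (not banker's) rounding matches how printed percentages are
    conventionally reported.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    count = int(np.asarray(flags, dtype=bool).sum())
    pct = Decimal(100 * count) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))
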