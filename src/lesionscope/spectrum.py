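"""Substitution-class and trinucleotide-context mutational spectra.

Spectra are kept in three resolutions: the 12 directional substitution
classes (strand as reported), the 6 pyrimidine-collapsed classes
(C>A, C>G, C>T, T>A, T>C, T>G after reverse-complementing purine refs),
and the 96 trinucleotide-context classes (6 x 16 flanking contexts).
Group comparisons use per-class odds ratios with Fisher exact tests and
rank-based statistics; catalog comparison uses Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLASSES_12",
    "CLASSES_6",
    "CONTEXTS_96",
    "SpectrumCounts",
    "SpectrumComparison",
    "classify_substitution",
    "build_spectrum",
    "mutation_rate",
    "compare_spectra",
    "signature_similarity",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = ("A", "C", "G", "T")
CLASSES_12 = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if r != a)
CLASSES_6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CONTEXTS_96 = tuple(
    f"{l}[{cls}]{r}"
    for cls in CLASSES_6 for l in BASES for r in BASES)


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def classify_substitution(
    ref: str, alt: str, left_base: str, right_base: str
) -> tuple[str, str, str]:
    """Classify one SNV into directional, collapsed, and context classes.

    Purine references are reverse-complemented to the pyrimidine
    representative, flipping and complementing the flanking context.
    Raises on non-substitutions or ambiguous (non-ACGT) bases.
    """
    ref, alt = ref.upper(), alt.upper()
    left, right = left_base.upper(), right_base.upper()
    for b in (ref, alt, left, right):
        if b not in _COMP:
            raise ValueError(f"unclassifiable base {b!r}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    class_12 = f"{ref}>{alt}"
    if ref in ("C", "T"):
        class_6 = class_12
        context = f"{left}[{class_6}]{right}"
    else:
        class_6 = f"{_COMP[ref]}>{_COMP[alt]}"
        context = f"{_COMP[right]}[{class_6}]{_COMP[left]}"
    return class_12, class_6, context


@dataclass
class SpectrumCounts:
    counts_12: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CLASSES_12})
    counts_6: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CLASSES_6})
    counts_96: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CONTEXTS_96})
    n_total: int = 0
    n_excluded: int = 0     # indels, N-context, edge-of-contig calls

    def add(self, class_12: str, class_6: str, context: str) -> None:
        self.counts_12[class_12] += 1
        self.counts_6[class_6] += 1
        self.counts_96[context] += 1
        self.n_total += 1

    def fractions_6(self) -> pd.Series:
        s = pd.Series(self.counts_6, dtype=float)
        return s / s.sum() if s.sum() else s

    def fractions_12(self) -> pd.Series:
        s = pd.Series(self.counts_12, dtype=float)
        return s / s.sum() if s.sum() else s

    def vector_96(self, normalize: bool = False) -> np.ndarray:
        v = np.array([self.counts_96[c] for c in CONTEXTS_96], dtype=float)
        if normalize and v.sum():
            v = v / v.sum()
        return v


def build_spectrum(calls, reference) -> SpectrumCounts:
    """Accumulate a spectrum over SNV calls.

    ``reference`` provides flanking bases: either a mapping/pyfaidx-style
    object indexed as reference[chrom][pos - 1] (0-based within contig,
    str result), or a callable (chrom, pos) -> triplet string centered on
    pos.  Indels and calls without both flanks are excluded with a tally.
    """
    spec = SpectrumCounts()
    for call in calls:
        ref, alt = call.ref.upper(), call.alt.upper()
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            spec.n_excluded += 1
            continue
        try:
            if callable(reference):
                triplet = str(reference(call.chrom, call.pos)).upper()
            else:
                contig = reference[call.chrom]
                if call.pos < 2 or call.pos > len(contig) - 1:
                    spec.n_excluded += 1
                    continue
                triplet = str(contig[call.pos - 2:call.pos + 1]).upper()
        except KeyError as exc:
            raise ValueError(
                f"call {call.chrom}:{call.pos} outside reference") from exc
        if len(triplet) != 3:
            spec.n_excluded += 1
            continue
        if triplet[1] != ref:
            raise ValueError(
                f"reference mismatch at {call.chrom}:{call.pos}: "
                f"expected {ref}, reference has {triplet[1]}")
        try:
            spec.add(*classify_substitution(ref, alt, triplet[0], triplet[2]))
        except ValueError:
            spec.n_excluded += 1
    return spec


def mutation_rate(n_somatic: int, target_bp: int) -> float:
    """Mutations per megabase of target territory."""
    if target_bp <= 0:
        raise ValueError("target_bp must be positive")
    if n_somatic < 0:
        raise ValueError("n_somatic must be non-negative")
    return n_somatic / (target_bp / 1e6)


@dataclass
class SpectrumComparison:
    odds_ratios: pd.Series          # per collapsed class
    fisher_p: pd.Series
    ranks_a: pd.Series              # 1 = most frequent of the 12 classes
    ranks_b: pd.Series
    wilcoxon_p: float | None = None


def _class_or(table: np.ndarray) -> float:
    a, b, c, d = table.ravel().astype(float)
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def compare_spectra(
    a: SpectrumCounts,
    b: SpectrumCounts,
    per_sample_fractions: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> SpectrumComparison:
    """Compare two spectra class by class.

    Per collapsed class the 2x2 table (class vs rest, group a vs b) gives
    a sample odds ratio (Haldane-Anscombe 0.5 on zero cells) and a
    two-sided Fisher exact p.  The 12 directional classes are ranked by
    fraction, descending (rank 1 = most frequent, ties mid-ranked).  When
    paired per-sample class-fraction frames are supplied, a Wilcoxon
    signed-rank test on the paired per-sample fractions is added.
    """
    if a.n_total == 0 or b.n_total == 0:
        raise ValueError("cannot compare an empty spectrum")
    ors, ps = {}, {}
    for cls in CLASSES_6:
        table = np.array([
            [a.counts_6[cls], a.n_total - a.counts_6[cls]],
            [b.counts_6[cls], b.n_total - b.counts_6[cls]],
        ])
        ors[cls] = _class_or(table)
        ps[cls] = stats.fisher_exact(table)[1]
    fr_a, fr_b = a.fractions_12(), b.fractions_12()
    ranks_a = pd.Series(stats.rankdata(-fr_a.to_numpy()), index=fr_a.index)
    ranks_b = pd.Series(stats.rankdata(-fr_b.to_numpy()), index=fr_b.index)
    wil_p = None
    if per_sample_fractions is not None:
        fa, fb = per_sample_fractions
        x = fa.mean(axis=0).to_numpy()
        y = fb.mean(axis=0).to_numpy()
        if not np.allclose(x, y):
            wil_p = float(stats.wilcoxon(x, y)[1])
        else:
            wil_p = 1.0
    return SpectrumComparison(
        odds_ratios=pd.Series(ors), fisher_p=pd.Series(ps),
        ranks_a=ranks_a, ranks_b=ranks_b, wilcoxon_p=wil_p)


def signature_similarity(
    spectrum: SpectrumCounts, catalog: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of the 96-vector against catalog signatures.

    ``catalog`` is a 96-row frame (one column per signature) indexed by
    context labels or positionally aligned to the canonical 96 ordering.
    Signatures that are constant get rho = NaN.
    """
    if len(catalog) != 96:
        raise ValueError("catalog must have 96 rows")
    if set(CONTEXTS_96).issubset(set(catalog.index)):
        catalog = catalog.loc[list(CONTEXTS_96)]
    v = spectrum.vector_96(normalize=True)
    rows = []
    for name in catalog.columns:
        w = catalog[name].to_numpy(dtype=float)
        if np.allclose(w, w[0]) or np.allclose(v, v[0]):
            rows.append((name, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(v, w)
        rows.append((name, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["signature", "rho", "p"]).set_index(
        "signature")
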