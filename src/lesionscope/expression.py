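"""Differential-expression statistics on fluorescence-scale matrices.

Fold-changes are computed on the raw (unlogged) scale with the signed
convention (fc = ratio if >= 1 else -1/ratio), t-tests on log2 values,
and false-discovery rates by the Storey q-value procedure (smoother-based
pi0 estimate with a Benjamini-Hochberg fallback at pi0 = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "differential_expression",
    "qvalue",
    "estimate_pi0",
    "two_tier_stratify",
]


@dataclass
class ExpressionMatrix:
    """Probes/genes x samples matrix of non-negative abundance values."""

    values: pd.DataFrame
    groups: pd.Series | None = None   # sample -> group label

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.groups is not None:
            missing = set(self.values.columns) - set(self.groups.index)
            if missing:
                raise ValueError(f"samples without group label: {missing}")


@dataclass
class DEResult:
    table: pd.DataFrame   # columns: fc, t, p, q, excluded


def _signed_fc(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    r = mean_a / mean_b
    return np.where(r >= 1.0, r, -1.0 / r)


def differential_expression(
    m: ExpressionMatrix,
    group_a: str | list[str],
    group_b: str | list[str],
    equal_var: bool = False,
) -> DEResult:
    """Per-probe raw-scale signed fold-change, t-test on log2, q-values.

    ``group_a``/``group_b`` name groups from ``m.groups`` or give explicit
    sample lists.  Welch's t is the default; pooled-variance optional.
    Probes with a zero group mean are flagged excluded and carry NaN
    statistics.
    """
    def resolve(g):
        if isinstance(g, str):
            if m.groups is None:
                raise ValueError("no group labels attached to the matrix")
            return list(m.groups.index[m.groups == g])
        return list(g)

    sa, sb = resolve(group_a), resolve(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 samples per group")
    A = m.values[sa].to_numpy(dtype=float)
    B = m.values[sb].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    excluded = (mean_a == 0) | (mean_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = _signed_fc(mean_a, mean_b)
    ok = ~excluded
    t = np.full(len(fc), np.nan)
    p = np.full(len(fc), np.nan)
    if ok.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(
                np.log2(np.maximum(A[ok], 1e-300)),
                np.log2(np.maximum(B[ok], 1e-300)),
                axis=1, equal_var=equal_var)
        t[ok], p[ok] = res.statistic, res.pvalue
    # identical constant groups yield 0/0 -> treat as no evidence
    p = np.where(ok & ~np.isfinite(p), 1.0, p)
    t = np.where(ok & ~np.isfinite(t), 0.0, t)
    q = np.full(len(fc), np.nan)
    if ok.any():
        q[ok] = qvalue(p[ok])
    fc = np.where(excluded, np.nan, fc)
    table = pd.DataFrame(
        {"fc": fc, "t": t, "p": p, "q": q, "excluded": excluded},
        index=m.values.index)
    return DEResult(table=table)


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's pi0: cubic-smoother over pi0(lambda), evaluated at max lambda.

    Falls back to 1.0 (Benjamini-Hochberg behavior) when the estimate
    leaves (0, 1] or too few distinct lambdas are usable.
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    if len(lambdas) < 4:
        est = pi0_l[-1]
    else:
        try:
            spline = UnivariateSpline(lambdas, pi0_l, k=3)
            est = float(spline(lambdas[-1]))
        except Exception:
            est = float(pi0_l[-1])
    if not np.isfinite(est) or est > 1.0 or est <= 0.0:
        return 1.0
    return est


def qvalue(p: np.ndarray | list[float]) -> np.ndarray:
    """Storey-style q-values: q_(i) = min_{j>=i} pi0 * m * p_(j) / j."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = estimate_pi0(p) if m >= 100 else 1.0
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.minimum(qs, 1.0)
    out = np.empty(m)
    out[order] = qs
    return out


def two_tier_stratify(
    values: pd.Series, buffer: float = 0.05
) -> pd.Series:
    """Median split into high/low, excluding a quantile buffer at the split.

    Cases whose quantile rank falls within +/- ``buffer`` of 0.5 are
    excluded (label NaN); the rest are labeled "high"/"low".  Errors on a
    degenerate (constant) score vector or on buffer >= 0.5.
    """
    if buffer >= 0.5 or buffer < 0:
        raise ValueError("buffer must lie in [0, 0.5)")
    if len(values) < 3:
        raise ValueError("need >= 3 cases to stratify")
    v = values.astype(float)
    if v.nunique() <= 1:
        raise ValueError("constant scores: no valid two-tier split")
    # mid-quantile ranks in (0, 1)
    qrank = (stats.rankdata(v.to_numpy()) - 0.5) / len(v)
    labels = pd.Series(
        np.where(qrank >= 0.5, "high", "low"), index=v.index, dtype=object)
    if buffer > 0:
        buffered = np.abs(qrank - 0.5) < buffer
        labels[buffered] = np.nan
    return labels
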