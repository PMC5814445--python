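"""Drug-combination screen analytics with the ZIP reference model.

A plate is a 7x7 matrix of two-drug concentrations (log-spaced over a
1000-fold range) plus monotherapy wells and positive/negative controls.
Raw luminescence is normalized to percent inhibition, monotherapy
responses are fit with a four-parameter logistic (Hill) curve, and each
combination well is scored against the zero-interaction-potency (ZIP)
expectation y_zip = y_a + y_b - y_a*y_b; the per-well delta (observed
minus expected, in percentage points) is positive for synergy.  Cohort
ranking uses within-case ranks (highest delta = highest rank), rank-sums,
the Friedman test, and pairwise Wilcoxon signed-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponsePlate",
    "HillFit",
    "DeltaResult",
    "hill",
    "normalize_inhibition",
    "fit_hill",
    "zip_delta",
    "rank_combinations",
]


@dataclass
class DoseResponsePlate:
    """One two-drug combination plate.

    ``grid`` is raw luminescence indexed by drug-A concentration (rows)
    and drug-B concentration (columns), both in nM.  ``mono_a``/``mono_b``
    hold the monotherapy wells (dose -> raw value); ``pos``/``neg`` are
    control-well values (toxic reference / vehicle).
    """

    drug_a: str
    drug_b: str
    grid: pd.DataFrame
    mono_a: pd.Series
    mono_b: pd.Series
    pos: list[float]
    neg: list[float]
    plate_id: str = ""

    def __post_init__(self) -> None:
        for axis in (self.grid.index, self.grid.columns):
            conc = np.asarray(axis, dtype=float)
            if (conc <= 0).any():
                raise ValueError("non-positive concentration on plate axis")
        if not self.pos or not self.neg:
            raise ValueError("plate needs >= 1 positive and negative control")


@dataclass
class HillFit:
    emin: float
    emax: float
    ec50: float
    slope: float
    rss: float
    converged: bool = True
    low_signal: bool = False

    def predict(self, dose: np.ndarray | float) -> np.ndarray | float:
        return hill(dose, self.emin, self.emax, self.ec50, self.slope)


def hill(x, emin, emax, ec50, slope):
    """Four-parameter logistic: emin + (emax-emin) / (1 + (ec50/x)^slope)."""
    x = np.asarray(x, dtype=float)
    return emin + (emax - emin) / (1.0 + (ec50 / x) ** slope)


def _control_means(plate: DoseResponsePlate) -> tuple[float, float]:
    return float(np.mean(plate.neg)), float(np.mean(plate.pos))


def normalize_inhibition(
    raw, neg_mean: float, pos_mean: float, mode: str = "as-printed"
):
    """Raw luminescence to percent inhibition.

    mode "as-printed": 100 * (neg - well) / (pos + neg) — the screen's
    stated normalization, with the unusual sum denominator; mode "span"
    (conventional): 100 * (neg - well) / (neg - pos).  Values are not
    clipped and may leave [0, 100].
    """
    raw = np.asarray(raw, dtype=float)
    if mode == "as-printed":
        denom = pos_mean + neg_mean
    elif mode == "span":
        denom = neg_mean - pos_mean
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0:
        raise ValueError("degenerate controls: zero denominator")
    return 100.0 * (neg_mean - raw) / denom


def normalize_plate(
    plate: DoseResponsePlate, mode: str = "span"
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Percent-inhibition grid and monotherapy vectors for one plate."""
    neg, pos = _control_means(plate)
    grid = pd.DataFrame(
        normalize_inhibition(plate.grid.to_numpy(), neg, pos, mode),
        index=plate.grid.index, columns=plate.grid.columns)
    ma = pd.Series(normalize_inhibition(plate.mono_a.to_numpy(), neg, pos,
                                        mode), index=plate.mono_a.index)
    mb = pd.Series(normalize_inhibition(plate.mono_b.to_numpy(), neg, pos,
                                        mode), index=plate.mono_b.index)
    return grid, ma, mb


def fit_hill(doses: np.ndarray, responses: np.ndarray) -> HillFit:
    """Least-squares Hill fit of percent-inhibition monotherapy data.

    Multi-start over slope {0.5, 1, 2, 4} with EC50 initialized at the
    geometric median dose; bounds emin in [-20, 50], emax in [0, 120],
    slope in (0, 10].  Flat near-zero responses return a flagged
    low-signal fit.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(doses) < 4:
        raise ValueError("need >= 4 dose points for a Hill fit")
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    if np.ptp(responses) < 1.0 and np.abs(responses).max() < 5.0:
        base = float(np.mean(responses))
        return HillFit(base, base, float(np.median(doses)), 1.0,
                       float(((responses - base) ** 2).sum()),
                       converged=True, low_signal=True)
    ec50_0 = float(np.exp(np.median(np.log(doses))))
    lo = [-20.0, 0.0, doses.min() / 1e3, 1e-6]
    hi = [50.0, 120.0, doses.max() * 1e3, 10.0]
    best: HillFit | None = None
    for slope0 in (0.5, 1.0, 2.0, 4.0):
        p0 = [max(min(responses.min(), 50.0), -20.0),
              min(max(responses.max(), 1.0), 120.0), ec50_0, slope0]
        p0 = np.clip(p0, lo, hi)
        try:
            popt, _ = curve_fit(
                hill, doses, responses, p0=p0, bounds=(lo, hi),
                maxfev=20000, xtol=1e-13, ftol=1e-13, gtol=1e-13)
        except RuntimeError:
            continue
        rss = float(((hill(doses, *popt) - responses) ** 2).sum())
        if best is None or rss < best.rss:
            best = HillFit(*map(float, popt), rss)
    if best is None:
        base = float(np.mean(responses))
        return HillFit(base, base, ec50_0, 1.0,
                       float(((responses - base) ** 2).sum()),
                       converged=False)
    return best


@dataclass
class DeltaResult:
    delta: pd.DataFrame           # per-well, percentage points
    summary: float                # mean over the whole matrix
    low_dose_summary: float       # mean over wells with both doses in window
    low_dose_window: tuple[float, float] = (1.0, 300.0)
    mode: str = "span"
    fit_a: HillFit | None = None
    fit_b: HillFit | None = None


def zip_delta(
    plate: DoseResponsePlate,
    mode: str = "span",
    low_dose_window: tuple[float, float] = (1.0, 300.0),
    fit_a: HillFit | None = None,
    fit_b: HillFit | None = None,
) -> DeltaResult:
    """ZIP delta scores for one plate.

    Observed inhibition fractions are clipped to [0, 1]; the
    zero-interaction expectation combines the fitted monotherapy
    fractions multiplicatively (probabilistic independence).  Per-well
    delta = 100 * (y_obs - y_zip); the low-dose summary averages wells
    with both concentrations inside the window (inclusive).
    """
    grid, mono_a, mono_b = normalize_plate(plate, mode)
    if fit_a is None:
        fit_a = fit_hill(mono_a.index.to_numpy(float), mono_a.to_numpy())
    if fit_b is None:
        fit_b = fit_hill(mono_b.index.to_numpy(float), mono_b.to_numpy())
    da = grid.index.to_numpy(float)
    db = grid.columns.to_numpy(float)
    ya = np.clip(np.asarray(fit_a.predict(da)) / 100.0, 0.0, 1.0)
    yb = np.clip(np.asarray(fit_b.predict(db)) / 100.0, 0.0, 1.0)
    y_zip = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]
    y_obs = np.clip(grid.to_numpy() / 100.0, 0.0, 1.0)
    delta = 100.0 * (y_obs - y_zip)
    lo, hi_w = low_dose_window
    in_win = ((da >= lo) & (da <= hi_w))[:, None] & \
             ((db >= lo) & (db <= hi_w))[None, :]
    if not in_win.any():
        raise ValueError("no well inside the low-dose window")
    return DeltaResult(
        delta=pd.DataFrame(delta, index=grid.index, columns=grid.columns),
        summary=float(delta.mean()),
        low_dose_summary=float(delta[in_win].mean()),
        low_dose_window=low_dose_window,
        mode=mode, fit_a=fit_a, fit_b=fit_b)


@dataclass
class RankingResult:
    ranks: pd.DataFrame           # case x combination, highest delta = k
    rank_sums: pd.Series
    friedman_stat: float
    friedman_p: float
    pairwise_wilcoxon: pd.DataFrame


def rank_combinations(deltas: pd.DataFrame) -> RankingResult:
    """Cross-case ranking of combination low-dose delta summaries.

    ``deltas`` is cases x combinations, complete (no imputation).
    Within each case combinations are ranked ascending so the highest
    delta receives rank k (ties mid-ranked); rank-sums per combination
    always total n*k*(k+1)/2.  The Friedman test (tie-corrected, as
    implemented in scipy) and pairwise two-sided Wilcoxon signed-rank
    tests accompany the ranking.
    """
    if deltas.isna().any().any():
        raise ValueError("missing delta cells; ranking requires completeness")
    k = deltas.shape[1]
    if k < 2:
        raise ValueError("need >= 2 combinations")
    ranks = deltas.rank(axis=1, method="average", ascending=True)
    rank_sums = ranks.sum(axis=0)
    cols = [deltas[c].to_numpy() for c in deltas.columns]
    if all(np.array_equal(cols[0], c) for c in cols[1:]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(*cols)
    combos = list(deltas.columns)
    rows = []
    for i, ca in enumerate(combos):
        for cb in combos[i + 1:]:
            diff = deltas[ca].to_numpy() - deltas[cb].to_numpy()
            if np.allclose(diff, 0):
                pw = 1.0
            else:
                pw = float(stats.wilcoxon(diff)[1])
            rows.append({"combo_a": ca, "combo_b": cb, "p": pw})
    return RankingResult(
        ranks=ranks, rank_sums=rank_sums,
        friedman_stat=float(stat), friedman_p=float(p),
        pairwise_wilcoxon=pd.DataFrame(rows))
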