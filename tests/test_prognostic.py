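"""Survival-index tests: extremes, Cox scores, SAM FDR, median polish."""

import numpy as np
import pandas as pd
import pytest

from lesionscope.prognostic import (
    SurvivalRecord,
    cox_score_stats,
    logrank_test,
    median_polish,
    probe_index,
    sam_survival,
    select_extremes,
    train_index,
)


def records(times, events=None, prefix="C"):
    events = events if events is not None else [True] * len(times)
    return [SurvivalRecord(f"{prefix}{i}", t, e)
            for i, (t, e) in enumerate(zip(times, events))]


class TestSelectExtremes:
    def test_basic_split(self):
        long_ids, short_ids = select_extremes(
            records([100, 250, 900, 1200]))
        assert len(short_ids) == 2 and len(long_ids) == 2

    def test_boundaries_exclusive(self):
        recs = records([800, 300, 900, 100])
        long_ids, short_ids = select_extremes(recs)
        assert "C0" not in long_ids + short_ids   # exactly 800: neither
        assert "C1" not in long_ids + short_ids   # exactly 300: neither

    def test_short_requires_event(self):
        recs = records([100, 150, 900], events=[False, True, True])
        long_ids, short_ids = select_extremes(recs)
        assert short_ids == ["C1"]     # censored at 100 is not poor outcome

    def test_degenerate_error(self):
        with pytest.raises(ValueError):
            select_extremes(records([500, 500, 500]))


def brute_force_cox_score(x, time, event):
    """Independent score/variance computation (no ties assumed)."""
    u = v = 0.0
    for j in range(len(time)):
        if not event[j]:
            continue
        risk = time >= time[j]
        mu = x[risk].mean()
        u += x[j] - mu
        v += (x[risk] ** 2).mean() - mu ** 2
    return u, np.sqrt(v)


class TestCoxScore:
    def test_matches_brute_force(self, rng):
        n = 30
        time = rng.exponential(500, n)
        event = rng.random(n) < 0.7
        X = rng.normal(size=(5, n))
        r, s = cox_score_stats(X, time, event)
        for i in range(5):
            u_bf, s_bf = brute_force_cox_score(X[i], time, event)
            assert r[i] == pytest.approx(u_bf)
            assert s[i] == pytest.approx(s_bf)

    def test_invariant_to_case_order(self, rng):
        n = 20
        time = rng.exponential(500, n)
        event = rng.random(n) < 0.7
        X = rng.normal(size=(3, n))
        r1, s1 = cox_score_stats(X, time, event)
        perm = rng.permutation(n)
        r2, s2 = cox_score_stats(X[:, perm], time[perm], event[perm])
        assert np.allclose(r1, r2) and np.allclose(s1, s2)

    def test_efron_tied_events_finite(self, rng):
        time = np.array([5.0, 5.0, 5.0, 8.0, 8.0, 10.0])
        event = np.array([True, True, False, True, True, False])
        X = rng.normal(size=(4, 6))
        r, s = cox_score_stats(X, time, event)
        assert np.isfinite(r).all() and (s >= 0).all()


class TestSamSurvival:
    def make_data(self, rng, n_probes=60, n=20, signal_rows=()):
        time = rng.exponential(500, n)
        event = np.ones(n, dtype=bool)
        X = rng.normal(size=(n_probes, n))
        for row in signal_rows:
            X[row] = -np.log(time) + rng.normal(0, 0.1, n)
        expr = pd.DataFrame(X, index=[f"p{i}" for i in range(n_probes)],
                            columns=[f"C{i}" for i in range(n)])
        recs = pd.DataFrame({"time": time, "event": event},
                            index=expr.columns)
        return expr, recs

    def test_constructed_effect_attains_max_score(self, rng):
        expr, recs = self.make_data(rng, signal_rows=(7,))
        res = sam_survival(expr, recs, n_perm=50, seed=1)
        assert np.abs(res.scores).idxmax() == "p7"

    def test_null_probe_high_fdr(self, rng):
        expr, recs = self.make_data(rng)
        res = sam_survival(expr, recs, n_perm=100, seed=1)
        # on pure noise nothing should be called at a strict FDR
        assert res.called_at(0.05) == [] or len(res.called_at(0.05)) <= 2

    def test_fdr_monotone_in_delta(self, rng):
        expr, recs = self.make_data(rng, signal_rows=(0, 1))
        res = sam_survival(expr, recs, n_perm=50, seed=2)
        assert (np.diff(res.fdr_table["fdr"]) <= 1e-12).all()

    def test_deterministic_under_seed(self, rng):
        expr, recs = self.make_data(rng, signal_rows=(3,))
        r1 = sam_survival(expr, recs, n_perm=50, seed=9)
        r2 = sam_survival(expr, recs, n_perm=50, seed=9)
        pd.testing.assert_frame_equal(r1.fdr_table, r2.fdr_table)
        assert r1.s0 == r2.s0

    def test_requires_events(self):
        expr = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        recs = pd.DataFrame({"time": [1, 2, 3, 4],
                             "event": [False] * 4}, index=list("abcd"))
        with pytest.raises(ValueError):
            sam_survival(expr, recs, n_perm=10, seed=0)


class TestMedianPolish:
    def test_hand_iterated_2x2(self):
        overall, row, col, resid = median_polish(
            np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert overall == pytest.approx(2.5)
        assert row == pytest.approx([-1.0, 1.0])
        assert col == pytest.approx([-0.5, 0.5])
        assert np.allclose(resid, 0.0)

    def test_constant_matrix(self):
        overall, row, col, resid = median_polish(np.full((3, 4), 7.0))
        assert overall == pytest.approx(7.0)
        assert np.allclose(row, 0) and np.allclose(col, 0)
        assert np.allclose(resid, 0)

    def test_single_row(self):
        overall, row, col, resid = median_polish(
            np.array([[1.0, 5.0, 9.0]]))
        assert overall + row[0] == pytest.approx(5.0)
        assert np.allclose(overall + row[:, None] + col + resid,
                           [[1, 5, 9]])

    def test_reconstruction_identity(self, rng):
        M = rng.normal(size=(7, 11))
        overall, row, col, resid = median_polish(M)
        recon = overall + row[:, None] + col[None, :] + resid
        assert np.allclose(recon, M, atol=1e-12)
        # residual row/col medians vanish at convergence
        assert np.abs(np.median(resid, axis=1)).max() < 1e-6
        assert np.abs(np.median(resid, axis=0)).max() < 1e-6

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            median_polish(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestTrainIndex:
    def test_recovers_planted_probes(self, small_cohort):
        b = small_cohort
        expr = np.log2(b.expression)
        m = train_index(expr, b.survival.loc[expr.columns],
                        n_perm=100, seed=0)
        planted = {p for p in expr.index if p.startswith("P_surv")}
        assert set(m.probes) & planted
        assert len(set(m.probes) - planted) <= 1
        assert len(m.index) == expr.shape[1]

    def test_no_signal_raises_with_diagnostics(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(50, 30)),
            index=[f"p{i}" for i in range(50)],
            columns=[f"C{i}" for i in range(30)])
        times = np.concatenate([rng.uniform(20, 290, 15),
                                rng.uniform(810, 2000, 15)])
        recs = pd.DataFrame(
            {"time": times, "event": [True] * 30}, index=expr.columns)
        with pytest.raises(ValueError, match="SAM pass"):
            train_index(expr, recs, n_perm=50, seed=3)

    def test_index_is_overall_plus_column_effect(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 8)),
                            index=list("abc"),
                            columns=[f"C{i}" for i in range(8)])
        idx = probe_index(expr, ["a", "b", "c"])
        overall, _, col, _ = median_polish(expr.to_numpy())
        assert np.allclose(idx.to_numpy(), overall + col)


class TestLogrank:
    def test_identical_groups_null(self):
        times = np.array([100, 200, 300, 400.0] * 2)
        events = np.array([True] * 8)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        stat, p, km = logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_observed_minus_expected(self):
        # textbook two-group fixture, all events, no ties
        t1 = np.array([1.0, 3.0, 5.0])
        t2 = np.array([2.0, 4.0, 6.0])
        times = np.concatenate([t1, t2])
        events = np.ones(6, dtype=bool)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        # hand computation of the log-rank chi-square
        o_minus_e = 0.0
        var = 0.0
        for t in sorted(times):
            at_risk = times >= t
            n = at_risk.sum()
            n1 = (at_risk & (groups == "a")).sum()
            d = 1
            e1 = d * n1 / n
            o1 = 1 if (times == t).argmax() < 3 else 0
            o_minus_e += o1 - e1
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_stat = o_minus_e ** 2 / var
        stat, p, _ = logrank_test(times, events, groups)
        assert stat == pytest.approx(expected_stat)

    def test_power_under_strong_hazard_ratio(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            t1 = rng.exponential(300, 100)
            t2 = rng.exponential(900, 100)
            times = np.concatenate([t1, t2])
            events = np.ones(200, dtype=bool)
            groups = np.array(["a"] * 100 + ["b"] * 100)
            _, p, _ = logrank_test(times, events, groups)
            hits += p < 0.01
        assert hits >= 95

    def test_one_group_empty_error(self):
        with pytest.raises(ValueError):
            logrank_test(np.array([1.0, 2.0]), np.array([True, True]),
                         np.array(["a", "a"]))
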