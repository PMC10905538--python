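"""Product-limit estimation, pooling, normalization, log-rank, response."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tidi import survival, reference


def make_table(times, statuses, run_id="run1", line_id="HN0",
               population="1:1"):
    times = [np.nan if s == 2 else t for t, s in zip(times, statuses)]
    return pd.DataFrame({"trap_id": range(len(times)),
                         "event_time_h": times, "status_code": statuses,
                         "population": population, "run_id": run_id,
                         "line_id": line_id})


def km_oracle(times, statuses, t_query, horizon=24.0):
    """Brute-force product-limit: literal product over distinct event times,
    recomputing the risk set by iteration each time."""
    obs = [(t if s == 1 else horizon, s == 1)
           for t, s in zip(times, statuses)]
    s = 1.0
    for te in sorted({t for t, e in obs if e}):
        if te > t_query:
            break
        n = sum(1 for t, _ in obs if t >= te)
        d = sum(1 for t, e in obs if e and t == te)
        s *= (n - d) / n
    return s


class TestKaplanMeier:
    def test_hand_example(self):
        tab = make_table([2.0, 5.0, None, None], [1, 1, 2, 2])
        c = survival.km_estimate(tab, 24.0)
        assert c.at(24.0) == pytest.approx(0.5)
        assert c.at(3.0) == pytest.approx(0.75)

    def test_no_events_survival_one(self):
        tab = make_table([None] * 8, [2] * 8)
        c = survival.km_estimate(tab, 24.0)
        assert np.all(c.S == 1.0)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="no traps"):
            survival.km_estimate(make_table([], []), 24.0)

    def test_curve_invariants(self):
        rng = np.random.default_rng(3)
        t = np.ceil(rng.exponential(9, 40) * 3) / 3
        s = np.where(t <= 24, 1, 2)
        tab = make_table(np.where(s == 1, t, np.nan), s)
        c = survival.km_estimate(tab, 24.0)
        assert c.S[0] == 1.0 and c.times[0] == 0.0
        assert np.all(np.diff(c.S) <= 1e-12)          # non-increasing
        assert np.all(np.diff(c.n_risk[1:]) <= 0)
        assert 0 <= c.S.min() and c.S.max() <= 1

    def test_end_censoring_survivors_over_n0(self):
        rng = np.random.default_rng(4)
        t = np.ceil(rng.exponential(15, 60) * 3) / 3
        s = np.where(t <= 24, 1, 2)
        tab = make_table(np.where(s == 1, t, np.nan), s)
        c = survival.km_estimate(tab, 24.0)
        assert c.at(24.0) == pytest.approx((s == 2).sum() / 60)

    @pytest.mark.parametrize("n", [1, 2, 5, 12, 20])
    def test_matches_bruteforce_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            t = np.round(rng.exponential(8, n) * 3) / 3 + 1 / 3
            s = np.where(t <= 24, rng.integers(1, 3, n), 2)
            tab = make_table(np.where(s == 1, t, np.nan), s)
            c = survival.km_estimate(tab, 24.0)
            for q in (1.0, 6.0, 12.0, 24.0):
                assert c.at(q) == pytest.approx(
                    km_oracle(np.where(s == 1, t, np.nan), s, q))

    def test_exhaustive_small_status_patterns(self):
        """All status assignments over a fixed small time grid agree with
        the brute-force oracle."""
        times = [2.0, 2.0, 8.0, 16.0]
        for statuses in itertools.product([1, 2], repeat=4):
            tab = make_table(times, statuses)
            c = survival.km_estimate(tab, 24.0)
            for q in (2.0, 10.0, 24.0):
                assert c.at(q) == pytest.approx(
                    km_oracle(times, statuses, q))

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(7)
        t = np.ceil(rng.exponential(10, 50) * 3) / 3
        s = np.where(t <= 24, 1, 2)
        tab = make_table(np.where(s == 1, t, np.nan), s)
        c = survival.km_estimate(tab, 24.0)
        kmf = KaplanMeierFitter().fit(np.where(s == 1, t, 24.0), s == 1)
        for q in (4.0, 12.0, 24.0):
            assert c.at(q) == pytest.approx(float(kmf.predict(q)))


class TestTable1Values:
    """Published 24-h survivabilities recovered from reconstructed
    per-trap event tables (end-censoring makes S(24) = survivors/n0)."""

    @pytest.mark.parametrize("line,n_traps,s24", [
        ("HN9", 263, 0.9924),
        ("HN5", 221, 0.3439),
        ("HN10", 525, 0.7409),
    ])
    def test_pooled_one_to_one_survivability(self, line, n_traps, s24):
        pooled = survival.pool_runs(
            reference.synthetic_event_tables(line, "1:1"))
        assert len(pooled) == n_traps
        c = survival.km_estimate(pooled, 24.0)
        assert abs(c.at(24.0) - s24) <= 1e-4

    def test_hn9_survivors_over_n0(self):
        assert 261 / 263 == pytest.approx(0.9924, abs=5e-5)

    def test_hn5_run_counts(self):
        tabs = reference.synthetic_event_tables("HN5", "1:1")
        assert sorted(len(t) for t in tabs) == [83, 138]


class TestPooling:
    def test_pool_counts(self):
        a = make_table([1.0, None], [1, 2], run_id="run1")
        b = make_table([2.0, None, None], [1, 2, 2], run_id="run2")
        assert len(survival.pool_runs([a, b])) == 5

    def test_pool_identity(self):
        a = make_table([1.0], [1])
        out = survival.pool_runs([a])
        pd.testing.assert_frame_equal(out, a)

    def test_pool_self_guarded(self):
        a = make_table([1.0], [1])
        with pytest.raises(ValueError, match="run_id"):
            survival.pool_runs([a, a])

    def test_pool_mixed_lines_rejected(self):
        a = make_table([1.0], [1], line_id="HN1")
        b = make_table([1.0], [1], run_id="run2", line_id="HN2")
        with pytest.raises(ValueError, match="line"):
            survival.pool_runs([a, b])


class TestNormalization:
    def _curve(self, times, s):
        n = len(times)
        return survival.SurvivalCurve(np.asarray(times, float),
                                      np.asarray(s, float),
                                      np.arange(n, 0, -1),
                                      np.zeros(n, int), np.zeros(n, int),
                                      n)

    def test_degenerate_control_identity(self):
        exp = self._curve([0, 12, 24], [1.0, 0.8, 0.6])
        cont = self._curve([0, 12, 24], [1.0, 1.0, 1.0])
        out = survival.normalize_survival(exp, cont)
        assert out.degenerate_control
        np.testing.assert_allclose(out.S_norm, exp.S)

    def test_pointwise_arithmetic(self):
        exp = self._curve([0, 24], [1.0, 0.5])
        cont = self._curve([0, 24], [1.0, 0.8])
        with pytest.warns(UserWarning):
            out = survival.normalize_survival(exp, cont)
        assert out.S_norm[-1] == pytest.approx((0.5 - 0.8) / 0.2)  # -1.5

    def test_self_normalization_spans_unit_interval(self):
        c = self._curve([0, 8, 16, 24], [1.0, 0.9, 0.7, 0.4])
        out = survival.normalize_survival(c, c)
        assert out.S_norm.max() == pytest.approx(1.0)
        assert out.S_norm.min() == pytest.approx(0.0)


class TestLogRank:
    def test_identical_groups_null(self):
        a = make_table([2.0, 5.0, None], [1, 1, 2], run_id="run1")
        b = make_table([2.0, 5.0, None], [1, 1, 2], run_id="run2")
        r = survival.logrank_test(a, b)
        assert r.chi_square == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(11)
        t1 = np.ceil(rng.exponential(10, 30) * 3) / 3
        t2 = np.ceil(rng.exponential(5, 25) * 3) / 3
        a = make_table(np.where(t1 <= 24, t1, np.nan),
                       np.where(t1 <= 24, 1, 2))
        b = make_table(np.where(t2 <= 24, t2, np.nan),
                       np.where(t2 <= 24, 1, 2))
        r1 = survival.logrank_test(a, b)
        r2 = survival.logrank_test(b, a)
        assert r1.chi_square == pytest.approx(r2.chi_square)

    def test_invariance_to_time_rescaling(self):
        rng = np.random.default_rng(12)
        t1 = rng.exponential(10, 25)
        t2 = rng.exponential(4, 25)
        def tab(t, scale):
            s = np.where(t <= 24, 1, 2)
            return make_table(np.where(s == 1, t * scale, np.nan), s)
        r1 = survival.logrank_test(tab(t1, 1), tab(t2, 1), horizon_h=24)
        r2 = survival.logrank_test(tab(t1, 2), tab(t2, 2), horizon_h=48)
        assert r1.chi_square == pytest.approx(r2.chi_square)

    def test_no_events_warns(self):
        a = make_table([None, None], [2, 2])
        b = make_table([None], [2], run_id="run2")
        with pytest.warns(UserWarning):
            r = survival.logrank_test(a, b)
        assert (r.chi_square, r.p_value) == (0.0, 1.0)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll
        rng = np.random.default_rng(13)
        t1 = np.ceil(rng.exponential(12, 40) * 3) / 3
        t2 = np.ceil(rng.exponential(6, 35) * 3) / 3
        s1, s2 = np.where(t1 <= 24, 1, 2), np.where(t2 <= 24, 1, 2)
        a = make_table(np.where(s1 == 1, t1, np.nan), s1)
        b = make_table(np.where(s2 == 1, t2, np.nan), s2)
        r = survival.logrank_test(a, b)
        ref = ll(np.where(s1 == 1, t1, 24.0), np.where(s2 == 1, t2, 24.0),
                 s1 == 1, s2 == 1)
        assert r.chi_square == pytest.approx(ref.test_statistic)
        assert r.p_value == pytest.approx(ref.p_value)

    def test_power_against_separated_hazards(self):
        """lambda 0.01 vs 0.06 /h at n=200: rejection nearly always."""
        rng = np.random.default_rng(14)
        reject = 0
        reps = 50
        for _ in range(reps):
            t1 = np.ceil(rng.exponential(1 / 0.01, 200) * 3) / 3
            t2 = np.ceil(rng.exponential(1 / 0.06, 200) * 3) / 3
            s1, s2 = np.where(t1 <= 24, 1, 2), np.where(t2 <= 24, 1, 2)
            a = make_table(np.where(s1 == 1, t1, np.nan), s1)
            b = make_table(np.where(s2 == 1, t2, np.nan), s2)
            reject += survival.logrank_test(a, b).p_value < 0.05
        assert reject / reps >= 0.95


class TestResponse:
    def test_threshold_boundary_is_nonresponder(self):
        # exactly 0.75 survivability: strict < keeps it nonresponder
        tab = make_table([1.0] * 25 + [None] * 75, [1] * 25 + [2] * 75)
        call = survival.classify_response(tab, "X")
        assert call.S_at_24h == pytest.approx(0.75)
        assert call.label == "nonresponder"

    def test_hn5_responder_hn9_nonresponder(self):
        for line, want in [("HN5", "responder"), ("HN9", "nonresponder")]:
            pooled = survival.pool_runs(
                reference.synthetic_event_tables(line, "1:1"))
            assert survival.classify_response(pooled, line).label == want

    @given(st.floats(0.01, 0.99))
    def test_label_consistent_with_threshold(self, s24):
        n = 100
        k = int(round((1 - s24) * n))
        tab = make_table([1.0] * k + [None] * (n - k),
                         [1] * k + [2] * (n - k))
        call = survival.classify_response(tab, "X", threshold=0.75)
        assert (call.label == "responder") == (call.S_at_24h < 0.75)
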