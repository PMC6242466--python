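import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hdscreen.difftest import (
    TestParams,
    bh_adjust,
    call_hits,
    day_test,
    hit_sets,
    regularized_t,
    regularized_variance,
    window_background_variance,
)


def oracle_regularized_t(control, drug, s0c, s0d, conf):
    """Direct scalar evaluation of the posterior-variance t-test."""
    nc, nd = len(control), len(drug)
    mc = sum(control) / nc
    md = sum(drug) / nd
    s2c = sum((x - mc) ** 2 for x in control) / (nc - 1)
    s2d = sum((x - md) ** 2 for x in drug) / (nd - 1)
    vc = (conf * s0c + (nc - 1) * s2c) / (conf + nc - 2)
    vd = (conf * s0d + (nd - 1) * s2d) / (conf + nd - 2)
    t = (md - mc) / math.sqrt(vc / nc + vd / nd)
    df = nc + nd + 2 * conf - 4
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def oracle_bh(p):
    """Hand-coded Benjamini-Hochberg step-up adjustment."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestWindowBackgroundVariance:
    def test_equal_variances_passed_through(self):
        out = window_background_variance(np.arange(10.0), np.full(10, 0.7), 5)
        np.testing.assert_allclose(out, 0.7)

    def test_full_window_gives_global_mean(self):
        var = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = window_background_variance(np.arange(5.0), var, 5)
        np.testing.assert_allclose(out, 3.0)

    def test_hand_worked_truncated_windows(self):
        means = np.array([1.0, 2.0, 3.0, 4.0, 5.0])  # already ranked
        var = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = window_background_variance(means, var, 3)
        np.testing.assert_allclose(out, [1.5, 2.0, 3.0, 4.0, 4.5])

    def test_respects_ranking_not_input_order(self):
        means = np.array([4.0, 1.0, 2.0, 3.0])  # rank order: s1, s2, s3, s0
        var = np.array([40.0, 10.0, 20.0, 30.0])
        out = window_background_variance(means, var, 3)
        # ranked variances (10, 20, 30, 40); truncated windows give
        # (15, 20, 30, 35), mapped back to input order
        np.testing.assert_allclose(out, [35.0, 15.0, 20.0, 30.0])

    def test_oversized_window_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            out = window_background_variance(np.arange(4.0), np.ones(4), 9)
        np.testing.assert_allclose(out, 1.0)


class TestRegularizedT:
    def test_worked_example_conf15(self):
        control = np.array([[1.0, 1.2, 0.8, 1.0]])
        drug = np.array([[2.0, 2.2, 1.8, 2.0]])
        t, df, p, delta = regularized_t(control, drug, [0.04], [0.04], conf=15)
        # posterior variance (15*0.04 + 3*0.02667)/17 = 0.04 in both groups
        assert abs(t[0] - 1.0 / math.sqrt(0.02)) < 1e-6
        assert df[0] == 4 + 4 + 30 - 4
        assert delta[0] == pytest.approx(1.0)

    def test_equal_means_give_null_result(self):
        x = np.array([[1.0, 2.0, 3.0]])
        t, _, p, _ = regularized_t(x, x.copy(), [0.5], [0.5], conf=15)
        assert t[0] == 0.0 and p[0] == 1.0

    def test_large_conf_shrinks_to_background(self):
        s2, n, s0 = 0.9, 4, 0.04
        v = regularized_variance(s2, n, s0, conf=1e9)
        assert abs(v - s0) < 1e-6

    def test_matches_scalar_oracle_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            nc, nd = rng.integers(2, 7, 2)
            control = rng.normal(0, 1, nc)
            drug = rng.normal(0.4, 1.2, nd)
            s0c, s0d = rng.uniform(0.01, 2.0, 2)
            conf = rng.uniform(0.5, 40.0)
            t, df, p, _ = regularized_t(
                control[None, :], drug[None, :], [s0c], [s0d], conf=conf
            )
            ot, odf, op = oracle_regularized_t(list(control), list(drug), s0c, s0d, conf)
            assert abs(t[0] - ot) < 1e-9
            assert abs(df[0] - odf) < 1e-9
            assert abs(p[0] - op) < 1e-9

    def test_shrinkage_bounds_relative_to_student(self):
        rng = np.random.default_rng(1)
        control = rng.normal(0, 1, (50, 4))
        drug = rng.normal(0.5, 1, (50, 4))
        s2c = control.var(axis=1, ddof=1)
        s2d = drug.var(axis=1, ddof=1)
        hi = np.maximum(s2c, s2d) * 2 + 0.1  # background above both variances
        t_reg, _, _, _ = regularized_t(control, drug, hi, hi, conf=15)
        t_student = stats.ttest_ind(drug, control, axis=1).statistic
        assert (np.abs(t_reg) <= np.abs(t_student) + 1e-12).all()

    def test_too_few_replicates_yield_p_one(self):
        control = np.array([[1.0, np.nan, np.nan, np.nan]])
        drug = np.array([[2.0, 2.1, 1.9, 2.0]])
        t, _, p, _ = regularized_t(control, drug, [0.1], [0.1], conf=15)
        assert t[0] == 0.0 and p[0] == 1.0


class TestBHAdjust:
    def test_hand_worked_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.04])
        np.testing.assert_allclose(out, [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_hand_coded_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), oracle_bh(p), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestCallHits:
    @staticmethod
    def day_frame(strain, day, p_adj, delta):
        return {
            "strain_id": strain,
            "day": day,
            "p_raw": p_adj / 2,
            "p_adj": p_adj,
            "delta": delta,
        }

    def test_two_consistent_days_make_a_hit(self):
        df = pd.DataFrame(
            [
                self.day_frame("s1", 3, 0.005, 1.0),
                self.day_frame("s1", 4, 0.005, 0.8),
                self.day_frame("s1", 5, 0.5, 0.2),
            ]
        )
        out = call_hits(df, TestParams())
        assert out.loc[0, "is_hit"]
        assert out.loc[0, "direction"] == "+"
        assert out.loc[0, "n_days_significant"] == 2

    def test_single_day_is_not_a_hit(self):
        df = pd.DataFrame(
            [self.day_frame("s1", 3, 0.005, 1.0), self.day_frame("s1", 4, 0.5, 1.0)]
        )
        assert not call_hits(df, TestParams()).loc[0, "is_hit"]

    def test_opposite_sign_days_do_not_combine(self):
        df = pd.DataFrame(
            [self.day_frame("s1", 3, 0.005, 1.0), self.day_frame("s1", 4, 0.005, -1.0)]
        )
        assert not call_hits(df, TestParams()).loc[0, "is_hit"]

    def test_hit_sets_are_disjoint(self):
        rows = []
        for s in range(30):
            for d in (1, 2, 3):
                rows.append(
                    self.day_frame(f"s{s}", d, 0.001 if s % 3 else 0.5,
                                   (-1.0) ** s * 0.5)
                )
        hits = call_hits(pd.DataFrame(rows), TestParams())
        up, down = hit_sets(hits)
        assert not (up & down)

    def test_raw_threshold_option(self):
        df = pd.DataFrame(
            [
                self.day_frame("s1", 3, 0.018, 1.0),
                self.day_frame("s1", 4, 0.018, 1.0),
            ]
        )
        assert not call_hits(df, TestParams()).loc[0, "is_hit"]
        raw = TestParams(adjusted_threshold=False)
        assert call_hits(df, raw).loc[0, "is_hit"]  # raw p = adj/2 = 0.009


class TestDayTest:
    def test_runs_on_normalized_screen(self, small_screen):
        from hdscreen.normalize import normalize_table

        _, truth, table = small_screen
        norm = normalize_table(table)
        res = day_test(norm, 2)
        assert len(res) == 500
        assert res["p_adj"].between(0, 1).all()
        assert (res["p_adj"] >= res["p_raw"] - 1e-12).all()
        # spiked strains should dominate the smallest p-values
        top = set(res.nsmallest(20, "p_raw")["strain_id"])
        assert len(top & set(truth.spiked)) >= 15

    def test_rejects_raw_tables(self, small_screen):
        _, _, table = small_screen
        with pytest.raises(ValueError):
            day_test(table, 1)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            TestParams(window=4)
        with pytest.raises(ValueError):
            TestParams(conf=-1)
        with pytest.raises(ValueError):
            TestParams(alpha=0.0)
        with pytest.raises(ValueError):
            TestParams(min_days=0)
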