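import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import stagenet as sn
from stagenet.errors import DegenerateInputError
from stagenet.stats_core import spearman_against_rows


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def spearman_no_tie_formula(x, y):
    """rs = 1 - 6*sum(d^2) / (n*(n^2-1)) -- valid only without ties."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(x)
    return 1.0 - 6.0 * np.sum((rx - ry) ** 2) / (n * (n ** 2 - 1))


def spearman_permutation_p(x, y, rs_obs):
    """Exact two-sided permutation p for |rs| under the rank-permutation null."""
    n = len(x)
    xr = sps.rankdata(x)
    xc = xr - xr.mean()
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    pc = perms - perms.mean(axis=1, keepdims=True)
    rs_all = (pc @ xc) / np.sqrt((pc ** 2).sum(axis=1) * (xc ** 2).sum())
    return float(np.mean(np.abs(rs_all) >= abs(rs_obs) - 1e-12))


def mann_whitney_enumeration_p(x, y):
    """Exact two-sided p by enumerating all group-label assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    idx = range(len(pooled))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2.0
    us = [sum(ranks[list(c)]) - n1 * (n1 + 1) / 2
          for c in itertools.combinations(idx, n1)]
    us = np.asarray(us)
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12))


def km_product_limit(times, events):
    """Hand product-limit computation over distinct event times."""
    order = np.argsort(times, kind="stable")
    times, events = np.asarray(times, float)[order], np.asarray(events, bool)[order]
    out, s = [], 1.0
    for t in sorted(set(times[events])):
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / n_at_risk
        out.append((t, s))
    return out


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_perfect_monotone(self):
        assert sn.spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]).rs == 1.0

    def test_perfect_anti_monotone(self):
        assert sn.spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]).rs == -1.0

    def test_hand_computed_no_tie_case(self):
        # 1 - 6*4/60 = 0.6
        res = sn.spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.rs == pytest.approx(0.6)

    def test_perfect_correlation_p_positive(self):
        res = sn.spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert 0 < res.p_value <= 1

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            sn.spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_matches_no_tie_formula(self, rng):
        for n in (5, 8, 20, 50):
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            assert sn.spearman(x, y).rs == pytest.approx(
                spearman_no_tie_formula(x, y), abs=1e-12)

    def test_p_close_to_exact_permutation_small_n(self, rng):
        # the t-approximation tracks the exact permutation null at tiny n
        for n in (5, 6, 7):
            for _ in range(5):
                x = rng.permutation(n).astype(float)
                y = rng.permutation(n).astype(float)
                res = sn.spearman(x, y)
                p_exact = spearman_permutation_p(x, y, res.rs)
                assert abs(res.p_value - p_exact) <= 0.1

    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry_and_monotone_invariance(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=12)
        y = r.normal(size=12)
        rs = sn.spearman(x, y).rs
        assert sn.spearman(y, x).rs == pytest.approx(rs)
        assert sn.spearman(np.exp(x), y).rs == pytest.approx(rs)  # strict increasing
        assert sn.spearman(x, 3 * y + 7).rs == pytest.approx(rs)

    def test_vectorized_matches_scalar(self, rng):
        hub = rng.normal(size=30)
        rows = rng.normal(size=(20, 30))
        rows[3] = np.round(rows[3])  # inject ties
        rows[7] = 5.0  # constant row
        rs, p, const = spearman_against_rows(hub, rows)
        assert const[7] and math.isnan(rs[7])
        for i in range(20):
            if const[i]:
                continue
            ref = sn.spearman(hub, rows[i])
            assert rs[i] == pytest.approx(ref.rs, abs=1e-12)
            assert p[i] == pytest.approx(ref.p_value, rel=1e-9)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_exact_small_case(self):
        res = sn.mann_whitney([1, 2], [3, 4], mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.direction == "group2_higher"

    def test_identical_samples(self):
        res = sn.mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0
        assert res.direction == "none"

    def test_all_constant(self):
        res = sn.mann_whitney([5, 5, 5], [5, 5])
        assert res.p_value == 1.0 and res.direction == "none"

    def test_exact_matches_enumeration(self, rng):
        for n1, n2 in [(3, 4), (4, 4), (5, 3)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = sn.mann_whitney(x, y, mode="exact")
            assert res.p_value == pytest.approx(
                mann_whitney_enumeration_p(x, y), abs=1e-12)

    def test_exact_and_normal_agree_tie_free(self, rng):
        # |delta p| <= 0.01 for tie-free inputs with n1*n2 in [100, 400]
        for n1, n2 in [(10, 10), (20, 15), (20, 20)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2) + 0.5
            pe = sn.mann_whitney(x, y, mode="exact").p_value
            pn = sn.mann_whitney(x, y, mode="normal").p_value
            assert abs(pe - pn) <= 0.01

    def test_large_shift_highly_significant(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50) + 3.0
        res = sn.mann_whitney(x, y)
        assert res.p_value < 1e-3
        assert res.direction == "group2_higher"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sn.mann_whitney([], [1, 2])

    def test_auto_mode_switches_on_ties_and_size(self, rng):
        # tie-free, n1*n2 <= 400 -> exact result
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert sn.mann_whitney(x, y, "auto").p_value == \
            sn.mann_whitney(x, y, "exact").p_value
        # ties -> normal approximation
        xt = np.round(x)
        yt = np.round(y)
        assert sn.mann_whitney(xt, yt, "auto").p_value == \
            sn.mann_whitney(xt, yt, "normal").p_value


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_hand_computed_curve(self):
        curve = sn.km_fit([1, 2, 3], [True, False, True])
        assert curve.times == (1.0, 3.0)
        assert curve.survival[0] == pytest.approx(2 / 3)
        assert curve.survival[1] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        curve = sn.km_fit([5, 6, 7], [False, False, False])
        assert curve.times == ()
        assert curve.survival_at(100.0) == 1.0

    def test_all_events_distinct_times_telescoping(self):
        curve = sn.km_fit([1, 2, 3, 4], [True] * 4)
        assert curve.survival == pytest.approx((0.75, 0.5, 0.25, 0.0))
        assert curve.at_risk == (4, 3, 2, 1)

    def test_matches_one_minus_ecdf_no_censoring(self, rng):
        times = rng.exponential(100, size=40)
        curve = sn.km_fit(times, [True] * 40)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(1.0 - np.mean(times <= t), abs=1e-12)

    def test_matches_hand_product_limit_with_censoring(self, rng):
        times = np.round(rng.exponential(50, size=30)) + 1
        events = rng.random(30) < 0.7
        if not events.any():
            events[0] = True
        curve = sn.km_fit(times, events)
        oracle = km_product_limit(times, events)
        assert list(curve.times) == [t for t, _ in oracle]
        assert list(curve.survival) == pytest.approx([s for _, s in oracle])

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sn.km_fit([-1, 2], [True, True])

    def test_survival_non_increasing(self, rng):
        times = rng.exponential(10, size=50)
        events = rng.random(50) < 0.6
        s = sn.km_fit(times, events).survival
        assert all(a >= b for a, b in zip(s, s[1:]))


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

class TestLogrank:
    def test_identical_groups(self):
        t = [1, 2, 3, 4, 5]
        e = [True, True, False, True, False]
        res = sn.logrank(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0
        assert res.direction == "none"

    def test_label_swap_invariance(self, rng):
        t1 = rng.exponential(100, size=20)
        t2 = rng.exponential(50, size=25)
        e1 = rng.random(20) < 0.8
        e2 = rng.random(25) < 0.8
        a = sn.logrank(t1, e1, t2, e2)
        b = sn.logrank(t2, e2, t1, e1)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_time_shift_invariance(self, rng):
        t1 = rng.exponential(100, size=15)
        t2 = rng.exponential(40, size=15)
        e = [True] * 15
        a = sn.logrank(t1, e, t2, e)
        b = sn.logrank(t1 + 500, e, t2 + 500, e)
        assert a.statistic == pytest.approx(b.statistic)

    def test_no_events_vacuous(self):
        res = sn.logrank([1, 2], [False, False], [3, 4], [False, False])
        assert res.p_value == 1.0 and res.direction == "none"

    def test_direction_worse_group(self, rng):
        t_bad = rng.exponential(20, size=40)
        t_good = rng.exponential(200, size=40)
        res = sn.logrank(t_bad, [True] * 40, t_good, [True] * 40)
        assert res.direction == "group1_higher"  # group1 has worse survival
        assert res.p_value < 0.01

    def test_power_under_hazard_ratio_three(self):
        # HR=3, n=100/100, 20% censoring: rejection rate above 0.9
        rng = np.random.default_rng(404)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            t1 = rng.exponential(1.0, size=100)       # hazard 1
            t2 = rng.exponential(1.0 / 3.0, size=100)  # hazard 3
            e1 = rng.random(100) >= 0.2
            e2 = rng.random(100) >= 0.2
            t1 = np.where(e1, t1, t1 * rng.random(100))
            t2 = np.where(e2, t2, t2 * rng.random(100))
            if sn.logrank(t1, e1, t2, e2).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.9
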