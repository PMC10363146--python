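"""Statistical primitives: Spearman correlation, Mann-Whitney U,
Kaplan-Meier estimation and the two-group log-rank test.

Thin, contract-enforcing wrappers around scipy.stats and lifelines.  The
wrappers pin down the exact variants used throughout the pipeline: tie-aware
(mid-rank) Spearman with the two-sided t-approximation p-value; Mann-Whitney
with exact enumeration on small tie-free inputs and the tie- and
continuity-corrected normal approximation otherwise; the product-limit
survival estimator; and the 1-df Mantel-Cox chi-square.  All p-values are
clamped into (0, 1] so that perfect correlations report the smallest
representable positive p rather than 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError

_TINY_P = float(np.nextafter(0, 1))

#: Exact Mann-Whitney enumeration is used below this product of group sizes
#: (tie-free inputs only); above it the normal approximation takes over.
MW_EXACT_MAX_PRODUCT = 400


def _clamp_p(p: float) -> float:
    if not np.isfinite(p):
        return 1.0
    return float(min(max(p, _TINY_P), 1.0))


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    rs: float
    p_value: float
    n: int


def spearman(x, y) -> CorrelationResult:
    """Tie-aware Spearman correlation with two-sided t-approximation p.

    rs is the Pearson correlation of mid-ranks; the p-value comes from
    ``t = rs * sqrt((n-2) / (1-rs^2))`` on n-2 degrees of freedom, the
    standard large-sample approximation.  Requires n >= 4 and at least two
    distinct values per vector (a constant vector raises
    :class:`DegenerateInputError`; callers exclude such genes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman needs two equal-length 1-d vectors")
    n = x.size
    if n < 4:
        raise ValueError(f"spearman needs n >= 4, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector: Spearman undefined")
    res = sps.spearmanr(x, y)
    rs = float(res.statistic)
    if abs(abs(rs) - 1.0) < 1e-12:  # snap numerical noise on perfect ranks
        return CorrelationResult(rs=math.copysign(1.0, rs), p_value=_TINY_P, n=n)
    return CorrelationResult(rs=rs, p_value=_clamp_p(float(res.pvalue)), n=n)


def spearman_against_rows(hub: np.ndarray, rows: np.ndarray):
    """Vectorized Spearman of one vector against every row of a matrix.

    Returns ``(rs, p, constant_mask)`` where constant rows get NaN rs/p and
    ``constant_mask`` True.  Mid-ranks are used, so results match
    :func:`spearman` gene-by-gene (verified in the test suite).
    """
    hub = np.asarray(hub, dtype=float)
    rows = np.asarray(rows, dtype=float)
    n = hub.size
    if n < 4:
        raise ValueError(f"need n >= 4 samples, got {n}")
    if np.ptp(hub) == 0:
        raise DegenerateInputError("hub expression constant in this group")
    hr = sps.rankdata(hub)
    rr = sps.rankdata(rows, axis=1)
    constant = np.ptp(rows, axis=1) == 0

    hr_c = hr - hr.mean()
    rr_c = rr - rr.mean(axis=1, keepdims=True)
    denom = np.sqrt((hr_c ** 2).sum() * (rr_c ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (rr_c @ hr_c) / denom
    rs = np.clip(rs, -1.0, 1.0)
    near_one = np.abs(np.abs(rs) - 1.0) < 1e-12
    rs[near_one] = np.sign(rs[near_one])

    with np.errstate(invalid="ignore", divide="ignore"):
        t = rs * np.sqrt((n - 2) / (1.0 - rs ** 2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rs) >= 1.0, _TINY_P, p)
    p = np.clip(p, _TINY_P, 1.0)
    rs[constant] = np.nan
    p[constant] = np.nan
    return rs, p, constant


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    direction: str  # 'group1_higher' | 'group2_higher' | 'none'


def mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    *mode* ``'exact'`` enumerates the null distribution (tie-free inputs);
    ``'normal'`` uses the tie- and continuity-corrected normal
    approximation; ``'auto'`` picks exact when ``n1*n2 <= 400`` and the
    pooled sample is tie-free.  ``direction`` reports which group is
    stochastically higher (U1 relative to its null mean), ``'none'`` on an
    exact split.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney needs non-empty groups")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (x.size * y.size <= MW_EXACT_MAX_PRODUCT and not has_ties) \
            else "normal"
    u_mid = x.size * y.size / 2.0
    if np.ptp(pooled) == 0:
        # all values identical: no evidence either way (normal variance is 0)
        return TestResult(statistic=u_mid, p_value=1.0, direction="none")
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    if u1 > u_mid:
        direction = "group1_higher"
    elif u1 < u_mid:
        direction = "group2_higher"
    else:
        direction = "none"
    return TestResult(statistic=u1, p_value=_clamp_p(float(res.pvalue)),
                      direction=direction)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve evaluated at the distinct event times."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    n_events: tuple[int, ...]

    def survival_at(self, t: float) -> float:
        """S(t): step function, 1 before the first event."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s

    def restricted_mean(self, horizon: float) -> float:
        """Area under the curve up to *horizon* (restricted mean survival)."""
        area, prev_t, prev_s = 0.0, 0.0, 1.0
        for ti, si in zip(self.times, self.survival):
            if ti >= horizon:
                break
            area += prev_s * (ti - prev_t)
            prev_t, prev_s = ti, si
        area += prev_s * (horizon - prev_t)
        return area


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``S(t) = prod over event times t_i <= t of (1 - d_i / n_i)``.  A
    censored-only sample yields an empty step list, i.e. a flat curve at 1.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be equal-length 1-d vectors")
    if times.size and times.min() < 0:
        raise ValueError("negative survival time")
    if not events.any():
        return KMCurve(times=(), survival=(), at_risk=(), n_events=())
    kmf = KaplanMeierFitter().fit(times, event_observed=events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    t = tuple(float(v) for v in ev.index)
    sf = kmf.survival_function_["KM_estimate"]
    s = tuple(float(sf.loc[ti]) for ti in ev.index)
    return KMCurve(times=t, survival=s,
                   at_risk=tuple(int(v) for v in ev["at_risk"]),
                   n_events=tuple(int(v) for v in ev["observed"]))


# ---------------------------------------------------------------------------
# Log-rank (Mantel-Cox)
# ---------------------------------------------------------------------------

def logrank(times1, events1, times2, events2) -> TestResult:
    """Two-group log-rank test; 1-df chi-square from sum(O - E) with the
    hypergeometric variance at each pooled event time.

    ``direction`` names the group with the worse survival (lower restricted
    mean over the pooled follow-up): ``'group1_higher'`` means group 1 has
    the higher risk.  With no events anywhere the test is vacuous: p = 1,
    direction 'none'.
    """
    from lifelines.statistics import logrank_test

    t1 = np.asarray(times1, dtype=float)
    t2 = np.asarray(times2, dtype=float)
    e1 = np.asarray(events1, dtype=bool)
    e2 = np.asarray(events2, dtype=bool)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("logrank needs non-empty groups")
    if not e1.any() and not e2.any():
        return TestResult(statistic=0.0, p_value=1.0, direction="none")
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    chi2 = float(res.test_statistic)
    p = _clamp_p(float(res.p_value))
    horizon = float(max(t1.max(), t2.max()))
    rm1 = km_fit(t1, e1).restricted_mean(horizon)
    rm2 = km_fit(t2, e2).restricted_mean(horizon)
    if np.isclose(rm1, rm2):
        direction = "none"
    else:
        direction = "group1_higher" if rm1 < rm2 else "group2_higher"
    return TestResult(statistic=chi2, p_value=p, direction=direction)
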