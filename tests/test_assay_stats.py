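"""Welch t-test, significance stars, relative viability, deposition
comparison and the ThT dose-trend statistic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mshts.assay_stats import (
    STAR_THRESHOLDS_ALT, STAR_THRESHOLDS_DEFAULT, ThTTrace, deposition_compare,
    relative_viability, star_label, tht_dose_trend, traces_from_wide, welch_t,
)
from mshts.synthetic import ThTTruth, simulate_tht, simulate_viability


# ---------------------------------------------------------------------------
# Welch t-test

def test_identical_samples_give_null_result():
    x = [1.0, 2.0, 3.0]
    res = welch_t(x, x)
    assert res.t_stat == 0.0
    assert res.p_two_sided == 1.0
    assert res.stars == ""


def test_welch_matches_bruteforce_formulas():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([2.0, 3.0, 4.0])
    res = welch_t(x, y)
    sx2, sy2 = x.var(ddof=1) / 3, y.var(ddof=1) / 3
    t = (x.mean() - y.mean()) / math.sqrt(sx2 + sy2)
    df = (sx2 + sy2) ** 2 / (sx2 ** 2 / 2 + sy2 ** 2 / 2)
    assert res.t_stat == pytest.approx(t, rel=1e-12)
    assert res.df == pytest.approx(df, rel=1e-12)
    assert res.p_two_sided == pytest.approx(
        2 * sps.t.sf(abs(t), df), rel=1e-12)


def test_equal_n_equal_variance_matches_pooled_student():
    """With equal n and equal sample variances, Welch's t and df coincide
    with the pooled two-sample Student formulas."""
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = x + 2.5  # identical variance, shifted mean
    res = welch_t(x, y)
    n = x.size
    sp2 = (x.var(ddof=1) + y.var(ddof=1)) / 2
    t_pooled = (x.mean() - y.mean()) / math.sqrt(sp2 * 2 / n)
    assert res.t_stat == pytest.approx(t_pooled, abs=1e-10)
    assert res.df == pytest.approx(2 * n - 2, abs=1e-10)


def test_welch_antisymmetry():
    x = [1.0, 5.0, 2.0]
    y = [4.0, 4.5, 6.0, 5.5]
    a, b = welch_t(x, y), welch_t(y, x)
    assert a.t_stat == pytest.approx(-b.t_stat, rel=1e-12)
    assert a.p_two_sided == pytest.approx(b.p_two_sided, rel=1e-12)


def test_welch_rejects_tiny_samples():
    with pytest.raises(ValueError, match=">= 2"):
        welch_t([1.0], [1.0, 2.0])


def test_welch_zero_variance_conventions():
    same = welch_t([2.0, 2.0], [2.0, 2.0])
    assert same.p_two_sided == 1.0
    diff = welch_t([3.0, 3.0], [2.0, 2.0])
    assert diff.p_two_sided == 0.0 and diff.stars == "***"


def test_welch_agrees_with_scipy(rng):
    for _ in range(20):
        x = rng.normal(0, 1, rng.integers(3, 12))
        y = rng.normal(0.5, 2, rng.integers(3, 12))
        res = welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.t_stat == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)
        assert res.df == pytest.approx(ref.df, rel=1e-10)


# ---------------------------------------------------------------------------
# stars

@pytest.mark.parametrize("p,expected", [
    (0.04, "*"), (0.5, ""), (0.009, "**"), (0.004, "***"), (0.05, ""),
])
def test_star_label_default_profile(p, expected):
    assert star_label(p) == expected


def test_star_label_alternate_profile_differs_at_third_level():
    assert star_label(0.004, STAR_THRESHOLDS_DEFAULT) == "***"
    assert star_label(0.004, STAR_THRESHOLDS_ALT) == "**"
    assert star_label(0.0005, STAR_THRESHOLDS_ALT) == "***"


def test_star_label_rejects_invalid_p():
    for p in (-0.1, 1.1, float("nan")):
        with pytest.raises(ValueError):
            star_label(p)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(0, 1), st.floats(0, 1))
def test_star_label_monotone(p1, p2):
    lo, hi = sorted((p1, p2))
    assert len(star_label(lo)) >= len(star_label(hi))


# ---------------------------------------------------------------------------
# relative viability

def test_relative_viability_examples():
    groups = {"ctl": [0.8, 0.8], "treated": [0.32, 0.32], "dead": [0.0, 0.0]}
    rel = relative_viability(groups, "ctl")
    assert rel["ctl"] == pytest.approx(100.0)
    assert rel["treated"] == pytest.approx(40.0)
    assert rel["dead"] == 0.0


def test_relative_viability_gain_invariance(rng):
    raw = {"ctl": rng.uniform(0.5, 1.0, 6), "t": rng.uniform(0.2, 0.6, 6)}
    scaled = {k: 3.7 * v for k, v in raw.items()}
    a = relative_viability(raw, "ctl")
    b = relative_viability(scaled, "ctl")
    assert a["t"] == pytest.approx(b["t"], rel=1e-12)


def test_relative_viability_requires_positive_control():
    with pytest.raises(ValueError, match="control"):
        relative_viability({"ctl": [0.0, 0.0], "t": [1.0, 1.0]}, "ctl")
    with pytest.raises(ValueError, match="not present"):
        relative_viability({"t": [1.0, 1.0]}, "ctl")


# ---------------------------------------------------------------------------
# deposition comparison

def test_deposition_identical_group_gives_p1():
    groups = {"abeta_only": [10.0, 11.0, 9.0], "t1": [10.0, 11.0, 9.0]}
    out = deposition_compare(groups, "abeta_only")
    assert out.iloc[0].p == pytest.approx(1.0)
    assert out.iloc[0].direction == "none"


def test_deposition_strong_reduction_is_significant():
    """Generator-backed power check: a 5-fold deposition reduction with
    small replicate noise is detected at p < 0.01."""
    rng = np.random.default_rng(7)
    ref = 500.0 + rng.normal(0, 10, 3)
    treated = 100.0 + rng.normal(0, 10, 3)
    out = deposition_compare({"abeta_only": ref, "f5": treated}, "abeta_only")
    row = out.iloc[0]
    assert row.p < 0.01
    assert row.direction == "reduction"


def test_deposition_order_invariance(rng):
    groups = {"abeta_only": rng.normal(10, 1, 4), "a": rng.normal(8, 1, 4),
              "b": rng.normal(5, 1, 4)}
    out1 = deposition_compare(groups, "abeta_only")
    out2 = deposition_compare(dict(reversed(list(groups.items()))), "abeta_only")
    pd.testing.assert_frame_equal(out1, out2)


def test_deposition_missing_reference():
    with pytest.raises(ValueError, match="reference"):
        deposition_compare({"a": [1.0, 2.0]}, "abeta_only")


# ---------------------------------------------------------------------------
# ThT dose trend

def make_traces(endpoints, concs=(0.2, 2.0, 20.0), control=1000.0):
    times = np.linspace(0, 24, 5)
    traces = [ThTTrace("abeta", 0.0, times, np.linspace(0, control, 5))]
    for c, e in zip(concs, endpoints):
        traces.append(ThTTrace(f"c{c}", c, times, np.linspace(0, e, 5)))
    return traces


def test_strictly_decreasing_endpoints_give_perfect_agreement():
    res = tht_dose_trend(make_traces([800.0, 500.0, 100.0]))
    assert res.agreement == pytest.approx(-1.0)
    assert res.trend == "decreasing"
    np.testing.assert_allclose(res.endpoints["relative_to_control"],
                               [0.8, 0.5, 0.1])


def test_equal_endpoints_report_no_trend():
    res = tht_dose_trend(make_traces([500.0, 500.0, 500.0]))
    assert res.agreement == 0.0
    assert res.trend == "no trend"


def test_permutation_p_matches_enumeration():
    """4 concentrations: the one-sided permutation p-value equals the
    fraction of the 24 endpoint orderings with rank agreement at least as
    negative as observed (independent enumeration oracle)."""
    concs = (0.2, 2.0, 6.0, 20.0)
    ends = [800.0, 650.0, 700.0, 100.0]
    res = tht_dose_trend(make_traces(ends, concs=concs))

    def rho(order):
        return sps.spearmanr(concs, order).statistic

    count = sum(rho(perm) <= res.agreement + 1e-12
                for perm in itertools.permutations(ends))
    assert res.p_perm == pytest.approx(count / math.factorial(4))
    assert res.p_perm < 0.2


def test_trend_errors():
    traces = make_traces([800.0, 500.0, 100.0])
    bad = ThTTrace("x", 5.0, np.linspace(0, 20, 4), np.zeros(4))
    with pytest.raises(ValueError, match="time grid"):
        tht_dose_trend(traces + [bad])
    with pytest.raises(ValueError, match="amyloid-only"):
        tht_dose_trend(traces[1:])
    with pytest.raises(ValueError, match=">= 3"):
        tht_dose_trend(traces[:3])


def test_trend_on_simulated_tht_traces():
    truth = ThTTruth(1000.0, 0.5, 8.0, inhibition_fn=lambda c: c / (c + 2.0))
    wide = simulate_tht(truth, [0.0, 0.2, 2.0, 20.0], np.linspace(0, 24, 25),
                        noise_sd=0.0, seed=0)
    res = tht_dose_trend(traces_from_wide(wide))
    assert res.trend == "decreasing"
    assert res.agreement == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# simulator-backed calibration (small here; the full-size run lives in the
# acceptance suite)

def test_welch_power_on_simulated_viability():
    """Aggregation-only at 40 % vs treated at 65 % viability with small
    noise is significant at p < 0.05."""
    means = {"vehicle_control": 1.0, "abeta_only": 0.40, "treated": 0.65}
    df = simulate_viability(means, n_reps=6, noise_sd=0.03, seed=2)
    by = {g: s["absorbance"].to_numpy() for g, s in df.groupby("group")}
    res = welch_t(by["treated"], by["abeta_only"])
    assert res.p_two_sided < 0.05
    assert res.t_stat > 0
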