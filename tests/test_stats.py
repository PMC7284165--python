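"""Circular V-test, ANOVA/Tukey, paired tests and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hippodwi.stats import (anova_tukey, axial_mean, build_report, correlate,
                            paired_test, vtest)


def _tidy(values_by_group, parameter="FA", roi="CA1"):
    rows = []
    for group, values in values_by_group.items():
        for i, v in enumerate(values):
            rows.append({"slice_id": f"{group}_{i}", "animal": f"a{i}",
                         "group": group, "roi": roi, "parameter": parameter,
                         "value": v, "density_CA1": np.nan,
                         "density_CA3": np.nan, "density_GCL": np.nan,
                         "gcl_width": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# V-test

def test_vtest_perfect_alignment_closed_form():
    """n=8 angles exactly at mu0: V=n, u=sqrt(2n)=4, p=1-Phi(4)."""
    res = vtest(np.full(8, 37.0), 37.0)
    assert res.statistic == pytest.approx(4.0, abs=1e-12)
    assert res.pvalue == pytest.approx(sps.norm.sf(4.0), rel=1e-12)
    assert res.pvalue == pytest.approx(3.17e-5, rel=0.01)
    assert res.significant


def test_vtest_axial_180_invariance(rng):
    angles = rng.uniform(0, 180, size=50)
    shifted = angles.copy()
    shifted[::3] += 180.0
    a, b = vtest(angles, 90.0), vtest(shifted, 90.0)
    assert a.statistic == pytest.approx(b.statistic, abs=1e-10)
    assert a.pvalue == pytest.approx(b.pvalue, abs=1e-12)


def test_vtest_small_samples_rejected():
    with pytest.raises(ValueError):
        vtest(np.array([]), 0.0)
    with pytest.raises(ValueError):
        vtest(np.array([1.0, 2.0, 3.0, 4.0]), 0.0)


def test_vtest_detects_concentration_not_offset(rng):
    """Angles concentrated 90 degrees away from mu0 must not reject."""
    angles = 90.0 + rng.vonmises(0.0, 20.0, size=100) * 90 / np.pi
    assert vtest(angles, 90.0).significant
    assert not vtest(angles, 0.0).significant


def test_axial_mean_wraps():
    assert axial_mean(np.array([179.0, 1.0])) == pytest.approx(0.0, abs=1e-8)


# ---------------------------------------------------------------------------
# ANOVA / Tukey

def test_anova_f_equals_squared_t_for_two_groups(rng):
    x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
    table = _tidy({"control": x, "ipsilateral": y})
    res = anova_tukey(table, "FA", across="group")
    t = sps.ttest_ind(x, y).statistic
    assert res[0].statistic == pytest.approx(t ** 2, rel=1e-10)


def test_tukey_matches_studentized_range_oracle(rng):
    """Adjusted p-values agree with a hand-rolled all-pairs studentized-range
    computation on a three-group toy dataset."""
    data = {"a": rng.normal(0, 1, 6), "b": rng.normal(0.8, 1, 9),
            "c": rng.normal(1.6, 1, 6)}
    table = _tidy(data)
    res = anova_tukey(table, "FA", across="group")
    # independent oracle: pooled MSE + studentized range distribution
    ns = {k: len(v) for k, v in data.items()}
    n_tot = sum(ns.values())
    k = len(data)
    mse = sum(((v - v.mean()) ** 2).sum() for v in data.values()) / (n_tot - k)
    for r in res[1:]:
        g1, g2 = r.extra["level_a"], r.extra["level_b"]
        diff = data[g2].mean() - data[g1].mean()
        se = np.sqrt(mse / 2 * (1 / ns[g1] + 1 / ns[g2]))
        q = abs(diff) / se
        p_expected = sps.studentized_range.sf(q, k, n_tot - k)
        assert r.statistic == pytest.approx(diff, rel=1e-10)
        assert r.pvalue == pytest.approx(p_expected, abs=1e-6)


def test_anova_null_calibration(rng):
    hits = 0
    reps = 500
    for _ in range(reps):
        groups = {g: rng.normal(0, 1, 6) for g in ("a", "b", "c")}
        f, p = sps.f_oneway(*groups.values())
        hits += p < 0.05
    assert 0.02 <= hits / reps <= 0.09


def test_anova_requires_two_levels():
    table = _tidy({"control": np.arange(5.0)})
    with pytest.raises(ValueError):
        anova_tukey(table, "FA", across="group")


# ---------------------------------------------------------------------------
# paired tests

def test_paired_identical_vectors_flagged_degenerate():
    v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    table = _tidy({"ipsilateral": v, "contralateral": v})
    res = paired_test(table, "FA", "CA1")
    assert res.statistic == 0.0
    assert np.isnan(res.pvalue)
    assert res.extra["zero_variance"]
    assert not res.significant


def test_paired_constant_shift(rng):
    x = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
    table = _tidy({"ipsilateral": x + 1.0, "contralateral": x})
    assert paired_test(table, "FA", "CA1").extra["zero_variance"]
    jitter = x + 1.0 + rng.normal(0, 0.01, 5)
    table = _tidy({"ipsilateral": jitter, "contralateral": x})
    res = paired_test(table, "FA", "CA1")
    assert res.pvalue < 0.05
    assert res.extra["mean_diff"] > 0


# ---------------------------------------------------------------------------
# correlations

def test_correlation_exact_linear():
    x = np.arange(6.0)
    table = _tidy({"ipsilateral": 2 * x})
    table["density_CA1"] = np.tile(x, 1)
    res = correlate(table, "FA", "CA1", "density_CA1")
    assert res.statistic == pytest.approx(1.0, abs=1e-12)


def test_correlation_null_calibration(rng):
    hits = 0
    reps = 1000
    for _ in range(reps):
        x, y = rng.normal(size=21), rng.normal(size=21)
        hits += sps.pearsonr(x, y).pvalue < 0.05
    assert 0.03 <= hits / reps <= 0.07


def test_correlation_constant_column_is_undefined():
    table = _tidy({"ipsilateral": np.arange(6.0)})
    table["gcl_width"] = 0.38
    res = correlate(table, "FA", "CA1", "gcl_width")
    assert np.isnan(res.statistic) and not res.significant


# ---------------------------------------------------------------------------
# report

def test_build_report_collects_tests_and_summaries(rng):
    table = _tidy({"control": rng.normal(0.6, 0.05, 6),
                   "ipsilateral": rng.normal(0.3, 0.05, 9)})
    results = anova_tukey(table, "FA", across="group")
    report = build_report(results, table)
    assert len(report.tests) == len(results)
    assert {"roi", "group", "parameter", "mean", "std", "n"} <= set(
        report.summaries.columns)
    row = report.summaries.set_index("group").loc["control"]
    assert row["n"] == 6
    bonf = build_report(results, table, bonferroni=True)
    assert (bonf.tests["alpha"] < report.tests["alpha"]).all()
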