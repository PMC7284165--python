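"""Region-wise statistical workflow.

Operates on a tidy per-slice ROI parameter table with columns
``slice_id, group, roi, parameter, value`` plus slice-level histology
columns (``density_CA1, density_CA3, density_GCL, gcl_width``), and on
pooled axial orientation samples.  Implements:

- the V-test for non-uniformity of axial orientations against a
  hypothesized mean direction (angle doubling applied by default, since
  dendrite/axon orientations have no polarity and are 180-degree periodic);
- one-way ANOVA with Tukey HSD post-hoc contrasts across ROIs or groups;
- paired t-tests for within-slice ipsilateral/contralateral comparisons;
- Pearson correlations between diffusion parameters and histology, pooled
  or restricted to the ipsilateral group.

The unit of analysis is the slice: per-slice ROI means enter the group
tests.  No multiple-testing correction is applied by default (a Bonferroni
option exists); the significance threshold alpha defaults to 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "DWI_PARAMETERS",
    "HISTOLOGY_COLUMNS",
    "TestResult",
    "StatsReport",
    "axial_mean",
    "axial_resultant",
    "vtest",
    "anova_tukey",
    "paired_test",
    "correlate",
    "build_report",
]

DWI_PARAMETERS = ("FA", "MD", "dvD", "lrD", "dvlr_ratio")
HISTOLOGY_COLUMNS = ("density_CA1", "density_CA3", "density_GCL", "gcl_width")
GROUPS = ("control", "ipsilateral", "contralateral")


@dataclass
class TestResult:
    """One statistical test: statistic, p-value and significance flag."""

    name: str
    statistic: float
    pvalue: float
    contrast: str = ""
    alpha: float = 0.05
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.pvalue) and self.pvalue < self.alpha)

    def to_row(self) -> dict:
        return {"test": self.name, "contrast": self.contrast,
                "statistic": self.statistic, "pvalue": self.pvalue,
                "alpha": self.alpha, "significant": self.significant,
                **self.extra}


# ---------------------------------------------------------------------------
# circular statistics

def axial_mean(angles_deg: np.ndarray) -> float:
    """Mean axial direction (degrees in [0, 180)) by angle doubling."""
    phi = np.radians(2.0 * np.asarray(angles_deg, dtype=float))
    mean2 = np.angle(np.exp(1j * phi).mean())
    return float(np.degrees(mean2) / 2.0 % 180.0)


def axial_resultant(angles_deg: np.ndarray) -> float:
    """Mean resultant length of the doubled angles (0 = uniform)."""
    phi = np.radians(2.0 * np.asarray(angles_deg, dtype=float))
    return float(np.abs(np.exp(1j * phi).mean()))


def vtest(angles_deg: np.ndarray, mu0_deg: float, alpha: float = 0.05,
          axial: bool = True, name: str = "vtest") -> TestResult:
    """V-test for non-uniformity against a hypothesized mean direction.

    For axial data (default) angles are doubled first: phi_i = 2 theta_i,
    phi0 = 2 mu0; the test is otherwise undefined for 180-degree-periodic
    orientations.  V = sum cos(phi_i - phi0), u = V sqrt(2/n), and the
    one-sided p-value is the standard normal upper tail of u (adequate for
    n >= 5; exact small-n tables are not implemented).
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("vtest needs at least 5 angles, got none")
    if angles.size < 5:
        raise ValueError(f"vtest needs at least 5 angles, got {angles.size}")
    mult = 2.0 if axial else 1.0
    phi = np.radians(mult * (angles % (360.0 / mult)))
    phi0 = np.radians(mult * mu0_deg)
    v = float(np.cos(phi - phi0).sum())
    n = angles.size
    u = v * np.sqrt(2.0 / n)
    p = float(sps.norm.sf(u))
    return TestResult(name=name, statistic=u, pvalue=p,
                      contrast=f"mu0={mu0_deg:g}", alpha=alpha,
                      extra={"V": v, "n": n,
                             "axial_mean": axial_mean(angles)})


# ---------------------------------------------------------------------------
# group comparisons

def _filter(table: pd.DataFrame, within: dict | None) -> pd.DataFrame:
    sub = table
    for col, val in (within or {}).items():
        sub = sub[sub[col] == val]
    return sub


def anova_tukey(table: pd.DataFrame, parameter: str, across: str = "group",
                within: dict | None = None, alpha: float = 0.05,
                ) -> list[TestResult]:
    """One-way ANOVA plus Tukey HSD contrasts for one parameter.

    ``across`` names the factor column ("group" or "roi"); ``within``
    optionally filters rows first (e.g. ``{"roi": "CA1"}``).  Returns the
    omnibus F-test followed by one TestResult per pairwise contrast with
    studentized-range adjusted p-values.  Contrast statistics are mean
    differences (second level minus first).
    """
    if across not in ("group", "roi"):
        raise ValueError("across must be 'group' or 'roi'")
    sub = _filter(table[table["parameter"] == parameter], within)
    levels = sorted(sub[across].unique())
    if len(levels) < 2:
        raise ValueError(f"need >= 2 {across} levels, got {levels}")
    samples = [sub.loc[sub[across] == lev, "value"].to_numpy()
               for lev in levels]
    if min(len(s) for s in samples) < 2:
        raise ValueError("need >= 2 observations per level")

    label = "/".join(f"{k}={v}" for k, v in (within or {}).items()) or "all"
    f, p = sps.f_oneway(*samples)
    results = [TestResult(name=f"anova[{parameter}]", statistic=float(f),
                          pvalue=float(p), contrast=f"{across}:{label}",
                          alpha=alpha,
                          extra={"levels": ",".join(map(str, levels))})]
    tk = pairwise_tukeyhsd(sub["value"].to_numpy(),
                           sub[across].to_numpy(), alpha=alpha)
    for (g1, g2), diff, padj in zip(
            [(tk.groupsunique[i], tk.groupsunique[j])
             for i, j in zip(*np.triu_indices(len(tk.groupsunique), 1))],
            tk.meandiffs, tk.pvalues):
        results.append(TestResult(
            name=f"tukey[{parameter}]", statistic=float(diff),
            pvalue=float(padj), contrast=f"{g2}-{g1} ({label})", alpha=alpha,
            extra={"level_a": str(g1), "level_b": str(g2), "scope": label}))
    return results


def paired_test(table: pd.DataFrame, parameter: str, roi: str,
                groups: tuple[str, str] = ("ipsilateral", "contralateral"),
                pair_on: str = "animal", alpha: float = 0.05) -> TestResult:
    """Two-sided paired t-test between two groups matched by ``pair_on``.

    Used for within-slice ipsilateral-vs-contralateral comparisons.  Pairs
    with zero within-pair variance are degenerate: the statistic is
    reported as 0 with p = NaN and a flag in ``extra``.
    """
    sub = table[(table["parameter"] == parameter) & (table["roi"] == roi)]
    a = sub[sub["group"] == groups[0]].set_index(pair_on)["value"]
    b = sub[sub["group"] == groups[1]].set_index(pair_on)["value"]
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError(f"need >= 2 matched pairs, got {len(common)}")
    x, y = a.loc[common].to_numpy(), b.loc[common].to_numpy()
    name = f"paired[{parameter},{roi}]"
    contrast = f"{groups[0]}-{groups[1]}"
    if np.allclose(np.std(x - y), 0.0):
        return TestResult(name=name, statistic=0.0, pvalue=np.nan,
                          contrast=contrast, alpha=alpha,
                          extra={"n_pairs": len(common),
                                 "zero_variance": True,
                                 "mean_diff": float(np.mean(x - y))})
    t, p = sps.ttest_rel(x, y)
    return TestResult(name=name, statistic=float(t), pvalue=float(p),
                      contrast=contrast, alpha=alpha,
                      extra={"n_pairs": len(common), "zero_variance": False,
                             "mean_diff": float(np.mean(x - y))})


def correlate(table: pd.DataFrame, dwi_param: str, roi: str,
              histology_param: str, subset: str = "all",
              alpha: float = 0.05) -> TestResult:
    """Pearson correlation between a per-slice DWI parameter and histology.

    ``subset`` is "all" (pooled across groups) or a group name, typically
    "ipsilateral" for the intra-group correlations that show DWI tracks
    lesion severity rather than group membership.
    """
    if histology_param not in table.columns:
        raise ValueError(f"no histology column {histology_param!r}")
    sub = table[(table["parameter"] == dwi_param) & (table["roi"] == roi)]
    if subset != "all":
        sub = sub[sub["group"] == subset]
    sub = sub.dropna(subset=["value", histology_param])
    if len(sub) < 3:
        raise ValueError(f"need >= 3 slices for a correlation, got {len(sub)}")
    x = sub["value"].to_numpy()
    y = sub[histology_param].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # constant column: correlation undefined, reported non-significant
        r, p = np.nan, np.nan
    else:
        r, p = sps.pearsonr(x, y)
    return TestResult(name=f"pearson[{dwi_param}({roi}) vs {histology_param}]",
                      statistic=float(r), pvalue=float(p),
                      contrast=f"subset={subset}", alpha=alpha,
                      extra={"n": len(sub)})


# ---------------------------------------------------------------------------
# report assembly

@dataclass
class StatsReport:
    """Machine-readable collection of all test results and summaries."""

    tests: pd.DataFrame          # one row per TestResult
    summaries: pd.DataFrame      # per roi x group x parameter mean/sd/n
    alpha: float = 0.05

    def section(self, prefix: str) -> pd.DataFrame:
        return self.tests[self.tests["test"].str.startswith(prefix)]

    def to_csv(self, tests_path, summaries_path) -> None:
        self.tests.to_csv(tests_path, index=False)
        self.summaries.to_csv(summaries_path, index=False)

    def to_json(self, path) -> None:
        import json
        payload = {"alpha": self.alpha,
                   "tests": self.tests.to_dict(orient="records"),
                   "summaries": self.summaries.to_dict(orient="records")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-ROI, per-group parameter means and standard deviations."""
    g = (table.groupby(["roi", "group", "parameter"])["value"]
         .agg(["mean", "std", "count"]).reset_index())
    return g.rename(columns={"count": "n"})


def build_report(results: Iterable[TestResult], table: pd.DataFrame,
                 alpha: float = 0.05,
                 bonferroni: bool = False) -> StatsReport:
    """Assemble test results and group summaries into one report.

    With ``bonferroni=True`` the per-test alpha is divided by the number
    of tests (off by default: the workflow reports unadjusted p < alpha).
    """
    results = list(results)
    if bonferroni and results:
        adj = alpha / len(results)
        results = [TestResult(r.name, r.statistic, r.pvalue, r.contrast,
                              adj, r.extra) for r in results]
    rows = [r.to_row() for r in results]
    tests = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["test", "contrast", "statistic", "pvalue", "alpha",
                 "significant"])
    return StatsReport(tests=tests, summaries=summarize(table), alpha=alpha)
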