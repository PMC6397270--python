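"""Comparative statistics: paired layer tests, variance-ratio tests,
correlations, one-way region ANOVAs and Tukey HSD post-hoc tables.

These treat grid cells as independent observations, as is conventional for
pelt-survey comparisons, even though neighboring cells are spatially
correlated; p-values are therefore somewhat anti-conservative and should be
read alongside the spatial cluster analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pelt_model import PeltGrid


class StatsError(ValueError):
    pass


@dataclass
class TestResult:
    statistic: float
    df: float | tuple
    p_value: float
    estimate: float            # mean difference / variance ratio / r
    ci_low: float = np.nan
    ci_high: float = np.nan
    name: str = ""


@dataclass
class TukeyRow:
    level_a: str
    level_b: str
    difference: float          # mean(a) - mean(b)
    ci_half_width: float       # 95% family-wise half-width
    p_adj: float


@dataclass
class TukeyTable:
    factor: str
    rows: list[TukeyRow]

    def __len__(self) -> int:
        return len(self.rows)


def paired_layer_test(topcoat, undercoat, alpha: float = 0.05) -> TestResult:
    """Paired t-test on per-cell differences (topcoat - undercoat).

    Two-sided; the estimate is the mean difference with its 95% CI.
    """
    tc = np.asarray(topcoat, dtype=float)
    uc = np.asarray(undercoat, dtype=float)
    if tc.shape != uc.shape:
        raise StatsError("layers must be matched cell-by-cell")
    n = len(tc)
    if n < 3:
        raise StatsError("need >= 3 matched pairs")
    diff = tc - uc
    if np.var(diff, ddof=1) == 0:
        raise StatsError("zero variance of paired differences")
    res = stats.ttest_rel(tc, uc)
    mean_d = float(diff.mean())
    se = float(diff.std(ddof=1) / np.sqrt(n))
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    return TestResult(statistic=float(res.statistic), df=n - 1,
                      p_value=float(res.pvalue), estimate=mean_d,
                      ci_low=mean_d - tcrit * se, ci_high=mean_d + tcrit * se,
                      name="paired t-test")


def variance_ratio_test(sample_a, sample_b) -> TestResult:
    """F-test for equality of variances: F = var_a / var_b, two-sided."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each sample needs >= 2 points")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if vb == 0:
        raise StatsError("zero variance in denominator sample")
    f = float(va / vb)
    dfn, dfd = len(a) - 1, len(b) - 1
    cdf = stats.f.cdf(f, dfn, dfd)
    p = float(min(1.0, 2 * min(cdf, 1 - cdf)))
    return TestResult(statistic=f, df=(dfn, dfd), p_value=p, estimate=f,
                      name="variance-ratio F-test")


def layer_correlation(topcoat, undercoat, alpha: float = 0.05) -> TestResult:
    """Pearson correlation of matched cells with a Fisher-z 95% CI."""
    tc = np.asarray(topcoat, dtype=float)
    uc = np.asarray(undercoat, dtype=float)
    n = len(tc)
    if n < 3:
        raise StatsError("need >= 3 pairs")
    if np.var(tc) == 0 or np.var(uc) == 0:
        raise StatsError("constant input: correlation undefined")
    r, p = stats.pearsonr(tc, uc)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    if n > 3 and abs(r) < 1:
        zr = np.arctanh(r)
        half = zcrit / np.sqrt(n - 3)
        lo, hi = np.tanh(zr - half), np.tanh(zr + half)
    else:
        lo = hi = np.nan
    return TestResult(statistic=float(r), df=n - 2, p_value=float(p),
                      estimate=float(r), ci_low=float(lo), ci_high=float(hi),
                      name="Pearson correlation")


def _groups(grid_or_values, factor):
    """Split values by factor level; accepts a PeltGrid or (values, labels)."""
    if isinstance(grid_or_values, PeltGrid):
        vals = grid_or_values.thg
        labels = np.array([getattr(p, factor) for p in grid_or_values.points])
    else:
        vals, labels = grid_or_values
        vals = np.asarray(vals, dtype=float)
        labels = np.asarray(labels)
    out = {}
    for lev in sorted(set(labels.tolist())):
        out[lev] = vals[labels == lev]
    return out


def region_anova(grid_or_values, factor: str = "anatomical_region") -> TestResult:
    """One-way fixed-effects ANOVA of THg across region levels."""
    groups = _groups(grid_or_values, factor)
    small = [lev for lev, v in groups.items() if len(v) < 2]
    if small:
        raise StatsError(f"level(s) with < 2 points: {', '.join(small)}")
    if len(groups) < 2:
        raise StatsError("need >= 2 levels")
    arrays = list(groups.values())
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    return TestResult(statistic=float(f), df=(k - 1, n - k),
                      p_value=float(p), estimate=float(ssb),
                      name=f"one-way ANOVA ({factor})")


def tukey_hsd(grid_or_values, factor: str = "anatomical_region",
              alpha: float = 0.05) -> TukeyTable:
    """All pairwise level differences with Tukey-adjusted p and 95% CIs.

    CI half-widths come from the studentized-range distribution at the
    family-wise level; with two levels the adjusted p reduces to the ordinary
    equal-variance two-sample t-test p.
    """
    groups = _groups(grid_or_values, factor)
    small = [lev for lev, v in groups.items() if len(v) < 2]
    if small:
        raise StatsError(f"level(s) with < 2 points: {', '.join(small)}")
    if len(groups) < 2:
        raise StatsError("need >= 2 levels")
    levels = list(groups.keys())
    arrays = [groups[lev] for lev in levels]
    res = stats.tukey_hsd(*arrays)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    rows = []
    for i in range(len(levels)):
        for j in range(i):
            diff = float(arrays[i].mean() - arrays[j].mean())
            half = float((ci.high[i, j] - ci.low[i, j]) / 2)
            rows.append(TukeyRow(level_a=levels[i], level_b=levels[j],
                                 difference=diff, ci_half_width=half,
                                 p_adj=float(res.pvalue[i, j])))
    return TukeyTable(factor=factor, rows=rows)


def layer_summary(grid: PeltGrid) -> dict:
    """Per-layer summary: n, mean, sd, min, max of THg (and MeHg if assayed)."""
    v = grid.thg
    out = {"pelt_id": grid.pelt_id, "layer": grid.layer, "n": len(v),
           "mean": float(v.mean()), "sd": float(v.std(ddof=1)),
           "min": float(v.min()), "max": float(v.max())}
    mehg = grid.mehg
    if np.any(~np.isnan(mehg)):
        m = mehg[~np.isnan(mehg)]
        out.update({"mehg_n": int(m.size), "mehg_mean": float(m.mean()),
                    "mehg_sd": float(m.std(ddof=1)) if m.size > 1 else np.nan,
                    "mehg_min": float(m.min()), "mehg_max": float(m.max())})
    return out
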