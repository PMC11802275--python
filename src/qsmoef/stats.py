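"""Two-group comparison statistics and effect sizes for regional cohorts.

Implements the classical analysis layer of a two-group regional imaging
study: Kolmogorov-Smirnov normality screening that routes each comparison
to an independent-samples t-test (pooled by default, Welch optional) or a
Mann-Whitney U test; chi-square / Fisher exact for categorical tables;
Pearson / Spearman correlation; Bonferroni adjustment; and Cohen's d with
its correlation-style companion r, classified by the conventional cutoffs

    d: trivial < 0.2 <= small < 0.5 <= medium < 0.8 <= large
    r: trivial < 0.1 <= small < 0.3 <= medium < 0.5 <= large.

Cohen's d uses the pooled standard deviation

    s_p = sqrt(((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a + n_b - 2))

and is computable from printed (mean, SD, n) summaries alone, which is how
published group tables are checked here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .params import StatsParams

D_CUTOFFS = ((0.2, "trivial"), (0.5, "small"), (0.8, "medium"))
R_CUTOFFS = ((0.1, "trivial"), (0.3, "small"), (0.5, "medium"))


def classify_d(d: float) -> str:
    for bound, label in D_CUTOFFS:
        if abs(d) < bound:
            return label
    return "large"


def classify_r(r: float) -> str:
    for bound, label in R_CUTOFFS:
        if abs(r) < bound:
            return label
    return "large"


@dataclass(frozen=True)
class GroupSummary:
    """Printed summary statistics of one region for two groups."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    def __post_init__(self) -> None:
        if self.sd_a < 0 or self.sd_b < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("group sizes must be >= 2")


@dataclass(frozen=True)
class EffectSize:
    d: float
    r: float
    interpretation_d: str
    interpretation_r: str

    @property
    def interpretation(self) -> str:
        return self.interpretation_d


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p: float
    p_adjusted: float | None
    test: str
    effect: EffectSize | None


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p: float
    method: str
    x_name: str = "x"
    y_name: str = "y"


def _d_to_r(d: float, n_a: int, n_b: int) -> float:
    # standard d -> r conversion with the unequal-n correction factor
    a = (n_a + n_b) ** 2 / (n_a * n_b)
    return d / math.sqrt(d**2 + a)


def cohens_d_from_summary(s: GroupSummary) -> EffectSize:
    """Pooled-SD Cohen's d (absolute) from printed (mean, SD, n) pairs."""
    pooled_var = ((s.n_a - 1) * s.sd_a**2 + (s.n_b - 1) * s.sd_b**2) / (s.n_a + s.n_b - 2)
    if pooled_var <= 0:
        raise ValueError("both group SDs are zero; effect size undefined")
    d = abs(s.mean_b - s.mean_a) / math.sqrt(pooled_var)
    r = _d_to_r(d, s.n_a, s.n_b)
    return EffectSize(d=d, r=r, interpretation_d=classify_d(d), interpretation_r=classify_r(r))


def cohens_d_from_samples(a, b) -> EffectSize:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    s = GroupSummary(
        mean_a=a.mean(), sd_a=a.std(ddof=1), n_a=len(a),
        mean_b=b.mean(), sd_b=b.std(ddof=1), n_b=len(b),
    )
    return cohens_d_from_summary(s)


def choose_and_run_test(
    sample_a, sample_b, alpha_normality: float = 0.05,
    params: StatsParams | None = None,
) -> ComparisonResult:
    """Normality-screened two-group comparison.

    Each group is tested for normality with a Kolmogorov-Smirnov test
    against a normal with the sample's own mean and SD; if both pass at
    ``alpha_normality`` the comparison is an independent-samples t-test
    (pooled, or Welch if configured), otherwise a Mann-Whitney U test
    (exact for small tie-free samples, asymptotic with tie correction
    otherwise).  The result carries Cohen's d from the raw samples and the
    companion effect size r = Z / sqrt(N).
    """
    if params is None:
        params = StatsParams(alpha_normality=alpha_normality)
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    n_total = len(a) + len(b)

    degenerate = a.std() == 0 and b.std() == 0
    if degenerate and np.all(a == b[0]):
        effect = EffectSize(0.0, 0.0, classify_d(0.0), classify_r(0.0))
        return ComparisonResult(0.0, 1.0, None, "degenerate", effect)

    def _normal(x):
        if x.std(ddof=1) == 0:
            return False
        return sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue > params.alpha_normality

    if _normal(a) and _normal(b):
        res = sps.ttest_ind(a, b, equal_var=not params.use_welch)
        test = "welch_t" if params.use_welch else "student_t"
        stat, p = float(res.statistic), float(res.pvalue)
        z = sps.norm.isf(min(p / 2, 0.5 - 1e-16)) * np.sign(stat if stat != 0 else 1.0)
    else:
        n_max = max(len(a), len(b))
        ties = len(np.unique(np.concatenate([a, b]))) < n_total
        method = "exact" if (n_max <= params.exact_mannwhitney_max_n and not ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "mann_whitney"
        stat, p = float(res.statistic), float(res.pvalue)
        mu = len(a) * len(b) / 2.0
        sigma = math.sqrt(len(a) * len(b) * (n_total + 1) / 12.0)
        z = (stat - mu) / sigma if sigma > 0 else 0.0
    try:
        es = cohens_d_from_samples(a, b)
    except ValueError:
        es = None
    r = abs(z) / math.sqrt(n_total)
    if es is not None:
        es = EffectSize(es.d, r, es.interpretation_d, classify_r(r))
    return ComparisonResult(statistic=stat, p=p, p_adjusted=None, test=test, effect=es)


def categorical_test(table) -> ComparisonResult:
    """2x2 categorical comparison: Fisher exact if any expected cell < 5, else chi-square."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table entries must be nonnegative integers")
        t = t.astype(int)
    if t.sum() == 0:
        raise ValueError("empty contingency table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if np.any(expected < 5):
        stat, p = sps.fisher_exact(t, alternative="two-sided")
        test = "fisher_exact"
    else:
        chi2 = sps.chi2_contingency(t, correction=False)
        stat, p = float(chi2.statistic), float(chi2.pvalue)
        test = "chi_square"
    return ComparisonResult(statistic=float(stat), p=float(p), p_adjusted=None,
                            test=test, effect=None)


def correlate(x, y, method: str = "pearson",
              x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 4:
        raise ValueError("correlation needs at least 4 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one variable; correlation undefined")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(coefficient=float(res.statistic), p=float(res.pvalue),
                             method=method, x_name=x_name, y_name=y_name)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p -> min(1, m*p), order preserved."""
    p = list(float(v) for v in p_values)
    if any(v < 0 or v > 1 for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return [min(1.0, m * v) for v in p]


def compare_cohort(cohort: pd.DataFrame, params: StatsParams | None = None,
                   bonferroni_adjust: bool = True) -> pd.DataFrame:
    """Region-wise two-group comparison of a tidy cohort table.

    ``cohort`` needs columns (subject_id, group, region, value) with exactly
    two group labels.  Returns one row per region with group summaries, the
    chosen test, raw and Bonferroni-adjusted p, and both effect sizes.
    """
    groups = sorted(cohort["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    rows = []
    regions = list(dict.fromkeys(cohort["region"]))
    for region in regions:
        sub = cohort[cohort["region"] == region]
        a = sub.loc[sub["group"] == ga, "value"].to_numpy()
        b = sub.loc[sub["group"] == gb, "value"].to_numpy()
        res = choose_and_run_test(a, b, params=params)
        rows.append({
            "region": region,
            f"mean_{ga}": a.mean(), f"sd_{ga}": a.std(ddof=1), f"n_{ga}": len(a),
            f"mean_{gb}": b.mean(), f"sd_{gb}": b.std(ddof=1), f"n_{gb}": len(b),
            "test": res.test, "statistic": res.statistic, "p": res.p,
            "cohens_d": res.effect.d if res.effect else np.nan,
            "effect_r": res.effect.r if res.effect else np.nan,
            "interpretation_d": res.effect.interpretation_d if res.effect else "",
            "interpretation_r": res.effect.interpretation_r if res.effect else "",
        })
    out = pd.DataFrame(rows)
    if bonferroni_adjust:
        out["p_bonferroni"] = bonferroni(out["p"].tolist())
    return out


def effects_from_summary_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Effect sizes from a summary CSV (region, mean_a, sd_a, n_a, mean_b, sd_b, n_b)."""
    rows = []
    for _, row in summary.iterrows():
        es = cohens_d_from_summary(GroupSummary(
            mean_a=row["mean_a"], sd_a=row["sd_a"], n_a=int(row["n_a"]),
            mean_b=row["mean_b"], sd_b=row["sd_b"], n_b=int(row["n_b"]),
        ))
        rows.append({
            "region": row["region"],
            "group_a": f"{row['mean_a']:.2f} ± {row['sd_a']:.2f}",
            "group_b": f"{row['mean_b']:.2f} ± {row['sd_b']:.2f}",
            "cohens_d": es.d, "effect_r": es.r,
            "interpretation_d": es.interpretation_d,
            "interpretation_r": es.interpretation_r,
        })
    return pd.DataFrame(rows)


def report_table(results: pd.DataFrame) -> str:
    """Plain-text rendering of a comparison table (regions x statistics)."""
    if len(results) == 0:
        raise ValueError("no results to report")
    return results.to_string(index=False, float_format=lambda v: f"{v:.3f}")
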