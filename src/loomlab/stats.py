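"""Normality-routed test selection and the named tests used by all stages.

Dataset comparisons are routed by Shapiro–Wilk normality and Levene
equal-variance checks at alpha = 0.05: normal data get (paired) t tests,
otherwise Wilcoxon signed-rank / rank-sum tests.  Two-tailed throughout.
Also provides the chi-square test of independence (plain Pearson, no
continuity correction), Pearson correlation, and two-way repeated-measures
/ mixed ANOVA with Bonferroni or Tukey pairwise comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "route_test",
    "chi2_independence",
    "pearson_corr",
    "rm_anova_multcomp",
    "bonferroni",
]


@dataclass
class TestResult:
    statistic: float
    p: float
    test_name: str
    correction: str = "none"
    details: dict = field(default_factory=dict)


def _is_normal(*samples: np.ndarray, alpha: float = 0.05) -> bool:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in samples:
            if sps.shapiro(s).pvalue < alpha:
                return False
        if len(samples) == 2 and sps.levene(*samples).pvalue < alpha:
            return False
    return True


def route_test(
    x: np.ndarray,
    y: np.ndarray | None = None,
    paired: bool = False,
    family: str = "auto",
    alpha: float = 0.05,
) -> TestResult:
    """Two-sample (or one-sample) comparison with normality routing.

    ``family="auto"`` runs Shapiro–Wilk on each sample (and Levene across
    samples) at ``alpha``; normal data are compared with a (paired) t
    test, non-normal with Wilcoxon signed-rank (paired) or rank-sum
    (unpaired).  ``family`` may force ``"t"``, ``"rank"`` or ``"ks"``.
    Fewer than 3 observations per group defaults to the rank family with
    a warning.
    """
    x = np.asarray(x, float)
    if y is not None:
        y = np.asarray(y, float)
        if paired and x.size != y.size:
            raise ValueError("paired samples must have equal lengths")
    if family == "ks":
        if y is None:
            raise ValueError("ks requires two samples")
        r = sps.ks_2samp(x, y)
        return TestResult(float(r.statistic), float(r.pvalue), "two-sample KS")

    if family == "auto":
        if x.size < 3 or (y is not None and y.size < 3):
            warnings.warn("fewer than 3 observations; defaulting to rank test")
            family = "rank"
        else:
            samples = (x,) if y is None else (x, y)
            family = "t" if _is_normal(*samples, alpha=alpha) else "rank"

    if y is None:
        if family == "t":
            r = sps.ttest_1samp(x, 0.0)
            return TestResult(float(r.statistic), float(r.pvalue), "one-sample t")
        r = sps.wilcoxon(x, zero_method="wilcox")
        return TestResult(float(r.statistic), float(r.pvalue), "Wilcoxon signed-rank")
    if paired:
        if family == "t":
            r = sps.ttest_rel(x, y)
            return TestResult(float(r.statistic), float(r.pvalue), "paired t")
        if np.allclose(x, y):
            return TestResult(0.0, 1.0, "Wilcoxon signed-rank")
        r = sps.wilcoxon(x, y, zero_method="wilcox")
        return TestResult(float(r.statistic), float(r.pvalue), "Wilcoxon signed-rank")
    if family == "t":
        r = sps.ttest_ind(x, y)
        return TestResult(float(r.statistic), float(r.pvalue), "two-sample t")
    r = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(float(r.statistic), float(r.pvalue), "Wilcoxon rank-sum")


def chi2_independence(table: np.ndarray) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    obs = np.asarray(table, float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return TestResult(float(chi2), float(p), "chi-square independence",
                      details={"dof": int(dof)})


def pearson_corr(x: np.ndarray, y: np.ndarray) -> TestResult:
    r = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return TestResult(float(r.statistic), float(r.pvalue), "Pearson correlation")


def bonferroni(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values (multiplied by m, capped at 1)."""
    p = np.asarray(p_values, float)
    m = m if m is not None else p.size
    return np.minimum(p * m, 1.0)


def rm_anova_multcomp(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str | None = None,
    correction_method: str = "bonferroni",
) -> dict:
    """Repeated-measures (or mixed) ANOVA with pairwise comparisons.

    ``data`` is long-format with one row per observation.  With a
    ``between`` factor a mixed ANOVA (between x within + interaction) is
    run; otherwise a one-way rm-ANOVA with Greenhouse–Geisser correction
    applied when the sphericity assumption fails.  Subjects missing a
    condition are excluded listwise with a warning.  Pairwise follow-ups
    use paired t tests with Bonferroni correction or Tukey's HSD.
    """
    import pingouin as pg

    df = data.copy()
    counts = df.groupby(subject)[within].nunique()
    full = counts.max()
    incomplete = counts[counts < full].index
    if len(incomplete):
        warnings.warn(f"excluding {len(incomplete)} subject(s) missing a condition")
        df = df[~df[subject].isin(incomplete)]
    dup = df.groupby([subject, within]).size()
    if between is None and (dup > 1).any():
        raise ValueError("duplicated condition per subject")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if between is not None:
            aov = pg.mixed_anova(
                data=df, dv=dv, within=within, subject=subject, between=between
            )
        else:
            aov = pg.rm_anova(
                data=df, dv=dv, within=within, subject=subject, correction=True
            )

    if correction_method == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        grouping = df[between] if between is not None else df[within]
        tk = pairwise_tukeyhsd(df[dv], grouping)
        pairwise = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairwise = pg.pairwise_tests(
                data=df, dv=dv, within=within, subject=subject,
                between=between, padjust="bonf",
            )
    return {"anova": aov, "pairwise": pairwise}
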