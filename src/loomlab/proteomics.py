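"""Peptidoform-to-protein quantification and differential testing.

The reprocessing chain: (1) per-sample renormalisation in log space by
damped (Levenberg–Marquardt) least squares against row anchors, (2)
empirical-Bayes location/scale batch correction preserving group means,
(3) protein-group quantification under the best-flyer hypothesis — a mean
relative profile across member peptidoforms, anchored to the mean
intensity of the group's most intense peptidoform, using only unique
peptidoforms when at least three are available — and (4) a two-sided
moderated t test with empirical-Bayes variance shrinkage, Benjamini–
Hochberg adjustment, and a regulated flag combining significance with a
fold-change rule derived from control-to-average-control ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "renormalize_lm",
    "correct_batch",
    "quantify_protein_groups",
    "differential_test",
    "DifferentialResult",
]

LOG2_OVER_LOG10 = math.log10(2.0)


# ---------------------------------------------------------------------------
# Levenberg-Marquardt renormalisation
# ---------------------------------------------------------------------------

def renormalize_lm(
    values: pd.DataFrame, max_missing_frac: float = 0.9
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample additive offsets in log space by damped least squares.

    Fits one offset per sample minimising the residuals of each entry
    against its row median (the row anchor), using
    ``scipy.optimize.least_squares(method="lm")``.  Offsets are constrained
    to sum to zero.  Samples with more than 90% missing values are excluded
    from the fit (offset 0, warning).  Missing values stay missing.

    Returns ``(corrected, offsets)`` where ``corrected = values - offsets``.
    """
    X = values.to_numpy(dtype=float)
    n_rows, n_cols = X.shape
    if n_cols < 2:
        raise ValueError("need at least 2 samples")
    usable = np.isnan(X).mean(axis=0) <= max_missing_frac
    if not usable.all():
        warnings.warn(
            f"excluding {int((~usable).sum())} sample(s) with >90% missing values"
        )

    idx = np.flatnonzero(usable)

    def residuals(offsets_free: np.ndarray) -> np.ndarray:
        offsets = np.zeros(n_cols)
        offsets[idx[:-1]] = offsets_free
        offsets[idx[-1]] = -offsets_free.sum()  # sum-to-zero constraint
        corrected = X - offsets
        anchors = np.nanmedian(corrected, axis=1, keepdims=True)
        res = (corrected - anchors)[:, usable].ravel()
        return np.nan_to_num(res, nan=0.0)

    x0 = np.zeros(idx.size - 1)
    sol = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12)
    offsets = np.zeros(n_cols)
    offsets[idx[:-1]] = sol.x
    offsets[idx[-1]] = -sol.x.sum()
    corrected = pd.DataFrame(
        X - offsets, index=values.index, columns=values.columns
    )
    return corrected, pd.Series(offsets, index=values.columns, name="offset")


# ---------------------------------------------------------------------------
# ComBat-style batch correction
# ---------------------------------------------------------------------------

def correct_batch(
    values: pd.DataFrame,
    batch: np.ndarray,
    group: np.ndarray | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes location/scale batch adjustment (ComBat-style).

    Features are standardised against a model that retains the biological
    group means; per-batch location and scale parameters are shrunk with
    parametric empirical Bayes (normal prior on locations, inverse-gamma
    on scales) and removed.  Singleton batches receive a location-only
    adjustment with a warning.
    """
    X = values.to_numpy(dtype=float).copy()
    batch = np.asarray(batch)
    batches = np.unique(batch)
    if len(batches) < 2:
        raise ValueError("need at least 2 batches")
    n_feat, n_samp = X.shape

    # full design: one column per batch plus reference-coded group effects
    if group is None:
        group = np.zeros(n_samp, dtype=int)
    group = np.asarray(group)
    glevels = np.unique(group)
    batch_design = np.column_stack([(batch == b).astype(float) for b in batches])
    cov_design = np.column_stack(
        [np.ones((n_samp, 0))] + [(group == g).astype(float) for g in glevels[1:]]
    ) if len(glevels) > 1 else np.zeros((n_samp, 0))
    design = np.hstack([batch_design, cov_design])
    n_batch = len(batches)
    batch_frac = np.array([(batch == b).mean() for b in batches])

    # feature-wise OLS of the full model; the standardisation mean uses the
    # batch-size-weighted average of the batch intercepts plus covariates
    stand_mean = np.empty_like(X)
    resid = np.empty_like(X)
    for i in range(n_feat):
        m = ~np.isnan(X[i])
        if m.sum() <= design.shape[1]:
            stand_mean[i] = np.nanmean(X[i])
            resid[i] = X[i] - stand_mean[i]
            continue
        beta, *_ = np.linalg.lstsq(design[m], X[i, m], rcond=None)
        grand = float(batch_frac @ beta[:n_batch])
        stand_mean[i] = grand + cov_design @ beta[n_batch:]
        resid[i] = X[i] - design @ beta
    pooled_sd = np.sqrt(np.nanmean(resid**2, axis=1))
    pooled_sd[~np.isfinite(pooled_sd) | (pooled_sd == 0)] = 1.0
    Z = (X - stand_mean) / pooled_sd[:, None]

    adjusted = Z.copy()
    for b in batches:
        cols = batch == b
        nb = int(cols.sum())
        gamma_hat = np.nanmean(Z[:, cols], axis=1)  # per-feature location
        if nb < 2:
            warnings.warn(f"singleton batch {b!r}: location-only adjustment")
            adjusted[:, cols] = Z[:, cols] - gamma_hat[:, None]
            continue
        delta_hat = np.nanvar(Z[:, cols], axis=1, ddof=1)  # per-feature scale
        delta_hat[~np.isfinite(delta_hat) | (delta_hat == 0)] = 1.0

        # parametric EB priors across features
        g_bar = np.nanmean(gamma_hat)
        t2 = np.nanvar(gamma_hat)
        d_bar = np.nanmean(delta_hat)
        s2 = np.nanvar(delta_hat)
        # inverse-gamma moments
        lam = (d_bar**2 + 2 * s2) / s2 if s2 > 0 else 2.0
        theta = (d_bar**3 + d_bar * s2) / s2 if s2 > 0 else d_bar

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(30):
            g_new = (nb * t2 * gamma_hat + delta_star * g_bar) / (
                nb * t2 + delta_star
            ) if t2 > 0 else np.full_like(gamma_hat, g_bar)
            ssq = np.nansum(
                (Z[:, cols] - g_new[:, None]) ** 2, axis=1
            )
            d_new = (theta + 0.5 * ssq) / (nb / 2 + lam - 1)
            if np.allclose(g_new, gamma_star) and np.allclose(d_new, delta_star):
                gamma_star, delta_star = g_new, d_new
                break
            gamma_star, delta_star = g_new, d_new
        adjusted[:, cols] = (Z[:, cols] - gamma_star[:, None]) / np.sqrt(
            np.maximum(delta_star[:, None], 1e-12)
        )

    out = adjusted * pooled_sd[:, None] + stand_mean
    out[np.isnan(X)] = np.nan
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# best-flyer protein-group quantification
# ---------------------------------------------------------------------------

def quantify_protein_groups(
    matrix: pd.DataFrame,
    sample_cols: list[str],
    min_unique_for_exclusive: int = 3,
) -> pd.DataFrame:
    """Protein-group profiles under the best-flyer hypothesis.

    For each protein group: the *relative* step averages the mean-centred
    member peptidoform profiles per sample (unique peptidoforms only when
    at least ``min_unique_for_exclusive`` are available, otherwise razor
    peptidoforms are included too); the *absolute* step shifts the profile
    so its mean equals the mean intensity of the group's most intense
    peptidoform.  Phosphopeptidoforms (id containing ``"Phospho"``) and
    their unmodified counterparts are excluded.  Groups with no usable
    peptidoforms are dropped and logged.

    Returns a DataFrame indexed by ``protein_group`` with the sample
    columns plus ``n_unique``.
    """
    phospho_ids = matrix.loc[
        matrix["peptidoform_id"].str.contains("Phospho", case=False),
        "peptidoform_id",
    ]
    phospho_bases = set(
        phospho_ids.str.replace(r"\[?Phospho[^\]]*\]?", "", regex=True)
    )
    usable = ~(
        matrix["peptidoform_id"].isin(phospho_ids)
        | matrix["peptidoform_id"].isin(phospho_bases)
    )

    out_rows = []
    dropped = []
    for pg, sub in matrix.loc[usable].groupby("protein_group", sort=True):
        uniq = sub[sub["is_unique"].astype(bool)]
        members = uniq if len(uniq) >= min_unique_for_exclusive else sub
        vals = members[sample_cols].to_numpy(dtype=float)
        if np.isnan(vals).all():
            dropped.append(pg)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            row_means = np.nanmean(vals, axis=1, keepdims=True)
            profile = np.nanmean(vals - row_means, axis=0)  # relative step
            best_flyer = float(np.nanmax(np.nanmean(vals, axis=1)))
            profile = profile - np.nanmean(profile) + best_flyer  # absolute step
        out_rows.append(
            {
                "protein_group": pg,
                **dict(zip(sample_cols, profile)),
                "n_unique": int(uniq["is_unique"].sum()),
            }
        )
    if dropped:
        warnings.warn(f"dropped {len(dropped)} protein group(s) with no usable data")
    return pd.DataFrame(out_rows).set_index("protein_group")


# ---------------------------------------------------------------------------
# moderated t test
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    table: pd.DataFrame  # per-group log2_fc, t, p, p_adj, regulated
    d0: float  # prior degrees of freedom
    s0_sq: float  # prior variance
    fc_threshold: float  # |log2 FC| rule from control ratios


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (Smyth 2004).

    Given sample variances ``s2`` on ``df`` degrees of freedom, estimates
    the prior degrees of freedom d0 and prior variance s0^2 such that
    ``s2 ~ s0^2 F(df, d0)``, by matching the mean and variance of
    ``log s2``.
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    e = np.log(s2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    target = e_var - float(polygamma(1, df / 2.0))
    if target <= 0:
        return math.inf, float(np.exp(e_mean - digamma(df / 2.0) + math.log(df / 2.0)))

    # solve trigamma(d0/2) = target by Newton on y = d0/2
    y = 0.5 + 1.0 / target
    for _ in range(50):
        tri = float(polygamma(1, y))
        tetra = float(polygamma(2, y))
        step = -(tri - target) / tetra
        y = max(y + step, 1e-6)
        if abs(step) < 1e-10:
            break
    d0 = 2.0 * y
    s0_sq = float(
        np.exp(
            e_mean
            + digamma(d0 / 2.0)
            - digamma(df / 2.0)
            + math.log(df / d0)
        )
    )
    return d0, s0_sq


def differential_test(
    proteins: pd.DataFrame,
    groups: np.ndarray,
    control_label: str = "ctrl",
    alpha: float = 0.05,
    p_threshold: float | None = None,
    fc_threshold: float | None = None,
    fc_percentile: float = 95.0,
) -> DifferentialResult:
    """Two-sided moderated t test between two sample groups.

    Per protein, the group-mean difference is tested with an empirical-
    Bayes moderated t statistic: the residual variance is shrunk towards a
    prior ``s0^2`` with ``d0`` prior degrees of freedom estimated across
    proteins by method of moments on ``log s^2``; p-values use a t
    distribution on ``d + d0`` df and are BH-adjusted.  ``log2_fc`` is the
    mean difference converted from log10.  The regulated flag requires BH
    significance at ``alpha`` (or raw ``p < p_threshold`` when given) and
    ``|log2 FC|`` above ``fc_threshold``; when no threshold is given it is
    the ``fc_percentile``-th percentile of |log2(control_i /
    mean(controls))| ratios, the control-to-average-control rule.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly 2 groups required")
    other = [l for l in labels if l != control_label][0]
    sample_cols = [c for c in proteins.columns if c != "n_unique"]
    X = proteins[sample_cols].to_numpy(dtype=float)
    a = X[:, groups == control_label]
    b = X[:, groups == other]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")

    n1 = (~np.isnan(a)).sum(axis=1)
    n2 = (~np.isnan(b)).sum(axis=1)
    m1 = np.nanmean(a, axis=1)
    m2 = np.nanmean(b, axis=1)
    v1 = np.nanvar(a, axis=1, ddof=1)
    v2 = np.nanvar(b, axis=1, ddof=1)
    df = n1 + n2 - 2.0
    pooled = ((n1 - 1) * np.nan_to_num(v1) + (n2 - 1) * np.nan_to_num(v2)) / df

    d0, s0_sq = _fit_f_dist(pooled, float(np.median(df)))
    if math.isinf(d0):
        s_tilde = np.full_like(pooled, s0_sq)
        df_total = np.full_like(pooled, np.inf)
    else:
        s_tilde = (d0 * s0_sq + df * pooled) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s_tilde * (1.0 / n1 + 1.0 / n2))
    diff_log10 = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = diff_log10 / se
    p = 2.0 * t_dist.sf(np.abs(t_stat), df_total)
    p = np.clip(p, 0.0, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]

    log2_fc = diff_log10 / LOG2_OVER_LOG10
    if fc_threshold is None:
        ctrl_mean = np.nanmean(a, axis=1, keepdims=True)
        ratios = np.abs((a - ctrl_mean) / LOG2_OVER_LOG10)
        fc_threshold = float(np.nanpercentile(ratios, fc_percentile))
    if p_threshold is not None:
        significant = p < p_threshold
    else:
        significant = p_adj < alpha
    regulated = significant & (np.abs(log2_fc) > fc_threshold)

    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "t": t_stat,
            "p": p,
            "p_adj": p_adj,
            "regulated": regulated,
        },
        index=proteins.index,
    )
    return DifferentialResult(table, d0, s0_sq, fc_threshold)
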