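"""Pre/post-milking feature screening and inter-observer comparison.

A biomarker is called *expressed* when the paired t-test on the pre/post
values reaches P < 0.01 and the magnitude of Cohen's d exceeds 1.2.  Cohen's d
uses the pooled standard deviation of the two condition groups; the paired
variant (d_z) and an unpaired t-test are available behind flags.  No
multiple-testing correction is applied by default; Benjamini-Hochberg can be
switched on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ZeroVarianceError",
    "ExpressionResult",
    "paired_ttest",
    "cohens_d",
    "expression_screen",
    "interobserver_compare",
]

P_THRESH_DEFAULT = 0.01
D_THRESH_DEFAULT = 1.2


class ZeroVarianceError(ValueError):
    """The statistic is undefined because the relevant variance is zero."""


def _as_pairs(pre, post) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
        raise ValueError("pre and post must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    return a, b


def paired_ttest(pre, post, paired: bool = True) -> float:
    """Two-sided Student's t-test p-value for a feature's pre/post values.

    Paired by default (same teats in both conditions).  Raises
    :class:`ZeroVarianceError` when the test statistic is undefined (all
    differences identical in the paired case).
    """
    a, b = _as_pairs(pre, post)
    if paired:
        d = b - a
        if np.allclose(d, d[0]):
            raise ZeroVarianceError("paired differences have zero variance")
        return float(stats.ttest_rel(b, a).pvalue)
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        raise ZeroVarianceError("both groups are constant")
    return float(stats.ttest_ind(b, a).pvalue)


def cohens_d(pre, post, pooled: bool = True) -> float:
    """Cohen's d for the post-vs-pre mean difference (signed).

    d = (mean_post - mean_pre) / s_pooled with the classical pooled SD
    s_pooled = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)).  With
    ``pooled=False`` the paired effect size d_z = mean(diff)/sd(diff) is
    returned instead.
    """
    a, b = _as_pairs(pre, post)
    if pooled:
        n1, n2 = a.size, b.size
        s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        if s2 <= 0:
            raise ZeroVarianceError("zero pooled variance")
        return float((b.mean() - a.mean()) / np.sqrt(s2))
    d = b - a
    sd = d.std(ddof=1)
    if sd <= 0:
        raise ZeroVarianceError("paired differences have zero variance")
    return float(d.mean() / sd)


@dataclass
class ExpressionResult:
    """Per-feature screen outcome plus the headline counts.

    ``table`` has one row per feature with columns ``p_value``, ``cohens_d``,
    ``abs_d``, ``percent_diff``, ``significant``, ``effect``, ``expressed`` and
    ``degenerate``; ``counts`` holds the number of features that are
    significant-only, effect-only, and both (expressed).
    """

    table: pd.DataFrame
    counts: dict[str, int]
    p_thresh: float
    d_thresh: float


def expression_screen(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    p_thresh: float = P_THRESH_DEFAULT,
    d_thresh: float = D_THRESH_DEFAULT,
    paired: bool = True,
    pooled_d: bool = True,
    fdr: bool = False,
) -> ExpressionResult:
    """Screen every feature column for pre/post-milking expression.

    ``pre`` and ``post`` are feature tables (rows = teats, columns = features)
    sharing an index (the pairing key) and identical columns.  The percent
    difference column is |mean_post - mean_pre| / |mean_pre| * 100.  Features
    whose test is degenerate (zero variance) are flagged and never expressed.
    With ``fdr`` the p-values are Benjamini-Hochberg adjusted before
    thresholding (off by default).
    """
    if pre.empty or post.empty:
        raise ValueError("empty feature table")
    if list(pre.columns) != list(post.columns):
        if set(pre.columns) != set(post.columns):
            raise ValueError("pre and post tables have different feature sets")
        post = post[pre.columns]
    if set(pre.index) != set(post.index):
        raise ValueError("pre and post tables have different pairing keys")
    post = post.loc[pre.index]

    rows = []
    for name in pre.columns:
        a = pre[name].to_numpy(float)
        b = post[name].to_numpy(float)
        try:
            p = paired_ttest(a, b, paired=paired)
            d = cohens_d(a, b, pooled=pooled_d)
            degenerate = False
        except ZeroVarianceError:
            p, d, degenerate = np.nan, np.nan, True
        mean_pre, mean_post = a.mean(), b.mean()
        pct = np.abs(mean_post - mean_pre) / np.abs(mean_pre) * 100 if mean_pre != 0 else np.inf
        rows.append((name, p, d, pct, degenerate))

    tbl = pd.DataFrame(
        rows, columns=["feature", "p_value", "cohens_d", "percent_diff", "degenerate"]
    ).set_index("feature")
    if fdr:
        from statsmodels.stats.multitest import multipletests  # optional path

        ok = tbl["p_value"].notna()
        adj = tbl["p_value"].copy()
        if ok.any():
            adj.loc[ok] = multipletests(tbl.loc[ok, "p_value"], method="fdr_bh")[1]
        tbl["p_value"] = adj
    tbl["abs_d"] = tbl["cohens_d"].abs()
    tbl["significant"] = (tbl["p_value"] < p_thresh).fillna(False)
    tbl["effect"] = (tbl["abs_d"] > d_thresh).fillna(False)
    tbl["expressed"] = tbl["significant"] & tbl["effect"]
    counts = {
        "significant": int(tbl["significant"].sum()),
        "effect": int(tbl["effect"].sum()),
        "expressed": int(tbl["expressed"].sum()),
    }
    return ExpressionResult(table=tbl, counts=counts, p_thresh=p_thresh, d_thresh=d_thresh)


def interobserver_compare(feat_a: pd.DataFrame, feat_b: pd.DataFrame) -> pd.DataFrame:
    """Per-feature paired p and |d| between two observers' feature tables.

    Both tables must cover the same ROIs (index) and features (columns).
    Returns a DataFrame with ``p_value``, ``abs_d`` and ``degenerate`` per
    feature; summary minima/maxima are in ``df.attrs["summary"]``.  An
    agreement like the study's (all P > 0.07, |d| < 0.36) indicates that
    segmentation differences between observers do not move the biomarkers.
    """
    if list(feat_a.columns) != list(feat_b.columns):
        raise ValueError("feature name mismatch between observers")
    if list(feat_a.index) != list(feat_b.index):
        if set(feat_a.index) != set(feat_b.index):
            raise ValueError("observers cover different ROI sets")
        raise ValueError("ROI correspondence differs between tables; align the indexes")
    if len(feat_a) < 2:
        raise ValueError("need at least 2 shared ROIs")

    rows = []
    for name in feat_a.columns:
        a = feat_a[name].to_numpy(float)
        b = feat_b[name].to_numpy(float)
        try:
            p = paired_ttest(a, b)
            d = abs(cohens_d(a, b))
            degenerate = False
        except ZeroVarianceError:
            # identical values across observers: perfect agreement
            p, d, degenerate = np.nan, 0.0, True
        rows.append((name, p, d, degenerate))
    out = pd.DataFrame(rows, columns=["feature", "p_value", "abs_d", "degenerate"]).set_index(
        "feature"
    )
    out.attrs["summary"] = {
        "min_p": float(np.nanmin(out["p_value"])) if out["p_value"].notna().any() else np.nan,
        "max_abs_d": float(out["abs_d"].max()),
    }
    return out
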