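"""Per-feature association models for cross-sectional and longitudinal data.

Three model families cover the analysis battery:

* cross-sectional OLS of a (clr-taxon or log2-metabolite) feature on a
  binary group indicator, one sample per subject;
* linear mixed models with a random intercept per subject for outcomes
  measured across repeated time points (REML fit, Wald z inference on the
  fixed slope);
* ANCOVA on last-minus-first changes with the first-time-point value as
  covariate and the dynamics group as the modeled factor.

Benjamini-Hochberg FDR control is applied separately per adjustment family
(metadata group x data type; taxonomic ranks are adjusted together within a
family).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

RESULT_COLUMNS = [
    "feature", "feature_kind", "rank", "outcome", "metadata_group",
    "model_kind", "coefficient", "p_value", "fdr", "n", "flag",
]


def _result_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return df


def fit_cross_sectional(features: pd.DataFrame, outcome,
                        feature_kind: str = "taxon", rank: str | None = None,
                        outcome_name: str = "group",
                        metadata_group: str = "health_status") -> pd.DataFrame:
    """OLS of each feature on a binary group indicator.

    ``features``: samples x features (already transformed); ``outcome``: a
    binary vector aligned with the rows.  The coefficient is the group
    contrast (mean of group 1 minus group 0); p is the two-sided t-test of
    the slope, identical to an equal-variance two-sample t-test.  Features
    constant across all samples get coefficient 0, p = 1 and a
    ``degenerate`` flag so adjustment family sizes stay stable.
    """
    y = np.asarray(outcome)
    if y.dtype == bool:
        y = y.astype(int)
    uniq = np.unique(y)
    if uniq.size != 2:
        raise ValueError(f"outcome must be binary, got levels {uniq}")
    g = y == uniq.max()
    X = features.to_numpy(dtype=float)
    n0, n1 = int((~g).sum()), int(g.sum())
    n = n0 + n1
    if min(n0, n1) < 2:
        raise ValueError("each group needs at least 2 samples")
    m0 = X[~g].mean(axis=0)
    m1 = X[g].mean(axis=0)
    coef = m1 - m0
    ss = ((X[~g] - m0) ** 2).sum(axis=0) + ((X[g] - m1) ** 2).sum(axis=0)
    dof = n - 2
    sp2 = ss / dof
    se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    degenerate = X.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.isnan(p) & (coef == 0), 1.0, p)
    p = np.where(np.isinf(t), 0.0, p)
    rows = []
    for j, feat in enumerate(features.columns):
        rows.append(dict(
            feature=feat, feature_kind=feature_kind, rank=rank,
            outcome=outcome_name, metadata_group=metadata_group,
            model_kind="linear",
            coefficient=0.0 if degenerate[j] else float(coef[j]),
            p_value=1.0 if degenerate[j] else float(p[j]),
            fdr=np.nan, n=n,
            flag="degenerate" if degenerate[j] else "",
        ))
    return _result_frame(rows)


def fit_cross_sectional_continuous(features: pd.DataFrame, outcome,
                                   feature_kind: str = "taxon",
                                   rank: str | None = None,
                                   outcome_name: str = "outcome",
                                   metadata_group: str = "metabolites"
                                   ) -> pd.DataFrame:
    """OLS of each feature on a continuous outcome, one sample per subject.

    Vectorized simple regression; the slope t-test is the Pearson
    correlation test.  Constant features are flagged degenerate with p = 1.
    """
    y = np.asarray(outcome, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant")
    X = features.to_numpy(dtype=float)
    n = y.size
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxy = yc @ Xc
    sxx = (yc * yc).sum()
    syy = (Xc * Xc).sum(axis=0)
    degenerate = syy == 0
    coef = np.where(degenerate, 0.0, sxy / sxx)  # feature ~ outcome slope
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(degenerate, 0.0, sxy**2 / (sxx * syy))
        t = np.sqrt(np.clip(r2, 0, 1 - 1e-15) * (n - 2)
                    / (1 - np.clip(r2, 0, 1 - 1e-15)))
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(t, n - 2))
    rows = []
    for j, feat in enumerate(features.columns):
        rows.append(dict(
            feature=feat, feature_kind=feature_kind, rank=rank,
            outcome=outcome_name, metadata_group=metadata_group,
            model_kind="linear", coefficient=float(coef[j]),
            p_value=float(p[j]), fdr=np.nan, n=n,
            flag="degenerate" if degenerate[j] else ""))
    return _result_frame(rows)


def fit_longitudinal(features: pd.DataFrame, outcome, subject_ids,
                     feature_kind: str = "taxon", rank: str | None = None,
                     outcome_name: str = "outcome",
                     metadata_group: str = "longitudinal") -> pd.DataFrame:
    """Linear mixed model per feature: feature ~ outcome + (1 | subject).

    REML fit with Wald z inference on the fixed slope.  Rows with a missing
    outcome are dropped.  A constant outcome is unidentifiable and flagged
    with no estimate; non-converging fits fall back to OLS and are flagged.
    """
    import statsmodels.api as sm

    y = pd.Series(np.asarray(outcome, dtype=float), index=features.index)
    subj = pd.Series(np.asarray(subject_ids), index=features.index)
    keep = ~y.isna()
    y, subj = y[keep], subj[keep]
    feats = features.loc[keep]
    n = len(y)
    rows = []
    if y.nunique() <= 1:
        for feat in features.columns:
            rows.append(dict(
                feature=feat, feature_kind=feature_kind, rank=rank,
                outcome=outcome_name, metadata_group=metadata_group,
                model_kind="mixed", coefficient=np.nan, p_value=np.nan,
                fdr=np.nan, n=n, flag="constant_outcome"))
        return _result_frame(rows)
    exog = np.column_stack([np.ones(n), y.to_numpy()])
    groups = subj.to_numpy()
    for feat in features.columns:
        endog = feats[feat].to_numpy(dtype=float)
        coef = p = np.nan
        flag = ""
        if endog.std() == 0:
            coef, p, flag = 0.0, 1.0, "degenerate"
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.MixedLM(endog, exog, groups=groups).fit(
                        reml=True, method="lbfgs", maxiter=200, disp=False)
                coef = float(res.fe_params[1])
                z = res.fe_params[1] / res.bse_fe[1]
                p = float(2.0 * stats.norm.sf(abs(z)))
                if not np.isfinite(p):
                    raise ValueError("non-finite Wald p")
            except Exception:
                ols = sm.OLS(endog, exog).fit()
                coef = float(ols.params[1])
                p = float(ols.pvalues[1])
                flag = "ols_fallback"
        rows.append(dict(
            feature=feat, feature_kind=feature_kind, rank=rank,
            outcome=outcome_name, metadata_group=metadata_group,
            model_kind="mixed", coefficient=coef, p_value=p,
            fdr=np.nan, n=n, flag=flag))
    return _result_frame(rows)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one family.

    Textbook step-up: sort, scale p_(i) by m/i, take the reverse running
    minimum, cap at 1.  (Implemented directly with the m/i product so the
    result is bitwise the step-up definition; library variants that divide
    by i/m differ in the last ulp.)
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def adjust_by_family(results: pd.DataFrame,
                     family_keys: tuple[str, ...] = ("metadata_group",
                                                     "feature_kind")
                     ) -> pd.DataFrame:
    """Fill the ``fdr`` column, adjusting separately within each family.

    The default family is (metadata group, data type); taxonomic ranks are
    adjusted together within a family.  Rows with missing p-values (e.g.
    unidentifiable fits) are left unadjusted and excluded from the family.
    """
    out = results.copy()
    out["fdr"] = np.nan
    for _, idx in out.groupby(list(family_keys), dropna=False).groups.items():
        mask = out.loc[idx, "p_value"].notna()
        sub = out.loc[idx][mask]
        if len(sub):
            out.loc[sub.index, "fdr"] = bh_adjust(sub["p_value"].to_numpy())
    return out


def ancova_first_last(features: pd.DataFrame, group, first_samples,
                      last_samples, feature_kind: str = "taxon",
                      rank: str | None = None,
                      outcome_name: str = "dynamics",
                      metadata_group: str = "dynamics") -> pd.DataFrame:
    """ANCOVA on last-minus-first changes per subject.

    Delta = feature(last) - feature(first) is modeled on the (binary) group
    with the first-time-point value as covariate; the group-effect p is
    reported.  ``first_samples``/``last_samples`` are aligned sample-ID
    sequences, one pair per subject; ``group`` is per subject.  If either
    group holds fewer than 2 subjects, the analysis is skipped with a
    warning and an empty table is returned.
    """
    import statsmodels.api as sm

    g = np.asarray(group)
    uniq = np.unique(g)
    if uniq.size != 2:
        raise ValueError(f"group must be binary, got levels {uniq}")
    ind = (g == uniq.max()).astype(float)
    if min((ind == 0).sum(), (ind == 1).sum()) < 2:
        warnings.warn("a dynamics group has fewer than 2 subjects; "
                      "ANCOVA skipped", stacklevel=2)
        return _result_frame([])
    first = features.loc[list(first_samples)].to_numpy(dtype=float)
    last = features.loc[list(last_samples)].to_numpy(dtype=float)
    delta = last - first
    n = len(ind)
    rows = []
    for j, feat in enumerate(features.columns):
        X = np.column_stack([np.ones(n), ind, first[:, j]])
        if delta[:, j].std() == 0 and first[:, j].std() == 0:
            coef, p, flag = 0.0, 1.0, "degenerate"
        else:
            res = sm.OLS(delta[:, j], X).fit()
            coef, p, flag = float(res.params[1]), float(res.pvalues[1]), ""
            if np.isnan(p):
                coef, p, flag = 0.0, 1.0, "degenerate"
        rows.append(dict(
            feature=feat, feature_kind=feature_kind, rank=rank,
            outcome=outcome_name, metadata_group=metadata_group,
            model_kind="ancova", coefficient=coef, p_value=p,
            fdr=np.nan, n=n, flag=flag))
    return _result_frame(rows)


def one_vs_rest(categories, min_size: int = 5) -> dict[str, np.ndarray]:
    """One indicator vector per diagnosis category of size >= ``min_size``.

    Categories below the minimum size are skipped, mirroring the exclusion
    of very small diagnosis groups from one-vs-rest comparisons.  A single
    category yields no contrasts.
    """
    cats = pd.Series(categories)
    counts = cats.value_counts()
    if counts.size < 2:
        return {}
    out = {}
    for cat in sorted(counts.index[counts >= min_size]):
        out[str(cat)] = (cats == cat).to_numpy().astype(int)
    return out
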