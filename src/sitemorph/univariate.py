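"""Per-feature case-control tests with per-family BH-FDR control."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def feature_ttests(
    features: pd.DataFrame, labels, equal_var: bool = True
) -> pd.DataFrame:
    """Two-sample t statistic and two-sided p per feature.

    Classical pooled-variance (Student's) t by default; ``equal_var=False``
    switches to Welch.  Input is expected on the univariate analysis path
    (matched, covariate- and site-factor-corrected data).
    """
    y = np.asarray(
        [1 if v in (1, "case", True) else 0 for v in np.asarray(labels).ravel()], dtype=int
    )
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("both groups need n >= 2")
    a = features.to_numpy(float)[y == 1]
    b = features.to_numpy(float)[y == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    zero_var = ~np.isfinite(t)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} feature(s) with zero pooled variance; p undefined",
            RuntimeWarning, stacklevel=2,
        )
    return pd.DataFrame({"t": t, "p": p}, index=features.columns)


def bh_adjust(pvalues: pd.Series, family_labels: pd.Series | None = None) -> pd.Series:
    """Benjamini-Hochberg step-up q-values, applied separately per family.

    ``q = min_{j >= rank} p_(j) * m / j`` capped at 1, computed independently
    within each family label.  NaN p-values stay NaN and do not count
    towards m.
    """
    p = pd.Series(pvalues, dtype=float)
    finite = p.dropna()
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if family_labels is None:
        family_labels = pd.Series("all", index=p.index)
    q = pd.Series(np.nan, index=p.index)
    for fam in pd.unique(family_labels):
        idx = p.index[(family_labels == fam) & p.notna()]
        if len(idx) == 0:
            continue
        _, q_fam, _, _ = multipletests(p.loc[idx].to_numpy(), method="fdr_bh")
        q.loc[idx] = q_fam
    return q


def univariate_analysis(
    features: pd.DataFrame,
    labels,
    atlas: pd.DataFrame,
    stage: str = "pre_global",
    equal_var: bool = True,
) -> pd.DataFrame:
    """t-tests + per-family BH adjustment; one row per feature.

    Columns: family, stage, t, p, q.  Features missing from the atlas (e.g.
    the appended ICV column) inherit their own family label.
    """
    res = feature_ttests(features, labels, equal_var=equal_var)
    fam = pd.Series(
        [atlas.loc[f, "family"] if f in atlas.index else "other" for f in res.index],
        index=res.index,
    )
    res.insert(0, "family", fam)
    res.insert(1, "stage", stage)
    res["q"] = bh_adjust(res["p"], res["family"])
    return res
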