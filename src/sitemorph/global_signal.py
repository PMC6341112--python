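"""Global structural signal: assembly, residualization controls, prediction.

The 22-member global feature set consists of the atlas-designated whole-brain
summary features (including intracranial volume), a per-subject median of all
ventricle features, and a per-subject median across the active family's
regional features.  Regional features can be residualized against the
covariate-adjusted globals via additive linear models (fit on training
subjects only in leave-site-out mode), with two controls: repeating the
residualization with row-permuted global features (does residualization per
se destroy signal?) and re-running classification with permuted diagnostic
labels (the chance band).  Tree-ensemble regression quantifies how much
variance in each regional feature the globals explain out-of-bag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .atlas import FAMILY_MEDIAN, PLACEHOLDERS, VENTRICLE_MEDIAN, regional_features
from .evaluate import ClassifierSpec, LosoResult, classify_fold, prepare_loso_folds
from .metrics import EvaluationResult
from .normalize import residualize_against


def assemble_global_features(
    features: pd.DataFrame, atlas: pd.DataFrame, family: str
) -> pd.DataFrame:
    """Assemble the global feature set from a (normalized) feature table.

    Members: measured atlas-designated globals (incl. the ICV column appended
    during normalization), the per-subject ventricle median, and the
    per-subject median of the active family's regional features.  Medians are
    computed from the covariate-adjusted values, consistent with treating the
    globals as covariate-adjusted regressors.
    """
    designated = [
        f for f in atlas.index[atlas["is_global"]]
        if f not in PLACEHOLDERS and f in features.columns
    ]
    missing = [
        f for f in atlas.index[atlas["is_global"]]
        if f not in PLACEHOLDERS and f not in features.columns
    ]
    if missing:
        raise ValueError(f"designated global feature(s) absent from table: {missing[:5]}")
    vents = [f for f in atlas.index[atlas["is_ventricle"]] if f in features.columns]
    if not vents:
        raise ValueError("no ventricle features available for the ventricle median")
    regional = [f for f in regional_features(atlas, family) if f in features.columns]
    if not regional:
        raise ValueError(f"no regional features of family {family!r} present")

    out = features[designated].copy()
    out[VENTRICLE_MEDIAN] = features[vents].median(axis=1)
    out[FAMILY_MEDIAN] = features[regional].median(axis=1)
    expected = int(atlas["is_global"].sum())
    if len(out.columns) != expected:
        raise ValueError(
            f"assembled {len(out.columns)} global features, atlas expects {expected}"
        )
    return out


def residualize_against_globals(
    features: pd.DataFrame,
    globals_: pd.DataFrame,
    fit_subjects: pd.Index | None = None,
    audit=None,
) -> pd.DataFrame:
    """Residualize each feature against all global features additively."""
    if not features.index.equals(globals_.index):
        if set(features.index) != set(globals_.index):
            raise ValueError("feature and global tables cover different subjects")
        globals_ = globals_.loc[features.index]
    return residualize_against(
        features, globals_, fit_subjects=fit_subjects, audit=audit,
        stage="global_residualization_fit",
    )


def _global_transform(atlas, family, permutation=None):
    """Fold transform: residualize regionals against fold-assembled globals.

    The residualization models are fit on the fold's training subjects only;
    ``permutation`` (a row permutation array) yields the permuted-covariate
    control.
    """

    def transform(feats: pd.DataFrame, fold) -> pd.DataFrame:
        g = assemble_global_features(feats, atlas, family)
        if permutation is not None:
            g = pd.DataFrame(
                g.to_numpy()[permutation(len(g))], index=g.index, columns=g.columns
            )
        return residualize_against_globals(
            feats, g, fit_subjects=fold.train_ids, audit=fold.audit
        )

    return transform


def loso_with_global_residualization(
    features, phenotypes, atlas, family, cohorts=None, spec=None, folds=None
) -> LosoResult:
    """Leave-site-out classification after residualizing against the globals."""
    spec = spec or ClassifierSpec()
    if folds is None:
        folds = prepare_loso_folds(features, phenotypes, atlas, cohorts, spec)
    transform = _global_transform(atlas, family)
    per_site = {f.site: classify_fold(f, spec, transform=transform) for f in folds}
    return LosoResult(per_site=per_site, folds=folds)


def permuted_global_control(
    folds, atlas, family, spec: ClassifierSpec, B: int = 100, seed: int = 0
) -> np.ndarray:
    """Median leave-site-out AUC per repetition with row-permuted globals."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(B)
    for b in range(B):
        perm_seed = int(rng.integers(2**31 - 1))

        def permutation(n, _s=perm_seed):
            return np.random.default_rng(_s).permutation(n)

        transform = _global_transform(atlas, family, permutation=permutation)
        rep_spec = ClassifierSpec(**{**spec.__dict__, "seed": int(rng.integers(2**31 - 1))})
        aucs = [classify_fold(f, rep_spec, transform=transform).auc for f in folds]
        out[b] = float(np.median(aucs))
    return out


def permuted_diagnosis_control(
    folds, spec: ClassifierSpec, B: int = 100, seed: int = 0,
    transform=None,
) -> np.ndarray:
    """Median leave-site-out AUC per repetition with within-cohort permuted labels.

    Matching and covariate normalization are label-free given the matched
    sets, so only the (optionally transformed) classification is re-run.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(B)
    for b in range(B):
        aucs = []
        rep_spec = ClassifierSpec(**{**spec.__dict__, "seed": int(rng.integers(2**31 - 1))})
        for fold in folds:
            labels = fold.labels.copy()
            for site in labels.index.groupby(fold.sites).values():
                labels.loc[site] = labels.loc[rng.permutation(site)].to_numpy()
            aucs.append(classify_fold(fold, rep_spec, transform=transform, labels=labels).auc)
        out[b] = float(np.median(aucs))
    return out


def globals_only_classification(
    folds, atlas, family, spec: ClassifierSpec
) -> LosoResult:
    """Leave-site-out classification using only the 22 global features."""

    def transform(feats, fold):
        g = assemble_global_features(feats, atlas, family)
        if g.shape[1] == 0:
            raise ValueError("empty global feature set")
        return g

    per_site = {f.site: classify_fold(f, spec, transform=transform) for f in folds}
    return LosoResult(per_site=per_site, folds=folds)


def oob_explained_variance(
    feature_values: pd.DataFrame,
    globals_: pd.DataFrame,
    n_trees: int = 300,
    seed: int = 0,
) -> pd.Series:
    """Out-of-bag R² of tree-ensemble regressions of each feature on the globals.

    R² = 1 - OOB-MSE / Var(feature), floored at 0 for reporting.  A feature
    with zero variance is undefined (NaN) and signalled via a warning.
    """
    import warnings

    g = globals_.loc[feature_values.index].to_numpy(float)
    out = {}
    rng = np.random.default_rng(seed)
    for col in feature_values.columns:
        y = feature_values[col].to_numpy(float)
        if np.ptp(y) == 0.0:
            warnings.warn(f"feature {col!r} has zero variance; R² undefined",
                          RuntimeWarning, stacklevel=2)
            out[col] = float("nan")
            continue
        reg = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=1 / 3,
            min_samples_leaf=5,
            oob_score=True,
            bootstrap=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        reg.fit(g, y)
        out[col] = float(max(reg.oob_score_, 0.0))
    return pd.Series(out)


def explained_variance_size_correlation(
    r2_per_feature: pd.Series, atlas: pd.DataFrame
) -> tuple[float, float]:
    """Spearman correlation between per-feature R² and atlas mean size."""
    r2 = r2_per_feature.dropna()
    if len(r2) < 3:
        raise ValueError("need at least 3 features for a rank correlation")
    if np.ptp(r2.to_numpy()) == 0.0:
        raise ValueError("explained-variance vector is constant; correlation undefined")
    sizes = atlas.loc[r2.index, "mean_size"].to_numpy(float)
    rho, p = stats.spearmanr(r2.to_numpy(), sizes)
    return float(rho), float(p)


def _pc1(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component scores and variance-explained fraction."""
    u, s_vals, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    scores = u[:, 0] * s_vals[0]
    if vt[0].sum() < 0:  # deterministic sign: loadings sum positive
        scores = -scores
    var_explained = float(s_vals[0] ** 2 / (s_vals**2).sum())
    return scores, var_explained


def top_feature_pc_global_association(
    top_density: list[str],
    top_surface: list[str],
    features: pd.DataFrame,
    globals_: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> dict:
    """PC1 of each family's top features vs. globals and confounds.

    Features are residualized against diagnosis, standardized, and the first
    principal component of each top set is correlated with the other set's
    PC1, with every global feature, and checked against the covariates.
    """
    if not top_density or not top_surface:
        raise ValueError("both top sets must be non-empty")
    ph = phenotypes.loc[features.index]
    diag = pd.DataFrame(
        {"case": (ph["diagnosis"] == "case").astype(float)}, index=features.index
    )
    adj = residualize_against(features[sorted(set(top_density) | set(top_surface))], diag)
    z = (adj - adj.mean()) / adj.std(ddof=0)

    report: dict = {}
    pcs = {}
    for name, top in (("density", top_density), ("surface", top_surface)):
        if len(top) == 1:
            scores = z[top[0]].to_numpy()
            var_exp = 1.0
            report[f"pc1_degenerate_{name}"] = True
        else:
            scores, var_exp = _pc1(z[list(top)].to_numpy())
        pcs[name] = scores
        report[f"pc1_var_explained_{name}"] = var_exp

    r, p = stats.pearsonr(pcs["density"], pcs["surface"])
    report["pc1_correlation"] = float(r)
    report["pc1_correlation_p"] = float(p)

    g = globals_.loc[features.index]
    global_assoc = {}
    for col in g.columns:
        for name in pcs:
            r, p = stats.pearsonr(pcs[name], g[col].to_numpy(float))
            global_assoc[f"{col}|{name}"] = {"r": float(r), "p": float(p)}
    report["global_associations"] = global_assoc

    confounds = {}
    age = ph["age"].to_numpy(float)
    numeric = {
        "icv": ph["icv"].to_numpy(float),
        "age": age,
        "age2": (age - age.mean()) ** 2,
        "sex": (ph["sex"] == "M").to_numpy(float),
    }
    for name in pcs:
        for cname, vals in numeric.items():
            r, p = stats.pearsonr(pcs[name], vals)
            confounds[f"{cname}|{name}"] = float(p)
        for cname in ("scanner_vendor", "field_strength", "cohort_id"):
            groups = [pcs[name][(ph[cname] == lvl).to_numpy()] for lvl in ph[cname].unique()]
            groups = [gr for gr in groups if len(gr) > 1]
            if len(groups) > 1:
                _, p = stats.f_oneway(*groups)
                confounds[f"{cname}|{name}"] = float(p)
    report["confound_p_values"] = confounds
    return report
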