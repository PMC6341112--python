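"""Cross-validation harnesses: leave-site-out, within-site OOB, external.

Leave-site-out: for each held-out cohort, matching is per-cohort (local), and
both covariate-normalization steps are refit on the remaining cohorts only
before the classifier is trained; the held-out cohort is only ever scored.
A :class:`~sitemorph.normalize.LeakageAudit` whose forbidden set is the
held-out cohort's subjects guards every fit.

Within-site: a forest trained on a single matched cohort is evaluated by its
out-of-bag votes, with significance from label-permutation re-training.

External: a classifier trained on all training cohorts is applied to
independent validation cohorts; accuracy is the fraction classified as not
affected (specificity for control cohorts, 1 - misclassification for case
cohorts of other disorders).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forest import train_site_stratified_forest
from .matching import match_cohorts, matched_subject_ids
from .metrics import EvaluationResult, roc_auc
from .normalize import (
    LeakageAudit,
    apply_between_dataset_model,
    apply_normalization,
    center_test_features,
    fit_apply_between_dataset_adjustment,
    fit_within_dataset_models,
    residualize_site_factor,
)


@dataclass
class ClassifierSpec:
    """Classifier and harness configuration (YAML-serializable)."""

    algorithm: str = "forest"          # forest | svm
    n_trees: int = 500                 # desk-scale default; the model contract is 5000
    s: int | None = None
    strict_bag: bool = False
    mtry: int | None = None
    cutoff: float = 0.5
    cost_grid: list | None = None
    center_test: bool = False
    skip_matching: frozenset = frozenset()
    seed: int = 0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["skip_matching"] = sorted(self.skip_matching)
        return d


@dataclass
class LosoFold:
    site: str
    features: pd.DataFrame            # normalized, train + test subjects
    train_ids: pd.Index
    test_ids: pd.Index
    labels: pd.Series                 # case/control for all subjects
    sites: pd.Series
    audit: LeakageAudit


@dataclass
class LosoResult:
    per_site: dict[str, EvaluationResult]
    folds: list[LosoFold] = field(default_factory=list, repr=False)

    @property
    def aucs(self) -> dict[str, float]:
        return {s: r.auc for s, r in self.per_site.items()}

    @property
    def median_auc(self) -> float:
        return float(np.median([r.auc for r in self.per_site.values()]))

    @property
    def auc_range(self) -> tuple[float, float]:
        vals = [r.auc for r in self.per_site.values()]
        return (float(min(vals)), float(max(vals)))

    @property
    def median_mean_sens_spec(self) -> float:
        return float(np.median([r.mean_sens_spec for r in self.per_site.values()]))

    @property
    def leakage_clean(self) -> bool:
        return all(f.audit.clean for f in self.folds)


def training_cohorts(phenotypes: pd.DataFrame) -> list[str]:
    """Cohorts containing schizophrenia-like cases (the training pool)."""
    has_sz = phenotypes[phenotypes["disorder_label"] == "SZ-like"]["cohort_id"].unique()
    return sorted(has_sz)


def prepare_loso_folds(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    atlas: pd.DataFrame,
    cohorts: list[str] | None = None,
    spec: ClassifierSpec | None = None,
    strict_audit: bool = True,
) -> list[LosoFold]:
    """Match cohorts and build one normalized train/test fold per held-out site.

    Folds are reusable: classification under different feature transforms or
    permuted labels can rerun on the same folds without repeating the
    (label-free) matching and normalization.
    """
    spec = spec or ClassifierSpec()
    if cohorts is None:
        cohorts = training_cohorts(phenotypes)
    if len(cohorts) < 3:
        raise ValueError("leave-site-out requires at least 3 sites")
    matched = match_cohorts(
        phenotypes, cohorts, seed=spec.seed, skip_matching=spec.skip_matching
    )
    ids = matched_subject_ids(matched)
    feats_m = features.loc[ids]
    ph = phenotypes.loc[ids]

    folds = []
    for held_out in cohorts:
        test_ids = feats_m.index[ph["cohort_id"] == held_out]
        test_labels = ph.loc[test_ids, "diagnosis"]
        if test_labels.nunique() < 2:
            warnings.warn(
                f"held-out site {held_out} lacks a class; skipped", RuntimeWarning,
                stacklevel=2,
            )
            continue
        train_cohorts = [c for c in cohorts if c != held_out]
        audit = LeakageAudit(forbidden=frozenset(test_ids), strict=strict_audit)
        m1 = fit_within_dataset_models(feats_m, ph, train_cohorts, atlas, audit=audit)
        normd = apply_normalization(m1, feats_m, ph)
        normd, _ = fit_apply_between_dataset_adjustment(
            normd, ph, train_cohorts, audit=audit
        )
        if spec.center_test:
            normd = center_test_features(normd, ph, held_out)
        folds.append(
            LosoFold(
                site=held_out,
                features=normd,
                train_ids=feats_m.index[ph["cohort_id"] != held_out],
                test_ids=test_ids,
                labels=ph["diagnosis"],
                sites=ph["cohort_id"],
                audit=audit,
            )
        )
    return folds


def classify_fold(
    fold: LosoFold,
    spec: ClassifierSpec,
    transform=None,
    labels: pd.Series | None = None,
) -> EvaluationResult:
    """Train on the fold's training sites, score its held-out site.

    ``transform(features, fold)`` may replace the feature table (e.g.
    residualization against global features, fit on training subjects only —
    the fold's audit guards it).  ``labels`` overrides the diagnosis column
    (permutation nulls).
    """
    feats = transform(fold.features, fold) if transform is not None else fold.features
    y = labels if labels is not None else fold.labels
    x_train = feats.loc[fold.train_ids]
    y_train = y.loc[fold.train_ids]
    if spec.algorithm == "forest":
        model = train_site_stratified_forest(
            x_train,
            y_train,
            fold.sites.loc[fold.train_ids],
            n_trees=spec.n_trees,
            s=spec.s,
            strict_bag=spec.strict_bag,
            mtry=spec.mtry,
            cutoff=spec.cutoff,
            seed=spec.seed,
        )
    elif spec.algorithm == "svm":
        from .svm import train_linear_svm

        model = train_linear_svm(
            x_train, y_train, cost_grid=spec.cost_grid, seed=spec.seed
        )
    else:
        raise ValueError(f"unknown algorithm {spec.algorithm!r}")
    scores = model.predict_score(feats.loc[fold.test_ids])
    if spec.algorithm == "svm":
        # decision values: classify by sign, mapped through a logistic for
        # the fixed 0.5 cutoff convention
        from .metrics import mean_sens_spec as _mss

        sens, spec_, mss = _mss(1 / (1 + np.exp(-scores)), y.loc[fold.test_ids], 0.5)
        return EvaluationResult(
            auc=roc_auc(scores, y.loc[fold.test_ids]),
            sensitivity=sens,
            specificity=spec_,
            mean_sens_spec=mss,
            n=len(scores),
            site=fold.site,
        )
    return EvaluationResult.from_scores(
        scores, y.loc[fold.test_ids], cutoff=spec.cutoff, site=fold.site
    )


def run_leave_site_out(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    atlas: pd.DataFrame,
    cohorts: list[str] | None = None,
    spec: ClassifierSpec | None = None,
    transform=None,
    folds: list[LosoFold] | None = None,
) -> LosoResult:
    """Full leave-site-out evaluation; returns per-site results and folds."""
    spec = spec or ClassifierSpec()
    if folds is None:
        folds = prepare_loso_folds(features, phenotypes, atlas, cohorts, spec)
    per_site = {}
    for fold in folds:
        per_site[fold.site] = classify_fold(fold, spec, transform=transform)
    return LosoResult(per_site=per_site, folds=folds)


def run_within_site(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    atlas: pd.DataFrame,
    cohort_id: str,
    spec: ClassifierSpec | None = None,
    n_label_perms: int = 1000,
) -> EvaluationResult:
    """Single-cohort OOB evaluation with label-permutation significance.

    The empirical p is the frequency of permutation OOB AUCs at least as
    high as the observed one (B = ``n_label_perms``).
    """
    spec = spec or ClassifierSpec()
    if n_label_perms < 1:
        raise ValueError("n_label_perms must be >= 1")
    matched = match_cohorts(
        phenotypes, [cohort_id], seed=spec.seed, skip_matching=spec.skip_matching
    )
    ids = matched[cohort_id].matched_subjects
    feats = features.loc[ids]
    ph = phenotypes.loc[ids]
    m1 = fit_within_dataset_models(feats, ph, [cohort_id], atlas)
    normd = apply_normalization(m1, feats, ph)
    y = (ph["diagnosis"] == "case").astype(int).to_numpy()
    sites = ph["cohort_id"].to_numpy()

    def _oob_auc(labels, seed):
        model = train_site_stratified_forest(
            normd, labels, sites,
            n_trees=spec.n_trees, s=spec.s, strict_bag=spec.strict_bag,
            mtry=spec.mtry, cutoff=spec.cutoff, seed=seed, store_trees=False,
        )
        ok = model.oob_counts_ > 0
        return roc_auc(model.oob_scores_[ok], labels[ok]), model

    observed, model = _oob_auc(y, spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    null = np.empty(n_label_perms)
    for b in range(n_label_perms):
        null[b], _ = _oob_auc(rng.permutation(y), int(rng.integers(2**31 - 1)))
    p = float(np.mean(null >= observed))
    ok = model.oob_counts_ > 0
    result = EvaluationResult.from_scores(
        model.oob_scores_[ok], y[ok], cutoff=spec.cutoff, site=cohort_id, p_value=p
    )
    result.extra["n_label_perms"] = n_label_perms
    result.extra["null_auc_mean"] = float(null.mean())
    result.extra["importances"] = model.importance_series
    return result


@dataclass
class FittedPipeline:
    """Normalization models + classifier trained on all training cohorts."""

    within_model: object
    between_model: object
    classifier: object
    train_cohorts: list[str]
    train_subjects: frozenset
    spec: ClassifierSpec

    def score(self, features: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.Series:
        normd = apply_normalization(self.within_model, features, phenotypes)
        normd = apply_between_dataset_model(self.between_model, normd, phenotypes)
        return pd.Series(self.classifier.predict_score(normd), index=features.index)


def train_full_classifier(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    atlas: pd.DataFrame,
    train_cohorts: list[str] | None = None,
    spec: ClassifierSpec | None = None,
) -> FittedPipeline:
    """Train matching + two-step normalization + classifier on all training cohorts."""
    spec = spec or ClassifierSpec()
    if train_cohorts is None:
        train_cohorts = training_cohorts(phenotypes)
    matched = match_cohorts(
        phenotypes, train_cohorts, seed=spec.seed, skip_matching=spec.skip_matching
    )
    ids = matched_subject_ids(matched)
    feats = features.loc[ids]
    ph = phenotypes.loc[ids]
    m1 = fit_within_dataset_models(feats, ph, train_cohorts, atlas)
    normd = apply_normalization(m1, feats, ph)
    normd, m2 = fit_apply_between_dataset_adjustment(normd, ph, train_cohorts)
    y = ph["diagnosis"]
    if spec.algorithm == "forest":
        clf = train_site_stratified_forest(
            normd, y, ph["cohort_id"],
            n_trees=spec.n_trees, s=spec.s, strict_bag=spec.strict_bag,
            mtry=spec.mtry, cutoff=spec.cutoff, seed=spec.seed,
        )
    else:
        from .svm import train_linear_svm

        clf = train_linear_svm(normd, y, cost_grid=spec.cost_grid, seed=spec.seed)
    return FittedPipeline(
        within_model=m1,
        between_model=m2,
        classifier=clf,
        train_cohorts=list(train_cohorts),
        train_subjects=frozenset(ids),
        spec=spec,
    )


def run_external_specificity(
    pipeline: FittedPipeline,
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    cohort_ids: list[str],
) -> dict[str, dict]:
    """Fraction of each validation cohort classified as not case-affected.

    Rejects any overlap between validation subjects and training subjects.
    """
    cutoff = pipeline.spec.cutoff if pipeline.spec.algorithm == "forest" else 0.0
    out = {}
    for cid in cohort_ids:
        subj = phenotypes.index[phenotypes["cohort_id"] == cid]
        subj = subj.intersection(features.index)
        overlap = set(subj) & set(pipeline.train_subjects)
        if overlap:
            raise ValueError(
                f"validation cohort {cid} overlaps training subjects, e.g. "
                f"{sorted(overlap)[:3]}"
            )
        scores = pipeline.score(features.loc[subj], phenotypes)
        ph = phenotypes.loc[subj]
        entry = {"n": len(subj), "fraction_classified_non_case": float(np.mean(scores <= cutoff))}
        for diag, grp in scores.groupby(ph["diagnosis"]):
            entry[f"non_case_rate_{diag}"] = float(np.mean(grp <= cutoff))
            entry[f"n_{diag}"] = int(len(grp))
        out[cid] = entry
    return out


def run_whole_dataset_oob(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    atlas: pd.DataFrame,
    cohorts: list[str] | None = None,
    spec: ClassifierSpec | None = None,
    feature_columns: list[str] | None = None,
):
    """Whole-dataset analysis path: matched, normalized, site-factor corrected.

    Returns ``(model, result, normalized_features, phenotypes_subset)``; the
    site-factor-corrected table is the input for univariate analyses and
    explained-variance regressions.
    """
    spec = spec or ClassifierSpec()
    if cohorts is None:
        cohorts = training_cohorts(phenotypes)
    matched = match_cohorts(
        phenotypes, cohorts, seed=spec.seed, skip_matching=spec.skip_matching
    )
    ids = matched_subject_ids(matched)
    feats = features.loc[ids]
    ph = phenotypes.loc[ids]
    m1 = fit_within_dataset_models(feats, ph, cohorts, atlas)
    normd = apply_normalization(m1, feats, ph)
    normd, _ = fit_apply_between_dataset_adjustment(normd, ph, cohorts)
    normd = residualize_site_factor(normd, ph)
    if feature_columns is not None:
        normd_clf = normd[feature_columns]
    else:
        normd_clf = normd
    model = train_site_stratified_forest(
        normd_clf, ph["diagnosis"], ph["cohort_id"],
        n_trees=spec.n_trees, s=spec.s, strict_bag=spec.strict_bag,
        mtry=spec.mtry, cutoff=spec.cutoff, seed=spec.seed, store_trees=False,
    )
    ok = model.oob_counts_ > 0
    y = (ph["diagnosis"] == "case").astype(int).to_numpy()
    result = EvaluationResult.from_scores(
        model.oob_scores_[ok], y[ok], cutoff=spec.cutoff, site="all"
    )
    return model, result, normd, ph
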