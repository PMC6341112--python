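"""Two-step, training-only covariate normalization with a leakage audit.

Step 1 (*within-dataset*): per training cohort, each feature is regressed on
age, age² (age centered at the pooled training mean), sex and intracranial
volume (ICV omitted for thickness-type features); per-cohort coefficients are
averaged unweighted into one final model per feature, which residualizes both
training and test data.  ICV is then appended as an additional feature.

Step 2 (*between-dataset*): the residualized features are regressed on
scanner-vendor and field-strength factors, fit on training cohorts only, and
residualized for train and test alike.  Test cohorts never enter any fit —
the :class:`LeakageAudit` makes that property assertable.

For whole-dataset (non-leave-site-out) analyses a separate site-factor
residualization removes site and vendor effects jointly on all data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COVARIATES = ["age", "age2", "sex", "icv"]


class LeakageError(RuntimeError):
    """A declared test subject entered a model fit."""


@dataclass
class LeakageAudit:
    """Records which subjects enter which fits; flags forbidden subjects.

    ``strict`` audits raise :class:`LeakageError` at the moment of leakage;
    non-strict audits only record violations (useful to *demonstrate* that a
    leaky configuration is caught).
    """

    forbidden: frozenset = frozenset()
    strict: bool = True
    events: list = field(default_factory=list)
    violations: list = field(default_factory=list)

    def check_fit(self, stage: str, subject_ids) -> None:
        ids = set(subject_ids)
        bad = sorted(ids & set(self.forbidden))
        self.events.append((stage, len(ids), len(bad)))
        if bad:
            self.violations.append((stage, bad))
            if self.strict:
                raise LeakageError(
                    f"stage {stage!r}: {len(bad)} held-out subject(s) in design "
                    f"matrix, e.g. {bad[:3]}"
                )

    @property
    def clean(self) -> bool:
        return not self.violations


@dataclass
class NormalizationModel:
    """Averaged per-feature covariate model with fit provenance."""

    step: str                      # within_dataset | between_dataset | site_factor
    fit_cohorts: list[str]
    coef: pd.DataFrame             # features x [intercept, age, age2, sex, icv]
    age_center: float
    icv_center: float
    thickness_features: list[str]

    def to_dict(self) -> dict:
        coef = {}
        for fid, row in self.coef.iterrows():
            coef[fid] = {k: float(v) for k, v in row.items() if np.isfinite(v)}
        return {
            "step": self.step,
            "fit_cohorts": list(self.fit_cohorts),
            "age_center": float(self.age_center),
            "icv_center": float(self.icv_center),
            "thickness_features": list(self.thickness_features),
            "coefficients": coef,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "NormalizationModel":
        coef = pd.DataFrame.from_dict(payload["coefficients"], orient="index")
        coef = coef.reindex(columns=["intercept"] + COVARIATES)
        coef.index.name = "feature_id"
        return cls(
            step=payload["step"],
            fit_cohorts=list(payload["fit_cohorts"]),
            coef=coef,
            age_center=float(payload["age_center"]),
            icv_center=float(payload["icv_center"]),
            thickness_features=list(payload["thickness_features"]),
        )


def _covariate_design(
    phenotypes: pd.DataFrame, subjects: pd.Index, age_center: float, icv_center: float
) -> pd.DataFrame:
    ph = phenotypes.loc[subjects]
    for col in ("age", "sex", "icv"):
        bad = ph.index[ph[col].isna()] if ph[col].dtype != object else ph.index[ph[col].isna()]
        if len(bad):
            raise ValueError(f"missing covariate {col!r} for subject(s) {list(bad[:3])}")
    a = ph["age"].to_numpy(dtype=float) - age_center
    return pd.DataFrame(
        {
            "intercept": 1.0,
            "age": a,
            "age2": a**2,
            "sex": (ph["sex"] == "M").to_numpy(dtype=float),
            "icv": ph["icv"].to_numpy(dtype=float) - icv_center,
        },
        index=subjects,
    )


def _lstsq_coefs(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return beta


def fit_within_dataset_models(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    train_cohorts: list[str],
    atlas: pd.DataFrame,
    audit: LeakageAudit | None = None,
) -> NormalizationModel:
    """Fit per-cohort covariate models and average their coefficients.

    Only subjects of ``train_cohorts`` that are present in ``features`` enter
    any design matrix.  A cohort with a constant covariate drops that
    coefficient (with a warning) and the average is taken over the cohorts
    that retain it.
    """
    if not train_cohorts:
        raise ValueError("at least one training cohort required")
    ph = phenotypes.loc[features.index]
    fit_mask = ph["cohort_id"].isin(train_cohorts)
    fit_subjects = features.index[fit_mask]
    if len(fit_subjects) == 0:
        raise ValueError("no training subjects found in feature table")
    if audit is not None:
        audit.check_fit("within_dataset_fit", fit_subjects)

    age_center = float(ph.loc[fit_subjects, "age"].mean())
    icv_center = float(ph.loc[fit_subjects, "icv"].mean())
    thickness = [
        f for f in features.columns
        if f in atlas.index and atlas.loc[f, "measure"] == "thickness"
    ]
    thick_mask = features.columns.isin(thickness)

    per_cohort = []
    for cid in train_cohorts:
        subj = features.index[ph["cohort_id"] == cid]
        if len(subj) == 0:
            continue
        design = _covariate_design(phenotypes, subj, age_center, icv_center)
        keep = ["intercept"]
        for col in COVARIATES:
            if np.ptp(design[col].to_numpy()) == 0.0:
                warnings.warn(
                    f"cohort {cid}: covariate {col!r} is constant; coefficient dropped",
                    RuntimeWarning, stacklevel=2,
                )
            else:
                keep.append(col)
        y = features.loc[subj].to_numpy(dtype=float)
        coef = pd.DataFrame(
            np.nan, index=features.columns, columns=["intercept"] + COVARIATES
        )
        # volume/area/density features: full design; thickness: no ICV term
        full_cols = keep
        b = _lstsq_coefs(design[full_cols].to_numpy(), y[:, ~thick_mask])
        coef.loc[~thick_mask, full_cols] = b.T
        if thick_mask.any():
            t_cols = [c for c in keep if c != "icv"]
            b = _lstsq_coefs(design[t_cols].to_numpy(), y[:, thick_mask])
            coef.loc[thick_mask, t_cols] = b.T
        per_cohort.append(coef)
    if not per_cohort:
        raise ValueError(f"no subjects found for training cohorts {train_cohorts}")

    stacked = np.stack([c.to_numpy() for c in per_cohort])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        avg = np.nanmean(stacked, axis=0)
    coef = pd.DataFrame(avg, index=features.columns, columns=["intercept"] + COVARIATES)
    coef.loc[thick_mask, "icv"] = np.nan  # thickness carries no ICV coefficient
    return NormalizationModel(
        step="within_dataset",
        fit_cohorts=list(train_cohorts),
        coef=coef,
        age_center=age_center,
        icv_center=icv_center,
        thickness_features=thickness,
    )


def apply_normalization(
    model: NormalizationModel,
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    add_icv: bool = True,
) -> pd.DataFrame:
    """Residualize features with a fitted model; append ICV as a feature."""
    missing = [f for f in features.columns if f not in model.coef.index]
    if missing:
        raise ValueError(f"model does not cover feature(s) {missing[:5]}")
    design = _covariate_design(
        phenotypes, features.index, model.age_center, model.icv_center
    )
    b = model.coef.loc[features.columns].fillna(0.0)
    pred = design[["intercept"] + COVARIATES].to_numpy() @ b[["intercept"] + COVARIATES].to_numpy().T
    out = pd.DataFrame(
        features.to_numpy(dtype=float) - pred, index=features.index, columns=features.columns
    )
    if add_icv:
        out["icv"] = phenotypes.loc[features.index, "icv"].to_numpy(dtype=float)
    return out


@dataclass
class BetweenDatasetModel:
    fit_cohorts: list[str]
    columns: list[str]             # dummy design columns used at fit time
    vendor_levels: list[str]
    field_levels: list[str]
    coef: pd.DataFrame             # features x columns


def _between_design(
    phenotypes: pd.DataFrame,
    subjects: pd.Index,
    vendor_levels: list[str],
    field_levels: list[str],
    warn_unseen: bool = False,
) -> pd.DataFrame:
    ph = phenotypes.loc[subjects]
    cols = {"intercept": np.ones(len(subjects))}
    for lvl in vendor_levels[1:]:
        cols[f"vendor[{lvl}]"] = (ph["scanner_vendor"] == lvl).to_numpy(float)
    for lvl in field_levels[1:]:
        cols[f"field[{lvl}]"] = (ph["field_strength"] == lvl).to_numpy(float)
    if warn_unseen:
        unseen_v = set(ph["scanner_vendor"]) - set(vendor_levels)
        unseen_f = set(ph["field_strength"]) - set(field_levels)
        if unseen_v or unseen_f:
            warnings.warn(
                f"levels absent from training treated as reference: "
                f"{sorted(unseen_v | unseen_f)}",
                RuntimeWarning, stacklevel=3,
            )
    return pd.DataFrame(cols, index=subjects)


def fit_apply_between_dataset_adjustment(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    train_cohorts: list[str],
    audit: LeakageAudit | None = None,
) -> tuple[pd.DataFrame, BetweenDatasetModel]:
    """Remove scanner-vendor and field-strength effects, fit on training only."""
    ph = phenotypes.loc[features.index]
    fit_subjects = features.index[ph["cohort_id"].isin(train_cohorts)]
    if len(fit_subjects) == 0:
        raise ValueError("no training subjects for between-dataset adjustment")
    if audit is not None:
        audit.check_fit("between_dataset_fit", fit_subjects)

    vendor_levels = sorted(ph.loc[fit_subjects, "scanner_vendor"].unique())
    field_levels = sorted(ph.loc[fit_subjects, "field_strength"].unique())
    design_fit = _between_design(phenotypes, fit_subjects, vendor_levels, field_levels)
    b = _lstsq_coefs(design_fit.to_numpy(), features.loc[fit_subjects].to_numpy(float))
    coef = pd.DataFrame(b.T, index=features.columns, columns=design_fit.columns)

    design_all = _between_design(
        phenotypes, features.index, vendor_levels, field_levels, warn_unseen=True
    )
    pred = design_all.to_numpy() @ coef.to_numpy().T
    out = pd.DataFrame(
        features.to_numpy(float) - pred, index=features.index, columns=features.columns
    )
    model = BetweenDatasetModel(
        fit_cohorts=list(train_cohorts),
        columns=list(design_fit.columns),
        vendor_levels=vendor_levels,
        field_levels=field_levels,
        coef=coef,
    )
    return out, model


def apply_between_dataset_model(
    model: BetweenDatasetModel, features: pd.DataFrame, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Apply a fitted between-dataset model to new data (unseen levels -> reference)."""
    design = _between_design(
        phenotypes, features.index, model.vendor_levels, model.field_levels, warn_unseen=True
    )
    pred = design[model.columns].to_numpy() @ model.coef[model.columns].to_numpy().T
    return pd.DataFrame(
        features.to_numpy(float) - pred, index=features.index, columns=features.columns
    )


def center_test_features(
    features: pd.DataFrame, phenotypes: pd.DataFrame, test_cohort: str
) -> pd.DataFrame:
    """Set each feature's mean in the test cohort exactly to zero.

    Training cohorts are untouched; the operation is idempotent.
    """
    out = features.copy()
    mask = phenotypes.loc[features.index, "cohort_id"] == test_cohort
    if mask.any():
        out.loc[mask.to_numpy()] -= out.loc[mask.to_numpy()].mean(axis=0)
    return out


def residualize_site_factor(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    audit: LeakageAudit | None = None,
) -> pd.DataFrame:
    """Whole-dataset residualization against site and vendor factors jointly.

    When vendor is aliased with site (each site uses one vendor) the vendor
    columns add no rank and are dropped with a warning.
    """
    ph = phenotypes.loc[features.index]
    if audit is not None:
        audit.check_fit("site_factor_fit", features.index)
    site_d = pd.get_dummies(ph["cohort_id"], prefix="site", drop_first=True, dtype=float)
    vendor_d = pd.get_dummies(ph["scanner_vendor"], prefix="vendor", drop_first=True, dtype=float)
    base = np.column_stack([np.ones(len(ph)), site_d.to_numpy()])
    design = base
    if vendor_d.shape[1]:
        candidate = np.column_stack([base, vendor_d.to_numpy()])
        if np.linalg.matrix_rank(candidate) > np.linalg.matrix_rank(base):
            design = candidate
        else:
            warnings.warn(
                "scanner vendor is aliased with site; vendor factor dropped",
                RuntimeWarning, stacklevel=2,
            )
    b = _lstsq_coefs(design, features.to_numpy(float))
    resid = features.to_numpy(float) - design @ b
    return pd.DataFrame(resid, index=features.index, columns=features.columns)


def residualize_against(
    features: pd.DataFrame,
    regressors: pd.DataFrame,
    fit_subjects: pd.Index | None = None,
    audit: LeakageAudit | None = None,
    stage: str = "residualize_fit",
) -> pd.DataFrame:
    """OLS-residualize each feature column against ``regressors`` (+intercept).

    The models are fit on ``fit_subjects`` (default: all rows) and applied to
    every row.  Collinear regressor columns are dropped with a warning.
    """
    if fit_subjects is None:
        fit_subjects = features.index
    if audit is not None:
        audit.check_fit(stage, fit_subjects)
    g = regressors.loc[fit_subjects].to_numpy(float)
    x_fit = np.column_stack([np.ones(len(g)), g])
    rank = np.linalg.matrix_rank(x_fit)
    keep = list(range(x_fit.shape[1]))
    if rank < x_fit.shape[1]:
        # greedy pivot: keep columns that increase rank
        keep, cur = [0], x_fit[:, :1]
        for j in range(1, x_fit.shape[1]):
            cand = np.column_stack([cur, x_fit[:, j]])
            if np.linalg.matrix_rank(cand) > cur.shape[1]:
                keep.append(j)
                cur = cand
        dropped = [regressors.columns[j - 1] for j in range(1, x_fit.shape[1]) if j not in keep]
        warnings.warn(
            f"rank-deficient design; dropped collinear column(s) {dropped}",
            RuntimeWarning, stacklevel=2,
        )
    b = _lstsq_coefs(x_fit[:, keep], features.loc[fit_subjects].to_numpy(float))
    x_all = np.column_stack(
        [np.ones(len(features)), regressors.loc[features.index].to_numpy(float)]
    )[:, keep]
    resid = features.to_numpy(float) - x_all @ b
    return pd.DataFrame(resid, index=features.index, columns=features.columns)
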