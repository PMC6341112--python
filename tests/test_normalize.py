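"""Two-step covariate normalization: exact fits, averaging, leakage guard."""

import numpy as np
import pandas as pd
import pytest

from sitemorph.normalize import (
    LeakageAudit,
    LeakageError,
    apply_normalization,
    center_test_features,
    fit_apply_between_dataset_adjustment,
    fit_within_dataset_models,
    residualize_site_factor,
)


def _atlas(feature_ids, thickness=()):
    return pd.DataFrame(
        {
            "family": "surfacelike",
            "measure": ["thickness" if f in thickness else "volume" for f in feature_ids],
            "laterality": "none",
            "is_global": False,
            "is_ventricle": False,
            "mean_size": 10.0,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )


def _phenotypes(n_per_cohort, cohorts, seed=0, vendors=None, fields=None):
    rng = np.random.default_rng(seed)
    rows = []
    for ci, cid in enumerate(cohorts):
        for i in range(n_per_cohort):
            rows.append(dict(
                subject_id=f"{cid}_s{i:03d}",
                diagnosis="case" if i % 2 == 0 else "control",
                disorder_label="SZ-like" if i % 2 == 0 else "none",
                cohort_id=cid,
                age=float(rng.uniform(20, 60)),
                sex="M" if rng.random() < 0.5 else "F",
                icv=float(rng.normal(1450, 100)),
                scanner_vendor=(vendors or {}).get(cid, "vendorA"),
                field_strength=(fields or {}).get(cid, "3T"),
            ))
    return pd.DataFrame(rows).set_index("subject_id")


def test_noiseless_linear_feature_is_fit_exactly():
    ph = _phenotypes(40, ["C01"], seed=1)
    feats = pd.DataFrame({"f1": 2.0 * ph["age"].to_numpy()}, index=ph.index)
    model = fit_within_dataset_models(feats, ph, ["C01"], _atlas(["f1"]))
    assert model.coef.loc["f1", "age"] == pytest.approx(2.0, abs=1e-8)
    out = apply_normalization(model, feats, ph, add_icv=False)
    assert np.allclose(out["f1"], 0.0, atol=1e-8)


def test_coefficients_average_across_cohorts():
    # three cohorts with noiseless age slopes 1, 2, 3 -> averaged slope 2
    ph = _phenotypes(30, ["C01", "C02", "C03"], seed=2)
    slope = {"C01": 1.0, "C02": 2.0, "C03": 3.0}
    y = np.concatenate([
        slope[c] * ph.loc[ph["cohort_id"] == c, "age"].to_numpy()
        for c in ["C01", "C02", "C03"]
    ])
    feats = pd.DataFrame({"f1": y}, index=ph.index)
    model = fit_within_dataset_models(feats, ph, ["C01", "C02", "C03"], _atlas(["f1"]))
    assert model.coef.loc["f1", "age"] == pytest.approx(2.0, abs=1e-8)


def test_identical_cohorts_average_is_idempotent():
    ph = _phenotypes(30, ["C01", "C02"], seed=3)
    ph.loc[ph["cohort_id"] == "C02", ["age", "sex", "icv"]] = (
        ph.loc[ph["cohort_id"] == "C01", ["age", "sex", "icv"]].to_numpy()
    )
    rng = np.random.default_rng(0)
    vals = rng.normal(size=30)
    feats = pd.DataFrame({"f1": np.concatenate([vals, vals])}, index=ph.index)
    two = fit_within_dataset_models(feats, ph, ["C01", "C02"], _atlas(["f1"]))
    one = fit_within_dataset_models(
        feats.iloc[:30], ph.iloc[:30], ["C01"], _atlas(["f1"])
    )
    assert np.allclose(
        two.coef.fillna(0).to_numpy(), one.coef.fillna(0).to_numpy(), atol=1e-8
    )


def test_training_residuals_orthogonal_to_covariates_single_cohort():
    ph = _phenotypes(60, ["C01"], seed=4)
    rng = np.random.default_rng(1)
    feats = pd.DataFrame(rng.normal(size=(60, 3)), index=ph.index,
                         columns=["f1", "f2", "f3"])
    model = fit_within_dataset_models(feats, ph, ["C01"], _atlas(["f1", "f2", "f3"]))
    out = apply_normalization(model, feats, ph, add_icv=False)
    a = ph["age"].to_numpy() - model.age_center
    covs = {"age": a, "age2": a**2, "sex": (ph["sex"] == "M").to_numpy(float),
            "icv": ph["icv"].to_numpy()}
    for col in out.columns:
        assert abs(out[col].mean()) < 1e-10
        for cov in covs.values():
            r = np.corrcoef(out[col], cov)[0, 1]
            assert abs(r) < 1e-10


def test_thickness_features_carry_no_icv_coefficient():
    ph = _phenotypes(40, ["C01"], seed=5)
    rng = np.random.default_rng(2)
    feats = pd.DataFrame(rng.normal(size=(40, 2)), index=ph.index,
                         columns=["thick", "vol"])
    model = fit_within_dataset_models(
        feats, ph, ["C01"], _atlas(["thick", "vol"], thickness=("thick",))
    )
    assert np.isnan(model.coef.loc["thick", "icv"])
    assert np.isfinite(model.coef.loc["vol", "icv"])
    payload = model.to_dict()
    assert "icv" not in payload["coefficients"]["thick"]
    assert "icv" in payload["coefficients"]["vol"]


def test_identity_model_appends_icv_only():
    ph = _phenotypes(20, ["C01"], seed=6)
    feats = pd.DataFrame({"f1": np.arange(20.0)}, index=ph.index)
    model = fit_within_dataset_models(feats, ph, ["C01"], _atlas(["f1"]))
    model.coef.loc[:, :] = 0.0
    out = apply_normalization(model, feats, ph)
    assert np.allclose(out["f1"], feats["f1"])
    assert list(out.columns) == ["f1", "icv"]
    assert np.allclose(out["icv"], ph["icv"])


def test_held_out_cohort_with_shifted_means_keeps_nonzero_residuals():
    ph = _phenotypes(50, ["C01", "C02", "C03"], seed=7)
    rng = np.random.default_rng(3)
    vals = rng.normal(size=150)
    vals[ph["cohort_id"] == "C03"] += 5.0  # site shift in held-out cohort
    feats = pd.DataFrame({"f1": vals}, index=ph.index)
    model = fit_within_dataset_models(feats, ph, ["C01", "C02"], _atlas(["f1"]))
    out = apply_normalization(model, feats, ph, add_icv=False)
    assert abs(out.loc[ph["cohort_id"] == "C03", "f1"].mean()) > 1.0


def test_missing_covariate_rejected_with_subject_named():
    ph = _phenotypes(10, ["C01"], seed=8)
    ph.loc[ph.index[3], "age"] = np.nan
    feats = pd.DataFrame({"f1": np.zeros(10)}, index=ph.index)
    with pytest.raises(ValueError, match=ph.index[3]):
        fit_within_dataset_models(feats, ph, ["C01"], _atlas(["f1"]))


def test_leakage_audit_raises_when_test_subject_enters_fit():
    ph = _phenotypes(20, ["C01", "C02"], seed=9)
    feats = pd.DataFrame({"f1": np.zeros(40)}, index=ph.index)
    test_ids = ph.index[ph["cohort_id"] == "C02"]
    audit = LeakageAudit(forbidden=frozenset(test_ids))
    with pytest.raises(LeakageError):
        fit_within_dataset_models(
            feats, ph, ["C01", "C02"], _atlas(["f1"]), audit=audit
        )
    assert not audit.clean


def test_between_dataset_adjustment_removes_injected_vendor_offset():
    ph = _phenotypes(
        40, ["C01", "C02"], seed=10,
        vendors={"C01": "vendorA", "C02": "vendorB"},
    )
    rng = np.random.default_rng(4)
    vals = rng.normal(size=80)
    vals[(ph["scanner_vendor"] == "vendorB").to_numpy()] += 5.0
    feats = pd.DataFrame({"f1": vals}, index=ph.index)
    out, _ = fit_apply_between_dataset_adjustment(feats, ph, ["C01", "C02"])
    means = out.groupby(ph["scanner_vendor"].to_numpy())["f1"].mean()
    assert abs(means["vendorA"] - means["vendorB"]) < 1e-8


def test_single_vendor_training_only_removes_intercept():
    ph = _phenotypes(30, ["C01"], seed=11)
    feats = pd.DataFrame({"f1": np.arange(30.0)}, index=ph.index)
    out, _ = fit_apply_between_dataset_adjustment(feats, ph, ["C01"])
    assert np.allclose(out["f1"], feats["f1"] - feats["f1"].mean())


def test_unseen_test_vendor_warns_and_uses_reference():
    ph = _phenotypes(
        30, ["C01", "C02", "C03"], seed=12,
        vendors={"C01": "vendorA", "C02": "vendorB", "C03": "vendorC"},
    )
    feats = pd.DataFrame({"f1": np.zeros(90)}, index=ph.index)
    with pytest.warns(RuntimeWarning, match="reference"):
        fit_apply_between_dataset_adjustment(feats, ph, ["C01", "C02"])


def test_center_test_features_exact_and_idempotent():
    ph = _phenotypes(20, ["C01", "C02"], seed=13)
    rng = np.random.default_rng(5)
    feats = pd.DataFrame(rng.normal(3.0, 1.0, size=(40, 2)), index=ph.index,
                         columns=["f1", "f2"])
    out = center_test_features(feats, ph, "C02")
    test = ph["cohort_id"] == "C02"
    assert np.allclose(out.loc[test.to_numpy()].mean(), 0.0, atol=1e-12)
    # training untouched
    assert np.allclose(out.loc[~test.to_numpy()], feats.loc[~test.to_numpy()])
    again = center_test_features(out, ph, "C02")
    assert np.allclose(again.to_numpy(), out.to_numpy(), atol=1e-12)
    # constant feature in the test cohort becomes exactly zero
    const = feats.copy()
    const.loc[test.to_numpy(), "f1"] = 7.0
    assert np.allclose(
        center_test_features(const, ph, "C02").loc[test.to_numpy(), "f1"], 0.0
    )


def test_site_factor_residualization_equalizes_site_means():
    ph = _phenotypes(
        40, ["C01", "C02"], seed=14,
        vendors={"C01": "vendorA", "C02": "vendorB"},
    )
    rng = np.random.default_rng(6)
    vals = rng.normal(size=80)
    vals[(ph["cohort_id"] == "C02").to_numpy()] += 3.0
    feats = pd.DataFrame({"f1": vals}, index=ph.index)
    with pytest.warns(RuntimeWarning, match="aliased"):
        out = residualize_site_factor(feats, ph)
    means = out.groupby(ph["cohort_id"].to_numpy())["f1"].mean()
    assert np.allclose(means.to_numpy(), 0.0, atol=1e-8)
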