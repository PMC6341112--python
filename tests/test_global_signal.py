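"""Global feature assembly, residualization and explained variance."""

import numpy as np
import pandas as pd
import pytest

from sitemorph.atlas import FAMILY_DENSITY, FAMILY_MEDIAN, FAMILY_SURFACE, VENTRICLE_MEDIAN
from sitemorph.global_signal import (
    assemble_global_features,
    explained_variance_size_correlation,
    oob_explained_variance,
    residualize_against_globals,
    top_feature_pc_global_association,
)
from sitemorph.normalize import apply_normalization, fit_within_dataset_models


@pytest.fixture(scope="module")
def normalized_study(small_study):
    cfg, atlas, feats, ph, truth = small_study
    cohorts = ["C01", "C02", "C03", "C04"]
    sub = ph["cohort_id"].isin(cohorts)
    m1 = fit_within_dataset_models(feats[sub.to_numpy()], ph, cohorts, atlas)
    normd = apply_normalization(m1, feats[sub.to_numpy()], ph)
    return atlas, normd, ph.loc[normd.index], truth


class TestAssembly:
    def test_assembles_22_members(self, normalized_study):
        atlas, normd, ph, _ = normalized_study
        g = assemble_global_features(normd, atlas, FAMILY_DENSITY)
        assert g.shape[1] == 22
        assert VENTRICLE_MEDIAN in g.columns and FAMILY_MEDIAN in g.columns
        assert "icv" in g.columns

    def test_modes_differ_only_in_family_median(self, normalized_study):
        atlas, normd, ph, _ = normalized_study
        gd = assemble_global_features(normd, atlas, FAMILY_DENSITY)
        gs = assemble_global_features(normd, atlas, FAMILY_SURFACE)
        assert list(gd.columns) == list(gs.columns)
        same = [c for c in gd.columns if c != FAMILY_MEDIAN]
        assert np.allclose(gd[same].to_numpy(), gs[same].to_numpy())
        assert not np.allclose(gd[FAMILY_MEDIAN], gs[FAMILY_MEDIAN])

    def test_constant_rows_give_that_value_as_family_median(self, normalized_study):
        atlas, normd, _, _ = normalized_study
        const = normd.copy()
        regional = [c for c in const.columns
                    if c in atlas.index and not atlas.loc[c, "is_global"]]
        const.loc[:, regional] = 3.5
        g = assemble_global_features(const, atlas, FAMILY_DENSITY)
        assert np.allclose(g[FAMILY_MEDIAN], 3.5)

    def test_missing_ventricles_rejected(self, normalized_study):
        atlas, normd, _, _ = normalized_study
        vents = atlas.index[atlas["is_ventricle"]]
        with pytest.raises(ValueError, match="global feature"):
            assemble_global_features(normd.drop(columns=list(vents)), atlas,
                                     FAMILY_DENSITY)

    def test_single_ventricle_median_equals_it(self, normalized_study):
        atlas, normd, _, _ = normalized_study
        vents = [f for f in atlas.index[atlas["is_ventricle"]] if f in normd.columns]
        solo = atlas.copy()
        solo.loc[vents[1:], "is_ventricle"] = False
        g = assemble_global_features(normd, solo, FAMILY_DENSITY)
        assert np.allclose(g[VENTRICLE_MEDIAN], normd[vents[0]])


class TestResidualization:
    def test_exact_linear_combination_has_zero_residual(self, normalized_study):
        atlas, normd, _, _ = normalized_study
        g = assemble_global_features(normd, atlas, FAMILY_DENSITY)
        target = normd.copy()
        target["combo"] = g.iloc[:, 0] * 2.0 - g.iloc[:, 3] + 1.0
        resid = residualize_against_globals(target[["combo"]], g)
        assert np.abs(resid["combo"]).max() < 1e-8

    def test_orthogonal_feature_is_preserved(self, normalized_study):
        atlas, normd, _, _ = normalized_study
        g = assemble_global_features(normd, atlas, FAMILY_DENSITY)
        rng = np.random.default_rng(0)
        raw = rng.normal(size=len(g))
        # Gram-Schmidt: project out the globals exactly, then residualize
        x = np.column_stack([np.ones(len(g)), g.to_numpy()])
        beta, *_ = np.linalg.lstsq(x, raw, rcond=None)
        ortho = raw - x @ beta
        tab = pd.DataFrame({"ortho": ortho}, index=g.index)
        resid = residualize_against_globals(tab, g)
        assert np.allclose(resid["ortho"], ortho, atol=1e-8)

    def test_training_only_fit_leaves_test_residual_means_free(self, normalized_study):
        atlas, normd, ph, _ = normalized_study
        g = assemble_global_features(normd, atlas, FAMILY_DENSITY)
        train = normd.index[(ph["cohort_id"] != "C04").to_numpy()]
        test = normd.index[(ph["cohort_id"] == "C04").to_numpy()]
        resid = residualize_against_globals(normd, g, fit_subjects=train)
        train_means = resid.loc[train].mean()
        # training residual means vanish (OLS with intercept); test means not
        assert np.abs(train_means).max() < 1e-8
        assert np.abs(resid.loc[test].mean()).max() > 1e-6

    def test_training_residuals_orthogonal_to_each_global(self, normalized_study):
        atlas, normd, _, _ = normalized_study
        g = assemble_global_features(normd, atlas, FAMILY_DENSITY)
        resid = residualize_against_globals(normd, g)
        # regional columns only: global members have exactly-zero residuals
        sample = [c for c in resid.columns
                  if c in atlas.index and not atlas.loc[c, "is_global"]][:10]
        for col in sample:
            for gcol in g.columns:
                r = np.corrcoef(resid[col], g[gcol])[0, 1]
                assert abs(r) < 1e-10

    def test_collinear_global_columns_dropped_with_warning(self, normalized_study):
        atlas, normd, _, _ = normalized_study
        g = assemble_global_features(normd, atlas, FAMILY_DENSITY)
        g2 = g.copy()
        g2["dup"] = g.iloc[:, 0] * 2.0
        with pytest.warns(RuntimeWarning, match="collinear"):
            resid = residualize_against_globals(normd.iloc[:, :3], g2)
        assert resid.shape == normd.iloc[:, :3].shape


class TestExplainedVariance:
    def test_deterministic_function_of_one_global_is_recovered(self):
        rng = np.random.default_rng(3)
        n = 1200
        G = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=[f"g{i}" for i in range(6)])
        feat = pd.DataFrame({"det": 2.0 * G["g2"].to_numpy()})
        r2 = oob_explained_variance(feat, G, n_trees=200, seed=0)
        assert r2["det"] >= 0.9

    def test_independent_feature_has_near_zero_r2(self):
        rng = np.random.default_rng(4)
        n = 800
        G = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=[f"g{i}" for i in range(6)])
        feat = pd.DataFrame({"noise": rng.normal(size=n)})
        r2 = oob_explained_variance(feat, G, n_trees=200, seed=0)
        assert r2["noise"] <= 0.05

    def test_zero_variance_feature_signalled(self):
        G = pd.DataFrame(np.random.default_rng(5).normal(size=(50, 3)),
                         columns=["g0", "g1", "g2"])
        feat = pd.DataFrame({"const": np.ones(50)})
        with pytest.warns(RuntimeWarning, match="zero variance"):
            r2 = oob_explained_variance(feat, G, n_trees=20, seed=0)
        assert np.isnan(r2["const"])

    def test_size_correlation_sign_follows_loadings(self, small_study):
        cfg, atlas, feats, ph, truth = small_study
        # loadings scale with mean size, so larger structures carry more
        # global signal: explained variance should rank with size
        fake_r2 = pd.Series(
            truth.loadings.abs().sum(axis=1) ** 2, index=truth.loadings.index
        )
        rho, p = explained_variance_size_correlation(fake_r2, atlas)
        assert rho > 0.5

    def test_constant_r2_vector_rejected(self, small_study):
        _, atlas, _, _, truth = small_study
        const = pd.Series(0.3, index=truth.loadings.index)
        with pytest.raises(ValueError, match="constant"):
            explained_variance_size_correlation(const, atlas)

    def test_fewer_than_three_features_rejected(self, small_study):
        _, atlas, _, _, _ = small_study
        two = pd.Series([0.1, 0.5], index=atlas.index[:2])
        with pytest.raises(ValueError, match="at least 3"):
            explained_variance_size_correlation(two, atlas)


class TestPcAssociation:
    def test_shared_factors_give_correlated_pc1s(self, normalized_study):
        atlas, normd, ph, truth = normalized_study
        g = assemble_global_features(normd, atlas, FAMILY_DENSITY)
        dens = [f for f in truth.loadings.abs().sum(axis=1).sort_values().index
                if f in normd.columns and atlas.loc[f, "family"] == FAMILY_DENSITY][-8:]
        surf = [f for f in truth.loadings.abs().sum(axis=1).sort_values().index
                if f in normd.columns and atlas.loc[f, "family"] == FAMILY_SURFACE][-8:]
        rep = top_feature_pc_global_association(dens, surf, normd, g, ph)
        assert rep["pc1_correlation"] > 0.3
        assert 0 < rep["pc1_var_explained_density"] <= 1
        # PC1s should correlate with at least one global feature strongly
        rs = [v["r"] for v in rep["global_associations"].values()]
        assert max(np.abs(rs)) > 0.5

    def test_pc1_variance_equals_leading_eigenvalue(self, normalized_study):
        atlas, normd, ph, _ = normalized_study
        g = assemble_global_features(normd, atlas, FAMILY_DENSITY)
        cols = list(normd.columns[:6])
        rep = top_feature_pc_global_association(cols, cols, normd, g, ph)
        diag = pd.DataFrame({"case": (ph["diagnosis"] == "case").astype(float)})
        from sitemorph.normalize import residualize_against

        adj = residualize_against(normd[cols], diag.loc[normd.index])
        z = (adj - adj.mean()) / adj.std(ddof=0)
        eigvals = np.linalg.eigvalsh(np.corrcoef(z.to_numpy().T))
        assert rep["pc1_var_explained_density"] == pytest.approx(
            eigvals[-1] / len(cols), abs=1e-6
        )

    def test_empty_top_set_rejected(self, normalized_study):
        atlas, normd, ph, _ = normalized_study
        g = assemble_global_features(normd, atlas, FAMILY_DENSITY)
        with pytest.raises(ValueError, match="non-empty"):
            top_feature_pc_global_association([], ["icv"], normd, g, ph)
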