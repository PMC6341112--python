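"""Site-stratified forest contract, ROC-AUC and cutoff metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitemorph.forest import DEFAULT_N_TREES, forest_predict, train_site_stratified_forest
from sitemorph.metrics import mean_sens_spec, roc_auc

from conftest import brute_force_auc


def _toy(n_per_site=20, n_sites=2, p=5, separation=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = n_per_site * n_sites
    y = np.tile([0, 1], n // 2)
    x = rng.normal(size=(n, p))
    x[:, 0] += separation * y
    sites = np.repeat([f"S{i}" for i in range(n_sites)], n_per_site)
    return pd.DataFrame(x, columns=[f"f{i}" for i in range(p)]), y, sites


class TestRocAuc:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 100))
        labels = np.zeros(n, dtype=int)
        labels[: max(1, int(rng.integers(1, n)))] = 1
        rng.shuffle(labels)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        # coarse grid of scores forces ties
        scores = rng.integers(0, 6, size=n) / 5.0
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_perfect_ranking_and_all_ties(self):
        assert roc_auc([0.9, 0.1], ["case", "control"]) == 1.0
        assert roc_auc([0.4] * 10, [1, 0] * 5) == 0.5

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) + roc_auc(scores, 1 - labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestMeanSensSpec:
    def test_perfect_separation(self):
        sens, spec, mean = mean_sens_spec([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert (sens, spec, mean) == (1.0, 1.0, 1.0)

    def test_shifted_scores_degenerate_to_half(self):
        # every score above cutoff: sens 1, spec 0 even though AUC may be high
        sens, spec, mean = mean_sens_spec([0.6, 0.6, 0.6, 0.6], [1, 1, 0, 0])
        assert (sens, spec, mean) == (1.0, 0.0, 0.5)

    def test_absent_class_signalled_as_nan(self):
        sens, spec, mean = mean_sens_spec([0.9, 0.8], [1, 1], 0.5)
        assert sens == 1.0 and np.isnan(spec) and np.isnan(mean)


class TestForest:
    def test_defaults_expose_paper_contract(self):
        x, y, sites = _toy(n_per_site=10, p=9, seed=2)
        model = train_site_stratified_forest(x, y, sites, n_trees=20)
        assert DEFAULT_N_TREES == 5000
        assert model.mtry == 3  # floor(sqrt(9))

    def test_every_bag_has_exactly_s_subjects_per_site(self):
        x, y, sites = _toy(n_per_site=14, n_sites=3, seed=3)
        model = train_site_stratified_forest(x, y, sites, n_trees=60, seed=1)
        site_codes = pd.Series(sites)
        for bag in model.bags:
            counts = site_codes.iloc[bag].value_counts()
            assert set(counts) == {model.s}
            assert len(bag) == len(set(bag))  # drawn without replacement

    def test_strict_bag_uses_smallest_site_size(self):
        x, y, sites = _toy(n_per_site=10, n_sites=2, seed=4)
        strict = train_site_stratified_forest(x, y, sites, n_trees=10, strict_bag=True)
        assert strict.s == 10
        # every subject is always in-bag: OOB undefined for all
        assert (strict.oob_counts_ == 0).all()
        default = train_site_stratified_forest(x, y, sites, n_trees=50)
        assert default.s == int(np.ceil(0.632 * 10))
        assert (default.oob_counts_ > 0).all()

    def test_site_smaller_than_s_rejected(self):
        x, y, sites = _toy(n_per_site=10, n_sites=2, seed=5)
        with pytest.raises(ValueError, match="fewer than s"):
            train_site_stratified_forest(x, y, sites, n_trees=5, s=11)

    def test_reproducible_under_fixed_seed(self):
        x, y, sites = _toy(separation=1.0, seed=6)
        m1 = train_site_stratified_forest(x, y, sites, n_trees=40, seed=9)
        m2 = train_site_stratified_forest(x, y, sites, n_trees=40, seed=9)
        assert np.array_equal(m1.oob_scores_, m2.oob_scores_, equal_nan=True)
        assert np.allclose(m1.importances_, m2.importances_)

    def test_separable_feature_gives_perfect_oob_auc(self):
        x, y, sites = _toy(separation=8.0, seed=7)
        model = train_site_stratified_forest(x, y, sites, n_trees=100, seed=0)
        ok = model.oob_counts_ > 0
        assert roc_auc(model.oob_scores_[ok], y[ok]) == 1.0
        assert np.argmax(model.importances_) == 0

    def test_training_duplicate_scores_as_case_on_separable_data(self):
        x, y, sites = _toy(separation=8.0, seed=8)
        model = train_site_stratified_forest(x, y, sites, n_trees=100, seed=0)
        case_row = x[y == 1].iloc[[0]]
        assert forest_predict(model, case_row)[0] > 0.5

    def test_in_bag_votes_differ_from_oob_scores(self):
        x, y, sites = _toy(separation=1.0, seed=9)
        model = train_site_stratified_forest(x, y, sites, n_trees=100, seed=0)
        full_vote = forest_predict(model, x)
        ok = model.oob_counts_ > 0
        # full-tree votes are optimistic relative to OOB votes
        assert not np.allclose(full_vote[ok], model.oob_scores_[ok])

    def test_constant_test_features_get_identical_scores(self):
        x, y, sites = _toy(seed=10)
        model = train_site_stratified_forest(x, y, sites, n_trees=30, seed=0)
        const = pd.DataFrame(
            np.ones((5, x.shape[1])), columns=x.columns
        )
        scores = forest_predict(model, const)
        assert len(set(scores.tolist())) == 1

    def test_missing_feature_column_rejected(self):
        x, y, sites = _toy(seed=11)
        model = train_site_stratified_forest(x, y, sites, n_trees=10, seed=0)
        with pytest.raises(ValueError, match="missing feature"):
            forest_predict(model, x.drop(columns=["f0"]))

    def test_null_features_give_chance_level_oob_auc(self):
        aucs = []
        for seed in range(5):
            x, y, sites = _toy(n_per_site=50, n_sites=2, p=20, seed=100 + seed)
            model = train_site_stratified_forest(x, y, sites, n_trees=100, seed=seed)
            ok = model.oob_counts_ > 0
            aucs.append(roc_auc(model.oob_scores_[ok], y[ok]))
        assert 0.42 < np.mean(aucs) < 0.58
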