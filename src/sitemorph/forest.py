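"""Site-stratified random-forest classifier with out-of-bag scoring.

Each tree is grown on a bag containing exactly ``s`` subjects drawn without
replacement from every training site, so no site dominates any tree.  Trees
are unpruned Gini-split CARTs with ``mtry = floor(sqrt(p))`` candidate
features per split.  A subject's out-of-bag (OOB) score is the fraction of
trees whose bag excluded it that vote "case"; feature importance is the mean
unnormalised Gini (impurity) decrease across trees.

The literal stratification rule (``s`` equal to the size of the smallest
training site) leaves that site's subjects in-bag for every tree, so their
OOB scores are undefined.  The default therefore draws ``s = ceil(0.632 *
n_min)`` subjects per site — the in-bag fraction of a classical bootstrap —
keeping OOB scores defined everywhere; ``strict_bag=True`` restores the
literal rule and excludes always-in-bag subjects from OOB metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

DEFAULT_N_TREES = 5000


@dataclass
class ForestModel:
    """Trained ensemble: trees, bags, OOB scores and Gini importance."""

    n_trees: int
    s: int
    mtry: int
    cutoff: float
    feature_names: list[str]
    classes_: np.ndarray
    trees: list = field(default_factory=list, repr=False)
    bags: list = field(default_factory=list, repr=False)
    oob_scores_: np.ndarray | None = None     # per training subject, NaN if never OOB
    oob_counts_: np.ndarray | None = None
    importances_: np.ndarray | None = None    # mean Gini decrease per feature
    subject_ids: list[str] | None = None

    @property
    def importance_series(self) -> pd.Series:
        return pd.Series(self.importances_, index=self.feature_names)

    def oob_error(self) -> float:
        """Misclassification rate of OOB votes at the score cutoff."""
        ok = self.oob_counts_ > 0
        pred = (self.oob_scores_[ok] > self.cutoff).astype(int)
        return float(np.mean(pred != self._y[ok]))

    def predict_score(self, features) -> np.ndarray:
        """Fraction of all trees voting case, for new subjects."""
        if isinstance(features, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in features.columns]
            if missing:
                raise ValueError(f"missing feature column(s) {missing[:5]}")
            x = features[self.feature_names].to_numpy(float)
        else:
            x = np.asarray(features, dtype=float)
            if x.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} feature columns, got {x.shape[1]}"
                )
        if not self.trees:
            raise RuntimeError("model was trained without stored trees")
        votes = np.zeros(len(x))
        for tree in self.trees:
            votes += tree.predict(x)
        return votes / len(self.trees)


def _resolve_s(site_sizes: np.ndarray, s: int | None, strict_bag: bool) -> int:
    n_min = int(site_sizes.min())
    if s is None:
        s = n_min if strict_bag else math.ceil(0.632 * n_min)
    if s < 1:
        raise ValueError("per-site draw size s must be >= 1")
    if (site_sizes < s).any():
        raise ValueError(
            f"a training site has fewer than s={s} subjects "
            f"(smallest site n={n_min}); reduce s or drop the site"
        )
    return int(s)


def train_site_stratified_forest(
    features,
    labels,
    sites,
    n_trees: int = DEFAULT_N_TREES,
    s: int | None = None,
    strict_bag: bool = False,
    mtry: int | None = None,
    cutoff: float = 0.5,
    seed: int = 0,
    store_trees: bool = True,
    importance_only: bool = False,
) -> ForestModel:
    """Train the site-stratified ensemble.

    ``features`` may be a DataFrame (column names are kept for prediction-time
    validation) or an array.  ``labels`` are case(1)/control(0); strings
    ``case``/``control`` are accepted.  ``importance_only`` skips OOB
    bookkeeping and tree storage (used inside permutation nulls).
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        subject_ids = list(features.index)
        x = features.to_numpy(float)
    else:
        x = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(x.shape[1])]
        subject_ids = None
    y = np.asarray(
        [1 if v in (1, "case", True) else 0 for v in np.asarray(labels).ravel()],
        dtype=int,
    )
    sites = np.asarray(sites)
    n, p = x.shape
    if len(y) != n or len(sites) != n:
        raise ValueError("features, labels and sites must align")
    uniq, site_codes = np.unique(sites, return_inverse=True)
    site_sizes = np.bincount(site_codes)
    if (site_sizes < 2).any():
        raise ValueError("every training site needs at least 2 subjects")
    s_eff = _resolve_s(site_sizes, s, strict_bag)
    mtry_eff = int(mtry) if mtry else max(1, int(math.isqrt(p)))

    site_members = [np.flatnonzero(site_codes == k) for k in range(len(uniq))]
    rng = np.random.default_rng(seed)
    tree_seeds = rng.integers(0, 2**31 - 1, size=n_trees)

    votes = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    importances = np.zeros(p)
    trees: list = []
    bags: list = []
    oob_mask = np.empty(n, dtype=bool)
    for t in range(n_trees):
        bag = np.concatenate(
            [members[rng.permutation(len(members))[:s_eff]] for members in site_members]
        )
        tree = DecisionTreeClassifier(
            criterion="gini", max_features=mtry_eff, random_state=int(tree_seeds[t])
        )
        tree.fit(x[bag], y[bag])
        importances += tree.tree_.compute_feature_importances(normalize=False)
        if not importance_only:
            oob_mask.fill(True)
            oob_mask[bag] = False
            if oob_mask.any():
                pred = tree.predict(x[oob_mask])
                if tree.n_classes_ == 2:
                    votes[oob_mask] += pred
                else:  # single-class bag: tree predicts that class everywhere
                    votes[oob_mask] += pred
                counts[oob_mask] += 1
            bags.append(bag)
            if store_trees:
                trees.append(tree)

    model = ForestModel(
        n_trees=n_trees,
        s=s_eff,
        mtry=mtry_eff,
        cutoff=cutoff,
        feature_names=names,
        classes_=np.array([0, 1]),
        trees=trees,
        bags=bags,
        importances_=importances / n_trees,
        subject_ids=subject_ids,
    )
    model._y = y
    if not importance_only:
        with np.errstate(invalid="ignore"):
            model.oob_scores_ = np.where(counts > 0, votes / np.maximum(counts, 1), np.nan)
        model.oob_counts_ = counts
    return model


def forest_predict(model: ForestModel, features) -> np.ndarray:
    """Per-subject case score: fraction of all trees voting case."""
    return model.predict_score(features)
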