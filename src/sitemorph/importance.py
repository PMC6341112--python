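"""Feature-importance analyses on the site-stratified forest.

* Backward variable selection under the minimum-error-plus-one-SD rule:
  repeatedly drop the least important fraction of features, track the
  out-of-bag error, and return the smallest set whose error is within one
  binomial standard error of the minimum.
* Cross-disorder importance-overlap: a one-sided rank-sum permutation test of
  whether the top-m features of one classification task are also unusually
  important in another task's forest.
* Cross-cohort importance similarity: median pairwise Pearson correlation of
  importance profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .forest import train_site_stratified_forest


@dataclass
class ImportanceProfile:
    """Per-feature mean Gini decrease with a deterministic ranking."""

    importances: pd.Series
    source: str = ""

    @property
    def ranking(self) -> list[str]:
        # importance descending, ties broken by feature id
        order = sorted(
            self.importances.index, key=lambda f: (-self.importances[f], f)
        )
        return order

    def top(self, m: int) -> list[str]:
        return self.ranking[:m]


@dataclass
class SelectionResult:
    selected: list[str]
    m: int
    path: list[tuple[int, float]]          # (set size, OOB error) per round
    feature_sets: list[list[str]] = field(default_factory=list, repr=False)
    min_error: float = float("nan")
    threshold: float = float("nan")


def backward_feature_elimination(
    features: pd.DataFrame,
    labels,
    sites,
    drop_fraction: float = 0.2,
    n_trees: int = 500,
    s: int | None = None,
    strict_bag: bool = False,
    seed: int = 0,
    min_features: int = 2,
) -> SelectionResult:
    """Backward elimination with the min-error + 1 SD selection rule.

    Each round refits the forest, records the OOB misclassification rate and
    removes the lowest-importance ``drop_fraction`` of remaining features.
    The returned set is the smallest visited set whose OOB error does not
    exceed the minimum observed error plus one binomial standard error of
    that minimum.
    """
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in (0, 1)")
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features to eliminate")
    rng = np.random.default_rng(seed)
    current = list(features.columns)
    path: list[tuple[int, float]] = []
    sets: list[list[str]] = []
    n = len(features)
    while True:
        model = train_site_stratified_forest(
            features[current], labels, sites,
            n_trees=n_trees, s=s, strict_bag=strict_bag,
            seed=int(rng.integers(2**31 - 1)), store_trees=False,
        )
        path.append((len(current), model.oob_error()))
        sets.append(list(current))
        if len(current) <= min_features:
            break
        imp = ImportanceProfile(model.importance_series)
        n_keep = max(min_features, len(current) - max(1, math.floor(drop_fraction * len(current))))
        current = sorted(imp.ranking[:n_keep])

    errors = np.array([e for _, e in path])
    min_err = float(errors.min())
    se = math.sqrt(min_err * (1 - min_err) / n)
    threshold = min_err + se
    admissible = [i for i, e in enumerate(errors) if e <= threshold]
    best = max(admissible, key=lambda i: (i, -path[i][0]))  # smallest set = latest round
    selected = sets[best]
    return SelectionResult(
        selected=selected,
        m=len(selected),
        path=path,
        feature_sets=sets,
        min_error=min_err,
        threshold=threshold,
    )


@dataclass
class PermutationResult:
    observed_statistic: float
    null_draws: np.ndarray
    empirical_p: float
    B: int
    m: int

    def p_display(self) -> str:
        return f"<{1 / self.B:g}" if self.empirical_p == 0 else f"{self.empirical_p:g}"

    def to_dict(self) -> dict:
        return {
            "observed_statistic": float(self.observed_statistic),
            "empirical_p": float(self.empirical_p),
            "p_display": self.p_display(),
            "B": self.B,
            "m": self.m,
            "null_draws": [float(v) for v in self.null_draws],
        }


def rank_sum_statistic(importances: pd.Series, top_set: list[str]) -> float:
    """Rank-sum of the top-set importances among all features (ties: midranks).

    Larger values mean the top set is more important in this task.
    """
    ranks = rankdata(importances.to_numpy())
    mask = importances.index.isin(top_set)
    return float(ranks[mask].sum())


def importance_overlap_test(
    top_set: list[str],
    other_features: pd.DataFrame,
    other_labels,
    other_sites,
    B: int = 5000,
    n_trees: int = 500,
    n_trees_perm: int | None = 500,
    s: int | None = None,
    seed: int = 0,
) -> PermutationResult:
    """Are one task's top features unusually important in another task?

    The observed statistic is the rank-sum of the other task's importances
    over ``top_set`` versus the remaining features.  The null re-trains the
    other task's forest under within-site label permutation and recomputes
    the statistic; ``empirical_p`` is the frequency of null statistics at
    least as high as the observed one (#null >= obs, divided by B).
    Permutation forests may use a reduced tree count for tractability
    (``n_trees_perm``; pass None for strict parity with ``n_trees``).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    top_set = list(top_set)
    feature_set = set(other_features.columns)
    if not top_set or not set(top_set) < feature_set:
        raise ValueError("top_set must be a non-empty proper subset of the feature set")
    y = np.asarray(
        [1 if v in (1, "case", True) else 0 for v in np.asarray(other_labels).ravel()],
        dtype=int,
    )
    sites = np.asarray(other_sites)
    rng = np.random.default_rng(seed)

    def _importances(labels, ntree, tree_seed):
        model = train_site_stratified_forest(
            other_features, labels, sites, n_trees=ntree, s=s,
            seed=tree_seed, store_trees=False, importance_only=True,
        )
        return model.importance_series

    observed = rank_sum_statistic(
        _importances(y, n_trees, int(rng.integers(2**31 - 1))), top_set
    )
    n_perm_trees = n_trees if n_trees_perm is None else n_trees_perm
    null = np.empty(B)
    site_groups = [np.flatnonzero(sites == u) for u in np.unique(sites)]
    for b in range(B):
        y_perm = y.copy()
        for idx in site_groups:  # permute diagnosis within site
            y_perm[idx] = y[rng.permutation(idx)]
        null[b] = rank_sum_statistic(
            _importances(y_perm, n_perm_trees, int(rng.integers(2**31 - 1))), top_set
        )
    p = float(np.mean(null >= observed))
    return PermutationResult(
        observed_statistic=observed, null_draws=null, empirical_p=p, B=B, m=len(top_set)
    )


def cross_cohort_importance_similarity(profiles: list[ImportanceProfile]) -> float:
    """Median pairwise Pearson correlation of importance profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 importance profiles")
    base = list(profiles[0].importances.index)
    for p in profiles[1:]:
        if list(p.importances.index) != base:
            raise ValueError("importance profiles cover different feature sets")
    mat = np.vstack([p.importances.to_numpy() for p in profiles])
    corr = np.corrcoef(mat)
    iu = np.triu_indices(len(profiles), k=1)
    return float(np.median(corr[iu]))
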