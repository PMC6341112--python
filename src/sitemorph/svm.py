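"""Cost-tuned linear maximum-margin classifier.

The cost parameter is chosen from a log-spaced grid 1e-5..1e5 (11 values) by
10-fold cross-validation on the training data only; decision values serve as
classification scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC


def default_cost_grid() -> np.ndarray:
    return np.logspace(-5, 5, 11)


@dataclass
class LinearSVMModel:
    estimator: SVC
    best_cost: float
    cv_results: dict
    feature_names: list[str]

    def predict_score(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in features.columns]
            if missing:
                raise ValueError(f"missing feature column(s) {missing[:5]}")
            x = features[self.feature_names].to_numpy(float)
        else:
            x = np.asarray(features, dtype=float)
        return self.estimator.decision_function(x)


def train_linear_svm(
    features,
    labels,
    cost_grid=None,
    n_folds: int = 10,
    seed: int = 0,
) -> LinearSVMModel:
    """Fit a linear SVM with CV-tuned cost on training data only."""
    if cost_grid is None:
        cost_grid = default_cost_grid()
    cost_grid = np.asarray(cost_grid, dtype=float)
    if cost_grid.size < 2 or (cost_grid <= 0).any():
        raise ValueError("cost grid must contain >= 2 positive values")
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        x = features.to_numpy(float)
    else:
        x = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(x.shape[1])]
    y = np.asarray(
        [1 if v in (1, "case", True) else 0 for v in np.asarray(labels).ravel()], dtype=int
    )
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n_folds = min(n_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=max(2, n_folds), shuffle=True, random_state=seed)
    # iteration cap: huge-cost fits on non-separable data otherwise spin
    search = GridSearchCV(
        SVC(kernel="linear", max_iter=200_000),
        {"C": list(cost_grid)}, cv=cv, scoring="accuracy", n_jobs=1,
    )
    search.fit(x, y)
    return LinearSVMModel(
        estimator=search.best_estimator_,
        best_cost=float(search.best_params_["C"]),
        cv_results={
            "mean_test_score": search.cv_results_["mean_test_score"].tolist(),
            "costs": cost_grid.tolist(),
        },
        feature_names=names,
    )
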