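"""Shared fixtures: small seeded simulations reused across test modules."""

import warnings

import numpy as np
import pandas as pd
import pytest

from sitemorph.atlas import build_feature_atlas
from sitemorph.simulate import SimulationConfig, simulate_cohorts


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        yield


@pytest.fixture(scope="session")
def small_study():
    """4 training cohorts, scaled atlas, globally mediated case signal."""
    cfg = SimulationConfig(
        n_cohorts=4, n_cases=25, n_controls=25, n_density=20, n_surface=20,
        n_global=22, global_mediation=1.0, regional_effect_d=0.8,
        n_validation_cohorts=2, seed=42,
    )
    atlas = build_feature_atlas(cfg)
    features, phenotypes, truth = simulate_cohorts(cfg, atlas)
    return cfg, atlas, features, phenotypes, truth


@pytest.fixture(scope="session")
def null_study():
    """4 cohorts with no diagnosis effect at all."""
    cfg = SimulationConfig(
        n_cohorts=4, n_cases=20, n_controls=20, n_density=10, n_surface=16,
        n_global=3, regional_effect_d=0.0, adhd_effect_d=0.0, global_mediation=0.0,
        n_validation_cohorts=0, seed=7,
    )
    atlas = build_feature_atlas(cfg)
    features, phenotypes, truth = simulate_cohorts(cfg, atlas)
    return cfg, atlas, features, phenotypes, truth


def brute_force_auc(scores, labels) -> float:
    """Independent oracle: all case-control pairs, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for h in controls:
            if c > h:
                total += 1.0
            elif c == h:
                total += 0.5
    return total / (len(cases) * len(controls))


def brute_force_bh(pvals: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: q_i = min over j>=rank_i of p_(j)*m/j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q
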