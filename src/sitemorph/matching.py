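"""Per-cohort 1:1 propensity-score matching of cases to controls.

A logistic model of case status on age and sex yields per-subject propensity
scores; pairs are formed greedily on the logit scale, processing cases in a
seeded random order, each control used at most once.  Matching is performed
separately within each cohort.  Cohorts can be flagged to skip matching (the
small-cohort rule: fewer controls than cases and no demographic imbalance),
in which case all subjects pass through unmatched.  Controls not selected are
retained (they form validation material downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class MatchedCohort:
    cohort_id: str
    pairs: list[tuple[str, str]] = field(default_factory=list)
    unmatched_controls: list[str] = field(default_factory=list)
    unmatched_cases: list[str] = field(default_factory=list)
    skipped: bool = False
    passthrough: list[str] = field(default_factory=list)  # subjects kept when skipped

    @property
    def matched_subjects(self) -> list[str]:
        if self.skipped:
            return list(self.passthrough)
        return [s for pair in self.pairs for s in pair]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _propensity_logits(age: np.ndarray, male: np.ndarray, case: np.ndarray) -> np.ndarray:
    x = sm.add_constant(np.column_stack([age, male]), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(case.astype(float), x)
        res = model.fit(disp=0, maxiter=100)
    logits = x @ res.params
    if not np.all(np.isfinite(logits)) or np.abs(res.params).max() > 50:
        raise np.linalg.LinAlgError("degenerate propensity model")
    return logits


def propensity_match(
    phenotypes: pd.DataFrame,
    cohort_id: str,
    seed: int = 0,
    skip_matching: bool = False,
) -> MatchedCohort:
    """Match cases 1:1 to controls on age and sex within one cohort.

    Falls back to standardized covariate-distance matching (with a warning)
    when the propensity model degenerates (e.g. perfect separation).
    """
    sub = phenotypes[phenotypes["cohort_id"] == cohort_id]
    if sub.empty:
        raise ValueError(f"cohort {cohort_id!r} not present in phenotype table")
    case_mask = (sub["diagnosis"] == "case").to_numpy()
    if skip_matching:
        return MatchedCohort(cohort_id, skipped=True, passthrough=list(sub.index))
    if case_mask.all() or not case_mask.any():
        raise ValueError(f"cohort {cohort_id!r} lacks cases or controls; cannot match")

    age = sub["age"].to_numpy(dtype=float)
    male = (sub["sex"] == "M").to_numpy(dtype=float)
    try:
        score = _propensity_logits(age, male, case_mask)
        metric = score[:, None]
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn(
            f"degenerate propensity model in cohort {cohort_id}; "
            "falling back to covariate-distance matching",
            RuntimeWarning,
            stacklevel=2,
        )
        a = (age - age.mean()) / (age.std() or 1.0)
        metric = np.column_stack([a, male])

    ids = sub.index.to_numpy()
    case_idx = np.flatnonzero(case_mask)
    ctrl_idx = np.flatnonzero(~case_mask)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_idx))

    available = ctrl_idx.tolist()
    pairs: list[tuple[str, str]] = []
    unmatched_cases: list[str] = []
    for ci in case_idx[order]:
        if not available:
            unmatched_cases.append(ids[ci])
            continue
        dists = np.linalg.norm(metric[available] - metric[ci], axis=1)
        j = int(np.argmin(dists))
        pairs.append((ids[ci], ids[available.pop(j)]))
    return MatchedCohort(
        cohort_id,
        pairs=pairs,
        unmatched_controls=[ids[i] for i in available],
        unmatched_cases=unmatched_cases,
    )


def match_cohorts(
    phenotypes: pd.DataFrame,
    cohort_ids: list[str],
    seed: int = 0,
    skip_matching: set[str] | frozenset[str] = frozenset(),
) -> dict[str, MatchedCohort]:
    """Match each listed cohort independently with per-cohort spawned seeds."""
    seeds = np.random.SeedSequence(seed).spawn(len(cohort_ids))
    out = {}
    for cid, ss in zip(cohort_ids, seeds):
        out[cid] = propensity_match(
            phenotypes, cid, seed=int(ss.generate_state(1)[0] % 2**31),
            skip_matching=cid in skip_matching,
        )
    return out


def matched_subject_ids(matched: dict[str, MatchedCohort]) -> list[str]:
    return [s for mc in matched.values() for s in mc.matched_subjects]


def standardized_mean_difference(x_case: np.ndarray, x_control: np.ndarray) -> float:
    """SMD balance diagnostic: mean difference over pooled SD."""
    v = 0.5 * (np.var(x_case, ddof=1) + np.var(x_control, ddof=1))
    if v == 0:
        return 0.0
    return float((np.mean(x_case) - np.mean(x_control)) / np.sqrt(v))
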