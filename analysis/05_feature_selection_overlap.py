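#!/usr/bin/env python
"""Backward variable selection and cross-disorder importance overlap.

Selects the most important density-family features for the case-control
classification (minimum-error-plus-one-SD rule), then asks whether that top
set is also unusually important for classifying the bipolar-like and the
ADHD-like validation cohorts, via the rank-sum label-permutation test.
Also reports the cross-cohort similarity of within-site importance profiles.
Writes ``results/selection.tsv`` and ``results/importance_overlap.json``.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from sitemorph.atlas import FAMILY_DENSITY
from sitemorph.evaluate import (
    ClassifierSpec,
    run_whole_dataset_oob,
    run_within_site,
    training_cohorts,
)
from sitemorph.forest import train_site_stratified_forest
from sitemorph.importance import (
    ImportanceProfile,
    backward_feature_elimination,
    cross_cohort_importance_similarity,
    importance_overlap_test,
)
from sitemorph.io import load_tables

warnings.filterwarnings("ignore")
SEED = 20260105


def main() -> None:
    d = Path("results/tables")
    features, phenotypes, atlas = load_tables(
        d / "features.tsv", d / "phenotypes.tsv", d / "atlas.tsv"
    )
    _, _, site_corrected, ph_matched = run_whole_dataset_oob(
        features, phenotypes, atlas, spec=ClassifierSpec(n_trees=300, seed=SEED)
    )
    dens = [c for c in site_corrected.columns
            if c in atlas.index and atlas.loc[c, "family"] == FAMILY_DENSITY]
    sel = backward_feature_elimination(
        site_corrected[dens], ph_matched["diagnosis"], ph_matched["cohort_id"],
        n_trees=300, seed=SEED,
    )
    print(f"selected m={sel.m} density features "
          f"(min OOB error {sel.min_error:.3f}, threshold {sel.threshold:.3f})")
    # redundant global signal can select very few features; pad the top set
    # to 10 by pooled importance so the rank-sum comparison is non-degenerate
    pooled = train_site_stratified_forest(
        site_corrected[dens], ph_matched["diagnosis"], ph_matched["cohort_id"],
        n_trees=300, seed=SEED, store_trees=False,
    )
    top_set = list(sel.selected)[:14]
    for f in pooled.importance_series.sort_values(ascending=False).index:
        if len(top_set) >= 10:
            break
        if f not in top_set:
            top_set.append(f)
    pd.DataFrame(sel.path, columns=["n_features", "oob_error"]).to_csv(
        "results/selection.tsv", sep="\t", index=False
    )

    overlap = {}
    for cid, label in (("V02", "bipolar-like"), ("V03", "adult ADHD-like"),
                       ("V04", "adolescent ADHD-like")):
        sub = phenotypes[phenotypes["cohort_id"] == cid]
        res = importance_overlap_test(
            top_set, features.loc[sub.index, dens], sub["diagnosis"],
            sub["cohort_id"], B=200, n_trees=300, n_trees_perm=100, seed=SEED,
        )
        overlap[label] = res.to_dict()
        print(f"importance overlap vs {label}: rank-sum {res.observed_statistic:.0f}, "
              f"empirical p {res.p_display()}")
    Path("results/importance_overlap.json").write_text(
        json.dumps(overlap, indent=2)
    )

    profiles = []
    for cid in training_cohorts(phenotypes):
        res = run_within_site(features, phenotypes, atlas, cid,
                              ClassifierSpec(n_trees=300, seed=SEED),
                              n_label_perms=1)
        profiles.append(ImportanceProfile(
            res.extra["importances"][dens], source=cid
        ))
    sim = cross_cohort_importance_similarity(profiles)
    print(f"median cross-cohort importance correlation (density family): {sim:.3f}")


if __name__ == "__main__":
    main()
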