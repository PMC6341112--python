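"""Seeded end-to-end experiment orchestration with a run manifest.

``run_experiment`` executes the full analysis graph on a simulated
multi-site study: simulate -> match -> normalize (two-step) -> leave-site-out
and whole-dataset classification -> external specificity -> variable
selection and cross-disorder importance overlap -> global-signal
decomposition -> univariate stages.  Every stochastic element is seeded from
one master seed via ``numpy.random.SeedSequence`` spawning, and the manifest
records the config hash, per-stage output digests and the leakage audit, so
identical configs yield identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import global_signal as gs
from .atlas import FAMILY_DENSITY, FAMILY_SURFACE, regional_features
from .evaluate import (
    ClassifierSpec,
    prepare_loso_folds,
    run_external_specificity,
    run_leave_site_out,
    run_whole_dataset_oob,
    run_within_site,
    train_full_classifier,
    training_cohorts,
)
from .importance import backward_feature_elimination, importance_overlap_test
from .io import write_tables
from .simulate import SimulationConfig, simulate_cohorts
from .univariate import univariate_analysis


def _canonical(obj) -> str:
    return json.dumps(obj, sort_keys=True, default=str)


def config_hash(config: dict) -> str:
    return hashlib.sha256(_canonical(config).encode()).hexdigest()[:16]


def digest_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stage_seeds: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    leakage_audit: dict = field(default_factory=dict)

    def record(self, stage: str, path) -> None:
        self.digests[stage] = digest_file(path)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        )


DEFAULT_EXPERIMENT = {
    "simulation": {},          # SimulationConfig overrides
    "classifier": {},          # ClassifierSpec overrides
    "n_trees": 300,
    "within_site_perms": 100,
    "control_B": 100,
    "selection_trees": 200,
    "overlap_B": 100,
    "family": FAMILY_DENSITY,
    "stages": [
        "simulate", "loso", "whole_dataset", "within_site", "external",
        "selection", "global_decomposition", "univariate",
    ],
}


def _spawn_seeds(master_seed: int, names: list[str]) -> dict[str, int]:
    seqs = np.random.SeedSequence(master_seed).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % 2**31) for n, s in zip(names, seqs)}


def run_experiment(config: dict | None = None, outdir="results/experiment",
                   master_seed: int = 0) -> RunManifest:
    """Run the full analysis graph; write reports and the manifest to outdir."""
    cfg = {**DEFAULT_EXPERIMENT, **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    manifest = RunManifest(config_hash=config_hash(cfg), master_seed=master_seed)
    seeds = _spawn_seeds(
        master_seed,
        ["simulate", "loso", "whole", "within", "external", "selection",
         "decomp", "univariate"],
    )
    manifest.stage_seeds = seeds

    sim_cfg = SimulationConfig(**{"seed": seeds["simulate"], **cfg["simulation"]})
    from .atlas import build_feature_atlas

    atlas = build_feature_atlas(sim_cfg)
    features, phenotypes, truth = simulate_cohorts(sim_cfg, atlas)
    if "simulate" in stages:
        paths = write_tables(outdir / "tables", features, phenotypes, atlas,
                             truth=truth, config=sim_cfg)
        for name, p in paths.items():
            manifest.record(f"tables/{name}", p)

    spec = ClassifierSpec(**{"n_trees": cfg["n_trees"], **cfg["classifier"]})
    cohorts = training_cohorts(phenotypes)
    family_cols = list(regional_features(atlas, cfg["family"])) + [
        f for f in atlas.index[atlas["is_global"]] if f in features.columns
    ]
    report: dict = {"config_hash": manifest.config_hash}

    folds = None
    if {"loso", "global_decomposition"} & set(stages):
        folds = prepare_loso_folds(
            features, phenotypes, atlas, cohorts,
            ClassifierSpec(**{**spec.__dict__, "seed": seeds["loso"]}),
        )
    if "loso" in stages:
        loso = run_leave_site_out(features, phenotypes, atlas, cohorts,
                                  ClassifierSpec(**{**spec.__dict__, "seed": seeds["loso"]}),
                                  folds=folds)
        report["loso"] = {
            "median_auc": loso.median_auc,
            "auc_range": loso.auc_range,
            "per_site": {s: r.to_dict() for s, r in loso.per_site.items()},
            "leakage_clean": loso.leakage_clean,
        }
    if "whole_dataset" in stages:
        _, oob_res, site_corrected, ph_matched = run_whole_dataset_oob(
            features, phenotypes, atlas, cohorts,
            ClassifierSpec(**{**spec.__dict__, "seed": seeds["whole"]}),
        )
        report["whole_dataset_oob"] = oob_res.to_dict()
    if "within_site" in stages:
        within = {}
        for cid in cohorts:
            res = run_within_site(
                features, phenotypes, atlas, cid,
                ClassifierSpec(**{**spec.__dict__, "seed": seeds["within"]}),
                n_label_perms=cfg["within_site_perms"],
            )
            res.extra.pop("importances", None)
            within[cid] = res.to_dict()
        report["within_site"] = within
    if "external" in stages:
        pipeline = train_full_classifier(
            features, phenotypes, atlas, cohorts,
            ClassifierSpec(**{**spec.__dict__, "seed": seeds["external"]}),
        )
        validation = sorted(set(phenotypes["cohort_id"]) - set(cohorts))
        if validation:
            report["external_specificity"] = run_external_specificity(
                pipeline, features, phenotypes, validation
            )
    if "selection" in stages and "whole_dataset" in stages:
        sel = backward_feature_elimination(
            site_corrected[[c for c in family_cols if c in site_corrected.columns]],
            ph_matched["diagnosis"], ph_matched["cohort_id"],
            n_trees=cfg["selection_trees"], seed=seeds["selection"],
        )
        report["selection"] = {
            "m": sel.m, "selected": sel.selected, "min_error": sel.min_error,
            "path": sel.path,
        }
    if "global_decomposition" in stages and folds is not None:
        fam = cfg["family"]
        dspec = ClassifierSpec(**{**spec.__dict__, "seed": seeds["decomp"]})
        original = run_leave_site_out(features, phenotypes, atlas, cohorts, dspec,
                                      folds=folds)
        resid = gs.loso_with_global_residualization(
            features, phenotypes, atlas, fam, cohorts, dspec, folds=folds
        )
        perm_g = gs.permuted_global_control(folds, atlas, fam, dspec,
                                            B=cfg["control_B"], seed=seeds["decomp"])
        perm_d = gs.permuted_diagnosis_control(
            folds, dspec, B=cfg["control_B"], seed=seeds["decomp"] + 1,
            transform=gs._global_transform(atlas, fam),
        )
        gonly = gs.globals_only_classification(folds, atlas, fam, dspec)
        report["global_decomposition"] = {
            "original_auc": original.median_auc,
            "residualized_auc": resid.median_auc,
            "permuted_global_auc_mean": float(perm_g.mean()),
            "permuted_diagnosis_band": [
                float(np.quantile(perm_d, 0.025)), float(np.quantile(perm_d, 0.975))
            ],
            "globals_only_auc": gonly.median_auc,
        }
    if "univariate" in stages and "whole_dataset" in stages:
        uni_pre = univariate_analysis(site_corrected, ph_matched["diagnosis"], atlas,
                                      stage="pre_global")
        g = gs.assemble_global_features(site_corrected, atlas, cfg["family"])
        resid_feats = gs.residualize_against_globals(site_corrected, g)
        uni_post = univariate_analysis(resid_feats, ph_matched["diagnosis"], atlas,
                                       stage="post_global")
        uni = pd.concat([uni_pre, uni_post])
        uni_path = outdir / "univariate.tsv"
        uni.to_csv(uni_path, sep="\t", index_label="feature_id")
        manifest.record("univariate", uni_path)
        report["univariate"] = {
            "n_significant_pre": int((uni_pre["q"] < 0.05).sum()),
            "n_significant_post": int((uni_post["q"] < 0.05).sum()),
        }

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    manifest.record("report", report_path)
    manifest.to_json(outdir / "manifest.json")
    return manifest
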