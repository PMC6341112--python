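"""TSV/YAML table I/O with schema validation."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .atlas import ATLAS_COLUMNS, validate_atlas

PHENOTYPE_COLUMNS = [
    "diagnosis", "disorder_label", "cohort_id", "age", "sex", "icv",
    "scanner_vendor", "field_strength",
]
REQUIRED_COVARIATES = ["age", "sex", "icv", "cohort_id", "diagnosis"]


def write_tables(
    outdir,
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    atlas: pd.DataFrame,
    truth=None,
    config=None,
) -> dict[str, Path]:
    """Write feature/phenotype/atlas TSVs (+ optional ground truth, config YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / "features.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "atlas": outdir / "atlas.tsv",
    }
    features.to_csv(paths["features"], sep="\t", index_label="subject_id")
    phenotypes.to_csv(paths["phenotypes"], sep="\t", index_label="subject_id")
    atlas.to_csv(paths["atlas"], sep="\t", index_label="feature_id")
    if truth is not None:
        paths["ground_truth"] = outdir / "ground_truth.tsv"
        truth.to_frame().to_csv(paths["ground_truth"], sep="\t", index_label="feature_id")
    if config is not None:
        paths["config"] = outdir / "simulation_config.yaml"
        payload = config.__dict__ if hasattr(config, "__dict__") else dict(config)
        paths["config"].write_text(yaml.safe_dump(payload, sort_keys=True))
    return paths


def load_tables(
    feature_path, phenotype_path, atlas_path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate the three core tables.

    Checks: unique subject ids, complete covariates, atlas covering every
    feature column; failures name the offending subjects/columns.
    """
    features = pd.read_csv(
        feature_path, sep="\t", index_col="subject_id", float_precision="round_trip"
    )
    phenotypes = pd.read_csv(
        phenotype_path, sep="\t", index_col="subject_id", float_precision="round_trip"
    )
    atlas = pd.read_csv(
        atlas_path, sep="\t", index_col="feature_id", float_precision="round_trip"
    )

    problems = []
    for name, tab in (("features", features), ("phenotypes", phenotypes)):
        dup = tab.index[tab.index.duplicated()].unique().tolist()
        if dup:
            problems.append(f"{name}: duplicate subject ids {dup[:5]}")
    missing_ph = [s for s in features.index if s not in phenotypes.index]
    if missing_ph:
        problems.append(f"subjects without phenotype rows: {missing_ph[:5]}")
    for col in REQUIRED_COVARIATES:
        if col not in phenotypes.columns:
            problems.append(f"phenotypes: missing column {col!r}")
        else:
            bad = phenotypes.index[phenotypes[col].isna()].tolist()
            if bad:
                problems.append(f"phenotypes: missing {col!r} for subject(s) {bad[:5]}")
    for col in ATLAS_COLUMNS:
        if col not in atlas.columns:
            problems.append(f"atlas: missing column {col!r}")
    unknown = [c for c in features.columns if c not in atlas.index]
    if unknown:
        problems.append(f"feature columns absent from atlas: {unknown[:5]}")
    if problems:
        raise ValueError("invalid tables:\n  " + "\n  ".join(problems))
    validate_atlas(atlas)
    return features, phenotypes, atlas


def write_normalization_model(model, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(model.to_dict(), sort_keys=True))
    return path


def read_normalization_model(path):
    from .normalize import NormalizationModel

    return NormalizationModel.from_dict(yaml.safe_load(Path(path).read_text()))
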