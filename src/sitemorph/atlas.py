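"""Synthetic feature atlas for multi-site brain-morphometry cohorts.

The atlas is the feature-metadata table: one row per feature with its family
(grey-matter *density*-like regional measures vs. *surface*-reconstruction
measures of thickness/area/volume), measure type, laterality, a mean size on
an arbitrary population scale, and flags marking global summary features and
ventricle features.

Two feature ids are *placeholders*: ``ventricle_median`` and
``family_median``.  They have no measured column in a feature table; they are
computed per subject when the global feature set is assembled (see
:mod:`sitemorph.global_signal`).  Together with the measured summary features
and intracranial volume they make up the global set (22 members by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FAMILY_DENSITY = "densitylike"
FAMILY_SURFACE = "surfacelike"
FAMILIES = (FAMILY_DENSITY, FAMILY_SURFACE)

ICV = "icv"
VENTRICLE_MEDIAN = "ventricle_median"
FAMILY_MEDIAN = "family_median"
PLACEHOLDERS = (VENTRICLE_MEDIAN, FAMILY_MEDIAN)

ATLAS_COLUMNS = ["family", "measure", "laterality", "is_global", "is_ventricle", "mean_size"]

# Measured whole-brain summary features designated as globals, (id, family,
# measure, laterality, mean size, is_ventricle).  19 entries; with ICV and the
# two median placeholders the default global set has 22 members.  Bilateral
# aggregates are only used where no unilateral pair exists.
_DESIGNATED_GLOBALS = [
    ("gm_total_density", FAMILY_DENSITY, "density", "bilateral", 620.0, False),
    ("gm_hemisphere_lh_density", FAMILY_DENSITY, "density", "left", 310.0, False),
    ("gm_hemisphere_rh_density", FAMILY_DENSITY, "density", "right", 310.0, False),
    ("cerebellum_gm_density", FAMILY_DENSITY, "density", "bilateral", 110.0, False),
    ("mean_thickness_lh", FAMILY_SURFACE, "thickness", "left", 2.5, False),
    ("mean_thickness_rh", FAMILY_SURFACE, "thickness", "right", 2.5, False),
    ("total_surface_area_lh", FAMILY_SURFACE, "area", "left", 900.0, False),
    ("total_surface_area_rh", FAMILY_SURFACE, "area", "right", 900.0, False),
    ("cortical_gm_volume_lh", FAMILY_SURFACE, "volume", "left", 250.0, False),
    ("cortical_gm_volume_rh", FAMILY_SURFACE, "volume", "right", 250.0, False),
    ("subcortical_gm_volume", FAMILY_SURFACE, "volume", "bilateral", 60.0, False),
    ("cerebral_wm_volume", FAMILY_SURFACE, "volume", "bilateral", 470.0, False),
    ("cerebellum_volume", FAMILY_SURFACE, "volume", "bilateral", 140.0, False),
    ("brainstem_volume", FAMILY_SURFACE, "volume", "bilateral", 21.0, False),
    ("csf_volume", FAMILY_SURFACE, "volume", "bilateral", 1.2, False),
    ("lateral_ventricle_lh", FAMILY_SURFACE, "volume", "left", 8.0, True),
    ("lateral_ventricle_rh", FAMILY_SURFACE, "volume", "right", 8.0, True),
    ("third_ventricle", FAMILY_SURFACE, "volume", "bilateral", 1.0, True),
    ("fourth_ventricle", FAMILY_SURFACE, "volume", "bilateral", 1.7, True),
]
_N_DESIGNATED = len(_DESIGNATED_GLOBALS)  # 19


def build_feature_atlas(config) -> pd.DataFrame:
    """Build the feature-metadata table for a :class:`SimulationConfig`.

    Returns a DataFrame indexed by ``feature_id`` with columns
    ``family, measure, laterality, is_global, is_ventricle, mean_size``.
    Default sizes give 122 density-like + 152 surface-like measured features
    plus one ICV row and the two median placeholders.
    """
    n_density = int(config.n_density)
    n_surface = int(config.n_surface)
    n_global = int(config.n_global)
    if n_density < 1 or n_surface < 1:
        raise ValueError("each feature family needs at least one feature")
    if n_global < 3:
        raise ValueError("global set needs at least ICV and the two median placeholders")
    n_designated = n_global - 3  # measured summary features among the globals
    if n_designated > _N_DESIGNATED:
        raise ValueError(f"at most {_N_DESIGNATED + 3} global features supported")

    designated = _DESIGNATED_GLOBALS[:n_designated]
    n_des_density = sum(1 for d in designated if d[1] == FAMILY_DENSITY)
    n_des_surface = len(designated) - n_des_density
    if n_density <= n_des_density or n_surface <= n_des_surface:
        # family too small to host summary aggregates: plain regional atlas
        designated = []
        n_des_density = n_des_surface = 0

    rng = np.random.default_rng(int(config.seed) + 104729)
    rows: list[tuple] = []
    for fid, fam, meas, lat, size, vent in designated:
        rows.append((fid, fam, meas, lat, True, vent, size))

    # regional density-like features (AAL-style paired regions)
    n_reg = n_density - n_des_density
    for i in range(n_reg):
        side = "left" if i % 2 == 0 else "right"
        rid = f"density_region{i // 2 + 1:03d}_{'lh' if side == 'left' else 'rh'}"
        size = float(np.round(rng.lognormal(mean=np.log(6.0), sigma=0.7), 3))
        rows.append((rid, FAMILY_DENSITY, "density", side, False, False, size))

    # regional surface-based features: thickness / area / volume thirds
    n_reg = n_surface - n_des_surface
    measures = ["thickness", "area", "volume"]
    scales = {"thickness": 2.6, "area": 18.0, "volume": 5.0}
    for i in range(n_reg):
        meas = measures[(i // 2) % 3]
        side = "left" if i % 2 == 0 else "right"
        rid = f"{meas}_region{i // 6 + 1:03d}_{'lh' if side == 'left' else 'rh'}"
        if meas == "thickness":
            size = float(np.round(rng.normal(scales[meas], 0.25), 3))
        else:
            size = float(np.round(rng.lognormal(np.log(scales[meas]), 0.6), 3))
        rows.append((rid, FAMILY_SURFACE, meas, side, False, False, max(size, 0.2)))

    rows.append((ICV, FAMILY_SURFACE, "icv", "none", True, False, 1500.0))
    if designated:
        rows.append((VENTRICLE_MEDIAN, FAMILY_SURFACE, "volume", "none", True, False, 4.0))
        rows.append((FAMILY_MEDIAN, FAMILY_SURFACE, "volume", "none", True, False, 10.0))

    atlas = pd.DataFrame(
        rows, columns=["feature_id"] + ATLAS_COLUMNS
    ).set_index("feature_id")
    validate_atlas(atlas)
    return atlas


def validate_atlas(atlas: pd.DataFrame) -> None:
    """Check atlas invariants; raise ``ValueError`` on violation."""
    if atlas.index.duplicated().any():
        dup = atlas.index[atlas.index.duplicated()].tolist()
        raise ValueError(f"duplicate feature ids: {dup}")
    n_icv = int((atlas["measure"] == "icv").sum())
    if n_icv != 1:
        raise ValueError(f"expected exactly one ICV feature, found {n_icv}")
    if (atlas["mean_size"] <= 0).any():
        raise ValueError("mean_size must be positive")
    # a bilateral global must not coexist with its unilateral pair
    glob = atlas[atlas["is_global"]]
    bases = {}
    for fid, row in glob.iterrows():
        base = fid.replace("_lh", "").replace("_rh", "")
        bases.setdefault(base, set()).add(row["laterality"])
    for base, lats in bases.items():
        if "bilateral" in lats and {"left", "right"} <= lats:
            raise ValueError(f"bilateral global '{base}' duplicates unilateral pair")


def measured_features(atlas: pd.DataFrame, include_icv: bool = False) -> pd.Index:
    """Feature ids with measured columns (placeholders excluded)."""
    keep = ~atlas.index.isin(PLACEHOLDERS)
    if not include_icv:
        keep &= atlas["measure"].to_numpy() != "icv"
    return atlas.index[keep]


def regional_features(atlas: pd.DataFrame, family: str | None = None) -> pd.Index:
    """Measured, non-global regional feature ids, optionally one family."""
    keep = (~atlas["is_global"]) & (~atlas.index.isin(PLACEHOLDERS))
    if family is not None:
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        keep &= atlas["family"] == family
    return atlas.index[keep]
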