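"""Multi-site case-control cohort simulator with known ground truth.

The generator emulates the statistical structure of pooled multi-site
structural-MRI morphometry: per-feature covariate effects (age, age², sex,
intracranial volume), per-(site, feature) mean shifts plus scanner-vendor and
field-strength offsets, a small set of correlated per-subject *global factors*
(shared atrophy-like signal loading on every regional feature, more strongly
on larger structures, with ventricles loading negatively), and a disorder
effect that can be routed through the global factors (mediated), applied
directly to designated informative regional features, or split between the
two via ``global_mediation``.

Feature values are generated on a standardized latent scale ``z`` and mapped
to measurement units as ``mean_size * (1 + cv * z)`` with a 10% coefficient
of variation, so effect sizes quoted in the configuration are Cohen's-d-like
on the latent scale and invariant to structure size.

Cohorts: ``C01..C0k`` are matched training cohorts with schizophrenia-like
cases; validation cohorts are ``V01`` (healthy controls), ``V02``
(bipolar-like cases sharing the global-factor shift at reduced magnitude),
``V03`` (adult ADHD-like cases with an orthogonal regional signal) and
``V04`` (adolescent ADHD-like, ages 12-18).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import (
    FAMILY_DENSITY,
    FAMILY_SURFACE,
    build_feature_atlas,
    measured_features,
    regional_features,
)

VENDORS = ("vendorA", "vendorB", "vendorC")
FIELDS = ("3T", "1.5T")

AGE_CENTER = 40.0
ICV_MEAN = 1400.0
ICV_SEX_SHIFT = 120.0
ICV_SD = 110.0
FEATURE_CV = 0.10  # coefficient of variation mapping latent z to raw units


@dataclass
class SimulationConfig:
    """Study conditions for one simulated multi-site experiment.

    All effect sizes are on the standardized latent feature scale.
    ``global_mediation`` is the fraction of the case-control effect routed
    through the global factors: each factor mean is shifted by
    ``global_mediation * regional_effect_d`` in cases, while each informative
    regional feature receives a direct marginal shift of
    ``(1 - global_mediation) * regional_effect_d``.
    """

    n_cohorts: int = 4
    n_cases: int = 50
    n_controls: int = 50
    n_validation_cohorts: int = 4
    n_density: int = 122
    n_surface: int = 152
    n_global: int = 22
    # per-year / per-unit latent-scale covariate effects (feature-jittered)
    beta_age: float = -0.02
    beta_age2: float = -0.0004
    beta_sex: float = 0.3
    beta_icv: float = 0.4
    site_shift_sd: float = 0.3
    vendor_offset_sd: float = 0.2
    field_offset_sd: float = 0.15
    n_global_factors: int = 3
    factor_corr: float = 0.3
    factor_loading: float = 0.6
    global_mediation: float = 0.8
    regional_effect_d: float = 0.8
    n_regional_informative: int = 15
    bd_shift_scale: float = 0.75   # bipolar-like factor shift relative to cases
    adhd_effect_d: float = 0.5     # orthogonal regional signal in ADHD-like cohorts
    noise_sd: float = 1.0
    control_age_shift: float = 0.0  # age confound knob for matching experiments
    seed: int = 0

    def validate(self) -> None:
        for name in ("site_shift_sd", "vendor_offset_sd", "field_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.global_mediation <= 1.0:
            raise ValueError("global_mediation must lie in [0, 1]")
        if self.global_mediation > 0 and self.n_global_factors == 0 and self.regional_effect_d != 0:
            raise ValueError("mediation requested with n_global_factors=0")
        if min(self.n_cohorts, self.n_cases, self.n_controls) < 1:
            raise ValueError("cohort counts must be positive")
        if not 0 <= self.n_validation_cohorts <= 4:
            raise ValueError("n_validation_cohorts must be in 0..4")


@dataclass
class GroundTruth:
    """Injected effects, recorded for recovery tests and audits."""

    loadings: pd.DataFrame          # features x factors, latent scale
    factor_cov: np.ndarray          # K x K factor covariance
    betas: pd.DataFrame             # features x [age, age2, sex, icv], latent scale
    feature_scale: pd.Series        # raw units per latent z (cv * mean_size)
    site_offsets: pd.DataFrame      # cohorts x features, latent scale
    informative_features: list[str]     # direct case-signal carriers
    adhd_informative: list[str]         # orthogonal validation signal carriers
    marginal_d: pd.Series           # analytic marginal case-control d per feature
    config: SimulationConfig = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        out = self.betas.copy()
        out["feature_scale"] = self.feature_scale
        out["marginal_d"] = self.marginal_d
        out["informative"] = out.index.isin(self.informative_features)
        out["adhd_informative"] = out.index.isin(self.adhd_informative)
        for k in range(self.loadings.shape[1]):
            out[f"loading_{k + 1}"] = self.loadings.iloc[:, k]
        return out


def marginal_case_control_d(
    loadings: np.ndarray,
    factor_cov: np.ndarray,
    noise_sd: float,
    mediation: float,
    d: float,
    direct: np.ndarray,
) -> np.ndarray:
    """Analytic marginal Cohen's d per feature.

    Mean difference is ``mediation*d*sum_k(lambda_fk) + direct_f`` on the
    latent scale; the marginal SD is ``sqrt(lambda' Sigma lambda + noise^2)``.
    """
    if loadings.size:
        var_fac = np.einsum("fk,kl,fl->f", loadings, factor_cov, loadings)
        shift = mediation * d * loadings.sum(axis=1)
    else:
        var_fac = np.zeros(len(direct))
        shift = np.zeros(len(direct))
    sd = np.sqrt(var_fac + noise_sd**2)
    return (shift + direct) / sd


def _factor_cov(k: int, rho: float) -> np.ndarray:
    return (1 - rho) * np.eye(k) + rho * np.ones((k, k)) if k else np.zeros((0, 0))


def _cohort_plan(config: SimulationConfig) -> list[dict]:
    plan = []
    for i in range(config.n_cohorts):
        plan.append(
            dict(cohort=f"C{i + 1:02d}", disorder="SZ-like", n_cases=config.n_cases,
                 n_controls=config.n_controls, adolescent=False, training=True)
        )
    validation = [
        dict(cohort="V01", disorder="none", n_cases=0,
             n_controls=2 * config.n_controls, adolescent=False, training=False),
        dict(cohort="V02", disorder="BD-like", n_cases=config.n_cases,
             n_controls=config.n_controls, adolescent=False, training=False),
        dict(cohort="V03", disorder="ADHD-like", n_cases=config.n_cases,
             n_controls=config.n_controls, adolescent=False, training=False),
        dict(cohort="V04", disorder="ADHD-like", n_cases=config.n_cases,
             n_controls=config.n_controls, adolescent=True, training=False),
    ]
    plan.extend(validation[: config.n_validation_cohorts])
    for j, entry in enumerate(plan):
        entry["vendor"] = VENDORS[j % len(VENDORS)]
        entry["field"] = FIELDS[(j // len(VENDORS)) % len(FIELDS)]
    return plan


def simulate_cohorts(
    config: SimulationConfig, atlas: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate feature and phenotype tables under ``config``.

    Returns ``(features, phenotypes, truth)``.  ``features`` holds measured
    structural features only (ICV lives in the phenotype table and is appended
    as a predictor during normalization).  The same seed reproduces the
    tables exactly.
    """
    config.validate()
    if atlas is None:
        atlas = build_feature_atlas(config)
    rng = np.random.default_rng(int(config.seed))

    feats = measured_features(atlas, include_icv=False)
    meta = atlas.loc[feats]
    p = len(feats)
    k = int(config.n_global_factors)
    sigma = _factor_cov(k, config.factor_corr)

    # --- per-feature structural parameters (shared by all cohorts) ---------
    rel = np.sqrt(meta["mean_size"].to_numpy() / np.median(meta["mean_size"]))
    size_w = np.clip(rel, 0.4, 3.0)
    if k:
        lam = config.factor_loading * size_w[:, None] * np.abs(
            rng.normal(1.0, 0.2, size=(p, k))
        )
        lam[meta["is_ventricle"].to_numpy(), :] *= -1.0  # atrophy enlarges ventricles
    else:
        lam = np.zeros((p, 0))

    jitter = rng.uniform(0.5, 1.5, size=(p, 4))
    betas = pd.DataFrame(
        {
            "age": config.beta_age * jitter[:, 0],
            "age2": config.beta_age2 * jitter[:, 1],
            "sex": config.beta_sex * jitter[:, 2],
            "icv": config.beta_icv * jitter[:, 3],
        },
        index=feats,
    )
    betas.loc[meta["measure"] == "thickness", "icv"] = 0.0  # thickness is size-free

    regional = regional_features(atlas)
    n_inf = min(config.n_regional_informative, len(regional) // 2)
    picked = rng.choice(len(regional), size=2 * n_inf, replace=False)
    informative = list(regional[picked[:n_inf]])
    adhd_informative = list(regional[picked[n_inf:]])

    mu, d = config.global_mediation, config.regional_effect_d
    var_fac = np.einsum("fk,kl,fl->f", lam, sigma, lam) if k else np.zeros(p)
    sd_marginal = np.sqrt(var_fac + config.noise_sd**2)
    direct = np.zeros(p)
    direct[feats.isin(informative)] = (1 - mu) * d * sd_marginal[feats.isin(informative)]
    # orthogonal validation signal: mixed-sign regional shifts (no net
    # projection onto the shared global-atrophy direction)
    direct_adhd = np.zeros(p)
    adhd_mask = feats.isin(adhd_informative)
    signs = np.where(np.arange(int(adhd_mask.sum())) % 2 == 0, 1.0, -1.0)
    direct_adhd[adhd_mask] = config.adhd_effect_d * sd_marginal[adhd_mask] * signs

    plan = _cohort_plan(config)
    site_offsets = pd.DataFrame(
        rng.normal(0.0, config.site_shift_sd, size=(len(plan), p)),
        index=[e["cohort"] for e in plan],
        columns=feats,
    )
    vendor_off = {v: rng.normal(0.0, config.vendor_offset_sd, size=p) for v in VENDORS}
    field_off = {f: rng.normal(0.0, config.field_offset_sd, size=p) for f in FIELDS}

    # --- subjects ----------------------------------------------------------
    pheno_rows = []
    blocks = []
    for entry in plan:
        n = entry["n_cases"] + entry["n_controls"]
        is_case = np.zeros(n, dtype=bool)
        is_case[: entry["n_cases"]] = True
        lo, hi = (12.0, 18.0) if entry["adolescent"] else (18.0, 65.0)
        age = rng.uniform(lo, hi, size=n)
        if config.control_age_shift:
            # older control pool: controls span a wider upper age range while
            # still overlapping the cases, so matching can restore balance
            age[~is_case] = rng.uniform(
                lo, hi + 2 * config.control_age_shift, size=int((~is_case).sum())
            )
        male = rng.random(n) < 0.5
        icv = ICV_MEAN + ICV_SEX_SHIFT * male + rng.normal(0.0, ICV_SD, size=n)

        g = rng.multivariate_normal(np.zeros(k), sigma, size=n) if k else np.zeros((n, 0))
        if entry["disorder"] == "SZ-like":
            g[is_case] += mu * d
        elif entry["disorder"] == "BD-like":
            g[is_case] += config.bd_shift_scale * mu * d

        z = (
            betas["age"].to_numpy() * (age - AGE_CENTER)[:, None]
            + betas["age2"].to_numpy() * ((age - AGE_CENTER) ** 2)[:, None]
            + betas["sex"].to_numpy() * male[:, None]
            + betas["icv"].to_numpy() * ((icv - ICV_MEAN) / ICV_SD)[:, None]
            + site_offsets.loc[entry["cohort"]].to_numpy()[None, :]
            + vendor_off[entry["vendor"]][None, :]
            + field_off[entry["field"]][None, :]
            + g @ lam.T
            + rng.normal(0.0, config.noise_sd, size=(n, p))
        )
        if entry["disorder"] == "SZ-like":
            z[is_case] += direct[None, :]
        elif entry["disorder"] == "ADHD-like":
            z[is_case] += direct_adhd[None, :]

        scale = FEATURE_CV * meta["mean_size"].to_numpy()
        values = meta["mean_size"].to_numpy()[None, :] + scale[None, :] * z
        blocks.append(values)

        for j in range(n):
            pheno_rows.append(
                dict(
                    subject_id=f"{entry['cohort']}_s{j + 1:03d}",
                    diagnosis="case" if is_case[j] else "control",
                    disorder_label=entry["disorder"] if is_case[j] else "none",
                    cohort_id=entry["cohort"],
                    age=float(age[j]),
                    sex="M" if male[j] else "F",
                    icv=float(icv[j]),
                    scanner_vendor=entry["vendor"],
                    field_strength=entry["field"],
                )
            )

    phenotypes = pd.DataFrame(pheno_rows).set_index("subject_id")
    features = pd.DataFrame(
        np.vstack(blocks), index=phenotypes.index, columns=feats
    )

    truth = GroundTruth(
        loadings=pd.DataFrame(lam, index=feats, columns=[f"factor_{i+1}" for i in range(k)]),
        factor_cov=sigma,
        betas=betas,
        feature_scale=pd.Series(FEATURE_CV * meta["mean_size"].to_numpy(), index=feats),
        site_offsets=site_offsets,
        informative_features=informative,
        adhd_informative=adhd_informative,
        marginal_d=pd.Series(
            marginal_case_control_d(lam, sigma, config.noise_sd, mu, d, direct),
            index=feats,
        ),
        config=dataclasses.replace(config),
    )
    return features, phenotypes, truth


def null_config(**overrides) -> SimulationConfig:
    """A configuration with every diagnosis effect switched off."""
    base = dict(regional_effect_d=0.0, adhd_effect_d=0.0, global_mediation=0.0)
    base.update(overrides)
    return SimulationConfig(**base)
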