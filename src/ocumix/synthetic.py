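"""Synthetic cohort generator.

Individual-level data of the population study this package models are not
publicly deposited, so every analysis stage is exercised on generated
cohorts whose statistical structure mirrors the study: marginal
demographics and biometry calibrated to the published descriptive table, a
two-component axial-length structure linked to education, linear
education→biometry structural effects, and SNP instruments for education,
myopia and axial length.

Five frozen scenarios are provided (:func:`scenario_default`):

``table1``
    marginal distributions only — no structural effects.
``regression``
    linear education effects on axial length (0.06 mm/yr), anterior
    chamber depth (0.01 mm/yr) and spherical equivalent (total adjusted
    effect −0.10 D/yr via an anatomical −1.0 D/mm axial-length channel
    plus a −0.04 D/yr direct path).
``mediation``
    calibrated so the marginal education→SE effect is −0.18 D/yr and the
    axial-length-conditional effect −0.054 D/yr (proportion mediated 0.70).
``mr``
    50,000 persons, 70 education / 53 myopia / 21 axial-length SNPs;
    education GRS explains 5% of education variance; causal effects
    −0.35 D and +0.63 mm per SD of education; no pleiotropy by default.
``bimodal``
    axial length drawn from 0.72·N(23.45, 0.85²) + 0.28·N(25.10, 1.20²)
    with the short-education band (< 11 years) drawn from the emmetropic
    component, so that stratum is unimodal.

All randomness flows from a single ``numpy`` Generator seeded from the
config, so ``(config, seed)`` fully determines every output table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import BIOMETRY_FIELDS, CANONICAL_COLUMNS

__all__ = [
    "ScenarioConfig",
    "TruthRecord",
    "scenario_default",
    "generate_cohort",
    "generate_mixture_sample",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("table1", "regression", "mediation", "mr", "bimodal")

# allele pairs without strand ambiguity (no A/T, no C/G)
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]

#: default inter-eye noise SDs; only used to exercise eye averaging
DEFAULT_INTER_EYE_SD = {"al": 0.25, "se": 0.45, "acd": 0.10, "cc": 0.08, "lt": 0.10, "wtw": 0.15}


@dataclass
class ScenarioConfig:
    """Full parameterization of a synthetic cohort.

    Structural coefficients are in natural units (mm per year of education,
    D per mm, ...); ``causal_*_per_sd`` are on the per-SD-of-education
    scale used by the Mendelian-randomization scenario.
    """

    name: str = "custom"
    n_persons: int = 8532
    seed: int = 20240306

    # demographics
    sex_female_prob: float = 0.49
    age_low: float = 40.0
    age_high: float = 80.0

    # education
    edu_mean: float = 13.05
    edu_sd: float = 2.09
    grs_r2_edu: float = 0.0

    # genetics
    n_edu_snps: int = 0
    n_myo_snps: int = 0
    n_al_snps: int = 0
    maf_low: float = 0.10
    maf_high: float = 0.90

    # structural block
    beta_edu_al: float = 0.0          # mm per year
    beta_al_se: float = 0.0           # D per mm
    beta_edu_se_direct: float = 0.0   # D per year
    beta_edu_acd: float = 0.0         # mm per year
    beta_sex_al: float = 0.29         # mm, applied as +/- around the centre (male +)
    myo_grs_se_sd: float = 0.0        # D of myopic (negative) SE shift per SD of myopia GRS
    al_grs_al_sd: float = 0.0         # mm per SD of axial-length GRS
    sd_al_resid: float = 1.22
    sd_se_resid: float = 2.51
    al_mean: float = 23.74
    se_mean: float = -0.41
    acd_mean: float = 3.25
    acd_sd: float = 0.35
    cc_mean: float = 7.84
    cc_sd: float = 0.28
    lt_mean: float = 4.35
    lt_sd: float = 0.37
    wtw_mean: float = 12.21
    wtw_sd: float = 0.43

    # mixture block (bimodal scenario)
    al_mix_weights: tuple[float, ...] | None = None
    al_mix_means: tuple[float, ...] | None = None
    al_mix_sds: tuple[float, ...] | None = None
    bimodal_al_se_slope: float = -2.0     # D per mm, around al_mean
    sd_se_bimodal_resid: float = 1.0
    edu_short_cut: float = 11.0           # "0-10 years" band is edu < 11
    short_band_comp1_prob: float = 1.0    # P(component 1 | short education)

    # mr block
    causal_se_per_sd: float | None = None   # D per SD of education
    causal_al_per_sd: float | None = None   # mm per SD of education
    pleiotropy_frac: float = 0.0            # fraction of education SNPs with direct SE effects
    pleiotropy_mean: float = 0.0            # D per allele
    pleiotropy_sd: float = 0.0

    # eyes
    inter_eye_sd: dict = field(default_factory=lambda: dict(DEFAULT_INTER_EYE_SD))

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ValueError("n_persons must be >= 0")
        for p in ("sex_female_prob", "grs_r2_edu", "pleiotropy_frac", "short_band_comp1_prob"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{p}={v} outside [0, 1]")
        for p in ("edu_sd", "sd_al_resid", "sd_se_resid", "acd_sd", "cc_sd", "lt_sd", "wtw_sd"):
            if getattr(self, p) <= 0:
                raise ValueError(f"{p} must be > 0")
        if self.grs_r2_edu > 0 and self.n_edu_snps == 0:
            raise ValueError("grs_r2_edu > 0 requires n_edu_snps > 0")
        if self.al_mix_weights is not None:
            w = np.asarray(self.al_mix_weights, float)
            if abs(w.sum() - 1.0) > 1e-8:
                raise ValueError("al_mix_weights must sum to 1")
            if np.any(np.asarray(self.al_mix_sds, float) <= 0):
                raise ValueError("al_mix_sds must be > 0")


@dataclass
class TruthRecord:
    """Ground truth realized by :func:`generate_cohort` (for recovery tests)."""

    name: str
    seed: int
    coefficients: dict
    variants: pd.DataFrame      # variant_id, score_name, effect_allele, other_allele, maf, weight
    latent: pd.DataFrame        # person_id, raw/standardized genetic scores, component label

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "seed": self.seed,
            "coefficients": self.coefficients,
            "variants": self.variants.to_dict(orient="list"),
            "latent": self.latent.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _table1_base(**kw) -> ScenarioConfig:
    # residual axial-length SD net of the +/-0.29 mm sex shift (Var(+/-1) ~= 1)
    cfg = ScenarioConfig(
        name="table1",
        sd_al_resid=float(np.sqrt(1.22**2 - 0.29**2)),
        sd_se_resid=2.51,
        **kw,
    )
    return cfg


def scenario_default(name: str) -> ScenarioConfig:
    """Return the frozen configuration for a named scenario."""
    edu_var = 2.09**2
    if name == "table1":
        return _table1_base()

    if name == "regression":
        b_edu_al, b_al_se, b_edu_se = 0.06, -1.0, -0.04
        myo_shift = 0.30
        var_al = 1.22**2
        sd_al_resid = float(np.sqrt(var_al - b_edu_al**2 * edu_var - 0.29**2))
        # structured SE variance: AL channel + direct path + their covariance + GRS
        var_struct = (
            b_al_se**2 * var_al
            + b_edu_se**2 * edu_var
            + 2.0 * b_al_se * b_edu_se * (b_edu_al * edu_var)
            + myo_shift**2
        )
        return ScenarioConfig(
            name="regression",
            n_myo_snps=53,
            beta_edu_al=b_edu_al,
            beta_al_se=b_al_se,
            beta_edu_se_direct=b_edu_se,
            beta_edu_acd=0.01,
            myo_grs_se_sd=myo_shift,
            sd_al_resid=sd_al_resid,
            sd_se_resid=float(np.sqrt(2.51**2 - var_struct)),
            acd_sd=float(np.sqrt(0.35**2 - 0.01**2 * edu_var)),
        )

    if name == "mediation":
        return ScenarioConfig(
            name="mediation",
            n_myo_snps=53,
            beta_edu_al=0.06,
            beta_al_se=-2.1,
            beta_edu_se_direct=-0.054,   # marginal -0.18 = -0.054 + 0.06 * (-2.1)
            myo_grs_se_sd=0.30,
            sd_al_resid=float(np.sqrt(1.22**2 - 0.06**2 * edu_var - 0.29**2)),
            sd_se_resid=1.0,
        )

    if name == "mr":
        causal_se, causal_al = -0.35, 0.63
        myo_shift = float(np.sqrt(0.05) * 2.51)   # myopia GRS explains ~5% of SE variance
        al_shift = float(np.sqrt(0.05) * 1.22)
        return ScenarioConfig(
            name="mr",
            n_persons=50_000,
            n_edu_snps=70,
            n_myo_snps=53,
            n_al_snps=21,
            grs_r2_edu=0.05,
            causal_se_per_sd=causal_se,
            causal_al_per_sd=causal_al,
            myo_grs_se_sd=myo_shift,
            al_grs_al_sd=al_shift,
            sd_se_resid=float(np.sqrt(2.51**2 - causal_se**2 - myo_shift**2)),
            sd_al_resid=float(np.sqrt(1.22**2 - causal_al**2 - al_shift**2 - 0.29**2)),
        )

    if name == "bimodal":
        return ScenarioConfig(
            name="bimodal",
            al_mix_weights=(0.72, 0.28),
            al_mix_means=(23.45, 25.10),
            al_mix_sds=(0.85, 1.20),
            bimodal_al_se_slope=-2.0,
            sd_se_bimodal_resid=1.0,
        )

    raise ValueError(f"unknown scenario {name!r}; known: {SCENARIO_NAMES}")


def _draw_panel(rng, prefix, n_snps, maf_low, maf_high, signed):
    maf = rng.uniform(maf_low, maf_high, size=n_snps)
    if signed:
        weight = rng.normal(0.0, 0.2, size=n_snps)
    else:
        weight = np.abs(rng.normal(0.0, 0.2, size=n_snps)) + 0.02
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    eff = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oth = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    ids = [f"{prefix}{j + 1:04d}" for j in range(n_snps)]
    return pd.DataFrame(
        {"variant_id": ids, "effect_allele": eff, "other_allele": oth, "maf": maf, "weight": weight}
    )


def _standardized_score(dosages: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    raw = dosages @ weights
    sd = raw.std(ddof=1) if len(raw) > 1 else 0.0
    z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    return raw, z


def generate_cohort(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate (per-eye cohort, dosage matrix, score panels, truth record).

    The dosage matrix has ``person_id`` as first column; the panel table
    concatenates all scores (column ``score_name`` in
    ``{"education", "myopia", "axial_length"}``) with the true generative
    weights as effect estimates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons

    person_id = np.array([f"P{i + 1:06d}" for i in range(n)])
    female = rng.random(n) < config.sex_female_prob
    sex = np.where(female, "female", "male")
    sex_signed = np.where(female, -1.0, 1.0)
    age = rng.uniform(config.age_low, config.age_high, size=n)

    # --- genetics ---------------------------------------------------------
    panel_specs = [
        ("education", "edu", config.n_edu_snps, True),
        ("myopia", "myo", config.n_myo_snps, False),
        ("axial_length", "al", config.n_al_snps, False),
    ]
    panels = []
    dosage_blocks = {}
    z_scores = {"education": np.zeros(n), "myopia": np.zeros(n), "axial_length": np.zeros(n)}
    raw_scores = {k: np.zeros(n) for k in z_scores}
    for score_name, prefix, n_snps, signed in panel_specs:
        if n_snps == 0:
            continue
        pan = _draw_panel(rng, prefix, n_snps, config.maf_low, config.maf_high, signed)
        pan.insert(0, "score_name", score_name)
        panels.append(pan)
        d = rng.binomial(2, pan["maf"].to_numpy()[None, :], size=(n, n_snps)).astype(float)
        dosage_blocks[score_name] = (pan["variant_id"].tolist(), d)
        if n > 1:
            raw_scores[score_name], z_scores[score_name] = _standardized_score(
                d, pan["weight"].to_numpy()
            )
    panel_df = (
        pd.concat(panels, ignore_index=True)
        if panels
        else pd.DataFrame(
            columns=["score_name", "variant_id", "effect_allele", "other_allele", "maf", "weight"]
        )
    )
    all_ids = [v for ids, _ in dosage_blocks.values() for v in ids]
    dosage_df = pd.DataFrame(
        np.hstack([d for _, d in dosage_blocks.values()]) if dosage_blocks else np.empty((n, 0)),
        columns=all_ids,
    )
    dosage_df.insert(0, "person_id", person_id)

    # --- education --------------------------------------------------------
    r2 = config.grs_r2_edu
    edu_noise = rng.normal(0.0, 1.0, size=n)
    edu = config.edu_mean + config.edu_sd * (
        np.sqrt(r2) * z_scores["education"] + np.sqrt(1.0 - r2) * edu_noise
    )
    edu = np.clip(edu, 0.0, 20.0)
    edu_dev = edu - config.edu_mean
    z_edu = edu_dev / config.edu_sd

    # --- axial length -----------------------------------------------------
    component = np.zeros(n, dtype=int)
    if config.al_mix_weights is not None:
        short = edu < config.edu_short_cut
        f_short = short.mean() if n else 0.0
        w1 = config.al_mix_weights[0]
        p1_short = config.short_band_comp1_prob
        p1_long = (w1 - p1_short * f_short) / (1.0 - f_short) if f_short < 1.0 else w1
        p1 = np.where(short, p1_short, np.clip(p1_long, 0.0, 1.0))
        component = (rng.random(n) >= p1).astype(int)   # 0 = emmetropic component
        mu = np.asarray(config.al_mix_means, float)[component]
        sd = np.asarray(config.al_mix_sds, float)[component]
        al = rng.normal(mu, sd)
        se = (
            config.se_mean
            + config.bimodal_al_se_slope * (al - config.al_mean)
            + rng.normal(0.0, config.sd_se_bimodal_resid, size=n)
        )
    else:
        al = (
            config.al_mean
            + config.beta_edu_al * edu_dev
            + (config.causal_al_per_sd or 0.0) * z_edu
            + config.beta_sex_al * sex_signed
            + config.al_grs_al_sd * z_scores["axial_length"]
            + rng.normal(0.0, config.sd_al_resid, size=n)
        )
        se = (
            config.se_mean
            + config.beta_al_se * (al - config.al_mean)
            + config.beta_edu_se_direct * edu_dev
            + (config.causal_se_per_sd or 0.0) * z_edu
            - config.myo_grs_se_sd * z_scores["myopia"]
            + rng.normal(0.0, config.sd_se_resid, size=n)
        )

    # direct (pleiotropic) SNP effects on SE, bypassing education
    pleio = pd.DataFrame(columns=["variant_id", "alpha_se"])
    if config.pleiotropy_frac > 0 and "education" in dosage_blocks:
        ids, d = dosage_blocks["education"]
        m = len(ids)
        k = int(round(config.pleiotropy_frac * m))
        idx = rng.choice(m, size=k, replace=False)
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k)
        se = se + d[:, idx] @ alpha
        pleio = pd.DataFrame({"variant_id": [ids[i] for i in idx], "alpha_se": alpha})

    # --- remaining biometry ----------------------------------------------
    acd = config.acd_mean + config.beta_edu_acd * edu_dev + rng.normal(0, config.acd_sd, n)
    cc = rng.normal(config.cc_mean, config.cc_sd, n)
    lt = rng.normal(config.lt_mean, config.lt_sd, n)
    wtw = rng.normal(config.wtw_mean, config.wtw_sd, n)

    latent_biometry = {"se": se, "al": al, "acd": acd, "cc": cc, "lt": lt, "wtw": wtw}

    # --- per-eye rows -----------------------------------------------------
    school = np.where(edu < 10, "lowest", np.where(edu < 13, "intermediate", "higher"))
    vocational = np.where(edu >= 16, "university", np.where(edu >= 12, "vocational", "apprenticeship"))
    rows = []
    for eye in ("OD", "OS"):
        block = {
            "person_id": person_id,
            "age": age,
            "sex": sex,
            "education_years": edu,
            "school_level": school,
            "vocational_level": vocational,
            "eye": eye,
        }
        for f in BIOMETRY_FIELDS:
            s = config.inter_eye_sd.get(f, 0.0)
            block[f] = latent_biometry[f] + (rng.normal(0.0, s, n) if s > 0 else 0.0)
        block["lens_status"] = "phakic"
        rows.append(pd.DataFrame(block))
    cohort = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["person_id", "eye"], kind="stable")
        .reset_index(drop=True)
    ) if n else pd.DataFrame(columns=CANONICAL_COLUMNS)
    if n:
        cohort = cohort[CANONICAL_COLUMNS]

    coefficients = {
        "beta_edu_al": config.beta_edu_al,
        "beta_al_se": config.beta_al_se,
        "beta_edu_se_direct": config.beta_edu_se_direct,
        "beta_edu_se_total": config.beta_edu_se_direct + config.beta_edu_al * config.beta_al_se,
        "beta_edu_acd": config.beta_edu_acd,
        "beta_sex_al": config.beta_sex_al,
        "causal_se_per_sd": config.causal_se_per_sd,
        "causal_al_per_sd": config.causal_al_per_sd,
        "grs_r2_edu": config.grs_r2_edu,
    }
    truth = TruthRecord(
        name=config.name,
        seed=config.seed,
        coefficients=coefficients,
        variants=panel_df.merge(pleio, on="variant_id", how="left") if len(panel_df) else panel_df,
        latent=pd.DataFrame(
            {
                "person_id": person_id,
                "education_years": edu,
                "genetic_education_raw": raw_scores["education"],
                "genetic_myopia_raw": raw_scores["myopia"],
                "genetic_axial_length_raw": raw_scores["axial_length"],
                "z_education_grs": z_scores["education"],
                "z_myopia_grs": z_scores["myopia"],
                "z_axial_length_grs": z_scores["axial_length"],
                "component": component,
            }
        ),
    )
    return cohort, dosage_df, panel_df, truth


def generate_mixture_sample(
    weights, means, sds, n: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` values from a univariate Gaussian mixture; returns (values, labels)."""
    weights = np.asarray(weights, float)
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError(f"mixture weights sum to {weights.sum()}, not 1")
    if np.any(sds <= 0):
        raise ValueError("mixture sds must be > 0")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(weights), size=n, p=weights)
    values = rng.normal(means[labels], sds[labels])
    return values, labels
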