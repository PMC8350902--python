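"""Synthetic cohort generation for multimodal tau-biomarker analyses.

The generator emulates a memory-clinic cohort in which soluble (CSF/plasma
p-tau) and aggregated (tau-PET) markers of tau pathology are driven by a
single latent disease stage through a two-sigmoid cascade: amyloid burden
rises early along the stage axis, aggregated tau rises late. Soluble tau is
modelled as a state marker — a function of amyloid burden, age and APOE e4 —
while downstream consequences (cognition, cortical thickness, hippocampal
volume) are functions of aggregated tau only. This produces the differential
structure the analysis stages are designed to detect: fluid markers are more
tightly linked to early features (amyloid, age, APOE) and PET markers to late
features (cognition, atrophy), while the two modality families remain
strongly correlated with each other.

Observed variables are noisy affine (concentrations: log-affine) transforms
of the latent signals on scales that resemble published memory-clinic
distributions, so that reference-population cut-offs derived downstream land
near familiar values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

CU = "CU"
IMPAIRED = "IMPAIRED"

#: columns eligible for MCAR deletion and for chained-equation imputation
IMPUTABLE_COLUMNS = [
    "education",
    "apoe4",
    "csf_ab4240",
    "csf_ptau181",
    "csf_ptau217",
    "plasma_ptau181",
    "plasma_ptau217",
    "taupet_entorhinal",
    "taupet_meta",
    "mmse",
    "mem_z",
    "lang_z",
    "exec_z",
    "visuo_z",
    "hippo_tiv",
    "ad_sig_thickness",
]

#: columns that are never deleted and never imputed
PROTECTED_COLUMNS = ["id", "group", "dementia", "abeta_status", "age", "sex"]

#: structurally missing columns: excluded from both MCAR deletion and imputation
STRUCTURAL_COLUMNS = ["amyloid_pet"]

FLUID_MARKERS = ["csf_ptau181", "csf_ptau217", "plasma_ptau181", "plasma_ptau217"]
PET_MARKERS = ["taupet_entorhinal", "taupet_meta"]


def _default_noise_sd() -> dict[str, float]:
    # measurement noise on the latent (unit-ish) scale, per observed variable
    return {
        "csf_ptau181": 0.18,
        "csf_ptau217": 0.18,
        "plasma_ptau181": 0.35,
        "plasma_ptau217": 0.30,
        "taupet_entorhinal": 0.34,
        "taupet_meta": 0.28,
        "csf_ab4240": 0.008,
        "amyloid_pet": 0.08,
        "mmse": 1.2,
        "mem_z": 0.60,
        "lang_z": 0.70,
        "exec_z": 0.70,
        "visuo_z": 0.80,
        "hippo_tiv": 0.55,
        "ad_sig_thickness": 0.55,
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Slopes are unitless standardized effects on the latent scale; noise SDs
    are per observed variable on that variable's latent input scale.
    """

    n_participants: int = 400
    frac_impaired: float = 0.45
    age_mean: float = 70.0
    age_sd: float = 8.0
    apoe_prevalence: float = 0.45
    # latent cascade
    abeta_load_slope: float = 10.0
    abeta_mid: float = 0.35
    aggregated_lag: float = 0.30
    entorhinal_advance: float = 0.08
    apoe_abeta_logit: float = 1.5
    # soluble-tau (state) model
    soluble_from_abeta: float = 0.80
    soluble_from_age: float = 0.25
    soluble_from_apoe: float = 0.0  # APOE acts on amyloid burden; no direct soluble shift
    soluble_noise_sd: float = 0.18
    # downstream (late) model
    cognition_from_aggregated: float = 0.70
    thickness_from_aggregated: float = 0.60
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    # censoring / missingness
    plasma_detection_limit: float = 1.4
    plasma_lowest_measurable: float | None = None  # defaults to the detection limit
    missing_rate_mcar: float = 0.05
    dementia_frac_of_impaired: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_impaired", "apoe_prevalence", "missing_rate_mcar",
                     "dementia_frac_of_impaired"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        bad = [k for k, v in self.noise_sd.items() if v <= 0]
        if bad or self.soluble_noise_sd <= 0:
            raise ValueError(f"noise SDs must be positive (bad: {bad or 'soluble_noise_sd'})")
        if self.plasma_detection_limit <= 0:
            raise ValueError("plasma_detection_limit must be positive")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """The generator's true structure, kept for recovery tests.

    ``effects[feature][modality]`` is the configured standardized partial
    effect linking the feature to the FLUID (soluble) or PET (aggregated)
    latent; ``stage`` holds the per-participant latent disease stage in
    [0, 1], ``abeta``/``aggregated`` the latent burdens.
    """

    effects: dict[str, dict[str, float]]
    stage: np.ndarray
    abeta: np.ndarray
    soluble: np.ndarray
    aggregated: np.ndarray

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("stage", "abeta", "soluble", "aggregated"):
            d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        for k in ("stage", "abeta", "soluble", "aggregated"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a complete synthetic participant table plus its ground truth.

    Deterministic given ``config.seed``. The returned table has no missing
    cells; apply :func:`censor_plasma` and :func:`apply_missingness` to add
    detection-limit censoring and missingness.
    """
    cfg = config
    n = cfg.n_participants
    rng = np.random.default_rng([cfg.seed, 0])

    impaired = rng.random(n) < cfg.frac_impaired
    group = np.where(impaired, IMPAIRED, CU)
    # latent stage: impaired participants sit higher on the disease axis
    stage = np.where(impaired, rng.beta(5.0, 2.0, n), rng.beta(2.0, 5.0, n))

    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    age_z = (age - cfg.age_mean) / cfg.age_sd
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    education = np.clip(np.round(rng.normal(12.0, 3.5, n)), 6, 22)
    apoe4 = (rng.random(n) < cfg.apoe_prevalence).astype(int)

    # early sigmoid: amyloid burden, shifted up in APOE e4 carriers
    abeta = _sigmoid(cfg.abeta_load_slope * (stage - cfg.abeta_mid)
                     + cfg.apoe_abeta_logit * apoe4)
    abeta_c = 2.0 * abeta - 1.0
    # late sigmoids: aggregated tau, entorhinal slightly earlier than meta-ROI
    agg_mid = cfg.abeta_mid + cfg.aggregated_lag
    agg_meta = _sigmoid(cfg.abeta_load_slope * (stage - agg_mid))
    agg_ento = _sigmoid(cfg.abeta_load_slope * (stage - (agg_mid - cfg.entorhinal_advance)))
    t_meta_c = 2.0 * agg_meta - 1.0
    t_ento_c = 2.0 * agg_ento - 1.0

    soluble = (cfg.soluble_from_abeta * abeta_c
               + cfg.soluble_from_age * age_z
               + cfg.soluble_from_apoe * (apoe4 - cfg.apoe_prevalence)
               + rng.normal(0.0, cfg.soluble_noise_sd, n))

    nz = cfg.noise_sd

    def conc(scale: float, shape: float, key: str) -> np.ndarray:
        # log-affine transform keeps concentrations positive and right-skewed
        return scale * np.exp(shape * (soluble + rng.normal(0.0, nz[key], n)))

    csf_ptau181 = conc(55.0, 0.85, "csf_ptau181")
    csf_ptau217 = conc(90.0, 1.10, "csf_ptau217")
    plasma_ptau181 = conc(11.0, 0.55, "plasma_ptau181")
    plasma_ptau217 = conc(2.4, 0.90, "plasma_ptau217")

    taupet_meta = 1.47 + 0.27 * (t_meta_c + rng.normal(0.0, nz["taupet_meta"], n))
    taupet_ento = 1.55 + 0.30 * (t_ento_c + rng.normal(0.0, nz["taupet_entorhinal"], n))

    csf_ab4240 = 0.095 - 0.050 * abeta + rng.normal(0.0, nz["csf_ab4240"], n)
    csf_ab4240 = np.clip(csf_ab4240, 0.01, None)
    amyloid_pet = 1.15 + 0.75 * abeta + rng.normal(0.0, nz["amyloid_pet"], n)

    mmse = np.clip(np.round(29.0 - 7.0 * agg_meta + rng.normal(0.0, nz["mmse"], n)), 0, 30)
    cog = cfg.cognition_from_aggregated
    mem_z = -cog * t_meta_c + rng.normal(0.0, nz["mem_z"], n)
    lang_z = -0.85 * cog * t_meta_c + rng.normal(0.0, nz["lang_z"], n)
    exec_z = -0.90 * cog * t_meta_c + rng.normal(0.0, nz["exec_z"], n)
    visuo_z = -0.70 * cog * t_meta_c + rng.normal(0.0, nz["visuo_z"], n)

    thick = cfg.thickness_from_aggregated
    hippo_tiv = 2.45 + 0.30 * (-0.85 * thick * t_meta_c
                               + rng.normal(0.0, nz["hippo_tiv"], n))
    ad_sig_thickness = 2.60 + 0.20 * (-thick * t_meta_c
                                      + rng.normal(0.0, nz["ad_sig_thickness"], n))

    # ground-truth amyloid status thresholds the noise-free latent burden
    abeta_status = np.where(
        cfg.abeta_load_slope * (stage - cfg.abeta_mid) + cfg.apoe_abeta_logit * apoe4 > 0,
        "POS", "NEG")

    # hidden dementia sub-flag: the most advanced impaired participants;
    # drives structural amyloid-PET missingness only
    dementia = np.zeros(n, dtype=bool)
    if impaired.any() and cfg.dementia_frac_of_impaired > 0:
        d_imp = stage[impaired]
        q = np.quantile(d_imp, 1.0 - cfg.dementia_frac_of_impaired)
        dementia[impaired] = stage[impaired] > q

    table = pd.DataFrame({
        "id": [f"P{i:05d}" for i in range(n)],
        "group": group,
        "dementia": dementia,
        "age": age,
        "sex": sex,
        "education": education,
        "apoe4": apoe4,
        "csf_ab4240": csf_ab4240,
        "amyloid_pet": amyloid_pet,
        "abeta_status": abeta_status,
        "csf_ptau181": csf_ptau181,
        "csf_ptau217": csf_ptau217,
        "plasma_ptau181": plasma_ptau181,
        "plasma_ptau217": plasma_ptau217,
        "taupet_entorhinal": taupet_ento,
        "taupet_meta": taupet_meta,
        "mmse": mmse,
        "mem_z": mem_z,
        "lang_z": lang_z,
        "exec_z": exec_z,
        "visuo_z": visuo_z,
        "hippo_tiv": hippo_tiv,
        "ad_sig_thickness": ad_sig_thickness,
    })

    effects = {
        "abeta": {"FLUID": cfg.soluble_from_abeta, "PET": 0.0},
        "age": {"FLUID": cfg.soluble_from_age, "PET": 0.0},
        "apoe4": {"FLUID": cfg.soluble_from_apoe, "PET": 0.0},
        "cognition": {"FLUID": 0.0, "PET": cfg.cognition_from_aggregated},
        "thickness": {"FLUID": 0.0, "PET": cfg.thickness_from_aggregated},
    }
    truth = GroundTruth(effects=effects, stage=stage, abeta=abeta,
                        soluble=soluble, aggregated=agg_meta)
    return table, truth


def censor_plasma(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Apply the plasma p-tau217 assay detection limit.

    Values below the limit are replaced by the lowest measurable value
    (defaulting to the limit itself). The number of censored rows is logged
    and recorded in ``table.attrs['plasma_censored_n']``.
    """
    if config.plasma_detection_limit <= 0:
        raise ValueError("plasma_detection_limit must be positive")
    lowest = (config.plasma_lowest_measurable
              if config.plasma_lowest_measurable is not None
              else config.plasma_detection_limit)
    out = table.copy()
    below = out["plasma_ptau217"].notna() & (out["plasma_ptau217"] < config.plasma_detection_limit)
    out.loc[below, "plasma_ptau217"] = lowest
    out.attrs = dict(table.attrs)
    out.attrs["plasma_censored_n"] = int(below.sum())
    out.attrs["plasma_censored_ids"] = out.loc[below, "id"].tolist()
    return out


def apply_missingness(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Introduce MCAR missingness plus structural amyloid-PET missingness.

    Cells of the imputable columns are deleted completely at random at rate
    ``missing_rate_mcar``; amyloid PET is set missing for every participant
    with the dementia flag (the scan is never acquired in dementia, so these
    cells are structurally missing and must not be imputed). Identifiers,
    group, amyloid status and demographics are never deleted.
    """
    if not 0.0 <= config.missing_rate_mcar <= 1.0:
        raise ValueError("missing_rate_mcar must be in [0, 1]")
    rng = np.random.default_rng([config.seed, 1])
    out = table.copy()
    if config.missing_rate_mcar > 0:
        for col in IMPUTABLE_COLUMNS:
            mask = rng.random(len(out)) < config.missing_rate_mcar
            out.loc[mask, col] = np.nan
    if "dementia" in out.columns:
        out.loc[out["dementia"].astype(bool), "amyloid_pet"] = np.nan
    out.attrs = dict(table.attrs)
    out.attrs["structural_missing"] = {"amyloid_pet": "dementia"}
    return out


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a participant table as CSV (header row, empty cell = missing)."""
    table.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a participant table written by :func:`write_cohort_csv`."""
    # round_trip parsing keeps cached CSV stages bit-identical to in-memory ones
    df = pd.read_csv(path, float_precision="round_trip")
    if "dementia" in df.columns:
        df["dementia"] = df["dementia"].astype(bool)
    return df
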