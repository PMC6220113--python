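"""Seeded synthetic cohorts emulating a longitudinal breast-cancer study.

The generator reproduces the *design* of a 60-patient serum metabolomics
study -- three sampling timepoints (baseline, 6 and 12 months after
surgery), a chemotherapy / no-chemotherapy split, weight-gain labels, a
30-signal NMR (MRS) block, a 188-metabolite targeted-MS block with
realistic quality problems (below-LOD censoring, missingness,
instrumental spikes), a 105-variable lipoprotein subfraction panel and
frequency-domain 1-D spectra -- with every injected feature recorded in a
ground-truth ledger so downstream stages are testable without any
external data.

Concentrations are log-normal: for patient *i*, timepoint *t* and
variable *j*,

    log x_ijt = log mu_j + b_ij + delta_j(group_i, t) + e_ijt,

with per-(patient, variable) random intercepts ``b`` and residuals ``e``
whose variances are set from the configured intraclass correlation
(``icc``) and total log-scale standard deviation (``sigma_log``).
Group-by-time effects ``delta`` are additive on the natural-log scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats

from .containers import MetaboliteMatrix, SpectrumSet, validate_clinical
from .errors import ConfigurationError
from . import nmr

WEIGHT_GAIN_THRESHOLD_KG = 1.5

# ---------------------------------------------------------------------------
# measurement panels
# ---------------------------------------------------------------------------

_ACYLCARNITINES = [
    "C0", "C2", "C3", "C3:1", "C3-OH", "C4", "C4:1", "C4-OH", "C5", "C5:1",
    "C5-OH", "C5-DC", "C6", "C6:1", "C7-DC", "C8", "C8:1", "C9", "C10",
    "C10:1", "C10:2", "C12", "C12:1", "C12-DC", "C14", "C14:1", "C14:2",
    "C14:1-OH", "C14:2-OH", "C16", "C16:1", "C16:2", "C16-OH", "C16:1-OH",
    "C16:2-OH", "C18", "C18:1", "C18:2", "C18:1-OH", "C18:2-OH",
]
_AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr",
    "Val",
]
_BIOGENIC_AMINES = [
    "ADMA", "alpha-AAA", "Ac-Orn", "Carnosine", "Creatinine (MS)", "DOPA",
    "Dopamine", "Histamine", "Kynurenine", "Met-SO", "Nitro-Tyr", "OH-Pro",
    "PEA", "Putrescine", "Sarcosine", "SDMA", "Serotonin", "Spermidine",
    "Spermine", "Taurine", "total DMA",
]
_PC_AA_CHAINS = [
    "C24:0", "C26:0", "C28:1", "C30:0", "C30:2", "C32:0", "C32:1", "C32:2",
    "C32:3", "C34:1", "C34:2", "C34:3", "C34:4", "C36:0", "C36:1", "C36:2",
    "C36:3", "C36:4", "C36:5", "C36:6", "C38:0", "C38:1", "C38:3", "C38:4",
    "C38:5", "C38:6", "C40:1", "C40:2", "C40:3", "C40:4", "C40:5", "C40:6",
    "C42:0", "C42:1", "C42:2", "C42:4", "C42:5", "C42:6",
]
_PC_AE_CHAINS = [
    "C30:0", "C30:1", "C30:2", "C32:1", "C32:2", "C34:0", "C34:1", "C34:2",
    "C34:3", "C36:0", "C36:1", "C36:2", "C36:3", "C36:4", "C36:5", "C38:0",
    "C38:1", "C38:2", "C38:3", "C38:4", "C38:5", "C38:6", "C40:1", "C40:2",
    "C40:3", "C40:4", "C40:5", "C40:6", "C42:0", "C42:1", "C42:2", "C42:3",
    "C42:4", "C42:5", "C44:3", "C44:4", "C44:5", "C44:6",
]
_LYSO_PC_CHAINS = [
    "C14:0", "C16:0", "C16:1", "C17:0", "C18:0", "C18:1", "C18:2", "C20:3",
    "C20:4", "C24:0", "C26:0", "C26:1", "C28:0", "C28:1",
]
_SPHINGOLIPIDS = [
    "SM (OH) C14:1", "SM (OH) C16:1", "SM (OH) C22:1", "SM (OH) C22:2",
    "SM (OH) C24:1", "SM C16:0", "SM C16:1", "SM C18:0", "SM C18:1",
    "SM C20:2", "SM C22:3", "SM C24:0", "SM C24:1", "SM C26:0", "SM C26:1",
]


def ms_panel() -> pd.DataFrame:
    """The 188-metabolite targeted-MS panel (name -> chemical class)."""
    rows = []
    rows += [(n, "acylcarnitine") for n in _ACYLCARNITINES]
    rows += [(n, "amino_acid") for n in _AMINO_ACIDS]
    rows += [(n, "biogenic_amine") for n in _BIOGENIC_AMINES]
    rows += [("H1", "hexose")]
    rows += [(f"PC aa {c}", "phosphatidylcholine") for c in _PC_AA_CHAINS]
    rows += [(f"PC ae {c}", "phosphatidylcholine") for c in _PC_AE_CHAINS]
    rows += [(f"lysoPC a {c}", "lysophosphatidylcholine") for c in _LYSO_PC_CHAINS]
    rows += [(n, "sphingolipid") for n in _SPHINGOLIPIDS]
    panel = pd.DataFrame(rows, columns=["name", "var_class"]).set_index("name")
    assert len(panel) == 188, f"MS panel has {len(panel)} names, expected 188"
    return panel


# Lipoprotein subfraction grammar: density-ordered subfractions of VLDL
# (V1..V5; VLDL6 excluded for poor reliability), IDL (ID), LDL (L1..L6) and
# HDL (H1..H4) plus total plasma (TP); contents are triglycerides (TG),
# cholesterol (CH), free cholesterol (FC), phospholipids (PL) and
# apolipoproteins A1/A2/B (A1, A2, AB).  ApoA is not resolved for VLDL
# subfractions and apoB is absent from HDL, which yields exactly 105 codes.
_LIPO_PREFIXES = ["TP"] + [f"V{i}" for i in range(1, 6)] + ["ID"] + [
    f"L{i}" for i in range(1, 7)
] + [f"H{i}" for i in range(1, 5)]
_LIPO_CONTENTS = ["TG", "CH", "FC", "PL", "A1", "A2", "AB"]


def lipoprotein_panel() -> list[str]:
    """The 105 four-letter lipoprotein subfraction codes."""
    names = []
    for prefix in _LIPO_PREFIXES:
        for content in _LIPO_CONTENTS:
            if prefix.startswith("V") and content in ("A1", "A2"):
                continue
            if prefix.startswith("H") and content == "AB":
                continue
            names.append(prefix + content)
    assert len(names) == 105, f"lipoprotein panel has {len(names)} names"
    return names


def _lipo_class(name: str) -> str:
    return {"T": "TP", "V": "VLDL", "I": "IDL", "L": "LDL", "H": "HDL"}[name[0]]


# peaks per MRS metabolite: (center ppm, relative area, Lorentzian HWHM)
MRS_PEAK_TABLE: dict[str, list[tuple[float, float, float]]] = {
    "lipid1": [(0.840, 0.6, 0.012), (0.865, 0.4, 0.012)],
    "leucine": [(0.955, 0.5, 0.0025), (0.965, 0.5, 0.0025)],
    "isoleucine": [(1.010, 1.0, 0.0025)],
    "valine": [(1.060, 0.5, 0.0025), (1.070, 0.5, 0.0025)],
    "2-methylglutarate": [(1.125, 1.0, 0.0025)],
    "3-hydroxybutyrate": [(1.200, 1.0, 0.0025)],
    "lactate": [(1.3250, 0.375, 0.0022), (1.3375, 0.375, 0.0022), (4.115, 0.25, 0.0022)],
    "alanine": [(1.4580, 0.5, 0.0025), (1.4700, 0.5, 0.0025)],
    "lipid2": [(1.575, 1.0, 0.010)],
    "lysine": [(1.720, 1.0, 0.003)],
    "ornithine": [(1.800, 1.0, 0.003)],
    "acetate": [(1.920, 1.0, 0.002)],
    "glutamine+glutamate": [(2.080, 1.0, 0.004)],
    "methionine": [(2.140, 1.0, 0.0025)],
    "acetoacetate": [(2.270, 1.0, 0.002)],
    "glutamate": [(2.340, 1.0, 0.003)],
    "pyruvate": [(2.410, 1.0, 0.002)],
    "glutamine": [(2.470, 1.0, 0.003)],
    "citrate": [(2.560, 0.5, 0.003), (2.640, 0.5, 0.003)],
    "unknown": [(2.820, 1.0, 0.0025)],
    "creatine": [(3.030, 0.6, 0.002), (3.930, 0.4, 0.002)],
    "proline betaine": [(3.110, 1.0, 0.002)],
    "dimethyl sulfone": [(3.170, 1.0, 0.002)],
    "glucose": [(3.410, 0.35, 0.003), (3.440, 0.30, 0.003), (3.475, 0.35, 0.003)],
    "glycine": [(3.560, 1.0, 0.002)],
    "creatinine": [(4.060, 1.0, 0.002)],
    "tyrosine": [(6.900, 1.0, 0.0025)],
    "histidine": [(7.070, 1.0, 0.0025)],
    "phenylalanine": [(7.350, 0.5, 0.003), (7.390, 0.5, 0.003)],
    "formate": [(8.450, 1.0, 0.002)],
}


def mrs_panel() -> list[str]:
    """The 30 MRS metabolite names, in integration-table order."""
    return [name for name, _, _ in nmr._DEFAULT_REGIONS]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class EffectSpec(BaseModel):
    """A planted group-by-time log-fold-change on one variable."""

    variable_name: str
    group: Literal["chemo", "no_chemo", "gainer", "all"]
    timepoint: int
    log_fold_change: float


class SpectraConfig(BaseModel):
    """Rendering parameters for the synthetic 1-D spectra."""

    n_points: int = Field(32768, ge=512)
    ppm_min: float = -0.5
    ppm_max: float = 10.0
    noise_sd: float = 0.3
    baseline_amplitude: float = 4.0
    water_area: float = 30.0
    shift_sd: float = 0.015
    shift_max: float = 0.045
    area_scale: float = 1.0


def _default_effects() -> list[EffectSpec]:
    # kynurenine rises ~38% in chemotherapy recipients and ~25% in
    # non-recipients six months after surgery
    return [
        EffectSpec(variable_name="Kynurenine", group="chemo", timepoint=6,
                   log_fold_change=math.log(1.38)),
        EffectSpec(variable_name="Kynurenine", group="no_chemo", timepoint=6,
                   log_fold_change=math.log(1.25)),
    ]


class CohortConfig(BaseModel):
    """Design constants and noise model of the synthetic cohort.

    Defaults mirror the emulated study: 60 patients, 35 of whom receive
    chemotherapy; 52 with a 6-month weight measurement, 17 of those
    gaining >= 1.5 kg; MS data for 53 patients at baseline and 6 months
    with 48 of 188 metabolites failing the missing/LOD rule.
    """

    seed: int
    n_patients: int = Field(60, ge=4)
    chemo_fraction: float = Field(35 / 60, ge=0.0, le=1.0)
    gainer_fraction: float = Field(17 / 52, ge=0.0, le=1.0)
    weight_followup_missing: int = Field(8, ge=0)
    timepoints: list[int] = Field(default_factory=lambda: [0, 6, 12])
    icc: float = Field(0.5, ge=0.0, lt=1.0)
    sigma_log: float = Field(0.4, ge=0.0)
    missing_rate: float = Field(0.02, ge=0.0, le=1.0)
    lod_quantile: float = Field(0.02, ge=0.0, le=1.0)
    spike_rate: float = Field(0.005, ge=0.0, le=1.0)
    ms_timepoints: list[int] = Field(default_factory=lambda: [0, 6])
    ms_missing_patients: int = Field(7, ge=0)
    n_ms_low_quality: int = Field(48, ge=0)
    ms_low_quality_names: Optional[list[str]] = None
    lod_quantile_low_quality: float = Field(0.5, ge=0.0, le=1.0)
    n_qc_replicates: int = Field(20, ge=0)
    qc_cv: float = Field(0.06, ge=0.0)
    qc_cv_high: float = Field(0.22, ge=0.0)
    n_qc_high_cv: int = Field(5, ge=0)
    effect_registry: list[EffectSpec] = Field(default_factory=_default_effects)
    spectra: SpectraConfig = Field(default_factory=SpectraConfig)

    @field_validator("timepoints", "ms_timepoints")
    @classmethod
    def _timepoints_increasing(cls, v: list[int]) -> list[int]:
        if not v or v[0] != 0:
            raise ValueError("timepoints must start at 0")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("timepoints must be strictly increasing")
        return v

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if self.weight_followup_missing >= self.n_patients:
            raise ValueError("weight_followup_missing must leave observed patients")
        if self.ms_missing_patients >= self.n_patients:
            raise ValueError("ms_missing_patients must leave observed patients")
        if not set(self.ms_timepoints) <= set(self.timepoints):
            raise ValueError("ms_timepoints must be a subset of timepoints")
        for eff in self.effect_registry:
            if eff.timepoint not in self.timepoints or eff.timepoint == 0:
                raise ValueError(
                    f"effect on {eff.variable_name}: timepoint {eff.timepoint} "
                    "must be a configured non-baseline timepoint"
                )
        return self


def load_config(path: str) -> CohortConfig:
    """Read and validate a JSON or YAML cohort configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return CohortConfig(**doc)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(str(exc)) from exc


def config_schema() -> dict:
    """JSON schema the configuration document is validated against."""
    return CohortConfig.model_json_schema()


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the clinical table (one row per patient).

    Group sizes follow ``round(n * fraction)`` exactly.  Weight-gainer
    status is assigned first and the 6-month weight change drawn from the
    matching side of the 1.5 kg threshold, so the weight-gain label
    derived from the table reproduces the assignment.
    """
    rng = _rng(config, 0)
    n = config.n_patients
    ids = [f"P{i + 1:03d}" for i in range(n)]

    n_chemo = _round_half_up(n * config.chemo_fraction)
    chemo = np.zeros(n, dtype=bool)
    chemo[rng.permutation(n)[:n_chemo]] = True

    p_pre = np.where(chemo, 14 / 35, 4 / 25)
    menopause = np.where(rng.random(n) < p_pre, "pre", "post")

    age = np.where(
        chemo,
        np.clip(rng.normal(52.8, 7.0, n), 38, 69),
        np.clip(rng.normal(58.9, 5.5, n), 46, 68),
    ).round(0)

    endo_levels = np.array(["none", "tamoxifen", "AI", "AI+goserelin"])
    endocrine = np.empty(n, dtype=object)
    for is_chemo, probs in ((True, [4, 13, 17, 1]), (False, [16, 1, 7, 1])):
        idx = np.flatnonzero(chemo == is_chemo)
        p = np.asarray(probs, dtype=float)
        endocrine[idx] = rng.choice(endo_levels, size=idx.size, p=p / p.sum())

    radiation = rng.random(n) < np.where(chemo, 25 / 35, 22 / 25)
    herceptin = rng.random(n) < np.where(chemo, 3 / 35, 0.0)

    surgery_levels = np.array(["BCS", "mastectomy", "PRE"])
    surgery = np.empty(n, dtype=object)
    for is_chemo, probs in ((True, [22, 12, 1]), (False, [21, 3, 1])):
        idx = np.flatnonzero(chemo == is_chemo)
        p = np.asarray(probs, dtype=float)
        surgery[idx] = rng.choice(surgery_levels, size=idx.size, p=p / p.sum())

    weight0 = np.clip(rng.normal(70.8, 11.0, n), 48.0, 98.0).round(1)

    # follow-up weights: a fixed number of patients miss the 6-month visit
    missing_idx = rng.permutation(n)[: config.weight_followup_missing]
    observed = np.setdiff1d(np.arange(n), missing_idx)
    n_gain = _round_half_up(observed.size * config.gainer_fraction)
    gain_idx = rng.permutation(observed)[:n_gain]
    is_gainer = np.zeros(n, dtype=bool)
    is_gainer[gain_idx] = True

    delta6 = np.full(n, np.nan)
    delta6[observed] = WEIGHT_GAIN_THRESHOLD_KG - 0.1 - np.abs(
        rng.normal(0.0, 2.2, observed.size)
    )
    delta6[gain_idx] = WEIGHT_GAIN_THRESHOLD_KG + np.abs(rng.normal(0.0, 2.0, gain_idx.size))
    weight6 = np.round(weight0 + delta6, 1)
    # rounding to 0.1 kg must not move a change across the 1.5 kg threshold
    gained = (weight6 - weight0) >= WEIGHT_GAIN_THRESHOLD_KG
    fix = np.flatnonzero(is_gainer & ~gained)
    weight6[fix] = np.round(weight0[fix] + WEIGHT_GAIN_THRESHOLD_KG, 1)
    fix = np.flatnonzero(~is_gainer & gained)
    weight6[fix] = np.round(weight0[fix] + WEIGHT_GAIN_THRESHOLD_KG - 0.2, 1)
    weight12 = np.round(weight6 + rng.normal(0.0, 1.5, n), 1)

    hba1c = np.clip(rng.normal(5.7, 0.35, n), 4.5, 6.5).round(1)
    tc = np.clip(rng.normal(5.4, 0.9, n), 3.5, 8.0).round(2)
    hdl = np.clip(rng.normal(1.5, 0.33, n), 0.8, 2.8)
    hdl = np.minimum(hdl, 0.6 * tc - 0.05).round(2)
    tg = np.clip(np.exp(rng.normal(math.log(1.15), 0.35, n)), 0.4, 4.4).round(2)

    table = pd.DataFrame(
        {
            "patient_id": ids,
            "age": age,
            "menopausal_status": menopause,
            "chemo": chemo,
            "endocrine": endocrine,
            "radiation": radiation,
            "herceptin": herceptin,
            "surgery": surgery,
            "weight_kg_0": weight0,
            "weight_kg_6": weight6,
            "weight_kg_12": np.where(np.isnan(weight6), np.nan, weight12),
            "hba1c": hba1c,
            "tc": tc,
            "hdl": hdl,
            "tg": tg,
        }
    )
    return validate_clinical(table)


def _gainer_status(clinical: pd.DataFrame) -> pd.Series:
    """gainer / non_gainer / unknown from the 0- and 6-month weights."""
    delta = clinical["weight_kg_6"] - clinical["weight_kg_0"]
    out = pd.Series("unknown", index=clinical.index, dtype=object)
    out[delta >= WEIGHT_GAIN_THRESHOLD_KG] = "gainer"
    out[delta < WEIGHT_GAIN_THRESHOLD_KG] = "non_gainer"
    out.index = clinical["patient_id"].to_numpy()
    return out


def _group_mask(clinical: pd.DataFrame, group: str) -> pd.Series:
    """Boolean membership per patient_id for an effect group."""
    if group == "all":
        mask = pd.Series(True, index=clinical.index)
    elif group == "chemo":
        mask = clinical["chemo"].astype(bool)
    elif group == "no_chemo":
        mask = ~clinical["chemo"].astype(bool)
    elif group == "gainer":
        mask = (_gainer_status(clinical) == "gainer").to_numpy()
        mask = pd.Series(mask, index=clinical.index)
    else:  # pragma: no cover - guarded by pydantic
        raise ConfigurationError(f"unknown effect group {group!r}")
    mask.index = clinical["patient_id"].to_numpy()
    return mask


# ---------------------------------------------------------------------------
# metabolite blocks
# ---------------------------------------------------------------------------


@dataclass
class MetaboliteBlocks:
    """Simulated MRS and MS blocks with their ground-truth ledger."""

    mrs: MetaboliteMatrix
    ms: MetaboliteMatrix
    truth: dict = field(default_factory=dict)


def _simulate_block(
    *,
    clinical: pd.DataFrame,
    config: CohortConfig,
    names: list[str],
    classes: list[str],
    platform: str,
    mu: np.ndarray,
    timepoints: list[int],
    patient_ids: list[str],
    lod_quantiles: np.ndarray,
    missing_rate: float,
    spike_rate: float,
    rng: np.random.Generator,
    effects: list[EffectSpec],
) -> tuple[MetaboliteMatrix, dict]:
    n_pat, n_t, n_var = len(patient_ids), len(timepoints), len(names)
    sigma = config.sigma_log
    sd_b = sigma * math.sqrt(config.icc)
    sd_e = sigma * math.sqrt(1.0 - config.icc)

    log_mu = np.log(mu)
    b = rng.normal(0.0, 1.0, (n_pat, n_var)) * sd_b
    e = rng.normal(0.0, 1.0, (n_pat, n_t, n_var)) * sd_e
    log_x = log_mu[None, None, :] + b[:, None, :] + e

    effect_log: list[dict] = []
    pid_index = {p: i for i, p in enumerate(patient_ids)}
    for eff in effects:
        if eff.variable_name not in names:
            continue
        j = names.index(eff.variable_name)
        t_idx = timepoints.index(eff.timepoint) if eff.timepoint in timepoints else None
        if t_idx is None:
            continue
        members = _group_mask(clinical, eff.group)
        rows = [pid_index[p] for p in patient_ids if members.get(p, False)]
        log_x[rows, t_idx, j] += eff.log_fold_change
        effect_log.append(
            {
                "variable": eff.variable_name,
                "group": eff.group,
                "timepoint": eff.timepoint,
                "log_fold_change": eff.log_fold_change,
                "n_patients": len(rows),
            }
        )

    values = np.exp(log_x).reshape(n_pat * n_t, n_var)
    sample_meta = pd.DataFrame(
        {
            "patient_id": np.repeat(patient_ids, n_t),
            "timepoint_months": np.tile(timepoints, n_pat),
        }
    )

    # limits of detection from the configured baseline quantile
    lod = np.where(
        lod_quantiles > 0,
        np.exp(log_mu + stats.norm.ppf(np.clip(lod_quantiles, 1e-12, 1 - 1e-12)) * sigma),
        0.0,
    )
    censored = values < lod[None, :]

    observed = ~censored
    missing = observed & (rng.random(values.shape) < missing_rate)
    observed = observed & ~missing

    # instrumental spikes: huge values well beyond the 100x-median rule
    spike_mask = observed & (rng.random(values.shape) < spike_rate)
    medians = np.full(n_var, np.nan)
    for j in range(n_var):
        col = values[observed[:, j] & ~spike_mask[:, j], j]
        if col.size:
            medians[j] = np.median(col)
    spike_factor = rng.uniform(150.0, 500.0, values.shape)
    values = np.where(spike_mask, medians[None, :] * spike_factor, values)

    out = values.copy()
    out[censored | missing] = np.nan

    def _cells(mask: np.ndarray) -> list[list]:
        rr, cc = np.nonzero(mask)
        return [
            [sample_meta.loc[r, "patient_id"], int(sample_meta.loc[r, "timepoint_months"]), names[c]]
            for r, c in zip(rr.tolist(), cc.tolist())
        ]

    truth = {
        "platform": platform,
        "mu": dict(zip(names, mu.tolist())),
        "icc": config.icc,
        "sigma_log": sigma,
        "effects": effect_log,
        "censored": _cells(censored),
        "missing": _cells(missing),
    }
    # spikes with their injected value
    rr, cc = np.nonzero(spike_mask)
    truth["spikes"] = [
        [
            sample_meta.loc[r, "patient_id"],
            int(sample_meta.loc[r, "timepoint_months"]),
            names[c],
            float(values[r, c]),
        ]
        for r, c in zip(rr.tolist(), cc.tolist())
    ]

    var_meta = pd.DataFrame(
        {"platform": platform, "var_class": classes, "lod": lod}, index=pd.Index(names)
    )
    matrix = MetaboliteMatrix(
        pd.DataFrame(out, columns=names),
        sample_meta,
        var_meta,
        pd.DataFrame(censored, columns=names),
    )
    return matrix, truth


def simulate_metabolite_matrix(
    clinical: pd.DataFrame, config: CohortConfig
) -> MetaboliteBlocks:
    """Simulate the MRS (30-signal) and MS (188-metabolite) blocks.

    The MRS block covers every patient at every configured timepoint with
    no missingness (integrals always exist).  The MS block covers
    ``n_patients - ms_missing_patients`` patients at the MS timepoints and
    carries the configured censoring, missingness and spikes;
    ``n_ms_low_quality`` of its columns get a high-quantile LOD so they
    fail the downstream >30% missing/LOD rule.
    """
    panel = ms_panel()
    all_names = set(mrs_panel()) | set(panel.index) | set(lipoprotein_panel())
    for eff in config.effect_registry:
        if eff.variable_name not in all_names:
            raise ConfigurationError(f"effect on unknown variable {eff.variable_name!r}")

    patients = clinical["patient_id"].tolist()

    mrs_names = mrs_panel()
    rng_mrs = _rng(config, 1)
    mu_mrs = rng_mrs.uniform(0.7, 1.4, len(mrs_names))
    mrs, truth_mrs = _simulate_block(
        clinical=clinical,
        config=config,
        names=mrs_names,
        classes=["lipid" if n.startswith("lipid") else "small_molecule" for n in mrs_names],
        platform="MRS",
        mu=mu_mrs,
        timepoints=list(config.timepoints),
        patient_ids=patients,
        lod_quantiles=np.zeros(len(mrs_names)),
        missing_rate=0.0,
        spike_rate=0.0,
        rng=rng_mrs,
        effects=config.effect_registry,
    )

    rng_ms = _rng(config, 2)
    ms_names = list(panel.index)
    mu_ms = np.exp(rng_ms.uniform(math.log(5.0), math.log(200.0), len(ms_names)))
    if config.ms_low_quality_names is not None:
        unknown = set(config.ms_low_quality_names) - set(ms_names)
        if unknown:
            raise ConfigurationError(f"unknown low-quality MS names: {sorted(unknown)}")
        low_quality = list(config.ms_low_quality_names)
    else:
        effect_vars = {e.variable_name for e in config.effect_registry}
        candidates = [n for n in ms_names if n not in effect_vars]
        low_quality = list(
            rng_ms.choice(candidates, size=min(config.n_ms_low_quality, len(candidates)),
                          replace=False)
        )
    lod_q = np.where(
        np.isin(ms_names, low_quality), config.lod_quantile_low_quality, config.lod_quantile
    )
    ms_patients = patients[:]
    if config.ms_missing_patients:
        drop = set(rng_ms.choice(patients, size=config.ms_missing_patients, replace=False))
        ms_patients = [p for p in patients if p not in drop]
    ms, truth_ms = _simulate_block(
        clinical=clinical,
        config=config,
        names=ms_names,
        classes=list(panel["var_class"]),
        platform="MS",
        mu=mu_ms,
        timepoints=list(config.ms_timepoints),
        patient_ids=ms_patients,
        lod_quantiles=lod_q,
        missing_rate=config.missing_rate,
        spike_rate=config.spike_rate,
        rng=rng_ms,
        effects=config.effect_registry,
    )
    truth_ms["low_quality_variables"] = sorted(low_quality)
    return MetaboliteBlocks(mrs=mrs, ms=ms, truth={"MRS": truth_mrs, "MS": truth_ms})


def simulate_qc_replicates(config: CohortConfig) -> MetaboliteMatrix:
    """Repeated measurements of one pooled QC sample for the MS panel.

    Most metabolites get the baseline analytical CV; ``n_qc_high_cv`` of
    them get the elevated CV, mimicking a handful of borderline assays.
    """
    panel = ms_panel()
    rng = _rng(config, 5)
    names = list(panel.index)
    mu = np.exp(rng.uniform(math.log(5.0), math.log(200.0), len(names)))
    cv = np.full(len(names), config.qc_cv)
    high = rng.choice(len(names), size=config.n_qc_high_cv, replace=False)
    cv[high] = config.qc_cv_high
    n = config.n_qc_replicates
    values = mu[None, :] * (1.0 + rng.normal(0.0, 1.0, (n, len(names))) * cv[None, :])
    values = np.abs(values)
    sample_meta = pd.DataFrame(
        {"patient_id": [f"QC{i + 1:02d}" for i in range(n)], "timepoint_months": 0}
    )
    var_meta = pd.DataFrame(
        {"platform": "MS", "var_class": list(panel["var_class"]), "lod": 0.0},
        index=pd.Index(names),
    )
    return MetaboliteMatrix(pd.DataFrame(values, columns=names), sample_meta, var_meta)


def simulate_lipoprotein_panel(
    clinical: pd.DataFrame, config: CohortConfig
) -> MetaboliteMatrix:
    """Simulate the 105-variable lipoprotein subfraction panel.

    Correlation structure comes from latent per-sample factors: one
    global lipemia factor plus one factor per lipoprotein class
    (VLDL/IDL/LDL/HDL density axes), so variables within a class
    correlate more strongly than variables in different classes.  Values
    are strictly positive (log-normal).
    """
    names = lipoprotein_panel()
    rng = _rng(config, 3)
    patients = clinical["patient_id"].tolist()
    timepoints = list(config.timepoints)
    n_pat, n_t, n_var = len(patients), len(timepoints), len(names)

    base_mu = {"TG": 1.0, "CH": 1.2, "FC": 0.4, "PL": 1.5, "A1": 1.3, "A2": 0.3, "AB": 0.9}
    prefix_scale = {p: (1.0 if p == "TP" else rng.uniform(0.08, 0.45)) for p in _LIPO_PREFIXES}
    mu = np.array([base_mu[n[2:]] * prefix_scale[n[:2]] for n in names])

    classes = [_lipo_class(n) for n in names]
    class_levels = ["VLDL", "IDL", "LDL", "HDL"]
    # loading of each variable on its class factor; TP loads on all classes
    class_loading = np.zeros((n_var, len(class_levels)))
    for j, cls in enumerate(classes):
        if cls == "TP":
            class_loading[j, :] = 0.5
        else:
            class_loading[j, class_levels.index(cls)] = 1.0

    sigma = config.sigma_log
    sd_b = sigma * math.sqrt(config.icc)
    resid = sigma * math.sqrt(1.0 - config.icc)
    lam_g, lam_c = 0.35, 0.75
    lam_e = math.sqrt(max(0.0, 1.0 - lam_g**2 - lam_c**2))

    b = rng.normal(0.0, sd_b, (n_pat, 1, n_var))
    g = rng.normal(0.0, 1.0, (n_pat, n_t, 1))
    f = rng.normal(0.0, 1.0, (n_pat, n_t, len(class_levels)))
    e = rng.normal(0.0, 1.0, (n_pat, n_t, n_var))
    log_x = (
        np.log(mu)[None, None, :]
        + b
        + resid * (lam_g * g + lam_c * (f @ class_loading.T) + lam_e * e)
    )

    pid_index = {p: i for i, p in enumerate(patients)}
    for eff in config.effect_registry:
        if eff.variable_name not in names:
            continue
        j = names.index(eff.variable_name)
        t_idx = timepoints.index(eff.timepoint)
        members = _group_mask(clinical, eff.group)
        rows = [pid_index[p] for p in patients if members.get(p, False)]
        log_x[rows, t_idx, j] += eff.log_fold_change

    values = np.exp(log_x).reshape(n_pat * n_t, n_var)
    sample_meta = pd.DataFrame(
        {"patient_id": np.repeat(patients, n_t), "timepoint_months": np.tile(timepoints, n_pat)}
    )
    var_meta = pd.DataFrame(
        {"platform": "LIPO", "var_class": classes, "lod": 0.0}, index=pd.Index(names)
    )
    return MetaboliteMatrix(pd.DataFrame(values, columns=names), sample_meta, var_meta)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def ppm_axis(cfg: SpectraConfig) -> np.ndarray:
    """Descending ppm axis (conventional NMR display order)."""
    return np.linspace(cfg.ppm_max, cfg.ppm_min, cfg.n_points)


def render_spectrum(
    areas: dict[str, float],
    shift: float,
    cfg: SpectraConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one spectrum: Lorentzian peaks + water hump + baseline + noise.

    Peak areas are proportional to the supplied concentrations; the whole
    pattern is displaced by ``shift`` ppm (the global referencing offset).
    """
    ppm = ppm_axis(cfg)
    y = np.zeros_like(ppm)
    for name, area in areas.items():
        if name not in MRS_PEAK_TABLE:
            raise ConfigurationError(f"MRS variable {name!r} lacks a peak-table entry")
        for center, rel, gamma in MRS_PEAK_TABLE[name]:
            c = center + shift
            y += (area * cfg.area_scale * rel / math.pi) * gamma / ((ppm - c) ** 2 + gamma**2)
    if cfg.water_area > 0:
        c = 4.73 + shift
        gamma = 0.06
        y += (cfg.water_area / math.pi) * gamma / ((ppm - c) ** 2 + gamma**2)
    if cfg.baseline_amplitude > 0:
        y += cfg.baseline_amplitude * (0.55 + 0.45 * np.sin(2 * math.pi * ppm / 21.0 + 0.7))
    if cfg.noise_sd > 0 and rng is not None:
        y += rng.normal(0.0, cfg.noise_sd, ppm.size)
    return y


def simulate_spectra(matrix: MetaboliteMatrix, config: CohortConfig) -> SpectrumSet:
    """Render spectra for every sample of an MRS concentration block.

    Each sample gets one global chemical-shift offset (recorded in the
    truth ledger) drawn from a clipped normal distribution.
    """
    cfg = config.spectra
    mrs_names = [n for n in matrix.variables if n in MRS_PEAK_TABLE]
    missing = [n for n in matrix.variables if n not in MRS_PEAK_TABLE]
    if missing:
        raise ConfigurationError(f"MRS variables lacking peak-table entries: {missing}")
    rng = _rng(config, 4)
    n = matrix.n_samples
    shifts = np.clip(rng.normal(0.0, cfg.shift_sd, n), -cfg.shift_max, cfg.shift_max)
    intensities = np.empty((n, cfg.n_points))
    truth = []
    for i in range(n):
        conc = {name: float(matrix.values.iloc[i][name]) for name in mrs_names}
        intensities[i] = render_spectrum(conc, shifts[i], cfg, rng)
        truth.append(
            {
                "areas": {k: v * cfg.area_scale for k, v in conc.items()},
                "shift": float(shifts[i]),
            }
        )
    return SpectrumSet(
        ppm_axis(cfg), intensities, matrix.sample_meta.reset_index(drop=True), truth
    )


# ---------------------------------------------------------------------------
# cohort writer
# ---------------------------------------------------------------------------


def write_cohort(
    outdir: str,
    clinical: pd.DataFrame,
    blocks: MetaboliteBlocks,
    lipo: MetaboliteMatrix | None = None,
    spectra: SpectrumSet | None = None,
) -> list[str]:
    """Write clinical table, blocks, truth ledger and spectra as CSV/JSON."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = []
    clin_path = os.path.join(outdir, "clinical.csv")
    clinical.to_csv(clin_path, index=False)
    paths.append(clin_path)
    paths += blocks.mrs.to_csv(os.path.join(outdir, "mrs"))
    paths += blocks.ms.to_csv(os.path.join(outdir, "ms"))
    if lipo is not None:
        paths += lipo.to_csv(os.path.join(outdir, "lipoproteins"))
    truth_path = os.path.join(outdir, "truth.json")
    truth = dict(blocks.truth)
    if spectra is not None:
        paths += spectra.to_csv(os.path.join(outdir, "spectra"))
        truth["spectra"] = spectra.truth
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    paths.append(truth_path)
    return paths
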