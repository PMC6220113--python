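"""Study-shaped orchestration: run every planned comparison and report.

An :class:`AnalysisPlan` lists discriminant comparisons over the three
measurement blocks -- ``MET`` (cleaned MS metabolites joined with the
NMR integrals), ``MRS``, ``MS`` and ``LIPO`` -- using either the
multilevel (paired time-contrast) design or single-timepoint weight-gain
prediction.  :func:`run_full_analysis` executes, for a synthetic cohort
configuration: simulation, spectral preprocessing and integration, MS
quality control, every comparison's multivariate arm (grouped CV +
permutation + VIP), the univariate arm with per-block FDR, and Table-1
style clinical group tests; everything is deterministic given the seed.

The default plan holds ten comparisons mirroring a treatment-response
study: per treatment group (chemotherapy / no chemotherapy) multilevel
models of metabolites and lipoproteins at 6 and 12 months versus
baseline (the 12-month metabolite block is NMR-only, as targeted MS was
measured at baseline and 6 months), plus baseline weight-gain prediction
from both blocks.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cohort import (
    CohortConfig,
    generate_cohort,
    simulate_lipoprotein_panel,
    simulate_metabolite_matrix,
    simulate_qc_replicates,
    simulate_spectra,
)
from .containers import MetaboliteMatrix
from .errors import ConfigurationError
from .msqc import impute_missing_median, run_ms_qc
from .nmr import quantify_spectra
from .opls import (
    build_labeled_dataset,
    build_paired_dataset,
    cross_validate,
    fit_opls_da,
    permutation_test,
    vip_scores,
)
from .univariate import classify_weight_gain, fisher_exact_2x2, two_sample_t, univariate_table

SCHEMA_VERSION = 1

Block = Literal["MET", "MRS", "MS", "LIPO"]
Design = Literal["multilevel_time", "weight_gain_baseline", "weight_gain_6mo"]
Group = Literal["chemo", "no_chemo", "all"]


class Comparison(BaseModel):
    name: str
    block: Block
    design: Design
    group_filter: Group = "all"
    t_ref: int = 0
    t_cmp: Optional[int] = None

    def timepoints_needed(self) -> list[int]:
        if self.design == "multilevel_time":
            if self.t_cmp is None:
                raise ConfigurationError(f"{self.name}: multilevel design needs t_cmp")
            return [self.t_ref, self.t_cmp]
        return [0] if self.design == "weight_gain_baseline" else [6]


class CvSettings(BaseModel):
    n_folds: int = 10
    n_iter: int = 20
    max_orth: int = 3
    unit_variance: bool = True


class PermutationSettings(BaseModel):
    n_perm: int = 1000
    fix_n_orth: Optional[int] = None


class AnalysisPlan(BaseModel):
    """Which comparisons to run and how to validate them."""

    comparisons: list[Comparison]
    cv: CvSettings = Field(default_factory=CvSettings)
    permutation: PermutationSettings = Field(default_factory=PermutationSettings)
    univariate: bool = True


def default_plan(**overrides) -> AnalysisPlan:
    """The ten study-shaped comparisons (see module docstring)."""
    comparisons = []
    for group in ("chemo", "no_chemo"):
        comparisons += [
            Comparison(name=f"{group}_metabolites_6mo", block="MET",
                       design="multilevel_time", group_filter=group, t_cmp=6),
            Comparison(name=f"{group}_lipoproteins_6mo", block="LIPO",
                       design="multilevel_time", group_filter=group, t_cmp=6),
            Comparison(name=f"{group}_metabolites_12mo", block="MRS",
                       design="multilevel_time", group_filter=group, t_cmp=12),
            Comparison(name=f"{group}_lipoproteins_12mo", block="LIPO",
                       design="multilevel_time", group_filter=group, t_cmp=12),
        ]
    comparisons += [
        Comparison(name="weight_gain_metabolites_baseline", block="MET",
                   design="weight_gain_baseline"),
        Comparison(name="weight_gain_lipoproteins_baseline", block="LIPO",
                   design="weight_gain_baseline"),
    ]
    return AnalysisPlan(comparisons=comparisons, **overrides)


@dataclass
class AnalysisReport:
    """JSON-serializable result document with provenance."""

    data: dict

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "AnalysisReport":
        with open(path) as fh:
            return cls(json.load(fh))


def _block_timepoints(matrix: MetaboliteMatrix) -> set[int]:
    return set(matrix.sample_meta["timepoint_months"].tolist())


def validate_plan(plan: AnalysisPlan, blocks: dict[str, MetaboliteMatrix]) -> None:
    for comp in plan.comparisons:
        if comp.block not in blocks:
            raise ConfigurationError(f"{comp.name}: unknown block {comp.block}")
        have = _block_timepoints(blocks[comp.block])
        need = set(comp.timepoints_needed())
        if not need <= have:
            raise ConfigurationError(
                f"{comp.name}: block {comp.block} lacks timepoints {sorted(need - have)}"
            )


def combine_blocks(ms: MetaboliteMatrix, mrs: MetaboliteMatrix) -> MetaboliteMatrix:
    """Join MS and MRS blocks on their common (patient, timepoint) samples."""
    key = ["patient_id", "timepoint_months"]
    left = ms.sample_meta[key].reset_index(drop=True)
    right = mrs.sample_meta[key].reset_index(drop=True)
    li = {tuple(r): i for i, r in enumerate(left.to_numpy())}
    ri = {tuple(r): i for i, r in enumerate(right.to_numpy())}
    common = [k for k in li if k in ri]
    rows_l = [li[k] for k in common]
    rows_r = [ri[k] for k in common]
    values = pd.concat(
        [
            ms.values.iloc[rows_l].reset_index(drop=True),
            mrs.values.iloc[rows_r].reset_index(drop=True),
        ],
        axis=1,
    )
    censored = pd.concat(
        [
            ms.censored.iloc[rows_l].reset_index(drop=True),
            mrs.censored.iloc[rows_r].reset_index(drop=True),
        ],
        axis=1,
    )
    meta = left.iloc[rows_l].reset_index(drop=True)
    var_meta = pd.concat([ms.var_meta, mrs.var_meta])
    return MetaboliteMatrix(values, meta, var_meta, censored)


def _config_hash(config: CohortConfig, plan: AnalysisPlan) -> str:
    doc = json.dumps(
        {"config": config.model_dump(), "plan": plan.model_dump()}, sort_keys=True
    )
    return hashlib.sha256(doc.encode()).hexdigest()


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] & 0x7FFFFFFF)


def run_full_analysis(plan: AnalysisPlan, config: CohortConfig) -> AnalysisReport:
    """Simulate, preprocess, QC, and run every planned comparison."""
    clinical = generate_cohort(config)
    blocks_sim = simulate_metabolite_matrix(clinical, config)
    spectra = simulate_spectra(blocks_sim.mrs, config)
    mrs_measured = quantify_spectra(spectra)
    ms_clean, qc_report = run_ms_qc(blocks_sim.ms, simulate_qc_replicates(config))
    # the multivariate arm needs complete rows; the univariate mixed models
    # below keep the unimputed block
    ms_complete = impute_missing_median(ms_clean)
    lipo = simulate_lipoprotein_panel(clinical, config)

    blocks = {
        "MRS": mrs_measured,
        "MS": ms_complete,
        "LIPO": lipo,
        "MET": combine_blocks(ms_complete, mrs_measured),
    }
    validate_plan(plan, blocks)

    gain = classify_weight_gain(clinical)
    chemo_ids = clinical.loc[clinical["chemo"].astype(bool), "patient_id"].tolist()
    no_chemo_ids = clinical.loc[~clinical["chemo"].astype(bool), "patient_id"].tolist()
    group_patients = {"chemo": chemo_ids, "no_chemo": no_chemo_ids,
                      "all": clinical["patient_id"].tolist()}

    comparisons = {}
    for idx, comp in enumerate(plan.comparisons):
        matrix = blocks[comp.block]
        if comp.design == "multilevel_time":
            dataset = build_paired_dataset(
                matrix, comp.t_ref, comp.t_cmp, patients=group_patients[comp.group_filter]
            )
        else:
            t = 0 if comp.design == "weight_gain_baseline" else 6
            dataset = build_labeled_dataset(
                matrix, gain, t, positive="gainer", negative="non_gainer"
            )
        seed = _child_seed(config.seed, idx + 1)
        perm = permutation_test(
            dataset,
            n_perm=plan.permutation.n_perm,
            max_orth=plan.cv.max_orth,
            n_folds=plan.cv.n_folds,
            n_iter=plan.cv.n_iter,
            seed=seed,
            unit_variance=plan.cv.unit_variance,
            fix_n_orth=plan.permutation.fix_n_orth,
        )
        cv = cross_validate(
            dataset,
            max_orth=plan.cv.max_orth,
            n_folds=plan.cv.n_folds,
            n_iter=plan.cv.n_iter,
            seed=np.random.SeedSequence(seed).spawn(1)[0],
            unit_variance=plan.cv.unit_variance,
        )
        model = fit_opls_da(
            dataset.X, dataset.y, cv.chosen_n_orth,
            unit_variance=plan.cv.unit_variance, variables=dataset.variables,
        )
        vip = vip_scores(model).sort_values(ascending=False)
        comparisons[comp.name] = {
            "block": comp.block,
            "design": comp.design,
            "group_filter": comp.group_filter,
            "t_ref": comp.t_ref,
            "t_cmp": comp.t_cmp,
            "n_patients": int(dataset.n_patients),
            "excluded_patients": list(dataset.excluded_patients),
            "cv": cv.to_dict(),
            "permutation": perm.to_dict(),
            "vip": {k: float(v) for k, v in vip.items()},
        }

    univariate: dict[str, list] = {}
    if plan.univariate:
        for group in ("chemo", "no_chemo"):
            pats = group_patients[group]
            uni_blocks = {"MRS": mrs_measured, "MS": ms_clean, "LIPO": lipo}
            for block, test in (("MRS", "lmm"), ("MS", "lmm"), ("LIPO", "wilcoxon")):
                t_cmp = 6
                table = univariate_table(uni_blocks[block], block, 0, t_cmp, pats, test)
                univariate[f"{group}_{block}_6mo"] = json.loads(
                    table.to_json(orient="records")
                )

    clinical_tests = _clinical_tests(clinical, gain)

    report = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "seed": config.seed,
            "config_hash": _config_hash(config, plan),
            "pmet_version": __version__,
            "created_at": datetime.now(timezone.utc).isoformat(),
        },
        "qc": {
            "n_ms_variables_before": int(blocks_sim.ms.n_variables),
            "n_ms_variables_after": int(ms_clean.n_variables),
            "n_spikes_masked": int(qc_report.table["n_spikes_masked"].fillna(0).sum()),
        },
        "comparisons": comparisons,
        "univariate": univariate,
        "clinical_tests": clinical_tests,
    }
    return AnalysisReport(report)


def _crosstab(a: pd.Series, b: pd.Series) -> list[list[int]]:
    tab = pd.crosstab(a, b)
    return tab.to_numpy().tolist()


def _clinical_tests(clinical: pd.DataFrame, gain: pd.Series) -> dict:
    """Baseline group comparisons: t-tests and Fisher's exact tests."""
    chemo = clinical["chemo"].astype(bool).map({True: "chemo", False: "no_chemo"})
    out: dict[str, dict] = {}
    for var in ("age", "weight_kg_0", "hba1c"):
        res = two_sample_t(clinical[var].to_numpy(), chemo.to_numpy())
        out[f"{var}_by_chemo_ttest"] = {"statistic": res.statistic, "p": res.p_value}
    for var in ("menopausal_status", "radiation", "herceptin"):
        tab = pd.crosstab(clinical[var], chemo)
        if tab.shape == (2, 2):
            res = fisher_exact_2x2(tab.to_numpy())
            out[f"{var}_by_chemo_fisher"] = {
                "odds_ratio": res.odds_ratio, "p": res.p_value,
                "table": tab.to_numpy().tolist(),
            }
    gain_aligned = clinical["patient_id"].map(gain)
    known = gain_aligned.isin(["gainer", "non_gainer"])
    tab = pd.crosstab(clinical.loc[known, "menopausal_status"], gain_aligned[known])
    if tab.shape == (2, 2):
        res = fisher_exact_2x2(tab.to_numpy())
        out["menopausal_status_by_weight_gain_fisher"] = {
            "odds_ratio": res.odds_ratio, "p": res.p_value, "table": tab.to_numpy().tolist()
        }
    return out


def write_report(report: AnalysisReport, outdir: str) -> list[str]:
    """Write the JSON master document plus one CSV per table."""
    os.makedirs(outdir, exist_ok=True)
    paths = [os.path.join(outdir, "report.json")]
    report.to_json(paths[0])
    for name, comp in report.data.get("comparisons", {}).items():
        vip = pd.Series(comp["vip"], name="vip").rename_axis("variable")
        path = os.path.join(outdir, f"vip_{name}.csv")
        vip.to_csv(path)
        paths.append(path)
    for name, records in report.data.get("univariate", {}).items():
        path = os.path.join(outdir, f"univariate_{name}.csv")
        pd.DataFrame.from_records(records).to_csv(path, index=False)
        paths.append(path)
    return paths
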