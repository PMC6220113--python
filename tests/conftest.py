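import numpy as np
import pandas as pd
import pytest

import pmet
from pmet.containers import MetaboliteMatrix
from pmet.cohort import CohortConfig, SpectraConfig
from pmet.msqc import impute_missing_median


def matrix_from_arrays(
    values,
    patients,
    timepoints,
    *,
    platform="MS",
    lod=None,
    censored=None,
    var_names=None,
):
    """Assemble a MetaboliteMatrix from plain arrays (test helper)."""
    values = np.asarray(values, dtype=float)
    n_vars = values.shape[1]
    names = var_names or [f"m{j}" for j in range(n_vars)]
    vals = pd.DataFrame(values, columns=names)
    meta = pd.DataFrame({"patient_id": patients, "timepoint_months": timepoints})
    lods = np.zeros(n_vars) if lod is None else np.asarray(lod, dtype=float)
    var_meta = pd.DataFrame(
        {"platform": platform, "var_class": "test", "lod": lods}, index=pd.Index(names)
    )
    cens = None
    if censored is not None:
        cens = pd.DataFrame(np.asarray(censored, dtype=bool), columns=names)
        vals = vals.mask(cens)
    return MetaboliteMatrix(vals, meta, var_meta, cens)


def paired_matrix(rng, n_patients=10, n_vars=6, timepoints=(0, 6)):
    """Random positive two-timepoint matrix for paired-design tests."""
    patients = [f"P{i:02d}" for i in range(n_patients) for _ in timepoints]
    tps = list(timepoints) * n_patients
    values = np.exp(rng.normal(0.0, 0.5, (n_patients * len(timepoints), n_vars)))
    return matrix_from_arrays(values, patients, tps)


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size (60-patient) cohort with QC'd MS block, built once."""
    cfg = CohortConfig(seed=42)
    clinical = pmet.generate_cohort(cfg)
    blocks = pmet.simulate_metabolite_matrix(clinical, cfg)
    clean, report = pmet.run_ms_qc(blocks.ms, pmet.simulate_qc_replicates(cfg))
    return {
        "config": cfg,
        "clinical": clinical,
        "blocks": blocks,
        "ms_clean": clean,
        "ms_complete": impute_missing_median(clean),
        "qc_report": report,
    }


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        seed=101,
        n_patients=16,
        weight_followup_missing=2,
        ms_missing_patients=2,
        spectra=SpectraConfig(n_points=8192),
    )
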