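"""Targeted-MS quality control and cleaning.

Rule order is fixed and idempotent:

1. :func:`mask_outliers` -- entries strictly greater than 100x the column
   median (median over observed entries only, so spikes cannot shift
   their own threshold) become missing values,
2. :func:`filter_metabolites` -- columns whose pooled fraction of missing
   or below-LOD entries exceeds 30% are excluded,
3. :func:`impute_lod` -- surviving below-LOD cells are set to LOD/2.

The pooled reading of the 30% rule (missing + below-LOD together) is the
default; both fractions are reported separately in the
:class:`QcReport` so the alternative per-category reading can be audited.
Thresholds are configurable but default to 100x, 0.30, and CoV flags at
15% and 25%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MetaboliteMatrix
from .errors import ConfigurationError, ImputationError

OUTLIER_FACTOR = 100.0
MAX_MISSING_FRACTION = 0.30
COV_FLAG_PCT = 15.0
COV_FAIL_PCT = 25.0


@dataclass
class QcReport:
    """Per-metabolite QC bookkeeping.

    ``table`` has one row per input metabolite with columns
    ``missing_fraction``, ``below_lod_fraction``, ``excluded``,
    ``n_spikes_masked`` and (when QC replicates were supplied) ``cov_qc``.
    """

    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def merge(self, other: "QcReport") -> "QcReport":
        cols = [c for c in other.table.columns if c not in self.table.columns]
        table = self.table.join(other.table[cols], how="outer")
        for col in other.table.columns:
            if col in self.table.columns:
                table[col] = other.table[col].combine_first(self.table[col])
        return QcReport(table, self.warnings + other.warnings)

    def to_csv(self, path: str) -> None:
        self.table.rename_axis("variable").to_csv(path)


def _fractions(matrix: MetaboliteMatrix) -> pd.DataFrame:
    n = matrix.n_samples
    censored = matrix.censored.sum(axis=0) / n
    missing = (matrix.values.isna() & ~matrix.censored).sum(axis=0) / n
    return pd.DataFrame({"missing_fraction": missing, "below_lod_fraction": censored})


def mask_outliers(
    matrix: MetaboliteMatrix, factor: float = OUTLIER_FACTOR
) -> tuple[MetaboliteMatrix, QcReport]:
    """Mask entries strictly greater than ``factor`` x the column median.

    The median is taken over observed (non-missing, non-censored)
    entries; masked entries become missing values.  All-missing columns
    are skipped with a warning.
    """
    values = matrix.values.copy()
    masked_counts = {}
    warnings = []
    for col in values.columns:
        obs = values[col].dropna()
        if obs.empty:
            warnings.append(f"{col}: no observed values, outlier rule skipped")
            masked_counts[col] = 0
            continue
        cutoff = factor * float(obs.median())
        mask = values[col] > cutoff  # strict: exactly 100x the median is retained
        masked_counts[col] = int(mask.sum())
        values.loc[mask, col] = np.nan
    out = MetaboliteMatrix(values, matrix.sample_meta.copy(), matrix.var_meta.copy(),
                           matrix.censored.copy())
    report = _fractions(out)
    report["n_spikes_masked"] = pd.Series(masked_counts)
    return out, QcReport(report, warnings)


def filter_metabolites(
    matrix: MetaboliteMatrix, max_fraction: float = MAX_MISSING_FRACTION
) -> tuple[MetaboliteMatrix, QcReport]:
    """Drop columns with more than ``max_fraction`` missing-or-below-LOD.

    The rule is strict: a column at exactly the threshold survives.
    Surviving columns are unchanged; rows are never dropped.
    """
    report = _fractions(matrix)
    combined = report["missing_fraction"] + report["below_lod_fraction"]
    report["excluded"] = combined > max_fraction
    keep = [c for c in matrix.variables if not report.loc[c, "excluded"]]
    return matrix.select(keep), QcReport(report)


def impute_lod(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace below-LOD cells by LOD/2; leave every other cell untouched."""
    values = matrix.values.copy()
    censored = matrix.censored
    for col in matrix.variables:
        n_cens = int(censored[col].sum())
        if n_cens == 0:
            continue
        lod = matrix.var_meta.loc[col, "lod"]
        if not np.isfinite(lod) or lod <= 0:
            raise ImputationError(f"{col}: censored cells but no defined LOD")
        values.loc[censored[col], col] = lod / 2.0
    cleared = pd.DataFrame(False, index=values.index, columns=values.columns)
    return MetaboliteMatrix(values, matrix.sample_meta.copy(), matrix.var_meta.copy(), cleared)


def impute_missing_median(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Fill residual missing cells with the column median of observed values.

    Multivariate models need complete rows; this runs after the LOD rule
    so censored cells are already numeric.  Univariate mixed models
    should use the unimputed matrix (they tolerate missing visits).
    """
    values = matrix.values.copy()
    for col in matrix.variables:
        obs = values[col].dropna()
        if values[col].isna().any():
            if obs.empty:
                raise ImputationError(f"{col}: no observed values to impute from")
            values[col] = values[col].fillna(float(obs.median()))
    return MetaboliteMatrix(values, matrix.sample_meta.copy(), matrix.var_meta.copy(),
                            matrix.censored.copy())


def compute_cov(qc_samples: MetaboliteMatrix) -> pd.DataFrame:
    """Coefficient of variation (100*sd/mean, sample sd) per metabolite.

    Requires at least two QC replicates.  Flags metabolites above the
    15% and 25% levels.
    """
    if qc_samples.n_samples < 2:
        raise ConfigurationError("CoV needs at least 2 QC replicates")
    values = qc_samples.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    cov = 100.0 * sd / mean
    return pd.DataFrame(
        {
            "cov_qc": cov,
            "cov_over_15": cov > COV_FLAG_PCT,
            "cov_over_25": cov > COV_FAIL_PCT,
        }
    )


def run_ms_qc(
    matrix: MetaboliteMatrix,
    qc_samples: MetaboliteMatrix | None = None,
    *,
    outlier_factor: float = OUTLIER_FACTOR,
    max_missing_fraction: float = MAX_MISSING_FRACTION,
) -> tuple[MetaboliteMatrix, QcReport]:
    """Full QC chain: mask outliers, filter metabolites, impute LOD/2."""
    masked, rep1 = mask_outliers(matrix, outlier_factor)
    filtered, rep2 = filter_metabolites(masked, max_missing_fraction)
    cleaned = impute_lod(filtered)
    report = rep1.merge(rep2)
    if qc_samples is not None:
        cov = compute_cov(qc_samples)
        report = report.merge(QcReport(cov))
    return cleaned, report
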