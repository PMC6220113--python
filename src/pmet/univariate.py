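"""Univariate arm: mixed-model time trends, paired nonparametric tests,
group comparisons, per-block FDR, Friedewald LDL and weight-gain labels.

Parametric tests run on natural-log concentrations (MRS and MS blocks);
the lipoprotein subfractions use Wilcoxon signed-rank tests because of
their non-normality.  Multiple-testing correction is Benjamini-Hochberg
FDR applied within each data block (MRS, MS, LIPO) separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .containers import MetaboliteMatrix
from .errors import ConfigurationError, ConvergenceError, DesignError

WEIGHT_GAIN_THRESHOLD_KG = 1.5
FRIEDEWALD_TG_LIMIT = 4.5


@dataclass
class LmmResult:
    """Fixed time effect of a random-intercept linear mixed model."""

    variable: str
    time_effect: float  # natural-log scale
    std_error: float
    p_value: float
    n_patients_used: int
    degenerate: bool = False


def lmm_time_effect(
    matrix: MetaboliteMatrix,
    variable: str,
    t_ref: int = 0,
    t_cmp: int = 6,
    patients: list[str] | None = None,
) -> LmmResult:
    """Time trend of one metabolite between two timepoints.

    Natural-log concentrations are modelled with a fixed categorical
    timepoint effect and a random per-patient intercept, fitted by REML;
    the p-value is the Wald test on the time coefficient.  Patients with
    a single timepoint are retained (the mixed model tolerates missing
    visits), which is the point of using it over a paired t-test.
    """
    meta = matrix.sample_meta
    sel = meta["timepoint_months"].isin([t_ref, t_cmp]).to_numpy()
    if patients is not None:
        sel &= meta["patient_id"].isin(patients).to_numpy()
    values = matrix.values.loc[sel, variable]
    groups = meta.loc[sel, "patient_id"]
    times = meta.loc[sel, "timepoint_months"]
    keep = values.notna().to_numpy()
    values, groups, times = values[keep], groups[keep], times[keep]
    if (values <= 0).any():
        raise ConfigurationError(f"{variable}: non-positive values, cannot log-transform")
    n_patients = groups.nunique()
    if n_patients < 6:
        raise DesignError(f"{variable}: only {n_patients} patients with data")
    logc = np.log(values.to_numpy())
    is_cmp = (times == t_cmp).to_numpy().astype(float)

    # degenerate data (zero within-patient variability) break REML; report
    # the balanced paired estimate directly
    resid = logc - pd.Series(logc).groupby(groups.to_numpy()).transform("mean").to_numpy()
    if np.std(resid) < 1e-10:
        est = logc[is_cmp == 1].mean() - logc[is_cmp == 0].mean()
        return LmmResult(variable, float(est), 0.0, 1.0 if abs(est) < 1e-12 else 0.0,
                         int(n_patients), degenerate=True)

    exog = np.column_stack([np.ones_like(is_cmp), is_cmp])
    model = MixedLM(logc, exog, groups=groups.to_numpy())
    fit = None
    last_exc: Exception | None = None
    for method in (None, "powell"):
        try:
            with warnings.catch_warnings():
                # boundary fits (random-effect variance at zero) are expected
                # and still give a valid Wald test on the fixed time effect
                warnings.simplefilter("ignore")
                kwargs = {} if method is None else {"method": method}
                fit = model.fit(reml=True, **kwargs)
            break
        except Exception as exc:  # singular optimizer steps on boundary fits
            last_exc = exc
    if fit is None:
        raise ConvergenceError(f"{variable}: mixed model failed ({last_exc})") from last_exc
    est = float(fit.fe_params[1])
    se = float(fit.bse_fe[1])
    if not np.isfinite(se):
        raise ConvergenceError(f"{variable}: singular mixed-model fit")
    p = float(fit.pvalues[1])
    return LmmResult(variable, est, se, p, int(n_patients))


@dataclass
class TestResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def wilcoxon_signed_rank(paired_diffs: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties are mid-ranked; the null is exact
    for n <= 25 untied differences and a normal approximation with
    continuity correction otherwise.  All-zero input is degenerate with
    p = 1.
    """
    d = np.asarray(paired_diffs, dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return TestResult(0.0, 1.0, degenerate=True)
    if nonzero.size < 5:
        raise DesignError("need at least 5 non-zero differences")
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return TestResult(float(res.statistic), float(res.pvalue))


def two_sample_t(
    values: np.ndarray, group_labels: np.ndarray, *, welch: bool = False
) -> TestResult:
    """Two-sided two-sample t-test (pooled variance by default)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    levels = np.sort(pd.unique(labels))
    if levels.size != 2:
        raise ConfigurationError("exactly two groups required")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if min(a.size, b.size) < 2:
        raise DesignError("each group needs at least 2 observations")
    if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
        return TestResult(0.0, 1.0, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TestResult(float(res.statistic), float(res.pvalue))


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float


def fisher_exact_2x2(table) -> FisherResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums the hypergeometric probabilities of all tables with
    the same margins whose point probability does not exceed the observed
    one; the reported odds ratio is the conditional maximum-likelihood
    estimate.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ConfigurationError("expected a 2x2 table")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ConfigurationError("counts must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise ConfigurationError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ConfigurationError("both margins must be positive")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    odds = stats.contingency.odds_ratio(arr, kind="conditional")
    return FisherResult(float(odds.statistic), float(p))


def fdr_bh(p_values, block_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, computed per block.

    With ``block_labels`` given, the correction runs independently within
    each named block (e.g. MRS, MS and lipoprotein panels separately).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    q = np.empty_like(p)
    if block_labels is None:
        blocks = np.zeros(p.size, dtype=int)
    else:
        blocks = np.asarray(block_labels)
    for b in pd.unique(blocks):
        idx = blocks == b
        q[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return q


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """LDL cholesterol (mmol/L): tc − hdl − tg/2.2, valid for tg < 4.5."""
    if min(tc, hdl, tg) < 0:
        raise ConfigurationError("lipid inputs must be non-negative")
    if tg >= FRIEDEWALD_TG_LIMIT:
        raise ConfigurationError(
            f"Friedewald formula invalid for TG >= {FRIEDEWALD_TG_LIMIT} mmol/L"
        )
    return tc - hdl - tg / 2.2


def classify_weight_gain(clinical: pd.DataFrame) -> pd.Series:
    """gainer / non_gainer / unknown per patient.

    A gainer gained at least 1.5 kg between baseline and 6 months
    (boundary inclusive); a missing 6-month weight yields ``unknown``.
    """
    if clinical["weight_kg_0"].isna().any():
        raise ConfigurationError("baseline weight missing")
    delta = clinical["weight_kg_6"] - clinical["weight_kg_0"]
    out = pd.Series("unknown", index=clinical.index, dtype=object)
    out[delta >= WEIGHT_GAIN_THRESHOLD_KG] = "gainer"
    out[delta < WEIGHT_GAIN_THRESHOLD_KG] = "non_gainer"
    out.index = clinical["patient_id"].to_numpy()
    return out


def estimate_icc(matrix: MetaboliteMatrix, variables: list[str] | None = None) -> pd.Series:
    """One-way random-effects (ANOVA) intraclass correlation per variable.

    Uses the method-of-moments estimator with the unbalanced-design
    average group size; values are clipped to [0, 1).
    """
    variables = variables or matrix.variables
    groups = matrix.sample_meta["patient_id"].to_numpy()
    out = {}
    for var in variables:
        y = np.log(matrix.values[var].to_numpy())
        keep = np.isfinite(y)
        yv, g = y[keep], groups[keep]
        df = pd.DataFrame({"y": yv, "g": g})
        sizes = df.groupby("g").size()
        a = sizes.size
        n = yv.size
        gm = yv.mean()
        means = df.groupby("g")["y"].mean()
        ssb = float((sizes * (means - gm) ** 2).sum())
        ssw = float(((df["y"] - df["g"].map(means)) ** 2).sum())
        msb = ssb / (a - 1)
        msw = ssw / (n - a)
        k0 = (n - float((sizes**2).sum()) / n) / (a - 1)
        sigma_b = max(0.0, (msb - msw) / k0)
        out[var] = sigma_b / (sigma_b + msw) if (sigma_b + msw) > 0 else 0.0
    return pd.Series(out, name="icc")


# ---------------------------------------------------------------------------
# block-level tables
# ---------------------------------------------------------------------------


def univariate_table(
    matrix: MetaboliteMatrix,
    block: str,
    t_ref: int,
    t_cmp: int,
    patients: list[str] | None = None,
    test: str = "lmm",
) -> pd.DataFrame:
    """Per-variable time-trend tests with blockwise FDR.

    ``test='lmm'`` fits the mixed model per variable; ``test='wilcoxon'``
    runs signed-rank tests on complete within-patient differences (the
    lipoprotein convention).  Returns columns: variable, block, test,
    statistic, p, q.
    """
    rows = []
    for var in matrix.variables:
        try:
            if test == "lmm":
                res = lmm_time_effect(matrix, var, t_ref, t_cmp, patients)
                rows.append((var, block, "lmm", res.time_effect, res.p_value))
            elif test == "wilcoxon":
                diffs = _paired_differences(matrix, var, t_ref, t_cmp, patients)
                res = wilcoxon_signed_rank(diffs)
                rows.append((var, block, "wilcoxon", res.statistic, res.p_value))
            else:
                raise ConfigurationError(f"unknown test {test!r}")
        except (DesignError, ConvergenceError):
            rows.append((var, block, test, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["variable", "block", "test", "statistic", "p"])
    ok = table["p"].notna()
    table["q"] = np.nan
    if ok.any():
        table.loc[ok, "q"] = fdr_bh(table.loc[ok, "p"].to_numpy())
    return table


def _paired_differences(
    matrix: MetaboliteMatrix,
    variable: str,
    t_ref: int,
    t_cmp: int,
    patients: list[str] | None,
) -> np.ndarray:
    meta = matrix.sample_meta
    frames = {}
    for t in (t_ref, t_cmp):
        sel = (meta["timepoint_months"] == t).to_numpy()
        s = matrix.values.loc[sel, variable]
        s.index = meta.loc[sel, "patient_id"].to_numpy()
        frames[t] = s
    common = frames[t_ref].index.intersection(frames[t_cmp].index)
    if patients is not None:
        common = common.intersection(pd.Index(patients))
    d = (frames[t_cmp].loc[common] - frames[t_ref].loc[common]).to_numpy()
    return d[np.isfinite(d)]
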