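"""Multilevel OPLS-DA: paired transformation, NIPALS fit, VIP, grouped CV
and permutation testing.

The multilevel (paired) transformation turns two measurements per patient
into a pair of mirrored difference rows: if ``a`` is the reference-time
vector and ``b`` the comparison-time vector, the patient contributes
``(a - b, +1)`` and ``(b - a, -1)``.  Discriminating the two mirror
classes is a multivariate analogue of the paired t-test: between-patient
variation cancels exactly.

OPLS-DA is fitted NIPALS-style.  Each orthogonal round computes the PLS
weight ``w ∝ Xᵀy``, score ``t = Xw`` and loading ``p = Xᵀt/(tᵀt)``,
extracts the y-orthogonal part of the loading ``w_o ∝ p − (wᵀp)w``, and
deflates ``X`` by the orthogonal component ``t_o p_oᵀ``.  After
``n_orth`` rounds one predictive component is fitted on the deflated
matrix.  By construction every orthogonal score has zero correlation with
``y`` and the orthogonal scores are mutually orthogonal.

Validation is patient-grouped k-fold cross-validation repeated over
several random fold assignments; the orthogonal-component count is chosen
at the first local minimum of the mean classification error, and model
significance comes from a permutation test that preserves the pairing
(per-patient sign flips for multilevel data, patient-label shuffles
otherwise) with p = (#permuted ≥ observed)/n_perm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MetaboliteMatrix
from .errors import ConfigurationError, DesignError, FitError, PredictionError

_EPS = 1e-12

# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class DiscriminantDataset:
    """A labelled matrix for two-class discrimination with patient grouping."""

    X: np.ndarray
    y: np.ndarray
    patients: np.ndarray
    variables: list[str]
    paired: bool = False
    excluded_patients: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.patients = np.asarray(self.patients)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ConfigurationError("X and y are misaligned")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ConfigurationError("labels must be +1/-1")
        if not np.all(np.isfinite(self.X)):
            raise ConfigurationError("X contains non-finite values (impute first)")

    @property
    def n_patients(self) -> int:
        return np.unique(self.patients).size


class PairedDataset(DiscriminantDataset):
    """Mirrored within-patient difference rows (the multilevel design).

    Rows come in exact antisymmetric pairs (the second row of each
    patient is the negation of the first), labels are balanced, and each
    patient contributes exactly one pair.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        self.paired = True
        if self.X.shape[0] % 2:
            raise ConfigurationError("paired dataset needs an even number of rows")
        for i in range(0, self.X.shape[0], 2):
            if self.patients[i] != self.patients[i + 1]:
                raise ConfigurationError("pair rows must be adjacent per patient")
            if not np.allclose(self.X[i], -self.X[i + 1], atol=1e-10):
                raise ConfigurationError("pair rows must be antisymmetric")
            if self.y[i] != -self.y[i + 1]:
                raise ConfigurationError("pair labels must be mirrored")
        counts = pd.Series(self.patients).value_counts()
        if (counts != 2).any():
            raise ConfigurationError("each patient must contribute exactly one pair")

    @classmethod
    def from_differences(
        cls, diffs: np.ndarray, patients: list[str], variables: list[str],
        excluded: list[str] | None = None,
    ) -> "PairedDataset":
        """Build the mirrored design from per-patient difference vectors."""
        diffs = np.asarray(diffs, dtype=float)
        n = diffs.shape[0]
        X = np.empty((2 * n, diffs.shape[1]))
        X[0::2] = diffs
        X[1::2] = -diffs
        y = np.tile([1.0, -1.0], n)
        pats = np.repeat(np.asarray(patients), 2)
        return cls(X, y, pats, list(variables), excluded_patients=excluded or [])


def build_paired_dataset(
    matrix: MetaboliteMatrix,
    t_ref: int,
    t_cmp: int,
    *,
    patients: list[str] | None = None,
    min_patients: int = 6,
) -> PairedDataset:
    """Within-patient differences between two timepoints, mirrored.

    Patients with both timepoints contribute ``(x_ref − x_cmp, +1)`` and
    ``(x_cmp − x_ref, −1)``; patients missing either timepoint are
    excluded and listed on the result.  Requires imputed/cleaned data
    (no NaN) and at least ``min_patients`` complete patients.
    """
    meta = matrix.sample_meta
    wide: dict[int, pd.DataFrame] = {}
    for t in (t_ref, t_cmp):
        sel = meta["timepoint_months"] == t
        sub = matrix.values.loc[sel.to_numpy()]
        sub.index = meta.loc[sel.to_numpy(), "patient_id"].to_numpy()
        wide[t] = sub
    candidates = patients if patients is not None else list(
        dict.fromkeys(meta["patient_id"])
    )
    complete = [p for p in candidates if p in wide[t_ref].index and p in wide[t_cmp].index]
    excluded = [p for p in candidates if p not in complete]
    if len(complete) < min_patients:
        raise DesignError(
            f"only {len(complete)} patients have both timepoints (need {min_patients})"
        )
    diffs = wide[t_ref].loc[complete].to_numpy() - wide[t_cmp].loc[complete].to_numpy()
    if not np.all(np.isfinite(diffs)):
        raise ConfigurationError("matrix contains missing values; run QC/imputation first")
    return PairedDataset.from_differences(diffs, complete, matrix.variables, excluded)


def build_labeled_dataset(
    matrix: MetaboliteMatrix,
    labels: pd.Series,
    timepoint: int,
    *,
    positive: str,
    negative: str,
) -> DiscriminantDataset:
    """Single-timepoint two-class design (e.g. weight-gain prediction).

    ``labels`` maps patient_id to a category; patients with any other
    category (e.g. unknown) are excluded.
    """
    meta = matrix.sample_meta
    sel = (meta["timepoint_months"] == timepoint).to_numpy()
    sub = matrix.values.loc[sel]
    pats = meta.loc[sel, "patient_id"].to_numpy()
    keep, y = [], []
    for i, p in enumerate(pats):
        lab = labels.get(p)
        if lab == positive:
            keep.append(i)
            y.append(1.0)
        elif lab == negative:
            keep.append(i)
            y.append(-1.0)
    X = sub.to_numpy()[keep]
    if not np.all(np.isfinite(X)):
        raise ConfigurationError("matrix contains missing values; run QC/imputation first")
    return DiscriminantDataset(
        X, np.asarray(y), pats[keep], matrix.variables, paired=False
    )


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


@dataclass
class ScalingRecipe:
    center: bool
    unit_variance: bool
    means: np.ndarray
    scales: np.ndarray
    constant_columns: np.ndarray  # boolean flags


def scale_columns(
    X: np.ndarray, center: bool = True, unit_variance: bool = True
) -> tuple[np.ndarray, ScalingRecipe]:
    """Column centering and optional unit-variance (autoscaling).

    Zero-variance columns are centered but flagged and left with scale 1.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ConfigurationError("scaling needs at least two rows")
    means = X.mean(axis=0) if center else np.zeros(X.shape[1])
    sd = X.std(axis=0, ddof=1)
    constant = sd < _EPS
    scales = np.ones(X.shape[1])
    if unit_variance:
        scales = np.where(constant, 1.0, sd)
    recipe = ScalingRecipe(center, unit_variance, means, scales, constant)
    return (X - means) / scales, recipe


def apply_scaling(X: np.ndarray, recipe: ScalingRecipe) -> np.ndarray:
    return (np.asarray(X, dtype=float) - recipe.means) / recipe.scales


# ---------------------------------------------------------------------------
# model fit
# ---------------------------------------------------------------------------


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (one predictive component).

    ``w`` is the unit-norm predictive weight, ``p``/``t``/``q`` the
    predictive loading, score and y-loading; ``W_o``/``P_o``/``T_o`` hold
    the orthogonal components column-wise.
    """

    variables: list[str]
    recipe: ScalingRecipe
    w: np.ndarray
    p: np.ndarray
    t: np.ndarray
    q: float
    W_o: np.ndarray
    P_o: np.ndarray
    T_o: np.ndarray
    n_orth: int
    decision_threshold: float = 0.0


def fit_opls_da(
    X: np.ndarray,
    y: np.ndarray,
    n_orth: int = 0,
    *,
    center: bool = True,
    unit_variance: bool = True,
    variables: list[str] | None = None,
) -> OplsModel:
    """Fit OPLS-DA with ``n_orth`` orthogonal components (NIPALS).

    Raises :class:`~pmet.errors.FitError` when the residual rank is
    exhausted before ``n_orth`` components are extracted.
    """
    y = np.asarray(y, dtype=float)
    Xs, recipe = scale_columns(X, center, unit_variance)
    n_vars = Xs.shape[1]
    Xd = Xs.copy()
    W_o = np.zeros((n_vars, n_orth))
    P_o = np.zeros((n_vars, n_orth))
    T_o = np.zeros((Xs.shape[0], n_orth))
    for a in range(n_orth):
        w = Xd.T @ y
        nw = np.linalg.norm(w)
        if nw < _EPS:
            raise FitError("residual X'y vanished before predictive fit")
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-10:
            raise FitError(f"orthogonal rank exhausted after {a} components")
        w_o /= n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o
    w = Xd.T @ y
    nw = np.linalg.norm(w)
    if nw < _EPS:
        raise FitError("residual X'y vanished before predictive fit")
    w /= nw
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = float(y @ t / (t @ t))
    return OplsModel(
        variables=list(variables) if variables is not None else [f"v{i}" for i in range(n_vars)],
        recipe=recipe,
        w=w,
        p=p,
        t=t,
        q=q,
        W_o=W_o,
        P_o=P_o,
        T_o=T_o,
        n_orth=n_orth,
    )


def predict(model: OplsModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive scores and class labels for new samples.

    New data are scaled with the training recipe, stripped of the stored
    orthogonal components and projected on the predictive weight; the
    class is ``sign(score * q)`` with zero mapped to +1.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.w.size:
        raise PredictionError(
            f"expected {model.w.size} variables, got {X_new.shape[1]}"
        )
    Xd = apply_scaling(X_new, model.recipe)
    for a in range(model.n_orth):
        t_o = Xd @ model.W_o[:, a]
        Xd = Xd - np.outer(t_o, model.P_o[:, a])
    scores = Xd @ model.w
    labels = np.where(scores * model.q >= model.decision_threshold, 1.0, -1.0)
    return scores, labels


def vip_scores(model: OplsModel) -> pd.Series:
    """Variable importance in projection.

    With a single predictive component (the only one explaining
    y-variance; orthogonal components explain none by construction) the
    VIP reduces to ``sqrt(p_vars) * |w_j|``, so the squared scores
    average to one.
    """
    n_vars = model.w.size
    vip = np.sqrt(n_vars * model.w**2)
    return pd.Series(vip, index=model.variables, name="vip")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CvResult:
    """Cross-validated error curve and metrics at the chosen model size."""

    error_curve: np.ndarray
    sensitivity_curve: np.ndarray
    specificity_curve: np.ndarray
    chosen_n_orth: int
    accuracy: float
    sensitivity: float
    specificity: float
    n_folds: int
    n_iter: int

    def to_dict(self) -> dict:
        return {
            "error_curve": self.error_curve.tolist(),
            "sensitivity_curve": self.sensitivity_curve.tolist(),
            "specificity_curve": self.specificity_curve.tolist(),
            "chosen_n_orth": int(self.chosen_n_orth),
            "accuracy": float(self.accuracy),
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "n_folds": self.n_folds,
            "n_iter": self.n_iter,
        }


def select_components(error_curve: np.ndarray | list[float]) -> int:
    """First local minimum of the error curve; plateaus resolve leftward.

    If the curve decreases monotonically to its end the last index is
    returned.
    """
    err = np.asarray(error_curve, dtype=float)
    if err.size == 0:
        raise ConfigurationError("empty error curve")
    candidate = None
    for i in range(err.size - 1):
        if err[i + 1] > err[i]:
            candidate = i
            break
    if candidate is None:
        return err.size - 1
    while candidate > 0 and err[candidate - 1] <= err[candidate]:
        candidate -= 1
    return candidate


def _assign_folds(
    patients: np.ndarray,
    patient_labels: dict,
    n_folds: int,
    rng: np.random.Generator,
    stratify: bool,
) -> dict:
    """Random fold id per patient; stratified by class when requested."""
    unique = np.unique(patients)
    fold_of = {}
    if stratify:
        for lab in (1.0, -1.0):
            members = [p for p in unique if patient_labels[p] == lab]
            order = rng.permutation(len(members))
            offset = rng.integers(n_folds)
            for k, idx in enumerate(order):
                fold_of[members[idx]] = int((k + offset) % n_folds)
    else:
        order = rng.permutation(unique.size)
        splits = np.array_split(order, n_folds)
        for f, chunk in enumerate(splits):
            for idx in chunk:
                fold_of[unique[idx]] = f
    return fold_of


def _fold_curve_predict(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    n_levels: int,
    unit_variance: bool,
) -> np.ndarray:
    """Predicted labels for the test block at every orthogonal level.

    One deflation pass serves all levels: the orthogonal sequence for
    ``n_orth = k`` is a prefix of the sequence for ``k + 1``, so each
    round yields the predictive component of its truncation level before
    deflating further.  If the residual rank runs out, remaining levels
    reuse the last available prediction.
    """
    mu = Xtr.mean(axis=0)
    if unit_variance:
        sd = Xtr.std(axis=0, ddof=1)
        sd[sd < _EPS] = 1.0
    else:
        sd = 1.0
    Xc = (Xtr - mu) / sd
    Xe = (Xte - mu) / sd
    out = np.ones((n_levels, Xte.shape[0]))
    last = np.ones(Xte.shape[0])
    for a in range(n_levels):
        w = Xc.T @ ytr
        nw = np.sqrt(w @ w)
        if nw < _EPS:
            out[a:] = last
            return out
        w /= nw
        t = Xc @ w
        tt = t @ t
        q = (ytr @ t) / tt
        s = Xe @ w
        last = np.where(s * q >= 0.0, 1.0, -1.0)
        out[a] = last
        if a < n_levels - 1:
            p = Xc.T @ t / tt
            w_o = p - (w @ p) * w
            n_wo = np.sqrt(w_o @ w_o)
            if n_wo < 1e-10:
                out[a + 1 :] = last
                return out
            w_o /= n_wo
            t_o = Xc @ w_o
            p_o = Xc.T @ t_o / (t_o @ t_o)
            Xc -= np.outer(t_o, p_o)
            t_o_e = Xe @ w_o
            Xe -= np.outer(t_o_e, p_o)
    return out


def cross_validate(
    dataset: DiscriminantDataset,
    *,
    max_orth: int = 3,
    n_folds: int = 10,
    n_iter: int = 20,
    seed: int | np.random.SeedSequence | None = None,
    unit_variance: bool = True,
    y_override: np.ndarray | None = None,
) -> CvResult:
    """Patient-grouped k-fold CV of the OPLS-DA error curve.

    Folds partition patients, never rows, so both mirror rows of a
    patient always share a fold; scaling is refit inside every training
    fold.  Per-iteration sensitivity and specificity are pooled over
    folds and averaged over iterations; classification error is
    ``1 − (sensitivity + specificity)/2`` (equal to the raw error rate
    for the balanced multilevel design).
    """
    X = dataset.X
    y = dataset.y if y_override is None else np.asarray(y_override, dtype=float)
    patients = dataset.patients
    unique = np.unique(patients)
    if unique.size < n_folds:
        raise DesignError(f"{unique.size} patients < {n_folds} folds")
    patient_labels = {}
    if not dataset.paired:
        for p in unique:
            patient_labels[p] = y[patients == p][0]
    rng = np.random.default_rng(seed)
    n_levels = max_orth + 1
    sens = np.empty((n_iter, n_levels))
    spec = np.empty((n_iter, n_levels))
    pos = y > 0
    for it in range(n_iter):
        fold_of = _assign_folds(patients, patient_labels, n_folds, rng,
                                stratify=not dataset.paired)
        fold_ids = np.array([fold_of[p] for p in patients])
        pred = np.empty((n_levels, y.size))
        for f in range(n_folds):
            te = fold_ids == f
            tr = ~te
            if not te.any():
                continue
            assert not (set(patients[tr]) & set(patients[te])), "patient leaked across folds"
            pred[:, te] = _fold_curve_predict(X[tr], y[tr], X[te], n_levels, unit_variance)
        correct = pred == y[None, :]
        sens[it] = correct[:, pos].mean(axis=1)
        spec[it] = correct[:, ~pos].mean(axis=1)
    sens_curve = sens.mean(axis=0)
    spec_curve = spec.mean(axis=0)
    error_curve = 1.0 - (sens_curve + spec_curve) / 2.0
    chosen = select_components(error_curve)
    return CvResult(
        error_curve=error_curve,
        sensitivity_curve=sens_curve,
        specificity_curve=spec_curve,
        chosen_n_orth=chosen,
        accuracy=1.0 - error_curve[chosen],
        sensitivity=sens_curve[chosen],
        specificity=spec_curve[chosen],
        n_folds=n_folds,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Observed CV accuracy against its permutation null."""

    observed_accuracy: float
    permuted_accuracies: np.ndarray
    p_value: float
    p_label: str
    n_perm: int

    @classmethod
    def from_accuracies(
        cls, observed: float, permuted: np.ndarray
    ) -> "PermutationResult":
        permuted = np.asarray(permuted, dtype=float)
        n_perm = permuted.size
        if n_perm < 1:
            raise ConfigurationError("need at least one permutation")
        n_ge = int(np.sum(permuted >= observed - 1e-12))
        p = n_ge / n_perm
        label = f"<{1.0 / n_perm:g}" if n_ge == 0 else f"{p:g}"
        return cls(observed, permuted, p, label, n_perm)

    def to_dict(self) -> dict:
        return {
            "observed_accuracy": float(self.observed_accuracy),
            "p_value": float(self.p_value),
            "p_label": self.p_label,
            "n_perm": self.n_perm,
        }


def permutation_test(
    dataset: DiscriminantDataset,
    *,
    n_perm: int = 1000,
    max_orth: int = 3,
    n_folds: int = 10,
    n_iter: int = 20,
    seed: int | None = None,
    unit_variance: bool = True,
    fix_n_orth: int | None = None,
) -> PermutationResult:
    """Permutation significance of the cross-validated accuracy.

    The permutation scheme preserves the design: for paired data each
    patient's mirror pair keeps or flips its +1/−1 assignment at random
    (shuffling rows independently would break the antisymmetry and
    inflate the null); for unpaired data patient labels are shuffled
    across patients.  Component selection is rerun inside every
    permutation unless ``fix_n_orth`` pins it.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    ss = np.random.SeedSequence(seed)
    cv_seed, perm_seed, *perm_cv_seeds = ss.spawn(2 + n_perm)
    observed = cross_validate(
        dataset, max_orth=max_orth, n_folds=n_folds, n_iter=n_iter,
        seed=cv_seed, unit_variance=unit_variance,
    )
    obs_acc = (
        observed.accuracy
        if fix_n_orth is None
        else 1.0 - observed.error_curve[fix_n_orth]
    )
    label_rng = np.random.default_rng(perm_seed)
    unique = np.unique(dataset.patients)
    accs = np.empty(n_perm)
    for k in range(n_perm):
        if dataset.paired:
            flips = label_rng.choice([-1.0, 1.0], size=unique.size)
            flip_of = dict(zip(unique, flips))
            y_perm = dataset.y * np.array([flip_of[p] for p in dataset.patients])
        else:
            labels = {p: dataset.y[dataset.patients == p][0] for p in unique}
            shuffled = label_rng.permutation([labels[p] for p in unique])
            new = dict(zip(unique, shuffled))
            y_perm = np.array([new[p] for p in dataset.patients])
        res = cross_validate(
            dataset, max_orth=max_orth, n_folds=n_folds, n_iter=n_iter,
            seed=perm_cv_seeds[k], unit_variance=unit_variance, y_override=y_perm,
        )
        accs[k] = (
            res.accuracy if fix_n_orth is None else 1.0 - res.error_curve[fix_n_orth]
        )
    return PermutationResult.from_accuracies(obs_acc, accs)
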