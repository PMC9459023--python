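"""Cost-sensitive linear SVM with calibrated posteriors under LOPOCV.

The classifier is a linear-kernel SVM whose hinge loss is weighted by a
2x2 zero-diagonal misclassification-cost matrix; the default
``[[0, 1], [2, 0]]`` doubles the penalty on false negatives, shifting
the boundary toward sensitivity.  For a zero-diagonal cost matrix this
is exactly class-weighted hinge loss (each training example weighted by
the cost of misclassifying its true class), which is how it is realized
here on top of the libsvm solver.

Posterior probabilities come from Platt scaling: a sigmoid
``P(+1 | f) = 1 / (1 + exp(A f + B))`` fitted to the training decision
values by regularized maximum likelihood (the standard Lin-Huang-Weng
Newton iteration, with the usual smoothed targets that keep perfectly
separated folds finite).

Evaluation is leave-one-patient-out: for each patient, feature selection,
standardization, SVM training and calibration all run on the other
patients' sites only, and the held-out patient's sites receive posterior
scores from that fold's model.  Every site is scored exactly once by a
model that never saw its patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .feature_selection import FeatureTable, SelectionResult, select_features

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CostMatrix:
    """2x2 misclassification costs, rows = true class (-1 then +1),
    columns = predicted class.  The diagonal must be zero."""

    matrix: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 1.0], [2.0, 0.0]])
    )

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape != (2, 2):
            raise ValueError("cost matrix must be 2x2")
        if mat[0, 0] != 0 or mat[1, 1] != 0:
            raise ValueError("cost matrix diagonal must be zero")
        if np.any(mat < 0):
            raise ValueError("costs must be non-negative")
        object.__setattr__(self, "matrix", mat)

    @property
    def false_positive_cost(self) -> float:
        return float(self.matrix[0, 1])

    @property
    def false_negative_cost(self) -> float:
        return float(self.matrix[1, 0])

    def class_weights(self) -> dict[int, float]:
        """Hinge-loss weight per true class (the cost of getting it wrong)."""
        return {-1: self.false_positive_cost, +1: self.false_negative_cost}


@dataclass
class SvmModel:
    """Trained fold model: weights over the selected features plus the
    training-fold standardization and Platt calibration parameters."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    bias: float
    cost: CostMatrix
    support_indices: np.ndarray
    n_train: int
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    platt_a: float = 0.0
    platt_b: float = 0.0

    def decision_values(self, X_raw: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X_raw, dtype=float) - self.scaler_mean) / self.scaler_sd
        return Xs @ self.weights + self.bias

    def posterior(self, X_raw: np.ndarray) -> np.ndarray:
        f = self.decision_values(X_raw)
        # P(+1 | f) = 1 / (1 + exp(A f + B))
        return _sigmoid(-(self.platt_a * f + self.platt_b))


@dataclass
class CvResult:
    """Pooled LOPOCV output: one held-out posterior per site, plus the
    per-fold selections and models."""

    posteriors: pd.Series  # site id -> posterior of the positive class
    labels: pd.Series  # site id -> +/-1
    fold_patients: tuple[str, ...]
    fold_selections: dict[str, SelectionResult]
    fold_models: dict[str, SvmModel | None]
    mean_n_features: float
    mean_sv_ratio: float

    @property
    def n_folds(self) -> int:
        return len(self.fold_patients)

    def selection_counts(self) -> pd.Series:
        """How many folds selected each feature (descending)."""
        counts: dict[str, int] = {}
        for sel in self.fold_selections.values():
            for name in sel.selected:
                counts[name] = counts.get(name, 0) + 1
        return pd.Series(counts, dtype=int).sort_values(ascending=False)


def _sigmoid(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_cost_svm(
    X: np.ndarray,
    y: np.ndarray,
    cost: CostMatrix | None = None,
    C_reg: float = 1.0,
) -> SvmModel:
    """Linear SVM minimizing ``0.5 ||w||^2 + C_reg * sum_i c_i hinge_i``.

    ``c_i`` is the misclassification cost of example i's true class.
    ``X`` is expected to be standardized already (the model records an
    identity scaler; :func:`lopocv` substitutes the fold scaler).
    Support vectors are the training rows on or inside the margin
    (``y_i f(x_i) <= 1``).
    """
    cost = cost or CostMatrix()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contain a single class")
    svc = SVC(kernel="linear", C=C_reg, class_weight=cost.class_weights())
    svc.fit(X, y)
    w = svc.coef_.ravel()
    b = float(svc.intercept_[0])
    margins = y * (X @ w + b)
    support = np.flatnonzero(margins <= 1.0 + 1e-9)
    return SvmModel(
        feature_names=(),
        weights=w,
        bias=b,
        cost=cost,
        support_indices=support,
        n_train=len(y),
        scaler_mean=np.zeros(X.shape[1]),
        scaler_sd=np.ones(X.shape[1]),
    )


def sv_ratio(model: SvmModel) -> float:
    """Fraction of training observations that are support vectors."""
    return len(model.support_indices) / model.n_train


# ---------------------------------------------------------------------------
# Platt scaling
# ---------------------------------------------------------------------------

def calibrate_posterior(
    decision_values: np.ndarray, y: np.ndarray, max_iter: int = 200
) -> tuple[float, float]:
    """Fit the Platt sigmoid ``P(+1|f) = 1 / (1 + exp(A f + B))``.

    Regularized maximum likelihood on the training decision values, with
    the smoothed targets ``(N+ + 1)/(N+ + 2)`` and ``1/(N- + 2)`` that
    keep the fit finite on perfectly separated data.  Newton iteration
    with backtracking (deterministic).  Returns ``(A, B)``; ``A`` is
    negative whenever larger decision values favour the positive class.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(y, dtype=int)
    prior1 = np.sum(y == 1)
    prior0 = np.sum(y == -1)
    hi = (prior1 + 1.0) / (prior1 + 2.0)
    lo = 1.0 / (prior0 + 2.0)
    t = np.where(y == 1, hi, lo)

    def nll(a: float, b: float) -> float:
        z = a * f + b
        # log(1 + exp(z)) - t*... computed stably
        return float(np.sum(np.where(z >= 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z))) - (1.0 - t) * z))

    a, b = 0.0, float(np.log((prior0 + 1.0) / (prior1 + 1.0)))
    best = nll(a, b)
    eps = 1e-12
    for _ in range(max_iter):
        p = _sigmoid(a * f + b)
        d1 = p - (1.0 - t)  # gradient of nll wrt z
        g_a = float(np.sum(d1 * f))
        g_b = float(np.sum(d1))
        w = np.maximum(p * (1.0 - p), eps)
        h_aa = float(np.sum(w * f * f)) + eps
        h_ab = float(np.sum(w * f))
        h_bb = float(np.sum(w)) + eps
        det = h_aa * h_bb - h_ab * h_ab
        if det <= 0:
            break
        da = -(h_bb * g_a - h_ab * g_b) / det
        db = -(-h_ab * g_a + h_aa * g_b) / det
        step = 1.0
        while step >= 1e-10:
            cand = nll(a + step * da, b + step * db)
            if cand < best - 1e-12:
                a, b = a + step * da, b + step * db
                best = cand
                break
            step /= 2.0
        else:
            break
        if max(abs(da), abs(db)) < 1e-10:
            break
    return a, b


# ---------------------------------------------------------------------------
# Leave-one-patient-out cross-validation
# ---------------------------------------------------------------------------

class SingleClassFoldError(ValueError):
    """A training fold lost one of the two classes."""


def lopocv(
    table: FeatureTable,
    labels: pd.Series,
    cost: CostMatrix | None = None,
    max_nf: int = 10,
    C_reg: float = 1.0,
    fixed_features: tuple[str, ...] | None = None,
    selection_kwargs: dict | None = None,
) -> CvResult:
    """Leave-one-patient-out evaluation with per-fold feature selection.

    For each patient p: run the selection cascade on all-but-p (or use
    ``fixed_features`` verbatim, bypassing selection), standardize the
    selected columns on training rows, train the cost-weighted SVM,
    Platt-calibrate on training decision values, and score p's sites.

    A fold whose training partition is single-class raises
    :class:`SingleClassFoldError` naming the held-out patient.  A fold
    whose selection comes back empty scores its sites 0.5 (uninformative)
    and is logged.
    """
    cost = cost or CostMatrix()
    selection_kwargs = selection_kwargs or {}
    labels = labels.loc[table.values.index].astype(int)
    patients = pd.unique(table.patient_ids)
    if len(patients) < 2:
        raise ValueError("LOPOCV needs at least two patients")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present overall")
    if fixed_features is not None and len(fixed_features) == 0:
        raise ValueError("fixed feature list must be non-empty")

    posteriors: dict[str, float] = {}
    fold_selections: dict[str, SelectionResult] = {}
    fold_models: dict[str, SvmModel | None] = {}
    n_feats, ratios = [], []

    for patient in patients:
        held = table.patient_ids.index[table.patient_ids == patient]
        train_ids = table.patient_ids.index[table.patient_ids != patient]
        y_train = labels.loc[train_ids]
        if len(np.unique(y_train)) < 2:
            raise SingleClassFoldError(
                f"training fold excluding patient {patient!r} has a single class"
            )
        train_table = table.restrict_sites(train_ids)
        if fixed_features is not None:
            missing = set(fixed_features) - set(table.values.columns)
            if missing:
                raise ValueError(f"fixed features absent from table: {sorted(missing)}")
            sel = SelectionResult(
                survivors_step1=tuple(fixed_features),
                survivors_step2=tuple(fixed_features),
                selected=tuple(fixed_features),
                weights=tuple(0.0 for _ in fixed_features),
                max_nf=max(len(fixed_features), max_nf),
            )
        else:
            sel = select_features(train_table, y_train, max_nf, **selection_kwargs)
        fold_selections[patient] = sel
        n_feats.append(len(sel.selected))

        if sel.is_empty:
            logger.warning("fold %s: empty selection, scoring 0.5", patient)
            fold_models[patient] = None
            for sid in held:
                posteriors[sid] = 0.5
            continue

        cols = list(sel.selected)
        X_train = train_table.values[cols].to_numpy(dtype=float)
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X_std = (X_train - mu) / sd
        model = train_cost_svm(X_std, y_train.to_numpy(), cost, C_reg)
        model.feature_names = tuple(cols)
        model.scaler_mean = mu
        model.scaler_sd = sd
        f_train = X_std @ model.weights + model.bias
        a, b = calibrate_posterior(f_train, y_train.to_numpy())
        model.platt_a, model.platt_b = a, b
        fold_models[patient] = model
        ratios.append(sv_ratio(model))

        X_held = table.values.loc[held, cols].to_numpy(dtype=float)
        f_held = ((X_held - mu) / sd) @ model.weights + model.bias
        post = _sigmoid(-(a * f_held + b))  # A,B stored in the A<0 convention
        for sid, p in zip(held, post):
            posteriors[sid] = float(p)

    post_series = pd.Series(posteriors).loc[table.values.index]
    return CvResult(
        posteriors=post_series,
        labels=labels,
        fold_patients=tuple(patients),
        fold_selections=fold_selections,
        fold_models=fold_models,
        mean_n_features=float(np.mean(n_feats)),
        mean_sv_ratio=float(np.mean(ratios)) if ratios else float("nan"),
    )
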