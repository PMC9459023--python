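"""Leakage-safe three-step feature-selection cascade.

Applied independently inside every cross-validation fold, on training
rows only:

i.   variance filter — drop features with sample variance <= 0.03;
ii.  correlation filter — drop features whose absolute Pearson
     correlation with the +/-1 label is below 0.10 (boundary kept);
iii. L1-penalized (lasso) linear model over a decreasing regularization
     path, keeping the largest active set whose size does not exceed the
     configured cap ``max_nf``.

The variance threshold is a single number applied across modalities with
very different native scales (SNV-normalized spectra vs raw radiomics),
so by default radiomics columns are standardized before the variance
filter (making step i a no-op for them); ``prestandardize_rad=False``
restores the literal raw-variance behaviour.  Lasso always runs on
training-standardized columns.

If the lasso retains nothing while step ii survivors exist, the cascade
falls back to the top-``max_nf`` step-ii survivors ranked by
|correlation| (logged); if step ii itself empties the set, the result
carries an empty selection rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

logger = logging.getLogger(__name__)

VAR_THRESH_DEFAULT = 0.03
CORR_THRESH_DEFAULT = 0.10

#: Feature-set combinations exercised by the experiments.
COMBOS = ("FP", "HW", "Rad", "FP+HW", "FP+Rad", "FP+HW+Rad", "HW+Rad")


@dataclass
class FeatureTable:
    """Sites x named features, with per-feature modality tags.

    ``values`` is indexed by site id; ``tags`` maps feature name ->
    modality ("FP", "HW" or "Rad"); ``patient_ids`` maps site id ->
    patient id (needed for leave-one-patient-out folds).
    """

    values: pd.DataFrame
    tags: pd.Series
    patient_ids: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not self.values.columns.is_unique:
            raise ValueError("feature names must be unique")
        if not self.values.index.equals(self.patient_ids.index):
            raise ValueError("patient ids do not align with the site rows")
        missing = set(self.values.columns) - set(self.tags.index)
        if missing:
            raise ValueError(f"untagged features: {sorted(missing)[:5]} ...")

    @property
    def n_sites(self) -> int:
        return len(self.values)

    def subset(self, combo: str) -> "FeatureTable":
        """Restrict to a modality combination such as ``"FP+Rad"``."""
        parts = combo.split("+")
        unknown = set(parts) - {"FP", "HW", "Rad"}
        if unknown:
            raise ValueError(f"unknown feature-set name(s): {sorted(unknown)}")
        cols = [c for c in self.values.columns if self.tags[c] in parts]
        return FeatureTable(
            values=self.values[cols],
            tags=self.tags[cols],
            patient_ids=self.patient_ids,
        )

    def restrict_sites(self, site_ids) -> "FeatureTable":
        return FeatureTable(
            values=self.values.loc[site_ids],
            tags=self.tags,
            patient_ids=self.patient_ids.loc[site_ids],
        )


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one cascade run (feature names, not positions)."""

    survivors_step1: tuple[str, ...]
    survivors_step2: tuple[str, ...]
    selected: tuple[str, ...]
    weights: tuple[float, ...]
    max_nf: int
    fallback_used: bool = False

    def __post_init__(self) -> None:
        s1, s2, sel = set(self.survivors_step1), set(self.survivors_step2), set(self.selected)
        if not (sel <= s2 <= s1):
            raise ValueError("selection cascade is not nested")
        if len(self.selected) > self.max_nf:
            raise ValueError("selection exceeds max_nf cap")

    @property
    def is_empty(self) -> bool:
        return len(self.selected) == 0


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------

def variance_filter(X: np.ndarray, thresh: float = VAR_THRESH_DEFAULT) -> np.ndarray:
    """Indices of features whose sample variance is strictly above ``thresh``."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("variance filter needs at least two rows")
    return np.flatnonzero(X.var(axis=0, ddof=1) > thresh)


def correlation_filter(
    X: np.ndarray, y: np.ndarray, thresh: float = CORR_THRESH_DEFAULT
) -> np.ndarray:
    """Indices of features with |Pearson corr with the label| >= ``thresh``.

    ``y`` is +/-1.  Zero-variance features have correlation defined as 0
    and are removed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("correlation filter needs both classes present")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, (Xc * yc[:, None]).sum(axis=0) / denom, 0.0)
    return np.flatnonzero(np.abs(corr) >= thresh)


def lasso_cap(
    X_std: np.ndarray,
    y: np.ndarray,
    max_nf: int,
    n_alphas: int = 100,
    eps: float = 1e-2,
) -> tuple[np.ndarray, np.ndarray]:
    """Active set of the least-regularized lasso fit within the cap.

    Fits an L1-penalized linear model of the +/-1 label on standardized
    features along a geometric path of ``n_alphas`` penalties descending
    from the data-derived maximum.  Among path points whose active set
    has at most ``max_nf`` members, the one with the largest active set
    wins; ties go to the larger penalty (the sparser, more regularized
    fit).  Returns (indices, coefficients); both empty if no feature is
    ever active within the cap.
    """
    if max_nf < 1:
        raise ValueError("max_nf must be at least 1")
    X_std = np.asarray(X_std, dtype=float)
    if X_std.shape[1] == 0:
        raise ValueError("no features reached the lasso step")
    y = np.asarray(y, dtype=float)
    alphas, coefs, _ = lasso_path(X_std, y, alphas=n_alphas, eps=eps, max_iter=10000)
    active_sizes = (coefs != 0).sum(axis=0)
    candidates = np.flatnonzero(active_sizes <= max_nf)
    if candidates.size == 0 or active_sizes[candidates].max() == 0:
        return np.array([], dtype=int), np.array([])
    best_size = active_sizes[candidates].max()
    # alphas are descending, so the first candidate at best_size is the
    # largest-penalty one
    k = candidates[np.argmax(active_sizes[candidates] == best_size)]
    idx = np.flatnonzero(coefs[:, k])
    return idx, coefs[idx, k]


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def select_features(
    table: FeatureTable,
    y: pd.Series,
    max_nf: int,
    var_thresh: float = VAR_THRESH_DEFAULT,
    corr_thresh: float = CORR_THRESH_DEFAULT,
    prestandardize_rad: bool = True,
) -> SelectionResult:
    """Run the cascade i -> ii -> iii on training rows only.

    ``table`` must already be restricted to the training sites; every
    statistic (variances, correlations, standardization parameters, the
    lasso path) is estimated from those rows exclusively.
    """
    X = table.values.to_numpy(dtype=float)
    names = np.asarray(table.values.columns)
    yv = np.asarray(y.loc[table.values.index], dtype=float)

    X_var = X.copy()
    if prestandardize_rad:
        rad_cols = np.flatnonzero(table.tags[names].to_numpy() == "Rad")
        if rad_cols.size:
            mu = X[:, rad_cols].mean(axis=0)
            sd = X[:, rad_cols].std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            X_var[:, rad_cols] = (X[:, rad_cols] - mu) / sd

    idx1 = variance_filter(X_var, var_thresh)
    if idx1.size == 0:
        logger.warning("variance filter removed every feature")
        return SelectionResult((), (), (), (), max_nf)

    idx2 = idx1[correlation_filter(X[:, idx1], yv, corr_thresh)]
    if idx2.size == 0:
        logger.warning("correlation filter removed every feature")
        return SelectionResult(tuple(names[idx1]), (), (), (), max_nf)

    X2 = X[:, idx2]
    mu = X2.mean(axis=0)
    sd = X2.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X2_std = (X2 - mu) / sd

    sel_local, weights = lasso_cap(X2_std, yv, max_nf)
    fallback = False
    if sel_local.size == 0:
        # deterministic fallback: strongest step-ii survivors by |corr|
        fallback = True
        logger.warning("lasso retained nothing; falling back to top-|corr| features")
        Xc = X2 - X2.mean(axis=0)
        yc = yv - yv.mean()
        denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
        corr = np.where(denom > 0, (Xc * yc[:, None]).sum(axis=0) / denom, 0.0)
        order = np.argsort(-np.abs(corr), kind="stable")[:max_nf]
        sel_local = np.sort(order)
        weights = corr[sel_local]

    idx3 = idx2[sel_local]
    return SelectionResult(
        survivors_step1=tuple(names[idx1]),
        survivors_step2=tuple(names[idx2]),
        selected=tuple(names[idx3]),
        weights=tuple(float(w) for w in weights),
        max_nf=max_nf,
        fallback_used=fallback,
    )
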