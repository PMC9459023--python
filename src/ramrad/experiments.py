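"""Label assignment, ROC evaluation and the three experiment drivers.

Three binary prediction tasks are derived from per-site histology:

* ``gg_gt1``   — clinically significant cancer: +1 iff ISUP GG > 1
  (benign and GG1 are the negative class);
* ``gg_ge1``   — any cancer: +1 iff ISUP GG >= 1, benign negative;
* ``high_grade`` — as ``gg_ge1`` but tumor sites whose high-grade
  percentage is below 20% are excluded (benign sites always retained).

ROC analysis pools the held-out posteriors of all cross-validation folds
(one posterior per site), builds the empirical ROC by threshold sweep,
integrates AUC by the trapezoid rule, and reports accuracy, sensitivity
and specificity at the operating point closest (Euclidean) to the
(FPR, TPR) = (0, 1) corner; among equidistant thresholds the more
sensitive one wins, consistent with the false-negative-averse cost
design.  The cost matrix shapes training only — reported accuracy is the
plain proportion correct.

The drivers mirror the three study experiments: a feature-combination
comparison over {FP, HW, Rad} and their unions at a fixed selection cap,
a sweep of the cap from 2 to 18 with fold-frequency bookkeeping of the
selected features, and a prediction-task comparison that re-labels the
cohort and re-runs LOPOCV with a fixed consensus feature list (selection
bypassed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .classify_svm import CostMatrix, CvResult, lopocv
from .feature_selection import COMBOS, FeatureTable, SelectionResult

logger = logging.getLogger(__name__)

SCHEMES = ("gg_gt1", "gg_ge1", "high_grade")
HG_CUTOFF_PERCENT = 20.0

#: Label sentinel for sites excluded by a scheme.
EXCLUDED = 0


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def assign_labels(
    histology: pd.DataFrame, scheme: str, hg_cutoff: float = HG_CUTOFF_PERCENT
) -> pd.Series:
    """Per-site label in {+1, -1, 0}; 0 marks sites excluded by the scheme.

    ``histology`` needs columns ``isup_gg`` and ``hg_percent`` (the
    latter may be missing/NaN for benign sites only).  Under
    ``high_grade`` a tumor site with missing HG is an error.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown labeling scheme {scheme!r}")
    gg = histology["isup_gg"].astype(int)
    hg = histology["hg_percent"] if "hg_percent" in histology else pd.Series(np.nan, index=histology.index)
    if scheme == "gg_gt1":
        return pd.Series(np.where(gg > 1, 1, -1), index=histology.index)
    if scheme == "gg_ge1":
        return pd.Series(np.where(gg >= 1, 1, -1), index=histology.index)
    # high_grade
    tumor = gg >= 1
    missing = tumor & hg.isna()
    if missing.any():
        raise ValueError(
            f"high_grade scheme: tumor site(s) without HG%: {list(histology.index[missing])[:5]}"
        )
    labels = np.where(tumor, 1, -1)
    labels = np.where(tumor & (hg < hg_cutoff), EXCLUDED, labels)
    return pd.Series(labels, index=histology.index)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocSummary:
    """Empirical ROC with the closest-to-corner operating point."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    optimal_threshold: float
    optimal_fpr: float
    optimal_tpr: float
    accuracy: float
    sensitivity: float
    specificity: float


def roc_summary(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> RocSummary:
    """Pooled-score ROC, trapezoid AUC, closest-to-(0,1) operating point.

    A site is called positive when its score is >= the threshold.  The
    operating point minimizes the Euclidean distance to (FPR, TPR) =
    (0, 1); ties break toward higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    dist2 = fpr**2 + (1.0 - tpr) ** 2
    best = np.flatnonzero(dist2 == dist2.min())
    k = best[np.argmax(tpr[best])]  # tie -> higher sensitivity
    threshold = float(thr[k]) if np.isfinite(thr[k]) else float(scores.max() + 1.0)

    pred = np.where(scores >= threshold, 1, -1)
    tp = np.sum((pred == 1) & (y == 1))
    tn = np.sum((pred == -1) & (y == -1))
    fp = np.sum((pred == 1) & (y == -1))
    fn = np.sum((pred == -1) & (y == 1))
    return RocSummary(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        optimal_threshold=threshold,
        optimal_fpr=float(fpr[k]),
        optimal_tpr=float(tpr[k]),
        accuracy=float((tp + tn) / len(y)),
        sensitivity=float(tp / (tp + fn)),
        specificity=float(tn / (tn + fp)),
    )


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------

def _metrics_row(cv: CvResult) -> dict[str, float]:
    roc = roc_summary(cv.posteriors, cv.labels)
    return {
        "mean_n_features": cv.mean_n_features,
        "auc": roc.auc,
        "accuracy": roc.accuracy,
        "sensitivity": roc.sensitivity,
        "specificity": roc.specificity,
        "sv_ratio": cv.mean_sv_ratio,
    }


def feature_combination_experiment(
    table: FeatureTable,
    labels: pd.Series,
    combos: tuple[str, ...] = COMBOS,
    max_nf: int = 10,
    cost: CostMatrix | None = None,
    C_reg: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, CvResult]]:
    """One LOPOCV run per feature-set combination.

    Returns a report with one row per combination (mean selected
    features, AUC, accuracy, sensitivity, specificity, mean
    support-vector ratio) and the underlying per-combination CV results.
    """
    rows, cvs = [], {}
    for combo in combos:
        cv = lopocv(table.subset(combo), labels, cost=cost, max_nf=max_nf, C_reg=C_reg)
        cvs[combo] = cv
        rows.append({"features": combo, **_metrics_row(cv)})
    report = pd.DataFrame(rows).set_index("features")
    return report, cvs


def max_nf_sweep(
    table: FeatureTable,
    labels: pd.Series,
    combo: str = "FP+Rad",
    max_nf_values: tuple[int, ...] = tuple(range(2, 19)),
    cost: CostMatrix | None = None,
    C_reg: float = 1.0,
) -> tuple[pd.DataFrame, dict[int, CvResult]]:
    """Sweep the selection cap, reporting realized feature counts and metrics."""
    sub = table.subset(combo)
    rows, cvs = [], {}
    for max_nf in max_nf_values:
        cv = lopocv(sub, labels, cost=cost, max_nf=max_nf, C_reg=C_reg)
        cvs[max_nf] = cv
        rows.append({"max_nf": max_nf, **_metrics_row(cv)})
    return pd.DataFrame(rows).set_index("max_nf"), cvs


def consensus_features(
    fold_selections: dict[str, SelectionResult] | CvResult, min_count: int = 10
) -> pd.Series:
    """Features selected in strictly more than ``min_count`` folds.

    Accepts either a CvResult or its ``fold_selections`` mapping; returns
    feature name -> fold count, descending.
    """
    if isinstance(fold_selections, CvResult):
        counts = fold_selections.selection_counts()
    else:
        acc: dict[str, int] = {}
        for sel in fold_selections.values():
            for name in sel.selected:
                acc[name] = acc.get(name, 0) + 1
        counts = pd.Series(acc, dtype=int).sort_values(ascending=False)
    return counts[counts > min_count]


def prediction_task_experiment(
    table: FeatureTable,
    histology: pd.DataFrame,
    fixed_features: tuple[str, ...],
    schemes: tuple[str, ...] = SCHEMES,
    cost: CostMatrix | None = None,
    C_reg: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, CvResult]]:
    """Re-label, drop exclusions, and run LOPOCV with selection bypassed.

    One row per scheme: site/class counts plus accuracy, sensitivity and
    specificity at the pooled-ROC operating point.
    """
    if len(fixed_features) == 0:
        raise ValueError("fixed feature list must be non-empty")
    rows, cvs = [], {}
    for scheme in schemes:
        labels = assign_labels(histology, scheme)
        keep = labels.index[labels != EXCLUDED]
        y = labels.loc[keep]
        if (y == 1).sum() == 0 or (y == -1).sum() == 0:
            raise ValueError(f"scheme {scheme!r} leaves one class empty")
        sub = table.restrict_sites(keep)
        cv = lopocv(sub, y, cost=cost, max_nf=len(fixed_features), fixed_features=fixed_features, C_reg=C_reg)
        cvs[scheme] = cv
        roc = roc_summary(cv.posteriors, cv.labels)
        rows.append(
            {
                "task": scheme,
                "n_sites": int(len(keep)),
                "n_positive": int((y == 1).sum()),
                "n_negative": int((y == -1).sum()),
                "auc": roc.auc,
                "accuracy": roc.accuracy,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            }
        )
    return pd.DataFrame(rows).set_index("task"), cvs


# ---------------------------------------------------------------------------
# Planted-effect recovery bookkeeping
# ---------------------------------------------------------------------------

#: Radiomics identifiers responsive to the two planted imaging effects:
#: the ADC intensity drop shows up in the ADC first-order statistics; the
#: in-lesion b2000 noise decorrelation shows up in the b2000 GLCM
#: statistics and in the first-order dispersion statistics (entropy, SD,
#: mean absolute deviation, uniformity), whose sampling behaviour changes
#: with spatial correlation even at fixed marginal variance.
ADC_INTENSITY_IDS = tuple(f"r{i}" for i in range(17, 25))
B2000_TEXTURE_IDS = ("r35", "r38", "r39", "r40") + tuple(f"r{i}" for i in range(41, 49))


def planted_recovery_count(
    cv: CvResult | dict[str, SelectionResult],
    bands: tuple,
    min_count: int = 10,
    width_multiplier: float = 2.0,
) -> int:
    """How many planted effects reach fold-level consensus.

    Each planted effect defines a group of interchangeable feature
    representatives: for a spectral band (center, width) every FP shift
    within ``width_multiplier`` Gaussian widths (at least 6 cm^-1, an
    instrument-bandwidth floor) of the center; for the ADC intensity effect the ADC first-order
    identifiers; for the b2000 texture effect the b2000 GLCM and
    first-order dispersion identifiers.  An effect is recovered when
    strictly more than ``min_count`` folds selected at least one of its
    representatives — consensus is assessed at the effect level because
    collinear representatives of one effect (e.g. ADC Energy vs ADC
    Mean, or adjacent samples of one band) are interchangeable to an
    L1-penalized selector and would otherwise split their fold counts.
    The maximum is ``len(bands) + 2``.
    """
    fold_selections = cv.fold_selections if isinstance(cv, CvResult) else cv

    def group_count(member: callable) -> int:
        return sum(
            any(member(name) for name in sel.selected)
            for sel in fold_selections.values()
        )

    recovered = 0
    for band in bands:
        center, width = band if isinstance(band, tuple) else (band, 3.0)
        tol = max(width_multiplier * width, 6.0)

        def in_band(name: str, center=center, tol=tol) -> bool:
            return name.startswith("FP_") and abs(float(name.split("_", 1)[1]) - center) <= tol

        if group_count(in_band) > min_count:
            recovered += 1
    if group_count(lambda n: n in ADC_INTENSITY_IDS) > min_count:
        recovered += 1
    if group_count(lambda n: n in B2000_TEXTURE_IDS) > min_count:
        recovered += 1
    return recovered
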