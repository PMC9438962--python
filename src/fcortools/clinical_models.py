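"""Clinical modelling on hub FCOR features.

Composite motor scores (tremor-dominant and PIGD sums of MDS-UPDRS
sub-items), linear-SVM classification with stratified cross-validation,
first-principal-component scoring of patient features, Pearson associations,
and two-sample t-tests recomputed from printed summary statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import PIGD_ITEMS, TREMOR_ITEMS, UPDRS_PREFIX, ClinicalTable
from .errors import ParameterError


# ---------------------------------------------------------------------------
# Composite motor scores
# ---------------------------------------------------------------------------

def composite_scores(clinical: ClinicalTable) -> pd.DataFrame:
    """Tremor, PIGD and Part-III total scores per patient.

    Tremor is the sum of sub-items 2.10, 3.15, 3.16, 3.17 and 3.18; PIGD of
    2.12, 2.13, 3.10, 3.11 and 3.12; the Part-III total sums every available
    ``3.x`` item. A score whose constituent items are not all present is
    flagged missing (such patients are excluded from associations).
    """
    frame = clinical.frame
    patients = frame[frame["group"] == "patient"]
    item_cols = clinical.updrs_columns()
    part3 = [c for c in item_cols if c[len(UPDRS_PREFIX):].startswith("3.")]
    out = []
    for _, row in patients.iterrows():
        rec = {"subject_id": row["subject_id"]}
        for name, items in (("tremor", TREMOR_ITEMS), ("pigd", PIGD_ITEMS)):
            cols = [UPDRS_PREFIX + it for it in items]
            have = [c for c in cols if c in frame.columns and pd.notna(row.get(c))]
            if len(have) == len(items):
                rec[name] = float(sum(row[c] for c in have))
                rec[f"{name}_missing"] = False
            else:
                rec[name] = np.nan
                rec[f"{name}_missing"] = True
        vals = [row[c] for c in part3 if pd.notna(row.get(c))]
        if part3 and len(vals) == len(part3):
            rec["updrs3_total"] = float(sum(vals))
            rec["updrs3_missing"] = False
        else:
            rec["updrs3_total"] = np.nan
            rec["updrs3_missing"] = True
        out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def svm_cv_accuracy(features: np.ndarray | pd.DataFrame, labels: np.ndarray,
                    c: float = 1.0, folds: int = 10, seed: int = 0,
                    standardize: bool = True) -> float:
    """Stratified k-fold cross-validated accuracy (percent) of a linear SVM.

    Accuracy pools correct/total over the held-out folds. Standardization is
    fit inside each training fold, so no information leaks from test folds.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ParameterError("labels must contain exactly 2 classes")
    if folds == y.size:
        if counts.min() < 2:
            raise ParameterError("leave-one-out needs both classes twice")
        cv = LeaveOneOut()
    elif counts.min() < folds:
        raise ParameterError(
            f"smallest class has {counts.min()} subjects; cannot stratify "
            f"into {folds} folds")
    else:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    steps = ([StandardScaler()] if standardize else []) + [SVC(kernel="linear", C=c)]
    model = make_pipeline(*steps)
    pred = cross_val_predict(model, X, y, cv=cv)
    return float(100.0 * np.mean(pred == y))


# ---------------------------------------------------------------------------
# PCA scoring
# ---------------------------------------------------------------------------

def pca_first_component(features: np.ndarray | pd.DataFrame):
    """First principal component of a feature table.

    Returns ``(loadings, scores, variance_fraction)`` where loadings are the
    unit-norm leading eigenvector of the feature covariance with the
    largest-magnitude loading made positive, and scores are the centred data
    projected on it. Handles n < p through the SVD of the centred matrix.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ParameterError("PCA needs at least 2 rows and 2 columns")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ParameterError("zero-variance data: first component undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[0]
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
    scores = Xc @ loadings
    variance_fraction = float(S[0] ** 2 / np.sum(S ** 2))
    return loadings, scores, variance_fraction


# ---------------------------------------------------------------------------
# Associations
# ---------------------------------------------------------------------------

def pearson_assoc(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p (t-transform, df = n - 2); incomplete
    pairs are dropped listwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ParameterError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def summary_two_sample_t(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int) -> tuple[float, int]:
    """Pooled-variance two-sample t from printed summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ParameterError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ParameterError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df)


def summary_t_pvalue(t: float, df: int) -> float:
    return float(2.0 * special.stdtr(df, -abs(t)))
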