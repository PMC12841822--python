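"""Correlative species distribution model: predictor screening, random
forest with repeated stratified validation, and probability-raster prediction.

Screening is two-stage: a pairwise Pearson filter drops one of every pair of
bioclim layers correlated beyond |r| = 0.8, then an L1-penalized logistic
regression (penalty chosen by 5-fold CV with the one-standard-error rule)
zeroes out weak predictors.  The classifier is a random forest evaluated by
AUC, the True Skill Statistic and Cohen's kappa over 10 stratified random
70/30 splits, with permutation importances normalized to percent
contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score, log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .climate import BIOCLIM_NAMES, BioclimGrid
from .occurrences import OccurrenceSet

__all__ = [
    "PredictorTable",
    "ModelEvaluation",
    "VariableImportance",
    "extract_predictors",
    "pearson_filter",
    "lasso_screen",
    "screen_predictors",
    "tss_from_confusion",
    "kappa_from_confusion",
    "evaluate",
    "train_rf_cv",
    "predict_raster",
]


@dataclass
class PredictorTable:
    """Bioclim values sampled at occurrence/pseudo-absence locations."""

    data: pd.DataFrame          # one column per bioclim variable
    labels: np.ndarray          # 1 = presence, 0 = pseudo-absence

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.data) != self.labels.size:
            raise ValueError("table and labels length mismatch")
        if self.data.isna().any().any():
            raise ValueError("predictor table contains missing values")
        classes, counts = np.unique(self.labels, return_counts=True)
        if classes.size < 2 or counts.min() < 2:
            raise ValueError("need at least 2 records in each class")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ModelEvaluation:
    """AUC / TSS / kappa, per validation split and averaged."""

    auc_folds: np.ndarray
    tss_folds: np.ndarray
    kappa_folds: np.ndarray

    @property
    def auc(self) -> float:
        return float(np.mean(self.auc_folds))

    @property
    def tss(self) -> float:
        return float(np.mean(self.tss_folds))

    @property
    def kappa(self) -> float:
        return float(np.mean(self.kappa_folds))

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "tss": self.tss,
            "kappa": self.kappa,
            "auc_folds": self.auc_folds.tolist(),
            "tss_folds": self.tss_folds.tolist(),
            "kappa_folds": self.kappa_folds.tolist(),
        }


@dataclass
class VariableImportance:
    """Percent contribution per retained variable (sums to 100)."""

    contributions: pd.Series = field(default_factory=pd.Series)

    def top(self, n: int) -> list[str]:
        return list(self.contributions.sort_values(ascending=False).index[:n])


def extract_predictors(bioclim: BioclimGrid, points: OccurrenceSet) -> PredictorTable:
    """Sample every bioclim layer at each record's cell (nearest center);
    records on nodata cells are dropped."""
    lat_axis, lon_axis = bioclim.lat_axis, bioclim.lon_axis
    dlat = lat_axis[1] - lat_axis[0] if lat_axis.size > 1 else 1.0
    dlon = lon_axis[1] - lon_axis[0] if lon_axis.size > 1 else 1.0
    ilat = np.clip(np.round((points.lat - lat_axis[0]) / dlat).astype(int), 0, lat_axis.size - 1)
    ilon = np.clip(np.round((points.lon - lon_axis[0]) / dlon).astype(int), 0, lon_axis.size - 1)
    cols = {name: bioclim.layers[name][ilat, ilon] for name in BIOCLIM_NAMES}
    df = pd.DataFrame(cols)
    ok = ~df.isna().any(axis=1).to_numpy()
    labels = (points.label == "presence").astype(int)[ok]
    return PredictorTable(data=df.loc[ok].reset_index(drop=True), labels=labels)


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def pearson_filter(table: PredictorTable, threshold: float = 0.8) -> list[str]:
    """Greedy collinearity filter in fixed bio1..bio19 column order.

    A variable is dropped iff |r| with any already-retained variable exceeds
    the threshold, so the earlier variable of a correlated pair wins; the
    retained set has all pairwise |r| <= threshold.  Constant columns have
    undefined correlation and are dropped with a warning.
    """
    if len(table.data) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    retained: list[str] = []
    for name in table.variables:
        col = table.data[name].to_numpy(dtype=float)
        if np.std(col) == 0:
            warnings.warn(f"dropping constant predictor {name}", stacklevel=2)
            continue
        ok = True
        for kept in retained:
            r = np.corrcoef(col, table.data[kept].to_numpy(dtype=float))[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            retained.append(name)
    return retained


def lasso_screen(
    table: PredictorTable,
    variables: list[str] | None = None,
    seed: int = 0,
    n_c: int = 20,
) -> list[str]:
    """Variables with nonzero L1-logistic coefficients.

    Predictors are standardized; the penalty strength is chosen over a log
    grid by 5-fold stratified CV log-loss with the one-standard-error rule
    (strongest penalty within one SE of the minimum).  May legitimately
    return an empty list when no predictor carries signal.
    """
    variables = variables if variables is not None else table.variables
    X = table.data[variables].to_numpy(dtype=float)
    y = table.labels
    if np.unique(y).size < 2:
        raise ValueError("lasso screening needs both classes")
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    cs = np.logspace(-3, 2, n_c)
    n_splits = min(5, np.bincount(y).min())
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    mean_loss = np.empty(n_c)
    se_loss = np.empty(n_c)
    for i, c in enumerate(cs):
        losses = []
        for tr, te in cv.split(X, y):
            clf = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear", random_state=seed)
            clf.fit(X[tr], y[tr])
            losses.append(log_loss(y[te], clf.predict_proba(X[te])[:, 1], labels=[0, 1]))
        mean_loss[i] = np.mean(losses)
        se_loss[i] = np.std(losses, ddof=1) / np.sqrt(len(losses))
    best = int(np.argmin(mean_loss))
    # 1-SE rule: strongest penalty (smallest C) within one SE of the best
    within = np.flatnonzero(mean_loss <= mean_loss[best] + se_loss[best])
    c_star = cs[within.min()]
    clf = LogisticRegression(l1_ratio=1.0, C=c_star, solver="liblinear", random_state=seed)
    clf.fit(X, y)
    coefs = clf.coef_.ravel()
    return [v for v, c in zip(variables, coefs) if c != 0.0]


def screen_predictors(
    table: PredictorTable, threshold: float = 0.8, seed: int = 0
) -> list[str]:
    """Pearson filter then LASSO; falls back to the Pearson-retained set with
    a warning if the LASSO zeroes out everything."""
    retained = pearson_filter(table, threshold)
    selected = lasso_screen(table, retained, seed=seed)
    if not selected:
        warnings.warn(
            "LASSO screening removed every predictor; falling back to the "
            "Pearson-retained set",
            stacklevel=2,
        )
        return retained
    return selected


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def tss_from_confusion(tp: int, fn: int, tn: int, fp: int) -> float:
    """True Skill Statistic = sensitivity + specificity − 1."""
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def kappa_from_confusion(tp: int, fn: int, tn: int, fp: int) -> float:
    """Cohen's kappa from a 2×2 confusion table."""
    n = tp + fn + tn + fp
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    return (po - pe) / (1 - pe)


def evaluate(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float]:
    """AUC, TSS and kappa of probability scores against binary labels.

    AUC is the rank statistic; TSS and kappa are computed at the score
    threshold that maximizes TSS (ties broken toward the lowest threshold).
    Returns (auc, tss, kappa, threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("evaluation needs both classes present")
    auc = float(roc_auc_score(labels, scores))
    best_tss, best_thr = -np.inf, 0.5
    for thr in np.unique(scores):
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        fn = int(np.sum(~pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        fp = int(np.sum(pred & (labels == 0)))
        tss = tss_from_confusion(tp, fn, tn, fp)
        if tss > best_tss:
            best_tss, best_thr = tss, float(thr)
    kappa = float(cohen_kappa_score(labels, (scores >= best_thr).astype(int)))
    return auc, float(best_tss), kappa, best_thr


# ---------------------------------------------------------------------------
# Random forest with repeated stratified validation
# ---------------------------------------------------------------------------

def train_rf_cv(
    table: PredictorTable,
    variables: list[str] | None = None,
    folds: int = 10,
    train_frac: float = 0.7,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[RandomForestClassifier, ModelEvaluation, VariableImportance]:
    """Random forest over ``folds`` stratified random 70/30 splits.

    Each split trains on ``train_frac`` of the records (stratified by class)
    and evaluates AUC/TSS/kappa on the held-out rest; variable importance is
    the permutation importance on held-out data, averaged over splits and
    normalized to percent.  The returned model is refit on all records.
    """
    variables = variables if variables is not None else table.variables
    X = table.data[variables].to_numpy(dtype=float)
    y = table.labels
    splitter = StratifiedShuffleSplit(
        n_splits=folds, train_size=train_frac, random_state=seed
    )
    aucs, tsss, kappas = [], [], []
    importances = np.zeros(len(variables))
    for i, (tr, te) in enumerate(splitter.split(X, y)):
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ValueError("a class is absent from a validation split")
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + i, n_jobs=1)
        rf.fit(X[tr], y[tr])
        scores = rf.predict_proba(X[te])[:, 1]
        auc, tss, kappa, _ = evaluate(scores, y[te])
        aucs.append(auc)
        tsss.append(tss)
        kappas.append(kappa)
        perm = permutation_importance(
            rf, X[te], y[te], n_repeats=5, random_state=seed + i, scoring="roc_auc"
        )
        importances += np.maximum(perm.importances_mean, 0.0)
    total = importances.sum()
    if total == 0:
        contrib = pd.Series(np.full(len(variables), 100.0 / len(variables)), index=variables)
    else:
        contrib = pd.Series(importances / total * 100.0, index=variables)
    final = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    final.fit(X, y)
    evaluation = ModelEvaluation(
        auc_folds=np.asarray(aucs), tss_folds=np.asarray(tsss), kappa_folds=np.asarray(kappas)
    )
    return final, evaluation, VariableImportance(contributions=contrib)


def predict_raster(
    model: RandomForestClassifier, bioclim: BioclimGrid, variables: list[str]
) -> np.ndarray:
    """Per-cell presence probability in [0, 1]; NaN where any layer is nodata."""
    missing = [v for v in variables if v not in bioclim.layers]
    if missing:
        raise ValueError(f"bioclim grid lacks layer(s): {missing}")
    stack = np.stack([bioclim.layers[v] for v in variables], axis=-1)
    ok = np.all(np.isfinite(stack), axis=-1)
    out = np.full(ok.shape, np.nan)
    if ok.any():
        out[ok] = model.predict_proba(stack[ok])[:, 1]
    return out
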