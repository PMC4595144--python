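"""Nearest shrunken centroid ("prediction analysis of microarrays")
classification.

Per gene i and class k the standardised centroid offset is

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n)

with s_i the pooled within-class standard deviation and s0 a fudge
constant (median of the s_i). Soft-thresholding d'_ik =
sign(d_ik) * max(|d_ik| - delta, 0) shrinks uninformative genes to the
overall centroid; genes with d' = 0 in every class drop out of the
classifier. Prediction uses the discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k

with class probabilities proportional to exp(-delta_k / 2). The amount of
shrinkage is chosen by stratified cross-validation, preferring the
largest delta (fewest genes) at the minimum error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NearestShrunkenCentroid",
    "make_delta_grid",
    "cross_validate_delta",
    "ShrunkenCentroidModel",
    "fit_nsc",
    "smallest_gene_set_report",
]


class NearestShrunkenCentroid(ClassifierMixin, BaseEstimator):
    """Nearest shrunken centroid classifier (binary or multiclass).

    Parameters
    ----------
    delta : float
        Soft-threshold applied to the standardised centroid offsets.
    priors : array-like or None
        Class prior probabilities; empirical class frequencies when None.

    Attributes (after fit)
    ----------------------
    classes_ : sorted class labels (ties in the discriminant predict the
        first class, so with control < case labels a tie predicts control)
    overall_centroid_ : per-gene overall mean
    class_centroids_ : n_classes x n_genes shrunken centroids
    pooled_sd_, s0_ : per-gene pooled SD and the fudge constant
    dik_ : n_classes x n_genes standardised offsets before shrinkage
    active_genes_ : boolean mask of genes with a nonzero shrunken offset
    """

    def __init__(self, delta: float = 0.0, priors=None):
        self.delta = delta
        self.priors = priors

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        counts = np.bincount(y_idx)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < 3:
            raise ValueError("each class needs at least 3 samples")

        overall = X.mean(axis=0)
        class_means = np.stack([X[y_idx == k].mean(axis=0)
                                for k in range(len(self.classes_))])
        within_ss = np.zeros(p)
        for k in range(len(self.classes_)):
            within_ss += ((X[y_idx == k] - class_means[k]) ** 2).sum(axis=0)
        pooled_sd = np.sqrt(within_ss / (n - len(self.classes_)))
        if not np.any(pooled_sd > 0):
            raise ValueError("all genes have zero pooled within-class variance")
        s0 = float(np.median(pooled_sd))

        m_k = np.sqrt(1.0 / counts - 1.0 / n)
        denom = m_k[:, None] * (pooled_sd + s0)[None, :]
        dik = (class_means - overall) / denom
        shrunk = np.sign(dik) * np.maximum(np.abs(dik) - self.delta, 0.0)

        self.overall_centroid_ = overall
        self.class_centroids_ = overall + denom * shrunk
        self.pooled_sd_ = pooled_sd
        self.s0_ = s0
        self.dik_ = dik
        self.shrunken_dik_ = shrunk
        self.active_genes_ = (shrunk != 0).any(axis=0)
        self.priors_ = (counts / n if self.priors is None
                        else np.asarray(self.priors, float))
        if abs(self.priors_.sum() - 1.0) > 1e-8:
            raise ValueError("priors must sum to 1")
        self.n_features_in_ = p
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Discriminant delta_k(x) per sample and class (lower is closer)."""
        check_is_fitted(self, "class_centroids_")
        X = np.asarray(X, float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} genes, model was fit with {self.n_features_in_}"
            )
        s = (self.pooled_sd_ + self.s0_) ** 2
        scores = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            diff = X - self.class_centroids_[k]
            scores[:, k] = (diff**2 / s).sum(axis=1)
        return scores - 2.0 * np.log(self.priors_)

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        logp = -scores / 2.0
        logp -= logp.max(axis=1, keepdims=True)
        prob = np.exp(logp)
        return prob / prob.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        # argmin takes the first index on ties -> first (control) class
        return self.classes_[np.argmin(scores, axis=1)]


def make_delta_grid(model: NearestShrunkenCentroid, n_values: int = 30) -> np.ndarray:
    """Linear grid of shrinkage thresholds from 0 to max |d_ik|."""
    check_is_fitted(model, "dik_")
    return np.linspace(0.0, float(np.abs(model.dik_).max()), n_values)


def cross_validate_delta(X, y, delta_grid, n_folds: int = 10,
                         seed: int | None = None,
                         ) -> tuple[np.ndarray, float]:
    """Stratified K-fold misclassification per delta; chosen delta is the
    largest value attaining the minimum error (fewest genes at equal
    error). Folds that end up single-class are refolded with a new seed
    (up to 10 attempts)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    delta_grid = np.asarray(delta_grid, float)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng_seed = 0 if seed is None else seed
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=rng_seed + attempt)
        folds = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) >= 2 for tr, _ in folds):
            break
    else:
        raise ValueError("could not build folds containing both classes")
    errors = np.zeros((len(folds), len(delta_grid)))
    for f, (tr, te) in enumerate(folds):
        for j, delta in enumerate(delta_grid):
            m = NearestShrunkenCentroid(delta=delta).fit(X[tr], y[tr])
            errors[f, j] = (m.predict(X[te]) != y[te]).mean()
    cv_errors = errors.mean(axis=0)
    best = cv_errors.min()
    chosen = float(delta_grid[np.flatnonzero(cv_errors == best)[-1]])
    return cv_errors, chosen


@dataclass
class ShrunkenCentroidModel:
    """Fitted classifier state plus the cross-validation curve."""

    estimator: NearestShrunkenCentroid
    gene_ids: list[str]
    delta_grid: np.ndarray
    cv_errors: np.ndarray
    chosen_delta: float
    X_train: np.ndarray = field(repr=False)
    y_train: np.ndarray = field(repr=False)

    @property
    def active_genes(self) -> list[str]:
        mask = self.estimator.active_genes_
        return [g for g, a in zip(self.gene_ids, mask) if a]

    def to_json(self, path: str | Path) -> None:
        est = self.estimator
        payload = {
            "gene_ids": self.gene_ids,
            "classes": est.classes_.tolist(),
            "overall_centroid": est.overall_centroid_.tolist(),
            "class_centroids": est.class_centroids_.tolist(),
            "pooled_sd": est.pooled_sd_.tolist(),
            "s0": est.s0_,
            "priors": est.priors_.tolist(),
            "delta": est.delta,
            "delta_grid": self.delta_grid.tolist(),
            "cv_errors": self.cv_errors.tolist(),
            "chosen_delta": self.chosen_delta,
            "active_genes": self.active_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def fit_nsc(expr: pd.DataFrame, status, delta_grid=None, n_folds: int = 10,
            seed: int | None = None) -> ShrunkenCentroidModel:
    """Fit the classifier on probes x samples expression with CV-chosen delta."""
    X = expr.to_numpy(float).T
    y = np.asarray(status).astype(int)
    probe_ids = list(expr.index)
    if delta_grid is None:
        probe = NearestShrunkenCentroid().fit(X, y)
        delta_grid = make_delta_grid(probe)
    delta_grid = np.asarray(delta_grid, float)
    cv_errors, chosen = cross_validate_delta(X, y, delta_grid, n_folds, seed)
    est = NearestShrunkenCentroid(delta=chosen).fit(X, y)
    return ShrunkenCentroidModel(est, probe_ids, delta_grid, cv_errors, chosen, X, y)


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Misclassification rate, sensitivity and specificity (case label 1)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    mis = float((y_true != y_pred).mean())
    pos, neg = y_true == 1, y_true == 0
    sens = float((y_pred[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((y_pred[neg] == 0).mean()) if neg.any() else np.nan
    return {"misclassification": mis, "sensitivity": sens, "specificity": spec}


def predict_nsc(model: ShrunkenCentroidModel, expr_new: pd.DataFrame,
                status_new=None) -> dict:
    """Predict a probes x samples replication matrix with a fitted model.

    Returns per-sample class probabilities and predictions, plus aggregate
    confusion metrics when true labels are supplied. Raises (listing the
    probes) if the model's genes are missing from the new data.
    """
    missing = [g for g in model.gene_ids if g not in expr_new.index]
    if missing:
        raise ValueError(f"replication data lacks model gene(s): {missing[:5]} "
                         f"(+{max(0, len(missing) - 5)} more)")
    X = expr_new.loc[model.gene_ids].to_numpy(float).T
    proba = model.estimator.predict_proba(X)
    pred = model.estimator.predict(X)
    out = {
        "probabilities": pd.DataFrame(proba, index=expr_new.columns,
                                      columns=[str(c) for c in
                                               model.estimator.classes_]),
        "predicted": pd.Series(pred, index=expr_new.columns, name="predicted"),
    }
    if status_new is not None:
        out.update(evaluate_predictions(np.asarray(status_new), pred))
    return out


def smallest_gene_set_report(model: ShrunkenCentroidModel,
                             expr_new: pd.DataFrame, status_new,
                             error_ceiling: float) -> dict:
    """Smallest gene set meeting a replication misclassification ceiling.

    Scans the delta grid from most to least shrunken and returns the first
    (hence smallest) nonempty active gene set whose replication
    misclassification is <= `error_ceiling`. When no delta qualifies, the
    best achieved error is reported with an empty gene set flag.
    """
    if not 0 < error_ceiling <= 1:
        raise ValueError("error_ceiling must be in (0, 1]")
    X_new = expr_new.loc[model.gene_ids].to_numpy(float).T
    y_new = np.asarray(status_new).astype(int)
    best = None
    for delta in sorted(np.asarray(model.delta_grid, float), reverse=True):
        est = NearestShrunkenCentroid(delta=float(delta))
        est.fit(model.X_train, model.y_train)
        if not est.active_genes_.any():
            continue
        metrics = evaluate_predictions(y_new, est.predict(X_new))
        genes = [g for g, a in zip(model.gene_ids, est.active_genes_) if a]
        if metrics["misclassification"] <= error_ceiling:
            return {"delta": float(delta), "genes": genes, "qualified": True,
                    **metrics}
        if best is None or metrics["misclassification"] < best["misclassification"]:
            best = {"delta": float(delta), "n_genes": len(genes), **metrics}
    return {"qualified": False, "genes": [], "best_achieved": best}
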