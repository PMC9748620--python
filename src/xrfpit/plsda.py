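"""Two-class PLS-DA on autoscaled spectra.

Partial least squares discriminant analysis regresses a 0/1 class vector
(non_BP -> 0, BP -> 1) on the autoscaled spectra through latent variables
(LVs) that maximize covariance between X-scores and the class vector, using
the orthogonal-scores (NIPALS-style) deflation algorithm for a single
response:

    for each LV:  w = X' y / ||X' y||;  t = X w;  p = X' t / t't;
                  q = y' t / t't;  X <- X - t p'

Regression coefficients ``b = W (P' W)^{-1} q`` allow one-shot prediction
``yhat = X_scaled b + ybar``; a sample is labelled BP when its predicted
value reaches the 0.5 threshold (the two-class form of "assign to the class
with the highest prediction"; ties go to the risky BP class).

With as many LVs as the rank of X_scaled the fit coincides with ordinary
least squares — used as an independent oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import CLASS_LABELS, EnergyGrid
from .preprocessing import ScalingParams, apply_scaling, fit_scaling

__all__ = [
    "PLSDAModel",
    "encode_labels",
    "fit_plsda",
    "predict_plsda",
    "choose_n_lv",
    "coefficient_profile",
]

_RANK_TOL = 1e-10


@dataclass
class PLSDAModel:
    n_lv: int
    x_weights: np.ndarray  # (m, A)
    x_loadings: np.ndarray  # (m, A)
    y_loadings: np.ndarray  # (A,)
    x_scores: np.ndarray  # (n, A)
    coefficients: np.ndarray  # (m,), on the autoscaled X
    intercept: float
    scaling: ScalingParams
    explained_x_variance: np.ndarray  # percent per LV
    decision_threshold: float = 0.5
    class_coding: tuple = (("non_BP", 0.0), ("BP", 1.0))


def encode_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    bad = set(labels) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return (labels == "BP").astype(float)


def fit_plsda(X: np.ndarray, y_labels, n_lv: int) -> PLSDAModel:
    """Fit PLS-DA with ``n_lv`` latent variables; X is autoscaled internally."""
    X = np.asarray(X, dtype=float)
    y = encode_labels(y_labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present to fit PLS-DA")
    n, m = X.shape
    if not (1 <= n_lv <= min(n - 1, m)):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, m)}], got {n_lv}")

    Xs, scaling = fit_scaling(X, "autoscale")
    ybar = float(y.mean())
    yc = y - ybar
    x_tss = float(np.sum(Xs**2))

    Xd = Xs.copy()
    W = np.zeros((m, n_lv))
    P = np.zeros((m, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    expl = np.zeros(n_lv)
    for a in range(n_lv):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw <= _RANK_TOL * max(1.0, np.abs(yc).max()):
            raise ValueError(
                f"n_lv = {n_lv} exceeds the informative rank of X (stopped at {a} LVs)"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL:
            raise ValueError(
                f"n_lv = {n_lv} exceeds the rank of X_scaled (stopped at {a} LVs)"
            )
        p = Xd.T @ t / tt
        q[a] = float(yc @ t) / tt
        Xd -= np.outer(t, p)
        W[:, a], P[:, a], T[:, a] = w, p, t
        expl[a] = 100.0 * tt * float(p @ p) / x_tss

    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSDAModel(
        n_lv=n_lv,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        coefficients=b,
        intercept=ybar,
        scaling=scaling,
        explained_x_variance=expl,
    )


def predict_plsda(model: PLSDAModel, X_new: np.ndarray):
    """Continuous predictions and hard labels for new spectra.

    Applies the stored autoscaling (no re-estimation) and the 0.5 decision
    threshold; ties are assigned to the BP class.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"channel mismatch: model has {model.coefficients.shape[0]}, "
            f"input has {X_new.shape[1]}"
        )
    yhat = apply_scaling(X_new, model.scaling) @ model.coefficients + model.intercept
    labels = np.where(yhat >= model.decision_threshold, "BP", "non_BP")
    return yhat, labels


def choose_n_lv(X: np.ndarray, y_labels, max_lv: int = 10, k_folds: int = 5) -> int:
    """LV count maximizing venetian-blinds cross-validated balanced accuracy.

    Predictions are pooled over folds per candidate LV count; ties break
    toward the fewest LVs.
    """
    from .validation import confusion_metrics, venetian_folds  # local: avoids cycle

    X = np.asarray(X, dtype=float)
    y_labels = np.asarray(y_labels)
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    n = X.shape[0]
    folds = venetian_folds(n, k_folds)
    cap = min(max_lv, X.shape[1], n - int(np.bincount(folds).max()) - 1)
    cap = max(cap, 1)
    preds = {a: np.empty(n, dtype=object) for a in range(1, cap + 1)}
    for f in range(k_folds):
        test = folds == f
        for a in range(1, cap + 1):
            try:
                model = fit_plsda(X[~test], y_labels[~test], a)
            except ValueError:
                preds.pop(a, None)
                continue
            _, lab = predict_plsda(model, X[test])
            preds[a][test] = lab
    best_a, best_ba = 1, -np.inf
    for a in sorted(preds):
        ba = confusion_metrics(y_labels, preds[a].astype(str)).balanced_accuracy
        if ba > best_ba + 1e-12:
            best_a, best_ba = a, ba
    return best_a


def coefficient_profile(model: PLSDAModel, grid: EnergyGrid | None = None):
    """Per-channel |b| normalized to a maximum of 1.

    Returns a DataFrame (energy_keV, weight) when a grid is given, else the
    bare weight vector. The profile localizes which energies drive the
    classification (K/Ca lines for bitter pit).
    """
    w = np.abs(model.coefficients)
    peak = w.max()
    if peak <= 0:
        raise ValueError("all regression coefficients are zero; profile undefined")
    w = w / peak
    if grid is None:
        return w
    return pd.DataFrame({"energy_keV": grid.energies, "weight": w})
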