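"""PCA decomposition and Q-residual / Hotelling-T2 anomaly screening.

The decomposition X = T P' is computed by singular value decomposition of
the (already scaled) data matrix; scores T = U S, loadings P orthonormal.
Sample diagnostics relative to an A-component model:

* Q residual (squared prediction error): ``q_i = ||x_i - x_i P P'||^2``,
  with the Jackson-Mudholkar confidence limit from the residual eigenvalues.
* Hotelling T2: ``sum_a t_ia^2 / lambda_a`` over the retained components,
  with the F-distribution limit ``A (n-1)(n+1) / (n (n-A)) * F_{1-a}(A, n-A)``.

Samples exceeding either limit are screened out in a single pass before
classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import LabelledSpectraSet
from .preprocessing import ScalingParams, fit_scaling

__all__ = [
    "PCAModel",
    "OutlierReport",
    "fit_pca",
    "choose_n_components",
    "q_and_t2",
    "screen_outliers",
]


@dataclass
class PCAModel:
    n_components: int
    scores: np.ndarray  # (n, A)
    loadings: np.ndarray  # (m, A), orthonormal columns
    eigenvalues: np.ndarray  # retained, = s^2/(n-1)
    all_eigenvalues: np.ndarray = field(repr=False)
    explained_variance: np.ndarray  # percent, per retained component
    n_samples: int
    scaling: ScalingParams | None = None

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained_variance)


@dataclass
class OutlierReport:
    q_values: np.ndarray
    q_limit: float | None
    t2_values: np.ndarray
    t2_limit: float
    flagged: np.ndarray  # row indices
    confidence: float


def fit_pca(X_scaled: np.ndarray, A: int, scaling: ScalingParams | None = None) -> PCAModel:
    """Rank-A SVD decomposition of a scaled matrix.

    Sign convention: each loading vector's largest-magnitude element is made
    positive, so scores and loadings reproduce across platforms.
    """
    X = np.asarray(X_scaled, dtype=float)
    n, m = X.shape
    max_a = min(n - 1, m)
    if not (1 <= A <= max_a):
        raise ValueError(f"A must be in [1, {max_a}], got {A}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign convention
    for j in range(Vt.shape[0]):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    eig = s**2 / (n - 1)
    total = eig.sum()
    return PCAModel(
        n_components=A,
        scores=U[:, :A] * s[:A],
        loadings=Vt[:A].T,
        eigenvalues=eig[:A],
        all_eigenvalues=eig,
        explained_variance=100.0 * eig[:A] / total,
        n_samples=n,
        scaling=scaling,
    )


def choose_n_components(
    X_scaled: np.ndarray,
    A_max: int,
    k_folds: int = 7,
    threshold: float = 0.90,
) -> int:
    """Smallest A whose cross-validated explained variance reaches ``threshold``.

    Row-wise leave-group-out: each fold's rows are reconstructed through the
    loadings fitted on the remaining rows; CV explained variance is
    ``1 - PRESS / TSS``. Falls back to ``A_max`` with a warning when no A
    reaches the threshold (structureless data).
    """
    X = np.asarray(X_scaled, dtype=float)
    n, m = X.shape
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    k_folds = min(k_folds, n)
    folds = np.arange(n) % k_folds
    A_cap = min(A_max, m, n - int(np.bincount(folds).max()) - 1)
    A_cap = max(A_cap, 1)
    press = np.zeros(A_cap)
    tss = float(np.sum(X**2))
    for f in range(k_folds):
        test = folds == f
        Xtr, Xte = X[~test], X[test]
        _, _, Vt = np.linalg.svd(Xtr, full_matrices=False)
        for A in range(1, A_cap + 1):
            P = Vt[:A].T
            resid = Xte - (Xte @ P) @ P.T
            press[A - 1] += float(np.sum(resid**2))
    cv_explained = 1.0 - press / tss
    reached = np.flatnonzero(cv_explained >= threshold)
    if reached.size:
        return int(reached[0] + 1)
    warnings.warn(
        f"cross-validated explained variance never reached {threshold:.0%}; "
        f"returning A_max = {A_max}",
        stacklevel=2,
    )
    return int(min(A_max, A_cap))


def _jackson_mudholkar_limit(residual_eigenvalues: np.ndarray, confidence: float) -> float | None:
    lam = residual_eigenvalues[residual_eigenvalues > 1e-12]
    if lam.size == 0:
        return None
    t1, t2, t3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
    h0 = 1.0 - 2.0 * t1 * t3 / (3.0 * t2**2)
    if h0 <= 0:
        h0 = 1e-4
    z = stats.norm.ppf(confidence)
    base = z * np.sqrt(2.0 * t2 * h0**2) / t1 + 1.0 + t2 * h0 * (h0 - 1.0) / t1**2
    if base <= 0:
        return float(t1)  # degenerate residual spectrum; fall back to its mean energy
    return float(t1 * base ** (1.0 / h0))


def q_and_t2(
    model: PCAModel, X_scaled: np.ndarray, confidence: float = 0.95
) -> OutlierReport:
    """Per-sample Q residuals and Hotelling T2 with their confidence limits.

    When the model captures the full rank of the training data the Q
    statistic is identically zero and has no limit; screening then proceeds
    on T2 alone (with a warning).
    """
    X = np.asarray(X_scaled, dtype=float)
    A, n = model.n_components, model.n_samples
    P = model.loadings
    T = X @ P
    resid = X - T @ P.T
    q = np.sum(resid**2, axis=1)
    t2 = np.sum(T**2 / model.eigenvalues, axis=1)

    q_limit = _jackson_mudholkar_limit(model.all_eigenvalues[A:], confidence)
    if q_limit is None:
        warnings.warn("model spans the full data rank; Q limit undefined, using T2 only",
                      stacklevel=2)
    t2_limit = (
        A * (n - 1) * (n + 1) / (n * (n - A)) * stats.f.ppf(confidence, A, n - A)
    )
    flag_q = q > q_limit if q_limit is not None else np.zeros(len(q), dtype=bool)
    flagged = np.flatnonzero(flag_q | (t2 > t2_limit))
    return OutlierReport(
        q_values=q,
        q_limit=q_limit,
        t2_values=t2,
        t2_limit=float(t2_limit),
        flagged=flagged,
        confidence=confidence,
    )


def screen_outliers(
    sset: LabelledSpectraSet,
    A: int,
    confidence: float = 0.95,
    mode: str = "autoscale",
) -> tuple[LabelledSpectraSet, OutlierReport]:
    """Single-pass removal of samples beyond the Q or T2 limit.

    Scaling mode defaults to autoscaling to match the classifier
    preprocessing; exploration-style screening can use mean-centering.
    """
    X_scaled, params = fit_scaling(sset.X, mode, energies=sset.grid.energies)
    model = fit_pca(X_scaled, A, scaling=params)
    report = q_and_t2(model, X_scaled, confidence)
    if len(report.flagged) == sset.n_spectra:
        raise ValueError("all samples flagged as anomalous; screening aborted")
    keep = np.ones(sset.n_spectra, dtype=bool)
    keep[report.flagged] = False
    return sset.take(keep), report
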