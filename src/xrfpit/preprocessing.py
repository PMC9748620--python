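"""Energy-region selection, severity filtering, and column scaling.

Two scaling modes are supported: mean-centering (subtract column means) and
autoscaling (additionally divide by the column sample SD, n-1 denominator).
Scaling parameters are always estimated on training rows and re-applied to
new data without re-estimation, so cross-validation folds never leak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import BP_SEVERITIES, EnergyGrid, LabelledSpectraSet

__all__ = [
    "ScalingParams",
    "select_region",
    "filter_severity",
    "fit_scaling",
    "apply_scaling",
    "inverse_scaling",
]


@dataclass(frozen=True)
class ScalingParams:
    mode: str  # "mean_center" | "autoscale"
    column_means: np.ndarray
    column_sds: np.ndarray | None = None  # absent for mean_center

    def __post_init__(self) -> None:
        if self.mode not in ("mean_center", "autoscale"):
            raise ValueError(f"unknown scaling mode {self.mode!r}")
        if self.mode == "autoscale" and self.column_sds is None:
            raise ValueError("autoscale params require column_sds")


def select_region(sset: LabelledSpectraSet, e_lo: float, e_hi: float) -> LabelledSpectraSet:
    """Keep channels whose centers fall in the half-open interval [e_lo, e_hi)."""
    if e_lo >= e_hi:
        raise ValueError(f"e_lo ({e_lo}) must be < e_hi ({e_hi})")
    energies = sset.grid.energies
    # tolerance keeps a center that equals e_hi up to float rounding out of the
    # half-open interval (and one equal to e_lo in)
    tol = 1e-6 * sset.grid.step
    mask = (energies >= e_lo - tol) & (energies < e_hi - tol)
    if not mask.any():
        raise ValueError(f"region [{e_lo}, {e_hi}) keV selects no channels")
    idx = np.flatnonzero(mask)
    grid = EnergyGrid(
        e_min=float(energies[idx[0]]), step=sset.grid.step, n_channels=len(idx)
    )
    return LabelledSpectraSet(
        X=sset.X[:, idx],
        grid=grid,
        meta=sset.meta.reset_index(drop=True),
        fruit_records=sset.fruit_records,
    )


def filter_severity(sset: LabelledSpectraSet, include) -> LabelledSpectraSet:
    """Retain all non-BP fruit and BP fruit whose severity is in ``include``.

    Used to exclude mild cases from the affected class before classification.
    """
    include = set(include)
    if not include:
        raise ValueError("include must be a non-empty set of severities")
    unknown = include - set(BP_SEVERITIES)
    if unknown:
        raise ValueError(f"unknown severities {sorted(unknown)}; expected subset of {BP_SEVERITIES}")
    keep = sset.meta["label"].eq("non_BP") | sset.meta["severity"].isin(include)
    return sset.take(keep.to_numpy())


def fit_scaling(X: np.ndarray, mode: str, energies: np.ndarray | None = None):
    """Estimate scaling on ``X`` and return ``(X_scaled, ScalingParams)``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("scaling requires a 2-D matrix with n >= 2 rows")
    means = X.mean(axis=0)
    if mode == "mean_center":
        params = ScalingParams("mean_center", means)
    elif mode == "autoscale":
        sds = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sds <= 0)
        if bad.size:
            where = (
                f"channels at {np.asarray(energies)[bad][:10].round(4).tolist()} keV"
                if energies is not None
                else f"columns {bad[:10].tolist()}"
            )
            raise ValueError(f"autoscale undefined for zero-variance {where}")
        params = ScalingParams("autoscale", means, sds)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return apply_scaling(X, params), params


def apply_scaling(X_new: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Apply stored scaling parameters; never re-estimates."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[-1] != params.column_means.shape[0]:
        raise ValueError("column count does not match scaling parameters")
    out = X_new - params.column_means
    if params.mode == "autoscale":
        out = out / params.column_sds
    return out


def inverse_scaling(X_scaled: np.ndarray, params: ScalingParams) -> np.ndarray:
    out = np.asarray(X_scaled, dtype=float)
    if params.mode == "autoscale":
        out = out * params.column_sds
    return out + params.column_means
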