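"""Validation schemes and classification measures for the BP classifier.

Conventions follow the source study: sensitivity (Sn) is the fraction of
correctly classified *non-BP* samples, specificity (Sp) the fraction of
correctly classified BP samples, and balanced accuracy BA = (Sn + Sp) / 2.

Two schemes are provided besides the training fit:

* venetian-blinds k-fold cross-validation — the deterministic fold rule
  ``sample i -> fold i mod k`` — with metrics pooled over held-out folds;
* Monte-Carlo validation — repeated stratified random 20% holdouts with
  metrics averaged over iterations.

All splits are grouped by fruit: every measurement point of a fruit shares
its fold, avoiding pseudo-replication. Autoscaling is re-estimated inside
each training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import CLASS_LABELS, LabelledSpectraSet
from .plsda import fit_plsda, predict_plsda

__all__ = [
    "ClassificationMetrics",
    "confusion_metrics",
    "venetian_folds",
    "cross_validate_plsda",
    "monte_carlo_validate",
    "incidence",
]


@dataclass
class ClassificationMetrics:
    sensitivity: float  # correct non-BP fraction
    specificity: float  # correct BP fraction
    balanced_accuracy: float
    confusion: np.ndarray  # rows true (non_BP, BP) x cols predicted
    scheme: str = "training"
    per_iteration: pd.DataFrame | None = field(default=None, repr=False)


def confusion_metrics(true_labels, predicted_labels, scheme: str = "training") -> ClassificationMetrics:
    """Sn / Sp / BA and the 2x2 confusion table from label vectors."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for arr, name in ((t, "true"), (p, "predicted")):
        bad = set(arr) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown {name} labels: {sorted(bad)}")
    conf = np.zeros((2, 2), dtype=int)
    for i, ct in enumerate(CLASS_LABELS):
        for j, cp in enumerate(CLASS_LABELS):
            conf[i, j] = int(np.sum((t == ct) & (p == cp)))
    n_non, n_bp = conf[0].sum(), conf[1].sum()
    if n_non == 0:
        raise ValueError("class 'non_BP' absent from true labels; sensitivity undefined")
    if n_bp == 0:
        raise ValueError("class 'BP' absent from true labels; specificity undefined")
    sn = conf[0, 0] / n_non
    sp = conf[1, 1] / n_bp
    return ClassificationMetrics(
        sensitivity=float(sn),
        specificity=float(sp),
        balanced_accuracy=float((sn + sp) / 2.0),
        confusion=conf,
        scheme=scheme,
    )


def venetian_folds(n: int, k: int) -> np.ndarray:
    """Deterministic venetian-blinds assignment: sample i -> fold i mod k."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    return np.arange(n) % k


def _fruit_table(sset: LabelledSpectraSet, interleave_classes: bool) -> pd.DataFrame:
    """Fruit-level table (one row per fruit, first-appearance order),
    optionally reordered to alternate classes so i-mod-k folds stay balanced."""
    fr = sset.meta.drop_duplicates("fruit_id")[["fruit_id", "label"]].reset_index(drop=True)
    if not interleave_classes:
        return fr
    groups = [fr[fr["label"] == lab].reset_index(drop=True) for lab in CLASS_LABELS]
    rows = []
    for i in range(max(len(g) for g in groups)):
        for g in groups:
            if i < len(g):
                rows.append(g.iloc[i])
    return pd.DataFrame(rows).reset_index(drop=True)


def _rows_for_fruit(sset: LabelledSpectraSet, fruit_ids) -> np.ndarray:
    return sset.meta["fruit_id"].isin(set(fruit_ids)).to_numpy()


def cross_validate_plsda(
    sset: LabelledSpectraSet,
    k: int,
    n_lv: int,
    *,
    interleave_classes: bool = True,
) -> ClassificationMetrics:
    """Venetian-blinds k-fold CV of PLS-DA, grouped by fruit, pooled metrics."""
    fruit = _fruit_table(sset, interleave_classes)
    folds = venetian_folds(len(fruit), k)
    pred = np.empty(sset.n_spectra, dtype=object)
    for f in range(k):
        train_fruit = fruit.loc[folds != f, "fruit_id"]
        test_fruit = fruit.loc[folds == f, "fruit_id"]
        train = _rows_for_fruit(sset, train_fruit)
        test = _rows_for_fruit(sset, test_fruit)
        y_train = sset.labels[train]
        if len(set(y_train)) < 2:
            raise ValueError(
                f"training fold {f} contains a single class; "
                "use interleave_classes=True for class-aware fold ordering"
            )
        model = fit_plsda(sset.X[train], y_train, n_lv)
        _, lab = predict_plsda(model, sset.X[test])
        pred[test] = lab
    return confusion_metrics(sset.labels, pred.astype(str), scheme="venetian_cv")


def monte_carlo_validate(
    sset: LabelledSpectraSet,
    n_iter: int = 100,
    holdout_frac: float = 0.2,
    n_lv: int = 4,
    seed: int | None = None,
) -> ClassificationMetrics:
    """Repeated stratified random holdout validation (fruit-level splits).

    Each iteration holds out ``holdout_frac`` of the fruit per class, fits
    on the remainder and evaluates on the holdout; reported Sn/Sp/BA are
    means over iterations and the confusion counts are summed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not (0 < holdout_frac < 1):
        raise ValueError("holdout_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    fruit = sset.meta.drop_duplicates("fruit_id")[["fruit_id", "label"]]
    by_class = {lab: fruit.loc[fruit["label"] == lab, "fruit_id"].to_numpy()
                for lab in CLASS_LABELS}
    for lab, ids in by_class.items():
        if len(ids) < 2:
            raise ValueError(f"need at least 2 fruit of class {lab!r} for holdout validation")

    records = []
    conf = np.zeros((2, 2), dtype=int)
    for it in range(n_iter):
        for _attempt in range(10):
            test_ids: list = []
            for ids in by_class.values():
                n_test = max(1, int(round(holdout_frac * len(ids))))
                n_test = min(n_test, len(ids) - 1)  # keep both classes in training
                test_ids.extend(rng.choice(ids, size=n_test, replace=False))
            train = ~_rows_for_fruit(sset, test_ids)
            if len(set(sset.labels[train])) == 2:
                break
        else:
            raise ValueError("could not draw a holdout leaving both classes in training")
        test = ~train
        model = fit_plsda(sset.X[train], sset.labels[train], n_lv)
        _, lab = predict_plsda(model, sset.X[test])
        m = confusion_metrics(sset.labels[test], lab, scheme="monte_carlo")
        conf += m.confusion
        records.append(
            {"iteration": it, "Sn": m.sensitivity, "Sp": m.specificity, "BA": m.balanced_accuracy}
        )
    per_iter = pd.DataFrame(records)
    sn, sp = float(per_iter["Sn"].mean()), float(per_iter["Sp"].mean())
    return ClassificationMetrics(
        sensitivity=sn,
        specificity=sp,
        balanced_accuracy=float(per_iter["BA"].mean()),
        confusion=conf,
        scheme="monte_carlo",
        per_iteration=per_iter,
    )


def _round_half_up_1dp(x: float) -> float:
    return np.floor(x * 10.0 + 0.5) / 10.0


def incidence(meta: pd.DataFrame) -> pd.Series:
    """Percent of BP fruit per cultivar, to one decimal (round-half-up)."""
    if len(meta) == 0:
        raise ValueError("empty metadata; incidence undefined")
    fruit = meta.drop_duplicates("fruit_id")
    out = {}
    for cult, grp in fruit.groupby("cultivar"):
        pct = 100.0 * (grp["label"] == "BP").sum() / len(grp)
        out[cult] = _round_half_up_1dp(pct)
    return pd.Series(out, name="pct_BP")
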