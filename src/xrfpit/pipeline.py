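"""End-to-end orchestration of the two studies.

Study 1 (balanced 'Granny Smith' set): PCA exploration on mean-centered
spectra, per-element two-way ANOVA, K/Ca by deconvolution and by direct
ratio with their agreement R^2, and the within-fruit reproducibility CV.

Study 2 (orchard set): PCA Q/T2 anomaly screening, removal of mild-severity
fruit from the affected class, PLS-DA fitting, and the three evaluation
schemes (training, venetian-blinds CV, Monte-Carlo holdout) reported in a
Table-2-shaped metrics block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import LabelledSpectraSet
from .elemental import deconvolve_k_ca, kca_direct, line_intensity, r_squared, two_way_anova
from .io import read_spectra_table, write_spectra_table
from .pca import choose_n_components, fit_pca, screen_outliers
from .plsda import choose_n_lv, fit_plsda, predict_plsda
from .preprocessing import filter_severity, fit_scaling, select_region
from .synthetic import (
    GeneratorConfig,
    default_config,
    generate_balanced_study,
    generate_orchard_study,
)
from .validation import confusion_metrics, cross_validate_plsda, monte_carlo_validate

log = logging.getLogger("xrfpit")

__all__ = ["RunConfig", "run_study1", "run_study2"]


@dataclass
class RunConfig:
    """Flat, diffable run configuration (YAML-serializable)."""

    mode: str = "study1"  # "study1" | "study2"
    input_path: str | None = None  # load spectra table instead of generating
    seed: int = 0
    output_dir: str = "xrfpit_out"
    # generator
    n_per_class: int = 176
    n_fruit: int = 1000
    incidence: float = 0.184
    severity_mix: dict = field(
        default_factory=lambda: {"mild": 0.40, "moderate": 0.35, "severe": 0.25}
    )
    cultivar: str = "GS"
    points_per_fruit: int = 6
    between_fruit_cv: float = 0.20
    within_fruit_cv: float = 0.15
    # analysis
    region: tuple = (1.5, 4.95)
    severity_include: tuple = ("moderate", "severe")
    screening_components: int | None = 5
    screening_confidence: float = 0.95
    max_lv: int = 10
    n_lv: int | None = None  # fixed LV count; None -> choose by CV
    cv_folds: int = 5
    mc_iterations: int = 100
    holdout_frac: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.region, list):
            cfg.region = tuple(cfg.region)
        if isinstance(cfg.severity_include, list):
            cfg.severity_include = tuple(cfg.severity_include)
        return cfg

    def generator_config(self) -> GeneratorConfig:
        return default_config(
            points_per_fruit=self.points_per_fruit,
            between_fruit_cv=self.between_fruit_cv,
            within_fruit_cv=self.within_fruit_cv,
        )


def _load_or_generate(config: RunConfig) -> LabelledSpectraSet:
    if config.input_path is not None:
        path = Path(config.input_path)
        if not path.exists():
            raise FileNotFoundError(f"input spectra table not found: {path}")
        sset = read_spectra_table(path)
        log.info("loaded %d spectra x %d channels from %s", sset.n_spectra, sset.n_channels, path)
        return sset
    gen = config.generator_config()
    if config.mode == "study1":
        sset = generate_balanced_study(gen, config.n_per_class, seed=config.seed,
                                       cultivar=config.cultivar)
    else:
        sset = generate_orchard_study(
            gen, config.n_fruit, config.incidence, dict(config.severity_mix),
            seed=config.seed, cultivar=config.cultivar,
        )
    log.info("generated %d spectra x %d channels", sset.n_spectra, sset.n_channels)
    return sset


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))


def _per_fruit_mean_spectra(sset: LabelledSpectraSet):
    """Mean spectrum per fruit (averaging replicate points) plus fruit meta."""
    idx = sset.meta.groupby("fruit_id", sort=False).indices
    fruit_ids = list(idx)
    X = np.stack([sset.X[rows].mean(axis=0) for rows in idx.values()])
    meta = sset.meta.drop_duplicates("fruit_id").set_index("fruit_id").loc[fruit_ids]
    return X, meta.reset_index()


def run_study1(config: RunConfig, write: bool = True) -> dict:
    """Balanced-study ionomics report; optionally writes CSV/JSON artifacts."""
    from .synthetic import DEFAULT_LINE_TABLE

    sset = _load_or_generate(config)
    sset = select_region(sset, *config.region)
    log.info("region %s keV -> %d channels", config.region, sset.n_channels)

    # PCA exploration on mean-centered spectra
    Xc, _ = fit_scaling(sset.X, "mean_center")
    A = choose_n_components(Xc, A_max=10)
    model = fit_pca(Xc, A)

    # per-element comparisons (K-alpha line of each element in the region)
    ka_lines = [
        ln for ln in DEFAULT_LINE_TABLE
        if ln.line_label == "Ka" and sset.grid.contains(ln.energy)
    ]
    elements = {}
    for ln in ka_lines:
        cmp = two_way_anova(sset, ln)
        elements[ln.element] = {
            "group_means": cmp.group_means,
            "p_status": cmp.anova_p_status,
            "p_position": cmp.anova_p_position,
            "p_interaction": cmp.anova_p_interaction,
        }

    # K/Ca by both methods on per-fruit mean spectra
    Xf, fmeta = _per_fruit_mean_spectra(sset)
    dec, dirr = [], []
    for row in Xf:
        fit = deconvolve_k_ca(row, sset.grid)
        dec.append(fit.ratio_deconvolved if fit.ratio_deconvolved is not None else np.nan)
        dirr.append(kca_direct(row, sset.grid))
    dec, dirr = np.asarray(dec), np.asarray(dirr)
    ok = np.isfinite(dec)
    r2 = r_squared(dec[ok], dirr[ok])

    # within-fruit reproducibility CV per element (percent)
    cv = {}
    for ln in ka_lines:
        vals = np.array(
            [line_intensity(sset.X[i], sset.grid, ln) for i in range(sset.n_spectra)]
        )
        per_fruit = pd.DataFrame({"fruit_id": sset.meta["fruit_id"], "v": vals}).groupby(
            "fruit_id", sort=False
        )["v"]
        counts = per_fruit.count()
        cvs = (per_fruit.std(ddof=1) / per_fruit.mean())[counts > 1]
        cv[ln.element] = float(100.0 * cvs.mean()) if len(cvs) else None

    report = {
        "mode": "study1",
        "seed": config.seed,
        "version": __version__,
        "n_spectra": sset.n_spectra,
        "n_fruit": int(sset.meta["fruit_id"].nunique()),
        "pca": {
            "n_components": A,
            "explained_variance_pct": model.explained_variance.tolist(),
            "cumulative_pct": model.cumulative_explained.tolist(),
        },
        "elements": elements,
        "kca": {
            "r2_agreement": r2,
            "mean_ratio_deconvolved": {
                lab: float(np.nanmean(dec[(fmeta["label"] == lab).to_numpy()]))
                for lab in ("non_BP", "BP")
            },
            "mean_ratio_direct": {
                lab: float(np.mean(dirr[(fmeta["label"] == lab).to_numpy()]))
                for lab in ("non_BP", "BP")
            },
        },
        "reproducibility_cv_pct": cv,
    }
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(elements).T.rename_axis("element").to_csv(out / "ionomics.csv")
        pd.DataFrame(
            {"fruit_id": fmeta["fruit_id"], "label": fmeta["label"],
             "kca_deconvolved": dec, "kca_direct": dirr}
        ).to_csv(out / "kca_ratios.csv", index=False)
        _write_json({"config": asdict(config), **report}, out / "run.json")
    return report


def _metrics_row(m, n_lv):
    return {"scheme": m.scheme, "LVs": n_lv, "BA": m.balanced_accuracy,
            "Sn": m.sensitivity, "Sp": m.specificity}


def run_study2(config: RunConfig, write: bool = True) -> dict:
    """Orchard-study classification report (screen, filter, PLS-DA, validate)."""
    sset = _load_or_generate(config)
    sset = select_region(sset, *config.region)
    log.info("region %s keV -> %d channels", config.region, sset.n_channels)

    n0 = sset.n_spectra
    A = config.screening_components
    if A is None:
        Xs, _ = fit_scaling(sset.X, "autoscale", energies=sset.grid.energies)
        A = choose_n_components(Xs, A_max=10)
    sset, outrep = screen_outliers(sset, A, config.screening_confidence, mode="autoscale")
    log.info("screening removed %d of %d spectra (A=%d)", len(outrep.flagged), n0, A)

    n_before = sset.n_spectra
    sset = filter_severity(sset, config.severity_include)
    log.info("severity filter %s kept %d of %d spectra",
             config.severity_include, sset.n_spectra, n_before)
    if len(set(sset.labels)) < 2:
        raise ValueError("a single class remains after screening/filtering; cannot classify")

    n_lv = config.n_lv or choose_n_lv(sset.X, sset.labels, max_lv=config.max_lv,
                                      k_folds=config.cv_folds)
    log.info("using %d latent variables", n_lv)

    model = fit_plsda(sset.X, sset.labels, n_lv)
    _, train_pred = predict_plsda(model, sset.X)
    m_train = confusion_metrics(sset.labels, train_pred, scheme="training")
    m_cv = cross_validate_plsda(sset, config.cv_folds, n_lv)
    m_mc = monte_carlo_validate(sset, config.mc_iterations, config.holdout_frac, n_lv,
                                seed=config.seed)

    metrics = pd.DataFrame([_metrics_row(m, n_lv) for m in (m_train, m_cv, m_mc)])
    report = {
        "mode": "study2",
        "seed": config.seed,
        "version": __version__,
        "cultivar": config.cultivar,
        "n_spectra_input": n0,
        "n_outliers_removed": int(len(outrep.flagged)),
        "n_spectra_modelled": sset.n_spectra,
        "n_lv": int(n_lv),
        "metrics": metrics.to_dict(orient="records"),
    }
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        pd.DataFrame({"flagged_row": outrep.flagged,
                      "q": outrep.q_values[outrep.flagged],
                      "t2": outrep.t2_values[outrep.flagged]}).to_csv(
            out / "outliers.csv", index=False)
        _write_json({"config": asdict(config), **report}, out / "run.json")
    return report


def generate_dataset(config: RunConfig, path) -> LabelledSpectraSet:
    """Generate the configured dataset and write it as a spectra table."""
    sset = _load_or_generate(config)
    write_spectra_table(sset, path)
    return sset
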