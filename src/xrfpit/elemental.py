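"""Univariate ionomics: line intensities, K/Ca ratios, group comparisons.

The K/Ca ratio — the classical bitter-pit risk proxy — is computed two ways:

* **deconvolution**: nonlinear least squares on the 3.0-4.3 keV window with
  four Gaussians at the fixed K Ka/Kb and Ca Ka/Kb energies (3.31, 3.59,
  3.69, 4.01 keV), one shared width, free non-negative amplitudes and a
  constant background. Deconvolution matters because the K Kb line (3.59 keV)
  sits under the Ca Ka line (3.69 keV); the ratio uses the Ka areas only,
  the Kb amplitudes are fitted to de-bias the overlap.
* **direct ratio**: background-subtracted raw peak height at K Ka divided by
  that at Ca Ka, the field-usable shortcut.

Per-element group contrasts use a fixed-effects two-way ANOVA (BP status x
measurement point, with interaction; type-II sums of squares), plus ECDF and
Tukey box summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.formula.api import ols

from .datasets import EnergyGrid, LabelledSpectraSet
from .synthetic import ElementLine

__all__ = [
    "KCaFit",
    "GroupComparison",
    "line_intensity",
    "deconvolve_k_ca",
    "kca_direct",
    "ratio_agreement",
    "two_way_anova",
    "anova_two_way_table",
    "group_summaries",
    "K_KA",
    "CA_KA",
]

K_KA = 3.31
K_KB = 3.59
CA_KA = 3.69
CA_KB = 4.01
DECONV_WINDOW = (3.0, 4.3)
DIRECT_BG_REGION = (4.4, 4.9)  # line-free under the default line table
DEFAULT_HALF_WINDOW = 0.06


@dataclass
class KCaFit:
    """Result of the four-Gaussian K/Ca deconvolution of one spectrum."""

    areas: dict[str, float]  # keys: K_Ka, K_Kb, Ca_Ka, Ca_Kb
    background: float
    sigma: float
    fit_rss: float
    converged: bool
    ratio_deconvolved: float | None = None
    ratio_direct: float | None = None


@dataclass
class GroupComparison:
    """Two-way ANOVA and distribution summaries for one element's intensity."""

    element: str
    group_means: dict[str, float]
    anova_p_status: float
    anova_p_position: float
    anova_p_interaction: float
    ecdf: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=dict)
    box_stats: dict[str, dict] = field(default_factory=dict)


def line_intensity(
    counts: np.ndarray,
    grid: EnergyGrid,
    line: ElementLine | float,
    half_window: float = DEFAULT_HALF_WINDOW,
) -> float:
    """Maximum observed count in ``[energy - hw, energy + hw]``."""
    energy = line.energy if isinstance(line, ElementLine) else float(line)
    energies = grid.energies
    lo, hi = energy - half_window, energy + half_window
    if lo < energies[0] or hi > energies[-1]:
        raise ValueError(
            f"window [{lo:.4f}, {hi:.4f}] keV extends outside the grid "
            f"[{energies[0]:.4f}, {energies[-1]:.4f}]"
        )
    mask = (energies >= lo) & (energies <= hi)
    return float(np.max(np.asarray(counts, dtype=float)[mask]))


def _gauss_sum(energies, amps, centers, sigma, bg):
    y = np.full_like(energies, bg, dtype=float)
    for a, c in zip(amps, centers):
        y += a * np.exp(-((energies - c) ** 2) / (2.0 * sigma * sigma))
    return y


def deconvolve_k_ca(
    counts: np.ndarray,
    grid: EnergyGrid,
    *,
    sigma_init: float = 0.064,
    window: tuple[float, float] = DECONV_WINDOW,
) -> KCaFit:
    """Fit the K/Ca region and return Ka/Kb areas and the deconvolved ratio.

    Centers are fixed; the single shared Gaussian width and the constant
    background are free; amplitudes are bounded below at zero. Areas are
    ``amplitude * sigma * sqrt(2*pi)``. If the fit does not converge the
    ratio is left absent.
    """
    energies = grid.energies
    if energies[0] > window[0] or energies[-1] < window[1]:
        raise ValueError(f"grid must cover the {window} keV deconvolution window")
    mask = (energies >= window[0]) & (energies <= window[1])
    e = energies[mask]
    y = np.asarray(counts, dtype=float)[mask]
    centers = (K_KA, K_KB, CA_KA, CA_KB)
    names = ("K_Ka", "K_Kb", "Ca_Ka", "Ca_Kb")

    bg0 = max(float(np.min(y)), 0.0)
    params = lmfit.Parameters()
    params.add("sigma", value=sigma_init, min=0.02, max=0.25)
    params.add("background", value=bg0, min=0.0)
    for name, c in zip(names, centers):
        h0 = max(float(y[np.argmin(np.abs(e - c))]) - bg0, 1.0)
        params.add(f"amp_{name}", value=h0, min=0.0)

    def residual(p):
        amps = [p[f"amp_{n}"].value for n in names]
        return _gauss_sum(e, amps, centers, p["sigma"].value, p["background"].value) - y

    out = lmfit.minimize(residual, params, method="leastsq", max_nfev=2000)
    p = out.params
    sigma = float(p["sigma"].value)
    areas = {n: float(p[f"amp_{n}"].value) * sigma * math.sqrt(2 * math.pi) for n in names}
    converged = bool(out.success)
    ratio = None
    if converged and areas["Ca_Ka"] > 1e-12:
        ratio = areas["K_Ka"] / areas["Ca_Ka"]
    return KCaFit(
        areas=areas,
        background=float(p["background"].value),
        sigma=sigma,
        fit_rss=float(np.sum(np.asarray(out.residual) ** 2)),
        converged=converged,
        ratio_deconvolved=ratio,
    )


def _direct_background(counts, grid, bg_region):
    energies = grid.energies
    mask = (energies >= bg_region[0]) & (energies < bg_region[1])
    if not mask.any():
        raise ValueError(f"background region {bg_region} keV not covered by the grid")
    return float(np.mean(np.asarray(counts, dtype=float)[mask]))


def kca_direct(
    counts: np.ndarray,
    grid: EnergyGrid,
    *,
    half_window: float = 0.01,
    bg_region: tuple[float, float] = DIRECT_BG_REGION,
) -> float:
    """Direct K/Ca: background-subtracted raw peak heights at 3.31 / 3.69 keV.

    The height is read at the apex — the channel(s) within ``half_window``
    (default 0.01 keV, i.e. the channel nearest the characteristic energy).
    A wider window must not be used for the Ca reading: the K Kb shoulder at
    3.59 keV overtakes the Ca apex at the edge of a +/-0.06 keV window for
    high-K/Ca fruit. The background is the mean count over the line-free
    4.4-4.9 keV region, making the ratio invariant to an overall rescaling
    of the spectrum.
    """
    bg = _direct_background(counts, grid, bg_region)
    k = line_intensity(counts, grid, K_KA, half_window) - bg
    ca = line_intensity(counts, grid, CA_KA, half_window) - bg
    if ca <= 0:
        raise ValueError("Ca peak height does not exceed background; direct ratio undefined")
    return k / ca


def r_squared(x, y) -> float:
    """Squared Pearson correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def ratio_agreement(sset: LabelledSpectraSet) -> float:
    """R^2 between per-spectrum deconvolved and direct K/Ca ratios."""
    dec, dirr = [], []
    for i in range(sset.n_spectra):
        fit = deconvolve_k_ca(sset.X[i], sset.grid)
        if fit.ratio_deconvolved is None:
            continue
        dec.append(fit.ratio_deconvolved)
        dirr.append(kca_direct(sset.X[i], sset.grid))
    if len(dec) < 3:
        raise ValueError("need at least 3 spectra with both ratios defined")
    return r_squared(dec, dirr)


def anova_two_way_table(values, factor_a, factor_b) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction, type-II sums of squares.

    Returns the statsmodels ANOVA table with rows C(a), C(b), C(a):C(b),
    Residual. Raises on empty cells or zero residual degrees of freedom /
    zero within-cell variance.
    """
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "a": list(factor_a), "b": list(factor_b)}
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("both factors need at least 2 levels")
    cell_sizes = df.groupby(["a", "b"], observed=True).size()
    full = df["a"].nunique() * df["b"].nunique()
    if len(cell_sizes) < full:
        present = set(cell_sizes.index)
        missing = [
            (a, b)
            for a in df["a"].unique()
            for b in df["b"].unique()
            if (a, b) not in present
        ]
        raise ValueError(f"empty cells in the two-way layout: {missing}")
    if (cell_sizes < 2).any():
        raise ValueError("each cell needs at least 2 replicates")
    model = ols("y ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    total_ss = float(table["sum_sq"].sum())
    if (
        table.loc["Residual", "sum_sq"] <= 1e-12 * max(total_ss, 1e-300)
        or not np.isfinite(table["F"].iloc[:3]).all()
    ):
        raise ValueError("zero within-group variance; F statistics undefined")
    return table


def two_way_anova(
    sset: LabelledSpectraSet,
    line: ElementLine,
    half_window: float = DEFAULT_HALF_WINDOW,
) -> GroupComparison:
    """Compare one element's line intensity across BP status x measurement point."""
    vals = np.array(
        [line_intensity(sset.X[i], sset.grid, line, half_window) for i in range(sset.n_spectra)]
    )
    table = anova_two_way_table(vals, sset.meta["label"], sset.meta["point"])
    by_class = {
        lab: vals[(sset.meta["label"] == lab).to_numpy()] for lab in sset.meta["label"].unique()
    }
    summaries = group_summaries(by_class)
    return GroupComparison(
        element=line.element,
        group_means={lab: float(v.mean()) for lab, v in by_class.items()},
        anova_p_status=float(table.loc["C(a)", "PR(>F)"]),
        anova_p_position=float(table.loc["C(b)", "PR(>F)"]),
        anova_p_interaction=float(table.loc["C(a):C(b)", "PR(>F)"]),
        ecdf={lab: s["ecdf"] for lab, s in summaries.items()},
        box_stats={lab: s["box"] for lab, s in summaries.items()},
    )


def group_summaries(values_by_class: dict) -> dict:
    """ECDF and Tukey box statistics per class.

    ECDF is the right-continuous step function (sorted values, cumulative
    fractions (i+1)/n). Box stats use the linear-interpolation (type-7)
    quantile convention; whiskers reach the most extreme data point within
    1.5 x IQR of the quartiles, the rest are outliers.
    """
    out = {}
    for lab, vals in values_by_class.items():
        v = np.sort(np.asarray(vals, dtype=float))
        if v.size < 1:
            raise ValueError(f"class {lab!r} has no values")
        frac = np.arange(1, v.size + 1) / v.size
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        out[lab] = {
            "ecdf": (v, frac),
            "box": {
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "whisker_lo": float(inside.min()),
                "whisker_hi": float(inside.max()),
                "outliers": v[(v < lo_fence) | (v > hi_fence)],
            },
        }
    return out
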