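"""Synthetic handheld-XRF apple spectra with bitter-pit-dependent structure.

The generator emulates 15-s handheld XRF acquisitions of the apple calyx
region in the 1.5-8 keV window. Each element contributes Gaussian K-alpha /
K-beta emission lines on a flat background; bitter-pit (BP) fruit carry
multiplicative shifts of the expected line amplitudes (higher K, lower Ca).
Dispersion has three seeded sources: a between-fruit lognormal factor per
element, a within-fruit (per measurement point) lognormal factor shared by
all lines of a spectrum, and Poisson counting noise per channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import (
    BP_SEVERITIES,
    CLASS_LABELS,
    EnergyGrid,
    LabelledSpectraSet,
    build_energy_grid,
)

__all__ = [
    "ElementLine",
    "GeneratorConfig",
    "FruitRecord",
    "DEFAULT_LINE_TABLE",
    "default_config",
    "build_energy_grid",
    "simulate_fruit",
    "render_spectrum",
    "generate_balanced_study",
    "generate_orchard_study",
]


@dataclass(frozen=True)
class ElementLine:
    """One characteristic emission line of an element.

    ``relative_emission`` scales the line height relative to the element's
    K-alpha height (1.0 for K-alpha itself, ~0.12 for K-beta).
    """

    element: str
    line_label: str
    energy: float
    relative_emission: float = 1.0

    def __post_init__(self) -> None:
        if not (1.5 <= self.energy <= 8.0):
            raise ValueError(
                f"{self.element} {self.line_label} at {self.energy} keV is outside "
                "the instrument range [1.5, 8] keV"
            )
        if not (0 < self.relative_emission <= 1):
            raise ValueError("relative_emission must be in (0, 1]")


#: Default line table: K-alpha/K-beta pairs for the six elements the XRF
#: spectra resolve in apple skin. K-beta relative emission defaults to 0.12.
DEFAULT_LINE_TABLE: tuple[ElementLine, ...] = (
    ElementLine("Si", "Ka", 1.74, 1.0),
    ElementLine("Si", "Kb", 1.83, 0.12),
    ElementLine("P", "Ka", 2.02, 1.0),
    ElementLine("P", "Kb", 2.14, 0.12),
    ElementLine("S", "Ka", 2.31, 1.0),
    ElementLine("S", "Kb", 2.46, 0.12),
    ElementLine("Cl", "Ka", 2.68, 1.0),
    ElementLine("Cl", "Kb", 2.82, 0.12),
    ElementLine("K", "Ka", 3.31, 1.0),
    ElementLine("K", "Kb", 3.59, 0.12),
    ElementLine("Ca", "Ka", 3.69, 1.0),
    ElementLine("Ca", "Kb", 4.01, 0.12),
)

#: Expected K-alpha peak heights (counts) for non-BP fruit; reproduces the
#: observed peak ordering K >> Ca > Cl >> S > P > Si.
DEFAULT_BASELINES: dict[str, float] = {
    "K": 20_000.0,
    "Ca": 4_000.0,
    "Cl": 3_000.0,
    "S": 800.0,
    "P": 600.0,
    "Si": 500.0,
}

#: Multiplicative amplitude effect of BP (moderate severity) per element.
DEFAULT_BP_EFFECTS: dict[str, float] = {
    "K": 1.30,
    "Ca": 0.65,
    "Cl": 1.0,
    "P": 1.0,
    "Si": 1.10,
    "S": 1.15,
}

#: Exponent applied to the log-effect by severity. The per-class effects above
#: describe fruit with clear (moderate/severe) symptoms; mild fruit carry an
#: attenuated effect, sitting closest to the healthy class and hardest to
#: classify.
DEFAULT_SEVERITY_EXPONENTS: dict[str, float] = {
    "mild": 0.4,
    "moderate": 1.0,
    "severe": 1.0,
}


@dataclass
class GeneratorConfig:
    """All knobs of the spectra generator, with study-calibrated defaults."""

    grid: EnergyGrid = field(default_factory=lambda: build_energy_grid(1.5, 8.0, 0.0115))
    line_table: tuple[ElementLine, ...] = DEFAULT_LINE_TABLE
    baseline_amplitudes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    bp_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BP_EFFECTS))
    severity_exponents: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_EXPONENTS)
    )
    between_fruit_cv: float = 0.20
    within_fruit_cv: float = 0.15
    detector_sigma: float = 0.064
    background_level: float = 50.0
    points_per_fruit: int = 6
    poisson_noise: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("between_fruit_cv", "within_fruit_cv"):
            cv = getattr(self, name)
            if not (0 <= cv < 1):
                raise ValueError(f"{name} must be in [0, 1), got {cv}")
        if self.detector_sigma <= 0:
            raise ValueError("detector_sigma must be positive")
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")
        if self.points_per_fruit < 1:
            raise ValueError("points_per_fruit must be >= 1")
        for el, amp in self.baseline_amplitudes.items():
            if amp <= 0:
                raise ValueError(f"baseline amplitude for {el} must be positive")
        missing = {ln.element for ln in self.line_table} - set(self.baseline_amplitudes)
        if missing:
            raise ValueError(f"no baseline amplitude for elements: {sorted(missing)}")

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def default_config(**kw) -> GeneratorConfig:
    """The study conditions as a config; keyword overrides allowed."""
    return GeneratorConfig(**kw)


@dataclass
class FruitRecord:
    """One fruit with its latent expected line amplitudes.

    Severity encodes the visual pit count at the calyx end: mild < 2 pits,
    moderate 3-5, severe > 5; ``none`` if and only if the fruit is non-BP.
    """

    fruit_id: str
    cultivar: str
    class_label: str
    severity: str
    true_amplitudes: dict[str, float]

    def __post_init__(self) -> None:
        if (self.severity == "none") != (self.class_label == "non_BP"):
            raise ValueError("severity 'none' iff class 'non_BP'")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal factor(s) with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


def _effect(config: GeneratorConfig, element: str, severity: str) -> float:
    base = config.bp_effects.get(element, 1.0)
    expo = config.severity_exponents.get(severity, 1.0)
    return base**expo


def simulate_fruit(
    config: GeneratorConfig,
    class_label: str,
    rng: np.random.Generator,
    *,
    fruit_id: str = "fruit-0",
    cultivar: str = "GS",
    severity: str | None = None,
) -> FruitRecord:
    """Draw one fruit's latent expected K-alpha amplitudes.

    Amplitude(element) = baseline x class effect x unit-mean lognormal with
    CV ``between_fruit_cv``. Non-BP fruit have class effect 1 for all
    elements; BP fruit use ``bp_effects`` raised to the severity exponent.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {CLASS_LABELS}")
    if severity is None:
        severity = "none" if class_label == "non_BP" else "moderate"
    amplitudes: dict[str, float] = {}
    for el in sorted(config.baseline_amplitudes):
        eff = 1.0 if class_label == "non_BP" else _effect(config, el, severity)
        amplitudes[el] = (
            config.baseline_amplitudes[el] * eff * float(_lognormal_factor(rng, config.between_fruit_cv))
        )
    return FruitRecord(
        fruit_id=fruit_id,
        cultivar=cultivar,
        class_label=class_label,
        severity=severity,
        true_amplitudes=amplitudes,
    )


def expected_spectrum(fruit: FruitRecord, config: GeneratorConfig) -> np.ndarray:
    """Noise-free expected counts: background + sum of Gaussian lines."""
    energies = config.grid.energies
    y = np.full(config.grid.n_channels, float(config.background_level))
    two_s2 = 2.0 * config.detector_sigma**2
    for line in config.line_table:
        if not config.grid.contains(line.energy):
            raise ValueError(
                f"line {line.element} {line.line_label} at {line.energy} keV "
                "lies outside the energy grid"
            )
        amp = fruit.true_amplitudes[line.element] * line.relative_emission
        y += amp * np.exp(-((energies - line.energy) ** 2) / two_s2)
    return y


def render_spectrum(
    fruit: FruitRecord, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """One measurement-point realization of the fruit's spectrum.

    The line signal is scaled by a per-point unit-mean lognormal factor
    (within-fruit heterogeneity of the calyx tissue) and the resulting
    expected counts are Poisson-realized per channel; with Poisson noise
    disabled the expectation itself is returned.
    """
    base = expected_spectrum(fruit, config)
    if config.within_fruit_cv > 0:
        f = float(_lognormal_factor(rng, config.within_fruit_cv))
        y = config.background_level + f * (base - config.background_level)
    else:
        y = base
    if config.poisson_noise:
        return rng.poisson(y).astype(float)
    return y


def _render_fruit_rows(fruit, config, rng, rows, meta_rows, n_points):
    for point in range(1, n_points + 1):
        rows.append(render_spectrum(fruit, config, rng))
        meta_rows.append(
            (fruit.fruit_id, fruit.cultivar, point, fruit.class_label, fruit.severity)
        )


def _assemble(rows, meta_rows, config, fruits) -> LabelledSpectraSet:
    meta = pd.DataFrame(
        meta_rows, columns=["fruit_id", "cultivar", "point", "label", "severity"]
    )
    return LabelledSpectraSet(
        X=np.asarray(rows, dtype=float), grid=config.grid, meta=meta, fruit_records=fruits
    )


def generate_balanced_study(
    config: GeneratorConfig,
    n_per_class: int,
    seed: int | None = None,
    *,
    cultivar: str = "GS",
) -> LabelledSpectraSet:
    """Balanced two-class dataset: ``n_per_class`` fruit per class, replicate
    measurement points per fruit, classes interleaved in row order.

    BP fruit are assigned moderate or severe severity with equal probability,
    mirroring a training set built from fruit with clear symptoms.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    rows: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    fruits: list[FruitRecord] = []
    for i in range(n_per_class):
        for label in ("non_BP", "BP"):
            sev = None if label == "non_BP" else str(rng.choice(["moderate", "severe"]))
            fruit = simulate_fruit(
                config,
                label,
                rng,
                fruit_id=f"{cultivar}-{label}-{i:04d}",
                cultivar=cultivar,
                severity=sev,
            )
            fruits.append(fruit)
            _render_fruit_rows(fruit, config, rng, rows, meta_rows, config.points_per_fruit)
    return _assemble(rows, meta_rows, config, fruits)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def generate_orchard_study(
    config: GeneratorConfig,
    n_fruit: int,
    incidence: float,
    severity_mix: dict[str, float],
    seed: int | None = None,
    *,
    cultivar: str = "GS",
) -> LabelledSpectraSet:
    """Unbalanced orchard dataset: one calyx spectrum per fruit.

    ``round(n_fruit * incidence)`` fruit (round-half-up) are BP, with
    severities allocated deterministically from ``severity_mix`` by largest
    remainder; fruit order is a seeded shuffle.
    """
    if n_fruit < 1:
        raise ValueError("n_fruit must be >= 1")
    if not (0 <= incidence <= 1):
        raise ValueError("incidence must be in [0, 1]")
    if set(severity_mix) - set(BP_SEVERITIES):
        raise ValueError(f"severity_mix keys must be among {BP_SEVERITIES}")
    total = sum(severity_mix.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"severity_mix must sum to 1, got {total}")

    n_bp = _round_half_up(n_fruit * incidence)
    # largest-remainder allocation of BP fruit over severities
    sevs = [s for s in BP_SEVERITIES if severity_mix.get(s, 0) > 0]
    raw = {s: n_bp * severity_mix[s] for s in sevs}
    counts = {s: int(math.floor(raw[s])) for s in sevs}
    short = n_bp - sum(counts.values())
    for s in sorted(sevs, key=lambda s: raw[s] - math.floor(raw[s]), reverse=True)[:short]:
        counts[s] += 1

    severities = ["none"] * (n_fruit - n_bp) + [s for s in sevs for _ in range(counts[s])]
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    order = rng.permutation(n_fruit)
    rows: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    fruits: list[FruitRecord] = []
    for i, idx in enumerate(order):
        sev = severities[idx]
        label = "non_BP" if sev == "none" else "BP"
        fruit = simulate_fruit(
            config,
            label,
            rng,
            fruit_id=f"{cultivar}-orchard-{i:05d}",
            cultivar=cultivar,
            severity=None if sev == "none" else sev,
        )
        fruits.append(fruit)
        _render_fruit_rows(fruit, config, rng, rows, meta_rows, n_points=1)
    return _assemble(rows, meta_rows, config, fruits)
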