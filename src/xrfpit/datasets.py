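"""Core in-memory containers for XRF spectra datasets.

A dataset couples a counts matrix ``X`` (one row per measurement, one column
per detector channel) with an :class:`EnergyGrid` describing the channel
centers in keV and a per-row metadata table (fruit id, cultivar, measurement
point, bitter-pit class and severity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASS_LABELS = ("non_BP", "BP")
SEVERITIES = ("none", "mild", "moderate", "severe")
BP_SEVERITIES = ("mild", "moderate", "severe")
CULTIVARS = ("GS", "BF", "FJ")

#: metadata columns every dataset carries, in serialization order
META_COLUMNS = ("fruit_id", "cultivar", "point", "label", "severity")


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform energy axis: channel ``i`` is centered at ``e_min + i * step`` keV."""

    e_min: float
    step: float
    n_channels: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")

    @property
    def energies(self) -> np.ndarray:
        """Channel-center energies in keV, strictly increasing."""
        return self.e_min + self.step * np.arange(self.n_channels)

    @property
    def e_max(self) -> float:
        """Upper edge of the covered half-open interval [e_min, e_max)."""
        return self.e_min + self.step * self.n_channels

    def contains(self, energy: float) -> bool:
        """True when ``energy`` lies within the span of channel centers."""
        return self.e_min <= energy <= self.energies[-1]


def build_energy_grid(e_min: float, e_max: float, step: float, *, tol: float = 1e-9) -> EnergyGrid:
    """Build the grid of channel centers covering ``[e_min, e_max)``.

    The channel count is ``floor((e_max - e_min) / step + tol)``; the small
    tolerance keeps exact divisions (e.g. 3.45 keV / 0.0115 keV = 300) from
    losing a channel to floating-point rounding.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if e_max <= e_min:
        raise ValueError(f"e_max ({e_max}) must exceed e_min ({e_min})")
    n = int(np.floor((e_max - e_min) / step + tol))
    if n < 1:
        raise ValueError("energy range shorter than one channel")
    return EnergyGrid(e_min=e_min, step=step, n_channels=n)


@dataclass
class LabelledSpectraSet:
    """Spectra matrix plus aligned per-row metadata.

    Attributes
    ----------
    X
        ``(n, m)`` float array of counts, ``m == grid.n_channels``.
    grid
        Shared energy axis.
    meta
        DataFrame with columns :data:`META_COLUMNS`, one row per spectrum.
    fruit_records
        Optional list of generator ground-truth records (latent amplitudes),
        kept for parameter-recovery tests; absent for loaded data.
    """

    X: np.ndarray
    grid: EnergyGrid
    meta: pd.DataFrame
    fruit_records: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n spectra x m channels)")
        if self.X.shape[1] != self.grid.n_channels:
            raise ValueError(
                f"X has {self.X.shape[1]} channels but grid has {self.grid.n_channels}"
            )
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("meta rows and X rows must align 1:1")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta missing columns: {missing}")
        if self.X.size and self.X.min() < 0:
            raise ValueError("counts must be non-negative")
        bad = set(self.meta["label"]) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        bad = set(self.meta["severity"]) - set(SEVERITIES)
        if bad:
            raise ValueError(f"unknown severities: {sorted(bad)}")
        mism = (self.meta["severity"].eq("none")) != (self.meta["label"].eq("non_BP"))
        if mism.any():
            raise ValueError("severity 'none' must coincide exactly with label 'non_BP'")

    @property
    def n_spectra(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    def fruit_ids(self) -> np.ndarray:
        """Unique fruit ids in order of first appearance."""
        return self.meta["fruit_id"].drop_duplicates().to_numpy()

    def take(self, rows) -> "LabelledSpectraSet":
        """Row subset (positional indices or boolean mask), metadata kept aligned."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return LabelledSpectraSet(
            X=self.X[rows],
            grid=self.grid,
            meta=self.meta.iloc[rows].reset_index(drop=True),
        )
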