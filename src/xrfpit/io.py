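"""Plain-CSV serialization of spectra datasets.

Dialect: header ``fruit_id,cultivar,point,label,severity`` followed by one
column per channel named by its center energy in keV with four decimals
(``1.5000``, ``1.5115``, ...); one data row per spectrum, UTF-8, '.' decimal
separator. Channel identity is carried by the headers, not column order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import CLASS_LABELS, META_COLUMNS, SEVERITIES, EnergyGrid, LabelledSpectraSet

__all__ = ["SpectraFormatError", "write_spectra_table", "read_spectra_table"]


class SpectraFormatError(ValueError):
    """Raised when a spectra table violates the CSV dialect."""


def write_spectra_table(sset: LabelledSpectraSet, path) -> None:
    """Write the dataset as a CSV spectra table (counts to 4 decimals)."""
    path = Path(path)
    cols = [f"{e:.4f}" for e in sset.grid.energies]
    df = pd.concat(
        [
            sset.meta.loc[:, list(META_COLUMNS)].reset_index(drop=True),
            pd.DataFrame(sset.X, columns=cols),
        ],
        axis=1,
    )
    try:
        df.to_csv(path, index=False, float_format="%.4f")
    except OSError as exc:
        raise OSError(f"cannot write spectra table to {path}: {exc}") from exc


def read_spectra_table(path) -> LabelledSpectraSet:
    """Read a CSV spectra table, reconstructing the energy grid from headers."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read spectra table from {path}: {exc}") from exc

    for col in META_COLUMNS:
        if col not in df.columns:
            raise SpectraFormatError(f"missing metadata column {col!r} in {path}")
    chan_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not chan_cols:
        raise SpectraFormatError(f"no channel columns in {path}")
    try:
        energies = np.array([float(c) for c in chan_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric channel header in {path}: {exc}") from exc
    if len(energies) > 1:
        dif = np.diff(energies)
        if (dif <= 0).any():
            raise SpectraFormatError("channel headers must be strictly increasing")
        step = (energies[-1] - energies[0]) / (len(energies) - 1)
        if np.abs(dif - step).max() > 1e-6:
            raise SpectraFormatError("channel headers must be uniformly spaced")
    else:
        step = 1.0  # single channel: spacing unrecoverable, nominal 1 keV
    grid = EnergyGrid(e_min=float(energies[0]), step=float(step), n_channels=len(energies))

    bad = set(df["label"].astype(str)) - set(CLASS_LABELS)
    if bad and len(df):
        raise SpectraFormatError(f"unknown class labels {sorted(bad)}; expected {CLASS_LABELS}")
    bad = set(df["severity"].astype(str)) - set(SEVERITIES)
    if bad and len(df):
        raise SpectraFormatError(f"unknown severities {sorted(bad)}; expected {SEVERITIES}")

    meta = df.loc[:, list(META_COLUMNS)].copy()
    if len(df):
        meta["point"] = meta["point"].astype(int)
    X = df.loc[:, chan_cols].to_numpy(dtype=float) if len(df) else np.empty((0, len(chan_cols)))
    try:
        return LabelledSpectraSet(X=X, grid=grid, meta=meta)
    except ValueError as exc:
        raise SpectraFormatError(str(exc)) from exc
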