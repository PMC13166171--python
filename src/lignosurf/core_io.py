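"""Domain containers and plain-text I/O for XY spectra and tidy report tables.

All measured traces are carried as :class:`Spectrum` objects whose axis is
normalised to ascending order on load, so every downstream window is stated
in axis units (degrees 2θ, cm⁻¹ or eV) and never in sample indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SpectrumError

logger = logging.getLogger(__name__)

MIN_POINTS = 8

_DELIMITERS = (",", "\t", ";")


class AxisKind(str, Enum):
    """Physical meaning of the spectral abscissa."""

    TWO_THETA_DEG = "two_theta_deg"
    WAVENUMBER_CM = "wavenumber_cm-1"
    BINDING_ENERGY_EV = "binding_energy_eV"


@dataclass(frozen=True)
class Spectrum:
    """One measured trace: intensity (counts or absorbance) against an axis.

    Parameters
    ----------
    axis_kind : AxisKind
        Unit/meaning of the axis (2θ°, wavenumber cm⁻¹ or binding energy eV).
    axis : ndarray
        Strictly ascending axis values.
    intensity : ndarray
        Non-negative finite intensities, same length as ``axis``.
    label : str
        Free-text identifier.
    metadata : mapping
        Auxiliary strings (timepoint day, region name, replicate id).
    """

    axis_kind: AxisKind
    axis: np.ndarray
    intensity: np.ndarray
    label: str = ""
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if axis.ndim != 1 or intensity.ndim != 1:
            raise SpectrumError("axis and intensity must be one-dimensional")
        if axis.size != intensity.size:
            raise SpectrumError(
                f"axis ({axis.size}) and intensity ({intensity.size}) lengths differ"
            )
        if axis.size < MIN_POINTS:
            raise SpectrumError(
                f"too few points: {axis.size} < {MIN_POINTS} required"
            )
        if not np.all(np.isfinite(axis)):
            raise SpectrumError("axis contains non-finite values")
        if not np.all(np.isfinite(intensity)):
            raise SpectrumError("intensity contains non-finite values")
        diffs = np.diff(axis)
        if np.all(diffs > 0):
            pass
        elif np.all(diffs < 0):
            axis = axis[::-1].copy()
            intensity = intensity[::-1].copy()
        else:
            raise SpectrumError("axis is not strictly monotone")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "metadata", dict(self.metadata))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.axis_kind == other.axis_kind
            and np.array_equal(self.axis, other.axis)
            and np.array_equal(self.intensity, other.intensity)
            and self.label == other.label
            and dict(self.metadata) == dict(other.metadata)
        )

    def __len__(self) -> int:
        return int(self.axis.size)

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of points with ``lo <= axis <= hi``."""
        return (self.axis >= lo) & (self.axis <= hi)

    def scaled(self, factor: float) -> "Spectrum":
        """Return a copy with intensity multiplied by ``factor``."""
        return Spectrum(
            self.axis_kind, self.axis, self.intensity * factor, self.label, self.metadata
        )


@dataclass(frozen=True)
class TimeSeries:
    """A (day, value) series sampled on a strictly increasing day grid."""

    days: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if days.size != values.size:
            raise ValueError("days and values lengths differ")
        if days.size and np.any(days < 0):
            raise ValueError("days must be non-negative")
        if days.size > 1 and not np.all(np.diff(days) > 0):
            raise ValueError("days must be strictly increasing")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.days.size)


def _detect_delimiter(lines: Sequence[str]) -> str:
    counts = {d: 0 for d in _DELIMITERS}
    for line in lines[:20]:
        for d in _DELIMITERS:
            counts[d] += line.count(d)
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        # whitespace-separated fallback
        return " "
    return best


def read_xy_spectrum(
    path: str | Path,
    axis_kind: AxisKind | str,
    *,
    delimiter: str | None = None,
    header_rows: int = 0,
    decimal: str = ".",
    label: str | None = None,
    metadata: Mapping[str, str] | None = None,
) -> Spectrum:
    """Read a two-column XY spectral file (CSV/TSV, '#' comment lines allowed).

    Rows whose fields do not parse as finite numbers are dropped with a
    logged count. The axis is normalised to ascending order; duplicate axis
    values raise :class:`SpectrumError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    axis_kind = AxisKind(axis_kind)

    raw_lines = path.read_text().splitlines()
    data_lines = [
        ln for ln in raw_lines[header_rows:] if ln.strip() and not ln.lstrip().startswith("#")
    ]
    delim = delimiter or _detect_delimiter(data_lines)

    xs: list[float] = []
    ys: list[float] = []
    dropped = 0
    for line in data_lines:
        parts = line.split() if delim == " " else line.split(delim)
        parts = [p.strip() for p in parts if p.strip()]
        if len(parts) < 2:
            dropped += 1
            continue
        try:
            if decimal != ".":
                parts = [p.replace(decimal, ".") for p in parts]
            x, y = float(parts[0]), float(parts[1])
        except ValueError:
            dropped += 1
            continue
        if not (np.isfinite(x) and np.isfinite(y)):
            dropped += 1
            continue
        xs.append(x)
        ys.append(y)

    if dropped:
        logger.info("read_xy_spectrum: dropped %d unparseable/non-finite rows from %s", dropped, path)
    if len(xs) < MIN_POINTS:
        raise SpectrumError(
            f"too few points: {len(xs)} valid rows in {path} (need ≥ {MIN_POINTS})"
        )

    axis = np.array(xs)
    intensity = np.array(ys)
    order = np.argsort(axis, kind="stable")
    axis = axis[order]
    intensity = intensity[order]
    if np.any(np.diff(axis) == 0):
        raise SpectrumError(f"duplicate axis values in {path}")

    return Spectrum(
        axis_kind,
        axis,
        intensity,
        label=label if label is not None else path.stem,
        metadata=metadata or {},
    )


def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write one CSV per named tidy table under ``out_dir``.

    Values are rendered with 12 significant digits so a read-back reproduces
    them within 1e-9 relative; returns the written paths.
    """
    if not tables:
        raise ValueError("no tables to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        target = out_dir / f"{name}.csv"
        df.to_csv(target, index=False, float_format="%.12g")
        written.append(target)
    return written


def write_xy_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum back to two-column CSV (full float precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"# axis_kind: {spectrum.axis_kind.value}\n")
        for x, y in zip(spectrum.axis, spectrum.intensity):
            fh.write(f"{float(x)!r},{float(y)!r}\n")
    return path
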