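"""FTIR band absorbances and the standard lignocellulose ratio indices.

Band absorbance is read as the window maximum around a nominal centre,
optionally after a local linear baseline anchored at the window edges.
The indices are the usual degradation trackers: syringyl/guaiacyl lignin
ratio, three IR crystallinity ratios, and the Nelson–O'Connor style lateral
order index (LOI), total crystallinity index (TCI) and hydrogen-bond
intensity (HBI). All are ratios of band absorbances, hence invariant under
uniform scaling of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .core_io import Spectrum
from .errors import WindowError

Baseline = Literal["none", "local_linear"]


@dataclass(frozen=True)
class BandDefinition:
    """A named absorbance band: window ``center ± half_window`` in cm⁻¹."""

    name: str
    center: float
    half_window: float = 8.0

    def __post_init__(self) -> None:
        if not 400.0 <= self.center <= 4000.0:
            raise ValueError(f"band center {self.center} outside 400–4000 cm⁻¹")
        if self.half_window <= 0:
            raise ValueError("half_window must be positive")


#: Default band set: (numerator, denominator) centres per index.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "sg_ratio": (1329.0, 1270.0),
    "r_1317_1512": (1317.0, 1512.0),
    "r_1127_897": (1127.0, 897.0),
    "r_2900_897": (2900.0, 897.0),
    "loi": (1430.0, 898.0),
    "tci": (1372.0, 2900.0),
    "hbi": (3400.0, 1320.0),
}


@dataclass(frozen=True)
class FTIRIndices:
    """Dimensionless FTIR ratio indices for one spectrum."""

    sg_ratio: float
    r_1317_1512: float
    r_1127_897: float
    r_2900_897: float
    loi: float
    tci: float
    hbi: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sg_ratio": self.sg_ratio,
            "r_1317_1512": self.r_1317_1512,
            "r_1127_897": self.r_1127_897,
            "r_2900_897": self.r_2900_897,
            "loi": self.loi,
            "tci": self.tci,
            "hbi": self.hbi,
        }


def band_absorbance(
    spectrum: Spectrum,
    band: BandDefinition,
    baseline: Baseline = "none",
    mode: Literal["height", "area"] = "height",
    anchor_factor: float = 3.0,
) -> float:
    """Absorbance of ``band``: window maximum (or integrated area).

    With ``baseline="local_linear"`` a straight line through two anchor
    points at ``center ± anchor_factor·half_window`` is subtracted first.
    The anchors sit well outside the peak-pick window so an isolated band's
    own shoulders do not lift the baseline; anchors beyond the spectrum
    range are clamped to its ends.
    """
    lo = band.center - band.half_window
    hi = band.center + band.half_window
    if lo < spectrum.axis[0] or hi > spectrum.axis[-1]:
        raise WindowError(
            f"band {band.name!r} window [{lo}, {hi}] outside spectrum range "
            f"[{spectrum.axis[0]:.4g}, {spectrum.axis[-1]:.4g}]"
        )
    mask = spectrum.window_mask(lo, hi)
    if mask.sum() < 2:
        raise WindowError(f"band {band.name!r} window contains fewer than 2 points")
    x = spectrum.axis[mask]
    y = spectrum.intensity[mask].astype(float)

    if baseline == "local_linear":
        x_lo = max(band.center - anchor_factor * band.half_window, spectrum.axis[0])
        x_hi = min(band.center + anchor_factor * band.half_window, spectrum.axis[-1])
        y_lo = float(np.interp(x_lo, spectrum.axis, spectrum.intensity))
        y_hi = float(np.interp(x_hi, spectrum.axis, spectrum.intensity))
        slope = (y_hi - y_lo) / (x_hi - x_lo)
        y = y - (y_lo + slope * (x - x_lo))

    if mode == "area":
        return float(np.trapezoid(y, x))
    return float(y.max())


def ftir_indices(
    spectrum: Spectrum,
    bands: Mapping[str, tuple[float, float]] | None = None,
    half_window: float = 8.0,
    baseline: Baseline = "none",
    mode: Literal["height", "area"] = "height",
) -> FTIRIndices:
    """Compute all ratio indices from configured (numerator, denominator) bands.

    Raises ``ValueError`` when any denominator absorbance is non-positive
    (band absent from the spectrum).
    """
    band_map = dict(DEFAULT_BANDS)
    if bands:
        band_map.update(bands)

    values: dict[str, float] = {}
    for name, (num_center, den_center) in band_map.items():
        a_num = band_absorbance(
            spectrum, BandDefinition(f"{name}_num", num_center, half_window), baseline, mode
        )
        a_den = band_absorbance(
            spectrum, BandDefinition(f"{name}_den", den_center, half_window), baseline, mode
        )
        if a_den <= 0:
            raise ValueError(
                f"denominator band at {den_center} cm⁻¹ has non-positive absorbance"
            )
        values[name] = a_num / a_den
    return FTIRIndices(**values)
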