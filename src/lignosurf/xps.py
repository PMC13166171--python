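"""XPS region deconvolution and surface-composition ratios.

A high-resolution region (C1s, O1s or N1s) is modelled as 1–4 Gaussian
components on a smooth background. After background subtraction the
components are fitted by non-negative least squares; each component's area
is ``height · sigma · √(2π)`` and relative contributions are normalised over
the fitted components of that region.

The C1s envelope is summarised by the conventional four components

* C1 — C–(C,H): unoxidised carbon (lignin aliphatics/aromatics),
* C2 — C–O: alcohol/ether carbon (cellulose backbone),
* C3 — C=O / O–C–O: carbonyl and acetal carbon,
* C4 — COOH: carboxyl carbon,

from which oxidation-state ratios are derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from lmfit import Model, Parameters

from .core_io import Spectrum
from .errors import FitError, SpectrumError

Background = Literal["linear", "shirley"]

#: Conventional C1s component centres (eV) for C1..C4.
DEFAULT_C1S_CENTERS = (284.8, 286.4, 288.1, 289.2)
#: O1s components: O1 (O–C=O, lignin), O2 (C–O, carbohydrate), O3 (C=O).
DEFAULT_O1S_CENTERS = (530.5, 529.0, 531.8)
#: N1s centre from protein/bacterial surface nitrogen.
DEFAULT_N1S_CENTER = 404.9


@dataclass(frozen=True)
class XPSComposition:
    """Surface elemental percentages and their derived atomic ratios."""

    c_pct: float
    o_pct: float
    n_pct: float
    oc_ratio: float
    cn_ratio: float


@dataclass(frozen=True)
class CarbonEnvelope:
    """Relative contribution % of the four C1s components."""

    c1: float
    c2: float
    c3: float
    c4: float

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3", "c4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FittedComponent:
    center_ev: float
    sigma_ev: float
    height: float
    area: float


@dataclass(frozen=True)
class ComponentFit:
    """Result of a Gaussian deconvolution of one XPS region."""

    components: tuple[FittedComponent, ...]
    shares_percent: tuple[float, ...]
    background: Background
    residual_norm: float

    @property
    def total_area(self) -> float:
        return sum(c.area for c in self.components)


def average_surveys(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise mean of two surveys of the same region.

    Identical grids are averaged directly; otherwise both traces are
    re-gridded by linear interpolation onto the intersection of their axis
    ranges (grid of the first survey restricted to the overlap).
    """
    if a.axis_kind != b.axis_kind:
        raise SpectrumError("cannot average surveys with different axis kinds")
    if np.array_equal(a.axis, b.axis):
        return Spectrum(
            a.axis_kind, a.axis, 0.5 * (a.intensity + b.intensity),
            label=f"mean({a.label},{b.label})",
        )
    lo = max(a.axis[0], b.axis[0])
    hi = min(a.axis[-1], b.axis[-1])
    if lo >= hi:
        raise SpectrumError("survey axis ranges do not overlap")
    mask = a.window_mask(lo, hi)
    grid = a.axis[mask]
    if grid.size < 8:
        raise SpectrumError("survey overlap contains too few points")
    ya = a.intensity[mask]
    yb = np.interp(grid, b.axis, b.intensity)
    return Spectrum(
        a.axis_kind, grid, 0.5 * (ya + yb), label=f"mean({a.label},{b.label})"
    )


def _subtract_background(
    x: np.ndarray, y: np.ndarray, background: Background, edge_points: int = 5
) -> np.ndarray:
    """Remove a linear or Shirley background estimated from the region edges."""
    n = min(edge_points, max(1, x.size // 10))
    y_lo = float(y[:n].mean())
    y_hi = float(y[-n:].mean())
    if background == "linear":
        base = y_lo + (y_hi - y_lo) * (x - x[0]) / (x[-1] - x[0])
        return y - base
    if background == "shirley":
        # Iterative Shirley: background at x proportional to the integrated
        # signal above background at higher kinetic energy (here: to the right).
        base = np.full_like(y, y_lo)
        for _ in range(50):
            signal = y - base
            cum = np.concatenate(([0.0], np.cumsum(0.5 * (signal[1:] + signal[:-1]) * np.diff(x))))
            total = cum[-1]
            if total <= 0:
                break
            new = y_lo + (y_hi - y_lo) * cum / total
            if np.max(np.abs(new - base)) < 1e-9 * max(abs(y_hi), abs(y_lo), 1.0):
                base = new
                break
            base = new
        return y - base
    raise ValueError(f"unknown background {background!r}")


def _multi_gaussian(x: np.ndarray, **params: float) -> np.ndarray:
    n = len(params) // 3
    out = np.zeros_like(x)
    for i in range(n):
        h = params[f"h{i}"]
        c = params[f"c{i}"]
        s = params[f"s{i}"]
        out = out + h * np.exp(-0.5 * ((x - c) / s) ** 2)
    return out


def fit_components(
    region: Spectrum,
    init: Sequence[tuple[float, float]],
    background: Background = "linear",
    center_window_ev: float = 0.4,
) -> ComponentFit:
    """Deconvolute a region into Gaussian components.

    Parameters
    ----------
    region : Spectrum
        Binding-energy region trace.
    init : sequence of (center_eV, sigma_eV)
        Initial guesses, one per component (1–4 components).
    background : {"linear", "shirley"}
        Background model subtracted before fitting.
    center_window_ev : float
        Half-width of the box constraint on each fitted centre.
    """
    if not 1 <= len(init) <= 4:
        raise ValueError(f"expected 1–4 components, got {len(init)}")
    x = region.axis
    y = region.intensity.astype(float)
    lo, hi = float(x[0]), float(x[-1])
    for center, _sigma in init:
        if not lo <= center <= hi:
            raise ValueError(f"init center {center} eV outside region [{lo}, {hi}] eV")

    y_sub = _subtract_background(x, y, background)

    n = len(init)
    model = Model(_multi_gaussian)
    params = Parameters()
    peak = max(float(y_sub.max()), 1e-9)
    for i, (center, sigma) in enumerate(init):
        params.add(f"h{i}", value=peak / n, min=0.0)
        params.add(
            f"c{i}", value=center,
            min=max(lo, center - center_window_ev),
            max=min(hi, center + center_window_ev),
        )
        # widths constrained near the initial guess: region broadening is
        # instrument-dominated, and loose widths let overlapped neighbours
        # exchange area
        params.add(f"s{i}", value=sigma, min=sigma / 2.0, max=sigma * 2.0)

    result = model.fit(y_sub, params, x=x)
    if not result.success:
        raise FitError("XPS component fit did not converge")

    edge_tol = (hi - lo) / 100.0
    comps: list[FittedComponent] = []
    for i in range(n):
        h = float(result.params[f"h{i}"].value)
        c = float(result.params[f"c{i}"].value)
        s = float(result.params[f"s{i}"].value)
        if c - lo < edge_tol or hi - c < edge_tol:
            raise FitError(f"component {i} collapsed onto the region edge at {c:.2f} eV")
        comps.append(FittedComponent(center_ev=c, sigma_ev=s, height=h,
                                     area=h * s * math.sqrt(2.0 * math.pi)))

    total = sum(c.area for c in comps)
    if total <= 0:
        raise FitError("all fitted component areas are zero")
    shares = tuple(100.0 * c.area / total for c in comps)
    residual = float(np.linalg.norm(result.residual))
    return ComponentFit(
        components=tuple(comps), shares_percent=shares,
        background=background, residual_norm=residual,
    )


def elemental_ratios(c_pct: float, o_pct: float, n_pct: float) -> XPSComposition:
    """O/C and C/N atomic ratios from surface elemental percentages."""
    if c_pct <= 0:
        raise ValueError("C% must be positive")
    if n_pct <= 0:
        raise ValueError("N% must be positive for the C/N ratio")
    if o_pct < 0:
        raise ValueError("O% must be non-negative")
    return XPSComposition(
        c_pct=c_pct, o_pct=o_pct, n_pct=n_pct,
        oc_ratio=o_pct / c_pct, cn_ratio=c_pct / n_pct,
    )


def oxygenated_ratio(envelope: CarbonEnvelope) -> float:
    """C_oxygenated / C_unoxygenated = (C2 + C3 + C4) / C1.

    The COOH component counts as oxygenated carbon alongside C–O and C=O.
    """
    if envelope.c1 <= 0:
        raise ValueError("C1 must be positive")
    return (envelope.c2 + envelope.c3 + envelope.c4) / envelope.c1


def acid_base_balance(
    envelope: CarbonEnvelope, form: Literal["grouped", "simple"] = "grouped"
) -> float:
    """Acid/base microenvironment balance of the C1s envelope.

    ``grouped`` (default) computes (C2 + C4)/(C1 + C3): electron donors over
    acceptors, the form consistent with reported lignocellulose envelopes.
    ``simple`` computes the bare C2/C1 variant.
    """
    if form == "grouped":
        den = envelope.c1 + envelope.c3
        if den <= 0:
            raise ValueError("C1 + C3 must be positive")
        return (envelope.c2 + envelope.c4) / den
    if form == "simple":
        if envelope.c1 <= 0:
            raise ValueError("C1 must be positive")
        return envelope.c2 / envelope.c1
    raise ValueError(f"unknown form {form!r}")


def co_over_oxidized(envelope: CarbonEnvelope) -> float:
    """C–O over the fully oxidised carbon pool: C2 / (C3 + C4)."""
    den = envelope.c3 + envelope.c4
    if den <= 0:
        raise ValueError("C3 + C4 must be positive")
    return envelope.c2 / den
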