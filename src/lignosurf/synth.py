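"""Synthetic spectra and time series with recorded ground truth.

Every generator returns ``(data, GroundTruth)`` where the ground-truth
sidecar records the exact construction parameters and seed, so each
analysis stage can be tested for parameter recovery without any external
instrument data. Generators are bit-for-bit deterministic under a fixed
seed.

Noise models: multiplicative Gaussian for count spectra (XRD, XPS),
additive Gaussian for absorbance spectra (FTIR) and time series — matching
the dominant noise character of each measurement while staying simple.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from . import xrd
from .core_io import AxisKind, Spectrum, TimeSeries
from .errors import FitError


@dataclass(frozen=True)
class GroundTruth:
    """Self-describing sidecar for one generated dataset."""

    generator: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {"generator": self.generator, "params": self.params, "seed": self.seed},
            indent=2, default=float,
        ))
        return path


def _gauss(x: np.ndarray, center: float, height: float, sigma: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _sigma_from_fwhm(fwhm: float) -> float:
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def make_diffractogram(
    cri_target: float,
    fwhm_002: float = 0.3,
    baseline: float = 100.0,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
    amorphous_height: float = 300.0,
    amorphous_fwhm: float = 7.0,
) -> tuple[Spectrum, GroundTruth]:
    """Diffractogram on the 10–50° grid (step 0.02°) hitting a Segal CrI target.

    The trace is a crystalline 002 Gaussian at 22.5° over a broad amorphous
    halo centred at 18.6° on a constant baseline. The crystalline height is
    solved numerically so that the Segal height extraction (max in the
    crystalline window, min in the amorphous window) returns ``cri_target``
    exactly in the noiseless limit on this grid.
    """
    if not 0.0 <= cri_target < 100.0:
        raise ValueError(f"CrI target {cri_target} outside [0, 100)")
    if fwhm_002 <= 0:
        raise ValueError("fwhm_002 must be positive")

    axis = np.arange(10.0, 50.0 + 1e-9, 0.02)
    sigma_c = _sigma_from_fwhm(fwhm_002)
    sigma_a = _sigma_from_fwhm(amorphous_fwhm)
    base_profile = baseline + _gauss(axis, 18.6, amorphous_height, sigma_a)

    def cri_of(height_c: float) -> float:
        y = base_profile + _gauss(axis, 22.5, height_c, sigma_c)
        spec = Spectrum(AxisKind.TWO_THETA_DEG, axis, y)
        return xrd.segal_cri(xrd.extract_segal_intensities(spec))

    hi = (baseline + amorphous_height) * 1e6
    try:
        height_c = optimize.brentq(
            lambda h: cri_of(h) - cri_target, 0.0, hi, xtol=1e-10
        )
    except ValueError as exc:
        raise FitError(f"no crystalline height satisfies CrI={cri_target}: {exc}") from exc

    y = base_profile + _gauss(axis, 22.5, height_c, sigma_c)
    rng = np.random.default_rng(seed)
    if noise_sd_frac > 0:
        y = y * (1.0 + noise_sd_frac * rng.standard_normal(axis.size))
        y = np.clip(y, 0.0, None)

    truth = GroundTruth(
        generator="diffractogram",
        params={
            "cri_target": cri_target, "fwhm_002": fwhm_002,
            "crystalline_height": height_c, "crystalline_center": 22.5,
            "amorphous_center": 18.6, "amorphous_height": amorphous_height,
            "amorphous_fwhm": amorphous_fwhm, "baseline": baseline,
            "noise_sd_frac": noise_sd_frac,
        },
        seed=seed,
    )
    spec = Spectrum(AxisKind.TWO_THETA_DEG, axis, y, label=f"synthetic_xrd_cri{cri_target:g}")
    return spec, truth


def make_ir_spectrum(
    bands: Sequence[tuple[float, float, float]],
    offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    step: float = 1.0,
) -> tuple[Spectrum, GroundTruth]:
    """Absorbance spectrum on the 400–4000 cm⁻¹ range.

    ``bands`` is a list of (center cm⁻¹, height, sigma cm⁻¹) Gaussians added
    onto a constant offset, with additive Gaussian noise of SD ``noise_sd``.
    The default 1 cm⁻¹ sampling is finer than the 4 cm⁻¹ optical resolution,
    as in interpolated instrument exports, so band maxima are not clipped by
    the grid.
    """
    axis = np.arange(400.0, 4000.0 + 1e-9, step)
    y = np.full(axis.size, float(offset))
    for center, height, sigma in bands:
        if not 400.0 <= center <= 4000.0:
            raise ValueError(f"band center {center} outside 400–4000 cm⁻¹")
        if height < 0:
            raise ValueError("band heights must be non-negative")
        y = y + _gauss(axis, center, height, sigma)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(axis.size)
    truth = GroundTruth(
        generator="ir_spectrum",
        params={"bands": [list(b) for b in bands], "offset": offset, "noise_sd": noise_sd},
        seed=seed,
    )
    return Spectrum(AxisKind.WAVENUMBER_CM, axis, y, label="synthetic_ftir"), truth


def make_xps_region(
    components: Sequence[tuple[float, float, float]],
    total_area: float = 1.0e4,
    background: tuple[float, float] = (0.0, 50.0),
    noise_sd_frac: float = 0.0,
    seed: int = 0,
    pad_ev: float = 5.0,
    step_ev: float = 0.05,
) -> tuple[Spectrum, GroundTruth]:
    """XPS region: Gaussian components on a linear background.

    ``components`` is a list of (center eV, sigma eV, area share); shares
    must sum to 1 within 1e-9. The grid spans the component centres ±
    ``pad_ev`` at ``step_ev`` spacing. ``background`` is (slope, intercept)
    in counts per eV and counts.
    """
    if not components:
        raise ValueError("need at least one component")
    shares = np.array([c[2] for c in components], dtype=float)
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError(f"area shares sum to {shares.sum()!r}, expected 1")
    centers = np.array([c[0] for c in components], dtype=float)
    lo = centers.min() - pad_ev
    hi = centers.max() + pad_ev
    axis = np.arange(lo, hi + 1e-9, step_ev)
    if centers.size > 1:
        gaps = np.diff(np.sort(centers))
        if np.any(gaps < 2 * step_ev):
            raise ValueError("component centres closer than 2 grid steps")

    slope, intercept = background
    y = intercept + slope * (axis - axis[0])
    for center, sigma, share in components:
        area = total_area * share
        height = area / (sigma * math.sqrt(2.0 * math.pi))
        y = y + _gauss(axis, center, height, sigma)
    rng = np.random.default_rng(seed)
    if noise_sd_frac > 0:
        y = y * (1.0 + noise_sd_frac * rng.standard_normal(axis.size))
        y = np.clip(y, 0.0, None)
    truth = GroundTruth(
        generator="xps_region",
        params={
            "components": [list(c) for c in components],
            "total_area": total_area, "background": list(background),
            "noise_sd_frac": noise_sd_frac,
        },
        seed=seed,
    )
    return Spectrum(AxisKind.BINDING_ENERGY_EV, axis, y, label="synthetic_xps"), truth


def make_decay_series(
    y0: float,
    rate: float,
    days: Sequence[float] = (0.0, 3.0, 6.0, 9.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    model: Literal["exponential", "linear"] = "exponential",
    name: str = "synthetic_decay",
) -> tuple[TimeSeries, GroundTruth]:
    """Monotone decay series on the sampling grid with additive noise.

    ``exponential``: y = y0·exp(−rate·t); ``linear``: y = y0 − rate·t.
    """
    if y0 <= 0:
        raise ValueError("y0 must be positive")
    t = np.asarray(days, dtype=float)
    if model == "exponential":
        y = y0 * np.exp(-rate * t)
    elif model == "linear":
        y = y0 - rate * t
    else:
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(t.size)
    truth = GroundTruth(
        generator="decay_series",
        params={"y0": y0, "rate": rate, "days": list(t), "noise_sd": noise_sd,
                "model": model},
        seed=seed,
    )
    return TimeSeries(t, y, name=name), truth
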