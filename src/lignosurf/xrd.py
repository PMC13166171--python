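"""Cellulose crystallinity from X-ray diffractograms.

Two classical estimators are provided:

* the Segal height method — crystallinity index
  ``CrI% = 100 · (I002 − Iam) / I002`` with I002 the peak height of the 002
  reflection near 2θ = 22.5° and Iam the amorphous intensity near 18.6°,
  both taken on raw counts with no baseline removal;
* the Scherrer equation — crystallite size ``CS = k·λ / (β·cos θ)`` from the
  full width at half maximum of the 002 reflection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lmfit.models import GaussianModel, LinearModel

from .core_io import Spectrum
from .errors import FitError, WindowError

#: Default Segal windows (degrees 2θ): crystalline 002 region and amorphous trough.
CRYSTALLINE_WINDOW = (21.5, 23.5)
AMORPHOUS_WINDOW = (17.6, 19.6)

#: Cu Kα wavelength in nm.
CU_KALPHA_NM = 0.15418

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SegalIntensities:
    """Peak-height pair for the Segal crystallinity index."""

    i002: float
    iam: float

    def __post_init__(self) -> None:
        if self.i002 <= 0:
            raise ValueError(f"I002 must be positive, got {self.i002}")
        if self.iam < 0:
            raise ValueError(f"Iam must be non-negative, got {self.iam}")


@dataclass(frozen=True)
class ScherrerParams:
    """Inputs to the Scherrer crystallite-size equation.

    ``beta`` and ``theta`` are in radians; ``theta`` is the Bragg angle,
    i.e. half the peak position in 2θ. ``lambda_nm`` defaults to Cu Kα.
    """

    beta: float
    theta: float
    k: float = 0.94
    lambda_nm: float = CU_KALPHA_NM

    def __post_init__(self) -> None:
        if self.k <= 0 or self.lambda_nm <= 0:
            raise ValueError("k and lambda must be positive")
        if not 0 < self.beta < math.pi:
            raise ValueError(f"beta must lie in (0, π), got {self.beta}")
        if not 0 <= self.theta < math.pi / 2:
            raise ValueError(f"theta must lie in [0, π/2), got {self.theta}")


@dataclass(frozen=True)
class XRDResult:
    """Bundle of Segal and Scherrer outputs for one diffractogram."""

    segal: SegalIntensities
    cri_percent: float
    peak_center_2theta: float
    fwhm_deg: float
    cs_nm: float


def segal_cri(segal: SegalIntensities) -> float:
    """Segal crystallinity index in percent.

    May be negative when the amorphous intensity exceeds the 002 height
    (heavily degraded samples); callers should flag such values.
    """
    return 100.0 * (segal.i002 - segal.iam) / segal.i002


def _check_window(spectrum: Spectrum, window: tuple[float, float], min_points: int = 3) -> np.ndarray:
    lo, hi = window
    if lo >= hi:
        raise WindowError(f"empty window {window}")
    if lo < spectrum.axis[0] or hi > spectrum.axis[-1]:
        raise WindowError(
            f"window {window} outside axis range "
            f"[{spectrum.axis[0]:.4g}, {spectrum.axis[-1]:.4g}]"
        )
    mask = spectrum.window_mask(lo, hi)
    if mask.sum() < min_points:
        raise WindowError(f"window {window} contains {int(mask.sum())} points (< {min_points})")
    return mask


def extract_segal_intensities(
    diffractogram: Spectrum,
    crystalline_window: tuple[float, float] = CRYSTALLINE_WINDOW,
    amorphous_window: tuple[float, float] = AMORPHOUS_WINDOW,
) -> SegalIntensities:
    """Pick I002 (max in crystalline window) and Iam (min in amorphous window).

    Heights are taken on raw counts without background subtraction, per the
    classical Segal convention. The amorphous value is the window minimum
    rather than the intensity at exactly 18.6°, which is robust to the axis
    sampling grid.
    """
    cmask = _check_window(diffractogram, crystalline_window)
    amask = _check_window(diffractogram, amorphous_window)
    i002 = float(diffractogram.intensity[cmask].max())
    iam = float(diffractogram.intensity[amask].min())
    return SegalIntensities(i002=i002, iam=iam)


def fit_peak_fwhm(
    diffractogram: Spectrum,
    window: tuple[float, float] = CRYSTALLINE_WINDOW,
) -> tuple[float, float, float]:
    """Fit one Gaussian on a local linear baseline inside ``window``.

    Returns ``(center_deg, fwhm_deg, amplitude)`` where amplitude is the
    fitted peak height above the baseline. The baseline is linear rather
    than constant because the amorphous-halo tail under the 002 reflection
    is locally sloped; a constant offset systematically inflates the fitted
    width of broad peaks. Raises :class:`FitError` when the fit does not
    converge, the amplitude is non-positive, or the component collapses
    onto the window edge (no genuine peak in the window).
    """
    mask = _check_window(diffractogram, window, min_points=5)
    x = diffractogram.axis[mask]
    y = diffractogram.intensity[mask]

    lo, hi = float(x[0]), float(x[-1])
    span = hi - lo
    model = GaussianModel(prefix="g_") + LinearModel(prefix="bg_")
    height0 = float(y.max() - y.min())
    sigma0 = span / 6.0
    center0 = float(x[int(np.argmax(y))])
    params = model.make_params()
    params["g_center"].set(value=center0, min=lo, max=hi)
    params["g_sigma"].set(value=sigma0, min=span / 200.0, max=span)
    # lmfit Gaussian 'amplitude' is the area: height·sigma·sqrt(2π)
    params["g_amplitude"].set(value=max(height0, 1e-12) * sigma0 * math.sqrt(2 * math.pi), min=0.0)
    params["bg_slope"].set(value=(float(y[-1]) - float(y[0])) / span)
    params["bg_intercept"].set(value=float(y.min()) - ((float(y[-1]) - float(y[0])) / span) * lo)

    result = model.fit(y, params, x=x)
    if not result.success:
        raise FitError("peak fit did not converge")
    center = float(result.params["g_center"].value)
    sigma = float(result.params["g_sigma"].value)
    height = float(result.params["g_height"].value)
    fwhm = FWHM_PER_SIGMA * sigma

    edge_tol = span / 50.0
    if height <= 1e-3 * float(np.ptp(y)):
        raise FitError("fitted amplitude is negligible: no peak in window")
    if center - lo < edge_tol or hi - center < edge_tol:
        raise FitError("fitted peak collapsed onto the window edge: no interior maximum")
    if fwhm > 2.0 * span:
        raise FitError("fitted width exceeds the window: no resolvable peak")
    return center, fwhm, height


def scherrer_cs(params: ScherrerParams) -> float:
    """Crystallite size in nm from Scherrer broadening."""
    return params.k * params.lambda_nm / (params.beta * math.cos(params.theta))


def analyze_diffractogram(
    diffractogram: Spectrum,
    crystalline_window: tuple[float, float] = CRYSTALLINE_WINDOW,
    amorphous_window: tuple[float, float] = AMORPHOUS_WINDOW,
    k: float = 0.94,
    lambda_nm: float = CU_KALPHA_NM,
) -> XRDResult:
    """Full XRD stage: Segal CrI plus Scherrer CS from the fitted 002 peak."""
    segal = extract_segal_intensities(diffractogram, crystalline_window, amorphous_window)
    cri = segal_cri(segal)
    center, fwhm_deg, _amp = fit_peak_fwhm(diffractogram, crystalline_window)
    beta = math.radians(fwhm_deg)
    theta = math.radians(center / 2.0)
    cs = scherrer_cs(ScherrerParams(beta=beta, theta=theta, k=k, lambda_nm=lambda_nm))
    return XRDResult(
        segal=segal,
        cri_percent=cri,
        peak_center_2theta=center,
        fwhm_deg=fwhm_deg,
        cs_nm=cs,
    )
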