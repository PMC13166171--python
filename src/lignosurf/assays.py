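"""Scalar screening-assay computations.

Covers the spectrophotometric screens used to rank candidate strains:
platinum–cobalt colour units for lignin decolourisation, Congo Red
decolourisation percent for cellulolytic activity, and gravimetric
substrate degradation percent.
"""

from __future__ import annotations

from typing import Literal

#: A465 of the 500-CU platinum–cobalt standard solution.
PT_CO_STANDARD_A = 0.132

DegradationConvention = Literal["weight_loss", "residual"]


def colour_units(a_sample: float, a_standard: float = PT_CO_STANDARD_A) -> float:
    """Colour units: CU = 500 · A_sample / A_standard.

    Linear in the sample absorbance; the standard is the 500-CU
    platinum–cobalt solution (A465 = 0.132 by default).
    """
    if a_standard <= 0:
        raise ValueError("standard absorbance must be positive")
    if a_sample < 0:
        raise ValueError("sample absorbance must be non-negative")
    return 500.0 * a_sample / a_standard


def percent_decolorization(a_before: float, a_after: float) -> float:
    """Congo Red decolourisation %: 100 · (A_before − A_after) / A_before."""
    if a_before <= 0:
        raise ValueError("pre-degradation absorbance must be positive")
    if a_after < 0:
        raise ValueError("post-degradation absorbance must be non-negative")
    return 100.0 * (a_before - a_after) / a_before


def degradation_percent(
    w_before: float,
    w_after: float,
    convention: DegradationConvention = "weight_loss",
) -> float:
    """Gravimetric substrate degradation percent.

    ``weight_loss`` (default) is 100·(W_before − W_after)/W_before — the
    quantity usually reported as "degradation %". ``residual`` is the
    literal mass-remaining form 100·W_after/W_before; the two conventions
    sum to 100 for any valid mass pair.
    """
    if w_before <= 0 or w_after <= 0:
        raise ValueError("masses must be positive")
    if convention == "weight_loss":
        if w_after > w_before:
            raise ValueError("post-degradation mass exceeds initial mass")
        return 100.0 * (w_before - w_after) / w_before
    if convention == "residual":
        return 100.0 * w_after / w_before
    raise ValueError(f"unknown convention {convention!r}")
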