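"""Surface lignin coverage (SLC) from XPS O/C ratios.

Three estimators are implemented, in increasing order of rigour:

1. **Legacy linear mixing** — SLC% interpolated between pure-cellulose
   (O/C 0.83) and pure-lignin (O/C 0.33) endmembers. Known to produce
   out-of-range values for low-lignin substrates such as rice straw; such
   values are returned with an explicit flag.

2. **Stoichiometric mass balance** — the surface is modelled as S
   anhydro-sugar units (C6O5, segment molar mass 162.1 g/mol) and L lignin
   phenylpropane segments (C9.92O3.32, 183.5 g/mol). The observed atomic
   ratio r = O/C then fixes the lignin mole fraction

       s_lignin = L/(L+S) = (5 − 6r) / (1.68 + 3.92r)

   which is 0 at the carbohydrate endmember (r = 5/6) and 1 at the lignin
   endmember (r = 3.32/9.92). The weight fraction follows from the segment
   molar-mass ratio ρ = 183.5/162.1:  w = ρs / (1 + (ρ − 1)s).

3. **Excess-carbon correction** — measured O/C ratios are biased low by
   carbon-rich lignin contamination. Referenced to theoretical cellulose
   (O/C 0.833) and rice-straw-derived cellulose (O/C 0.74), the excess
   carbon fraction is k = (0.833 − 0.74)/(0.833 + 1), and the corrected
   ratio solves  1/r_corr = (1 − k)(1/r_meas + 1) − 1.  The lignin O/C
   contribution is r_corr − r_meas and SLC% = 100·(r_corr − r_meas)/r_corr.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Stoichiometry:
    """Empirical surface stoichiometry of carbohydrate and lignin segments."""

    carb_c: float = 6.0
    carb_o: float = 5.0
    carb_molar_mass: float = 162.1
    lignin_c: float = 9.92
    lignin_o: float = 3.32
    lignin_molar_mass: float = 183.5

    def __post_init__(self) -> None:
        for name in ("carb_c", "carb_o", "carb_molar_mass",
                     "lignin_c", "lignin_o", "lignin_molar_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def oc_carbohydrate(self) -> float:
        return self.carb_o / self.carb_c

    @property
    def oc_lignin(self) -> float:
        return self.lignin_o / self.lignin_c

    @property
    def mass_ratio(self) -> float:
        """ρ = M_lignin / M_carbohydrate (1.132 with the defaults)."""
        return self.lignin_molar_mass / self.carb_molar_mass


@dataclass(frozen=True)
class CorrectionReferences:
    """Reference cellulose O/C values anchoring the excess-carbon correction."""

    oc_theoretical_cellulose: float = 5.0 / 6.0
    oc_ricestraw_cellulose: float = 0.74

    def __post_init__(self) -> None:
        if not 0 < self.oc_ricestraw_cellulose <= self.oc_theoretical_cellulose < 1:
            raise ValueError(
                "require 0 < rice-straw cellulose O/C ≤ theoretical O/C < 1"
            )


#: Default references; note the theoretical O/C is quoted as 0.833 in print.
DEFAULT_REFERENCES = CorrectionReferences(
    oc_theoretical_cellulose=0.833, oc_ricestraw_cellulose=0.74
)


@dataclass(frozen=True)
class LegacySLC:
    """Legacy linear-mixing SLC with its out-of-range flag."""

    slc_percent: float
    out_of_range: bool


@dataclass(frozen=True)
class SLCResult:
    """Corrected surface-lignin-coverage bundle for one measured O/C."""

    oc_measured: float
    oc_corrected: float
    oc_lignin: float
    slc_percent: float
    s_lignin: float
    w_lignin: float


def slc_legacy(
    oc_sample: float, oc_lignin: float = 0.33, oc_cellulose: float = 0.83
) -> LegacySLC:
    """Two-endmember linear mixing estimate of SLC%.

    Flags (rather than clamps) values outside [0, 100]; the out-of-range
    behaviour on low-lignin substrates is exactly why the corrected
    mass-balance estimator exists.
    """
    if oc_lignin >= oc_cellulose:
        raise ValueError("lignin endmember O/C must be below the cellulose endmember")
    value = 100.0 * (oc_cellulose - oc_sample) / (oc_cellulose - oc_lignin)
    return LegacySLC(slc_percent=value, out_of_range=not 0.0 <= value <= 100.0)


def lignin_mole_fraction(oc_ratio: float, st: Stoichiometry | None = None) -> float:
    """Lignin segment mole fraction s = L/(L+S) from an O/C ratio.

    Returns the raw value; results outside [0, 1] indicate an O/C outside
    the two stoichiometric endmembers and are the caller's to flag.
    """
    st = st or Stoichiometry()
    num = st.carb_o - st.carb_c * oc_ratio
    den = (st.carb_o - st.lignin_o) + (st.lignin_c - st.carb_c) * oc_ratio
    if den <= 0:
        raise ValueError(f"degenerate stoichiometric denominator {den}")
    return num / den


def lignin_weight_fraction(s_lignin: float, st: Stoichiometry | None = None) -> float:
    """Lignin weight fraction from the mole fraction via segment molar masses."""
    if not 0.0 <= s_lignin <= 1.0:
        raise ValueError(f"mole fraction {s_lignin} outside [0, 1]")
    st = st or Stoichiometry()
    rho = st.mass_ratio
    return rho * s_lignin / (1.0 + (rho - 1.0) * s_lignin)


def mole_fraction_from_weight(w_lignin: float, st: Stoichiometry | None = None) -> float:
    """Algebraic inverse of :func:`lignin_weight_fraction`."""
    if not 0.0 <= w_lignin <= 1.0:
        raise ValueError(f"weight fraction {w_lignin} outside [0, 1]")
    st = st or Stoichiometry()
    rho = st.mass_ratio
    return w_lignin / (rho - (rho - 1.0) * w_lignin)


def excess_carbon_fraction(ref: CorrectionReferences | None = None) -> float:
    """Excess-carbon fraction k = (OC_theoretical − OC_ricestraw)/(OC_theoretical + 1)."""
    ref = ref or DEFAULT_REFERENCES
    return (ref.oc_theoretical_cellulose - ref.oc_ricestraw_cellulose) / (
        ref.oc_theoretical_cellulose + 1.0
    )


def corrected_oc(oc_measured: float, k: float) -> float:
    """Excess-carbon-corrected O/C: 1/r_corr = (1 − k)(1/r_meas + 1) − 1."""
    if oc_measured <= 0:
        raise ValueError("measured O/C must be positive")
    if not 0.0 <= k < 1.0:
        raise ValueError(f"excess fraction k={k} outside [0, 1)")
    inv = (1.0 - k) * (1.0 / oc_measured + 1.0) - 1.0
    if inv <= 0:
        raise ValueError(
            f"correction with k={k} yields non-positive corrected ratio for O/C={oc_measured}"
        )
    return 1.0 / inv


def slc_corrected(
    oc_measured: float,
    ref: CorrectionReferences | None = None,
    st: Stoichiometry | None = None,
) -> SLCResult:
    """Full corrected-SLC chain for one measured O/C ratio.

    Reports the lignin O/C contribution (corrected − measured), the SLC%
    share of the corrected ratio, and the stoichiometric mole/weight
    fractions evaluated at the corrected ratio (clipped to [0, 1] for the
    weight-fraction conversion only).
    """
    ref = ref or DEFAULT_REFERENCES
    st = st or Stoichiometry()
    k = excess_carbon_fraction(ref)
    oc_corr = corrected_oc(oc_measured, k)
    oc_lig = oc_corr - oc_measured
    slc_pct = 100.0 * oc_lig / oc_corr
    s_lig = lignin_mole_fraction(oc_corr, st)
    w_lig = lignin_weight_fraction(min(max(s_lig, 0.0), 1.0), st)
    return SLCResult(
        oc_measured=oc_measured,
        oc_corrected=oc_corr,
        oc_lignin=oc_lig,
        slc_percent=slc_pct,
        s_lignin=s_lig,
        w_lignin=w_lig,
    )
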