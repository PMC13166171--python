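# Methods

This note documents the models, numerical choices and limitations behind
each analysis stage, and what the synthetic-data generators do and do not
emulate.

## Data model

All traces are `Spectrum` objects (axis in 2θ°, cm⁻¹ or eV; intensity in
counts or absorbance). The axis is normalised to ascending order on load and
every analysis window is specified in axis units, never sample indices, so
instrument export orientation is irrelevant. Rows with unparseable or
non-finite fields are dropped with a logged count rather than raised on —
instrument exports routinely carry sentinel rows. Duplicate axis values are
an error (they make interpolation and window logic ambiguous). Spectra need
at least 8 points; time series need strictly increasing day values.

## XRD

**Segal crystallinity.** CrI% = 100·(I002 − Iam)/I002 with I002 the maximum
raw intensity in the crystalline window (default 21.5–23.5° 2θ) and Iam the
minimum raw intensity in the amorphous window (default 17.6–19.6°). Heights
are taken on raw counts with no background subtraction, following the
classical height method; the amorphous value is the window minimum rather
than the intensity at exactly 18.6° so the estimate does not depend on the
sampling grid phase. CrI may legitimately be negative for heavily degraded
material (amorphous trough above the 002 height); it is returned unclamped.

Raw max/min picking has a known extreme-value sensitivity: under
multiplicative noise of fraction f, the window maximum is biased high and
the minimum low by a couple of f·I, which biases CrI upward by roughly
(100 − CrI)·O(2f). At f = 1% this is ~1 percentage point — smaller than
typical between-replicate spread, and averaged away by replicate
measurements, but worth knowing when comparing single scans.

**002 peak width.** The FWHM for the Scherrer equation comes from a
least-squares fit of one Gaussian on a *linear* local baseline inside the
crystalline window. A constant offset was tried first and rejected: the
amorphous-halo tail under the 002 reflection is locally sloped, and with a
constant baseline the Gaussian absorbs the slope, inflating the fitted
width of broad (≈1°) peaks by tens of percent. With the linear baseline the
width is recovered within ~2% across the tested grid. Fits whose amplitude
is negligible relative to the data range, or whose centre collapses onto a
window edge, are rejected as "no peak" rather than returned.

**Scherrer size.** CS = k·λ/(β·cos θ) with k = 0.94 and λ = 0.15418 nm
(Cu Kα) by default; λ is configurable. β is the fitted FWHM converted to
radians and θ is half the fitted peak position. No instrumental-broadening
deconvolution is applied, so CS is a lower bound when instrumental width is
non-negligible.

## FTIR

Band absorbance is the window maximum in `center ± half_window`
(half-window default 8 cm⁻¹), optionally after subtracting a straight line
through two anchor points at ±3 half-windows from the centre. The anchors
deliberately sit outside the peak-pick window: anchoring at the window
edges would subtract the band's own shoulders for bands wider than the
window (a σ = 6 cm⁻¹ band loses ~40% of its height that way). Peak heights
rather than integrated areas are the default because the ratio indices are
conventionally height-based; areas are available behind `mode="area"`.

Index band centres default to: S/G 1329/1270, plus 1317/1512, 1127/897,
2900/897, LOI 1430/898, TCI 1372/2900, HBI 3400/1320 — the standard
Nelson–O'Connor-style conventions. All centres are configurable because
published studies differ in the exact positions. A non-positive denominator
absorbance (band absent) raises rather than returning infinity.

## XPS

Regions are modelled as 1–4 Gaussians on a background. The background
default is linear through the region edges; an iterative Shirley background
is available. Components are parameterised by height, centre and width with
non-negative heights, centres box-constrained near their initial guesses
(±0.4 eV default) and widths constrained within a factor of two of the
initial width. The width constraint matters: region broadening is dominated
by the shared instrument response, and with loose widths two overlapped
neighbours (e.g. the C3/C4 pair, 1.1 eV apart) can exchange area freely
while barely changing the residual. Areas are height·σ·√(2π) and relative
contributions are normalised over the fitted components of the region.
Published survey-normalised contribution tables (rows not summing to 100)
can be consumed directly as `CarbonEnvelope` values; the ratio operations
are scale-invariant so the normalisation convention does not affect them.

Envelope ratios: oxygenated/unoxygenated carbon is (C2+C3+C4)/C1 — the
COOH component counts as oxygenated. The acid/base balance defaults to the
grouped form (C2+C4)/(C1+C3), which is the form consistent with reported
lignocellulose envelope tables; the bare C2/C1 variant is available via
`form="simple"`. Default component centres are C1s 284.8/286.4/288.1/289.2
eV, O1s 530.5/529.0 (+531.8 for C=O), N1s 404.9 eV, all configurable.

Two same-region surveys are averaged pointwise; offset grids are linearly
interpolated onto the intersection of their ranges (grid of the first
survey). Si2p regions are out of scope.

## Surface lignin coverage

The legacy estimator interpolates linearly between pure-cellulose
(O/C 0.83) and pure-lignin (O/C 0.33) endmembers. It is retained because
its failure is informative: on low-lignin, oxidised surfaces it leaves
[0, 100]% and the result carries an explicit out-of-range flag.

The stoichiometric model treats the surface as S anhydro-sugar units
(C6O5, segment molar mass 162.1 g/mol — H is invisible to XPS but carries
mass, hence segment masses rather than formula masses) and L lignin
phenylpropane segments (C9.92O3.32, 183.5 g/mol). Counting O and C atoms
gives the mole fraction s = (5 − 6r)/(1.68 + 3.92r) at observed O/C = r,
exactly 0 and 1 at the two endmembers (r = 5/6 and 3.32/9.92); the weight
fraction follows from the segment-mass ratio ρ = 183.5/162.1 as
w = ρs/(1 + (ρ−1)s). The mole fraction is returned unclamped so values
outside [0, 1] can flag an O/C outside the endmember interval.

The excess-carbon correction assumes the carbon surplus contributed by
lignin contamination is the same proportion of the total signal in
rice-straw-derived cellulose (reference O/C 0.74) as in the measured
sample. Relative to theoretical cellulose (O/C 0.833) this fixes the excess
fraction k = (0.833 − 0.74)/(0.833 + 1) ≈ 0.0507, and the corrected ratio
solves 1/r_corr = (1 − k)(1/r_meas + 1) − 1. The correction can only raise
O/C (equality iff k = 0) and is strictly increasing in both k and r_meas on
its valid domain; inputs for which the right-hand side is non-positive are
rejected. SLC% = 100·(r_corr − r_meas)/r_corr is reported alongside the
stoichiometric fractions evaluated at r_corr; the two notions of "lignin
share" (an O/C share and a mole fraction) are deliberately reported
separately since they need not coincide.

## Trend statistics

**Exact Mann–Kendall.** S = Σ_{i<j} sign(v_j − v_i); the null is obtained
by enumerating all n! orderings of the observed values (3 ≤ n ≤ 8), which
handles ties without any correction because the actual data are permuted.
The one-sided p is the tail probability in the observed direction, and a
strictly monotone n = 4 series attains p = 1/24 ≈ 0.042 — significant
one-sided at 0.05 but not two-sided (2/24 ≈ 0.083). One-sided is the
default report because at n = 4 it is the only way a monotone trend can
clear 0.05; the two-sided value is always reported alongside.

**Decay fits.** Exponential y0·e^(−kt) (requires positive values; started
from the log-linear fit) or straight line. The CI on the rate/slope is a
seeded residual bootstrap-t: residuals are leverage-adjusted
(r/√(1−h), recentred) for the linear model or √(n/(n−p))-rescaled for the
exponential, resampled with replacement onto the fitted trajectory, and
each of the (default 2000) refits is studentised by its own standard
error. Plain percentile intervals were tried first and rejected: at n = 4
with two fitted parameters the raw residuals underestimate the error scale
by √2 and percentile intervals ignore the heavy tails of the studentised
statistic, giving ~75% coverage at nominal 95%; the bootstrap-t variant
reaches ~92% in the package's own coverage simulation. Pair resampling is
not offered — at n = 4 it degenerates. A noiseless series returns a
degenerate CI at the estimate; R² is defined as 0 for a constant series.

**Correlations** are scipy's product-moment and rank coefficients with a
zero-variance guard.

## Synthetic data

Generators exist so that every analyzer can be tested against known ground
truth with no instrument data. Design choices:

- **Diffractograms**: 10–50° at 0.02° steps; a crystalline Gaussian at
  22.5° over a broad amorphous Gaussian halo centred at 18.6° (default
  height 300 counts over a 100-count baseline, FWHM 7°). The crystalline
  height is solved numerically (root-finding on the actual grid) so the
  Segal extraction reproduces the requested CrI *exactly* in the noiseless
  limit — the generator targets the estimator's own convention, not an
  abstract crystalline fraction.
- **IR spectra**: sums of Gaussians on 400–4000 cm⁻¹ at 1 cm⁻¹ sampling
  (finer than the 4 cm⁻¹ optical resolution, as in interpolated exports, so
  band maxima are not clipped by the grid), additive noise.
- **XPS regions**: Gaussians with prescribed area shares on a linear
  background, 0.05 eV grid spanning the centres ±5 eV, multiplicative
  noise.
- **Decay series**: exponential or linear trajectories on the day grid with
  additive noise.

Noise is multiplicative for count spectra (XRD, XPS) and additive for
absorbance and time series, matching the dominant noise character of each
measurement. All generators are bit-for-bit deterministic under a fixed
seed.

What the generators do **not** emulate: Lorentz-polarisation and
multi-peak allomorph structure in diffraction, spin–orbit doublets and
charge shift in photoemission, atmospheric/KBr artefacts in IR, and any
correlated (non-white) noise. Passing recovery tests therefore demonstrate
correctness of the estimators under idealised single-peak/white-noise
conditions, not robustness to every real-data pathology.

## Problem sizes

The recovery suites use 200 synthetic XPS envelopes, a 3×3 CrI/FWHM grid,
and 200 replicate bootstrap-coverage simulations at 2000 resamples each —
sizes chosen so the whole test suite completes in well under a minute on a
single core while keeping Monte-Carlo noise on the checked proportions
small (±~1.5% on a 95% proportion at n = 200).

## Known limitations

- Single-survey quantification (relative sensitivity factors, charge
  calibration, depth profiling) is out of scope; elemental percentages are
  consumed as given.
- The Segal index is a convention, not a physical crystalline fraction; its
  raw height-picking carries the noise bias quantified above.
- The excess-carbon correction's reference O/C values are substrate
  constants; applying the defaults to non-rice-straw material requires
  re-anchoring `CorrectionReferences`.
- The exact Mann–Kendall enumeration is O(n!) and restricted to n ≤ 8 by
  design; larger series should use the standard tie-corrected normal
  approximation, which this package deliberately does not provide.
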