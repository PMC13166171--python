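# lignosurf

Quantitative surface chemistry of microbial lignocellulose degradation.

When bacteria deconstruct a lignocellulosic substrate such as rice straw, the
surface changes in ways that standard materials-characterisation techniques
can track: the cellulose crystallinity falls (XRD), lignin and cellulose band
ratios shift (FTIR), and the surface becomes more oxidised as the carbon-rich
lignin wrap is stripped away (XPS). `lignosurf` packages the quantitative
analysis of such a degradation time course for microbiologists and biomass
chemists: each stage is a small, tested function, every analyzer has a
matching synthetic-data generator with known ground truth, and a pipeline
assembles per-timepoint reports with small-sample trend statistics.

## What it computes

**XRD** — Segal crystallinity index and Scherrer crystallite size:

```
CrI% = 100 · (I002 − Iam) / I002          CS = k·λ / (β·cos θ)
```

with I002 the 002 peak height near 2θ = 22.5°, Iam the amorphous intensity
near 18.6° (both on raw counts), β the FWHM of the 002 reflection from a
Gaussian-plus-linear-baseline fit, and λ = 0.15418 nm (Cu Kα) by default.

**FTIR** — band-ratio indices from window-maximum absorbances: the
syringyl/guaiacyl lignin ratio A1329/A1270, the crystallinity ratios
A1317/A1512, A1127/A897 and A2900/A897, the lateral order index
LOI = A1430/A898, total crystallinity index TCI = A1372/A2900 and
hydrogen-bond intensity HBI = A3400/A1320 (centres configurable).

**XPS** — Gaussian deconvolution of C1s/O1s/N1s regions with linear or
Shirley background, elemental O/C and C/N ratios, and the carbon-envelope
ratios (C2+C3+C4)/C1, (C2+C4)/(C1+C3) and C2/(C3+C4) over the conventional
C1 (C–C/C–H), C2 (C–O), C3 (C=O/O–C–O), C4 (COOH) components.

**Surface lignin coverage (SLC)** — three estimators of the lignin fraction
of the fibre surface from the measured O/C ratio r:

1. legacy linear mixing between pure-cellulose (0.83) and pure-lignin (0.33)
   endmembers — flagged when it leaves [0, 100]%, its known failure mode on
   low-lignin substrates;
2. a stoichiometric mass balance treating the surface as anhydro-sugar units
   (C6O5, 162.1 g/mol) and lignin phenylpropane segments (C9.92O3.32,
   183.5 g/mol): s_lignin = (5 − 6r)/(1.68 + 3.92r);
3. an excess-carbon correction referenced to theoretical (0.833) and
   rice-straw-derived (0.74) cellulose O/C: with
   k = (0.833 − 0.74)/1.833 ≈ 0.0507, the corrected ratio solves
   1/r_corr = (1 − k)(1/r_meas + 1) − 1, the lignin contribution is
   r_corr − r_meas, and SLC% = 100·(r_corr − r_meas)/r_corr.

**Trend statistics** — the exact Mann–Kendall test (full permutation
enumeration, valid at n = 4 where the normal approximation is not),
first-order decay fits with seeded residual bootstrap-t confidence
intervals, and Pearson/Spearman correlations.

## Worked example

Generate a synthetic day-0 diffractogram (CrI 30.08%, 002 FWHM 0.3°, 1%
noise) and analyse it:

```
$ lignosurf synth xrd --cri 30.08 --fwhm 0.3 --noise 0.01 --seed 7 --out scan_day0.csv
$ lignosurf xrd --input scan_day0.csv
i002,iam,cri_percent,peak_center_2theta,fwhm_deg,cs_nm
548.347,378.296,31.0115,22.4999,0.296472,28.5576
```

The Segal extraction reads the 002 height (548) and amorphous trough (378)
and returns CrI = 31.0% — within noise of the 30.08% construction target —
and the fitted 0.296° FWHM gives a 28.6 nm crystallite.

Corrected surface lignin coverage from a measured O/C of 0.85:

```
$ lignosurf slc --oc 0.85 --legacy
oc_measured,oc_corrected,oc_lignin,slc_percent,s_lignin,w_lignin,slc_legacy_percent,slc_legacy_out_of_range
0.85,0.938048,0.0880475,9.38625,-0.11728,0,-4,True
```

The excess-carbon correction raises 0.85 to 0.938; the 0.088 difference is
the lignin O/C contribution, 9.4% of the corrected ratio. The legacy mixing
estimator returns −4% — flagged out of range, illustrating why the corrected
estimator exists. (The negative stoichiometric mole fraction says the
corrected ratio sits above the pure-carbohydrate endmember 5/6.)

Exact trend test on a four-timepoint coverage series:

```
$ lignosurf trend mk --input slc_series.csv
{"s": -6, "n": 4, "p_one_sided": 0.0417, "p_two_sided": 0.0833, "direction": "decreasing"}
```

S = −6 is the maximal decreasing statistic at n = 4; the exact one-sided
p = 1/24 is the probability that a random ordering of four distinct values
is strictly decreasing.

A full study (per-day spectra plus composition tables listed in a YAML
manifest) runs with `lignosurf run --manifest study.yaml --out results/`,
producing one tidy CSV per technique plus a trend table and a run log.

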