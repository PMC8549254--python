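# cmrsv

Regional contributions to left-ventricular stroke volume from segmented
cine-CMR contours, with synthetic deforming-ventricle phantoms and CRT
outcome statistics.

## The problem

In heart failure with conduction delay (typically left bundle branch
block), the left ventricle ejects blood through three distinct motions:
descent of the atrioventricular (AV) plane toward the apex (longitudinal
function), inward motion of the free wall (lateral), and motion of the
interventricular septum (septal).  In dyssynchrony the septum may move
*toward the right ventricle* during systole — a negative contribution to
stroke volume.  Quantifying these three contributions from cardiac MR is of
interest both for characterising dyssynchronous failure and as a candidate
predictor of response to cardiac resynchronization therapy (CRT).

This package implements that quantification from segmented short-axis
contour stacks plus long-axis AV-plane landmarks, together with everything
needed to exercise and validate it at the desk: analytic phantoms, a
synthetic cohort generator, and the outcome statistics used in CRT response
studies.

## The method

Given epicardial/endocardial contours at end diastole (ED) and end systole
(ES), two RV insertion points per slice, and six AV-plane landmarks per
phase:

- **Volumetrics** — slice summation: `V = Σ A_k · (thickness + gap)`;
  `SV = EDV − ESV`, `EF = SV / EDV`, mass = 1.05 g/ml × myocardial volume.
- **Longitudinal contribution** — AVPD is the mean ED→ES displacement of
  the six landmarks projected on the long axis;
  `SV_long = AVPD × mean of the two largest ED epicardial areas` among
  slices encompassed by the AV-plane excursion, and
  `SV_long% = 100 · SV_long / SV`.
- **Radial contributions** — per slice, the signed area swept between the
  ED and ES epicardial contours, split at the RV insertion points into a
  septal and a free-wall (lateral) part, summed (× slice spacing) over
  slices apical to the ES AV-plane position.  The septal term is signed:
  negative when the septum moves net toward the right ventricle.
- **Outcome statistics** — responder = ≥ 15 % LVESV reduction at follow-up;
  2×2 odds ratios with Woolf 95 % CIs; Student t / chi-squared / Fisher
  group comparisons; univariable logistic screening (p < 0.25) feeding a
  multivariable model; noncentral-t sample-size computation.

Because the myocardium is incompressible, the ejected volume equals the
total epicardial volume change, which is why every decomposition term uses
epicardial contours.  The decomposition is not exactly conservative; the
remainder is reported as `residual_pct`, never redistributed.  See
`docs/methods.md` for conventions, tolerances and limitations.

## Worked example

Generate a healthy-control-like cylinder phantom (AVPD 15.3 mm, modest
radial motion) and decompose it:

```sh
cmrsv phantom generate --seed 7 -o work/
cmrsv regional compute work/phantom.json -o work/out
cat work/out/results.csv
```

```
subject_id,edv_ml,esv_ml,sv_ml,ef_pct,mass_g,cardiac_output_l_min,avpd_mm,basal_area_cm2,sv_long_ml,sv_long_pct,sv_lat_ml,sv_lat_pct,sv_sept_ml,sv_sept_pct,residual_pct,flags
phantom-cylinder-seed7,132.89,45.80,87.09,65.54,147.71,,15.30,34.20,52.32,60.08,25.23,28.97,8.67,9.95,1.00,
```

Reading the row: the phantom ejects 87 ml (EF 66 %); the 15.3 mm AV-plane
descent over a 34.2 cm² base accounts for 52.3 ml (60.1 % of SV), free-wall
inward motion for 29.0 %, septal motion for a further 10.0 % (positive:
toward the LV), leaving a 1.0 % residual from basal-area averaging and
slice discretization.  A dyssynchronous ventricle would instead show a
negative `sv_sept_pct`.

Cohort side — simulate a 65-patient cohort with the structure of a CRT
study and analyse it:

```sh
cmrsv cohort simulate --seed 3 -o work/cohort.csv
cmrsv cohort analyze work/cohort.csv -o work/analysis
cmrsv stats power --delta 7 --sd 16 --ratio 0.7567567567567568
# n = 97 per experimental group (control n = 73.4054), achieved power 0.803
```

`work/analysis/table_contingency.csv` then holds the per-predictor 2×2
counts, odds ratios and test p-values; the logistic screening tables sit
alongside.

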