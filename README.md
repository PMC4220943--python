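# cephorient

Superimposition of repeated 3D cephalometric digitizations by **4-point
plane orientation**, with a full error analysis of the procedure.

When a radiologist digitizes craniofacial landmarks on a CBCT volume, the
coordinates live in scanner space, so repeated digitizations (or scans)
must first be *reoriented* into a common anatomical frame before they can
be compared. One of the simplest such frames uses four cranial-base
landmarks: the midpoint between the most posterior points of the lesser
wings of the sphenoid (**MLWS**, the origin), nasion (**Na**), sella
(**S**) and basion (**Ba**). The anteroposterior *y* axis runs parallel
to the Na–S line; the vertical *z* axis is the perpendicular dropped from
Ba onto that line; the transverse *x* axis completes the right-handed
system.

Reorientation is rigid, but because *every* landmark — including the four
reference points — is placed with error, each trial is reoriented by a
slightly different frame, and the post-reorientation disagreement between
two trials (the **reorientation error** `Y`) exceeds the raw placement
disagreement (the **locating error** `Db`). This package implements the
frame construction, the error statistics, and the regression model that
explains `Y`:

```
Y ≈ b0 + b1·Db + b2·DX + b3·A3r
```

where, for each landmark and trial pair,

- `Db` — Euclidean distance between the two placements (mm, scanner space);
- `DX` — perpendicular distance of the pair-averaged landmark from the
  reoriented x axis (mm); points far below/above the cranial base are
  most sensitive to pitch errors of the frame;
- `A3r = α + β + γ` — sum of the angles, seen from the averaged landmark,
  subtended by the two placements of Na, S and Ba (degrees); a
  landmark's-eye view of how much the reference configuration shifted.

The package also provides ICC(3,1) reproducibility per coordinate, an
SPSS-style stepwise (entry p < 0.05, removal p > 0.10) OLS fit with VIF
diagnostics and a 3-SD outlier screen, and a seeded synthetic-cohort
generator whose per-landmark anisotropic noise and skull geometry are
calibrated to published repeat-digitization measurements — so the entire
pipeline is testable without any patient data.

## Worked example

```python
from cephorient import (CohortConfig, generate_cohort, compute_error_records,
                        summarize_records, assemble_rows, fit_all_scopes)

cohort = generate_cohort(CohortConfig(seed=1))       # 20 patients x 3 trials
records = compute_error_records(cohort.trials)       # 60 pairs x 19 landmarks
print(summarize_records(records))
rows = assemble_rows(records)                        # 900 rows, 15 landmarks
total = fit_all_scopes(rows, candidates=("Db", "DX", "A3r"))["Total"]
print(total.predictors, total.coefficients, total.adj_r_squared)
```

Per-landmark summary (selected rows, mm and degrees):

```
landmark   Y mean(SD)    Db mean(SD)   DX mean   A3r mean
MLWS       0.00(0.00)    0.34(0.15)      0.00       -
Na         0.66(0.28)    0.60(0.26)     67.26       -
Ans        1.03(0.59)    0.43(0.19)     54.66      1.80
Me         3.02(1.83)    0.75(0.38)    126.29      0.70
GoR        2.35(1.21)    1.11(0.52)     92.73      0.88
```

MLWS is its own frame origin, so its reorientation error is identically
zero; for every other landmark the mean `Y` exceeds the mean `Db`, and
`Y` grows with distance from the x axis (compare Me at ~126 mm with Ans
at ~55 mm). The pooled stepwise fit on this cohort selects all three
predictors:

```
Total: Y = b0 + 0.658·Db + 0.015·DX + 0.267·A3r
       adjusted R² = 0.213, VIF = {Db: 1.00, DX: 1.39, A3r: 1.39},
       18 of 900 rows excluded as >3 SD outliers
```

i.e. about 21% of the reorientation-error variance is explained by the
three factors, each with negligible collinearity — a model structure that
closely matches fits on human digitizations (pooled coefficients
Db 0.758, DX 0.018 per mm, A3r 0.545 per degree; these are available as
`cephorient.REFERENCE_FIT_COEFFICIENTS` and drive
`predict_marginal`: e.g. 0.018 × 100 mm = 1.8 mm of extra reorientation
error per 10 cm of DX).

ICC(3,1) for every landmark coordinate on this cohort exceeds 0.995:
between-patient anatomy dwarfs digitization noise, so single-observer
repeated digitization is highly reliable even though superimposition
error is not negligible.

The same pipeline is scriptable from the shell:

```sh
cephorient simulate --out cohort.csv --seed 1
cephorient reorient --in cohort.csv --out reoriented.csv
cephorient metrics  --in cohort.csv --records records.csv --summary-prefix tables_
cephorient regress  --records records.csv --out regression.json
cephorient icc      --in cohort.csv --out icc.csv
cephorient report   --out-dir results/ --seed 1     # all of the above
```

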