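# Methods

## The 4-point anatomical frame

Given one digitization trial, the frame is built from MLWS, Na, S, Ba:

- `y = (Na − S) / |Na − S|` — anteroposterior, positive toward Na;
- `foot = S + ((Ba − S)·y) y` — perpendicular foot of Ba on the Na–S
  line; `z = (foot − Ba) / |foot − Ba|` — vertical, positive from Ba up
  toward the cranial base;
- `x = y × z` — transverse, completing a right-handed basis;
- origin at MLWS.

Reorientation maps each point `P` to `((P−o)·x, (P−o)·y, (P−o)·z)`. The
map is rigid, so inter-landmark distances are preserved exactly and the
origin landmark maps to the zero vector — which is why MLWS has
identically zero reorientation error in every analysis.

Conventions that the source description leaves open and that we fix
once: positive axis directions (anterior / superior as above; all error
statistics are invariant to these sign choices, which affect only signed
coordinate reporting), and the reading of "the line orthogonal to the y
axis through Ba" as the perpendicular dropped from Ba onto the Na–S
line. Degeneracy (Na = S, or Ba on the Na–S line) is declared below a
tolerance of 1e-6 mm — far below digitization noise (~0.3 mm), far above
double-precision rounding. Coordinates are treated as continuous mm
values; no voxel quantization is modelled.

## Error statistics

For a pair of trials (same patient, same image):

- **Db** and the per-axis absolute differences are computed in scanner
  coordinates, before any reorientation.
- **Y** reorients each trial with the frame from its *own* reference
  landmarks and takes the distance between the two images of the
  landmark. If the reference landmarks agree exactly across trials the
  two frames coincide and Y = Db (a shared rigid map preserves
  distances); reference-landmark noise adds frame error on top.
- **DX** (and the auxiliary DY, DZ, D0 axis/origin distances) use a
  single frame built from the *pair-averaged* reference landmarks,
  applied to the pair-averaged landmark. The alternative — averaging the
  two per-trial reoriented positions — differs only at second order in
  the noise; we fix the averaged-frame construction and document it.
- **A3r** is computed in scanner coordinates (both trials digitize the
  same image, so the averaged landmark and the reference placements live
  in one space): for each of Na, S, Ba the angle at the averaged
  landmark between its two placements, via the arccosine of the clamped
  normalized dot product, summed and expressed in degrees. A reference
  placement within 1e-6 mm of the averaged landmark is degenerate. A3r
  is reported per pair (not averaged over pairs) and only for the 15
  analysis landmarks; for the reference landmarks themselves it is
  stored as NaN.

**ICC.** Reproducibility is ICC(3,1) — two-way mixed effects, single
rater, consistency — per landmark per axis, patients as targets and
trials as raters (computed via `pingouin`, cross-checked against the
ANOVA mean-square formula in the tests). This form matches the design:
one observer repeating measurements on fixed subjects.

**Summaries.** Mean and sample SD (n−1 denominator; a single value
reports SD as NaN); quartiles by inclusive linear interpolation between
order statistics. Both conventions are choices among equally defensible
ones and affect only the descriptive tables.

## Regression

One row per (patient, pair, analysis landmark); the four reference
landmarks are excluded because their placements *define* the frame. With
the default design this gives 20 × 3 × 15 = 900 pooled rows and 300 per
pair scope. Rows from the same patient/landmark are pooled as
independent observations — a clustering caveat inherited from the study
design this mirrors; no mixed-effects correction is attempted.

- **Outlier rule**: rows whose response Y lies more than 3 sample SDs
  from the scope mean are dropped, in a single pass, before fitting
  (configurable; with zero SD nothing is dropped). The screened variable
  is the response.
- **Stepwise OLS**: forward entry by smallest partial p-value while
  p < 0.05, backward removal while a selected predictor (other than the
  one just entered) has p > 0.10 — the defaults of the classic
  stepwise implementations; both thresholds configurable. An empty model
  is a valid result, not an error. Duplicated candidates or a
  rank-deficient design at any step raise a collinearity error. Once the
  residual sum of squares is numerically zero relative to the total, no
  further entries are attempted (partial p-values on an exact fit are
  meaningless).
- **Diagnostics**: VIF per selected predictor from auxiliary
  regressions, adjusted R², coefficient p-values (reported at full
  precision, mirrored at 3 decimals). An intercept is always fitted and
  reported but flagged `intercept_comparable = False`: the reference
  fits on human data report none.
- **Candidates** default to {Db, DX, A3r, DY, DZ, D0}: the last three
  encode the hypothesis that distance from the y/z axes or from the
  origin drives the error, which fits on human digitizations rejected.
- `predict_marginal` returns B × delta with no intercept — the marginal
  reading of the linear model ("1 mm more locating error ⇒ ~0.76 mm more
  reorientation error" with the pooled reference coefficients).

## Synthetic cohorts

The generator emulates the reference study design — 20 patients, 3
trials by one observer on the same image — in three layers:

1. **Template.** A fixed 19-landmark skull in the anatomical frame.
   Each analysis landmark sits at exactly its published mean
   perpendicular distance from the x axis (Ans 55.35 … Me 126.63 mm);
   the split of that distance into y/z (an elevation angle) and the
   bilateral transverse offsets are *not* constrained by any published
   value and are hard-coded plausible adult dimensions, with bilateral
   pairs mirrored in x. The four reference landmarks are placed
   midsagittally such that the frame built from the template is exactly
   canonical. Downstream calibration checks depend only on the
   constrained distances.
2. **Between-patient anatomy and placement.** Global size factor
   N(1, 0.03), per-landmark isotropic jitter N(0, 2 mm) — invented,
   realistic magnitudes whose role is to make between-patient variance
   dwarf digitization noise (ICC > 0.99), as observed in practice — and
   a rigid scanner placement: per-axis rotations N(0, 5°) and
   translations N(0, 10 mm), typical head-positioning variation.
3. **Digitization noise.** Independent Gaussian noise per landmark,
   axis and trial, applied in scanner axes (where an observer's error
   arises). Only the mean/SD of absolute repeat differences are
   published, not a noise law; Gaussian is chosen for tractability and
   calibrated through the half-normal identity: if both placements have
   per-axis SD σ, the absolute difference has mean 2σ/√π, so
   σ = mean_abs_diff · √π / 2 (e.g. 0.89 mm → σ = 0.789 mm).

All randomness flows from one integer seed through a single
`numpy.random.Generator`; identical seeds give identical cohorts.

What the generator does **not** model: systematic (bias) error,
voxelization, rater drift/learning, correlated errors between nearby
landmarks, and real anatomical covariance structure. Consequently,
passing tests demonstrate that the *pipeline* computes the intended
quantities and that the study's qualitative findings (Y ≥ Db, ICC >
0.99, a ~0.2 adjusted-R² three-factor model with VIF ≈ 1) follow from
its stated noise structure — not that the generator reproduces real
patients. One visible artefact: in the stylized template most landmarks
lie near the midsagittal plane, so DX, DY and D0 are strongly collinear
and the stepwise fit on synthetic data may pick DY in place of DX; on
human data the y/z/origin distances were rejected. The synthetic cohort
cannot adjudicate that distinction, which is why fits intended to mirror
the reference model are run with candidates restricted to
{Db, DX, A3r}.

## Problem sizes and determinism

Default analyses use the 20 × 3 study design (60 pairs, 900 regression
rows). Calibration checks use 1e5 Monte-Carlo draws per landmark-axis;
selection-behaviour simulations use 100 replicates at n = 900; ICC
behaviour under pure noise uses 200 subjects. These sizes make every
statistical assertion's sampling error small relative to its tolerance
while keeping the full suite fast. All stochastic tests fix their seeds.

## Known limitations

- Pooled OLS ignores within-patient clustering (by design, to mirror
  the reference analysis).
- The stepwise procedure inherits the usual caveats of data-driven
  selection (post-selection p-values are optimistic); with three
  pure-noise decoys and entry p = 0.05, the probability that no decoy
  enters is ≈ 0.95³ ≈ 0.86 per fit — exact recovery of a true predictor
  set therefore fails in roughly one fit in seven even when every true
  predictor is fully powered.
- Real supplementary coordinate tables are XLSX; this package reads
  only the CSV interchange schema (`patient_id,trial_id,landmark,x_mm,
  y_mm,z_mm`) — convert spreadsheets to CSV externally.
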