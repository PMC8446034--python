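# Methods

This note records the models, parameter choices and numerical conventions
behind `bonescreen`, and what the synthetic experiments do and do not
demonstrate.

## Morphometry

The six landmarks are interpreted in millimetres with x rightward and
y downward (pixel coordinates are 0-based at pixel centres and convert to
mm by multiplying with the pixel spacing). Heights are Euclidean
distances within the anterior, posterior and middle pairs. The width is
the mean of the superior-edge (anterior-superior ↔ posterior-superior) and
inferior-edge distances — the symmetric reading of "mean distance between
the anterior and posterior points"; pairings that mix superior with
inferior points were rejected because they measure diagonals, not width.
Note that when `h_a ≠ h_p` the edges slant, so the measured width
slightly exceeds the horizontal anterior–posterior separation; the width
is defined as the measured edge mean, not the horizontal separation.

The three deformity criteria use strict `<` at 0.8, 0.6 and 0.55: a ratio
exactly at its threshold is normal. They intentionally detect only
moderate-to-severe deformity; no attempt is made to grade mild (Genant
grade 1) changes. When several criteria fire, the reported label follows
the precedence severe > wedge/crush > biconcave — a collapse severe enough
for the third criterion dominates shape distinctions, and asymmetric
height loss dominates mid-plate depression. The precedence is a
documented package choice, not an external convention.

Degenerate configurations — coincident height pairs, a self-intersecting
hexagonal outline — raise `DegenerateGeometryError` rather than being
silently measured.

## Quality assessment

Detector scores are the maximum probability-map response over grid cells
whose centres fall inside the ROI polygon, boundary inclusive (a cell
centre exactly on the polygon edge counts as inside). Scores at or above
their threshold are positive; the default operating point is 0.5 on all
channels and is configurable, since real detector operating points are
deployment-specific.

Neighbour exclusion compares each vertebra's predicted T-score against
the mean of its up-to-two nearest assessable vertebrae in the L1–L4
chain: an interior vertebra uses its adjacent neighbour on each side; a
chain endpoint uses the two nearest inward vertebrae (a pure
single-neighbour rule would let one interior outlier drag its endpoint
neighbour out with it, misattributing the deviation). A deviation
strictly greater than 1.0 T-score units excludes the vertebra — the
ISCD-style "more than 1.0 T-score difference from neighbours" reading of
the exclusion rule; the delta is configurable. The decision is a single
simultaneous pass on pre-exclusion values: cascading re-evaluation could
empty the chain and has no principled stopping rule. The metric defaults
to predicted T-scores; predicted BMD is supported via configuration.

The scan-level rule requires at least two assessable vertebrae; the
surviving vertebrae of a failed scan are marked `too_few_vertebrae` so
the report shows why the scan as a whole was rejected.

## BMD regression

Preprocessing: bilinear resample to 0.15 mm spacing; if the result
overflows 512 px it is scaled down uniformly (letterbox) and then padded
symmetrically with zeros to 512×512; the full frame is min–max normalised
to [0, 1], with a constant frame mapping to 0.5. Normalising the full
frame last makes the operation idempotent. Per-image min–max is used
because absolute radiographic intensity varies with exposure and is not a
reliable density signal.

Augmentation (training only) draws rotation, isotropic scale, translation
and shear uniformly from configured half-widths (defaults ±10°, ±5%
scale and translation, 0° shear); all-zero ranges are exactly the
identity, and a fixed generator state reproduces the transform.

The reference model keeps the published contract — backbone features, two
fully connected layers with ReLU, vertebra one-hot of length 4 appended
before the final layer, L1 loss, fourfold cross-validation with the
ensemble mean at inference — but uses a deliberately small, dependency-free
backbone: 8×8 block means plus global mean and SD (66 features, frozen),
with only the head trained (full-batch Adam, default 300 epochs, learning
rate 0.01, hidden width 16, features standardised on the training folds).
Fold assignment is a seeded random partition without replacement with
sizes differing by at most one; each member trains on three folds and the
per-epoch loss is logged. Predictions are clamped at a 0.01 g/cm² floor
(logged when it occurs), and the ensemble mean is by construction bounded
by the member extremes. No member is ever rejected from the ensemble; the
member spread is reported so callers can monitor disagreement. Any
backbone callable mapping a preprocessed grid to a feature vector can be
substituted to scale the model up.

## Synthetic phantoms

The phantom generator defines the study conditions for every downstream
test; its defaults are not tuning knobs.

*Images.* A phantom ROI is a 16-bit frame: uniform background of 10 000
grey levels with a centred "bone" disc at 30 000, plus optional additive
Gaussian noise truncated to the 16-bit range (a standard radiographic
noise proxy). The disc's *area fraction* is affine in true BMD (0.05 at
0.2 g/cm² to 0.30 at 1.6 g/cm²), so the noise-free mean intensity is an
affine, strictly monotone map of BMD up to pixel discretisation of the
disc radius — and, because the signal is geometric rather than
photometric, it survives per-image min–max normalisation. The default
rendering is 64 px at 1.2 mm spacing, i.e. exactly 512 px at the model's
0.15 mm working resolution. All generators are pure functions of their
arguments; identical (spec, seed) gives bit-identical images.

*Landmarks.* Deformity families scale the base heights: wedge scales
`h_a` by 1−severity (middle interpolated halfway), biconcave scales
`h_m`, and crush/severe-flat scale all three heights uniformly (the
simplest geometry reducing the stated heights; the two families are
therefore geometrically identical and differ only in label). Severity 0
reproduces the identity geometry in every family, and for the wedge
family the first criterion fires exactly when severity > 0.2.

*Cohorts.* Osteoporosis status is Bernoulli per patient with default
prevalence 21.5% (hip) and 43.3% (spine), matching the screening
populations the package emulates. The patient's lowest T-score is drawn
uniformly from (−4.2, −2.5] when osteoporotic, (−2.5, 1.5) otherwise;
per-ROI T-scores sit at or above that minimum (half-normal offsets, SD
0.25) with one ROI attaining it. BMD follows from representative
young-adult references (hip 0.942/0.122, spine 1.047/0.110 g/cm²; these
are configuration defaults, not published constants, and real deployments
must supply their own). DXA measurement noise is Gaussian with SD
0.01 g/cm² — a precision-level assumption, since no repeatability figure
is available for the emulated cohorts. Ages are clipped normals (mean 72
hip / 67 spine, SD 11), the female fraction is 77.4% / 79.6%, and
radiograph–DXA intervals are exponential with medians 29 / 16 days capped
at 180.

*What passing tests show.* Phantoms demonstrate that the pipeline's
measurement, exclusion and decision logic is correct and that the
regression contract can recover a density signal through preprocessing.
They are not photorealistic: no trabecular texture, osteophytes, bowel
gas, soft tissue or projection effects. Recovery r ≈ 0.99 on phantoms
says nothing about clinical accuracy on radiographs, which depends on
trained detectors and clinical-scale backbones that are out of scope
here.

## Risk model and triage

The bundled `ToyLogisticRiskModel` is explicitly *not* FRAX: it is a
fixed logistic form in age, sex, BMI and BMD that produces plausibly
scaled 10-year percentages so the risk-classification plumbing
(inclusive ≥20% major / ≥3% hip cut-offs) can be tested. A real
deployment plugs in an external calculator behind the same `predict`
signature. Device cross-calibration is an affine map per site with
configurable coefficients (identity by default).

Triage follows the half-open intervals `(-inf, T1)`, `[T1, T2)`,
`[T2, inf)`; a value exactly at T1 is referred for DXA and exactly at T2
is classified non-osteoporotic. Triage operates on either predicted BMD
or predicted T-score; mixing scales within one cohort is rejected by the
configuration schema. Reported percentages round half-up to one decimal.

## Evaluation statistics

Calibration regresses measured on predicted, so slope 1 /
calibration-in-the-large 0 is the ideal; calibration-in-the-large equals
the Bland–Altman bias (mean of measured − predicted) by construction, and
the test suite asserts the identity. RMSE is the root mean squared OLS
residual with denominator n. AUROC is the trapezoidal/rank-statistic area
with tie correction; AUPRC is step-wise average precision (not PR
trapezoids — the two differ and the choice is deliberate). Lower
predicted BMD is oriented as more positive for osteoporosis. The odds
ratio uses the Woolf log-interval, adding 0.5 to every cell when any cell
is zero. Wilson intervals are provided for proportions.

The threshold search is exhaustive over observed values: T1 is the
largest threshold whose below-threshold positives attain PPV ≥ target
(capturing the most positives subject to the constraint), T2 the smallest
threshold whose at-or-above negatives attain NPV ≥ target. An
unattainable target returns an explicit no-solution result rather than
raising.

## Problem sizes

The default test and acceptance runs use 400 training + 100 held-out
phantoms at 64 px (seconds per run), 1000 random landmark sets for the
morphometry oracle suite, 500 random map/polygon pairs for the QA oracle
suite, and pipeline smoke cohorts of 12–40 patients — sizes chosen so the
whole suite exercises every code path in well under a minute per module
while keeping the statistical checks (binomial prevalence recovery,
held-out correlation) comfortably powered.

## Known limitations

* The synthetic detector reads ground-truth labels; detector errors and
  partial-volume responses are not modelled.
* Phantom geometry encodes density in disc area; models that exploit
  texture cannot be meaningfully compared on these phantoms.
* The reference backbone is intentionally tiny; it is a contract
  implementation, not a clinical-accuracy baseline.
* Spine triage operating points are meaningful only on the T-score scale
  unless a site-specific reference table is supplied to map them to BMD.
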