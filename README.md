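# bonescreen

Opportunistic osteoporosis screening from radiograph regions of interest
(ROIs): six-point vertebral morphometry with automated deformity criteria,
radiograph quality assessment, a pluggable areal-BMD regressor,
T-score / fracture-risk classification, and the dual-threshold triage that
decides who can be classified immediately and who needs a confirmatory DXA
scan. Every stage runs end to end on synthetic phantom data with known
ground truth, so the whole pipeline is testable on a laptop without any
clinical images.

## Who this is for

Researchers and engineers building or validating opportunistic screening
pipelines: radiographs acquired for other indications are re-used to flag
patients at risk of osteoporosis, at no extra cost or radiation. The
package provides the measurement and decision layer of such a pipeline;
the upstream landmark/lesion detectors are pluggable inputs.

## The method

**Morphometry.** Each lumbar vertebra (L1–L4) is summarised by six
landmarks — two anterior, two posterior, two mid-plate — giving anterior,
posterior and middle heights `h_a, h_p, h_m` and width `w`. Three ratio
criteria in the Genant semiquantitative spirit flag moderate-to-severe
compression deformity (all inequalities strict):

```
min(h_a, h_p) / max(h_a, h_p) < 0.8     (wedge / crush)
h_m / max(h_a, h_p)           < 0.6     (biconcave)
max(h_a, h_p) / w             < 0.55    (severe collapse)
```

**Quality assessment.** Hip ROIs are excluded when the maximum response of
a fracture or implant detector inside the ROI polygon reaches its
threshold. Spine scans pass a three-step filter: implant/VCF detection,
the morphometric criteria above, then exclusion of vertebrae whose
predicted T-score deviates from their assessable neighbours by more than
1.0 (ISCD-style). If a scan keeps fewer than two assessable vertebrae it
is rejected as a whole.

**BMD regression.** ROIs are resampled to 0.15 mm pixel spacing,
letterboxed to 512×512 and min–max normalised; a backbone encodes the
grid into features and two fully connected layers (ReLU) output areal BMD
in g/cm²; spine models receive the vertebra level as a one-hot vector of
length 4 before the last layer. Training minimises the L1 loss under
fourfold cross-validation; inference averages the four fold-models. The
bundled reference backbone is a fixed pooled-intensity encoder with a
trainable numpy head — small enough to train in seconds on phantoms, and
replaceable by any callable satisfying the same contract.

**Risk and triage.** T = (BMD − young-adult mean)/SD; osteoporosis is
T ≤ −2.5; 10-year fracture-risk percentages from a pluggable risk model
are high at ≥20% (major osteoporotic) and ≥3% (hip). Triage against two
operating points T1 < T2 (chosen so PPV ≥ 95% below T1 and NPV ≥ 95% at or
above T2): `value < T1` → classified osteoporotic, `T1 ≤ value < T2` →
refer for DXA, `value ≥ T2` → classified non-osteoporotic. The evaluation
module supplies the threshold search plus Pearson/R²/RMSE, calibration
slope and calibration-in-the-large, Bland–Altman agreement, AUROC/AUPRC
and confusion-table statistics.

## Worked example

```python
from bonescreen.phantom import PhantomSpec, Deformity, generate_vertebra_landmarks
from bonescreen.morphometry import compute_morphometry, morphometry_table

specs = [("L1", Deformity.NONE, 0.0), ("L2", Deformity.WEDGE, 0.35),
         ("L3", Deformity.BICONCAVE, 0.5), ("L4", Deformity.NONE, 0.0)]
rows = [compute_morphometry(generate_vertebra_landmarks(
            PhantomSpec(true_bmd=0.8, deformity=d, severity=s), vertebra_level=lv))
        for lv, d, s in specs]
print(morphometry_table(rows).round(3).to_string(index=False))
```

```
vertebra_level  h_a_mm  h_p_mm  h_m_mm   w_mm   r1    r2    r3    c1    c2    c3  abnormal      deformity
            L1   25.00    25.0  25.000 35.000 1.00 1.000 0.714 False False False     False         normal
            L2   16.25    25.0  20.625 35.272 0.65 0.825 0.709  True False False      True wedge_or_crush
            L3   25.00    25.0  12.500 35.000 1.00 0.500 0.714 False  True False      True      biconcave
            L4   25.00    25.0  25.000 35.000 1.00 1.000 0.714 False False False     False         normal
```

The 35% wedge reduces the anterior height to 16.25 mm, so the wedge/crush
ratio 0.65 fires the first criterion; the 50% biconcave deformity halves
the middle height (ratio 0.50 < 0.6). Both vertebrae would be excluded by
QA, leaving L1 and L4 assessable — still two, so the scan remains usable.

Triaging a predicted hip BMD of 0.500 g/cm² against the operating points
T1 = 0.513 and T2 = 0.580 g/cm²:

```python
from bonescreen.triage import t_score, triage
t_score(0.50, 0.942, 0.122)                  # -3.62
triage(0.500, 0.513, 0.580).category.value   # 'classified_osteoporotic'
```

The full pipeline is also available from a shell:

```bash
bonescreen simulate --n 200 --site spine --seed 1 --out-dir study/
bonescreen train    --config config.yaml --out model.json
bonescreen screen   --config config.yaml
```

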