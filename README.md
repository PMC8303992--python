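# fmisodyn

Longitudinal ¹⁸F-FMISO-PET hypoxia monitoring for chemo-radiotherapy (CRT) of
head-and-neck cancer: a tested, reusable pipeline that segments the hypoxic
sub-volume (HSV) of a tumor, quantifies how it changes in **size** and
**location** between a baseline scan (W0) and in-treatment scans (weeks 2 and
5, W2/W5), extracts 130 radiomic features and their longitudinal relative
deviations (delta-radiomics), and relates both to treatment outcome
(progression-free and overall survival, local recurrence, distant
metastasis).

Because clinical FMISO-PET datasets of this kind are not shareable, the
package ships a synthetic longitudinal cohort generator with the same
statistical structure (SUV background near 1 g/mL, hypoxic cores above the
segmentation threshold, controllable size change, spatial drift, zone-level
heterogeneity, and outcomes linked to the hypoxia dynamics), so every stage
is exercised end-to-end without any download.

## Method

**Segmentation.** A voxel of the SUV volume inside the clinician-drawn boost
volume belongs to the HSV when

```
SUV(v) ≥ TBR × mean(SUV over background ROI),     TBR = 1.4
```

**Hypoxia dynamics.** With the baseline HSV as reference and a later HSV as
comparison, the relative volume difference is `ΔV = 100·(V_new − V_ref)/V_ref`
and patients are classed increasing (IH: ΔV ≥ 15 %), stable
(SH: −15 % < ΔV < 15 %) or decreasing hypoxia (DH: ΔV ≤ −15 %).  Spatial
overlap is summarised by DICE = 2|A∩B|/(|A|+|B|), sensitivity |A∩B|/|A| and
positive predictive value |A∩B|/|B|.  The **classification parameter**

```
CP = DICE (SH) | Sens. (IH) | PPV (DH)
```

equals 1 exactly when the contours overlap completely in the branch's sense,
regardless of the size change: geographically static hypoxia scores CP ≈ 1,
dynamic hypoxia CP ≈ 0.

**Delta-radiomics.** Inside the baseline HSV (transferred unchanged to the
co-registered later scans), 130 features are computed: 10 first-order/
histogram/shape features and 40 texture features (9 GLCM, 13 GLRLM, 13 GLSZM,
5 NGTDM) under three pre-processing variants — fixed-bin-width discretization
(W = 0.01 g/mL), a 3D wavelet band-pass filter (mixed sub-bands weighted 2:1),
and equal-probability quantization.  Longitudinal change per feature is
`Δ_RF = (RF_Wk − RF_W0)/|RF_W0|`.

**Outcome statistics.** Kaplan–Meier/log-rank on a median split of CP;
multivariate Cox hazard ratios with 95 % CI; Mann–Whitney U for binary
endpoints; single-feature logistic models with class-stratified
("imbalance-adjusted") bootstrap estimates of AUC and specificity;
Benjamini–Hochberg FDR correction per endpoint and time-point; a Spearman
redundancy filter (|r| > 0.8); and a predictor counts only when its corrected
significance holds at **both** W2 and W5.

## Worked example

```bash
fmisodyn run-all --n-patients 10 --seed 21 --out scratch/demo
```

or equivalently in Python:

```python
from fmisodyn import CohortSpec, RunConfig, analyze_cohort, generate_cohort_studies

studies = generate_cohort_studies(CohortSpec(n_patients=10, seed=21,
                                             grid_shape=(32, 32, 32),
                                             lesion_radius_mm=(6.0, 9.0),
                                             drift_mm=8.0))
out = analyze_cohort(studies, RunConfig(n_boot=50, auc_for="none"))
print(out["dynamics"][["patient_id", "pair", "size_class", "cp", "delta_v"]].head(4))
print({k: out["cp_survival_w2"][k] for k in ("n_high", "n_low", "logrank_p")})
```

prints

```
  patient_id   pair size_class        cp    delta_v
0       P000  W0-W2         DH  1.000000 -26.153846
1       P000  W0-W5         DH  1.000000 -47.692308
2       P001  W0-W2         IH  0.994975  31.658291
3       P001  W0-W5         IH  1.000000  42.211055
{'n_high': 4, 'n_low': 4, 'logrank_p': 0.9452330909498692}
```

Patient P000's hypoxic volume shrinks past the −15 % band at both follow-ups
(decreasing hypoxia) while staying exactly in place (CP = PPV = 1:
geographically static); P001's grows (increasing hypoxia) and still covers
the baseline contour almost completely (CP = Sens. ≈ 1).  The cohort-level
log-rank p-value compares progression-free survival between the CP-high
(geographically static) and CP-low (dynamic) halves of the classifiable
patients; at ten patients it is, as expected, not significant.

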