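# ramrad

Multimodal classification of prostate tissue sites from *in-situ* Raman
spectroscopy and co-located mpMRI radiomics.

During image-guided prostate interventions, an optical probe can acquire
Raman spectra directly at tissue sites of interest; the same sites can
be mapped back onto the preoperative multiparametric MRI (T2, ADC,
b2000) through the MRI↔TRUS registration transform, and quantitative
radiomics computed around them.  `ramrad` implements the full analysis
pipeline for classifying such sites by histologic grade:

* **Raman preprocessing** — cosmic-ray rejection across replicate
  acquisitions, averaging, iterative-polynomial autofluorescence
  removal, standard normal variate (SNV) normalization, Raman-shift
  axis assignment.  Fingerprint (1801 samples) and high-wavenumber
  (2801 samples) regions.
* **Radiomics** — 8 first-order + 8 GLCM features per MRI sequence
  (48 identifiers r1–r48) on a 5-mm spherical ROI at each co-located
  site, with anisotropic voxel grids handled in physical millimetres.
* **Feature selection** — a leakage-safe per-fold cascade: variance
  filter (var > 0.03), label-correlation filter (|r| ≥ 0.10), and an
  L1-penalized linear model capped at `max_nf` retained features.
* **Classification** — a cost-sensitive linear SVM
  (½‖w‖² + C·Σ cᵢ·hinge, cost matrix [[0,1],[2,0]] doubling the
  false-negative penalty) with Platt-calibrated posteriors, evaluated
  by leave-one-patient-out cross-validation (LOPOCV); pooled-posterior
  ROC with the operating point closest to the (0,1) corner.
* **Experiments** — feature-combination comparison
  ({FP, HW, Rad} and unions), a selection-cap sweep (2–18) with
  fold-frequency consensus features, and three prediction tasks
  (ISUP GG>1, GG≥1, and a high-grade task excluding tumor sites with
  <20% high-grade pattern).

No clinical data are distributed; a first-class synthetic-cohort
generator (`ramrad.synthetic_cohort`) emulates the study design —
18 patients, 47 sites, replicate spectra, MRI triplets, registration
transforms and histology — with configurable class-effect structure
(discriminative Raman bands, ADC lesion contrast, b2000 lesion
texture).  See `docs/methods.md` for the model and all defaults.

## Worked example

```python
import ramrad as rr

cohort = rr.generate_cohort(rr.SyntheticConfig(seed=1))
table, histology = rr.extract_features(cohort)      # 47 sites x 4650 features
labels = rr.assign_labels(histology, "gg_gt1")      # +1 iff ISUP GG > 1

cv = rr.lopocv(table.subset("FP+Rad"), labels, max_nf=10)
roc = rr.roc_summary(cv.posteriors, cv.labels)
print(f"AUC {roc.auc:.3f}  accuracy {roc.accuracy:.3f} "
      f"sensitivity {roc.sensitivity:.3f}  specificity {roc.specificity:.3f}")
print(f"mean selected features {cv.mean_n_features:.1f}  "
      f"support-vector ratio {cv.mean_sv_ratio:.2f}")
print(rr.consensus_features(cv, min_count=10))
```

prints (seed 1):

```
AUC 0.923  accuracy 0.915 sensitivity 0.952  specificity 0.885
mean selected features 9.8  support-vector ratio 0.08
r38           18
r17           17
FP_1772.00    16
FP_1341.11    16
FP_999.67     16
FP_988.78     13
r18           13
r29           11
dtype: int64
```

i.e. on this synthetic cohort the fused spectral+imaging model separates
clinically significant (GG>1) from other sites with AUC ≈ 0.92, selects
on average ~10 of the 4650 features per fold, and the consensus set
(features selected in more than 10 of the 18 folds) sits at the planted
discriminative Raman shifts (988–1000, 1341, 1772 cm⁻¹) and the planted
radiomics effects: r17/r18 (ADC Energy/Total energy, the lesion's ADC
drop) and r38 (b2000 SD, its texture heterogeneity).

A thin CLI wraps the same functions:

```bash
ramrad simulate --out cohort/ --seed 1
ramrad preprocess --in cohort/ --out processed/
ramrad radiomics --sites cohort/sites.tsv --volumes cohort/volumes \
       --transforms cohort/transforms --out rad.tsv
ramrad run --config run.yaml --out results/
```

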