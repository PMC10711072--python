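# nigraquant

Quantitative neuromelanin–iron MRI analysis of the substantia nigra (SN)
for Parkinson's disease (PD) research.

Dopaminergic neurons of the SN carry neuromelanin (hyperintense on
NM-sensitive T1 TSE MRI) and degenerate in PD with concomitant iron
accumulation (elevated susceptibility on QSM, in ppb).  `nigraquant`
implements the quantitative side of a case–control midbrain MRI protocol:

* **Feature extraction** — nine SN-mask parameters per subject across
  three modalities.  For the NM volume: mean signal, the *contrast range*
  (ratio of the 90th to the 10th percentile of in-mask signal), mask area,
  and the area surviving a high-signal threshold (background mean +
  *k*·SD, default *k* = 3).  For QSM: mean susceptibility χ, mask area,
  and the area of iron-poor voxels (χ < 70 ppb, a nigrosome surrogate).
  For SMWI (susceptibility map-weighted imaging, synthesised here from QSM
  and the SWI magnitude with weight w(χ)ᵖ, linear between 70 and 170 ppb,
  p = 4): mean signal, mask area, and low-signal area.  Areas pool both
  hemispheres over three analysis slices, in mm².
* **Composite marker** — the product

  ```
  composite = (NM₉₀ₜₕ / NM₁₀ₜₕ) × Size(NM high) × Size(QSM χ<70)
  ```

  All three factors fall in PD, so low values indicate disease.
* **Statistics** — pooled-SD effect sizes (Hedges' g, uncorrected
  variant), t/Kruskal–Wallis group tests, empirical ROC with DeLong 95%
  CIs and Youden operating points, Bonferroni-screened Spearman grids
  against clinical scores (UPDRS-I/II/III, MMSE, age), ICC(2,1), Fleiss'
  and Cohen's kappa.
* **Synthetic phantom** — since no imaging data are deposited, a
  calibrated generator emulates the study cohort (111 controls / 80
  patients): per-group feature and clinical marginals, a one-factor
  latent-severity copula reproducing the pooled feature–clinical rank
  correlations, and (optionally) full NIfTI volumes whose extracted
  features reproduce the generated truth exactly at zero noise, with a
  posterolateral→anteromedial NM depigmentation gradient.

## Worked example

```bash
nigraquant run --out out --seed 0
# composite AUC: 0.938
```

This simulates the calibrated 191-subject cohort, extracts/loads the nine
SN parameters, appends the composite marker, and writes the report bundle
(`features.csv`, `group_stats.csv`, `roc_summary.csv`, `roc_curves.csv`,
`correlations.csv`, `ratings.csv`, `summary.json`, `report.md`).  The
classification section of `report.md` from that exact run:

| feature           |   auc | cutoff  | sensitivity | specificity | accuracy |
|:------------------|------:|--------:|------------:|------------:|---------:|
| nm_contrast_range | 0.808 |   1.036 |       0.675 |       0.973 |    0.848 |
| nm_size_high      | 0.801 |  56.541 |       0.838 |       0.631 |    0.717 |
| qsm_size_low      | 0.885 |  38.540 |       0.700 |       0.892 |    0.812 |
| composite         | 0.938 | 1882.93 |       0.888 |       0.874 |    0.880 |

Reading: each single SN parameter separates patients from controls with
AUC ≈ 0.80–0.89; their product discriminates with AUC 0.94 at a Youden
cutoff of ≈ 1.9 × 10³ (subjects below the cutoff are classified PD).  The
run also reports simulated reader agreement (e.g. Cohen's κ = 0.915
between the two senior readers) and segmentation reliability
(ICC 0.886/0.951/0.972 for NM/QSM/SMWI measures).

Library use mirrors the CLI:

```python
from nigraquant import PhantomConfig, generate_feature_table
from nigraquant.composite import add_composite
from nigraquant.stats import group_summary_table

features, subjects = generate_feature_table(PhantomConfig(seed=0))
table3 = group_summary_table(add_composite(features),
                             ["qsm_chi_mean", "composite"])
```

Volume-level simulation (`--image-level`) writes per-subject NIfTI
volumes and masks; `nigraquant extract` recomputes the feature row from
them.

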