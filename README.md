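# tilquant

Quantification of tumour-infiltrating lymphocytes (TILs) from H&E-stained
slide images, and validation of lymphocyte density as a predictor of
pathological complete response (pCR) to neoadjuvant chemotherapy in breast
cancer.

Manual TIL scoring is poorly reproducible; a computational measurement is
objective and automatable. `tilquant` implements the full measurement and
analysis chain as a tested, reusable package:

1. **Synthetic slides and cohorts** — marked spatial point patterns of
   cancer / stromal / lymphocyte nuclei (Poisson or Thomas-clustered),
   rendered to H&E-like RGB rasters, plus trial cohorts whose pCR outcome
   follows a known logistic model. Every downstream stage can therefore be
   validated against ground truth without any external data.
2. **Nucleus segmentation** — colour deconvolution into haematoxylin/eosin
   channels, Otsu thresholding and a distance-transform watershed.
3. **Cell classification** — an RBF support-vector machine over seven
   morphology/intensity features assigns each nucleus to cancer, stromal
   or lymphocyte.
4. **Lymphocyte density** — the core statistic: for every detected
   lymphocyte the average Euclidean distance *R* to its *N* = 50 nearest
   lymphocytes is computed with a KD-tree, the local density estimated as

   *ρ* = *N* / (π *R*²),

   and the **median of *ρ* over all lymphocytes** is the slide's summary.
   Pre→post treatment change is `post − pre` (and `ln(post/pre)`).
5. **Association analyses** — univariable/multivariable logistic regression
   of pCR on density with odds ratios and Wald 95% CIs, Kruskal–Wallis
   tests for categorical covariates, ER-stratified Cox proportional-hazards
   models (Efron ties) for overall and disease-free survival, and
   trial-flow accounting with integer-percent reporting.

## Worked example

```python
import numpy as np
import tilquant as tq
from tilquant.classify import extract_features
from tilquant.segmentation import match_to_ground_truth

# a 0.5 x 0.5 mm synthetic slide with non-overlapping nuclei
cfg = tq.SyntheticConfig(field_width_um=500, field_height_um=500,
                         lymphocyte_intensity=300, cancer_intensity=300,
                         stromal_intensity=300, min_separation_um=18, seed=5)
slide = tq.simulate_slide(cfg)
objects, h = tq.segment_image(slide.image,
                              tq.SegmentationParams(microns_per_pixel=0.5))
print(f"detected {len(objects)} nuclei (ground truth: {slide.n_cells})")

# train the SVM on ground-truth labels, classify, and measure density
assigned, _, _ = match_to_ground_truth(
    objects, slide.cells[["x_um", "y_um"]].to_numpy(),
    slide.cells["radius_um"].to_numpy())
keep = assigned >= 0
feats = [extract_features(o, h, 0.5) for o, k in zip(objects, keep) if k]
labels = slide.cells["class"].to_numpy()[assigned[keep]]
clf = tq.train_classifier(feats, labels, seed=0)
pred = np.array(tq.classify_cells(clf, feats))
lymph_xy = np.array([o.centroid_um for o, k in zip(objects, keep) if k])[pred == "lymphocyte"]
s = tq.lymphocyte_density(lymph_xy, n_target=50, slide_id="demo")
print(f"lymphocytes: {s.n_lymphocytes}, k = {s.k_used}, "
      f"median density = {s.median_density:.2e} per um^2")

# a synthetic cohort and the multivariable pCR model
cohort = tq.simulate_cohort(tq.CohortConfig(n_patients=5000, seed=1))
fit = tq.fit_logistic(cohort, "pcr", ("pre_density", "grade", "er_status",
                                      "age", "node_status", "arm",
                                      "tumour_size_cat"))
print(tq.format_fit_table(fit).to_string(index=False))
```

prints

```
detected 161 nuclei (ground truth: 157)
lymphocytes: 55, k = 50, median density = 2.95e-04 per um^2
                 variable         categories odds_ratio     ci_95  p_value    n
Median lymphocyte density         Continuous       2.06 1.73–2.46 <0.00001 5000
                    Grade              1,2,3       3.03 2.63–3.49 <0.00001 5000
                ER status Negative, Positive       0.28 0.24–0.33 <0.00001 5000
                      Age         Continuous       0.98 0.97–0.99 <0.00001 5000
              Node status Negative, Positive       0.62 0.53–0.73 <0.00001 5000
             Chemotherapy   BEV+D FEC, D FEC       0.61 0.52–0.72 <0.00001 5000
              Tumour size    <=50 mm, >50 mm       0.91 0.73–1.14     0.41 5000
```

The segmentation recovers essentially all isolated nuclei; the measured
median density (about 3×10⁻⁴ lymphocytes/µm² at a simulated intensity of
300/mm²) is proportional to the true intensity; and the fitted odds ratio
for density (2.06, CI 1.73–2.46) recovers the cohort generator's configured
effect of 2.13 per density unit, with the covariate odds ratios likewise
matching their configured values.

A CLI wraps the same stages end to end:

```sh
tilquant run-all --config pipeline.toml --outdir out/ --seed 7
```

writing per-stage CSVs, the per-slide density summary, regression tables,
the cohort-flow accounting and a provenance manifest.

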