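# petcontour

Validation of single-value-threshold FDG-PET tumor contouring against
cross-sectional histology, with a digital phantom that emulates the
acquisition.

## The problem

PET-based radiotherapy planning needs a contour separating viable tumor
from necrosis and from surrounding normal tissue. The most common recipes
are single-value count thresholds: a percentage of the hottest tumor voxel
(C_max), a percentage of the peak 3×3×3-voxel mean containing that voxel
(C_peak), or a multiple of liver background in the PERCIST style
(k · C_liver_mean + 2 · C_liver_SD, liver statistics over a 6 mm sphere).
Which threshold actually covers the *viable* part of a heterogeneous tumor
is an empirical question, and answering it requires a ground truth richer
than the specimen's outer dimensions.

This package implements the validation framework used to answer that
question in a rodent model: each pathologist-style histology cut surface
is rigidly registered (via skin fiducial markers) to the PET slice at the
same cranial–caudal level; the fine histology label image (viable /
necrotic / normal / air at ~0.13 mm pixels) is resampled to the 1 mm PET
grid by plurality of overlapped area; and each gross tumor area (GTA, all
pixels at or above a threshold) is scored per pair of images, restricted
to the whole tumor area on histology (WTA_H):

* **sensitivity** = viable tumor pixels covered by the GTA / all viable pixels,
* **specificity** = necrotic pixels excluded by the GTA / all necrotic pixels,
* **GTA_OE/WTA_H** = GTA pixels spilling outside the tumor, relative to tumor area.

All single-value thresholds on one slice trace a single ROC curve per
image pair; its area is computed through the Gini coefficient
(G = 2·AUC − 1, evaluated with the trapezoidal identity). Across pairs,
means and robust SEs come from an intercept-only GEE with exchangeable
working correlation over sectioning positions (two cut surfaces per
position are correlated), and 95% CIs from a 10,000-sample cluster
bootstrap.

Because no real rat dataset ships with the package, a `phantom` module
generates the whole study synthetically — body, liver, a ≥3 cm tumor with
central and peripheral necrosis, sub-resolution viable cords, smooth
within-class uptake heterogeneity, skin fiducials, 2 mm FWHM PSF and
Poisson counting noise — together with exact ground truth for every
downstream stage.

## Worked example

```python
import petcontour as pc

model = pc.ContouringValidation.from_phantoms(pc.default_cohort(2, seed=7))
res = model.fit(n_boot=2000, seed=7)
print(res.summary())
```

prints (excerpt):

```
Single-value-threshold PET contouring vs histology
==========================================================
subjects: 2   image pairs: 14
mean per-pair AUC: 0.990  (95% CI 0.977-0.996)

Method I - % of C_max
----------------------------------------------------------
 param    sens        (95% CI)    spec   oe/wta
    15   1.000 (1.000-1.000)   0.530    0.156
    20   0.999 (0.997-1.000)   0.600    0.108
    25   0.998 (0.996-0.999)   0.669    0.062
    30   0.988 (0.985-0.990)   0.782    0.040
    35   0.960 (0.956-0.964)   0.884    0.031
```

Reading: at 30–35% of C_max the contour still covers ≥96% of the viable
tumor while spilling only 3–4% of the tumor's area into surrounding
tissue; pushing the threshold to 50% trades a large sensitivity loss for a
near-zero spill. `res.per_pair` holds the pixel-level counts per
(pair, method, threshold), `res.aggregate` the GEE/bootstrap table, and
`res.plot_roc_grid()` / `res.plot_threshold_curves()` the standard
figures.

The same pipeline runs from the shell:

```bash
petcontour phantom --seed 4 --out phantom_dir      # volume + sections + manifest
petcontour run --config run.yaml --out run_dir     # full validation run
petcontour report --run run_dir                    # tables + ROC/threshold figures
```

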