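# Methods

## Scope and model

The package quantifies how well single-value count thresholds on an
FDG-PET volume delineate the viable portion of a heterogeneous tumor,
using per-slice histology labels as ground truth. The unit of analysis is
a *registered pair*: one transverse PET slice (1 mm pixels) and one cut
surface's label image resampled to the same grid. The classification is
deliberately two-dimensional and per-surface — a PET slice is compared to
the cut face of the frozen block under the assumption that the viable /
necrotic distribution varies little within the slice thickness. No
volumetric overlap metric (Dice/Jaccard) is computed; the design question
is pixelwise coverage of viable tissue, spill into necrosis, and spill
out of the tumor.

### Thresholds

* `cmax_pct`: p% of C_max, the hottest voxel in a *tumor search region*
  (the true tumor mask dilated by 3 mm by default). The search region is
  an explicit input because any C_max definition needs a bound on where
  "tumor" may be; making it explicit keeps that choice out of the
  algorithm. Default grid p = 15, 20, …, 90.
* `cpeak_pct`: p% of C_peak, the highest 27-voxel mean over all 3×3×3
  cubes that (a) contain a voxel attaining C_max and (b) lie fully inside
  the volume. If several voxels tie at C_max, all are examined and the
  global maximum taken — deterministic and order-independent. Cubes may
  extend outside the search region (they are image neighborhoods, not
  tumor subsets); partially out-of-volume cubes are excluded rather than
  averaged over fewer voxels.
* `liver_multiple`: k · C_liver_mean + 2 · C_liver_SD for
  k ∈ {1.5, 3, 4, 5, 6, 7}, liver statistics over the voxels whose
  centers fall in a 6 mm diameter sphere at a user-supplied liver
  location. The 2·SD term is applied at every k (k = 1.5 is the
  PERCIST-style background threshold). SD is the sample standard
  deviation (ddof = 1).

A gross tumor area is `pixel >= threshold` (inclusive), evaluated over
the whole slice: spill into normal tissue and air is exactly what the
overestimation ratio measures, so the GTA must be allowed to reach it.
Nesting (larger threshold ⊆ smaller threshold) follows from inclusivity
and is asserted in tests.

### Classification and ROC

Within a pair, the test population is WTA_H = viable ∪ necrotic pixels of
the resampled histology; normal tissue and air are excluded. Sensitivity
and specificity are therefore functions of the GTA's intersection with
WTA_H only; pixels outside WTA_H enter only through
GTA_OE/WTA_H = |GTA \ WTA_H| / |WTA_H| (which may exceed 1). Pairs
missing a class (e.g. a section plane that misses the necrosis) have the
corresponding metric undefined; they are flagged and excluded from that
metric's aggregation rather than imputed.

All thresholds of all three methods on one slice are single values of the
same image, so they trace one ROC curve per pair. Points are pooled over
methods, deduplicated by absolute counts, anchored at (0,0) and (1,1) and
sorted by (1 − specificity, sensitivity) — the conventional ROC
orientation. AUC is computed through the Gini coefficient with the
trapezoidal identity G = Σ Δx (y_k + y_{k−1}) − 1, AUC = (G+1)/2, which
is algebraically the trapezoidal area; the dual route (Gini identity vs
independent trapezoid integration) is kept as a test, not collapsed.

### Aggregation

Two cut surfaces per sectioning position are correlated, so surfaces are
clustered by position. The marginal mean and a robust (sandwich) SE come
from an intercept-only GEE with identity link and exchangeable working
correlation (richer structures are unidentifiable with clusters of
size ≤ 2); statsmodels provides the estimator, and closed-form oracles
(singleton-cluster sandwich SE, balanced-cluster point estimate) pin its
behavior in tests. A constant response makes the GEE scale zero, which
the library cannot iterate on; that degenerate case returns the constant
with SE 0 directly. The default 95% interval is the percentile CI from a
cluster bootstrap (resample positions with replacement, 10,000 draws,
recompute the pooled mean); the GEE SE is reported alongside. Whether
robust or model-based SEs are "the" right companion is under-determined
in this design; robust is the default because it stays valid when the
working correlation is wrong.

## The phantom

The generator emulates a rodent acquisition: a 128×128×120 grid of 1 mm
voxels; an elliptic-cylinder body; an ellipsoidal liver; a ≥ 3 cm
dorsal tumor bulging out of the body; central plus near-surface
peripheral necrosis; two sub-resolution viable cords (r ≈ 0.5 / 0.75 mm)
traversing the central necrosis; two skin fiducial point sources at each
of 3–5 transverse sectioning lines; isotropic Gaussian PSF of 2 mm FWHM;
Poisson counting noise. Each sectioning position yields a rostral and a
caudal surface, cut at adjacent slice planes and digitized at 0.125 mm
pixels.

Intensity model, in order: class means painted on the label volume →
multiplicative log-normal within-class field → fiducial point sources →
PSF → noise. The fiducials are added *before* the PSF because they are
physical radiotracer sources imaged by the same scanner; their activities
vary log-normally (CV 0.3) marker to marker, as hand-spotted droplets do.

### Parameter defaults and rationale

| parameter | default | why |
|---|---|---|
| uptake, viable | 300 counts/voxel | strongly FDG-avid tumor; count level at which Poisson noise (CV ≈ 6%) is visible but not dominant |
| uptake, necrotic | 30 | cold necrosis, 10:1 tumor-to-necrosis contrast |
| uptake, normal / liver | 15 / 25 | 6 × liver mean + 2 SD then lands near 30–35% of C_max and the 1.5× PERCIST threshold near 15%, matching where those thresholds operate in vivo |
| within-class CV | 0.2, correlation length 5 mm | FDG heterogeneity is perfusion-driven and spatially graded; an independent per-voxel field would be annihilated by the 2 mm PSF. The smooth log-normal field survives blurring and gives C_max ≈ 1.5–2× the typical viable value, the regime in which 50% thresholds lose substantial viable tumor while ≤ 35% thresholds do not |
| PSF FWHM | 2 mm | small-animal scanner resolution |
| fiducial activity | 10,000 counts (CV 0.3) | markers clearly brighter than tumor, as in fused images |
| histology pixel | 0.125 mm | 8× finer than PET, so block-downsampling is exact-integer; 0.127 mm (200 DPI) is still supported through the general area-overlap resampler |

The thin viable structures (the sub-voxel shell over the peripheral lobe
and the cords through the core) are what give the phantom partial-volume
behavior at low thresholds: their blurred values fall far below the
plateau, so sensitivity keeps responding across the whole 15–90% grid
instead of saturating at 1.

### Truth construction and numerical choices

* Labels use codes 0 = air, 1 = normal, 2 = necrotic, 3 = viable. Voxel
  and pixel centers sit at (i + 0.5)·pitch; indices are 0-based; PET
  slice 0 is the most cranial. One stated convention everywhere.
* The coarse label volume is voxel-center rasterized, except at
  sectioning planes where the slice is the area-plurality downsample of
  the fine surface — this makes "fine sections reproduce coarse truth
  under exact block-downsampling" an identity, not an approximation.
* All plurality votes (phantom downsampling and registration resampling)
  share one tie rule: viable > necrotic > normal > air. Viable-first is
  the conservative reading — ambiguous tissue counts as tumor.
* Registration is a least-squares Procrustes fit (rotation + translation;
  optional similarity scale behind a flag, off by default since the
  original alignment procedure is not documented to have scaled).
  Axis-aligned transforms use exact separable rectangle-overlap areas;
  rotated transforms accumulate fine-pixel areas at transformed centers
  (error ≤ half a fine pixel, negligible at 8× resolution ratio).
* All randomness flows from one seed through named `SeedSequence`
  substreams (field, noise, fiducials); identical config ⇒ bit-identical
  phantom, and identical run config ⇒ byte-identical CSVs.

### What the phantom does not emulate

Tomographic reconstruction (the row-action ML algorithm and its
correlated noise texture), attenuation/scatter/decay corrections,
respiratory motion, tissue shrinkage during freezing/sectioning,
registration error beyond what fiducial noise induces, and anatomy beyond
body + liver + tumor. Passing tests therefore demonstrate that the
*analysis machinery* is correct and that its qualitative conclusions are
stable over a realistic intensity model — not that the specific printed
sensitivities of any in vivo study are recovered, since those depend on
biology (true uptake distributions) the phantom only parametrizes.

## Problem sizes

Unit tests run on 64×64×48 phantoms with the same anatomical structure.
The cohort-level checks and `scripts/acceptance.py` use the shipped
default: 8 phantoms at full 128×128×120 resolution, 3–5 sectioning
positions each (66 registered pairs at the default seeds), 38 thresholds
per animal, 10,000 bootstrap draws in the script (1,000 in the test
suite's cohort checks). The qualitative-pattern test also reruns the
cohort with viable/necrotic uptake scaled by 0.75 and 1.25 to confirm the
conclusions are not an artifact of one uptake setting.

## Known limitations

* With only two fiducials per plane the rigid fit is exactly determined
  up to reflection; noise in marker placement translates directly into
  registration error (the phantom's markers are noise-free by default).
* GEE with ~25–35 clusters is asymptotic; no small-sample DF correction
  is applied to the sandwich SE (the bootstrap CI is the primary
  interval).
* The per-pair ROC uses the finite threshold grid, not all possible
  cutpoints, exactly as the validation design prescribes; AUC is thus a
  grid-trapezoid quantity.
* Specificity is undefined for sections without necrosis; such pairs are
  excluded from that metric, which can shift its aggregate composition
  relative to sensitivity's.
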