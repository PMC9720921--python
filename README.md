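# hiikit

Quantifying the shape irregularity of intracerebral hematomas on CT, and
evaluating that irregularity as a predictor of hematoma expansion.

Irregularly shaped hematomas are a known warning sign for early hematoma
expansion after spontaneous intracerebral hemorrhage (ICH), but "irregular"
is usually judged by eye. The **hematoma irregularity index (HII)** turns it
into a number by comparing two equivalent-sphere radii computed from the
hematoma's surface area *S* (mm²) and volume *V* (mm³):

```
R1 = √(S/π) / 2          radius of the sphere with surface area S
R2 = (3V / 4π)^(1/3)     radius of the sphere with volume V
HII = 100 · R1 / R2
```

Because the sphere minimizes surface area for a given volume (the
isoperimetric inequality, S³ ≥ 36πV²), HII = 100 exactly for a ball and
grows with lobulation, elongation or fragmentation. The index is
dimensionless and scale-invariant.

`hiikit` implements the full chain from CT to report:

- **volume_io** — NIfTI and DICOM-series readers with mandatory HU rescale
  and physical voxel spacing; mask I/O.
- **segmentation** — 40–100 HU window thresholding (inclusive, configurable),
  26-connected component selection (largest or seeded), optional exclusion
  masks for intraventricular blood.
- **geometry** — marching-cubes surface extraction with Gaussian
  anti-aliasing of the binary field, mesh surface area, divergence-theorem
  volume, voxel-count volume, optional Taubin smoothing.
- **hii** — shape metrics, the HII formula, and the hematoma-expansion rule
  (growth > 33% relative or > 12.5 mL absolute, strict).
- **phantoms** — synthetic CT generators (spheres, ellipsoids, lobulated
  blobs, thick-slice resampling) with analytic or brute-force ground truth.
- **cohort_stats** — the evaluation statistics: normality-gated baseline
  comparisons, crude/adjusted logistic regression with Wald CIs,
  Hosmer–Lemeshow, ROC with DeLong CI and Youden cutoff, one-way ICC(1,1),
  plus a seeded cohort simulator.
- **cli** — a thin `hii` command (`case`, `cohort`, `fixtures`, `simulate`).

## Worked example

```python
from hiikit import make_sphere_phantom, make_lobulated_phantom, \
    segment_hematoma, compute_hii_for_mask

for label, (volume, _) in {
    "sphere r=15 mm": make_sphere_phantom(15.0, 0.5),
    "lobulated (5 lobes)": make_lobulated_phantom(
        n_lobes=5, lobe_radius_range_mm=(5.0, 8.0), center_spread_mm=8.0,
        spacing_mm=0.5, seed=7, compute_truth=False),
}.items():
    m = compute_hii_for_mask(segment_hematoma(volume))
    print(f"{label:>22}:  S = {m.surface_area_mm2:8.1f} mm²   "
          f"V = {m.volume_mL:5.1f} mL   HII = {m.hii:.1f}")
```

prints

```
        sphere r=15 mm:  S =   2821.2 mm²   V =  14.1 mL   HII = 100.1
   lobulated (5 lobes):  S =   1774.4 mm²   V =   5.8 mL   HII = 106.4
```

The ball reads ~100 (the theoretical minimum); the lobulated blob carries
surplus surface for its volume, and the index quantifies exactly that
surplus. On a simulated 93-patient cohort (`examples/03_cohort_analysis.py`)
the chain reports, among other things,

```
hii                      1.209 (1.119-1.305)      0.0000     # crude OR per index point
ROC (HII): AUC=0.877 (95% CI 0.805-0.948), Youden cutoff=120.4
```

i.e. each HII point multiplies the odds of expansion by ~1.21, and the
cutoff that best separates expanders from non-expanders sits near 120.

More narrative walk-throughs live in `examples/` (phantom measurement, the
expansion rule at its boundaries, the cohort chain, rater reliability). The
same functionality is scriptable from the shell:

```
hii fixtures --out phantoms/ --seed 0
hii case --input phantoms/sphere_r20_sp0.5.nii.gz --out report.json
hii simulate --n 93 --seed 1 --out cohort.csv
hii cohort --table cohort.csv --out cohort_report.json
```

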