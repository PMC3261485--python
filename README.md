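# corddti

Spinal-cord diffusion tensor imaging (DTI) analysis with a synthetic
cord-phantom generator, for characterizing fractional anisotropy (FA) and
mean diffusivity (MD) along the cervical, thoracic and lumbar cord and
comparing them between regions.

## The problem

DTI of the spinal cord is used to detect and monitor white-matter damage,
but interpreting patient scans requires healthy reference values per cord
region — and an analysis that avoids operator-dependent manual tissue
segmentation. This package implements a feature-space segmentation
pipeline for whole-cord ROIs:

1. **Tensor fit** — per voxel, the diffusion tensor `D` is estimated by
   linear least squares on log-signals, `ln S_i = ln S0 − b_i gᵢᵀ D gᵢ`,
   from 20 diffusion directions at b = 700 s/mm² plus one b = 0 volume.
   From the eigenvalues λ₁ ≥ λ₂ ≥ λ₃ (in 10⁻³ mm²/s):

   MD = (λ₁ + λ₂ + λ₃) / 3
   FA = √( 3/2 · Σᵢ (λᵢ − λ̄)² / Σᵢ λᵢ² )

2. **Tissue clustering** — cord voxels form a continuum in the (MD, FA)
   plane; k-means (k = 3) partitions them into white matter (high FA, low
   MD), grey matter (lower FA) and CSF (high MD, near isotropic). Each
   cluster is then *restricted* to voxels within 20% of the distance from
   its centroid to the nearest other centroid, discarding the in-between
   voxels most affected by partial-volume mixing, and the retained labels
   are mapped back onto the image for anatomical plausibility checks.

3. **Regional statistics** — per-subject tissue centroids are summarized
   per region (mean ± SD), compared between regions with Welch's unequal-
   variance t-test (Bonferroni-corrected), and regional WM FA is regressed
   on the grey-matter cross-sectional area percentage (18% cervical,
   13.2% thoracic, 36.3% lumbar).

Because no scan data are distributed, the package includes a first-class
**phantom generator**: an elliptical cord with a grey-matter butterfly,
CSF rim, partial-volume mixing by in-plane supersampling, per-tissue
T2-weighted b0 signals, the interleaved 28-slice acquisition geometry and
Rician noise. Every downstream stage is tested against this known ground
truth. See `docs/methods.md` for the model details and its limitations.

## Worked example

```python
import numpy as np
import corddti as c

scheme = c.make_gradient_scheme(20, 700.0)           # 21 volumes
phantom = c.build_phantom("cervical", (64, 64, 28), seed=1)
print(f"GM area fraction: {phantom.gm_area_fraction:.1f}%")

dwi = c.simulate_dwi(phantom, scheme, snr=20.0, seed=1)
maps = c.fit_scalar_maps(dwi)                        # FA, MD per ROI voxel
model = c.segment_tissues(maps, seed=1)              # k-means + restriction
for tissue, (md, fa, n) in model.tissue_centroids().items():
    print(f"{tissue}: MD {md:.2f}  FA {fa:.2f}  ({n} voxels)")
```

Output:

```
GM area fraction: 18.5%
WM: MD 1.04  FA 0.67  (575 voxels)
CSF: MD 2.93  FA 0.07  (777 voxels)
GM: MD 1.66  FA 0.46  (156 voxels)
```

The retained white-matter centroid sits near the generator's WM values
(MD 0.97 × 10⁻³ mm²/s, FA 0.70); grey matter and CSF centroids are pulled
slightly toward the partial-volume continuum, exactly as in real cord
data. A full multi-subject, three-region study with summary tables and
between-region comparisons:

```sh
corddti run --subjects 9 --seed 1 --out results/study
```

There is also a CLI for the individual stages (`corddti simulate`,
`fit`, `cluster`, `report`), reading and writing NIfTI volumes and
FSL-style `bval`/`bvec` text files.

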