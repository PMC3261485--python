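# Methods

This note documents the models, parameter choices and numerical decisions
behind `corddti`, and states what the synthetic validation can and cannot
show about real spinal-cord data.

## Cord phantom

### Geometry

Each region is an elliptical cord cross-section, constant along the slice
axis up to a smooth ±2% per-slice caliber modulation (seeded, so phantoms
are reproducible and subjects differ anatomically). Semi-axes
(transverse × antero-posterior, mm): cervical 6.0 × 4.2, thoracic
4.8 × 4.0, lumbar 5.5 × 4.5 — approximately the adult cord at C4–C7,
T3–T8 and the lumbosacral enlargement. A 1.2 mm CSF rim surrounds the
cord; the analysis ROI is the whole canal (cord + rim), emulating a
manually drawn whole-cord ROI generous enough that near-pure CSF voxels
enter the analysis (the reported CSF cluster diffusivities of
≈ 3 × 10⁻³ mm²/s in healthy-cord studies imply such voxels are present).

The grey matter is a butterfly ("H") in cord-normalized coordinates with
a **fixed skeleton**: four horn lobes whose tips reach 62% of the cord
radius, joined by a commissural bridge. In real cords the H spans most of
the cross-section at every level; what varies regionally is how *thick*
its arms are. The generator therefore solves (by bisection on a
supersampled unit-disk grid, cached) for the **arm thickness** that
realizes the requested grey-matter area fraction — 18% cervical, 13.2%
thoracic, 36.3% lumbar by default. Ventral lobes are 1.7× thicker than
dorsal ones (bulky motor-neuron pools versus slender dorsal horns), which
is what gives the cervical and lumbar phantoms a population of
grey-matter-dominated voxels at 1.2 mm resolution, as real enlargement-
level cords have; thoracic horns remain sub-voxel, as in reality.

Partial-volume fractions are computed by 4 × 4 in-plane supersampling of
the continuous region functions and renormalized to a partition of unity
inside the canal. There is no through-plane mixing: the cord is treated
as straight within each 3 mm slice.

### Tissue model and signal

Each tissue is an axially symmetric tensor (λ₂ = λ₃, principal axis along
the cord) constructed from target (MD, FA): WM (0.97, 0.70), GM
(1.80, 0.44), CSF (3.00, 0.05), all in 10⁻³ mm²/s. These defaults are
healthy-cord cluster-centroid values; note the GM pair already reflects
partial-volume-contaminated in vivo clusters rather than pure grey-matter
tissue, which keeps the phantom's cluster structure comparable to
published centroids.

The noise-free signal mixes **signals, not tensors**:

    S_i = S0 · Σ_t f_t · w_t · exp(−b_i gᵢᵀ D_t gᵢ)

so a mixed voxel decays multi-exponentially, producing the intermediate
FA/MD continuum seen in real cord data. `w_t` is the tissue's relative
b = 0 signal. A spin-echo EPI cord protocol runs at TE ≈ 100 ms, so the
b0 is strongly T2-weighted; combining proton density (WM ≈ 0.65,
GM ≈ 0.8, CSF ≈ 1.0) with T2 decay (cord tissue ≈ 70–75 ms, CSF ≈ 2 s)
gives the defaults w = (1.0, 1.35, 6.0). This term matters: with a flat
b0, cord-edge WM/CSF mixtures land mid-feature-space on top of grey
matter; with the realistic bright-CSF b0 they are signal-dominated by CSF
and cluster near the CSF mode, reproducing the qualitative cluster
anatomy of real data (setting every `w_t = 1` recovers the flat-b0
model, and the unit tests of the mixing formula use it).

Noise is Rician — the magnitude of two independent Gaussian-perturbed
channels — with channel σ = S0 / SNR, SNR referenced to the white-matter
b = 0 signal. Default SNR 20, S0 = 1000 (arbitrary units; any positive
constant, recorded in output metadata).

### Acquisition geometry

The gradient scheme is a deterministic Fibonacci-lattice hemisphere
sampling (n = 20 at b = 700 s/mm², one b = 0), verified rank-6 for the
tensor design. The interleaved slice planner reproduces 7 series of 4
slices (3 mm thick, 18 mm gaps) shifted by one slice thickness, yielding
28 contiguous slices per region; slice centers live on a 1-D mm axis with
0 at the first slice of series 1.

## Tensor fitting

Ordinary least squares on log-signals, with ln S0 estimated jointly as a
seventh unknown (robust to b0 noise); a weighted variant (weights = S²,
the first-order variance approximation for log-transformed magnitude
data) is available but off by default. Nonpositive signals are clamped to
half the smallest positive masked signal and the voxel flagged; voxels
with non-finite estimates or any nonpositive eigenvalue are flagged too,
and flagged voxels are excluded from the scalar maps and clustering. FA
is computed on raw eigenvalues and clipped to [0, 1] only when negative
eigenvalues were present. All diffusivities are carried in 10⁻³ mm²/s so
MD and FA are both order one — this is also the feature scaling used for
clustering.

## Clustering and the partial-volume restriction

k-means (k = 3, k-means++ initialization, 10 restarts, fixed seed) on raw
(MD, FA) coordinates; a z-scored variant was evaluated and is strictly
worse on the phantom (it stretches the partial-volume band), so raw
coordinates are the only supported path. The restriction retains, per
cluster, voxels within `0.2 ×` the distance from the cluster's centroid
to the nearest *other* centroid ("nearest adjacent centroid" read as a
cluster-level quantity). Tissue identities come from centroid geometry
alone — CSF has the highest MD, then WM the higher FA of the remaining
two; cluster-size expectations (WM largest, CSF smallest) are demoted to
warnings because on a whole-canal ROI the CSF cluster can rival WM in
size. The density surface (50 × 50 histogram over [0, max MD] × [0, 1])
is diagnostic output only.

### Retention behaviour (known limitation)

On this sharp-boundary phantom at SNR 20, the pure-tissue clusters retain
60–90% of their voxels under the restriction, but the middle (grey
matter) cluster retains only ≈ 40–65% depending on region and seed
(minimum ≈ 41% over regions × seeds 1–3; the acceptance script computes
this number). The cause is structural, not noise: the middle cluster
inevitably inherits the WM–GM partial-volume band, whose members lie along
a ribbon in feature space mostly beyond 20% of the inter-centroid
distance, and noise-free retention is no better. In vivo reports of > 50%
retention in every cluster therefore likely reflect feature clouds whose
middle cluster is blob-dominated (physiological variability, residual
motion, smoother effective resolution) rather than ribbon-dominated. A
phantom with boundary blurring or within-tissue heterogeneity would raise
the middle cluster's mode mass; both are out of scope here and would make
ground-truth bookkeeping less crisp.

## Regional statistics

The unit of analysis is one (MD, FA) centroid per tissue per subject per
region — the mean over the subject's retained voxels — because voxels
within a subject are not independent. Between-region comparisons use
Welch's two-sample t-test (the defensible reading of an "unequal sample
sizes and unequal variance" t-test) with Welch–Satterthwaite degrees of
freedom; subjects missing a tissue are dropped from that comparison,
which is how unequal sample sizes arise. Bonferroni correction defaults
to m = 18 (3 region pairs × 3 tissues × 2 metrics), configurable;
significance is reported both at uncorrected P < 0.001 and corrected
P < 0.05. The FA-versus-grey-matter regression is ordinary least squares
with R² = 1 − SSres/SStot.

A calibration experiment (in the test suite) runs the full pipeline on
identically distributed cohorts — 9 subjects per group, 200 replicates at
a reduced 32 × 32 × 8 grid, each subject with their own anatomy seed and
noise realization — and checks that the raw α = 0.05 rejection rate stays
within its binomial 95% bounds. Subject-level anatomy variation matters
here: with a single shared phantom the subject statistics are slightly
heavy-tailed and the test becomes conservative.

## Problem sizes and determinism

Default study grids are 64 × 64 × 28 voxels at 1.2 × 1.2 × 3 mm; the
calibration experiment uses 32 × 32 × 8. Every stochastic step (phantom
caliber, Rician noise, k-means initialization) takes an explicit seed,
and per-subject seeds are derived arithmetically from the study seed, so
repeat runs are byte-identical. Pipeline outputs carry a configuration
hash and all seeds in JSON sidecars.

## Other limitations

No cardiac-motion or CSF-pulsation simulation (the emulated protocol is
cardiac-gated), no EPI distortion, eddy currents, point-spread blurring
or multi-coil reconstruction; no eigenvector or tractography output; no
spatial priors in the segmentation (whole-region pooling, as the
feature-space method intends). Passing tests demonstrate correctness of
the estimators and the segmentation logic on data from this generative
model — they do not certify accuracy on scanner data with motion,
distortion and coil inhomogeneity.
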