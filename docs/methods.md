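# Methods

`rpemosaic` quantifies the retinal pigment epithelium (RPE) mosaic in
dark-field adaptive-optics trans-scleral flood-illumination (AO-TFI)
images: per-image quality masking, Voronoi tessellation morphometrics,
segmentation of intracellular hypo-reflective areas, landmark registration
onto the infrared-fundus frame, multimodal grading bookkeeping, and
Welch-corrected group comparisons. Because clinical AO-TFI images are not
publicly available, every stage is validated against a seeded synthetic
mosaic generator whose ground truth (cell centers, cell polygons, blob
contours, degraded regions) is known exactly. This note documents the
models, the defaults and why, the numerical choices, and what the
synthetic validation does and does not establish.

## Synthetic mosaic model

The healthy RPE appears in AO-TFI as a honeycomb of polygonal cells with
hypo-reflective interiors and bright edges over a mixed-reflectance
background. The generator reproduces exactly that contrast structure and
nothing more:

* **Cell positions.** A hexagonal lattice with spacing *s* (default
  14 µm, a typical perifoveal RPE center-to-center distance), each site
  displaced by an isotropic Gaussian with SD `disorder × s`. `disorder=0`
  is a perfect lattice (every interior Voronoi cell a regular hexagon of
  area (√3/2)s²; 6 neighbors each), and raising it increases
  neighbor-count dispersion monotonically — the lattice-level analogue of
  the epithelial disorganization reported in disease.
* **Rendering.** Bright ridges (default 0.85) along the Voronoi edges of
  the generated centers, darker interiors (0.40), per-cell hypo-reflective
  blobs drawn at 0.3 × interior brightness, a smooth low-frequency
  background field (amplitude `background_mix`, default 0.06) emulating
  the mixed reflectance of adjacent layers, and additive Gaussian noise
  (`noise_sd`, default 0.02). All intensities live in [0, 1] before
  16-bit quantization on export.
* **Blobs.** Intracellular hypo-reflective areas (pigment-granule
  clusters) are discs of radius `blob_radius` (default 2.2 µm) whose
  radial profile is perturbed by a band-limited harmonic series (orders
  2–6) with peak relative amplitude `blob_roughness`; roughness 0 gives
  digitized discs (solidity ≈ 1, circularity ≈ 1). Blob centers are
  rejection-sampled inside the cell polygon eroded by the maximal blob
  radius, with a minimum separation that prevents two blobs from merging;
  consequently every drawn contour lies strictly inside its parent cell
  and each connected dark component corresponds to one ground-truth blob.
  Raising roughness lowers mean solidity and circularity and raises the
  dispersion of solidity and perimeter — the direction of the reported
  disease effect.
* **Degraded areas.** `lowq_fraction > 0` replaces a vertical band of
  that area fraction with a strongly blurred, contrast-flattened (15%)
  version of itself, feathered over 8 px on the sharp side because an
  abrupt defocus edge would itself be sharp structure. The band emulates
  the blurred areas that quality masking must remove in practice (e.g.
  under serous detachments).
* **Cohorts.** `generate_cohort` draws two groups of eyes; the disease
  group overrides `disorder` (0.08 → 0.20) and `blob_roughness`
  (0.10 → 0.30). Eye metadata: age ~ N(40, 10) y, axial length
  AL ~ N(23.5, 0.8) mm, refraction spherical equivalent
  RE ~ N(−0.5, 1.5) D truncated to the inclusion window (−6, +5) D.
  Randomness derives from one root `numpy.random.SeedSequence`, with one
  spawned child per image, so cohorts are bit-reproducible and images are
  independent.

What the generator deliberately does **not** model: trans-scleral
dark-field image formation, the photoreceptor layer, vessels, optical
PSFs, spatially correlated noise, eye-motion artifacts. Passing the
synthetic validation therefore shows that the *operators* are correct on
images with the documented contrast structure, not that their outputs on
clinical data would match a reference reading of those images.

## Quality masking

The study's learned quality scorer is proprietary; this package uses a
deterministic spectral proxy. Per non-overlapping tile (default 64 px),

    score = clip( RMS(fine band) / RMS(cell band) / 1.25, 0, 1 )

where the fine band is a difference-of-Gaussians at the ridge scale
(σ = 0.5 and 1.2 px) and the cell band a DoG bracketing the expected cell
frequency (σ = spacing/6 and spacing/2). A sharp honeycomb carries strong
ridge harmonics (ratio > 1 → score 1); defocus drains the fine band far
faster than the cell band, collapsing the score. The ratio form makes the
score exactly invariant to global intensity scaling; constant tiles score
0. The calibration constant 1.25 was fixed once so that the sharp
synthetic fixture scores > 0.8 and a heavily blurred copy (Gaussian
σ = 4 px) scores < 0.2, with about 6× separation between those regimes.
A per-tile contrast normalization (band RMS / tile SD) was rejected: blur
shrinks total tile contrast faster than band energy, so blurred tiles
would score *higher*. Known limitation: pure noise has fine-band energy
and can score sharp — the proxy ranks blur/defocus, not SNR.

Masking thresholds the per-tile score (default 0.5; the reference
workflow's threshold is unpublished) and an image is included only if its non-masked portion
exceeds 5% strictly *and* at least `min_cells` (default 10) cells were
detected.

## Tessellation

Cell centers are local minima of a cell-scale DoG (σ = 0.25 s and 1.0 s),
picked by non-maximum suppression with radius 0.45 × spacing and
restricted to the analyzable mask. The radius was chosen on ground truth:
0.6 × spacing merges adjacent jittered cells (≈ 88% recall) whereas
0.45 × gives ≥ 99% recall at < 1% spurious detections on the default
fixture. Detection assumes dark interiors; inverted-contrast input
returns meaningless points but does not fail.

The Voronoi partition of the detected centers is clipped to the field
rectangle (distant ghost sites bound all regions; only boundary cells pay
for exact polygon clipping). Two cells are neighbors when they share a
clipped Voronoi edge longer than 1 px; cocircular degeneracies are broken
by a deterministic 2×10⁻⁶ px jitter. Cells touching the image boundary or
owning a masked pixel are border-filtered: dropped from the statistics
and their pixels added to the masked set, so the density denominator is
the post-filter unmasked area. Because the flag set is defined against
the quality mask, the filter is idempotent.

Per-cell metrics: shoelace area (µm²), polygon perimeter (µm), equivalent
diameter 2√(A/π), and neighbor count. The neighbor count of a kept cell
is its degree in the **full** detected graph — border-filtered cells
still count as neighbors. Counting only kept cells would depress the
outermost kept cells' counts (their dropped neighbors would vanish),
which is precisely the clipping bias the border filter exists to remove;
with the full-graph convention a perfect lattice yields exactly 6
neighbors, SD 0. Per-image summaries are means and sample SDs (ddof = 1),
density in cells/mm², and the non-masked portion. Coordinates: origin at
the top-left pixel center, x rightward, y downward; µm = px × pixel size.

## Hypo-reflective segmentation

Pixels below the locally adaptive (non-uniform) threshold
`local_mean − k · local_SD − 10⁻⁶` (uniform window, default 96 px;
k = 0.8; the 10⁻⁶ absorbs filter rounding on structureless areas) and
inside the mask are labeled; components outside [4 px, one cell area] are
discarded. Contours are traced at the 0.5 iso-level and regularized with
a 3-point closed moving average: the raw marching-squares staircase
biases perimeters ≈ 5% high, which would depress every circularity (a
digitized disc would measure ≈ 0.90 instead of ≈ 0.98).

Descriptors: solidity = area / convex-hull area; circularity = 4πA/P²,
the standard isoperimetric form — the region's area relative to that of
the circle with the same perimeter, the only convention bounded by 1;
this choice is recorded in the output metadata. Degenerate
zero-area contours are dropped and counted. Regions are not assigned to
parent cells for the statistics (image-level aggregates only); a
cell-assignment debug output exists. On the default fixture ≥ 90% of
ground-truth blobs are recovered with IoU ≥ 0.7.

## Registration and stitching

Physical scaling uses the eye-specific pixel-size equation
`a·RE + b·(AL − 23.5) + c` (µm/px). The device calibration constants are
not public: the defaults a = 0.02, b = 0.5, c = 0.7 are placeholders with
plausible magnitudes and must be configured for real data.

Landmark registration fits a similarity transform (one scale, rotation,
translation) to ≥ 4 point pairs by the least-squares Umeyama/Procrustes
solution, reporting per-landmark residual RMS; landmark sets with a
principal-axis spread ratio below 0.05 (nearly collinear vessel picks)
are rejected as degenerate. Warping exports the montage both at the IR
fundus pixel size (20 µm/px default) and at native resolution, with
bilinear interpolation and validity masks; out-of-field pixels are 0.

Stitching is translation-only: each tile is refined against the
already-placed tile with the largest nominal overlap by phase
correlation, falling back to the nominal offset with a warning when
overlaps are under 16 px; overlaps are blended by distance-to-edge
feathering. This replaces general mosaicking software deliberately — the
montage geometry is a solved problem and not the subject of this package.

## Grading and tabulation

Grades are a deterministic function of the per-image modality flags:
NSD → 1; all normal → 0; BAF+IR+AO-TFI abnormal → 2; IR+AO-TFI only → 3;
AO-TFI only → 4. Combinations the scheme does not enumerate (e.g. BAF
abnormal with IR normal) map to an explicit `ungradable` sentinel rather
than a guessed grade. Stages: sub-retinal fluid → active; alterations
without fluid → resolved; neither → healthy contralateral. Percentages
are rounded half-up to integers, the convention that reproduces every
reference tabulation value
(32/52 → 62, 7/125 → 6); denominators (all images, healthy-area images,
grade-4 images) are logged with each table. AO-TFI subtype tables are
multi-label, so their percentages need not sum to 100.

## Group statistics

Per-eye features are the means over that eye's included perifoveal images
(zones Z1–Z4); foveal (Z5) and discretionary (Z6) images and patients'
healthy contralateral eyes are excluded. Baseline matching trims, while
any of age/AL/RE group means differ by at least the tolerance (defaults
10 y, 0.6 mm, 1.5 D), the single eye whose value lies furthest outside
the other group's range (or, if none is outside, furthest from the other
group's mean); the exact matching algorithm of the original workflow is
unpublished, so this documented range-trimming rule stands in for it and
the trimmed IDs are reported. Comparisons use the unpaired Welch t-test,
two-sided, significance at p < 0.05, no multiple-testing correction (raw
per-feature p-values, flagged in the report header). Eyes are treated as
independent units; eye-within-patient correlation is not modeled.

## Simulation studies (power and type-I error)

The replicate-cohort studies run the package's measurement operators at
the statistic level: per eye, one simulated 160×160 px field is
tessellated for the neighbor-count SD, and 40 generated blob contours are
measured for the shape descriptors; per-eye values are compared with
Welch's t-test exactly as the image pipeline does. Pixel rendering is
skipped there (its fidelity is established separately by the
ground-truth detection and segmentation tests); this is what makes
hundreds of replicates tractable. Group sizes are 12 disease vs 33
healthy eyes — the scale of a single-center AO-TFI cohort — with one
field per eye. Power uses 100 seeded cohorts with
the default effect (disorder 0.08→0.20, roughness 0.10→0.30); a cohort
counts as a detection only if p < 0.05 *and* the difference has the
reported direction. Type-I error uses 1000 zero-effect cohorts on the
mean-circularity feature. The field size and blob count are scaled-down
study conditions chosen once; they are far below a real image's thousands
of cells, so per-eye features are noisier than in practice and the
detection rates reported are conservative.

## Pipeline

`run_quantify` composes synthesize (or load) → quality map → mask →
detect → tessellate → border-filter → metrics → segment → descriptors →
per-eye aggregation → Welch report, writing per-image/per-eye/comparison
CSVs, the exclusion list with reasons, the serialized config, and a
manifest with SHA-256 hashes of every output; identical configs reproduce
identical CSVs. In the synthetic path, grade flags are derived from group
membership (healthy → grade 0, disease → grade 4) as bookkeeping
placeholders — grading real images requires the reader-supplied flags, as
in the original two-reader workflow. The `rpemosaic` CLI exposes `synth`,
`quantify`, `register`, `grade` and `report` subcommands; exit code 2
marks validation errors, 1 computation errors.

## Known limitations

* The quality proxy and the classical center detector replace trained
  models; their absolute scores/detections are not interchangeable with
  the proprietary pipeline's, even though the downstream contracts are.
* Solidity/circularity of very small regions (a few pixels) are dominated
  by digitization; the default 4 px minimum area is a floor, not a cure.
* The pixel-size coefficients are placeholders (see above).
* Synthetic cohorts sample eye metadata independently of the morphometric
  effect, so baseline matching is exercised but never load-bearing in the
  simulations.
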