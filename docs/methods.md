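# Methods

## Scope and data model

The package quantifies how well PAT compositional contrast (lipid at 1210 nm,
hemoglobin at 1100 nm, 1400 nm off-resonance control) agrees with 3D
light-sheet virtual histology (iSPIM eosin and DRAQ5-nuclei channels) in
breast-biopsy volumes. All volumes use axis order **(scan, depth, lateral)**
with voxel centers, 0-based indices, and millimetres throughout; the scan axis
is the stepper-motor direction (0.193 mm pitch), and the depth axis increases
away from the imaged surface. Anterior and posterior acquisitions of a biopsy
are independent datasets limited to the 2 mm light-sheet imaging depth; no
attempt is made to fuse them.

An **analysis region** is exactly three contiguous scan slices whose middle
slice is matched to one histology plane; at the 0.193 mm step a region spans
(3 − 1) × 0.193 = 0.386 mm of biopsy. Five regions per biopsy side are placed
at evenly spaced scan positions, kept off the first/last slice where the
tissue block grazes the volume edge.

## Synthetic phantom

Because no clinical volumes are distributed, every quantitative claim is
exercised on a synthetic phantom with known ground truth. The phantom emulates
a ~5.3 × 2.0 × 4.7 mm fixed biopsy block:

* **Geometry.** The tissue block is the volume inset by a 0.12 mm margin
  (the anterior face is the cut surface). Adipose lobules and carcinoma foci
  are overlapping random spheres; ducts and vessels are random-walk tubes
  (duct walls carry a lumen carved by erosion). Paint order is ducts →
  carcinoma → adipose → vessels, with later classes never repainting earlier
  ones, so classes whose volume fraction is controlled (adipose, carcinoma)
  meet their targets directly; realized fractions stay within ±20 % relative
  of targets at the default scale (geometric packing limits exactness, and
  very small phantoms are boundary-dominated).
* **Chromophores.** Lipid concentration 0.9 in adipose, 0 elsewhere;
  hemoglobin 0.9 in vessels, 0 elsewhere (arbitrary units in [0, 1]). No
  instrument calibration exists for absolute concentrations; these are free
  modelling parameters fixed once.
* **Nuclei.** Poisson point process per class, densities (mm⁻³) carcinoma
  8000 ≈ duct wall 8000 ≫ stroma 600 > adipose 100, mirroring the observed
  morphology ordering. Each nucleus renders as a Gaussian spot (σ = 12 µm).
* **PAT render.** signal ∝ concentration × exp(−depth / L) with a single
  effective fluence decay length L (default 4 mm — the depth dependence of
  fluence is only qualitative, so a one-parameter exponential stands in for a
  transport model), blurred with a fixed anisotropic Gaussian PSF
  (σ = 0.12 / 0.04 / 0.08 mm along scan/depth/lateral, a stand-in for a
  40 MHz transducer; no acoustic simulation), resampled to the PAT grid,
  plus zero-mean Gaussian noise (σ = 0.03), clipped non-negative. The
  off-resonance channel uses zero concentration (noise only).
* **iSPIM render.** Eosin level by class (stroma 0.80, duct wall 0.90,
  carcinoma 0.85, adipose 0.10, lumen 0.05, vessel 0.30) — lipid displaces
  the eosinophilic matrix, so adipose is eosin-dim; a small PSF blur, optional
  periodic multiplicative stripe emulating stitching seams, additive noise.
* **Ultrasound.** Class-dependent echogenicity map under multiplicative gamma
  speckle; duct lumina hypoechoic; background zero. Used only for tissue
  masking and co-registration, never scored.
* **Reproducibility.** One `numpy` Generator seeded from `PhantomParams.seed`
  threads through truth generation and every render in a fixed order; a fixed
  seed reproduces all channels bit-exactly.

The default working grid is 20 µm isotropic for the truth/iSPIM volumes
(≈ 6 × 10⁶ voxels at full extent). A physical light-sheet system samples
finer; 20 µm is the package's chosen working resolution, coarse enough for
routine regeneration in tests while leaving ≈ 10× finer sampling than the PAT
grid. Tests use smaller extents (≈ 3–4.5 mm) except where realistic geometry
matters (parameter recovery, 20 + 30 ROI placement), which run at full
default scale.

**What the phantom does not emulate:** acoustic wave propagation and
reconstruction artifacts, optical scattering/Monte-Carlo fluence, real H&E
texture, deformation between modalities (channels are perfectly co-registered
by construction), and histology sectioning distortion. Passing tests
demonstrate that the *analysis chain* is correct and calibrated, not that the
modality itself reaches any particular clinical accuracy.

## Preprocessing

* `median_stack` collapses the 10 frames acquired per motor position to a
  per-pixel median (even counts average the two middle order statistics).
* `crop_to_depth` keeps voxels whose center depth is inside the imaging
  window; `from_surface="far"` supports posterior-side data stored in the
  anterior frame and equals flip → crop → flip.
* `local_contrast_enhance` is an edge-preserving base/detail decomposition
  (bilateral or Gaussian base, configurable) with gain on the detail layer,
  output clipped to the input range; gain 0 is the identity. The underlying
  operation is a generic `localcontrast`-style operator because no specific
  algorithm is pinned down for this step; it is applied per slice, since it
  feeds per-slice thresholding.
* `match_slices_ncc` assists the (fundamentally manual) cross-modality slice
  correspondence: per A-slice argmax of |NCC| within a window of a coarse
  map, with monotonicity enforced. The *magnitude* is used because eosin is
  contrast-inverted relative to PAT lipid (adipose is lipid-bright,
  eosin-dim), making the correct match strongly negatively correlated.
  iSPIM volumes are brought to the PAT grid by anti-aliased resampling
  (Gaussian pre-smooth at half the downsampling ratio, then linear
  interpolation) before any cross-modality comparison.

## Thresholding

PAT channels use Otsu's method per slice (per-volume available): the
threshold maximizing σ²ᵦ(t) = ω₀ω₁(μ₀ − μ₁)² over a 256-bin histogram on the
min–max intensity range. Class means are computed from per-bin intensity
sums (exact, not bin centers), ties break toward the lower threshold, and the
returned value sits just below the winning bin edge so that the strict
`intensity > t` positivity rule assigns edge-valued pixels consistently.
Positivity is strict `>` by convention.

iSPIM channels use conventional histogram thresholding: one threshold point
per analysis region from the smoothed in-tissue histogram (Gaussian kernel,
3-bin bandwidth), taken as the midpoint of the deepest valley between the two
most prominent modes; per-region points are averaged and the average applied
to the whole dataset. Unimodal regions fall back to a configurable intensity
percentile (default 95th) with a logged warning — nuclei-channel histograms
are routinely unimodal because nuclei occupy a small area fraction. Eosin
binarization uses inverted polarity (`intensity < t` ⇒ lipid pixel).
Artifact masks (e.g. manually segmented stitching seams) force pixels to 0
and remove them from every denominator.

## Composition

The composition-positive value of a pixel is the integer count (0..3) of
positive binarized slices in its region; the "averaged" tissue-composition
map is exactly count / 3, so the sum and average formulations are provably
consistent (property-tested). Percent composition is
100 × positive / valid-tissue pixels; the denominator is the tissue mask
(Otsu foreground of the ultrasound or eosin channel, closed, hole-filled,
largest connected component) minus artifact pixels. A whole-frame denominator
would dilute percentages arbitrarily with the field of view, which is why no
absolute percentage from any real acquisition is treated as a reference
value here.

## ROI scoring and ROC

ROIs are 0.66 × 0.66 mm squares — one third of the 2 mm imaging depth, with
0.66 taken as printed rather than recomputed as 2/3 mm. Two rubrics map a
ROI's composition-positive counts to an ordinal score:

* **lipid/hemoglobin**: 1 if no positive pixel; 3 if pixels with count ≥ 2
  make up ≥ 50 % of the valid ROI; else 2.
* **nuclei**: 1 if no positive pixel; 3 if any pixel has count ≥ 2; else 2.

The clauses overlap as stated; precedence 3 → 2 → 1 is the only reading under
which each ROI gets exactly one score, and is applied explicitly (documented
as an interpretation). ROIs with under 50 % valid pixels are rejected rather
than silently scored. On phantoms, placement is automated from truth labels:
cancerous ROIs centered on carcinoma pixels, non-cancerous ROIs centered on
content classes with no carcinoma inside the box, non-overlapping within a
map, seed-reproducible; on real data ROIs come from the config verbatim.

AUC is the rank formulation U/(n₁n₀) with ties counted ½, which coincides
with threshold-sweep ROC for ordinal data. Lipid channels use inverted
polarity (low score ⇒ cancerous); one pooled score per ROI per channel is
computed on the region's composition map (the only reading consistent with
counts up to 3).

## Statistics

Continuous composition comparisons pass a normality gate: Shapiro–Wilk per
group at α = 0.05; failures retry under log then reciprocal (that order, as
listed), choosing the first transform under which all groups pass; transforms
are skipped with a note when non-positive values make them undefined; if
nothing passes, the rank-based route is taken and recorded. Parametric
comparisons are one-way ANOVA with Tukey HSD. Ordinal ROI scores use the
tie-corrected Kruskal–Wallis H with Dunn's pairwise z-tests,
z = (R̄ᵢ − R̄ⱼ)/√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ)); the
family-wise adjustment defaults to Holm (configurable to Bonferroni or none)
because no specific adjustment is prescribed for this step. Dunn's test is
implemented in-package (no suitable installed implementation) and verified
against hand-computed values. Cross-modality lipid concordance is OLS
regression with R² = squared Pearson correlation.

Calibration is verified by simulation: under a 3-group Gaussian null
(n = 20/group, 2000 replicates) both omnibus tests' rejection rates at
α = 0.05 must fall inside the binomial 99 % band; ANOVA power against a 3 SD
shift exceeds 0.99 over 1000 replicates.

## Virtual H&E

`pseudo_color_he` maps eosin + nuclei fluorescence through a Beer–Lambert
absorbance model, RGB = exp(−(k_H·nuclei·OD_H + k_E·eosin·OD_E)), with the
standard hematoxylin (0.65, 0.70, 0.29) and eosin (0.07, 0.99, 0.11)
optical-density vectors. It is a deliberately simple visual-QC device —
published stain-conversion algorithms are more elaborate — and is excluded
from all quantitative paths. Zero input renders white; luminance is monotone
non-increasing in each input.

## Pipeline, seeds, numerical choices

A single YAML config drives `run_full`; defaults are materialized into the
stored config copy, and the manifest records the config hash, seeds, stage
outputs and all warnings (threshold fallbacks, rejected ROIs, skipped
transforms). Per-stage seeds derive from one master seed via
`SeedSequence.spawn`, so stages are independently reproducible and a rerun
with the same config reproduces all numeric outputs exactly.

Degenerate inputs are rejected rather than guessed at: constant images have
no threshold; empty masks, single-class AUC inputs and all-identical
Kruskal–Wallis data raise informative errors. The tissue mask pads by edge
replication before morphological closing so array borders are not eroded.
Known limitations: no deformable registration (correspondence is explicit
data), no multi-level or adaptive thresholding, no automatic stripe
detection (artifact masks are user-supplied), and the phantom's channel
noise model is additive Gaussian (plus ultrasound speckle) rather than
modality-accurate.
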