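# patquant

Quantitative assessment of photoacoustic tomography (PAT) contrast against
3D light-sheet virtual histology in breast biopsies.

## The problem

Breast-conserving surgery fails in a large fraction of cases because positive
tumor margins are only discovered in post-operative histology. Dual-modality
PAT + ultrasound could characterize margins non-destructively at the bedside:
1210 nm light excites lipid, 1100 nm excites hemoglobin, and cancer-infiltrated
tissue is characteristically **lipid-poor**. Validating that claim requires
comparing volumetric PAT against a histology-grade 3D reference. Inverted
selective plane illumination microscopy (iSPIM) of cleared, Eosin/DRAQ5-stained
tissue provides exactly that: a co-registered virtual-histology volume with an
eosin (stroma) channel and a nuclei channel.

`patquant` implements the complete quantitative workflow for this comparison,
and a synthetic co-registered multimodal **phantom generator** with known
ground truth so every stage is testable without clinical data:

1. **phantom** — renders five channels (PAT lipid / hemoglobin /
   off-resonance, ultrasound, iSPIM eosin / nuclei) from a ground-truth tissue
   model (adipose lobules, stroma, ducts, carcinoma foci, vessels) viewed from
   the anterior and posterior side with exponential fluence decay in depth.
2. **preprocess** — frame median averaging, depth cropping to the 2 mm
   light-sheet window, edge-aware local contrast enhancement, NCC-assisted
   slice correspondence.
3. **thresholding** — Otsu binarization of PAT channels (threshold t*
   maximizing the between-class variance σ²ᵦ(t) = ω₀ω₁(μ₀−μ₁)²) and
   region-averaged histogram-valley thresholds for iSPIM channels, with
   artifact masks excluded from all denominators.
4. **composition** — composition-positive pixel maps: per-pixel count
   (0..3) of positive binarized slices in each 3-slice analysis region, and
   percent composition over the tissue mask.
5. **roi_scoring** — ordinal 1–3 scoring of 0.66 × 0.66 mm ROIs under two
   rubrics (lipid/hemoglobin and nuclei), and rank-based ROC AUC
   (Mann–Whitney, ties ½; lipid polarity inverted: low lipid ⇒ cancer).
6. **stats** — Shapiro–Wilk normality gate with log/reciprocal transforms,
   one-way ANOVA + Tukey HSD, tie-corrected Kruskal–Wallis + Dunn post-hoc,
   OLS regression for cross-modality concordance.
7. **virtual_he** — Beer–Lambert pseudo-H&E rendering for visual QC.
8. **pipeline** — YAML-config-driven end-to-end runs with a reproducibility
   manifest, plus the `patquant` CLI.

## Worked example

```python
import patquant as pq

cfg = {
    "mode": "phantom", "seed": 7, "out_dir": "demo_run",
    "phantom": {"extent_mm": [4.5, 1.9, 4.5],
                "ispim_spacing": [0.03, 0.03, 0.03],
                "pat_spacing": [0.193, 0.06, 0.06],
                "carcinoma_radius_mm": [0.4, 0.55]},
    "n_cancerous_rois": 8, "n_non_cancerous_rois": 12,
}
manifest = pq.run_full(cfg)
```

or equivalently `patquant run --config demo.yaml`. The run writes
`composition.csv`, `roi_scores.csv`, `auc.json`, `stats.json` and
`manifest.json` into `demo_run/`. With the config above it prints/stores:

| quantity | value | meaning |
|---|---|---|
| mean pooled lipid % (PAT / iSPIM) | 35.6 / 33.8 | the two modalities report nearly the same lipid composition |
| lipid regression | slope 0.991, R² = 0.913 | strong cross-modality concordance over the 10 analysis regions |
| AUC, PAT lipid / iSPIM lipid | 0.757 / 0.743 | low lipid score discriminates the carcinoma-labeled ROIs |
| AUC, iSPIM nuclei | 0.95 | carcinoma foci in this phantom are strongly nuclei-dense |
| Kruskal–Wallis, PAT lipid scores | H = 3.93, p = 0.047 | cancerous vs non-cancerous score distributions differ at α = 0.05 |

The phantom's carcinoma foci are rendered lipid-poor and nuclei-dense, so an
AUC above 0.5 with the inverted lipid polarity means the pipeline recovers the
planted biology. The hemoglobin channel's AUC is near 0.5 here because vessels
are placed independently of the carcinoma foci.

A stand-alone phantom can be exported for inspection with
`patquant phantom generate --config phantom.yaml --out phantom_dir --seed 2`
(multi-page TIFF per channel and side, truth volumes, `nuclei.csv`,
`metadata.json`).

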