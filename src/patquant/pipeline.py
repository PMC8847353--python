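"""End-to-end orchestration: phantom (or ingest) → preprocess → threshold →
composition → ROI scoring → statistics, with config validation and a run
manifest.

A single YAML config drives everything. Defaults are materialized into the
config copy stored with the run, so a manifest plus its config reproduces the
run exactly: seeds for each stage are derived from one master seed, and
re-running with the same config yields identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import composition as comp
from . import phantom as ph
from . import preprocess as pre
from . import roi_scoring as roisc
from . import stats as st
from . import thresholding as th
from .volume_io import (
    AnalysisRegion,
    ChannelVolume,
    ExperimentConfig,
    default_regions,
    load_config,
    read_volume,
    resample_to_grid,
    write_volume,
)

__version__ = "0.1.0"

#: channels that are quantitatively scored, with their rubric and ROC polarity
SCORED_CHANNELS = {
    "pat_lipid": ("vascular_lipid", "lower_positive"),
    "ispim_lipid": ("vascular_lipid", "lower_positive"),
    "pat_hemoglobin": ("vascular_lipid", "lower_positive"),
    "ispim_nuclei": ("nuclei", "higher_positive"),
}


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, seeds, outputs, warnings."""

    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def add_stage(self, name: str, **info) -> None:
        self.stages[name] = info

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "warnings": self.warnings,
            "outputs": self.outputs,
        }

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        self.outputs = sorted(
            str(p.relative_to(out_dir))
            for p in Path(out_dir).rglob("*")
            if p.is_file() and p.name != "manifest.json"
        )
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def _coerce_config(config) -> ExperimentConfig:
    if isinstance(config, ExperimentConfig):
        return config
    if isinstance(config, dict):
        return ExperimentConfig(raw=config)
    return load_config(config)


def _config_hash(cfg: ExperimentConfig) -> str:
    text = yaml.safe_dump(cfg.raw, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def phantom_params_from_config(cfg: ExperimentConfig, seed: int | None = None) -> ph.PhantomParams:
    kw = dict(cfg.get("phantom", {}) or {})
    for key in ("extent_mm", "pat_spacing", "ispim_spacing",
                "carcinoma_radius_mm", "adipose_lobule_radius_mm",
                "pat_psf_sigma_mm"):
        if key in kw:
            kw[key] = tuple(kw[key])
    if seed is not None:
        kw["seed"] = int(seed)
    elif "seed" not in kw:
        kw["seed"] = cfg.seed
    return ph.PhantomParams(**kw)


def validate_config(config) -> list[str]:
    """Structural + geometric validation; an empty list means runnable."""
    findings: list[str] = []
    try:
        cfg = _coerce_config(config)
    except (ValueError, OSError) as exc:
        return [f"config unreadable: {exc}"]
    mode = cfg.mode
    if mode not in ("phantom", "real"):
        findings.append(f"mode must be 'phantom' or 'real', got {mode!r}")
        return findings
    if mode == "phantom":
        try:
            phantom_params_from_config(cfg)
        except (TypeError, ValueError) as exc:
            findings.append(f"phantom parameters invalid: {exc}")
    else:
        chans = cfg.get("channels", {})
        if not chans:
            findings.append("real mode requires a 'channels' mapping")
        for side, mods in chans.items():
            for mod, path in mods.items():
                if not Path(path).exists():
                    findings.append(f"channel file missing: {side}/{mod}: {path}")
    for rspec in cfg.get("regions", []) or []:
        idx = rspec.get("slice_indices", [])
        if len(idx) != AnalysisRegion.N_SLICES:
            findings.append(
                f"region {rspec.get('region_index')} has {len(idx)} slices; "
                f"exactly {AnalysisRegion.N_SLICES} are required"
            )
    for i, rs in enumerate(cfg.get("rois", []) or []):
        if rs.get("side_mm", roisc.ROI_SIDE_MM_DEFAULT) <= 0:
            findings.append(f"roi {i}: side_mm must be positive")
        if any(v < 0 for v in rs.get("origin_mm", (0, 0))):
            findings.append(f"roi {i}: origin_mm must be non-negative")
    return findings


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def _threshold_region_slices(
    vol: ChannelVolume,
    regions: list[AnalysisRegion],
    tissue3d: np.ndarray,
    scheme: str,
    enhance_gain: float,
    positive: str,
    artifact3d: np.ndarray | None,
    captured: list[str],
) -> dict[int, list[th.BinaryVolume]]:
    """Binarize the three slices of each region under the channel's scheme.

    Otsu is applied per slice; the histogram scheme finds one threshold point
    per region (on in-tissue pixels), averages the points across regions, and
    applies the average to every slice. Out-of-tissue pixels are recorded as
    excluded.
    """
    slices: dict[int, list[np.ndarray]] = {}
    for region in regions:
        region.validate_against(vol)
        imgs = []
        for s in region.slice_indices:
            img = vol.data[s].astype(np.float64)
            if enhance_gain > 0 and np.ptp(img) > 0:
                img = pre.local_contrast_enhance(img, detail_gain=enhance_gain,
                                                 smoother="gaussian")
            imgs.append(img)
        slices[region.region_index] = imgs

    region_thresholds: dict[int, float] = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for region in regions:
            ri = region.region_index
            if scheme == "otsu":
                continue
            pooled = []
            for s, img in zip(region.slice_indices, slices[ri]):
                m = tissue3d[s]
                pooled.append(img[m] if m.any() else img.ravel())
            pooled_arr = np.concatenate(pooled)
            region_thresholds[ri] = th.histogram_region_threshold(pooled_arr)
    captured.extend(str(w.message) for w in caught)

    out: dict[int, list[th.BinaryVolume]] = {}
    if scheme == "otsu":
        for region in regions:
            ri = region.region_index
            outs = []
            for s, img in zip(region.slice_indices, slices[ri]):
                t = th.otsu_threshold(img)
                excl = ~tissue3d[s]
                if artifact3d is not None:
                    excl = excl | artifact3d[s]
                outs.append(th.average_and_apply([t], img, artifact_mask=excl,
                                                 modality=vol.modality, positive=positive))
            out[ri] = outs
    else:
        spec = th.ThresholdSpec(scheme="histogram_region_avg",
                                per_region=list(region_thresholds.values()))
        for region in regions:
            ri = region.region_index
            outs = []
            for s, img in zip(region.slice_indices, slices[ri]):
                excl = ~tissue3d[s]
                if artifact3d is not None:
                    excl = excl | artifact3d[s]
                outs.append(th.average_and_apply(spec, img, artifact_mask=excl,
                                                 modality=vol.modality, positive=positive))
            out[ri] = outs
    return out


def _labels_on_grid(truth: ph.PhantomTruth, target: ChannelVolume, side: str) -> np.ndarray:
    """Nearest-neighbour resample of truth labels onto a channel's grid."""
    from scipy import ndimage

    labels = truth.labels if side == "anterior" else truth.labels[:, ::-1, :]
    zoom = [t / s for s, t in zip(labels.shape, target.shape)]
    out = ndimage.zoom(labels, zoom, order=0, grid_mode=True, mode="nearest")
    # grid sizes can disagree by a voxel after cropping; pad/trim to match
    pads = []
    for axis, (have, want) in enumerate(zip(out.shape, target.shape)):
        if have > want:
            out = np.take(out, range(want), axis=axis)
        pads.append((0, max(0, want - have)))
    if any(p[1] for p in pads):
        out = np.pad(out, pads, mode="edge")
    return out


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_full(config, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the whole pipeline and write every artifact plus a manifest.

    Any stage failure aborts with the stage named; a partial manifest is
    written first.
    """
    cfg = _coerce_config(config)
    out = Path(out_dir) if out_dir is not None else cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(cfg), seed=cfg.seed)
    stage = "init"
    try:
        master = np.random.SeedSequence(cfg.seed)
        seeds = {name: int(s.generate_state(1)[0] % (2**31))
                 for name, s in zip(("phantom", "roi"), master.spawn(2))}

        # ----- phantom or ingest -------------------------------------------
        stage = "phantom" if cfg.mode == "phantom" else "ingest"
        sample_id = cfg.get("sample_id", "sample")
        truth = None
        if cfg.mode == "phantom":
            params = phantom_params_from_config(cfg, seed=seeds["phantom"])
            truth, anterior, posterior = ph.generate_phantom(params)
            sides = {"anterior": anterior, "posterior": posterior}
        else:
            params = None
            sides = {}
            for side, mods in cfg.get("channels", {}).items():
                sides[side] = {m: read_volume(p) for m, p in mods.items()}
            if not sides:
                raise ValueError("no channels configured")
        manifest.add_stage(stage, sides=sorted(sides), mode=cfg.mode)

        # ----- preprocess: bring iSPIM channels onto the PAT grid ----------
        stage = "preprocess"
        for side, chans in sides.items():
            ref = chans["pat_lipid"]
            for mod in ("ispim_eosin", "ispim_nuclei"):
                if mod in chans and chans[mod].shape != ref.shape:
                    chans[mod] = resample_to_grid(chans[mod], ref.shape, ref.spacing)
        manifest.add_stage(stage, grid="pat")

        # ----- tissue mask and analysis regions ----------------------------
        stage = "tissue_mask"
        masks = {}
        label_grids = {}
        for side, chans in sides.items():
            struct = chans.get("ultrasound", chans.get("ispim_eosin"))
            masks[side] = comp.tissue_mask([struct.data])
            if truth is not None:
                label_grids[side] = _labels_on_grid(truth, chans["pat_lipid"], side)
        n_regions = int(cfg.get("n_regions", 5))
        regions = {
            side: default_regions(chans["pat_lipid"].shape[0], n_regions,
                                  sample_id=sample_id, side=side)
            for side, chans in sides.items()
        }
        manifest.add_stage(stage, regions_per_side=n_regions)

        # ----- thresholding + composition ----------------------------------
        stage = "threshold_composition"
        enhance_gain = float(cfg.get("enhance_gain", 0.3))
        channel_plan = {
            "pat_lipid": ("pat_lipid", "otsu", "above"),
            "pat_hemoglobin": ("pat_hemoglobin", "otsu", "above"),
            "ispim_lipid": ("ispim_eosin", "histogram_region_avg", "below"),
            "ispim_nuclei": ("ispim_nuclei", "histogram_region_avg", "above"),
        }
        captured: list[str] = []
        cmaps: dict[tuple[str, str, int], comp.CompositionMap] = {}
        comp_rows = []
        for side, chans in sides.items():
            tissue3d = masks[side]
            for cname, (mod, scheme, positive) in channel_plan.items():
                if mod not in chans:
                    continue
                vol = chans[mod]
                per_region = _threshold_region_slices(
                    vol, regions[side], tissue3d, scheme, enhance_gain,
                    positive, None, captured,
                )
                for region in regions[side]:
                    ri = region.region_index
                    bins = per_region[ri]
                    cmap = comp.composition_positive_map(
                        bins, channel=cname, region_index=ri,
                        sample_id=sample_id, side=side,
                        spacing=(vol.spacing[1], vol.spacing[2]),
                    )
                    cmaps[(cname, side, ri)] = cmap
                    percents, valids = [], []
                    for s, b in zip(region.slice_indices, bins):
                        m = tissue3d[s]
                        percents.append(comp.percent_composition(b, m))
                        valids.append(int((m & b.valid).sum()))
                    rc = comp.RegionComposition(
                        sample_id=sample_id, side=side, region_index=ri,
                        channel=cname, per_slice_percent=percents,
                        per_slice_valid=valids,
                    )
                    for k, (p, v) in enumerate(zip(percents, valids)):
                        comp_rows.append({
                            "sample_id": sample_id, "side": side, "region": ri,
                            "channel": cname, "slice": region.slice_indices[k],
                            "percent": p, "valid_pixels": v,
                            "pooled_percent": rc.pooled_percent,
                        })
        comp_df = pd.DataFrame(comp_rows)
        comp_path = out / "composition.csv"
        comp_df.to_csv(comp_path, index=False)
        for key, cmap in cmaps.items():
            cname, side, ri = key
            tifffile.imwrite(out / f"cmap_{cname}_{side}_r{ri}.tiff",
                             cmap.counts.astype(np.uint8))
        manifest.warnings.extend(captured)
        manifest.add_stage(stage, composition_csv=str(comp_path), n_maps=len(cmaps))

        # ----- ROI placement + scoring -------------------------------------
        stage = "roi_scoring"
        score_rows = []
        aucs = {}
        if truth is not None:
            hist_label_maps = {}
            for side in sides:
                for region in regions[side]:
                    hist_label_maps[(sample_id, side, region.region_index)] = (
                        label_grids[side][region.histology_slice]
                    )
            ref = sides["anterior"]["pat_lipid"]
            spacing2d = (ref.spacing[1], ref.spacing[2])
            pspec = roisc.PlacementSpec(
                n_cancerous=int(cfg.get("n_cancerous_rois", 20)),
                n_non_cancerous=int(cfg.get("n_non_cancerous_rois", 30)),
                side_mm=float(cfg.get("roi_side_mm", roisc.ROI_SIDE_MM_DEFAULT)),
            )
            rois = roisc.place_rois(
                hist_label_maps, spacing2d, pspec, seed=seeds["roi"],
                carcinoma_label=ph.CARCINOMA,
                content_labels=(ph.ADIPOSE, ph.STROMA, ph.DUCT_WALL, ph.VESSEL),
                background_label=ph.BACKGROUND,
            )
        else:
            rois = [
                roisc.ROIBox(
                    sample_id=sample_id, side=r["side"],
                    region_index=int(r["region_index"]),
                    origin_mm=tuple(r["origin_mm"]),
                    side_mm=float(r.get("side_mm", roisc.ROI_SIDE_MM_DEFAULT)),
                    label=r["label"],
                )
                for r in cfg.get("rois", [])
            ]
        for roi in rois:
            for cname, (rubric, _pol) in SCORED_CHANNELS.items():
                key = (cname, roi.side, roi.region_index)
                if key not in cmaps:
                    continue
                try:
                    sc = roisc.score_roi(cmaps[key], roi, rubric)
                except ValueError as exc:
                    manifest.warnings.append(f"ROI rejected ({cname}): {exc}")
                    continue
                score_rows.append({
                    "sample_id": roi.sample_id, "side": roi.side,
                    "region": roi.region_index,
                    "origin_depth_mm": roi.origin_mm[0],
                    "origin_lateral_mm": roi.origin_mm[1],
                    "side_mm": roi.side_mm, "label": roi.label,
                    "channel": cname, "rubric": rubric, "score": sc.score,
                    "frac_ge2": sc.frac_ge2, "frac_ge1": sc.frac_ge1,
                })
        scores_df = pd.DataFrame(score_rows)
        scores_path = out / "roi_scores.csv"
        scores_df.to_csv(scores_path, index=False)
        if len(scores_df):
            for cname, (_rubric, pol) in SCORED_CHANNELS.items():
                sub = scores_df[scores_df.channel == cname]
                if sub.label.nunique() == 2:
                    aucs[cname] = roisc.auc_from_scores(
                        sub.score.to_numpy(), sub.label.to_numpy(), polarity=pol
                    )
        (out / "auc.json").write_text(json.dumps(aucs, indent=2))
        manifest.add_stage(stage, scores_csv=str(scores_path),
                           n_rois=len(rois), auc=aucs)

        # ----- statistics ---------------------------------------------------
        stage = "stats"
        stats_out: dict = {}
        if len(comp_df):
            piv = comp_df.drop_duplicates(["side", "region", "channel"])
            lipids = piv[piv.channel.isin(["pat_lipid", "ispim_lipid"])]
            wide = lipids.pivot_table(index=["side", "region"], columns="channel",
                                      values="pooled_percent")
            if {"pat_lipid", "ispim_lipid"} <= set(wide.columns) and len(wide) >= 3:
                slope, intercept, r2, p = st.regression_r2(
                    wide["ispim_lipid"], wide["pat_lipid"]
                )
                stats_out["lipid_regression"] = {
                    "slope": slope, "intercept": intercept, "r2": r2, "p": p,
                    "n": int(len(wide)),
                }
        if len(scores_df):
            for cname in scores_df.channel.unique():
                sub = scores_df[scores_df.channel == cname]
                groups = {
                    lab: sub[sub.label == lab].score.to_numpy()
                    for lab in sub.label.unique()
                }
                if len(groups) == 2 and all(len(v) >= 2 for v in groups.values()):
                    try:
                        rep = st.kruskal_dunn(groups)
                        stats_out[f"roi_scores_{cname}"] = rep.to_dict()
                    except ValueError as exc:
                        manifest.warnings.append(f"stats skipped ({cname}): {exc}")
        stats_path = out / "stats.json"
        stats_path.write_text(json.dumps(stats_out, indent=2, default=float))
        manifest.add_stage(stage, stats_json=str(stats_path))

        # materialized config copy
        (out / "config_used.yaml").write_text(yaml.safe_dump(cfg.raw, sort_keys=True))
    except Exception as exc:
        manifest.add_stage("FAILED", stage=stage, error=str(exc))
        manifest.write(out)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest.write(out)
    return manifest


def write_phantom_outputs(params: ph.PhantomParams, out_dir: str | Path) -> list[Path]:
    """Generate a phantom and write channels, truth and metadata to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, anterior, posterior = ph.generate_phantom(params)
    written: list[Path] = []
    for side, chans in (("anterior", anterior), ("posterior", posterior)):
        for mod, vol in chans.items():
            p = out / f"{side}_{mod}.tiff"
            write_volume(vol, p)
            written.append(p)
    tifffile.imwrite(out / "truth_labels.tiff", truth.labels)
    tifffile.imwrite(out / "truth_lipid.tiff", truth.lipid.astype(np.float32))
    tifffile.imwrite(out / "truth_hgb.tiff", truth.hemoglobin.astype(np.float32))
    pd.DataFrame(truth.nuclei_xyz_mm, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        out / "nuclei.csv", index=False
    )
    meta = {
        "spacing_truth": list(truth.spacing),
        "spacing_pat": list(params.pat_spacing),
        "extent_mm": list(params.extent_mm),
        "seed": params.seed,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(params).items()},
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    written += [out / "truth_labels.tiff", out / "truth_lipid.tiff",
                out / "truth_hgb.tiff", out / "nuclei.csv", out / "metadata.json"]
    return written
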