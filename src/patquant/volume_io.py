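"""Channel volumes, analysis regions and experiment configuration.

The geometric conventions used throughout the package live here:

* every volume is a 3D array in **slice-major** order ``(scan, depth, lateral)``,
  where the scan axis is the stepper-motor translation direction, the depth
  axis increases away from the anterior imaged surface, and the lateral axis
  spans the transducer / light-sheet width;
* physical coordinates refer to **voxel centers**, 0-based indices,
  millimetres everywhere;
* a biopsy side (anterior / posterior) is an independent dataset — the two
  acquisitions are never fused.

Volumes are exchanged on disk as multi-page grayscale TIFF stacks (one page
per scan slice) with a JSON metadata sidecar carrying spacing, modality and
side tags. Keeping metadata in an explicit sidecar rather than TIFF tags makes
the dialect testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

MODALITIES = (
    "pat_lipid",
    "pat_hemoglobin",
    "pat_off",
    "ultrasound",
    "ispim_eosin",
    "ispim_nuclei",
)
SIDES = ("anterior", "posterior")

#: laser wavelength (nm) conventionally associated with each PAT modality
PAT_WAVELENGTHS_NM = {"pat_hemoglobin": 1100, "pat_lipid": 1210, "pat_off": 1400}


@dataclass
class ChannelVolume:
    """One modality's 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array, axis order ``(scan, depth, lateral)``.
    spacing:
        ``(scan step mm, depth mm/px, lateral mm/px)``.
    modality:
        One of :data:`MODALITIES`.
    side:
        ``"anterior"`` or ``"posterior"``.
    wavelength_nm:
        Optional excitation/illumination wavelength.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str
    side: str = "anterior"
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume must be a non-empty 3D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive entries")
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size along (scan, depth, lateral)."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "ChannelVolume":
        """Copy of this volume carrying ``data`` and the same metadata."""
        return replace(self, data=data)


@dataclass(frozen=True)
class AnalysisRegion:
    """A named 3-slice window matched to one histology plane.

    Exactly three contiguous scan slices form a region; the middle slice is
    the one matched to the histology section.
    """

    sample_id: str
    side: str
    region_index: int
    slice_indices: tuple[int, int, int]

    N_SLICES = 3

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.slice_indices)
        object.__setattr__(self, "slice_indices", idx)
        if len(idx) != self.N_SLICES:
            raise ValueError(f"a region holds exactly {self.N_SLICES} slices, got {len(idx)}")
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValueError("slice indices must be contiguous along the scan axis")
        if min(idx) < 0:
            raise ValueError("slice indices must be non-negative")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")

    @property
    def histology_slice(self) -> int:
        """Index of the histology-matched (middle) slice."""
        return self.slice_indices[len(self.slice_indices) // 2]

    def validate_against(self, vol: ChannelVolume) -> None:
        if max(self.slice_indices) >= vol.shape[0]:
            raise ValueError(
                f"region {self.region_index} slices {self.slice_indices} exceed "
                f"volume scan extent {vol.shape[0]}"
            )


def region_span_mm(region: AnalysisRegion | int, scan_step_mm: float) -> float:
    """Biopsy length occupied by a region: (n_slices − 1) × scan step.

    Three slices at the 0.193 mm motor step span 0.386 mm. ``region`` may be
    an :class:`AnalysisRegion` or a bare slice count.
    """
    n = region if isinstance(region, int) else len(region.slice_indices)
    if n < 1:
        raise ValueError("a region needs at least one slice")
    return (n - 1) * float(scan_step_mm)


# ---------------------------------------------------------------------------
# TIFF + JSON sidecar I/O
# ---------------------------------------------------------------------------

_REQUIRED_META = ("spacing", "modality")


def write_volume(vol: ChannelVolume, path: str | Path) -> Path:
    """Write a multi-page TIFF (one page per scan slice) plus a JSON sidecar.

    Returns the sidecar path (``<path>.json``).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vol.data, photometric="minisblack")
    meta = {
        "spacing": list(vol.spacing),
        "modality": vol.modality,
        "side": vol.side,
        "wavelength_nm": vol.wavelength_nm,
        "axis_order": "scan,depth,lateral",
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_volume(path: str | Path, metadata: dict | str | Path | None = None) -> ChannelVolume:
    """Read a multi-page TIFF and its metadata sidecar into a ChannelVolume.

    ``metadata`` may be a dict, a path to a JSON file, or None (in which case
    ``<path>.json`` is used). Missing required keys are reported by name.
    """
    path = Path(path)
    if metadata is None:
        metadata = path.with_suffix(path.suffix + ".json")
    if isinstance(metadata, (str, Path)):
        metap = Path(metadata)
        if not metap.exists():
            raise FileNotFoundError(f"metadata sidecar not found: {metap}")
        try:
            metadata = json.loads(metap.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"garbled metadata JSON at {metap}: {exc}") from exc
    assert isinstance(metadata, dict)
    missing = [k for k in _REQUIRED_META if k not in metadata]
    if missing:
        raise KeyError(f"metadata missing required key(s): {', '.join(missing)}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a stack of 2D pages, got ndim={data.ndim}")
    return ChannelVolume(
        data=data,
        spacing=tuple(metadata["spacing"]),
        modality=metadata["modality"],
        side=metadata.get("side", "anterior"),
        wavelength_nm=metadata.get("wavelength_nm"),
    )


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Parsed experiment configuration driving a pipeline run.

    Holds per-sample channel paths (real-data mode) or phantom parameters
    (phantom mode), region/ROI definitions, threshold settings and output
    options. ``raw`` preserves the full parsed mapping so that defaults can be
    materialized back out with the run manifest.
    """

    raw: dict = field(default_factory=dict)

    @property
    def mode(self) -> str:
        return self.raw.get("mode", "phantom")

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def out_dir(self) -> Path:
        return Path(self.raw.get("out_dir", "patquant_out"))

    def get(self, key: str, default=None):
        return self.raw.get(key, default)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML experiment configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"unparseable config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    return ExperimentConfig(raw=raw)


def channel_paths(cfg: ExperimentConfig) -> dict[str, dict[str, Path]]:
    """Per-side, per-modality channel file paths for real-data runs."""
    out: dict[str, dict[str, Path]] = {}
    for side, chans in cfg.get("channels", {}).items():
        out[side] = {mod: Path(p) for mod, p in chans.items()}
    return out


def regions_from_config(cfg: ExperimentConfig, sample_id: str = "sample") -> list[AnalysisRegion]:
    regions = []
    for spec in cfg.get("regions", []):
        regions.append(
            AnalysisRegion(
                sample_id=spec.get("sample_id", sample_id),
                side=spec["side"],
                region_index=int(spec["region_index"]),
                slice_indices=tuple(spec["slice_indices"]),
            )
        )
    return regions


def default_regions(
    n_scan_slices: int,
    n_regions: int = 5,
    sample_id: str = "sample",
    side: str = "anterior",
) -> list[AnalysisRegion]:
    """Evenly spaced 3-slice analysis regions along the scan axis.

    Region centers are placed at evenly spaced quantiles of the scan range,
    mirroring the five histology-matched planes per biopsy side.
    """
    S = AnalysisRegion.N_SLICES
    if n_scan_slices < S:
        raise ValueError(f"need at least {S} scan slices, got {n_scan_slices}")
    n_regions = min(n_regions, n_scan_slices // S)
    # keep regions off the first/last slice, which often graze the block edge
    lo = 2 if n_scan_slices >= S * n_regions + 2 else 1
    centers = np.linspace(lo, n_scan_slices - 1 - lo, n_regions)
    regions = []
    used: set[int] = set()
    for k, c in enumerate(centers, start=1):
        mid = int(round(c))
        mid = min(max(mid, 1), n_scan_slices - 2)
        while {mid - 1, mid, mid + 1} & used and mid + 2 < n_scan_slices:
            mid += 1
        idx = (mid - 1, mid, mid + 1)
        used.update(idx)
        regions.append(
            AnalysisRegion(sample_id=sample_id, side=side, region_index=k, slice_indices=idx)
        )
    return regions


def resample_to_grid(
    vol: ChannelVolume, target_shape: Sequence[int], target_spacing: Sequence[float]
) -> ChannelVolume:
    """Resample a volume onto a coarser grid (e.g. iSPIM → PAT resolution).

    Downsampling is anti-aliased: the data are pre-smoothed with a Gaussian of
    sigma = downsampling ratio / 2 along each shrinking axis (a block-mean
    stand-in), then linearly interpolated onto the target grid.
    """
    from scipy import ndimage

    target_shape = tuple(int(n) for n in target_shape)
    ratios = [o / n for o, n in zip(vol.shape, target_shape)]
    sig = [max(r, 1.0) / 2.0 if r > 1.0 else 0.0 for r in ratios]
    data = vol.data.astype(np.float64)
    if any(s > 0 for s in sig):
        data = ndimage.gaussian_filter(data, sigma=sig)
    zoom = [n / o for o, n in zip(vol.shape, target_shape)]
    out = ndimage.zoom(data, zoom, order=1, grid_mode=True, mode="nearest")
    assert out.shape == target_shape
    return ChannelVolume(
        data=out,
        spacing=tuple(float(s) for s in target_spacing),
        modality=vol.modality,
        side=vol.side,
        wavelength_nm=vol.wavelength_nm,
    )
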