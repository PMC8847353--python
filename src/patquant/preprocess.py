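"""Pre-thresholding conditioning: frame averaging, depth cropping,
edge-aware local contrast enhancement, and slice-correspondence bookkeeping.

The acquisition pauses at each motor position and records a burst of frames;
`median_stack` collapses a burst to a single slice. PAT volumes are cropped
to the light-sheet imaging depth before any cross-modality comparison, and
each slice is passed through an edge-preserving base/detail decomposition
with gain applied to the detail layer (a `localcontrast`-style operator; the
smoother is configurable). Cross-modality slice co-registration is explicit
correspondence data — manual in origin — with a normalized-cross-correlation
assist for phantoms and well-behaved data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_bilateral

from .volume_io import ChannelVolume


@dataclass
class SliceCorrespondence:
    """Monotonic mapping from PAT slice indices to iSPIM slice indices."""

    pairs: list[tuple[int, int]]
    method: str = "manual"  # manual | ncc_assist

    def __post_init__(self) -> None:
        if self.method not in ("manual", "ncc_assist"):
            raise ValueError("method must be 'manual' or 'ncc_assist'")
        a_prev, b_prev = -1, -1
        for a, b in self.pairs:
            if a < 0 or b < 0:
                raise ValueError("slice indices must be non-negative")
            if a <= a_prev or b < b_prev:
                raise ValueError("correspondence must be monotonic along the scan axis")
            a_prev, b_prev = a, b

    def lookup(self, pat_slice: int) -> int:
        for a, b in self.pairs:
            if a == pat_slice:
                return b
        raise KeyError(f"no correspondence recorded for PAT slice {pat_slice}")


def median_stack(frames: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Per-pixel median of repeated frames acquired at one motor position.

    Even frame counts use the mean of the two middle order statistics.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share one shape")
    return np.median(np.stack(frames, axis=0), axis=0)


def crop_to_depth(
    vol: ChannelVolume, depth_mm: float, from_surface: str = "near"
) -> ChannelVolume:
    """Retain voxels whose depth-coordinate lies within ``depth_mm`` of the
    imaged surface.

    The stored depth axis increases away from the anterior surface.
    ``from_surface="near"`` measures from index 0; ``"far"`` measures from the
    last index (used when a posterior-side acquisition is stored in the
    anterior frame), and equals flip → near-crop → flip.
    """
    if from_surface not in ("near", "far"):
        raise ValueError("from_surface must be 'near' or 'far'")
    dz = vol.spacing[1]
    n = vol.shape[1]
    extent = n * dz
    if depth_mm > extent + 1e-9:
        raise ValueError(f"requested depth {depth_mm} mm exceeds volume depth {extent:.4g} mm")
    centers = (np.arange(n) + 0.5) * dz
    keep = int(np.sum(centers < depth_mm - 1e-12))
    keep = max(1, keep)
    if from_surface == "near":
        data = vol.data[:, :keep, :]
    else:
        data = vol.data[:, n - keep :, :]
    return vol.with_data(data)


def local_contrast_enhance(
    img: np.ndarray,
    detail_gain: float = 0.5,
    edge_threshold: float = 0.1,
    smoother: str = "bilateral",
    base_sigma: float = 3.0,
) -> np.ndarray:
    """Edge-aware local contrast enhancement of one slice.

    The image is split into an edge-preserving base layer and a detail layer
    (image − base); the detail layer is amplified by ``detail_gain`` and
    recombined, then clipped to the input range. ``edge_threshold`` sets the
    range-kernel width of the bilateral base relative to the image's dynamic
    range, so strong edges stay in the base layer and are not overshot.

    ``detail_gain = 0`` returns the input unchanged.
    """
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if detail_gain < 0:
        raise ValueError("detail_gain must be >= 0")
    if detail_gain == 0:
        return img.copy()
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return img.copy()
    if smoother == "bilateral":
        scaled = (img - lo) / (hi - lo)
        base = denoise_bilateral(
            scaled, sigma_color=max(edge_threshold, 1e-3), sigma_spatial=base_sigma
        )
        base = base * (hi - lo) + lo
    elif smoother == "gaussian":
        base = ndimage.gaussian_filter(img, sigma=base_sigma)
    else:
        raise ValueError("smoother must be 'bilateral' or 'gaussian'")
    detail = img - base
    out = base + (1.0 + detail_gain) * detail
    return np.clip(out, lo, hi)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def match_slices_ncc(
    vol_a: np.ndarray,
    vol_b: np.ndarray,
    coarse_map: list[tuple[int, int]] | None = None,
    window: int = 2,
) -> SliceCorrespondence:
    """For each A-slice, find the B-slice maximizing the magnitude of the
    normalized cross-correlation within ± ``window`` of a coarse mapping.

    The magnitude makes matching invariant to contrast polarity — the eosin
    channel is dim exactly where the PAT lipid channel is bright, so the best
    cross-modality match has a strongly *negative* correlation. Both volumes
    must already be resampled to a common in-plane grid. Monotonicity along
    the scan axis is enforced by a running maximum.
    """
    vol_a = np.asarray(vol_a, dtype=np.float64)
    vol_b = np.asarray(vol_b, dtype=np.float64)
    if vol_a.shape[1:] != vol_b.shape[1:]:
        raise ValueError("volumes must share an in-plane grid")
    na, nb = vol_a.shape[0], vol_b.shape[0]
    if coarse_map is None:
        coarse = {i: int(round(i * (nb - 1) / max(na - 1, 1))) for i in range(na)}
    else:
        coarse = dict(coarse_map)
    best = []
    for i in range(na):
        c = coarse.get(i, int(round(i * (nb - 1) / max(na - 1, 1))))
        lo, hi = max(0, c - window), min(nb, c + window + 1)
        if lo >= hi:
            raise ValueError(f"empty search window for A-slice {i}")
        scores = [abs(_ncc(vol_a[i], vol_b[j])) for j in range(lo, hi)]
        best.append(lo + int(np.argmax(scores)))
    best = np.maximum.accumulate(best)
    pairs = [(i, int(b)) for i, b in enumerate(best)]
    return SliceCorrespondence(pairs=pairs, method="ncc_assist")
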