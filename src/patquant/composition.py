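"""Composition-positive pixel maps and regional percent composition.

For each analysis region the binarized slices are summed pixel-wise: the
resulting integer count (0..S, with S = 3 slices per region) is the
composition-positive value of that pixel for that channel. The same map
divided by S is the averaged tissue-composition map used for topological
visualization — the sum form is canonical here and the average is a derived
view, which keeps the two formulations provably consistent.

Percent composition is taken over valid tissue pixels: the denominator is
the biopsy tissue mask minus artifact-excluded pixels (a whole-frame
denominator would dilute percentages arbitrarily with field of view).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .thresholding import BinaryVolume, otsu_threshold


@dataclass
class CompositionMap:
    """Per-pixel count of positive binarized slices within a region.

    ``counts`` is a 2D integer map in 0..S; ``valid`` excludes artifact and
    out-of-tissue pixels from every downstream denominator.
    """

    counts: np.ndarray
    n_slices: int
    channel: str
    valid: np.ndarray = None  # type: ignore[assignment]
    region_index: int | None = None
    sample_id: str | None = None
    side: str | None = None
    spacing: tuple[float, float] | None = None  # (depth, lateral) mm/px

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("composition map must be 2D")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.counts.max(initial=0) > self.n_slices:
            raise ValueError("counts cannot exceed the number of slices")
        if self.valid is None:
            self.valid = np.ones(self.counts.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.counts.shape:
            raise ValueError("valid mask must match counts geometry")

    @property
    def fraction(self) -> np.ndarray:
        """Averaged-slices view: counts / S, exactly."""
        return self.counts / self.n_slices


def composition_positive_map(
    binaries: list[np.ndarray | BinaryVolume],
    channel: str = "unknown",
    **meta,
) -> CompositionMap:
    """Sum S aligned binarized slices into a composition-positive map.

    The valid mask is the intersection of the per-slice valid masks.
    """
    if len(binaries) == 0:
        raise ValueError("need at least one binarized slice")
    arrays, valids = [], []
    for b in binaries:
        if isinstance(b, BinaryVolume):
            arrays.append(np.asarray(b.data))
            valids.append(b.valid)
        else:
            arrays.append(np.asarray(b))
            valids.append(np.ones(arrays[-1].shape, dtype=bool))
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("slices must share one shape")
    counts = np.zeros(shape, dtype=np.int16)
    for a in arrays:
        counts += a.astype(np.int16)
    valid = np.logical_and.reduce(valids)
    counts[~valid] = 0
    return CompositionMap(
        counts=counts, n_slices=len(arrays), channel=channel, valid=valid, **meta
    )


def tissue_mask(
    channels: list[np.ndarray],
    closing_radius: int = 2,
) -> np.ndarray:
    """Foreground ("inside the biopsy") mask from structural channels.

    Each channel (typically ultrasound or eosin) is Otsu-thresholded; the
    union of foregrounds is morphologically closed, hole-filled, and reduced
    to its largest connected component.
    """
    if len(channels) == 0:
        raise ValueError("need at least one channel")
    fg = None
    for ch in channels:
        ch = np.asarray(ch, dtype=np.float64)
        t = otsu_threshold(ch)
        this = ch > t
        fg = this if fg is None else (fg | this)
    assert fg is not None
    if closing_radius > 0:
        st = ndimage.generate_binary_structure(fg.ndim, 1)
        # pad by replication so closing does not erode at the array border
        r = closing_radius
        fgp = np.pad(fg, r, mode="edge")
        fgp = ndimage.binary_closing(fgp, structure=st, iterations=r)
        fg = fgp[tuple(slice(r, -r) for _ in range(fg.ndim))]
    fg = ndimage.binary_fill_holes(fg)
    labeled, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("empty foreground: no tissue detected in any channel")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return labeled == keep


def percent_composition(
    binary: np.ndarray | BinaryVolume, mask: np.ndarray
) -> float:
    """Percent of valid in-mask pixels that are composition positive."""
    if isinstance(binary, BinaryVolume):
        data, valid = binary.data, binary.valid
    else:
        data = np.asarray(binary)
        valid = np.ones(data.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape:
        raise ValueError("mask must match binary geometry")
    denom = int((mask & valid).sum())
    if denom == 0:
        raise ValueError("zero valid pixels under the mask")
    num = int(((data > 0) & mask & valid).sum())
    return 100.0 * num / denom


@dataclass
class RegionComposition:
    """Tidy record of per-region percent composition for one channel."""

    sample_id: str
    side: str
    region_index: int
    channel: str
    per_slice_percent: list[float]
    per_slice_valid: list[int]
    excluded_fraction: float = 0.0

    @property
    def pooled_percent(self) -> float:
        """Valid-pixel-weighted mean of the per-slice percents."""
        w = np.asarray(self.per_slice_valid, dtype=np.float64)
        p = np.asarray(self.per_slice_percent, dtype=np.float64)
        if w.sum() == 0:
            raise ValueError("no valid pixels in region")
        return float((p * w).sum() / w.sum())


def region_pipeline_counts(
    n_samples: int, n_regions_per_sample: int = 5, n_slices_per_region: int = 3
) -> dict[str, int]:
    """Structural audit of a run: total regions and post-processed images.

    Three samples at five regions of three slices give 15 regions and 45
    images.
    """
    regions = n_samples * n_regions_per_sample
    images = regions * n_slices_per_region
    return {
        "samples": n_samples,
        "regions_per_sample": n_regions_per_sample,
        "slices_per_region": n_slices_per_region,
        "total_regions": regions,
        "total_images": images,
    }
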