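"""Binarization of imaging channels under two schemes.

PAT channels are binarized with Otsu's method — the threshold maximizing the
between-class variance σ²_b(t) = ω₀ω₁(μ₀−μ₁)² of the two resulting pixel
classes. Light-sheet channels use conventional histogram thresholding: a
threshold point is read off the (smoothed) intensity histogram of each
analysis region, the per-region points are averaged, and the average is
applied to the whole dataset. Stitching-seam artifacts excluded from analysis
are carried as masks so that denominators omit them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal


@dataclass
class ThresholdSpec:
    """Record of how a channel was thresholded.

    ``averaged`` is always the arithmetic mean of ``per_region``.
    """

    scheme: str  # "otsu" | "histogram_region_avg"
    per_region: list[float]
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("otsu", "histogram_region_avg"):
            raise ValueError("scheme must be 'otsu' or 'histogram_region_avg'")
        if not self.per_region:
            raise ValueError("at least one per-region threshold point required")

    @property
    def averaged(self) -> float:
        return float(np.mean(self.per_region))


@dataclass
class BinaryVolume:
    """Binarized counterpart of a channel array.

    ``data`` ∈ {0, 1} with the source geometry; voxels under the artifact
    mask are forced to 0 and flagged in ``excluded`` so that downstream
    denominators can omit them.
    """

    data: np.ndarray
    modality: str
    threshold: float
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("binary volume values must be 0 or 1")
        if self.excluded is None:
            self.excluded = np.zeros(self.data.shape, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.excluded.shape != self.data.shape:
            raise ValueError("excluded mask must match data geometry")
        if self.data[self.excluded].any():
            raise ValueError("excluded voxels must be 0")

    @property
    def valid(self) -> np.ndarray:
        return ~self.excluded

    @property
    def excluded_fraction(self) -> float:
        return float(self.excluded.mean())


def otsu_threshold(img: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold on a min–max rescaled ``n_bins`` histogram.

    Returns the bin edge maximizing the between-class variance
    ω₀ω₁(μ₀−μ₁)², on the original intensity scale. Ties break toward the
    lower threshold. A pixel is called positive when its intensity is
    strictly greater than the returned value.
    """
    img = np.asarray(img, dtype=np.float64).ravel()
    lo, hi = float(img.min()), float(img.max())
    if lo == hi:
        raise ValueError("constant image has no Otsu threshold")
    counts, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    sums, _ = np.histogram(img, bins=n_bins, range=(lo, hi), weights=img)
    p = counts / counts.sum()

    w0 = np.cumsum(p)  # weight of class {bins <= t}
    w1 = 1.0 - w0
    # exact class means: per-bin intensity sums, not bin centers
    sum0 = np.cumsum(sums)
    n0 = np.cumsum(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / n0
        mu1 = (sum0[-1] - sum0) / (n0[-1] - n0)
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-np.inf)
    # candidate threshold after bin t is the upper edge of bin t; a pixel is
    # positive iff its bin index exceeds t, so nudge below the edge to keep
    # strict > consistent with edge-valued pixels
    t = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(np.nextafter(edges[t + 1], -np.inf))


def histogram_region_threshold(
    img_region: np.ndarray,
    bandwidth: float = 3.0,
    n_bins: int = 256,
    fallback_percentile: float = 95.0,
) -> float:
    """Threshold point from a region's smoothed intensity histogram.

    The histogram is smoothed with a Gaussian kernel of ``bandwidth`` bins;
    the threshold is the deepest valley between the two most prominent modes.
    Unimodal regions fall back to the configured intensity percentile with a
    warning.
    """
    img = np.asarray(img_region, dtype=np.float64).ravel()
    lo, hi = float(img.min()), float(img.max())
    if lo == hi:
        raise ValueError("constant region has no histogram threshold")
    counts, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    smooth = ndimage.gaussian_filter1d(counts.astype(np.float64), sigma=bandwidth)
    centers = (edges[:-1] + edges[1:]) / 2.0

    peaks, props = signal.find_peaks(smooth, prominence=smooth.max() * 0.05)
    if len(peaks) < 2:
        warnings.warn(
            "unimodal region histogram; falling back to the "
            f"{fallback_percentile:g}th percentile",
            stacklevel=2,
        )
        return float(np.percentile(img, fallback_percentile))
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    a, b = int(top2.min()), int(top2.max())
    between = smooth[a : b + 1]
    # the valley may be a flat trough; take the midpoint of the minimal run
    vmin = between.min()
    flat = np.flatnonzero(between <= vmin + 1e-12 * max(vmin, 1.0))
    valley = a + int(round(flat.mean()))
    return float(centers[valley])


def average_and_apply(
    thresholds: list[float] | ThresholdSpec,
    data: np.ndarray,
    artifact_mask: np.ndarray | None = None,
    modality: str = "unknown",
    positive: str = "above",
) -> BinaryVolume:
    """Average per-region threshold points and binarize a whole dataset.

    ``positive="above"`` marks intensity strictly greater than the averaged
    threshold (PAT lipid/hemoglobin, nuclei); ``"below"`` marks intensity
    strictly less (eosin-dim lipid pixels in the light-sheet channel).
    Artifact-masked voxels are zeroed and recorded as excluded.
    """
    if isinstance(thresholds, ThresholdSpec):
        t = thresholds.averaged
    else:
        if len(thresholds) == 0:
            raise ValueError("empty threshold list")
        t = float(np.mean(thresholds))
    if positive not in ("above", "below"):
        raise ValueError("positive must be 'above' or 'below'")
    data = np.asarray(data, dtype=np.float64)
    binary = (data > t) if positive == "above" else (data < t)
    binary = binary.astype(np.uint8)
    if artifact_mask is not None:
        artifact_mask = np.asarray(artifact_mask, dtype=bool)
        if artifact_mask.shape != data.shape:
            raise ValueError("artifact mask must match data geometry")
        binary[artifact_mask] = 0
    return BinaryVolume(
        data=binary, modality=modality, threshold=t,
        excluded=artifact_mask if artifact_mask is not None
        else np.zeros(data.shape, dtype=bool),
    )
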