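"""Virtual H&E pseudo-coloring of two-channel light-sheet slices.

A Beer–Lambert absorbance model turns co-registered eosin and nuclei
fluorescence into an H&E-like RGB image for visual QC:

    RGB = exp(−(k_H · nuclei · OD_H + k_E · eosin · OD_E))

with the standard hematoxylin and eosin optical-density color vectors. Zero
input transmits everything (white); each channel darkens its stain's hue
monotonically. This operator is a visual-QC device only and is excluded from
every quantitative path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# standard stain optical-density vectors (R, G, B)
OD_HEMATOXYLIN = np.array([0.65, 0.70, 0.29])
OD_EOSIN = np.array([0.07, 0.99, 0.11])


@dataclass
class RGBSlice:
    """H&E-like RGB image in [0, 1] with its provenance."""

    rgb: np.ndarray
    gains: tuple[float, float]
    source: str = ""

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.float64)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be (H, W, 3)")
        if self.rgb.min() < 0 or self.rgb.max() > 1:
            raise ValueError("rgb values must lie in [0, 1]")


def pseudo_color_he(
    eosin: np.ndarray,
    nuclei: np.ndarray,
    gains: tuple[float, float] = (1.5, 1.0),
    normalize: bool = True,
    source: str = "",
) -> RGBSlice:
    """Convert eosin + nuclei fluorescence to an H&E-like RGB slice.

    ``gains = (k_H, k_E)`` scale the two absorbances. With ``normalize`` each
    input is scaled by its own maximum (if positive) before the mapping so
    gains act on a common [0, 1] footing.
    """
    eosin = np.asarray(eosin, dtype=np.float64)
    nuclei = np.asarray(nuclei, dtype=np.float64)
    if eosin.shape != nuclei.shape:
        raise ValueError("eosin and nuclei slices must share one shape")
    if eosin.ndim != 2:
        raise ValueError("inputs must be 2D slices")
    if (eosin < 0).any() or (nuclei < 0).any():
        raise ValueError("fluorescence inputs must be non-negative")
    if normalize:
        if eosin.max() > 0:
            eosin = eosin / eosin.max()
        if nuclei.max() > 0:
            nuclei = nuclei / nuclei.max()
    k_h, k_e = gains
    od = (
        k_h * nuclei[..., None] * OD_HEMATOXYLIN[None, None, :]
        + k_e * eosin[..., None] * OD_EOSIN[None, None, :]
    )
    rgb = np.exp(-od)
    return RGBSlice(rgb=np.clip(rgb, 0.0, 1.0), gains=(float(k_h), float(k_e)), source=source)


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Rec. 709 luma of an RGB image."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return 0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1] + 0.0722 * rgb[..., 2]
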