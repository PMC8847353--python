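"""Ordinal ROI scoring of composition maps and ROC analysis of the scores.

Square 0.66 × 0.66 mm regions of interest — one third of the 2 mm imaging
depth — are placed in cancerous and non-cancerous tissue and scored 1–3 from
the composition-positive pixel counts under two rubrics:

* vascular/lipid rubric (PAT lipid, iSPIM lipid, PAT hemoglobin):
  score 1 — no contrast anywhere in the ROI;
  score 3 — pixels with count ≥ 2 compose at least 50% of the valid ROI;
  score 2 — otherwise (some positive pixels, 50% criterion not met).
* nuclei rubric (iSPIM DRAQ5): score 1 — no cellular content;
  score 3 — any pixel with count ≥ 2; score 2 — positives at count 1 only.

The rubric clauses overlap as written; they are resolved by precedence
(3 checked first, then 2, then 1), the only reading under which each ROI
receives exactly one score. Scores feed a rank-based ROC AUC
(Mann–Whitney with ties counted ½); for lipid channels the polarity is
inverted — low lipid marks cancerous tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import CompositionMap

ROI_SIDE_MM_DEFAULT = 0.66  # one third of the 2 mm imaging depth, as printed
ROI_CLASSES = ("cancerous", "non_cancerous")


@dataclass(frozen=True)
class ROIBox:
    """A square in-plane region in physical units with a class label."""

    sample_id: str
    side: str
    region_index: int
    origin_mm: tuple[float, float]  # (depth, lateral) of the box corner
    side_mm: float = ROI_SIDE_MM_DEFAULT
    label: str = "non_cancerous"

    def __post_init__(self) -> None:
        if self.side_mm <= 0:
            raise ValueError("ROI side length must be positive")
        if self.label not in ROI_CLASSES:
            raise ValueError(f"label must be one of {ROI_CLASSES}")

    def pixel_window(self, spacing: tuple[float, float]) -> tuple[slice, slice]:
        """Half-open pixel slices covering the box on a map with ``spacing``."""
        sl = []
        for o, s in zip(self.origin_mm, spacing):
            start = int(round(o / s))
            n = max(1, int(round(self.side_mm / s)))
            sl.append(slice(start, start + n))
        return sl[0], sl[1]


@dataclass
class ROIScore:
    """Ordinal 1–3 score of one ROI under one rubric, with the supporting
    pixel fractions (count ≥ 2 and count ≥ 1) it was derived from."""

    roi: ROIBox
    channel: str
    rubric: str  # "vascular_lipid" | "nuclei"
    score: int
    frac_ge2: float
    frac_ge1: float

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3):
            raise ValueError("score must be 1, 2 or 3")
        for f in (self.frac_ge2, self.frac_ge1):
            if not 0.0 <= f <= 1.0:
                raise ValueError("supporting fractions must lie in [0, 1]")


MIN_VALID_FRACTION = 0.5  # ROIs mostly under an artifact mask are rejected


def _roi_counts(cmap: CompositionMap, roi: ROIBox) -> tuple[np.ndarray, np.ndarray]:
    spacing = cmap.spacing or (1.0, 1.0)
    win = roi.pixel_window(spacing)
    if (
        win[0].start < 0 or win[1].start < 0
        or win[0].stop > cmap.counts.shape[0] or win[1].stop > cmap.counts.shape[1]
    ):
        raise ValueError(f"ROI at {roi.origin_mm} mm extends outside the composition map")
    counts = cmap.counts[win]
    valid = cmap.valid[win]
    if valid.sum() == 0 or valid.mean() < MIN_VALID_FRACTION:
        raise ValueError("ROI has fewer than 50% valid (unmasked) pixels")
    return counts, valid


def _fracs(counts: np.ndarray, valid: np.ndarray) -> tuple[float, float]:
    n = valid.sum()
    return float((counts[valid] >= 2).sum() / n), float((counts[valid] >= 1).sum() / n)


def score_roi_vascular_lipid(cmap: CompositionMap, roi: ROIBox) -> ROIScore:
    """Score an ROI under the lipid/hemoglobin rubric (precedence 3→2→1)."""
    counts, valid = _roi_counts(cmap, roi)
    f2, f1 = _fracs(counts, valid)
    if f2 >= 0.5:
        score = 3
    elif f1 > 0:
        score = 2
    else:
        score = 1
    return ROIScore(roi=roi, channel=cmap.channel, rubric="vascular_lipid",
                    score=score, frac_ge2=f2, frac_ge1=f1)


def score_roi_nuclei(cmap: CompositionMap, roi: ROIBox) -> ROIScore:
    """Score an ROI under the nuclei rubric (precedence 3→2→1)."""
    counts, valid = _roi_counts(cmap, roi)
    f2, f1 = _fracs(counts, valid)
    if f2 > 0:
        score = 3
    elif f1 > 0:
        score = 2
    else:
        score = 1
    return ROIScore(roi=roi, channel=cmap.channel, rubric="nuclei",
                    score=score, frac_ge2=f2, frac_ge1=f1)


def score_roi(cmap: CompositionMap, roi: ROIBox, rubric: str) -> ROIScore:
    if rubric == "vascular_lipid":
        return score_roi_vascular_lipid(cmap, roi)
    if rubric == "nuclei":
        return score_roi_nuclei(cmap, roi)
    raise ValueError(f"unknown rubric {rubric!r}")


# ---------------------------------------------------------------------------
# ROI placement on phantoms
# ---------------------------------------------------------------------------


@dataclass
class PlacementSpec:
    """How many ROIs of each class to place and on what content."""

    n_cancerous: int = 20
    n_non_cancerous: int = 30
    side_mm: float = ROI_SIDE_MM_DEFAULT


def place_rois(
    label_maps: dict[tuple[str, str, int], np.ndarray],
    spacing: tuple[float, float],
    spec: PlacementSpec,
    seed: int,
    carcinoma_label: int,
    content_labels: tuple[int, ...],
    background_label: int = 0,
) -> list[ROIBox]:
    """Automated, seed-reproducible ROI placement from phantom truth labels.

    ``label_maps`` maps (sample_id, side, region_index) → 2D truth-label map
    on the composition-map grid. Cancerous ROIs are centered on
    carcinoma-labeled pixels; non-cancerous ROIs are centered on pixels of
    the stated content classes with no carcinoma inside the box. Boxes are
    non-overlapping (within a map) and fully in bounds.
    """
    rng = np.random.default_rng(seed)
    n_px = None
    candidates: dict[str, list[tuple[tuple[str, str, int], int, int]]] = {
        "cancerous": [],
        "non_cancerous": [],
    }
    keys = sorted(label_maps.keys())
    for key in keys:
        lab = label_maps[key]
        n_px = max(1, int(round(spec.side_mm / spacing[0])))
        half = n_px // 2
        inb = np.zeros(lab.shape, dtype=bool)
        if lab.shape[0] > n_px and lab.shape[1] > n_px:
            inb[half : lab.shape[0] - (n_px - half), half : lab.shape[1] - (n_px - half)] = True
        carc = lab == carcinoma_label
        content = np.isin(lab, content_labels)
        for i, j in np.argwhere(carc & inb):
            candidates["cancerous"].append((key, int(i), int(j)))
        for i, j in np.argwhere(content & ~carc & inb):
            candidates["non_cancerous"].append((key, int(i), int(j)))
    if n_px is None:
        raise ValueError("no label maps supplied")

    placed: list[ROIBox] = []
    occupied: dict[tuple[str, str, int], np.ndarray] = {
        key: np.zeros(label_maps[key].shape, dtype=bool) for key in keys
    }
    half = n_px // 2
    for cls, want in (("cancerous", spec.n_cancerous), ("non_cancerous", spec.n_non_cancerous)):
        pool = candidates[cls]
        order = rng.permutation(len(pool))
        got = 0
        for idx in order:
            if got >= want:
                break
            key, i, j = pool[idx]
            lab = label_maps[key]
            i0, j0 = i - half, j - half
            win = (slice(i0, i0 + n_px), slice(j0, j0 + n_px))
            if occupied[key][win].any():
                continue
            box_lab = lab[win]
            if cls == "non_cancerous" and (box_lab == carcinoma_label).any():
                continue
            if (box_lab == background_label).mean() > 0.5:
                continue
            occupied[key][win] = True
            placed.append(
                ROIBox(
                    sample_id=key[0], side=key[1], region_index=key[2],
                    origin_mm=(i0 * spacing[0], j0 * spacing[1]),
                    side_mm=spec.side_mm, label=cls,
                )
            )
            got += 1
        if got < want:
            raise ValueError(
                f"insufficient qualifying area: placed {got}/{want} {cls} ROIs"
            )
    return placed


# ---------------------------------------------------------------------------
# ROC AUC from ordinal scores
# ---------------------------------------------------------------------------


def auc_from_scores(
    scores: list[int] | np.ndarray,
    labels: list[str] | np.ndarray,
    polarity: str = "higher_positive",
) -> float:
    """Rank-based ROC AUC of ordinal scores for the cancerous class.

    AUC = Mann–Whitney U / (n₁ n₀) with ties counted ½. With
    ``polarity="lower_positive"`` a *low* score indicates the positive
    (cancerous) class — the lipid channels' direction, since cancer is
    lipid-poor.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if polarity not in ("higher_positive", "lower_positive"):
        raise ValueError("polarity must be 'higher_positive' or 'lower_positive'")
    pos = labels == "cancerous"
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    s = -scores if polarity == "lower_positive" else scores
    ranks = rankdata(s)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
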