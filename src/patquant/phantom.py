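"""Synthetic co-registered multimodal breast-biopsy phantoms.

Generates a ground-truth tissue model of a fixed breast-biopsy block —
adipose lobules, fibrous stroma, milk ducts with nuclei-dense walls,
carcinoma foci (stroma-rich, lipid-poor, nuclei-dense) and blood vessels —
and renders the five imaging channels acquired from it on both the anterior
and posterior side:

* PAT at 1210 nm (lipid), 1100 nm (hemoglobin) and 1400 nm (off-resonance
  control), with single-exponential fluence decay in depth and an anisotropic
  Gaussian point-spread stand-in for a 40 MHz transducer;
* iSPIM eosin (stroma-bright, adipose-dim) and DRAQ5 nuclei channels, with an
  optional periodic multiplicative stripe emulating light-sheet stitching
  seams;
* ultrasound as a class-dependent echogenicity map under multiplicative
  speckle (used only for tissue-mask plumbing, never scored).

Geometry primitives are deliberately simple and seed-reproducible: lobules
and foci are overlapping random spheres, ducts and vessels are random-walk
tubes. All randomness flows from one seeded generator, so a fixed seed gives
bit-identical output.

Axis order everywhere is ``(scan, depth, lateral)``; the truth grid is the
(working-resolution) iSPIM grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage

from .volume_io import PAT_WAVELENGTHS_NM, ChannelVolume, resample_to_grid

# tissue class labels
BACKGROUND, ADIPOSE, STROMA, DUCT_LUMEN, DUCT_WALL, CARCINOMA, VESSEL = range(7)
CLASS_NAMES = {
    BACKGROUND: "background",
    ADIPOSE: "adipose",
    STROMA: "stroma",
    DUCT_LUMEN: "duct_lumen",
    DUCT_WALL: "duct_wall",
    CARCINOMA: "carcinoma",
    VESSEL: "vessel",
}


@dataclass
class PhantomParams:
    """Parameters of the synthetic biopsy block.

    All lengths in millimetres, axis order (scan, depth, lateral). Defaults
    emulate the ~5.3 × 2.0 × 4.7 mm cleared-biopsy volume imaged from both
    sides: the scan axis is stepped at the 0.193 mm motor pitch and depth is
    limited to the 2 mm clearing/imaging window per side.

    The per-class chromophore levels and nuclei densities are free modelling
    parameters (no instrument calibration exists for them); they are chosen to
    give the qualitative ordering the tissue types show in virtual histology:
    lipid high in adipose and absent in carcinoma, hemoglobin confined to
    vessels, nuclei density carcinoma ≈ duct wall >> stroma > adipose.
    """

    extent_mm: tuple[float, float, float] = (5.34, 1.98, 4.71)
    pat_spacing: tuple[float, float, float] = (0.193, 0.05, 0.05)
    ispim_spacing: tuple[float, float, float] = (0.02, 0.02, 0.02)

    # target volume fractions of tissue (remainder is stroma)
    class_fractions: dict = field(
        default_factory=lambda: {
            "adipose": 0.30,
            "carcinoma": 0.08,
            "duct": 0.04,
            "vessel": 0.015,
        }
    )
    carcinoma_focus_count: int = 3
    carcinoma_radius_mm: tuple[float, float] = (0.35, 0.6)
    adipose_lobule_radius_mm: tuple[float, float] = (0.25, 0.55)
    vessel_count: int = 4
    vessel_radius_mm: float = 0.08
    duct_count: int = 3
    duct_lumen_radius_mm: float = 0.12
    duct_wall_thickness_mm: float = 0.06

    # nuclei per mm^3 of each class
    nuclei_density_per_mm3: dict = field(
        default_factory=lambda: {
            "carcinoma": 8000.0,
            "duct_wall": 8000.0,
            "stroma": 600.0,
            "adipose": 100.0,
        }
    )

    # optics / acoustics
    fluence_decay_mm: float = 4.0
    pat_psf_sigma_mm: tuple[float, float, float] = (0.12, 0.04, 0.08)
    ispim_psf_sigma_mm: float = 0.012
    nuclei_spot_sigma_mm: float = 0.012

    # chromophore levels (arbitrary units in [0, 1])
    lipid_adipose: float = 0.9
    lipid_stroma: float = 0.0
    hemoglobin_vessel: float = 0.9

    # channel noise standard deviations (additive, on [0, 1]-scaled signal)
    noise_sd: dict = field(
        default_factory=lambda: {
            "pat_lipid": 0.03,
            "pat_hemoglobin": 0.03,
            "pat_off": 0.03,
            "ispim_eosin": 0.03,
            "ispim_nuclei": 0.02,
            "ultrasound": 0.0,
        }
    )
    speckle_variance: float = 0.3
    stripe_amplitude: float = 0.0
    stripe_period_mm: float = 0.68

    tissue_margin_mm: float = 0.12
    imaging_depth_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent_mm):
            raise ValueError("extents must be strictly positive")
        for sp in (self.pat_spacing, self.ispim_spacing):
            if any(s <= 0 for s in sp):
                raise ValueError("spacings must be strictly positive")
        fr = self.class_fractions
        if any(not (0.0 <= v <= 1.0) for v in fr.values()):
            raise ValueError("class fractions must lie in [0, 1]")
        if sum(fr.values()) > 1.0 + 1e-12:
            raise ValueError(
                f"class fractions sum to {sum(fr.values()):.3f} > 1; "
                "the stroma remainder would be negative"
            )
        if self.fluence_decay_mm <= 0:
            raise ValueError("fluence decay length must be positive (use np.inf for none)")

    @property
    def truth_shape(self) -> tuple[int, int, int]:
        return tuple(
            max(1, int(round(e / s))) for e, s in zip(self.extent_mm, self.ispim_spacing)
        )  # type: ignore[return-value]

    @property
    def pat_shape(self) -> tuple[int, int, int]:
        return tuple(
            max(1, int(round(e / s))) for e, s in zip(self.extent_mm, self.pat_spacing)
        )  # type: ignore[return-value]


@dataclass
class PhantomTruth:
    """Ground truth: label volume, chromophore maps, nuclei points, tissue mask.

    ``labels`` holds one integer tissue class per voxel on the truth grid;
    ``lipid`` and ``hemoglobin`` are concentration maps in [0, 1];
    ``nuclei_xyz_mm`` is an (N, 3) array of nucleus centers in mm (scan,
    depth, lateral); ``tissue_mask`` is True inside the biopsy block.
    """

    labels: np.ndarray
    lipid: np.ndarray
    hemoglobin: np.ndarray
    nuclei_xyz_mm: np.ndarray
    tissue_mask: np.ndarray
    spacing: tuple[float, float, float]

    def class_fraction(self, label: int) -> float:
        """Fraction of tissue voxels carrying ``label``."""
        tissue = int(self.tissue_mask.sum())
        if tissue == 0:
            return 0.0
        return float((self.labels == label).sum()) / tissue


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _sphere_mask(shape, center_vox, radius_vox) -> tuple[slice, ...] | None:
    """Bounding-box slices and boolean ball for a sphere; None if empty."""
    lo = [max(0, int(np.floor(c - r - 1))) for c, r in zip(center_vox, radius_vox)]
    hi = [min(n, int(np.ceil(c + r + 2))) for n, c, r in zip(shape, center_vox, radius_vox)]
    if any(l >= h for l, h in zip(lo, hi)):
        return None
    grids = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_vox, radius_vox))
    ball = d2 <= 1.0
    return (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2])), ball  # type: ignore[return-value]


def _paint_spheres_to_fraction(
    labels: np.ndarray,
    tissue: np.ndarray,
    label: int,
    target_fraction: float,
    radius_range_mm: tuple[float, float],
    spacing: tuple[float, float, float],
    rng: np.random.Generator,
    min_count: int = 0,
    max_count: int = 10000,
    paintable: Iterable[int] = (STROMA,),
) -> None:
    """Add random spheres of ``label`` until its tissue fraction reaches target."""
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        return
    paintable_set = set(paintable)
    count = 0
    shape = labels.shape
    while count < max_count:
        frac = float((labels == label).sum()) / n_tissue
        if count >= min_count and frac >= target_fraction:
            break
        if target_fraction <= 0 and count >= min_count:
            break
        r_mm = rng.uniform(*radius_range_mm)
        center_mm = [rng.uniform(r_mm, e - r_mm) if e > 2 * r_mm else e / 2
                     for e in (shape[0] * spacing[0], shape[1] * spacing[1], shape[2] * spacing[2])]
        center_vox = [c / s - 0.5 for c, s in zip(center_mm, spacing)]
        radius_vox = [r_mm / s for s in spacing]
        res = _sphere_mask(shape, center_vox, radius_vox)
        count += 1
        if res is None:
            continue
        box, ball = res
        region = labels[box]
        sel = ball & tissue[box] & np.isin(region, list(paintable_set))
        region[sel] = label


def _random_walk_tube(
    labels: np.ndarray,
    tissue: np.ndarray,
    label: int,
    radius_mm: float,
    spacing: tuple[float, float, float],
    rng: np.random.Generator,
    n_steps: int = 40,
    step_mm: float = 0.15,
    paintable: Iterable[int] = (STROMA, ADIPOSE),
) -> np.ndarray:
    """Paint a random-walk tube; returns the tube's boolean mask."""
    shape = labels.shape
    extent = [n * s for n, s in zip(shape, spacing)]
    pos = np.array([rng.uniform(0.15 * e, 0.85 * e) for e in extent])
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    tube = np.zeros(shape, dtype=bool)
    radius_vox = [radius_mm / s for s in spacing]
    for _ in range(n_steps):
        center_vox = [p / s - 0.5 for p, s in zip(pos, spacing)]
        res = _sphere_mask(shape, center_vox, radius_vox)
        if res is not None:
            box, ball = res
            tube[box] |= ball
        direction = direction + 0.4 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = pos + step_mm * direction
        pos = np.clip(pos, [0.05 * e for e in extent], [0.95 * e for e in extent])
    sel = tube & tissue & np.isin(labels, list(set(paintable)))
    labels[sel] = label
    tube &= sel | (labels == label)
    return tube


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------


def generate_truth(params: PhantomParams, rng: np.random.Generator) -> PhantomTruth:
    """Build the ground-truth label volume, chromophore maps and nuclei set."""
    shape = params.truth_shape
    sp = params.ispim_spacing
    labels = np.zeros(shape, dtype=np.uint8)

    # tissue block: full extent inset by a margin on lateral/scan faces and
    # the far depth face (the anterior surface is the cut face at depth 0)
    m = [max(0, int(round(params.tissue_margin_mm / s))) for s in sp]
    tissue = np.zeros(shape, dtype=bool)
    tissue[
        m[0] : shape[0] - m[0] or None,
        0 : shape[1] - m[1] or None,
        m[2] : shape[2] - m[2] or None,
    ] = True
    labels[tissue] = STROMA

    fr = params.class_fractions
    # paint order: ducts, carcinoma foci (which may engulf duct tissue, as
    # DCIS→IDC does), then adipose lobules on the remaining stroma, then
    # vessels — later classes never repaint earlier ones, so the fraction
    # targets of the classes controlled by fraction are met directly
    duct_frac = fr.get("duct", 0.0)
    if duct_frac > 0 and params.duct_count > 0:
        for _ in range(params.duct_count):
            wall_r = params.duct_lumen_radius_mm + params.duct_wall_thickness_mm
            tube = _random_walk_tube(
                labels, tissue, DUCT_WALL, wall_r, sp, rng, n_steps=30, step_mm=0.12
            )
            # carve the lumen inside the wall
            er = [max(1, int(round(params.duct_wall_thickness_mm / s))) for s in sp]
            lumen = ndimage.binary_erosion(
                tube, structure=np.ones((2 * er[0] + 1, 2 * er[1] + 1, 2 * er[2] + 1), bool)
            )
            labels[lumen & tissue] = DUCT_LUMEN
            if labels[tissue].size and (np.isin(labels, [DUCT_WALL, DUCT_LUMEN]).sum()
                                        / tissue.sum()) >= duct_frac:
                break

    carc_frac = fr.get("carcinoma", 0.0)
    if carc_frac > 0 and params.carcinoma_focus_count > 0:
        _paint_spheres_to_fraction(
            labels, tissue, CARCINOMA, carc_frac, params.carcinoma_radius_mm, sp, rng,
            min_count=params.carcinoma_focus_count,
            paintable=(STROMA, DUCT_WALL, DUCT_LUMEN),
        )

    _paint_spheres_to_fraction(
        labels, tissue, ADIPOSE, fr.get("adipose", 0.0),
        params.adipose_lobule_radius_mm, sp, rng,
    )

    vessel_frac = fr.get("vessel", 0.0)
    if vessel_frac > 0 and params.vessel_count > 0:
        for _ in range(params.vessel_count):
            _random_walk_tube(
                labels, tissue, VESSEL, params.vessel_radius_mm, sp, rng,
                n_steps=50, step_mm=0.12,
                paintable=(STROMA, ADIPOSE, CARCINOMA),
            )
            if (labels == VESSEL).sum() / tissue.sum() >= vessel_frac:
                break

    lipid = np.zeros(shape, dtype=np.float32)
    lipid[labels == ADIPOSE] = params.lipid_adipose
    if params.lipid_stroma > 0:
        lipid[labels == STROMA] = params.lipid_stroma
    hemoglobin = np.zeros(shape, dtype=np.float32)
    hemoglobin[labels == VESSEL] = params.hemoglobin_vessel

    nuclei = _sample_nuclei(labels, params, rng)

    return PhantomTruth(
        labels=labels,
        lipid=lipid,
        hemoglobin=hemoglobin,
        nuclei_xyz_mm=nuclei,
        tissue_mask=tissue,
        spacing=sp,
    )


_NUCLEI_CLASS = {
    "carcinoma": CARCINOMA,
    "duct_wall": DUCT_WALL,
    "stroma": STROMA,
    "adipose": ADIPOSE,
}


def _sample_nuclei(
    labels: np.ndarray, params: PhantomParams, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-sample nucleus centers per class, uniform within class voxels."""
    sp = params.ispim_spacing
    voxel_mm3 = sp[0] * sp[1] * sp[2]
    pts = []
    for name, density in sorted(params.nuclei_density_per_mm3.items()):
        label = _NUCLEI_CLASS.get(name)
        if label is None or density <= 0:
            continue
        idx = np.argwhere(labels == label)
        if idx.size == 0:
            continue
        n = rng.poisson(density * voxel_mm3 * len(idx))
        if n == 0:
            continue
        chosen = idx[rng.integers(0, len(idx), size=n)]
        jitter = rng.uniform(0.0, 1.0, size=chosen.shape)
        pts.append((chosen + jitter) * np.asarray(sp))
    if not pts:
        return np.empty((0, 3), dtype=np.float64)
    return np.concatenate(pts, axis=0)


# ---------------------------------------------------------------------------
# channel rendering
# ---------------------------------------------------------------------------

PAT_ROLES = {"lipid": "pat_lipid", "hemoglobin": "pat_hemoglobin", "off_resonance": "pat_off"}


def _depth_mm(shape_depth: int, spacing_depth: float) -> np.ndarray:
    """Depth coordinate (mm) of voxel centers along the depth axis."""
    return (np.arange(shape_depth) + 0.5) * spacing_depth


def _oriented(volume: np.ndarray, side: str) -> np.ndarray:
    """View of the truth volume with depth measured from the imaged surface."""
    return volume if side == "anterior" else volume[:, ::-1, :]


def _crop_depth_vox(shape_depth: int, spacing_depth: float, depth_mm: float) -> int:
    n = int(np.sum(_depth_mm(shape_depth, spacing_depth) < depth_mm - 1e-12))
    return max(1, n)


def render_pat_channel(
    truth: PhantomTruth,
    role: str,
    params: PhantomParams,
    side: str = "anterior",
    rng: np.random.Generator | None = None,
) -> ChannelVolume:
    """Render one PAT wavelength channel from the phantom truth.

    Signal model: chromophore concentration × exp(−depth / fluence decay
    length), blurred with the anisotropic PSF, downsampled to the PAT grid,
    plus zero-mean Gaussian noise, clipped to non-negative. The off-resonance
    role uses zero concentration everywhere (noise only).
    """
    if role not in PAT_ROLES:
        raise ValueError(f"unknown PAT role {role!r}; expected one of {sorted(PAT_ROLES)}")
    modality = PAT_ROLES[role]
    if rng is None:
        rng = np.random.default_rng(params.seed)

    conc = {"lipid": truth.lipid, "hemoglobin": truth.hemoglobin,
            "off_resonance": np.zeros_like(truth.lipid)}[role]
    conc = _oriented(conc, side).astype(np.float64)

    sp = truth.spacing
    decay = params.fluence_decay_mm
    if np.isfinite(decay):
        fluence = np.exp(-_depth_mm(conc.shape[1], sp[1]) / decay)
        signal = conc * fluence[None, :, None]
    else:
        signal = conc
    sigma_vox = [s / p for s, p in zip(params.pat_psf_sigma_mm, sp)]
    signal = ndimage.gaussian_filter(signal, sigma=sigma_vox)

    # crop each side to the imaging depth, then resample to the PAT grid
    nd = _crop_depth_vox(signal.shape[1], sp[1], params.imaging_depth_mm)
    signal = signal[:, :nd, :]
    interim = ChannelVolume(signal, sp, modality, side, PAT_WAVELENGTHS_NM.get(modality))
    pat_shape = (
        params.pat_shape[0],
        _crop_depth_vox(params.pat_shape[1], params.pat_spacing[1], params.imaging_depth_mm),
        params.pat_shape[2],
    )
    vol = resample_to_grid(interim, pat_shape, params.pat_spacing)

    sd = params.noise_sd.get(modality, 0.0)
    data = vol.data
    if sd > 0:
        data = data + rng.normal(0.0, sd, size=data.shape)
    data = np.clip(data, 0.0, None)
    return vol.with_data(data)


def render_ispim_channels(
    truth: PhantomTruth,
    params: PhantomParams,
    side: str = "anterior",
    rng: np.random.Generator | None = None,
) -> tuple[ChannelVolume, ChannelVolume]:
    """Render the eosin (stroma) and DRAQ5 (nuclei) light-sheet channels.

    Eosin is bright in stroma, duct wall and carcinoma, dim in adipose (lipid
    displaces the eosinophilic matrix). The nuclei channel is a sum of
    Gaussian spots at the sampled nucleus centers. Both may carry a periodic
    multiplicative stripe along the lateral axis emulating stitching seams.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sp = truth.spacing
    labels = _oriented(truth.labels, side)
    nd = _crop_depth_vox(labels.shape[1], sp[1], params.imaging_depth_mm)
    labels = labels[:, :nd, :]

    eosin_level = np.zeros(7)
    eosin_level[STROMA] = 0.80
    eosin_level[DUCT_WALL] = 0.90
    eosin_level[CARCINOMA] = 0.85
    eosin_level[ADIPOSE] = 0.10
    eosin_level[DUCT_LUMEN] = 0.05
    eosin_level[VESSEL] = 0.30
    eosin = eosin_level[labels]

    sigma_vox = [params.ispim_psf_sigma_mm / s for s in sp]
    eosin = ndimage.gaussian_filter(eosin, sigma=sigma_vox)

    # nuclei: deposit unit mass per nucleus then blur to spot size
    nuc = np.zeros(labels.shape, dtype=np.float64)
    pts = truth.nuclei_xyz_mm
    if pts.size:
        pts = pts.copy()
        if side == "posterior":
            full_depth = truth.labels.shape[1] * sp[1]
            pts[:, 1] = full_depth - pts[:, 1]
        vox = np.floor(pts / np.asarray(sp)).astype(int)
        inb = np.all((vox >= 0) & (vox < np.asarray(labels.shape)), axis=1)
        vox = vox[inb]
        np.add.at(nuc, (vox[:, 0], vox[:, 1], vox[:, 2]), 1.0)
        spot_vox = [params.nuclei_spot_sigma_mm / s for s in sp]
        nuc = ndimage.gaussian_filter(nuc, sigma=spot_vox)
        peak = nuc.max()
        if peak > 0:
            nuc = nuc / peak

    if params.stripe_amplitude > 0:
        lat_mm = (np.arange(labels.shape[2]) + 0.5) * sp[2]
        stripe = 1.0 + params.stripe_amplitude * np.sin(
            2 * np.pi * lat_mm / params.stripe_period_mm
        )
        eosin = eosin * stripe[None, None, :]
        nuc = nuc * stripe[None, None, :]

    out = []
    for data, modality, wl in ((eosin, "ispim_eosin", 488), (nuc, "ispim_nuclei", 647)):
        sd = params.noise_sd.get(modality, 0.0)
        if sd > 0:
            data = data + rng.normal(0.0, sd, size=data.shape)
        out.append(ChannelVolume(np.clip(data, 0.0, None), sp, modality, side, wl))
    return out[0], out[1]


ECHOGENICITY = np.array([0.0, 0.5, 0.65, 0.05, 0.75, 0.7, 0.3])  # per class label


def render_ultrasound(
    truth: PhantomTruth,
    params: PhantomParams,
    side: str = "anterior",
    rng: np.random.Generator | None = None,
) -> ChannelVolume:
    """Render a B-mode-like channel: echogenicity map × multiplicative speckle.

    Duct lumina are hypoechoic, background is zero. Used for tissue-mask
    plumbing and visual co-registration only — never for scoring.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sp = truth.spacing
    labels = _oriented(truth.labels, side)
    nd = _crop_depth_vox(labels.shape[1], sp[1], params.imaging_depth_mm)
    labels = labels[:, :nd, :]
    echo = ECHOGENICITY[labels]
    interim = ChannelVolume(echo, sp, "ultrasound", side)
    pat_shape = (
        params.pat_shape[0],
        _crop_depth_vox(params.pat_shape[1], params.pat_spacing[1], params.imaging_depth_mm),
        params.pat_shape[2],
    )
    vol = resample_to_grid(interim, pat_shape, params.pat_spacing)
    data = vol.data
    if params.speckle_variance > 0:
        k = 1.0 / params.speckle_variance
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=data.shape)
        data = data * speckle
    sd = params.noise_sd.get("ultrasound", 0.0)
    if sd > 0:
        data = data + rng.normal(0.0, sd, size=data.shape)
    return vol.with_data(np.clip(data, 0.0, None))


def generate_phantom(
    params: PhantomParams,
) -> tuple[PhantomTruth, dict[str, ChannelVolume], dict[str, ChannelVolume]]:
    """Generate truth plus the five rendered channels for each biopsy side.

    Returns ``(truth, anterior, posterior)`` where each side is a dict keyed
    by modality tag. Anterior and posterior view the same truth from opposite
    depth directions, each cropped to the imaging depth.
    """
    rng = np.random.default_rng(params.seed)
    truth = generate_truth(params, rng)
    sides = {}
    for side in ("anterior", "posterior"):
        chans: dict[str, ChannelVolume] = {}
        for role in ("lipid", "hemoglobin", "off_resonance"):
            vol = render_pat_channel(truth, role, params, side=side, rng=rng)
            chans[vol.modality] = vol
        eosin, nuclei = render_ispim_channels(truth, params, side=side, rng=rng)
        chans[eosin.modality] = eosin
        chans[nuclei.modality] = nuclei
        us = render_ultrasound(truth, params, side=side, rng=rng)
        chans[us.modality] = us
        sides[side] = chans
    return truth, sides["anterior"], sides["posterior"]
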