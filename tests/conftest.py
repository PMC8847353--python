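"""Shared fixtures: small seeded phantoms reused across the suite."""

import numpy as np
import pytest

import patquant as pq


def small_params(**overrides) -> pq.PhantomParams:
    """A fast ~3 × 1.6 × 3 mm phantom at 30 µm working resolution."""
    kw = dict(
        extent_mm=(3.0, 1.6, 3.0),
        ispim_spacing=(0.03, 0.03, 0.03),
        pat_spacing=(0.193, 0.06, 0.06),
        carcinoma_radius_mm=(0.3, 0.45),
        carcinoma_focus_count=2,
        seed=1,
    )
    kw.update(overrides)
    return pq.PhantomParams(**kw)


@pytest.fixture(scope="session")
def phantom_small():
    """(truth, anterior channels, posterior channels) for the small phantom."""
    return pq.generate_phantom(small_params())


@pytest.fixture(scope="session")
def truth_small(phantom_small):
    return phantom_small[0]


@pytest.fixture(scope="session")
def phantom_default():
    """Default-scale phantom (the study conditions); used by the recovery
    and ROI-placement tests that need realistic geometry."""
    return pq.generate_phantom(pq.PhantomParams(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_uniform_truth(
    label: int = pq.STROMA,
    shape=(20, 40, 30),
    spacing=(0.05, 0.05, 0.05),
    lipid: float = 0.0,
    hemoglobin: float = 0.0,
    nuclei=None,
) -> pq.PhantomTruth:
    """Hand-built truth volume of a single tissue class, for closed-form
    render checks."""
    labels = np.full(shape, label, dtype=np.uint8)
    lip = np.full(shape, lipid, dtype=np.float32)
    hgb = np.full(shape, hemoglobin, dtype=np.float32)
    if nuclei is None:
        nuclei = np.empty((0, 3))
    return pq.PhantomTruth(
        labels=labels,
        lipid=lip,
        hemoglobin=hgb,
        nuclei_xyz_mm=np.asarray(nuclei, dtype=np.float64),
        tissue_mask=labels != pq.BACKGROUND,
        spacing=spacing,
    )
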