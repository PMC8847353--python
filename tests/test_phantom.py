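"""Phantom generation: class-fraction control, determinism, render physics."""

import numpy as np
import pytest
from scipy import ndimage

import patquant as pq
from patquant.phantom import generate_truth

from conftest import make_uniform_truth, small_params


class TestTruthGeneration:
    def test_zero_carcinoma_fraction_gives_no_carcinoma_voxels(self):
        p = small_params(class_fractions={"adipose": 0.3, "carcinoma": 0.0})
        truth = generate_truth(p, np.random.default_rng(1))
        assert (truth.labels == pq.CARCINOMA).sum() == 0

    def test_same_seed_bit_identical(self):
        p = small_params(seed=1)
        t1, a1, p1 = pq.generate_phantom(p)
        t2, a2, p2 = pq.generate_phantom(p)
        np.testing.assert_array_equal(t1.labels, t2.labels)
        for mod in a1:
            np.testing.assert_array_equal(a1[mod].data, a2[mod].data)
            np.testing.assert_array_equal(p1[mod].data, p2[mod].data)

    def test_adipose_fraction_realized_within_20pct_relative(self, truth_small):
        frac = truth_small.class_fraction(pq.ADIPOSE)
        assert 0.24 <= frac <= 0.36  # target 0.30 ± 20% relative

    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            small_params(class_fractions={"adipose": 0.7, "carcinoma": 0.5})

    def test_chromophores_confined_to_their_classes(self, truth_small):
        t = truth_small
        assert np.all(t.labels[t.lipid > 0] == pq.ADIPOSE)
        assert np.all(t.labels[t.hemoglobin > 0] == pq.VESSEL)

    def test_nuclei_points_inside_tissue(self, truth_small):
        t = truth_small
        vox = np.floor(t.nuclei_xyz_mm / np.asarray(t.spacing)).astype(int)
        vox = np.clip(vox, 0, np.asarray(t.labels.shape) - 1)
        inside = t.tissue_mask[vox[:, 0], vox[:, 1], vox[:, 2]]
        assert inside.mean() > 0.999


class TestPATRender:
    def test_no_attenuation_limit_proportional_to_blurred_concentration(self):
        truth = make_uniform_truth(pq.STROMA, lipid=0.0)
        truth.labels[5:15, :, 5:25] = pq.ADIPOSE
        truth.lipid[5:15, :, 5:25] = 0.8
        p = small_params(
            extent_mm=(1.0, 2.0, 1.5),
            ispim_spacing=(0.05, 0.05, 0.05),
            pat_spacing=(0.05, 0.05, 0.05),
            fluence_decay_mm=np.inf,
            noise_sd={k: 0.0 for k in ("pat_lipid", "pat_hemoglobin", "pat_off")},
        )
        vol = pq.render_pat_channel(truth, "lipid", p)
        expected = ndimage.gaussian_filter(
            truth.lipid.astype(float),
            sigma=[s / sp for s, sp in zip(p.pat_psf_sigma_mm, truth.spacing)],
        )
        r = np.corrcoef(vol.data.ravel(), expected.ravel())[0, 1]
        assert r > 0.99

    def test_off_resonance_noiseless_is_all_zero(self, truth_small):
        p = small_params(noise_sd={"pat_off": 0.0})
        vol = pq.render_pat_channel(truth_small, "off_resonance", p)
        assert np.all(vol.data == 0)

    def test_unknown_role_rejected(self, truth_small):
        with pytest.raises(ValueError, match="role"):
            pq.render_pat_channel(truth_small, "water", small_params())

    def test_exponential_depth_decay_matches_closed_form(self):
        # uniform lipid slab, decay length 1 mm, no blur, no noise:
        # mean signal at depth 1 mm / surface ≈ e^−1
        truth = make_uniform_truth(pq.ADIPOSE, shape=(10, 40, 10),
                                   spacing=(0.05, 0.05, 0.05), lipid=1.0)
        p = small_params(
            extent_mm=(0.5, 2.0, 0.5),
            ispim_spacing=(0.05, 0.05, 0.05),
            pat_spacing=(0.05, 0.05, 0.05),
            fluence_decay_mm=1.0,
            pat_psf_sigma_mm=(1e-6, 1e-6, 1e-6),
            noise_sd={"pat_lipid": 0.0},
        )
        vol = pq.render_pat_channel(truth, "lipid", p)
        depth_px_1mm = int(round(1.0 / 0.05)) - 1  # voxel centered nearest 1 mm below
        surface = vol.data[:, 0, :].mean()
        deep = vol.data[:, depth_px_1mm, :].mean()
        depth_mm = (depth_px_1mm + 0.5) * 0.05
        expected_ratio = np.exp(-(depth_mm - 0.025))
        assert deep / surface == pytest.approx(expected_ratio, rel=0.05)


class TestISPIMRender:
    def test_empty_nuclei_channel_is_pure_noise(self):
        truth = make_uniform_truth(pq.STROMA)
        p = small_params(noise_sd={"ispim_eosin": 0.0, "ispim_nuclei": 0.01})
        _, nuc = pq.render_ispim_channels(truth, p)
        assert nuc.data.std() < 3 * 0.01
        assert abs(nuc.data[nuc.data > 0].mean()) < 0.05

    def test_stripe_amplitude_zero_gives_flat_columns(self):
        truth = make_uniform_truth(pq.STROMA)
        p = small_params(stripe_amplitude=0.0,
                         noise_sd={"ispim_eosin": 0.0, "ispim_nuclei": 0.0})
        eosin, _ = pq.render_ispim_channels(truth, p)
        col_means = eosin.data.mean(axis=(0, 1))
        assert np.ptp(col_means[2:-2]) < 1e-6

    def test_stripe_artifact_modulates_columns(self):
        truth = make_uniform_truth(pq.STROMA)
        p = small_params(stripe_amplitude=0.2, stripe_period_mm=0.5,
                         noise_sd={"ispim_eosin": 0.0, "ispim_nuclei": 0.0})
        eosin, _ = pq.render_ispim_channels(truth, p)
        col_means = eosin.data.mean(axis=(0, 1))
        assert np.ptp(col_means) > 0.1

    def test_noiseless_nuclei_peak_count_matches_point_count(self):
        from skimage.feature import peak_local_max

        # 100 nuclei on a well-separated grid
        xs = np.linspace(0.2, 1.8, 5)
        ys = np.linspace(0.2, 1.8, 5)
        zs = np.linspace(0.2, 1.4, 4)
        pts = np.array([[x, z, y] for x in xs for y in ys for z in zs])
        assert len(pts) == 100
        truth = make_uniform_truth(pq.STROMA, shape=(40, 32, 40),
                                   spacing=(0.05, 0.05, 0.05), nuclei=pts)
        p = small_params(extent_mm=(2.0, 1.6, 2.0),
                         ispim_spacing=(0.05, 0.05, 0.05),
                         nuclei_spot_sigma_mm=0.05,
                         noise_sd={"ispim_eosin": 0.0, "ispim_nuclei": 0.0})
        _, nuc = pq.render_ispim_channels(truth, p)
        peaks = peak_local_max(nuc.data, min_distance=2, threshold_abs=0.1)
        assert len(peaks) == 100

    def test_eosin_bright_in_stroma_dim_in_adipose(self, phantom_small, truth_small):
        _, ant, _ = phantom_small
        eosin = ant["ispim_eosin"].data
        labels = truth_small.labels[:, : eosin.shape[1], :]
        assert eosin[labels == pq.STROMA].mean() > 3 * eosin[labels == pq.ADIPOSE].mean()


class TestUltrasoundRender:
    def test_zero_speckle_gives_piecewise_constant_echogenicity(self):
        truth = make_uniform_truth(pq.STROMA)
        truth.labels[:, :, :5] = pq.BACKGROUND
        p = small_params(extent_mm=(1.0, 2.0, 1.5),
                         ispim_spacing=(0.05, 0.05, 0.05),
                         pat_spacing=(0.05, 0.05, 0.05),
                         speckle_variance=0.0,
                         noise_sd={"ultrasound": 0.0})
        vol = pq.render_ultrasound(truth, p)
        values = np.unique(np.round(vol.data, 6))
        assert set(values) <= {0.0, 0.65}

    def test_background_voxels_are_zero(self):
        truth = make_uniform_truth(pq.STROMA)
        truth.labels[:, :, :8] = pq.BACKGROUND
        p = small_params(extent_mm=(1.0, 2.0, 1.5),
                         ispim_spacing=(0.05, 0.05, 0.05),
                         pat_spacing=(0.05, 0.05, 0.05),
                         speckle_variance=0.3, noise_sd={"ultrasound": 0.0})
        vol = pq.render_ultrasound(truth, p)
        assert np.all(vol.data[:, :, :4] == 0)

    def test_duct_lumen_hypoechoic_vs_stroma(self, phantom_small, truth_small):
        _, ant, _ = phantom_small
        us = ant["ultrasound"]
        from patquant.pipeline import _labels_on_grid

        labels = _labels_on_grid(truth_small, us, "anterior")
        if (labels == pq.DUCT_LUMEN).sum() < 10:
            pytest.skip("phantom seed produced too little duct lumen on the PAT grid")
        assert us.data[labels == pq.DUCT_LUMEN].mean() < us.data[labels == pq.STROMA].mean()


class TestSideGeometry:
    def test_anterior_posterior_mirror_for_symmetric_truth(self):
        truth = make_uniform_truth(pq.ADIPOSE, shape=(10, 20, 10),
                                   spacing=(0.05, 0.05, 0.05), lipid=1.0)
        p = small_params(extent_mm=(0.5, 1.0, 0.5),
                         ispim_spacing=(0.05, 0.05, 0.05),
                         pat_spacing=(0.05, 0.05, 0.05),
                         noise_sd={"pat_lipid": 0.0})
        ant = pq.render_pat_channel(truth, "lipid", p, side="anterior")
        post = pq.render_pat_channel(truth, "lipid", p, side="posterior")
        np.testing.assert_allclose(ant.data, post.data, rtol=1e-10)

    def test_truth_to_render_correlation_noiseless(self, truth_small):
        p = small_params(noise_sd={"pat_lipid": 0.0})
        vol = pq.render_pat_channel(truth_small, "lipid", p)
        # matched blur + fluence + resample of the truth concentration
        from patquant.phantom import _crop_depth_vox, _depth_mm
        from patquant.volume_io import resample_to_grid

        conc = truth_small.lipid.astype(float)
        decay = p.fluence_decay_mm
        conc = conc * np.exp(-_depth_mm(conc.shape[1], 0.03) / decay)[None, :, None]
        conc = ndimage.gaussian_filter(
            conc, sigma=[s / 0.03 for s in p.pat_psf_sigma_mm]
        )
        nd = _crop_depth_vox(conc.shape[1], 0.03, p.imaging_depth_mm)
        interim = pq.ChannelVolume(conc[:, :nd, :], (0.03,) * 3, "pat_lipid")
        expected = resample_to_grid(interim, vol.shape, vol.spacing)
        r = np.corrcoef(vol.data.ravel(), expected.data.ravel())[0, 1]
        assert r > 0.99
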