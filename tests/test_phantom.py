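"""Phantom generator: geometry, imposed densities, nuclei sampling, metrics."""

import numpy as np
import pytest
from scipy import ndimage

import gliodensity as gd
from gliodensity.errors import ConfigurationError
from gliodensity.grids import LABELS, ScalarVolume, TissueLabelVolume, VoxelGrid
from gliodensity.phantom import bridge_mask, smooth_random_field


class TestBrainPhantom:
    def test_core_voxel_count_matches_sphere_volume(self, phantom96):
        # expected count from the analytic sphere volume on this grid
        expected = (4.0 / 3.0) * np.pi * 5.0**3 / phantom96.grid.voxel_volume_mm3
        observed = int(phantom96.core_mask.sum())
        assert abs(observed - expected) / expected < 0.15

    def test_deterministic_given_seed(self):
        a = gd.make_brain_phantom(shape=(48, 48, 48), core_radius_mm=2.0, seed=7)
        b = gd.make_brain_phantom(shape=(48, 48, 48), core_radius_mm=2.0, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_zero_core_radius_gives_tumor_free_brain(self):
        labels = gd.make_brain_phantom(shape=(48, 48, 48), core_radius_mm=0.0)
        assert not labels.core_mask.any()
        assert (labels.labels == LABELS["necrosis"]).sum() == 0

    def test_unembeddable_core_rejected(self):
        with pytest.raises(ConfigurationError):
            gd.make_brain_phantom(shape=(48, 48, 48), core_radius_mm=20.0)

    def test_label_set_closed_and_nested(self, phantom96):
        assert set(np.unique(phantom96.labels)) <= set(LABELS.values())
        # core and necrosis lie inside the brain; necrosis inside the core
        assert phantom96.core_mask.sum() > 0
        assert (phantom96.labels == LABELS["necrosis"]).sum() > 0
        assert not (phantom96.core_mask & ~phantom96.brain_mask).any()

    def test_white_matter_single_face_connected_component(self, phantom96):
        structure = ndimage.generate_binary_structure(3, 1)
        _, n = ndimage.label(phantom96.white_mask, structure=structure)
        assert n == 1

    def test_bridge_is_white_and_nonempty(self, phantom96):
        br = bridge_mask(phantom96)
        assert br.any()
        assert (phantom96.labels[br] == LABELS["white"]).all()


def _uniform_white(shape=(22, 22, 22), d_value=5.0):
    labels = TissueLabelVolume(
        VoxelGrid(shape, (0.5,) * 3), np.full(shape, LABELS["white"], np.uint8)
    )
    dmap = ScalarVolume(labels.grid, np.full(shape, d_value), units="mm")
    return labels, dmap


class TestInfiltrationProfile:
    truth = gd.DecayModelParams(1.05e5, 8.46, 0.59e5, "volume")

    def test_noiseless_at_zero_distance_is_core_plus_baseline(self):
        labels, dmap = _uniform_white(d_value=0.0)
        vol = gd.impose_infiltration_profile(labels, dmap, self.truth, noise_cv=0.0)
        assert np.allclose(vol.values, self.truth.c_core + self.truth.c_white)

    def test_noiseless_far_field_approaches_baseline(self):
        labels, dmap = _uniform_white(d_value=500.0)
        vol = gd.impose_infiltration_profile(labels, dmap, self.truth, noise_cv=0.0)
        assert np.allclose(vol.values, self.truth.c_white, rtol=1e-12)

    def test_lognormal_noise_preserves_mean(self):
        # n = 22^3 > 1e4 white voxels at fixed distance: sample mean within
        # 3 standard errors of the model value
        labels, dmap = _uniform_white(d_value=5.0)
        vol = gd.impose_infiltration_profile(labels, dmap, self.truth, noise_cv=0.2, seed=0)
        model = gd.predict_total_density(self.truth, 5.0)
        n = vol.values.size
        se = model * 0.2 / np.sqrt(n)
        assert abs(vol.values.mean() - model) < 3 * se

    def test_negative_parameter_rejected(self):
        labels, dmap = _uniform_white()
        bad = gd.DecayModelParams(-1.0, 8.46, 0.59e5, "volume")
        with pytest.raises(ValueError):
            gd.impose_infiltration_profile(labels, dmap, bad)
        with pytest.raises(ValueError):
            gd.impose_infiltration_profile(labels, dmap, self.truth, noise_cv=-0.1)

    def test_tissue_class_values(self, phantom96, distance96):
        vol = gd.impose_infiltration_profile(phantom96, distance96, self.truth, noise_cv=0.0)
        v = vol.values
        assert np.isnan(v[~phantom96.brain_mask]).all()
        gray = phantom96.labels == LABELS["gray"]
        assert np.allclose(v[gray], 1.5 * self.truth.c_white)
        white_fin = phantom96.white_mask & np.isfinite(distance96.values)
        expected = gd.predict_total_density(self.truth, distance96.values[white_fin])
        assert np.allclose(v[white_fin], expected)


class TestNucleiSampling:
    def test_uniform_density_expected_count(self, phantom48):
        # 2x2 voxels of pure tissue = 1 mm^2; surface intensity is
        # c_volume^(2/3) so the Poisson mean is 1e5^(2/3) ~ 2154
        window = (22, 24, 22, 24)
        assert phantom48.brain_mask[12, 22:24, 22:24].all()
        vol = ScalarVolume(phantom48.grid, np.full(phantom48.grid.shape, 1e5))
        slide = gd.sample_nuclei_slide(vol, phantom48, 12, window, seed=0)
        expected = 1e5 ** (2.0 / 3.0)
        assert abs(len(slide.nuclei) - expected) < 3 * np.sqrt(expected)

    def test_zero_density_zero_nuclei(self, phantom48):
        vol = ScalarVolume(phantom48.grid, np.zeros(phantom48.grid.shape))
        slide = gd.sample_nuclei_slide(vol, phantom48, 12, (20, 26, 20, 26), seed=0)
        assert len(slide.nuclei) == 0

    def test_fixed_seed_reproducible(self, phantom48):
        vol = ScalarVolume(phantom48.grid, np.full(phantom48.grid.shape, 5e4))
        a = gd.sample_nuclei_slide(vol, phantom48, 12, (20, 26, 20, 26), seed=3)
        b = gd.sample_nuclei_slide(vol, phantom48, 12, (20, 26, 20, 26), seed=3)
        assert np.array_equal(a.nuclei, b.nuclei)

    def test_every_nucleus_on_tissue_pixel(self, phantom48):
        vol = ScalarVolume(phantom48.grid, np.full(phantom48.grid.shape, 5e4))
        slide = gd.sample_nuclei_slide(vol, phantom48, 12, (18, 28, 18, 28), seed=1)
        px = np.floor(slide.nuclei).astype(int)
        assert slide.tissue_mask[px[:, 0], px[:, 1]].all()

    def test_counts_are_poisson_across_replicates(self, phantom48):
        # variance/mean of replicate counts over a fixed region ~ 1
        vol = ScalarVolume(phantom48.grid, np.full(phantom48.grid.shape, 2e4))
        counts = [
            len(gd.sample_nuclei_slide(vol, phantom48, 12, (22, 24, 22, 24), seed=s).nuclei)
            for s in range(200)
        ]
        fano = np.var(counts) / np.mean(counts)
        assert 0.8 < fano < 1.2

    def test_out_of_grid_slice_rejected(self, phantom48):
        vol = ScalarVolume(phantom48.grid, np.zeros(phantom48.grid.shape))
        with pytest.raises(IndexError):
            gd.sample_nuclei_slide(vol, phantom48, 99, (20, 26, 20, 26))
        with pytest.raises(IndexError):
            gd.sample_nuclei_slide(vol, phantom48, 12, (20, 26, 40, 60))


class TestEdemaMaskConstruction:
    def test_iso_mask_is_thresholded_distance(self, distance96):
        em = gd.make_edema_mask(distance96, "iso", 20.0)
        d = distance96.values
        assert np.array_equal(em.mask, np.isfinite(d) & (d <= 20.0))

    def test_zero_amplitude_perturbation_equals_iso(self, distance96):
        iso = gd.make_edema_mask(distance96, "iso", 20.0)
        pz = gd.make_edema_mask(distance96, "perturbed", 20.0, perturb_amp_mm=0.0, seed=5)
        assert np.array_equal(iso.mask, pz.mask)

    def test_perturbed_boundary_distance_spread(self, phantom96, distance96, domain96):
        # smooth perturbation (amp 10 mm, scale 15 mm) must visibly deform
        # the outline: 95th-5th percentile of boundary distances > 5 mm
        em = gd.make_edema_mask(distance96, "perturbed", 20.0, 10.0, 15.0, seed=1)
        b = gd.boundary_voxels(em.mask, phantom96.grid, domain=domain96)
        dv = distance96.values[tuple(b.indices.T)]
        assert np.quantile(dv, 0.95) - np.quantile(dv, 0.05) > 5.0

    def test_invalid_threshold_rejected(self, distance96):
        with pytest.raises(ValueError):
            gd.make_edema_mask(distance96, "iso", 0.0)
        with pytest.raises(ValueError):
            gd.make_edema_mask(distance96, "banana", 20.0)

    def test_smooth_field_deterministic_unit_variance(self):
        a = smooth_random_field((32, 32, 32), 4.0, seed=2)
        b = smooth_random_field((32, 32, 32), 4.0, seed=2)
        assert np.array_equal(a, b)
        assert abs(a.mean()) < 1e-12 and abs(a.std() - 1.0) < 1e-12


class TestMetricField:
    def test_unit_metric_is_identity(self, phantom48):
        field = gd.make_metric_field(phantom48, "unit")
        assert np.allclose(field.tensor, np.eye(3))

    def test_fiber_ratio_one_equals_unit(self, phantom48):
        unit = gd.make_metric_field(phantom48, "unit")
        fiber = gd.make_metric_field(phantom48, "fiber", 1.0)
        assert np.array_equal(unit.tensor, fiber.tensor)

    def test_fiber_eigenvalue_ratio_in_bridge(self, phantom48):
        field = gd.make_metric_field(phantom48, "fiber", 9.0)
        br = bridge_mask(phantom48)
        assert br.any()
        eigs = np.linalg.eigvalsh(field.tensor[br])
        assert np.allclose(eigs.max(axis=1) / eigs.min(axis=1), 9.0)
        outside = ~br
        assert np.allclose(field.tensor[outside], np.eye(3))

    def test_invalid_ratio_rejected(self, phantom48):
        with pytest.raises(ValueError):
            gd.make_metric_field(phantom48, "fiber", 0.5)
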