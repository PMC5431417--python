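"""Phantom generator: geometry, speckle statistics, determinism, features."""

import numpy as np
import pytest

from octindent.phantom import (
    AdiposeRegion,
    FibroticLayers,
    OCTVolume,
    PhantomSpec,
    make_phantom,
    pore_density_for_fraction,
    render_oct,
    true_strain,
    true_thickness,
)

from conftest import REF_STRESS


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"true_modulus": -1.0},
            {"true_modulus": 14.0, "thickness0": 0.0},
            {"true_modulus": 14.0, "voxel_pitch": (0.0, 0.011, 0.011)},
            {"true_modulus": 14.0, "speckle_contrast": 1.5},
            {"true_modulus": 14.0, "nonlinearity_beta": -0.1},
            # axial pitch coarser than the axial resolution undersamples surfaces
            {"true_modulus": 14.0, "voxel_pitch": (0.02, 0.011, 0.011)},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs)

    def test_feature_outside_extent_rejected(self):
        region = AdiposeRegion(center=(5.0, 5.0), radius=0.5, pore_density=100, pore_radius=0.03)
        with pytest.raises(ValueError, match="outside the lateral extent"):
            PhantomSpec(true_modulus=14.0, lateral_extent=(2.0, 2.0), adipose_region=region)


class TestGeometry:
    def test_featureless_sheet_has_constant_thickness(self, small_scene):
        xs = np.linspace(0.05, 1.45, 7)
        for x in xs:
            for y in xs:
                assert true_thickness(small_scene, 0.0, (x, y)) == pytest.approx(0.5)

    def test_zero_pore_density_matches_featureless(self):
        base = PhantomSpec(true_modulus=14.0, lateral_extent=(2.0, 2.0), rng_seed=5)
        with_zero = PhantomSpec(
            true_modulus=14.0,
            lateral_extent=(2.0, 2.0),
            rng_seed=5,
            adipose_region=AdiposeRegion((1.0, 1.0), 0.5, pore_density=0.0, pore_radius=0.03),
        )
        np.testing.assert_array_equal(
            make_phantom(base).reflectivity, make_phantom(with_zero).reflectivity
        )

    def test_footprint_strain_closed_form(self, small_scene):
        # eps = sigma / E: 0.92 / 14 = 0.0657143, compressed 0.4671 mm
        c = small_scene.spec.punch_center
        assert true_strain(small_scene.spec, REF_STRESS) == pytest.approx(0.92 / 14)
        assert true_thickness(small_scene, REF_STRESS, c) == pytest.approx(0.467143, abs=1e-6)

    def test_transition_annulus_is_strictly_intermediate_and_monotone(self):
        spec = PhantomSpec(true_modulus=14.0, lateral_extent=(2.4, 2.4), punch_diameter=0.8)
        scene = make_phantom(spec)
        cx, cy = spec.punch_center
        t_in = true_thickness(scene, REF_STRESS, (cx, cy))
        t_mid = true_thickness(scene, REF_STRESS, (cx + 0.6, cy))  # annulus centre
        t_out = true_thickness(scene, REF_STRESS, (cx + 0.9, cy))
        assert t_in < t_mid < t_out == pytest.approx(0.5)
        # monotone taper across the annulus
        rr = np.linspace(0.4, 0.8, 30)
        tt = [true_thickness(scene, REF_STRESS, (cx + r, cy)) for r in rr]
        assert np.all(np.diff(tt) > 0)

    def test_thickness_outside_extent_rejected(self, small_scene):
        with pytest.raises(ValueError, match="outside extent"):
            true_thickness(small_scene, 0.0, (5.0, 0.5))

    def test_footprint_thickness_decreases_with_stress(self, small_scene):
        c = small_scene.spec.punch_center
        stresses = [0.0, 0.5, 0.92, 1.5, 2.4]
        tt = [true_thickness(small_scene, s, c) for s in stresses]
        assert np.all(np.diff(tt) < 0)

    def test_unphysical_collapse_rejected(self, small_scene):
        with pytest.raises(ValueError, match="collapse"):
            render_oct(small_scene, 20.0, seed=0)

    def test_nonlinearity_beta_solves_apparent_stiffening_ratio(self):
        # beta chosen so E_eff(2.4)/E_eff(0.92) = 1.065
        beta = 0.065 / (2.4 - 1.065 * 0.92)
        spec = PhantomSpec(true_modulus=14.0, nonlinearity_beta=beta)
        e_low = 14.0 * (1 + beta * 0.92)
        e_high = 14.0 * (1 + beta * 2.4)
        assert e_high / e_low == pytest.approx(1.065)
        # rendered-geometry strains agree with the effective moduli
        assert true_strain(spec, 0.92) == pytest.approx(0.92 / e_low)
        assert true_strain(spec, 2.4) == pytest.approx(2.4 / e_high)


class TestRendering:
    def test_render_is_deterministic(self, small_scene):
        a = render_oct(small_scene, REF_STRESS, seed=7)
        b = render_oct(small_scene, REF_STRESS, seed=7)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        c = render_oct(small_scene, REF_STRESS, seed=8)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_intensities_valid(self, vol_compressed):
        assert np.all(np.isfinite(vol_compressed.intensity))
        assert np.all(vol_compressed.intensity >= 0)

    def test_speckle_contrast_matches_cov(self):
        # homogeneous in-tissue region, attenuation off: CoV == contrast to 2%
        for c in (0.15, 0.3):
            spec = PhantomSpec(
                true_modulus=14.0,
                lateral_extent=(1.5, 1.5),
                speckle_contrast=c,
                attenuation=0.0,
                rng_seed=1,
            )
            vol = render_oct(make_phantom(spec), 0.0, seed=3)
            # interior slab well inside the sheet
            pz = spec.voxel_pitch[0]
            k0 = int((0.12 + 0.1) / pz)
            k1 = int((0.12 + 0.4) / pz)
            region = vol.intensity[k0:k1]
            assert region.size >= 10_000
            cov = region.std() / region.mean()
            assert cov == pytest.approx(c, rel=0.02)

    def test_mean_thickness_outside_footprint_invariant_to_stress(self):
        spec = PhantomSpec(true_modulus=14.0, lateral_extent=(2.4, 2.4), punch_diameter=0.8)
        scene = make_phantom(spec)
        cx, cy = spec.punch_center
        probes = [(cx + 0.85, cy), (cx, cy + 0.9), (0.1, 0.1)]
        for sigma in (0.0, 0.92, 2.4):
            for p in probes:
                assert true_thickness(scene, sigma, p) == pytest.approx(0.5)

    def test_volume_validation(self):
        with pytest.raises(ValueError):
            OCTVolume(intensity=np.full((4, 4, 4), np.nan), voxel_pitch=(0.008, 0.011, 0.011))
        with pytest.raises(ValueError):
            OCTVolume(intensity=-np.ones((4, 4, 4)), voxel_pitch=(0.008, 0.011, 0.011))
        with pytest.raises(ValueError):
            OCTVolume(intensity=np.ones((4, 4, 4)), voxel_pitch=(0.0, 0.011, 0.011))


class TestFeatures:
    def test_banded_reflectivity_autocorrelation_peak(self):
        period = 0.05
        spec = PhantomSpec(
            true_modulus=14.0,
            lateral_extent=(1.0, 1.0),
            fibrotic_layers=FibroticLayers(band_period=period, band_contrast=0.5),
        )
        refl = make_phantom(spec).reflectivity
        col = refl[:, 10, 10] - refl[:, 10, 10].mean()
        ac = np.correlate(col, col, mode="full")[col.size - 1 :]
        ac /= ac[0]
        # largest non-zero-lag local maximum sits at one band period
        interior = np.arange(1, ac.size - 1)
        peaks = interior[(ac[interior] > ac[interior - 1]) & (ac[interior] >= ac[interior + 1])]
        best = peaks[np.argmax(ac[peaks])]
        pz = spec.voxel_pitch[0]
        assert best * pz == pytest.approx(period, abs=pz)

    def test_pore_volume_fraction_close_to_target(self):
        target = 0.2
        radius = 0.03
        dens = pore_density_for_fraction(target, radius)
        spec = PhantomSpec(
            true_modulus=14.0,
            lateral_extent=(2.0, 2.0),
            rng_seed=11,
            adipose_region=AdiposeRegion((1.0, 1.0), 0.8, pore_density=dens, pore_radius=radius),
        )
        refl = make_phantom(spec).reflectivity
        # fraction of low-reflectivity voxels inside the adipose disc
        x = (np.arange(refl.shape[1]) + 0.5) * spec.voxel_pitch[1]
        y = (np.arange(refl.shape[2]) + 0.5) * spec.voxel_pitch[2]
        inside = np.hypot(x[:, None] - 1.0, y[None, :] - 1.0) <= 0.8
        frac = float((refl[:, inside] < 0.5).mean())
        assert frac == pytest.approx(target, abs=0.05)
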