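"""Stress/strain/modulus chain and the measurement-uncertainty budget."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octindent.indentation import (
    ErrorBudget,
    Indenter,
    elastic_modulus,
    measure_site,
    measured_contact_area,
    nominal_contact_area,
    nonlinearity_percent,
    propagate_error_analytic,
    propagate_error_mc,
    strain_from_thickness,
    stress_from_load,
)
from octindent.morphology import IndentationSite

from conftest import REF_STRESS, uniform_map


def _result(E=14.0, stress=0.92, t0=0.5):
    """Build a consistent IndentationResult at the requested modulus."""
    from octindent.indentation import IndentationResult

    strain = stress / E
    return IndentationResult(
        site=IndentationSite("left_lateral", (1.0, 1.0), 1.5),
        contact_area=nominal_contact_area(3.0),
        stress=stress,
        thickness0=t0,
        thickness1=t0 * (1 - strain),
        strain=strain,
        modulus=stress / strain,
    )


class TestAreaStressStrain:
    def test_nominal_area_closed_form(self):
        assert nominal_contact_area(3.0) == pytest.approx(7.0686, abs=1e-4)
        assert nominal_contact_area(2.0 / math.sqrt(math.pi)) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            nominal_contact_area(0.0)

    def test_stress_from_load(self):
        # 0.663 g on the 3-mm punch face gives the working stress 0.92 kPa
        assert stress_from_load(0.663, 7.0686) == pytest.approx(0.920, abs=0.001)
        assert stress_from_load(2.0, 7.0686) == pytest.approx(
            2 * stress_from_load(1.0, 7.0686)
        )
        assert stress_from_load(1.0, 9.80665) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            stress_from_load(-1.0, 7.0)
        with pytest.raises(ValueError):
            stress_from_load(1.0, 0.0)

    def test_strain_from_thickness(self):
        assert strain_from_thickness(0.5, 0.46714) == pytest.approx(0.06571, abs=1e-4)
        assert strain_from_thickness(0.5, 0.5) == 0.0
        assert strain_from_thickness(0.5, 0.25) == 0.5
        with pytest.raises(ValueError, match="swapped"):
            strain_from_thickness(0.5, 0.6)

    def test_elastic_modulus(self):
        assert elastic_modulus(0.92, 0.92 / 14.0) == pytest.approx(14.0)
        assert elastic_modulus(0.92, 0.0657 / 2) == pytest.approx(
            2 * elastic_modulus(0.92, 0.0657)
        )
        with pytest.raises(ValueError):
            elastic_modulus(0.92, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        mass=st.floats(0.1, 10.0),
        area=st.floats(0.5, 50.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_stress_scale_equivariance(self, mass, area, scale):
        """Scaling mass and area together leaves the stress unchanged."""
        assert stress_from_load(mass * scale, area * scale) == pytest.approx(
            stress_from_load(mass, area)
        )


class TestMeasuredContactArea:
    def test_identical_maps_clip_with_warning(self):
        m = uniform_map(0.5)
        with pytest.warns(UserWarning, match="outside plausible band"):
            area, clipped = measured_contact_area(m, uniform_map(0.5), Indenter())
        assert clipped
        assert area == pytest.approx(0.5 * nominal_contact_area(3.0))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="same lateral grid"):
            measured_contact_area(uniform_map(0.5, 40), uniform_map(0.5, 30), Indenter())

    def test_fully_masked_compressed_map_rejected(self):
        m = uniform_map(0.5)
        m.mask[:] = True
        with pytest.raises(ValueError, match="fully masked"):
            measured_contact_area(m, uniform_map(0.5), Indenter())

    def test_counts_compressed_positions(self):
        m0 = uniform_map(0.5, 80)
        m1 = uniform_map(0.5, 80)
        m1.thickness[20:60, 20:60] = 0.45  # decrease of 50 um >> 2 pitches
        m1.bottom_depth = m1.top_depth + m1.thickness
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            area, _ = measured_contact_area(m1, m0, Indenter())
        expected = 40 * 40 * 0.011 * 0.011
        assert area == pytest.approx(max(expected, 0.5 * nominal_contact_area(3.0)))


class TestMeasureSite:
    def test_recovers_modulus_on_speckled_pair(self, vol_uncompressed, vol_compressed):
        site = IndentationSite("left_lateral", (0.75, 0.75), 0.5)
        res = measure_site(vol_uncompressed, vol_compressed, site)
        assert res.modulus == pytest.approx(14.0, rel=0.10)
        assert res.metadata["quantization_error_bound_kpa"] > 0
        assert 0 < res.strain < 1

    def test_no_compression_rejected(self, vol_uncompressed):
        site = IndentationSite("left_lateral", (0.75, 0.75), 0.5)
        with pytest.raises(ValueError, match="no detectable compression"):
            measure_site(vol_uncompressed, vol_uncompressed, site)

    def test_mismatched_volumes_rejected(self, vol_uncompressed):
        import dataclasses

        cropped = dataclasses.replace(
            vol_uncompressed, intensity=vol_uncompressed.intensity[:, :50, :50]
        )
        with pytest.raises(ValueError, match="co-registered"):
            measure_site(
                vol_uncompressed, cropped, IndentationSite("left_lateral", (0.3, 0.3), 0.2)
            )


class TestNonlinearity:
    def test_equal_moduli_zero_percent(self):
        low = _result(E=14.0, stress=0.92)
        high = _result(E=14.0, stress=2.4)
        assert nonlinearity_percent(low, high) == pytest.approx(0.0)

    def test_ten_percent_stiffening(self):
        low = _result(E=14.0, stress=0.92)
        high = _result(E=15.4, stress=2.4)
        assert nonlinearity_percent(low, high) == pytest.approx(10.0)

    def test_unordered_stresses_rejected(self):
        low = _result(E=14.0, stress=0.92)
        high = _result(E=14.0, stress=2.4)
        with pytest.raises(ValueError):
            nonlinearity_percent(high, low)


class TestErrorPropagation:
    def test_zero_budget_gives_zero_sd(self):
        res = _result()
        assert propagate_error_analytic(res, Indenter(), ErrorBudget()) == 0.0
        assert propagate_error_mc(res, Indenter(), ErrorBudget(), seed=1) == 0.0

    def test_analytic_closed_form(self):
        # relative SDs (1%, 1%, 1%, 5%) on (m, d, t0, delta) at E = 14 kPa:
        # 14 * sqrt(1e-4 + 4e-4 + 1e-4 + 25e-4) = 0.779 kPa
        res = _result(E=14.0)
        ind = Indenter()
        delta = res.thickness0 - res.thickness1
        budget = ErrorBudget(
            sd_mass=0.01 * ind.mass,
            sd_diameter=0.01 * ind.diameter,
            sd_thickness=0.01 * res.thickness0,
            sd_displacement=0.05 * delta,
        )
        assert propagate_error_analytic(res, ind, budget) == pytest.approx(0.779, abs=0.001)

    def test_analytic_homogeneity(self):
        res = _result()
        ind = Indenter()
        b1 = ErrorBudget(0.005, 0.02, 0.001, 0.003)
        b2 = ErrorBudget(0.01, 0.04, 0.002, 0.006)
        assert propagate_error_analytic(res, ind, b2) == pytest.approx(
            2 * propagate_error_analytic(res, ind, b1)
        )

    def test_mc_agrees_with_analytic_within_5pct(self):
        res = _result(E=14.0)
        ind = Indenter()
        delta = res.thickness0 - res.thickness1
        budget = ErrorBudget(
            sd_mass=0.01 * ind.mass,
            sd_diameter=0.01 * ind.diameter,
            sd_thickness=0.01 * res.thickness0,
            sd_displacement=0.05 * delta,
        )
        sd_a = propagate_error_analytic(res, ind, budget)
        sd_mc = propagate_error_mc(res, ind, budget, n_draws=100_000, seed=3)
        assert sd_mc == pytest.approx(sd_a, rel=0.05)

    def test_mc_deterministic(self):
        res = _result()
        budget = ErrorBudget(0.005, 0.02, 0.002, 0.002)
        a = propagate_error_mc(res, Indenter(), budget, seed=9)
        b = propagate_error_mc(res, Indenter(), budget, seed=9)
        assert a == b

    def test_mc_warns_on_many_rejections(self):
        res = _result(E=30.0)  # tiny displacement
        delta = res.thickness0 - res.thickness1
        budget = ErrorBudget(sd_displacement=1.5 * delta)
        with pytest.warns(UserWarning, match="rejected"):
            propagate_error_mc(res, Indenter(), budget, seed=4)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            propagate_error_mc(_result(), Indenter(), ErrorBudget(), n_draws=10)


class TestQuantizationFloor:
    def test_quantization_bound_reported_at_reference_conditions(
        self, vol_uncompressed, vol_compressed
    ):
        # t0 = 0.5 mm, E = 14 kPa, sigma = 0.92 kPa: displacement ~ 33 um,
        # about 4 axial voxels; the metadata must carry E*pitch/displacement
        site = IndentationSite("left_lateral", (0.75, 0.75), 0.5)
        res = measure_site(vol_uncompressed, vol_compressed, site)
        d = res.metadata["displacement_mm"]
        assert d == pytest.approx(0.5 * REF_STRESS / 14.0, rel=0.1)
        bound = res.metadata["quantization_error_bound_kpa"]
        assert bound == pytest.approx(res.modulus * 0.008 / d)
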