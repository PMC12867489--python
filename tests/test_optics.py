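"""Fabry-Perot physics: Airy function, figures of merit, transfer maps."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vipacascade as vc
from vipacascade.optics import CavitySpec, OpticalGeometry

C = 299792458.0


def resonant_thickness(m, index, wavelength, cos_theta=1.0):
    """Thickness putting the round-trip phase at exactly 2 pi m."""
    return m * wavelength / (2.0 * index * cos_theta)


class TestAiry:
    def test_no_mirrors_is_all_pass(self):
        assert vc.airy_transmission(0.73, 0.0, 1e-3, 1.5, 785e-9) == pytest.approx(1.0)

    def test_resonance_reaches_unity(self):
        d = resonant_thickness(10_000, 1.45, 785e-9)
        assert vc.airy_transmission(1.0, 0.94, d, 1.45, 785e-9) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_antiresonance_closed_form(self):
        # phase an odd multiple of pi: T = (1-R)^2/(1+R)^2
        d = resonant_thickness(10_000.5, 1.45, 785e-9)
        expected = (0.06 / 1.94) ** 2
        assert vc.airy_transmission(1.0, 0.94, d, 1.45, 785e-9) == pytest.approx(
            expected, rel=1e-9
        )
        assert expected == pytest.approx(9.566e-4, rel=1e-3)

    @given(
        r=st.floats(0.0, 0.99),
        phase=st.floats(0.0, 50.0),
    )
    def test_bounded_between_min_and_one(self, r, phase):
        d = phase * 785e-9 / (4 * math.pi * 1.45) + 1e-6
        t = vc.airy_transmission(1.0, r, d, 1.45, 785e-9)
        t_min = (1 - r) ** 2 / (1 + r) ** 2
        assert t_min - 1e-12 <= t <= 1 + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            vc.airy_transmission(1.0, 1.0, 1e-3, 1.45, 785e-9)
        with pytest.raises(ValueError):
            vc.airy_transmission(1.0, 0.9, -1e-3, 1.45, 785e-9)
        with pytest.raises(ValueError):
            vc.airy_transmission(0.0, 0.9, 1e-3, 1.45, 785e-9)

    @pytest.mark.parametrize("r", [0.5, 0.75, 0.9, 0.94, 0.96])
    def test_closed_form_contrast_and_mean(self, r):
        # fine grid: >= 64 samples per FWHM of the sharpest peak
        n = int(64 * vc.finesse(r) * 4)
        phase = np.linspace(0, 2 * np.pi, n, endpoint=False)
        t = (1 - r) ** 2 / (1 + r**2 - 2 * r * np.cos(phase))
        assert t.max() / t.min() == pytest.approx(vc.airy_contrast(r), rel=0.01)
        assert t.mean() == pytest.approx(vc.airy_mean_transmission(r), rel=0.01)

    def test_numeric_mean_transmission_matches_analytic(self):
        assert vc.mean_transmission(0.94) == pytest.approx(
            vc.airy_mean_transmission(0.94), rel=1e-4
        )


class TestScalars:
    def test_effective_reflectance(self):
        assert vc.effective_reflectance(1.0, 0.92) == pytest.approx(0.95917, abs=1e-5)
        assert vc.effective_reflectance(0.75, 0.75) == pytest.approx(0.75)
        assert vc.effective_reflectance(0.0, 0.9) == 0.0

    def test_fsr_of_standard_30ghz_plate(self):
        # 3.37 mm fused silica plate -> ~30 GHz
        assert vc.free_spectral_range(3.3700000e-3, 1.45) == pytest.approx(30.7, abs=0.1)

    def test_fsr_inverse_proportionality_and_identity(self):
        f1 = vc.free_spectral_range(2e-3, 1.5)
        f2 = vc.free_spectral_range(4e-3, 1.5)
        assert f1 == pytest.approx(2 * f2, rel=1e-12)
        assert vc.free_spectral_range(5e-3, 1.5) == pytest.approx(
            C / (2 * 1.5 * 5e-3) / 1e9, rel=1e-12
        )
        # fsr * 2 n d / c = 1 identically
        assert vc.free_spectral_range(3.7e-3, 1.33) * 1e9 * 2 * 1.33 * 3.7e-3 / C == (
            pytest.approx(1.0, rel=1e-12)
        )

    def test_finesse_values(self):
        assert round(vc.finesse(0.75)) == 11
        assert vc.finesse(0.75) == pytest.approx(10.88, abs=0.01)
        assert vc.finesse(0.94) == pytest.approx(math.pi * math.sqrt(0.94) / 0.06, rel=1e-12)

    @given(st.floats(0.01, 0.97))
    def test_finesse_monotone(self, r):
        assert vc.finesse(r + 0.02) > vc.finesse(r)


@pytest.fixture
def small_geometry():
    return OpticalGeometry(
        wavelength_m=785e-9,
        collimator_focal_m=50e-3,
        imaging_focal_m=200e-3,
        pixel_pitch_m=0.15e-6,
        sensor_shape=(16000, 4),
        pixel_pitch_x_m=1e-6,
    )


@pytest.fixture
def vipa():
    return CavitySpec(3.3700000e-3, 1.45, 1.0, 0.92, tilt_y_rad=np.deg2rad(2.0))


class TestAngleMapping:
    def test_axis_pixel_no_tilt_gives_unity(self, small_geometry):
        cav = CavitySpec(1e-3, 1.45, 0.9, 0.9)
        cos_t = vc.pixel_to_internal_cos(small_geometry.axis, small_geometry, cav)
        assert cos_t == pytest.approx(1.0, abs=1e-15)

    def test_off_axis_snell(self):
        # 3 mm displacement with a 300 mm imaging lens: theta_ext ~ 0.01 rad
        geom = OpticalGeometry(785e-9, 50e-3, 300e-3, 100e-6, (61, 3))
        cav = CavitySpec(1e-3, 1.45, 0.9, 0.9)
        row = geom.axis[0] + 30  # 30 px * 100 um = 3 mm
        got = vc.pixel_to_internal_cos((row, geom.axis[1]), geom, cav)
        theta_ext = 3e-3 / 300e-3
        expected = math.cos(math.asin(math.sin(theta_ext) / 1.45))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_mirror_symmetry_about_axis(self, small_geometry):
        cav = CavitySpec(1e-3, 1.45, 0.9, 0.9)
        r0, c0 = small_geometry.axis
        a = vc.pixel_to_internal_cos((r0 - 500, c0), small_geometry, cav)
        b = vc.pixel_to_internal_cos((r0 + 500, c0), small_geometry, cav)
        assert a == pytest.approx(b, rel=1e-14)

    def test_out_of_bounds_pixel(self, small_geometry):
        cav = CavitySpec(1e-3, 1.45, 0.9, 0.9)
        with pytest.raises(ValueError):
            vc.pixel_to_internal_cos((1e6, 0), small_geometry, cav)


class TestTransferMaps:
    def test_zero_reflectance_is_all_ones(self, small_geometry):
        cav = CavitySpec(1e-3, 1.45, 0.0, 0.0, tilt_y_rad=0.02)
        m = vc.cavity_transfer_map(cav, small_geometry)
        assert np.allclose(m.values, 1.0)

    def test_maxima_lie_on_resonances_one_fsr_apart(self, small_geometry, vipa):
        """Transmission maxima occur at integer round-trip phase, and
        successive maxima differ by exactly one order (one FSR)."""
        m = vc.cavity_transfer_map(vipa, small_geometry)
        col = int(small_geometry.axis[1])
        profile = m.values[:, col]
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(profile, height=0.5, distance=100)
        assert len(peaks) >= 2
        phases = []
        for p in peaks:
            cos_t = vc.pixel_to_internal_cos((float(p), col), small_geometry, vipa)
            phases.append(
                4 * np.pi * vipa.index * vipa.thickness_m * cos_t / 785e-9 / (2 * np.pi)
            )
        orders = np.array(phases)
        # each peak within a small fraction of an order of an integer
        assert np.all(np.abs(orders - np.round(orders)) < 0.02)
        # consecutive maxima exactly one order apart
        assert np.all(np.abs(np.diff(np.round(orders))) == 1)

    def test_cascade_single_equals_cavity(self, small_geometry, vipa):
        a = vc.cavity_transfer_map(vipa, small_geometry)
        b = vc.cascade_transfer_map([vipa], small_geometry)
        assert np.array_equal(a.values, b.values)

    def test_cascade_allpass_stage_is_identity(self, small_geometry, vipa):
        allpass = CavitySpec(1e-3, 1.45, 0.0, 0.0)
        a = vc.cascade_transfer_map([vipa], small_geometry)
        b = vc.cascade_transfer_map([vipa, allpass], small_geometry)
        assert np.allclose(a.values, b.values)

    def test_cascade_bounded_by_elementwise_min(self, small_geometry, vipa):
        etalon = vipa.replace(reflectance_front=0.94, reflectance_back=0.94)
        a = vc.cavity_transfer_map(vipa, small_geometry).values
        b = vc.cavity_transfer_map(etalon, small_geometry).values
        c = vc.cascade_transfer_map([vipa, etalon], small_geometry).values
        assert np.all(c <= np.minimum(a, b) + 1e-12)

    def test_cascade_empty_list_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            vc.cascade_transfer_map([], small_geometry)

    def test_joint_antiresonance_product(self):
        # two aligned R = 0.75 stages at anti-resonance: (1/49)^2
        lam, n = 785e-9, 1.45
        d = resonant_thickness(10_000.5, n, lam)
        geom = OpticalGeometry(lam, 50e-3, 200e-3, 1e-6, (3, 3))
        cav = CavitySpec(d, n, 0.75, 0.75)
        t = vc.cascade_transmission_at(
            geom.axis[0], geom.axis[1], [cav, cav], geom
        )
        assert t == pytest.approx((1.0 / 49.0) ** 2, rel=1e-9)

    def test_matched_etalon_thickness_restores_unity_peak(self, confocal):
        from scipy.optimize import minimize_scalar

        _, cavities, geometry = confocal
        vipa, etalon = cavities
        offset = vc.matched_etalon_thickness(vipa, etalon) - vipa.thickness_m
        assert 2.3e-9 < offset < 2.6e-9  # ~2.44 nm for 0.1 deg x-tilt
        matched = etalon.replace(thickness_m=vipa.thickness_m + offset)
        col = geometry.axis[1]
        rows = np.linspace(0, geometry.sensor_shape[0] - 1, 50001)
        t = vc.cascade_transmission_at(rows, col, [vipa, matched], geometry)
        r0 = rows[int(np.argmax(t))]
        res = minimize_scalar(
            lambda r: -vc.cascade_transmission_at(r, col, [vipa, matched], geometry),
            bounds=(r0 - 3, r0 + 3),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert -res.fun > 1 - 1e-6


class TestNonuniformTransfer:
    GH_PEAK_ORACLE = 0.8162421357  # quadrature over Normal(0, 1.5 nm), R = 0.94

    def test_zero_sigma_identical_to_ideal(self, small_geometry, vipa):
        ideal = vc.cavity_transfer_map(vipa, small_geometry)
        avg = vc.nonuniform_transfer(vipa, small_geometry, seed=1)
        assert np.array_equal(ideal.values, avg.values)

    def test_peak_below_unity_and_decreasing_in_sigma(self, small_geometry, vipa):
        peaks = []
        for sigma in (0.5e-9, 1.5e-9, 3e-9):
            cav = vipa.replace(
                reflectance_front=0.94, reflectance_back=0.94, thickness_sigma_m=sigma
            )
            m = vc.nonuniform_transfer(
                cav, small_geometry, num_samples=41, method="gauss-hermite"
            )
            peaks.append(m.max())
        assert all(p < 1.0 for p in peaks)
        assert peaks[0] > peaks[1] > peaks[2]

    def test_gauss_hermite_matches_quadrature_oracle(self, small_geometry, vipa):
        cav = vipa.replace(
            reflectance_front=0.94, reflectance_back=0.94, thickness_sigma_m=1.5e-9
        )
        m = vc.nonuniform_transfer(
            cav, small_geometry, num_samples=41, method="gauss-hermite"
        )
        # map peak limited by pixel sampling; small positive tolerance
        assert m.max() == pytest.approx(self.GH_PEAK_ORACLE, abs=2e-3)
        assert vc.peak_transmission_nonuniform(
            0.94, 3.37e-3, 1.45, 785e-9, 1.5e-9
        ) == pytest.approx(self.GH_PEAK_ORACLE, abs=1e-8)

    def test_seeded_draws_deterministic_and_near_oracle(self, small_geometry, vipa):
        cav = vipa.replace(
            reflectance_front=0.94, reflectance_back=0.94, thickness_sigma_m=1.5e-9
        )
        a = vc.nonuniform_transfer(cav, small_geometry, num_samples=201, seed=42)
        b = vc.nonuniform_transfer(cav, small_geometry, num_samples=201, seed=42)
        assert np.array_equal(a.values, b.values)
        assert a.max() == pytest.approx(self.GH_PEAK_ORACLE, rel=0.05)

    def test_converges_to_ideal_as_sigma_vanishes(self, small_geometry, vipa):
        ideal = vc.cavity_transfer_map(vipa, small_geometry).values
        errs = []
        for sigma in (1e-9, 1e-10, 1e-11):
            cav = vipa.replace(thickness_sigma_m=sigma)
            m = vc.nonuniform_transfer(
                cav, small_geometry, num_samples=21, method="gauss-hermite"
            )
            errs.append(np.abs(m.values - ideal).max())
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-4

    def test_invalid_sample_count(self, small_geometry, vipa):
        with pytest.raises(ValueError):
            vc.nonuniform_transfer(vipa, small_geometry, num_samples=0)


class TestValidation:
    def test_cavity_spec_invariants(self):
        with pytest.raises(ValueError):
            CavitySpec(-1e-3, 1.45, 0.9, 0.9)
        with pytest.raises(ValueError):
            CavitySpec(1e-3, 0.9, 0.9, 0.9)
        with pytest.raises(ValueError):
            CavitySpec(1e-3, 1.45, 1.2, 0.9)
        with pytest.raises(ValueError):
            CavitySpec(1e-3, 1.45, 1.0, 1.0)  # lossless limit undefined
        with pytest.raises(ValueError):
            CavitySpec(1e-3, 1.45, 0.9, 0.9, thickness_sigma_m=-1e-9)

    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            OpticalGeometry(785e-9, -50e-3, 200e-3, 1e-6, (10, 10))
        with pytest.raises(ValueError):
            OpticalGeometry(785e-9, 50e-3, 200e-3, 1e-6, (10, 10), axis_pixel=(20, 0))
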