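"""Core spectrum operations against hand-computed and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preedge import (
    BroadeningKernel,
    Spectrum,
    StickSpectrum,
    area,
    area_normalize,
    boxcar_bin,
    broaden_sticks,
    resample,
    subtract_spectra,
    sum_spectra,
)


class TestSpectrumInvariants:
    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            Spectrum([1.0, 2.0], [1.0])

    def test_rejects_non_increasing_energies(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum([1.0, 1.0, 2.0], [0.0, 0.0, 0.0])

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            Spectrum([1.0, 2.0], [np.nan, 0.0])

    def test_negative_intensities_allowed(self):
        s = Spectrum([1.0, 2.0], [-1.0, 1.0])  # difference spectra
        assert s.intensities[0] == -1.0


class TestResample:
    def test_identity_on_own_grid(self, random_spectrum):
        out = resample(random_spectrum, random_spectrum.energies)
        np.testing.assert_allclose(out.intensities, random_spectrum.intensities)
        assert out.meta == random_spectrum.meta

    def test_linear_function_exact(self):
        e = np.array([0.0, 0.5, 1.3, 2.0, 4.0])
        s = Spectrum(e, 2.0 * e + 1.0)
        q = np.array([0.2, 0.9, 1.7, 3.3])
        np.testing.assert_allclose(
            resample(s, q).intensities, 2.0 * q + 1.0, rtol=1e-14
        )

    def test_matches_two_point_interpolation_oracle(self, rng, random_spectrum):
        s = random_spectrum
        queries = np.sort(rng.uniform(s.energies[0], s.energies[-1], size=7))
        got = resample(s, queries).intensities
        for q, g in zip(queries, got):
            # independent per-point two-point interpolation
            j = np.searchsorted(s.energies, q)
            if s.energies[j] == q:
                expected = s.intensities[j]
            else:
                x0, x1 = s.energies[j - 1], s.energies[j]
                y0, y1 = s.intensities[j - 1], s.intensities[j]
                expected = y0 + (y1 - y0) * (q - x0) / (x1 - x0)
            assert g == pytest.approx(expected, rel=1e-12)

    def test_refuses_extrapolation(self, random_spectrum):
        lo = random_spectrum.energies[0]
        with pytest.raises(ValueError, match="extrapolation"):
            resample(random_spectrum, [lo - 1.0, lo + 1.0])


class TestBoxcarBin:
    def test_constant_unchanged(self):
        s = Spectrum(np.arange(9.0), np.full(9, 3.3))
        np.testing.assert_allclose(boxcar_bin(s, 5).intensities, 3.3)

    def test_window_one_is_identity(self, random_spectrum):
        out = boxcar_bin(random_spectrum, 1)
        np.testing.assert_array_equal(out.intensities, random_spectrum.intensities)

    def test_hand_computed_window3(self):
        s = Spectrum(np.arange(5.0), [0.0, 1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(
            boxcar_bin(s, 3).intensities, [0.5, 1.0, 2.0, 3.0, 3.5]
        )

    def test_even_window_rejected(self, random_spectrum):
        with pytest.raises(ValueError, match="odd"):
            boxcar_bin(random_spectrum, 4)

    def test_grid_preserved(self, random_spectrum):
        out = boxcar_bin(random_spectrum, 3)
        np.testing.assert_array_equal(out.energies, random_spectrum.energies)

    def test_white_noise_variance_reduced_by_window(self, rng):
        n = 20000
        s = Spectrum(np.arange(float(n)), rng.normal(0, 1, size=n))
        out = boxcar_bin(s, 5)
        interior = out.intensities[2:-2]
        ratio = np.var(s.intensities) / np.var(interior)
        assert 5 * 0.7 < ratio < 5 * 1.3


class TestArea:
    def test_constant_unit_area(self):
        s = Spectrum([0.0, 0.25, 1.0], [1.0, 1.0, 1.0])
        assert area(s, (0.0, 1.0)) == pytest.approx(1.0)

    def test_triangle(self):
        s = Spectrum([0.0, 1.0], [0.0, 1.0])
        assert area(s, (0.0, 1.0)) == pytest.approx(0.5)

    def test_partial_region_interpolates_endpoints(self):
        s = Spectrum([0.0, 1.0], [0.0, 1.0])
        # integral of y=x over [0.25, 0.75]
        assert area(s, (0.25, 0.75)) == pytest.approx(0.25)

    def test_against_fine_riemann_sum(self, rng):
        e = np.linspace(0.0, 10.0, 101)
        y = np.exp(-0.5 * (e - 5.0) ** 2) + 0.1 * np.sin(e)
        s = Spectrum(e, y)
        region = (1.234, 8.9)
        fine = np.linspace(region[0], region[1], 100 * 101)
        riemann = np.sum(np.interp(fine, e, y)) * (fine[1] - fine[0])
        assert area(s, region) == pytest.approx(riemann, rel=1e-4)

    def test_inverted_region_rejected(self, random_spectrum):
        lo, hi = random_spectrum.span
        with pytest.raises(ValueError, match="empty or inverted"):
            area(random_spectrum, (hi, lo))


class TestAreaNormalize:
    def test_halves_intensities(self):
        s = Spectrum([0.0, 1.0], [2.0, 2.0])  # area 2 over [0,1]
        out = area_normalize(s, (0.0, 1.0), 1.0)
        np.testing.assert_allclose(out.intensities, 1.0)

    def test_exact_target_and_idempotent(self, random_spectrum):
        region = random_spectrum.span
        out = area_normalize(random_spectrum, region, 3.7)
        assert area(out, region) == pytest.approx(3.7, rel=1e-12)
        again = area_normalize(out, region, 3.7)
        np.testing.assert_allclose(again.intensities, out.intensities, rtol=1e-12)

    def test_zero_area_rejected(self):
        s = Spectrum([0.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="cannot normalize"):
            area_normalize(s, (0.0, 1.0), 1.0)


class TestSubtractSum:
    def test_self_subtraction_zero(self, random_spectrum):
        out = subtract_spectra(random_spectrum, random_spectrum)
        np.testing.assert_allclose(out.intensities, 0.0)

    def test_constant_offset(self, random_spectrum):
        b = random_spectrum
        a = b.with_intensities(b.intensities + 0.5)
        np.testing.assert_allclose(subtract_spectra(a, b).intensities, 0.5)

    def test_sum_of_one_is_itself(self, random_spectrum):
        out = sum_spectra([random_spectrum])
        np.testing.assert_array_equal(out.intensities, random_spectrum.intensities)

    def test_sum_with_negation_is_zero(self, random_spectrum):
        neg = random_spectrum.with_intensities(-random_spectrum.intensities)
        np.testing.assert_allclose(
            sum_spectra([random_spectrum, neg]).intensities, 0.0
        )

    def test_four_site_sum_matches_loop_oracle(self, rng):
        e = np.linspace(6538.0, 6545.0, 50)
        parts = [Spectrum(e, rng.uniform(0, 1, size=50)) for _ in range(4)]
        got = sum_spectra(parts).intensities
        expected = np.zeros(50)
        for part in parts:
            for i in range(50):
                expected[i] += part.intensities[i]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_empty_sum_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sum_spectra([])


class TestBroadening:
    def test_single_stick_peak_position_and_area(self):
        st_ = StickSpectrum("Mn1", [6505.0], [2.5])
        kernel = BroadeningKernel("gaussian", fwhm=1.0)
        grid = np.arange(6495.0, 6515.0, 0.05)
        s = broaden_sticks(st_, kernel, grid)
        assert grid[np.argmax(s.intensities)] == pytest.approx(6505.0, abs=0.051)
        assert area(s, (grid[0], grid[-1])) == pytest.approx(2.5, rel=1e-6)

    def test_half_maximum_at_half_fwhm(self):
        st_ = StickSpectrum("Mn1", [6505.0], [1.0])
        kernel = BroadeningKernel("gaussian", fwhm=1.0)
        grid = np.array([6504.5, 6505.0, 6505.5])
        s = broaden_sticks(st_, kernel, grid)
        assert s.intensities[0] == pytest.approx(s.intensities[1] / 2, rel=1e-9)
        assert s.intensities[2] == pytest.approx(s.intensities[1] / 2, rel=1e-9)

    def test_linearity_two_sticks(self):
        kernel = BroadeningKernel("gaussian", fwhm=0.8)
        grid = np.arange(6500.0, 6512.0, 0.1)
        a = StickSpectrum("Mn2", [6504.0], [1.0])
        b = StickSpectrum("Mn2", [6507.0], [0.5])
        ab = StickSpectrum("Mn2", [6504.0, 6507.0], [1.0, 0.5])
        got = broaden_sticks(ab, kernel, grid).intensities
        expected = (
            broaden_sticks(a, kernel, grid).intensities
            + broaden_sticks(b, kernel, grid).intensities
        )
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    @pytest.mark.parametrize("shape", ["gaussian", "lorentzian", "pseudo_voigt"])
    def test_broadening_conserves_total_intensity(self, rng, shape):
        e = rng.uniform(6503.0, 6508.0, size=25)
        intens = rng.uniform(0.1, 2.0, size=25)
        sticks = StickSpectrum("Mn3", e, intens)
        kernel = BroadeningKernel(shape, fwhm=1.0)
        grid = np.arange(6503.0 - 60.0, 6508.0 + 60.0, 0.1)  # wide for Lorentzian tails
        s = broaden_sticks(sticks, kernel, grid)
        total = float(intens.sum())
        tol = 1e-4 if shape == "gaussian" else 2e-2  # Lorentzian tails decay slowly
        assert area(s, (grid[0], grid[-1])) == pytest.approx(total, rel=tol)

    def test_broadening_and_summation_commute(self, rng):
        kernel = BroadeningKernel("gaussian", fwhm=1.0)
        grid = np.arange(6500.0, 6512.0, 0.1)
        a = StickSpectrum("Mn1", rng.uniform(6504, 6507, 5), rng.uniform(0.1, 1, 5))
        b = StickSpectrum("Mn1", rng.uniform(6504, 6507, 7), rng.uniform(0.1, 1, 7))
        union = StickSpectrum(
            "Mn1",
            np.concatenate([a.energies, b.energies]),
            np.concatenate([a.intensities, b.intensities]),
        )
        lhs = broaden_sticks(union, kernel, grid).intensities
        rhs = sum_spectra(
            [broaden_sticks(a, kernel, grid), broaden_sticks(b, kernel, grid)]
        ).intensities
        np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-12 * lhs.max())

    def test_empty_sticks_give_zero_spectrum(self):
        st_ = StickSpectrum("Mn4", [], [])
        s = broaden_sticks(st_, BroadeningKernel(), np.arange(6500.0, 6510.0, 0.5))
        np.testing.assert_array_equal(s.intensities, 0.0)

    def test_invalid_fwhm_rejected(self):
        with pytest.raises(ValueError, match="fwhm"):
            BroadeningKernel("gaussian", fwhm=0.0)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    target=st.floats(0.1, 100.0),
    seed=st.integers(0, 2**16),
)
def test_area_normalize_hits_target_for_random_spectra(target, seed):
    rng = np.random.default_rng(seed)
    e = np.sort(rng.uniform(0, 10, size=12))
    e += np.arange(12) * 1e-6  # guard against duplicate draws
    y = rng.uniform(0.1, 5.0, size=12)
    s = Spectrum(e, y)
    out = area_normalize(s, s.span, target)
    assert area(out, s.span) == pytest.approx(target, rel=1e-12)
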