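"""Spectrum container, white-referencing, unmixing and the two indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenopine.spectra import (
    Spectrum,
    average_background,
    band_value,
    normalize_to_reflectance,
    pri,
    rep,
    unmix_seedling,
)
from phenopine.synthetic import mix_measurement


def make_spectrum(values, wl=None, role="measured"):
    values = np.asarray(values, dtype=float)
    if wl is None:
        wl = np.arange(500.0, 500.0 + values.size)
    return Spectrum(wl, values, role)


class TestSpectrum:
    def test_rejects_non_increasing_grid(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum(np.array([500.0, 500.0, 501.0]), np.zeros(3))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            Spectrum(np.array([500.0, 501.0]), np.zeros(3))

    def test_csv_round_trip(self, tmp_path, endmember):
        path = tmp_path / "s.csv"
        endmember.to_csv(path)
        back = Spectrum.from_csv(path, role="endmember")
        np.testing.assert_allclose(back.values, endmember.values)


class TestNormalize:
    def test_identity_raw_equals_white(self):
        raw = make_spectrum([120.0, 80.0], role="raw")
        out = normalize_to_reflectance(raw, raw)
        np.testing.assert_allclose(out.values, 0.99)

    @pytest.mark.parametrize("factor,expected", [(0.0, 0.0), (0.5, 0.495)])
    def test_fraction_of_white(self, factor, expected):
        white = make_spectrum([200.0, 400.0], role="white")
        raw = white.with_values(white.values * factor, role="raw")
        np.testing.assert_allclose(
            normalize_to_reflectance(raw, white).values, expected
        )

    def test_homogeneous_in_common_scaling(self):
        white = make_spectrum([200.0, 400.0, 100.0], role="white")
        raw = make_spectrum([60.0, 90.0, 20.0], role="raw")
        a = normalize_to_reflectance(raw, white).values
        b = normalize_to_reflectance(
            raw.with_values(raw.values * 3.7), white.with_values(white.values * 3.7)
        ).values
        np.testing.assert_allclose(a, b)

    def test_rejects_nonpositive_white(self):
        with pytest.raises(ValueError, match="non-positive"):
            normalize_to_reflectance(
                make_spectrum([1.0, 1.0], role="raw"),
                make_spectrum([1.0, 0.0], role="white"),
            )


class TestAverageBackground:
    def test_single_spectrum_is_itself(self, background):
        out = average_background([background])
        np.testing.assert_allclose(out.values, background.values)

    def test_mean_of_two(self):
        a = make_spectrum([0.01, 0.01])
        b = make_spectrum([0.03, 0.03])
        np.testing.assert_allclose(average_background([a, b]).values, 0.02)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            average_background([])

    def test_grid_mismatch_rejected(self):
        a = make_spectrum([0.1, 0.2])
        b = make_spectrum([0.1, 0.2], wl=np.array([600.0, 601.0]))
        with pytest.raises(ValueError, match="shared"):
            average_background([a, b])


class TestUnmixing:
    def test_full_coverage_returns_measurement(self, endmember, background):
        mixed = mix_measurement(endmember, background, 1.0)
        out = unmix_seedling(mixed, background, 1.0)
        np.testing.assert_allclose(out.values, mixed.values)

    def test_worked_halves(self):
        measured = make_spectrum([0.26, 0.26])
        bg = make_spectrum([0.02, 0.02], role="background")
        out = unmix_seedling(measured, bg, 0.5)
        np.testing.assert_allclose(out.values, 0.50)

    def test_low_coverage_refused(self, endmember, background):
        mixed = mix_measurement(endmember, background, 0.05)
        with pytest.raises(ValueError, match="floor"):
            unmix_seedling(mixed, background, 0.05)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(c1=st.floats(0.1, 1.0))
    def test_unmix_inverts_mix(self, c1, endmember, background):
        """unmix(mix(R1, R2, c1)) recovers R1 for any coverage above the floor."""
        mixed = mix_measurement(endmember, background, c1)
        out = unmix_seedling(mixed, background, c1)
        np.testing.assert_allclose(out.values, endmember.values, atol=1e-12)

    def test_out_of_range_flagged_not_clipped(self):
        measured = make_spectrum([0.9, 0.9])
        bg = make_spectrum([0.0, 0.0], role="background")
        out = unmix_seedling(measured, bg, 0.5)
        assert out.metadata["out_of_range"]
        assert np.all(out.values == 1.8)


class TestBandValue:
    def test_exact_hit(self, flat_spectrum):
        s = Spectrum(np.array([530.0, 531.0, 532.0]), np.array([1.0, 2.0, 3.0]))
        assert band_value(s, 531.0) == 2.0

    def test_nearest_on_1nm_grid(self):
        s = Spectrum(np.array([530.0, 531.0, 532.0]), np.array([1.0, 2.0, 3.0]))
        assert band_value(s, 531.4) == 2.0

    def test_tie_resolves_to_lower_wavelength(self):
        s = Spectrum(np.array([530.0, 532.0]), np.array([5.0, 7.0]))
        assert band_value(s, 531.0) == 5.0

    def test_out_of_range_rejected(self, flat_spectrum):
        with pytest.raises(ValueError, match="outside"):
            band_value(flat_spectrum(0.5), 3000.0)


def index_spectrum(bands: dict):
    wl = np.array(sorted(bands))
    return Spectrum(wl, np.array([bands[w] for w in wl]))


class TestPri:
    def test_zero_when_bands_equal(self):
        assert pri(index_spectrum({531.0: 0.04, 570.0: 0.04})) == 0.0

    def test_worked_example(self):
        assert pri(index_spectrum({531.0: 0.06, 570.0: 0.04})) == pytest.approx(0.2)

    def test_boundary_minus_one(self):
        assert pri(index_spectrum({531.0: 0.0, 570.0: 0.04})) == -1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            pri(index_spectrum({531.0: 0.0, 570.0: 0.0}))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(r531=st.floats(0.0, 1.0), r570=st.floats(0.0, 1.0))
    def test_bounded_for_nonnegative_reflectance(self, r531, r570):
        if r531 + r570 == 0:
            return
        assert -1.0 <= pri(index_spectrum({531.0: r531, 570.0: r570})) <= 1.0


class TestRep:
    def worked(self, r670, r700, r740, r780):
        return rep(index_spectrum({670.0: r670, 700.0: r700,
                                   740.0: r740, 780.0: r780}))

    def test_worked_example_720(self):
        assert self.worked(0.05, 0.10, 0.40, 0.45) == pytest.approx(720.0)

    def test_lower_anchor(self):
        # (R670 + R780)/2 equals R700 -> inflection pinned at 700 nm
        assert self.worked(0.05, 0.10, 0.40, 0.15) == pytest.approx(700.0)

    def test_upper_anchor(self):
        assert self.worked(0.35, 0.10, 0.40, 0.45) == pytest.approx(740.0)

    def test_flat_red_edge_rejected(self):
        with pytest.raises(ZeroDivisionError):
            self.worked(0.1, 0.2, 0.2, 0.3)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        r670=st.floats(0.01, 0.2), r700=st.floats(0.05, 0.3),
        r740=st.floats(0.35, 0.6), r780=st.floats(0.35, 0.6),
    )
    def test_within_interval_when_rre_bracketed(self, r670, r700, r740, r780):
        r_re = (r670 + r780) / 2.0
        if not min(r700, r740) <= r_re <= max(r700, r740):
            return
        assert 700.0 <= self.worked(r670, r700, r740, r780) <= 740.0
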