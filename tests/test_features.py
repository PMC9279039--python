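import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from capsfmri.features import (
    SpectrumConfig,
    alff,
    degree_centrality,
    falff,
    reho,
    spectrum,
)
from capsfmri.io import TimeSeriesVolume
from oracles import (
    alff_bin_enumeration,
    dc_bruteforce,
    falff_bin_enumeration,
    reho_bruteforce,
)


def _vol(arr, tr=2.0):
    return TimeSeriesVolume(np.asarray(arr, dtype=float), tr)


def _series_vol(series_list, tr=2.0):
    """Stack 1D series into an (n, 1, 1, T) volume."""
    return _vol(np.asarray(series_list)[:, None, None, :], tr)


class TestDegreeCentrality:
    def test_two_identical_one_orthogonal(self):
        t = np.arange(16.0)
        s = np.sin(2 * np.pi * t / 16)
        c = np.cos(2 * np.pi * t / 16)  # orthogonal to s
        dc = degree_centrality(_series_vol([s, s, c]))
        np.testing.assert_array_equal(dc.values.ravel(), [1, 1, 0])

    def test_anticorrelated_voxel_does_not_count(self, rng):
        s = rng.normal(size=20)
        dc = degree_centrality(_series_vol([s, s, -s]))
        assert dc.values.ravel()[2] == 0  # r = -1 is not > 0.25
        np.testing.assert_array_equal(dc.values.ravel(), [1, 1, 0])

    def test_absolute_mode_counts_anticorrelation(self, rng):
        s = rng.normal(size=20)
        dc = degree_centrality(_series_vol([s, s, -s]), absolute=True)
        np.testing.assert_array_equal(dc.values.ravel(), [2, 2, 2])

    def test_shared_series_gives_complete_graph(self, rng):
        s = rng.normal(size=20)
        vols = [s + 0.0 for _ in range(5)]
        dc = degree_centrality(_series_vol(vols))
        np.testing.assert_array_equal(dc.values.ravel(), 4)

    def test_zero_variance_voxel_flagged_with_zero_dc(self, rng):
        s = rng.normal(size=20)
        dc = degree_centrality(_series_vol([s, s, np.zeros(20)]))
        assert dc.values.ravel()[2] == 0
        assert dc.flags.ravel()[2]

    def test_matches_bruteforce_oracle(self, rng):
        data = rng.normal(size=(4, 3, 3, 24))
        dc = degree_centrality(_vol(data))
        np.testing.assert_array_equal(dc.values, dc_bruteforce(data))

    def test_threshold_validation(self, rng):
        with pytest.raises(ValueError, match="threshold"):
            degree_centrality(_vol(rng.normal(size=(2, 2, 2, 10))), threshold=1.0)


class TestReHo:
    def test_identical_monotone_series_give_unit_w(self):
        t = np.arange(12.0)
        data = np.broadcast_to(t, (3, 3, 3, 12)).copy()
        w = reho(_vol(data))
        np.testing.assert_allclose(w.values, 1.0, atol=1e-12)

    def test_two_opposite_monotone_series_give_zero_w(self):
        t = np.arange(10.0)
        data = np.stack([t, -t])[:, None, None, :]
        w = reho(_vol(data), neighborhood=7)
        np.testing.assert_allclose(w.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("neighborhood", [7, 19, 27])
    def test_matches_rank_sum_oracle(self, rng, neighborhood):
        data = rng.normal(size=(5, 5, 5, 20))
        w = reho(_vol(data), neighborhood=neighborhood)
        np.testing.assert_allclose(
            w.values, reho_bruteforce(data, neighborhood), atol=1e-10
        )

    def test_invalid_neighborhood(self, rng):
        with pytest.raises(ValueError, match="neighborhood"):
            reho(_vol(rng.normal(size=(3, 3, 3, 10))), neighborhood=9)


class TestSpectrum:
    def test_constant_series_is_dc_only(self):
        freqs, amp = spectrum(np.full(16, 3.0), fs=0.5)
        assert amp[0] == pytest.approx(48.0)
        np.testing.assert_allclose(amp[1:], 0.0, atol=1e-10)

    def test_on_bin_sinusoid_concentrates_at_half_t(self):
        T, h = 64, 5
        t = np.arange(T)
        series = np.sin(2 * np.pi * h * t / T)
        freqs, amp = spectrum(series, fs=0.5)
        assert amp[h] == pytest.approx(T / 2)
        mask = np.ones(amp.size, dtype=bool)
        mask[h] = False
        assert np.abs(amp[mask]).max() < 1e-9
        assert freqs[h] == pytest.approx(h * 0.5 / T)

    def test_parseval(self, rng):
        x = rng.normal(size=32)
        spec = np.fft.fft(x)
        assert (np.abs(spec) ** 2).sum() == pytest.approx(32 * (x**2).sum())


class TestALFF:
    def test_on_bin_sinusoid_and_linearity(self):
        T, tr = 128, 2.0
        t = np.arange(T) * tr
        f = 13 / (T * tr)  # in-band, exactly on bin 13
        series = np.sin(2 * np.pi * f * t)
        a1 = alff(_series_vol([series]), SpectrumConfig()).values.ravel()[0]
        a2 = alff(_series_vol([2 * series]), SpectrumConfig()).values.ravel()[0]
        assert a1 == pytest.approx(T / 2, rel=1e-10)
        assert a2 == pytest.approx(2 * a1, rel=1e-10)

    def test_out_of_band_sinusoid_is_zero(self):
        T, tr = 128, 2.0
        t = np.arange(T) * tr
        f = 51 / (T * tr)  # on-bin, ~0.199 Hz
        series = np.sin(2 * np.pi * f * t)
        assert alff(_series_vol([series])).values.ravel()[0] < 1e-8

    def test_matches_bin_enumeration_oracle(self, rng):
        series = rng.normal(size=64)
        got = alff(_series_vol([series])).values.ravel()[0]
        expected = alff_bin_enumeration(series, 0.5, 0.01, 0.08)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_power_mode_matches_squared_oracle(self, rng):
        series = rng.normal(size=64)
        got = alff(_series_vol([series]), SpectrumConfig(power_mode=True)).values.ravel()[0]
        expected = alff_bin_enumeration(series, 0.5, 0.01, 0.08, power=True)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_empty_band_is_configuration_error(self, rng):
        vol = _series_vol([rng.normal(size=16)], tr=0.01)  # bin spacing 6.25 Hz
        with pytest.raises(ValueError, match="no DFT bin"):
            alff(vol)


class TestFALFF:
    def test_band_limited_signal_gives_one(self):
        T, tr = 128, 2.0
        t = np.arange(T) * tr
        series = np.sin(2 * np.pi * (13 / (T * tr)) * t)
        assert falff(_series_vol([series])).values.ravel()[0] == pytest.approx(1.0, abs=1e-10)

    def test_equal_in_and_out_of_band_sinusoids_give_half(self):
        T, tr = 128, 2.0
        t = np.arange(T) * tr
        series = np.sin(2 * np.pi * (13 / (T * tr)) * t) + np.sin(
            2 * np.pi * (51 / (T * tr)) * t
        )
        assert falff(_series_vol([series])).values.ravel()[0] == pytest.approx(0.5, abs=1e-10)

    def test_matches_bin_enumeration_oracle(self, rng):
        series = rng.normal(size=64)
        got = falff(_series_vol([series])).values.ravel()[0]
        expected = falff_bin_enumeration(series, 0.5, 0.01, 0.08)
        assert got == pytest.approx(expected, abs=1e-10)

    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        series = rng.normal(size=64)
        a = falff(_series_vol([series])).values.ravel()[0]
        b = falff(_series_vol([scale * series])).values.ravel()[0]
        assert b == pytest.approx(a, abs=1e-10)

    def test_constant_series_flagged_zero(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            out = falff(_series_vol([np.full(64, 2.0), np.random.default_rng(0).normal(size=64)]))
        assert out.values.ravel()[0] == 0.0
        assert out.flags.ravel()[0]

    def test_range_invariant(self, rng):
        data = rng.normal(size=(4, 4, 4, 32))
        vals = falff(_vol(data)).values
        assert vals.min() >= 0.0 and vals.max() <= 1.0
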