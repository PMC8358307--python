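"""Spectral parameters: closed forms, oracle comparisons, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nptnet
from nptnet.errors import DegenerateBandError, DegenerateSignalError, DomainError
from nptnet.spectral import CANONICAL_BANDS, relative_power
from conftest import make_spectrum

FS = 1000.0
T = np.arange(5000) / FS


def tone(freq, phase=0.0):
    return np.sin(2 * np.pi * freq * T + phase)


class TestBlackmanTukey:
    def test_single_tone_concentration(self):
        s = nptnet.blackman_tukey_psd(tone(10.0), FS)
        near = s.densities[(s.frequencies >= 9) & (s.frequencies <= 11)].sum()
        wide = s.densities[(s.frequencies >= 8) & (s.frequencies <= 12)].sum()
        # ~2% of mass sits in a broadband O(1/n) autocorrelation edge floor,
        # so the +/-1 Hz concentration is just below 99%
        assert near >= 0.97
        assert wide >= 0.99

    def test_density_normalized(self, rng):
        s = nptnet.blackman_tukey_psd(rng.standard_normal(4000), FS)
        assert s.densities.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(s.densities >= 0)
        assert s.frequencies[0] >= 1.0 and s.frequencies[-1] <= 70.0

    def test_two_tone_band_balance_matches_periodogram(self):
        """Equal tones at 6 and 20 Hz split mass evenly, as in a periodogram."""
        x = tone(6.0) + tone(20.0, phase=1.0)
        s = nptnet.blackman_tukey_psd(x, FS)
        near6 = s.densities[np.abs(s.frequencies - 6) <= 2].sum()
        near20 = s.densities[np.abs(s.frequencies - 20) <= 2].sum()
        assert near6 == pytest.approx(near20, abs=0.02)
        # independent oracle: direct periodogram mass ratio
        from scipy.signal import periodogram

        f, p = periodogram(x, FS)
        m6 = p[np.abs(f - 6) <= 2].sum()
        m20 = p[np.abs(f - 20) <= 2].sum()
        assert m6 / m20 == pytest.approx(near6 / near20, abs=0.02)

    def test_constant_epoch_rejected(self):
        with pytest.raises(DegenerateSignalError):
            nptnet.blackman_tukey_psd(np.ones(1000), FS)

    def test_low_rate_rejected(self):
        with pytest.raises(DomainError):
            nptnet.blackman_tukey_psd(np.sin(T[:500]), 100.0)


class TestRelativePower:
    def test_alpha_tone(self):
        s = nptnet.blackman_tukey_psd(tone(10.0), FS)
        alpha = next(b for b in CANONICAL_BANDS if b.name == "Alpha")
        assert relative_power(s, alpha) >= 0.97

    def test_bands_tile_support(self, rng):
        s = nptnet.blackman_tukey_psd(rng.standard_normal(5000), FS)
        total = sum(relative_power(s, b) for b in CANONICAL_BANDS)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_equal_tones_split(self):
        s = nptnet.blackman_tukey_psd(tone(6.0) + tone(20.0, 1.0), FS)
        theta = next(b for b in CANONICAL_BANDS if b.name == "Theta")
        beta2 = next(b for b in CANONICAL_BANDS if b.name == "Beta2")
        assert relative_power(s, theta) == pytest.approx(0.5, abs=0.02)
        assert relative_power(s, beta2) == pytest.approx(0.5, abs=0.02)

    def test_band_outside_support(self):
        s = nptnet.blackman_tukey_psd(tone(10.0), FS)
        with pytest.raises(DomainError):
            relative_power(s, nptnet.BandDefinition("hf", 60.0, 90.0))


class TestQuantileFrequencies:
    def test_tone_identities(self):
        s = nptnet.blackman_tukey_psd(tone(10.0), FS)
        res = s.resolution
        assert nptnet.median_frequency(s) == pytest.approx(10.0, abs=res)
        assert nptnet.individual_alpha_frequency(s) == pytest.approx(10.0, abs=res)
        assert nptnet.spectral_edge_frequency(s) == pytest.approx(10.0, abs=1.5)

    def test_flat_spectrum_analytic(self):
        s = make_spectrum(np.ones(139))
        assert nptnet.median_frequency(s) == pytest.approx(35.5, abs=s.resolution)
        assert nptnet.spectral_edge_frequency(s) == pytest.approx(
            1 + 0.95 * 69, abs=s.resolution
        )
        assert nptnet.spectral_edge_frequency(s, coverage=1.0) == 70.0

    def test_iaf_peak_on_flat_background(self):
        """A symmetric alpha peak at 9 Hz dominates the 4-15 Hz median."""
        f = np.linspace(1.0, 70.0, 139)
        d = 0.01 + 10 * np.exp(-0.5 * ((f - 9.0) / 0.6) ** 2)
        s = make_spectrum(d)
        # numeric cumulative oracle over the restricted band
        mask = (f >= 4) & (f <= 15)
        dens = s.densities[mask] / s.densities[mask].sum()
        expected = f[mask][np.searchsorted(np.cumsum(dens), 0.5)]
        assert nptnet.individual_alpha_frequency(s) == pytest.approx(
            expected, abs=s.resolution
        )
        assert nptnet.individual_alpha_frequency(s) == pytest.approx(9.0, abs=s.resolution)

    def test_iaf_empty_band(self):
        f = np.linspace(1.0, 70.0, 139)
        d = np.where(f > 20, 1.0, 0.0)
        with pytest.raises(DegenerateBandError):
            nptnet.individual_alpha_frequency(make_spectrum(d))


class TestSpectralEntropy:
    def test_delta_distribution(self):
        d = np.zeros(139)
        d[40] = 1.0
        assert nptnet.spectral_entropy(make_spectrum(d)) == 0.0

    def test_flat(self):
        assert nptnet.spectral_entropy(make_spectrum(np.ones(139))) == pytest.approx(1.0)

    def test_two_equal_bins_closed_form(self):
        d = np.zeros(139)
        d[10] = d[100] = 1.0
        expected = np.log(2) / np.log(139)
        assert nptnet.spectral_entropy(make_spectrum(d)) == pytest.approx(expected)


@settings(max_examples=250, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_random_spectrum_invariants(seed):
    """Range/ordering invariants hold on arbitrary random spectra."""
    r = np.random.default_rng(seed)
    d = r.random(r.integers(10, 300)) ** 2
    s = make_spectrum(d + 1e-12)
    mf = nptnet.median_frequency(s)
    sef = nptnet.spectral_edge_frequency(s)
    se = nptnet.spectral_entropy(s)
    assert 1.0 <= mf <= 70.0
    assert mf <= sef <= 70.0
    assert 0.0 <= se <= 1.0
    total = sum(relative_power(s, b) for b in CANONICAL_BANDS)
    assert total == pytest.approx(1.0, abs=1e-9)


def test_quantiles_monotone_under_rightward_shift():
    """MF, IAF and SEF never decrease when spectral mass moves right."""
    base = np.exp(-0.5 * ((np.linspace(1, 70, 139) - 8.0) / 3.0) ** 2) + 0.01
    prev = (0.0, 0.0, 0.0)
    for shift in range(0, 60, 5):
        s = make_spectrum(np.roll(base, shift))
        cur = (
            nptnet.median_frequency(s),
            nptnet.individual_alpha_frequency(s),
            nptnet.spectral_edge_frequency(s),
        )
        assert cur[0] >= prev[0] and cur[2] >= prev[2]
        prev = cur
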