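"""Spectral parameters of a single epoch.

The normalized power spectral density (PSDn) is estimated with the
Blackman-Tukey method: the biased sample autocorrelation is tapered with a
Blackman lag window and Fourier transformed.  The resulting density is
restricted to the 1-70 Hz analysis band and renormalized to unit sum, so
every spectral parameter below is a functional of a discrete probability
distribution over frequency bins.

Five parameter families are derived from the PSDn:

* relative power (RP) in the six canonical bands delta (1-4 Hz),
  theta (4-8), alpha (8-13), beta-1 (13-19), beta-2 (19-30), gamma (30-70);
* median frequency (MF), the 50% quantile of the PSDn;
* individual alpha frequency (IAF), the median of the PSDn restricted to
  the extended alpha band 4-15 Hz;
* spectral entropy (SE), the Shannon entropy of the PSDn normalized by
  ``log(N)`` so it lies in [0, 1];
* spectral edge frequency (SEF), the 95% quantile of the PSDn.

Quantile-type parameters return the left edge of the first bin at which the
cumulative density reaches the threshold (smallest such frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len

from .errors import DegenerateBandError, DegenerateSignalError, DomainError, InputError

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "NormalizedSpectrum",
    "blackman_tukey_psd",
    "relative_power",
    "median_frequency",
    "individual_alpha_frequency",
    "spectral_entropy",
    "spectral_edge_frequency",
]

F_MIN = 1.0
F_MAX = 70.0


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (self.f_low < self.f_high):
            raise DomainError(f"band {self.name}: f_low must be < f_high")


CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("Delta", 1.0, 4.0),
    BandDefinition("Theta", 4.0, 8.0),
    BandDefinition("Alpha", 8.0, 13.0),
    BandDefinition("Beta1", 13.0, 19.0),
    BandDefinition("Beta2", 19.0, 30.0),
    BandDefinition("Gamma", 30.0, 70.0),
)


@dataclass
class NormalizedSpectrum:
    """Discrete PSDn on an evenly spaced grid spanning [1, 70] Hz.

    ``densities`` is non-negative and sums to one; ``frequencies`` is strictly
    increasing with constant resolution.
    """

    frequencies: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        if f.ndim != 1 or f.shape != d.shape or f.size < 2:
            raise InputError("spectrum needs matching 1-D frequency/density arrays")
        steps = np.diff(f)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise InputError("frequencies must be strictly increasing with constant step")
        if np.any(d < 0):
            raise InputError("densities must be non-negative")
        if abs(d.sum() - 1.0) > 1e-9:
            raise InputError("densities must sum to 1 within 1e-9")
        self.frequencies = f
        self.densities = d

    @property
    def resolution(self) -> float:
        """Frequency step in Hz."""
        return float(self.frequencies[1] - self.frequencies[0])

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.densities)


def blackman_tukey_psd(
    epoch: np.ndarray,
    sampling_rate: float,
    *,
    max_lag_fraction: float = 0.2,
    f_min: float = F_MIN,
    f_max: float = F_MAX,
) -> NormalizedSpectrum:
    """Blackman-Tukey PSDn of one epoch, restricted to [f_min, f_max] Hz.

    The biased autocorrelation is estimated up to a maximum lag of
    ``max_lag_fraction * len(epoch)`` samples, tapered with a Blackman lag
    window, and transformed with an FFT of length ``2 * max_lag`` (frequency
    resolution ``sampling_rate / (2 * max_lag)``).  Small negative spectral
    values caused by finite-lag truncation are clipped to zero before
    renormalization.
    """
    x = np.asarray(epoch, dtype=float).ravel()
    if x.size < 16:
        raise InputError(f"epoch too short for spectral estimation (n={x.size})")
    if not np.all(np.isfinite(x)):
        raise InputError("epoch contains non-finite samples")
    if sampling_rate / 2.0 < f_max:
        raise DomainError(
            f"sampling rate {sampling_rate} Hz cannot resolve {f_max} Hz"
        )
    if not 0 < max_lag_fraction <= 0.5:
        raise DomainError("max_lag_fraction must be in (0, 0.5]")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant epoch: spectrum undefined")

    x = x - x.mean()
    n = x.size
    max_lag = max(int(round(n * max_lag_fraction)), 2)

    # biased autocorrelation via FFT
    nfft_ac = next_fast_len(2 * n)
    spec = np.fft.rfft(x, nfft_ac)
    acf = np.fft.irfft(spec * np.conj(spec), nfft_ac)[: max_lag + 1] / n

    lag_window = np.blackman(2 * max_lag + 1)[max_lag:]
    acf_w = acf * lag_window

    nfft = 2 * max_lag
    c = np.zeros(nfft)
    c[0] = acf_w[0]
    c[1:max_lag] = acf_w[1:max_lag]
    c[-(max_lag - 1):] = acf_w[1:max_lag][::-1]
    c[max_lag] = acf_w[max_lag]
    psd = np.real(np.fft.rfft(c))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sampling_rate)

    mask = (freqs >= f_min) & (freqs <= f_max)
    if not np.any(mask):
        raise DomainError("no frequency bins fall inside the analysis band")
    dens = np.clip(psd[mask], 0.0, None)
    total = dens.sum()
    if total <= 0:
        raise DegenerateSignalError("no power inside the analysis band")
    return NormalizedSpectrum(freqs[mask], dens / total)


def _band_mask(spectrum: NormalizedSpectrum, band: BandDefinition) -> np.ndarray:
    f = spectrum.frequencies
    # the first bin may sit up to one resolution step above the band edge
    tol = spectrum.resolution + 1e-9
    if band.f_low < f[0] - tol or band.f_high > f[-1] + tol:
        raise DomainError(
            f"band {band.name} [{band.f_low}, {band.f_high}) outside spectrum "
            f"support [{f[0]}, {f[-1]}]"
        )
    mask = (f >= band.f_low - 1e-12) & (f < band.f_high - 1e-12)
    # the final canonical band is right-closed so the bands tile the support
    if band.f_high >= f[-1] - 1e-9:
        mask |= np.isclose(f, f[-1])
    return mask


def relative_power(spectrum: NormalizedSpectrum, band: BandDefinition) -> float:
    """Fraction of PSDn mass inside ``band``; in [0, 1]."""
    return float(spectrum.densities[_band_mask(spectrum, band)].sum())


def _cumulative_quantile(freqs: np.ndarray, dens: np.ndarray, q: float) -> float:
    """Smallest frequency at which the cumulative density reaches q."""
    cum = np.cumsum(dens)
    idx = int(np.searchsorted(cum, q - 1e-12))
    idx = min(idx, freqs.size - 1)
    return float(freqs[idx])


def median_frequency(spectrum: NormalizedSpectrum) -> float:
    """Frequency splitting the PSDn into two halves of equal power."""
    return _cumulative_quantile(spectrum.frequencies, spectrum.densities, 0.5)


def individual_alpha_frequency(
    spectrum: NormalizedSpectrum, f_low: float = 4.0, f_high: float = 15.0
) -> float:
    """Median frequency of the PSDn restricted to the extended alpha band.

    The 4-15 Hz slice is renormalized before taking the median, so the IAF
    always lies inside [4, 15] Hz.  Raises if the slice carries no power.
    """
    mask = (spectrum.frequencies >= f_low) & (spectrum.frequencies <= f_high)
    dens = spectrum.densities[mask]
    total = dens.sum()
    if not np.any(mask) or total <= 0:
        raise DegenerateBandError(
            f"no spectral power inside the extended alpha band [{f_low}, {f_high}] Hz"
        )
    return _cumulative_quantile(spectrum.frequencies[mask], dens / total, 0.5)


def spectral_entropy(spectrum: NormalizedSpectrum) -> float:
    """Normalized Shannon entropy of the PSDn; 0 (single bin) to 1 (flat)."""
    p = spectrum.densities
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz))
    return float(h / np.log(p.size))


def spectral_edge_frequency(
    spectrum: NormalizedSpectrum, coverage: float = 0.95
) -> float:
    """Smallest frequency whose cumulative PSDn reaches ``coverage``."""
    if not 0 < coverage <= 1:
        raise DomainError("coverage must be in (0, 1]")
    return _cumulative_quantile(spectrum.frequencies, spectrum.densities, coverage)
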