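"""Frequency recovery from time-resolved spectra.

The recovery chain mirrors how the dominant motion frequency is extracted
from a continuous spectrometer recording of the reflected laser line:

1. slice the cube at the laser wavelength (mean over a narrow band around
   632 nm) to obtain the intensity-time respiration waveform;
2. remove the linear trend (baseline / slow drift) so the near-DC peak
   does not mask the physiological one;
3. smooth with a short centered moving average to suppress high-frequency
   distortions;
4. take the magnitude DFT (zero-padded for a finer frequency sampling);
5. pick the largest peak inside the physiological search band, refined by
   three-point parabolic interpolation, and report it in Hz and
   breaths/minute (bpm = 60 * Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend as _linear_detrend

from .acquisition import TimeResolvedSpectra

__all__ = [
    "RespirationWaveform",
    "FrequencySpectrum",
    "FrequencyEstimate",
    "extract_waveform",
    "moving_average",
    "detrend",
    "dft_spectrum",
    "pick_frequency",
    "recover",
]

#: Default physiological search band, Hz (3-150 breaths/min with margin).
DEFAULT_BAND: tuple[float, float] = (0.05, 2.5)


@dataclass
class RespirationWaveform:
    """Intensity-time section at the laser line: the measured b(t)."""

    values: np.ndarray
    time_axis: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.values.shape != self.time_axis.shape:
            raise ValueError("values and time_axis must have equal length")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.time_axis[1] - self.time_axis[0])


@dataclass
class FrequencySpectrum:
    """One-sided magnitude spectrum, B(omega) of the measured waveform."""

    frequencies: np.ndarray
    magnitudes: np.ndarray
    resolution: float  # Hz per bin

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.frequencies.shape != self.magnitudes.shape:
            raise ValueError("frequencies and magnitudes must have equal length")


@dataclass
class FrequencyEstimate:
    """The recovered dominant frequency."""

    frequency: float  # Hz
    bpm: float  # breaths per minute, exactly 60 * frequency
    peak_magnitude: float
    bin_resolution: float  # Hz
    band_searched: tuple[float, float]
    provenance: dict = field(default_factory=dict)


def extract_waveform(
    spectra: TimeResolvedSpectra, center: float = 632.0, band_halfwidth: float = 2.0
) -> RespirationWaveform:
    """Per-frame mean intensity over wavelengths within ``center +/- hw``."""
    mask = np.abs(spectra.wavelength_axis - center) <= band_halfwidth
    if not mask.any():
        raise ValueError(
            f"no wavelength bins inside [{center - band_halfwidth}, "
            f"{center + band_halfwidth}] nm"
        )
    values = spectra.intensities[:, mask].mean(axis=1)
    return RespirationWaveform(
        values=values,
        time_axis=spectra.time_axis,
        provenance={"center_nm": center, "band_halfwidth_nm": band_halfwidth,
                    **spectra.metadata},
    )


def moving_average(wave: RespirationWaveform, window: int = 3) -> RespirationWaveform:
    """Centered moving average with a shrinking window at the edges.

    The window must be odd so the filter is zero-phase; at the boundaries
    the window truncates to the available samples rather than padding with
    phantom zeros, so constants pass through unchanged and short records
    are not biased.
    """
    n = len(wave.values)
    if window < 1 or window % 2 == 0 or window > n:
        raise ValueError(
            f"window must be odd, >= 1 and <= signal length {n}, got {window}"
        )
    if window == 1:
        return wave
    kernel = np.ones(window)
    sums = np.convolve(wave.values, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return RespirationWaveform(
        values=sums / counts,
        time_axis=wave.time_axis,
        provenance={**wave.provenance, "moving_average_window": window},
    )


def detrend(wave: RespirationWaveform) -> RespirationWaveform:
    """Subtract the least-squares linear fit (baseline and slow drift)."""
    if len(wave.values) < 2:
        raise ValueError("detrend needs at least 2 samples")
    return RespirationWaveform(
        values=_linear_detrend(wave.values, type="linear"),
        time_axis=wave.time_axis,
        provenance={**wave.provenance, "detrended": True},
    )


def dft_spectrum(wave: RespirationWaveform, zero_pad_factor: int = 4) -> FrequencySpectrum:
    """Magnitude DFT on the non-negative frequency half-axis.

    Zero padding refines the frequency sampling (resolution =
    sample_rate / (n * zero_pad_factor)) without adding information; the
    underlying transform satisfies Parseval's identity exactly.
    """
    t = wave.time_axis
    if len(t) < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > 1e-9:
        raise ValueError("time axis must be uniform; resample before the DFT")
    if zero_pad_factor < 1:
        raise ValueError("zero_pad_factor must be >= 1")
    n = len(wave.values)
    nfft = n * int(zero_pad_factor)
    mags = np.abs(np.fft.rfft(wave.values, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=float(dt[0]))
    return FrequencySpectrum(frequencies=freqs, magnitudes=mags,
                             resolution=freqs[1] - freqs[0])


def pick_frequency(
    spectrum: FrequencySpectrum,
    band: tuple[float, float] = DEFAULT_BAND,
    interpolate: bool = True,
) -> FrequencyEstimate:
    """Frequency of the largest magnitude inside ``band``.

    With ``interpolate`` the peak bin is refined by fitting a parabola
    through it and its two neighbours, giving sub-bin resolution.  Ties go
    to the lower frequency.
    """
    lo, hi = band
    if not (0.0 < lo < hi):
        raise ValueError(f"band must satisfy 0 < low < high, got {band}")
    mask = (spectrum.frequencies >= lo) & (spectrum.frequencies <= hi)
    if not mask.any():
        raise ValueError(f"band {band} Hz contains no spectrum bins")
    idx = np.flatnonzero(mask)
    k = idx[int(np.argmax(spectrum.magnitudes[idx]))]  # argmax -> first = lowest

    freq = float(spectrum.frequencies[k])
    peak = float(spectrum.magnitudes[k])
    if interpolate and 0 < k < len(spectrum.magnitudes) - 1:
        alpha = spectrum.magnitudes[k - 1]
        beta = spectrum.magnitudes[k]
        gamma = spectrum.magnitudes[k + 1]
        denom = alpha - 2.0 * beta + gamma
        if denom != 0.0:
            delta = float(np.clip(0.5 * (alpha - gamma) / denom, -0.5, 0.5))
            freq += delta * spectrum.resolution
            peak = float(beta - 0.25 * (alpha - gamma) * delta)
    freq = float(np.clip(freq, lo, hi))
    return FrequencyEstimate(
        frequency=freq,
        bpm=60.0 * freq,
        peak_magnitude=peak,
        bin_resolution=spectrum.resolution,
        band_searched=(lo, hi),
        provenance={"interpolated": bool(interpolate)},
    )


def recover(
    spectra: TimeResolvedSpectra,
    center: float = 632.0,
    band_halfwidth: float = 2.0,
    window: int = 3,
    band: tuple[float, float] = DEFAULT_BAND,
    interpolate: bool = True,
    zero_pad_factor: int = 4,
) -> FrequencyEstimate:
    """Full recovery chain: slice -> detrend -> smooth -> DFT -> peak pick."""
    wave = extract_waveform(spectra, center=center, band_halfwidth=band_halfwidth)
    wave = detrend(wave)
    wave = moving_average(wave, window=window)
    spectrum = dft_spectrum(wave, zero_pad_factor=zero_pad_factor)
    estimate = pick_frequency(spectrum, band=band, interpolate=interpolate)
    estimate.provenance.update(
        center_nm=center,
        band_halfwidth_nm=band_halfwidth,
        moving_average_window=window,
        zero_pad_factor=zero_pad_factor,
    )
    return estimate
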