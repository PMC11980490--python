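"""Plant electrical-signal analysis.

Plant surface potentials are low-frequency (typically < 5 Hz), non-stationary
voltage fluctuations arising from ion fluxes (K+, Na+, Ca2+, Cl-) across cell
membranes, recorded here with stem-inserted electrodes at 2000 Hz after
analog amplification. Two complementary summaries are computed:

* time-domain statistics — maximum, minimum, peak-to-peak amplitude and the
  dominant oscillation period (from the autocorrelation function);
* frequency-domain — a one-sided Fourier amplitude spectrum, normalized so a
  pure sinusoid of amplitude A reads A at its frequency, from which the
  characteristic sub-5 Hz frequency and its amplitude are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._exceptions import ParameterizationError, UndefinedFeatureError

__all__ = [
    "Signal",
    "SignalStats",
    "AmplitudeSpectrum",
    "CharacteristicPeak",
    "signal_stats",
    "estimate_period",
    "amplitude_spectrum",
    "characteristic_frequency",
]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled voltage time series.

    Parameters
    ----------
    samples : array of float
        Voltages in volts.
    fs : float
        Sampling frequency in Hz.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ParameterizationError(f"fs must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise ParameterizationError("signal needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ParameterizationError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def to_csv(self, path: str | Path) -> None:
        """Write a two-column CSV with header ``time_s,voltage_V``."""
        df = pd.DataFrame({"time_s": self.times, "voltage_V": self.samples})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Signal":
        """Read a ``time_s,voltage_V`` CSV; fs is inferred from time steps."""
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise ParameterizationError(f"{path}: needs at least 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        return cls(df["voltage_V"].to_numpy(dtype=float), fs)


@dataclass(frozen=True)
class SignalStats:
    """Time-domain signal summary.

    ``period_ms`` is NaN when the signal has no qualifying autocorrelation
    peak (aperiodic or constant signals).
    """

    max_v: float
    min_v: float
    peak_v: float
    period_ms: float

    @property
    def period_defined(self) -> bool:
        return bool(np.isfinite(self.period_ms))


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """One-sided amplitude spectrum with sinusoid-amplitude normalization."""

    freqs: np.ndarray
    amps: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        amps = np.asarray(self.amps, dtype=float)
        if freqs.shape != amps.shape:
            raise ParameterizationError("freqs and amps must align")
        if freqs.size >= 2 and not np.all(np.diff(freqs) > 0):
            raise ParameterizationError("freqs must be strictly increasing")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "amps", amps)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"freq_hz": self.freqs, "amplitude_V": self.amps}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class CharacteristicPeak:
    """Dominant low-frequency spectral component of a plant signal."""

    freq: float
    amp: float


def estimate_period(s: Signal, min_corr: float = 0.2) -> float:
    """Estimate the dominant oscillation period in milliseconds.

    The period is the lag of the first local maximum of the biased,
    normalized autocorrelation beyond lag zero whose value exceeds
    ``min_corr``, refined by quadratic interpolation over the neighboring
    lags. Autocorrelation (rather than zero crossings) is used because the
    recordings superpose a fast carrier oscillation on a slow drought-related
    wave; the fast component dominates the first autocorrelation peak.

    Raises
    ------
    UndefinedFeatureError
        If no autocorrelation peak qualifies (white noise, constant signal).
    """
    x = s.samples - s.samples.mean()
    n = x.size
    if n < 8:
        raise ParameterizationError("too few samples for period estimation")
    # Biased autocorrelation via FFT (zero-padded to avoid wrap-around).
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec), nfft)[:n] / n
    if r[0] <= 0:
        raise UndefinedFeatureError("constant signal has no period")
    r = r / r[0]
    peaks, _ = find_peaks(r[1:])
    peaks = peaks + 1
    qualifying = peaks[r[peaks] > min_corr]
    if qualifying.size == 0:
        raise UndefinedFeatureError("no qualifying autocorrelation peak")
    k = int(qualifying[0])
    lag = float(k)
    if 1 <= k < n - 1:
        denom = r[k - 1] - 2.0 * r[k] + r[k + 1]
        if denom < 0:
            lag = k + 0.5 * (r[k - 1] - r[k + 1]) / denom
    return lag / s.fs * 1000.0


def signal_stats(s: Signal) -> SignalStats:
    """Compute max, min, peak-to-peak amplitude and period of a signal.

    peak_v = max_v − min_v by construction. If the period is undefined
    (aperiodic signal) it is reported as NaN and the other statistics are
    still returned.
    """
    max_v = float(np.max(s.samples))
    min_v = float(np.min(s.samples))
    try:
        period_ms = estimate_period(s)
    except (UndefinedFeatureError, ParameterizationError):
        period_ms = float("nan")
    return SignalStats(max_v=max_v, min_v=min_v, peak_v=max_v - min_v, period_ms=period_ms)


def amplitude_spectrum(
    s: Signal, detrend: bool = True, window: str | None = None
) -> AmplitudeSpectrum:
    """One-sided Fourier amplitude spectrum.

    Normalization is 2|DFT|/N (DC and, for even N, the Nyquist bin unhalved),
    so a pure sinusoid of amplitude A whose frequency falls on a bin yields
    an amplitude reading of A. No taper is applied by default — the study's
    default acquisitions hold a whole number of cycles of every deterministic
    component — but ``window="hann"`` is available for real recordings.
    """
    x = np.asarray(s.samples, dtype=float)
    n = x.size
    if detrend:
        x = x - x.mean()
    if window is not None:
        if window != "hann":
            raise ParameterizationError(f"unsupported window {window!r}")
        w = np.hanning(n)
        x = x * w / w.mean()  # preserve sinusoid-amplitude normalization
    spec = np.fft.rfft(x)
    amps = 2.0 * np.abs(spec) / n
    amps[0] /= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / s.fs)
    return AmplitudeSpectrum(freqs=freqs, amps=amps)


def characteristic_frequency(
    spec: AmplitudeSpectrum, band_max: float = 5.0
) -> CharacteristicPeak | None:
    """Locate the dominant spectral component in (0, band_max] Hz.

    Plant electrical activity lives below ~5 Hz; the characteristic
    frequency is the amplitude-spectrum argmax over that band, DC excluded.
    Returns None when the band carries no energy.
    """
    if band_max <= 0:
        raise ParameterizationError("band_max must be positive")
    in_band = (spec.freqs > 0) & (spec.freqs <= band_max * (1 + 1e-12))
    if not np.any(in_band):
        raise ParameterizationError(
            f"spectrum does not cover (0, {band_max}] Hz"
        )
    band_amps = spec.amps[in_band]
    if np.all(band_amps == 0):
        return None
    idx = int(np.argmax(band_amps))
    freqs = spec.freqs[in_band]
    return CharacteristicPeak(freq=float(freqs[idx]), amp=float(band_amps[idx]))
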