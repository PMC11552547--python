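"""The three power/phase estimators consumed by every downstream measure.

1. **Multitaper** — the full 500 ms window is multiplied by K = 2*TW - 1
   orthonormal Slepian (DPSS) tapers and Fourier transformed, giving K
   independent estimates of power and phase on a 2 Hz grid.
2. **Binned** — the window is split into 10 nonoverlapping 50 ms segments,
   each Fourier transformed without tapering, giving 10 estimates on a
   20 Hz grid (the reciprocal of the segment length); spike counts per
   segment give 10 firing-rate estimates.
3. **Hilbert filterbank** — the window is band-pass filtered (4th-order
   Butterworth, center +/- 5 Hz, centers 6..200 Hz in 2 Hz steps) and the
   analytic signal gives instantaneous power and phase at all 1000 samples.

Power is the squared magnitude of the one-sided spectrum (doubled except at
DC and Nyquist).  All downstream quantities are ratios, dB differences,
correlations, or d', so the absolute scale convention is immaterial; the
scaling is fixed so that summing power over the full grid recovers the
window's energy (a Parseval check).  No zero padding is used, so the grid
resolutions are exactly 2 Hz and 20 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .core_data import SAMPLING_RATE_HZ, WINDOW_N_SAMPLES

FMAX_HZ = 200.0

#: Fine frequency grid (multitaper / Hilbert analyses), Hz.
FINE_GRID_STEP_HZ = 2.0
#: Binned-method frequency grid step, Hz (1 / 50 ms).
BINNED_GRID_STEP_HZ = 20.0

N_BINS = 10
BIN_DURATION_S = 0.05

HILBERT_CENTERS_HZ = np.arange(6.0, FMAX_HZ + 1e-9, 2.0)
HILBERT_HALF_BW_HZ = 5.0


@dataclass
class TaperBank:
    """K = 2*TW - 1 orthonormal Slepian tapers for a fixed window length."""

    n_samples: int
    time_bandwidth: float
    tapers: np.ndarray  # (K, n_samples)

    @property
    def n_tapers(self) -> int:
        return self.tapers.shape[0]


@dataclass
class SpectralEstimate:
    """Per-taper power and phase on a frequency grid.

    ``mean_power`` is the arithmetic mean of ``per_taper_power`` over tapers.
    Leading array axes (trials, electrodes, ...) are preserved; the taper
    axis is -2 and the frequency axis -1.
    """

    freqs_hz: np.ndarray
    per_taper_power: np.ndarray   # (..., K, n_freqs)
    per_taper_phase: np.ndarray   # (..., K, n_freqs)

    @property
    def mean_power(self) -> np.ndarray:
        return self.per_taper_power.mean(axis=-2)


@dataclass
class BinnedEstimate:
    """Per-50 ms-bin power, phase, and (optionally) firing rate."""

    freqs_hz: np.ndarray
    per_bin_power: np.ndarray     # (..., 10, n_freqs)
    per_bin_phase: np.ndarray     # (..., 10, n_freqs)
    per_bin_rate_hz: np.ndarray = None  # (..., 10)


@dataclass
class FilterBankEstimate:
    """Instantaneous power and phase from the Hilbert filterbank."""

    centers_hz: np.ndarray
    inst_power: np.ndarray        # (..., n_centers, n_samples)
    inst_phase: np.ndarray        # (..., n_centers, n_samples)


# ---------------------------------------------------------------------------
# Multitaper
# ---------------------------------------------------------------------------

def make_taper_bank(n_samples: int, time_bandwidth: float) -> TaperBank:
    """Build K = 2*TW - 1 orthonormal Slepian tapers ordered by concentration."""
    if n_samples != int(n_samples) or time_bandwidth != int(time_bandwidth):
        raise ValueError("n_samples and time_bandwidth must be integers")
    n_samples = int(n_samples)
    tw = int(time_bandwidth)
    if tw < 1:
        raise ValueError("time_bandwidth must be >= 1")
    k = 2 * tw - 1
    if n_samples < 2 * k:
        raise ValueError(f"n_samples={n_samples} too short for {k} tapers")
    tapers = signal.windows.dpss(n_samples, tw, Kmax=k)  # (K, n) even for K=1
    return TaperBank(n_samples=n_samples, time_bandwidth=tw, tapers=tapers)


def _one_sided_power(spectrum: np.ndarray, n: int, window_energy: float) -> np.ndarray:
    """One-sided |X|^2 scaled so the full-grid sum follows Parseval.

    With scale n * sum(w^2) the total over the one-sided grid equals the
    variance of the (pre-window) signal, for any window w, which puts the
    multitaper (unit-norm tapers) and binned (boxcar) estimators on a common
    power scale.
    """
    power = np.abs(spectrum) ** 2 / (n * window_energy)
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0  # exact Nyquist bin is not duplicated
    return power


def multitaper_spectrum(
    segment: np.ndarray,
    bank: TaperBank,
    fs: float = SAMPLING_RATE_HZ,
    fmax: float = FMAX_HZ,
) -> SpectralEstimate:
    """Per-taper power and phase of one or more segments.

    ``segment`` has samples on the last axis and must match the bank length.
    The grid is 0..``fmax`` in steps of fs / n_samples (2 Hz for the 500 ms
    window).  Pass ``fmax=None`` for the full one-sided grid.
    """
    segment = np.asarray(segment, dtype=np.float64)
    n = bank.n_samples
    if segment.shape[-1] != n:
        raise ValueError(
            f"segment length {segment.shape[-1]} does not match taper bank ({n})"
        )
    tapered = segment[..., np.newaxis, :] * bank.tapers  # (..., K, n)
    spectrum = np.fft.rfft(tapered, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    if fmax is not None:
        keep = freqs <= fmax + 1e-9
        freqs = freqs[keep]
        spectrum = spectrum[..., keep]
    power = _one_sided_power(spectrum, n, 1.0)  # tapers are unit-norm
    phase = np.where(np.abs(spectrum) > 0, np.angle(spectrum), 0.0)
    return SpectralEstimate(freqs_hz=freqs, per_taper_power=power,
                            per_taper_phase=phase)


# ---------------------------------------------------------------------------
# Binned
# ---------------------------------------------------------------------------

def binned_spectrum(
    segment: np.ndarray,
    spike_times_ms: np.ndarray = None,
    fs: float = SAMPLING_RATE_HZ,
    fmax: float = FMAX_HZ,
) -> BinnedEstimate:
    """Untapered Fourier power/phase in 10 nonoverlapping 50 ms bins.

    ``segment`` has 1000 samples on the last axis.  ``spike_times_ms`` are
    optional spike times in [-500, 0) ms; counts per 50 ms bin are converted
    to rates in Hz.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.shape[-1] != WINDOW_N_SAMPLES:
        raise ValueError("binned estimator expects 1000-sample segments")
    bin_len = int(fs * BIN_DURATION_S)
    bins = segment.reshape(segment.shape[:-1] + (N_BINS, bin_len))
    spectrum = np.fft.rfft(bins, axis=-1)
    freqs = np.fft.rfftfreq(bin_len, d=1.0 / fs)
    if fmax is not None:
        keep = freqs <= fmax + 1e-9
        freqs = freqs[keep]
        spectrum = spectrum[..., keep]
    power = _one_sided_power(spectrum, bin_len, float(bin_len))  # boxcar
    phase = np.where(np.abs(spectrum) > 0, np.angle(spectrum), 0.0)
    rates = None
    if spike_times_ms is not None:
        edges = np.linspace(-500.0, 0.0, N_BINS + 1)
        counts, _ = np.histogram(np.asarray(spike_times_ms), bins=edges)
        rates = counts / BIN_DURATION_S
    return BinnedEstimate(freqs_hz=freqs, per_bin_power=power,
                          per_bin_phase=phase, per_bin_rate_hz=rates)


def spike_rate_bins(spike_times_ms: np.ndarray) -> np.ndarray:
    """Firing rate (Hz) in the 10 nonoverlapping 50 ms bins of the window."""
    edges = np.linspace(-500.0, 0.0, N_BINS + 1)
    counts, _ = np.histogram(np.asarray(spike_times_ms), bins=edges)
    return counts / BIN_DURATION_S


# ---------------------------------------------------------------------------
# Hilbert filterbank
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _bandpass_sos(center_hz: float, fs: float) -> np.ndarray:
    lo = center_hz - HILBERT_HALF_BW_HZ
    hi = center_hz + HILBERT_HALF_BW_HZ
    try:
        sos = signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    except ValueError as exc:
        raise ValueError(f"unstable filter design at center {center_hz} Hz") from exc
    return sos


def hilbert_filterbank(
    segment: np.ndarray,
    fs: float = SAMPLING_RATE_HZ,
    centers_hz: np.ndarray = None,
) -> FilterBankEstimate:
    """Instantaneous power/phase per center frequency via the analytic signal.

    Zero-phase (forward-backward) Butterworth filtering is used so the
    instantaneous phase carries no filter delay.
    """
    segment = np.asarray(segment, dtype=np.float64)
    centers = HILBERT_CENTERS_HZ if centers_hz is None else np.asarray(centers_hz)
    n = segment.shape[-1]
    inst_power = np.empty(segment.shape[:-1] + (len(centers), n))
    inst_phase = np.empty_like(inst_power)
    for i, c in enumerate(centers):
        sos = _bandpass_sos(float(c), float(fs))
        filtered = signal.sosfiltfilt(sos, segment, axis=-1)
        analytic = signal.hilbert(filtered, axis=-1)
        inst_power[..., i, :] = np.abs(analytic) ** 2
        inst_phase[..., i, :] = np.angle(analytic)
    return FilterBankEstimate(centers_hz=centers, inst_power=inst_power,
                              inst_phase=inst_phase)
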