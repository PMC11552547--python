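"""Trial-averaged measures: PSTH, ERP, PPC, and trial-wise pair correlations.

The pairwise phase consistency (PPC) primitive here is the unbiased
estimator of the squared phase-locking value: the average cosine of the
phase difference over all pairs drawn from N phase samples,

    PPC = 2 / (N (N-1)) * sum_{j<k} cos(theta_j - theta_k)
        = (R^2 - N) / (N (N-1)),   R = |sum_j exp(i theta_j)|.

Unlike the raw phase-locking value it has no positive bias at small N, so
its null expectation is 0; its range is [-1/(N-1), 1].
"""

from __future__ import annotations

import numpy as np

from .core_data import SAMPLING_RATE_HZ, WINDOW_START_MS, WINDOW_END_MS

PSTH_BIN_MS = 10.0


def compute_psth(
    spike_trains: list,
    window_ms: tuple = (WINDOW_START_MS, WINDOW_END_MS),
    bin_ms: float = PSTH_BIN_MS,
) -> tuple:
    """Trial-averaged firing rate in nonoverlapping 10 ms bins.

    ``spike_trains`` is a list (one entry per trial) of spike-time arrays in
    ms relative to target onset.  Returns ``(bin_centers_ms, rate_hz)``.
    """
    start, end = window_ms
    edges = np.arange(start, end + bin_ms / 2, bin_ms)
    centers = edges[:-1] + bin_ms / 2.0
    if len(spike_trains) == 0:
        return centers, np.zeros(len(centers))
    counts = np.zeros(len(centers))
    for train in spike_trains:
        c, _ = np.histogram(np.asarray(train), bins=edges)
        counts += c
    rate = counts / (len(spike_trains) * bin_ms / 1000.0)
    return centers, rate


def compute_erp(segments: np.ndarray) -> np.ndarray:
    """Event-related potential: pointwise mean LFP across trials (axis 0)."""
    segments = np.asarray(segments)
    if segments.shape[0] < 1:
        raise ValueError("ERP requires at least one trial")
    return segments.mean(axis=0)


# ---------------------------------------------------------------------------
# PPC primitive
# ---------------------------------------------------------------------------

def ppc_core(phases: np.ndarray, axis: int = -1, method: str = "closed_form") -> np.ndarray:
    """Unbiased squared phase-locking value of N >= 2 phase samples.

    ``method='closed_form'`` uses (R^2 - N) / (N (N-1)); ``method='pairwise'``
    sums cos(theta_j - theta_k) over all pairs directly.  The two are
    algebraically identical and both are exposed so each can serve as an
    independent check on the other.
    """
    phases = np.asarray(phases, dtype=np.float64)
    n = phases.shape[axis]
    if n < 2:
        raise ValueError("PPC requires at least 2 phase samples")
    if method == "closed_form":
        c = np.cos(phases).sum(axis=axis)
        s = np.sin(phases).sum(axis=axis)
        r2 = c**2 + s**2
        return (r2 - n) / (n * (n - 1))
    if method == "pairwise":
        ph = np.moveaxis(phases, axis, -1)
        total = np.zeros(ph.shape[:-1])
        for j in range(n - 1):
            total += np.cos(ph[..., j + 1:] - ph[..., j:j + 1]).sum(axis=-1)
        return 2.0 * total / (n * (n - 1))
    raise ValueError(f"unknown method {method!r}")


def circular_mean(phases: np.ndarray, axis: int = -1) -> np.ndarray:
    """Argument of the mean unit vector (rotation-invariant mean angle)."""
    phases = np.asarray(phases, dtype=np.float64)
    return np.angle(np.exp(1j * phases).mean(axis=axis))


def single_electrode_ppc(per_trial_per_taper_phases: np.ndarray) -> np.ndarray:
    """Across-trial consistency of one electrode's absolute phase.

    Input shape ``(n_trials, n_tapers)`` or ``(n_trials, n_tapers, n_freqs)``.
    For each taper the PPC of the absolute phase is computed across trials;
    the result is the mean over tapers (scalar, or per-frequency array).
    """
    phases = np.asarray(per_trial_per_taper_phases)
    if phases.shape[0] < 2:
        raise ValueError("single-electrode PPC requires at least 2 trials")
    per_taper = ppc_core(phases, axis=0)       # (n_tapers[, n_freqs])
    return per_taper.mean(axis=0)


# ---------------------------------------------------------------------------
# Trial-wise pairwise measures
# ---------------------------------------------------------------------------

def trialwise_correlation(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Pearson correlation of two per-trial scalar series.

    Used for spike-count (rate) correlations and for LFP power correlations
    across trials.  Returns NaN (to be excluded from averages) if either
    series has zero variance.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D series of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 trials for a correlation")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def trialwise_pair_ppc(
    phases_a: np.ndarray, phases_b: np.ndarray
) -> np.ndarray:
    """LFP-LFP phase consistency of an electrode pair across trials.

    Inputs have shape ``(n_trials, n_tapers[, n_freqs])``.  Per trial, the
    per-taper phase differences are reduced to a single angle by the
    circular mean, and the PPC of those taper-averaged differences is taken
    across trials.
    """
    pa = np.asarray(phases_a)
    pb = np.asarray(phases_b)
    if pa.shape != pb.shape:
        raise ValueError("phase arrays must have matching shapes")
    diff = circular_mean(pa - pb, axis=1)      # (n_trials[, n_freqs])
    return ppc_core(diff, axis=0)
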