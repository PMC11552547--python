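"""Single-trial estimates of pairwise correlation and phase consistency.

Trial-wise correlation and PPC are defined across trials, so they cannot be
attached to an individual trial.  The estimators here instead exploit
multiple power/phase estimates *within* one trial:

* **binned** — 10 nonoverlapping 50 ms segments (20 Hz frequency grid);
* **taper** — 9 orthogonal Slepian tapers at TW = 5 on the full window
  (2 Hz grid); the estimates are independent because the tapers are
  orthogonal;
* **hilbert** — 1000 instantaneous estimates from the analytic signal of
  the band-pass filtered trace (2 Hz grid of center frequencies).

Power correlations from the binned and hilbert methods are **shuffle
corrected**: temporal structure that is locked to the stimulus rather than
to shared neural variability (e.g. adaptation ramps, the onset transient)
repeats across trials and inflates within-trial correlations.  Correlating
each trial's feature vector with every *nonsimultaneous* trial of the other
electrode estimates exactly that repeatable part, and subtracting the
average over nonsimultaneous pairings removes it.  The taper method has no
nonsimultaneous analog (all nine estimates cover the same window), so it is
not shuffle corrected; PPC values are never shuffle corrected.

The hilbert method's 1000 timepoints are strongly autocorrelated (the
band-pass filter's impulse response spans many samples), so its PPC level
is biased upward; only condition *differences* of that measure are
meaningful, never absolute levels.
"""

from __future__ import annotations

import numpy as np

from .trial_measures import ppc_core

#: Time-bandwidth product of the single-trial taper method (9 tapers).
SINGLE_TRIAL_TW = 5

METHODS = ("binned", "taper", "hilbert")
_SHUFFLE_CORRECTED = {"binned": True, "taper": False, "hilbert": True}


def _standardize(x: np.ndarray, axis: int) -> np.ndarray:
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = np.nan
    return z


def shuffle_corrected_correlation(
    features_a: np.ndarray, features_b: np.ndarray
) -> np.ndarray:
    """Shuffle-corrected within-trial correlation, one value per trial.

    Inputs are ``(n_trials, n_units)`` feature vectors (bins or timepoints).
    For trial t the raw value is r(a[t], b[t]); the correction subtracts the
    mean of r(a[t], b[s]) over all nonsimultaneous trials s != t.  Trials
    with a zero-variance vector yield NaN.
    """
    a = np.asarray(features_a, dtype=np.float64)
    b = np.asarray(features_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("expected matching (n_trials, n_units) arrays")
    n_trials, n_units = a.shape
    if n_trials < 2:
        raise ValueError("shuffle correction requires at least 2 trials")
    za = _standardize(a, axis=1)
    zb = _standardize(b, axis=1)
    r = za @ zb.T / n_units                    # r[t, s] = r(a[t], b[s])
    raw = np.diag(r).copy()
    cross = (np.nansum(r, axis=1) - raw) / (n_trials - 1)
    return raw - cross


def singletrial_correlation(
    power_a: np.ndarray, power_b: np.ndarray, method: str
) -> np.ndarray:
    """Per-trial, per-frequency power correlation of an electrode pair.

    Inputs have shape ``(n_trials, n_units, n_freqs)`` with the method's
    within-trial unit axis in the middle (10 bins, 9 tapers, or 1000
    timepoints).  Binned and hilbert results are shuffle corrected; the
    taper result is the raw across-taper Pearson correlation.  Returns
    ``(n_trials, n_freqs)``.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    a = np.asarray(power_a, dtype=np.float64)
    b = np.asarray(power_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("expected matching (n_trials, n_units, n_freqs) arrays")
    n_trials, n_units, n_freqs = a.shape
    out = np.empty((n_trials, n_freqs))
    if _SHUFFLE_CORRECTED[method]:
        for f in range(n_freqs):
            out[:, f] = shuffle_corrected_correlation(a[:, :, f], b[:, :, f])
    else:
        za = _standardize(a, axis=1)
        zb = _standardize(b, axis=1)
        out = (za * zb).sum(axis=1) / n_units
    return out


def singletrial_ppc(
    phase_a: np.ndarray, phase_b: np.ndarray, method: str
) -> np.ndarray:
    """Per-trial, per-frequency PPC of the between-electrode phase difference.

    The PPC primitive is applied to theta_a - theta_b across the method's
    within-trial units (10 bins / 9 tapers / 1000 timepoints); no shuffle
    correction is defined for PPC.  Returns ``(n_trials, n_freqs)``.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    pa = np.asarray(phase_a)
    pb = np.asarray(phase_b)
    if pa.shape != pb.shape or pa.ndim != 3:
        raise ValueError("expected matching (n_trials, n_units, n_freqs) arrays")
    return ppc_core(pa - pb, axis=1)
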