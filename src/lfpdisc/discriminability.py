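"""Band definitions, d' discriminability, and the measure-by-band summary.

Every single-trial measure (firing rate, band power, sine of the band
phase, single-trial pair correlation and PPC) is converted to a d' between
two trial groups:

    d' = (mu1 - mu2) / sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)),

the standardized mean difference with pooled (unbiased) standard deviation,
robust to unequal group sizes.  For normally distributed classes d' maps to
the ROC area via AUC = 0.5 + erf(d'/2)/2.

Contrast orientation is fixed: group 1 is attend-in / target-in (attention
contrasts) or hit (behavioral contrasts), so the signs of population-mean
d' values are directly comparable across measures.

Band averaging precedes d': averaging linear power over a band's
frequencies suppresses the (across-frequency independent) variability of
the spectral estimator and therefore yields larger d' than averaging
per-frequency d' values would.  Within gamma and high-gamma the harmonics
of the 20 Hz steady-state response (multiples of 20 Hz) are excluded from
the fine 2 Hz grids; on the coarse 20 Hz binned grid, where that would
empty the bands, only 60 Hz is excluded.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .core_data import (
    SessionRecording,
    select_analysis_trials,
)
from .onset_matching import match_onset_distributions
from .spectral_engine import (
    binned_spectrum,
    make_taper_bank,
    multitaper_spectrum,
    spike_rate_bins,
)
from .single_trial import (
    SINGLE_TRIAL_TW,
    shuffle_corrected_correlation,
    _standardize,
)
from .trial_measures import ppc_core

logger = logging.getLogger("lfpdisc")

#: Traditional frequency bands (Hz).
BANDS = {
    "alpha": (8.0, 12.0),
    "ssvep": (18.0, 22.0),
    "gamma": (40.0, 80.0),
    "high_gamma": (120.0, 200.0),
}

#: Bands whose fine-grid support excludes multiples of the 20 Hz SSVEP.
_HARMONIC_EXCLUDED = ("gamma", "high_gamma")

#: Contrast name -> (group1, group2) in terms of the four per-cue groups.
CONTRASTS = {
    "attention_hit": ("inH", "outH"),
    "attention_miss": ("inM", "outM"),
    "behavior_in": ("inH", "inM"),
    "behavior_out": ("outH", "outM"),
}

_CUE_CONDITIONS = {
    "valid": {"inH": "AIVH", "outH": "AOVH", "inM": "AIVM", "outM": "AOVM"},
    "neutral": {"inH": "TINH", "outH": "TONH", "inM": "TINM", "outM": "TONM"},
}


def band_support(band: str, grid: np.ndarray, binned: bool = False) -> np.ndarray:
    """Indices of the grid frequencies contributing to a band average.

    On fine (2 Hz) grids, gamma and high-gamma exclude multiples of 20 Hz
    (leaving supports of 42-78 Hz and 122-198 Hz); on the binned (20 Hz)
    grid only 60 Hz is excluded.  Raises if the support is empty (e.g.
    alpha on the binned grid).
    """
    lo, hi = BANDS[band]
    grid = np.asarray(grid, dtype=np.float64)
    mask = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    if binned:
        mask &= grid != 60.0
    elif band in _HARMONIC_EXCLUDED:
        mask &= np.mod(grid, 20.0) != 0.0
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(
            f"band {band!r} has empty support on the "
            f"{'binned' if binned else 'fine'} grid"
        )
    return idx


def band_average(values: np.ndarray, band: str, grid: np.ndarray,
                 binned: bool = False) -> np.ndarray:
    """Arithmetic mean of linear-scale values over the band's support.

    The frequency axis is the last axis of ``values``.
    """
    idx = band_support(band, grid, binned=binned)
    return np.asarray(values)[..., idx].mean(axis=-1)


def sine_phase(phase: np.ndarray, component: str = "sine") -> np.ndarray:
    """Linearize a circular phase for d': sin(phase) (or cos as a variant)."""
    if component == "sine":
        return np.sin(phase)
    if component == "cosine":
        return np.cos(phase)
    raise ValueError("component must be 'sine' or 'cosine'")


def dprime(group1: np.ndarray, group2: np.ndarray, axis: int = 0) -> np.ndarray:
    """Pooled-standard-deviation d' between two trial groups.

    ``axis`` is the trial axis; other axes (units, bands, frequencies) are
    vectorized over.  Zero pooled variance yields NaN (excluded, logged by
    callers), as does a group with fewer than 2 trials.
    """
    g1 = np.asarray(group1, dtype=np.float64)
    g2 = np.asarray(group2, dtype=np.float64)
    n1 = np.isfinite(g1).sum(axis=axis)
    n2 = np.isfinite(g2).sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(g1, axis=axis)
        m2 = np.nanmean(g2, axis=axis)
        v1 = np.nanvar(g1, axis=axis, ddof=1)
        v2 = np.nanvar(g2, axis=axis, ddof=1)
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        d = (m1 - m2) / np.sqrt(pooled)
    ok = (n1 >= 2) & (n2 >= 2) & (pooled > 0)
    return np.where(ok, d, np.nan)


def auc_from_dprime(d) -> np.ndarray:
    """ROC area for normally distributed classes: 0.5 + erf(d'/2)/2."""
    return 0.5 + erf(np.asarray(d, dtype=np.float64) / 2.0) / 2.0


# ---------------------------------------------------------------------------
# Per-trial feature tables
# ---------------------------------------------------------------------------

@dataclass
class SessionFeatures:
    """Per-trial, per-electrode spectral and spike features for one session.

    Computed once per session; every bootstrap iteration then only indexes
    into these tables.  ``power_fine`` is the TW = 3 (five-taper) multitaper
    mean power on the 2 Hz grid; ``taper_power``/``taper_phase`` are the
    nine TW = 5 single-trial estimates; ``bin_*`` are the ten 50 ms-bin
    estimates on the 20 Hz grid; ``phase_fine`` is the untapered full-window
    FFT phase used for the sine-of-phase measure.
    """

    fine_freqs: np.ndarray
    bin_freqs: np.ndarray
    rate_hz: np.ndarray        # (T, E)
    power_fine: np.ndarray     # (T, E, F)
    phase_fine: np.ndarray     # (T, E, F)
    taper_power: np.ndarray    # (T, E, 9, F)
    taper_phase: np.ndarray    # (T, E, 9, F)
    bin_power: np.ndarray      # (T, E, 10, Fb)
    bin_phase: np.ndarray      # (T, E, 10, Fb)
    bin_rate: np.ndarray       # (T, E, 10)


def compute_features(session: SessionRecording, tw_power: int = 3) -> SessionFeatures:
    """Compute all per-trial features the d' summary consumes."""
    segments = session.lfp.astype(np.float64)
    n_samples = segments.shape[-1]
    bank_mean = make_taper_bank(n_samples, tw_power)
    bank_single = make_taper_bank(n_samples, SINGLE_TRIAL_TW)
    est_mean = multitaper_spectrum(segments, bank_mean)
    est_single = multitaper_spectrum(segments, bank_single)
    binned = binned_spectrum(segments)
    spectrum = np.fft.rfft(segments, axis=-1)[..., : len(est_mean.freqs_hz)]
    phase_fine = np.where(np.abs(spectrum) > 0, np.angle(spectrum), 0.0)

    n_trials, n_elec = segments.shape[:2]
    rate = np.zeros((n_trials, n_elec))
    bin_rate = np.zeros((n_trials, n_elec, 10))
    for t in range(n_trials):
        for e in range(n_elec):
            times = session.spikes[t][e]
            rate[t, e] = len(times) / 0.5
            bin_rate[t, e] = spike_rate_bins(times)

    return SessionFeatures(
        fine_freqs=est_mean.freqs_hz,
        bin_freqs=binned.freqs_hz,
        rate_hz=rate,
        power_fine=est_mean.mean_power,
        phase_fine=phase_fine,
        taper_power=est_single.per_taper_power,
        taper_phase=est_single.per_taper_phase,
        bin_power=binned.per_bin_power,
        bin_phase=binned.per_bin_phase,
        bin_rate=bin_rate,
    )


def power_dprime_spectrum(
    features: SessionFeatures, idx1: np.ndarray, idx2: np.ndarray
) -> np.ndarray:
    """Per-electrode, per-frequency d' of multitaper power between two groups."""
    return dprime(features.power_fine[idx1], features.power_fine[idx2], axis=0)


def delta_psd_db(
    features: SessionFeatures, idx_a: np.ndarray, idx_b: np.ndarray
) -> np.ndarray:
    """Per-electrode change in PSD of group a relative to b, in decibels."""
    mean_a = features.power_fine[idx_a].mean(axis=0)
    mean_b = features.power_fine[idx_b].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 10.0 * np.log10(mean_a / mean_b)


# ---------------------------------------------------------------------------
# d' summary over measures x bands x contrasts
# ---------------------------------------------------------------------------

def _pair_band_features(features: SessionFeatures, electrodes: np.ndarray):
    """Group-independent per-trial pair features, band-averaged.

    Returns (pairs, taper_corr, taper_ppc, bin_ppc, bp_band) where
    ``taper_corr``/``taper_ppc`` have shape (T, n_pairs, n_bands) on the
    fine bands, ``bin_ppc`` shape (T, n_pairs, n_binned_bands) on the bands
    with nonempty binned support, and ``bp_band`` (T, E_sel, 10, n_binned
    bands) is the band-averaged per-bin power used later for shuffle-
    corrected correlations.
    """
    fine_bands = list(BANDS)
    binned_bands = [b for b in BANDS
                    if _has_support(b, features.bin_freqs, binned=True)]
    # band-averaged per-taper power, z-scored across tapers
    tp = np.stack(
        [band_average(features.taper_power[:, electrodes], b, features.fine_freqs)
         for b in fine_bands], axis=-1)                     # (T, Es, 9, B)
    z_tp = _standardize(tp, axis=2)
    bp_band = np.stack(
        [band_average(features.bin_power[:, electrodes], b, features.bin_freqs,
                      binned=True)
         for b in binned_bands], axis=-1)                   # (T, Es, 10, Bb)

    pairs = list(itertools.combinations(range(len(electrodes)), 2))
    t_corr, t_ppc, b_ppc = [], [], []
    for i, j in pairs:
        t_corr.append(np.nanmean(z_tp[:, i] * z_tp[:, j], axis=1))
        dphi = (features.taper_phase[:, electrodes[i]]
                - features.taper_phase[:, electrodes[j]])   # (T, 9, F)
        ppc_f = ppc_core(dphi, axis=1)                      # (T, F)
        t_ppc.append(np.stack(
            [band_average(ppc_f, b, features.fine_freqs) for b in fine_bands],
            axis=-1))
        dphi_b = (features.bin_phase[:, electrodes[i]]
                  - features.bin_phase[:, electrodes[j]])   # (T, 10, Fb)
        ppc_fb = ppc_core(dphi_b, axis=1)
        b_ppc.append(np.stack(
            [band_average(ppc_fb, b, features.bin_freqs, binned=True)
             for b in binned_bands], axis=-1))
    return (pairs, binned_bands,
            np.stack(t_corr, axis=1), np.stack(t_ppc, axis=1),
            np.stack(b_ppc, axis=1), bp_band)


def _has_support(band: str, grid: np.ndarray, binned: bool) -> bool:
    try:
        band_support(band, grid, binned=binned)
        return True
    except ValueError:
        return False


def _shuffle_corr_groups(bp_band, bin_rate_sel, pairs, groups):
    """Shuffle-corrected per-trial binned correlations, per group.

    Returns (lfp_vals, rate_vals): dicts group name -> arrays of shape
    (n_group_trials, n_pairs, n_binned_bands) and (n_group_trials, n_pairs).
    Correction averages over nonsimultaneous trials *within the same
    condition group*, so condition mean differences are not injected.
    """
    lfp_vals, rate_vals = {}, {}
    n_pairs = len(pairs)
    n_bands = bp_band.shape[-1]
    for name, idx in groups.items():
        n = len(idx)
        lfp = np.full((n, n_pairs, n_bands), np.nan)
        rat = np.full((n, n_pairs), np.nan)
        if n >= 2:
            for p, (i, j) in enumerate(pairs):
                for b in range(n_bands):
                    lfp[:, p, b] = shuffle_corrected_correlation(
                        bp_band[idx, i, :, b], bp_band[idx, j, :, b])
                rat[:, p] = shuffle_corrected_correlation(
                    bin_rate_sel[idx, i], bin_rate_sel[idx, j])
        lfp_vals[name] = lfp
        rate_vals[name] = rat
    return lfp_vals, rate_vals


def build_summary(
    session: SessionRecording,
    n_boot: int = 50,
    seed: int = 0,
    include_pairs: bool = True,
    phase_component: str = "sine",
    features: SessionFeatures = None,
    return_units: bool = False,
):
    """Bootstrap-averaged d' for every measure x band x contrast x cue type.

    Per array (RF side) and cue type, hit and miss trials are onset-matched
    within each attention condition; per bootstrap iteration, every measure
    is band-averaged per trial and a d' is computed per electrode (or pair)
    for the four contrasts; d' values are averaged across iterations first,
    and only then summarized (mean, SEM) across electrodes/pairs pooled
    over both arrays.  Negative d' values are reported as-is (sign flips
    happen only inside magnitude significance tests).

    Returns a tidy frame with columns measure, estimator, band, contrast,
    cue_type, mean_dprime, sem, n_units.
    """
    if features is None:
        features = compute_features(session)
    onsets = np.array([t.target_onset_ms for t in session.trials])
    fine_bands = list(BANDS)

    # accumulate per-unit bootstrap-averaged d' per key
    acc: dict = {}

    def _extend(key, values):
        acc.setdefault(key, []).extend(np.atleast_1d(values))

    for side_i, rf_side in enumerate(("left", "right")):
        electrodes = session.electrodes_with_rf(rf_side)
        if len(electrodes) == 0:
            continue
        conds = select_analysis_trials(session, rf_side)
        # single-electrode per-trial band features
        pw = np.stack(
            [band_average(features.power_fine[:, electrodes], b,
                          features.fine_freqs) for b in fine_bands], axis=-1)
        ph = np.stack(
            [band_average(sine_phase(features.phase_fine[:, electrodes],
                                     phase_component),
                          b, features.fine_freqs) for b in fine_bands], axis=-1)
        rate = features.rate_hz[:, electrodes]
        if include_pairs:
            (pairs, binned_bands, t_corr, t_ppc, b_ppc, bp_band) = \
                _pair_band_features(features, electrodes)
            bin_rate_sel = features.bin_rate[:, electrodes]

        for cue_i, (cue_type, cond_map) in enumerate(_CUE_CONDITIONS.items()):
            if cond_map["inH"] not in conds:
                continue
            cond_idx = {g: conds[c] for g, c in cond_map.items()}
            ss = np.random.SeedSequence(entropy=seed,
                                        spawn_key=(side_i, cue_i))
            sums: dict = {}
            for child in ss.spawn(n_boot):
                rng = np.random.default_rng(child)
                groups = {}
                for g_hit, g_miss in (("inH", "inM"), ("outH", "outM")):
                    match = match_onset_distributions(
                        onsets[cond_idx[g_hit]], onsets[cond_idx[g_miss]], rng,
                        hit_indices=cond_idx[g_hit],
                        miss_indices=cond_idx[g_miss])
                    groups[g_hit] = match.hit_indices
                    groups[g_miss] = match.miss_indices
                if include_pairs:
                    lfp_sc, rate_sc = _shuffle_corr_groups(
                        bp_band, bin_rate_sel, pairs, groups)
                for contrast, (g1, g2) in CONTRASTS.items():
                    i1, i2 = groups[g1], groups[g2]
                    per_key = {
                        ("firing_rate", "trialwise", ("spikes",)):
                            dprime(rate[i1], rate[i2]),
                        ("power", "multitaper", tuple(fine_bands)):
                            dprime(pw[i1], pw[i2]),
                        ("phase", "multitaper", tuple(fine_bands)):
                            dprime(ph[i1], ph[i2]),
                    }
                    if include_pairs:
                        per_key.update({
                            ("corr", "taper", tuple(fine_bands)):
                                dprime(t_corr[i1], t_corr[i2]),
                            ("ppc", "taper", tuple(fine_bands)):
                                dprime(t_ppc[i1], t_ppc[i2]),
                            ("ppc", "binned", tuple(binned_bands)):
                                dprime(b_ppc[i1], b_ppc[i2]),
                            ("corr", "binned", tuple(binned_bands)):
                                dprime(lfp_sc[g1], lfp_sc[g2]),
                            ("corr", "binned", ("spikes",)):
                                dprime(rate_sc[g1], rate_sc[g2]),
                        })
                    for (measure, estimator, bands), d in per_key.items():
                        key = (measure, estimator, bands, contrast)
                        sums[key] = d if key not in sums else sums[key] + d
            for (measure, estimator, bands, contrast), total in sums.items():
                avg = np.asarray(total) / n_boot
                for bi, band in enumerate(bands):
                    vals = avg[..., bi] if len(bands) > 1 else avg
                    _extend((measure, estimator, band, contrast, cue_type), vals)

    rows = []
    for (measure, estimator, band, contrast, cue_type), values in acc.items():
        values = np.asarray(values, dtype=np.float64)
        ok = np.isfinite(values)
        n = int(ok.sum())
        if n < values.size:
            logger.info("%d/%d units excluded (undefined d') for %s",
                        values.size - n, values.size,
                        (measure, estimator, band, contrast, cue_type))
        rows.append({
            "measure": measure, "estimator": estimator, "band": band,
            "contrast": contrast, "cue_type": cue_type,
            "mean_dprime": float(np.nanmean(values)) if n else np.nan,
            "sem": float(np.nanstd(values, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "n_units": n,
        })
    df = pd.DataFrame(rows)
    if return_units:
        units = {k: np.asarray(v, dtype=np.float64) for k, v in acc.items()}
        return df, units
    return df
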