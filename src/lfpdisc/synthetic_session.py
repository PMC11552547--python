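"""Generative model of V4-like sessions with known ground-truth effects.

Each synthetic trial emulates the statistical structure the analysis pipeline
assumes of the real task:

* a 20 Hz steady-state visually evoked potential (SSVEP) — the neural
  response entrained by the 10 Hz counterphasing Gabor, which drives two
  response peaks per stimulus cycle — with near-constant phase across trials
  (targets appear at contrast zero-crossings, i.e. on the SSVEP cycle grid,
  so the target-locked window preserves SSVEP phase up to a small jitter);
* condition-dependent band-limited oscillations: alpha (~10 Hz, stronger on
  miss trials and suppressed by attention), gamma (40-80 Hz) and high-gamma
  (120-200 Hz), both enhanced when attention / the target is in the
  receptive field;
* a common component of each oscillatory band shared across electrodes of
  the same array, controlling pairwise power correlations and phase
  consistency;
* 1/f ("pink") background noise, private to each electrode;
* exponential target-onset times (mean 3000 ms, range 500-5500 ms), a higher
  miss probability for early (<750 ms) targets, and a stimulus-onset
  transient that decays over a few hundred ms and therefore contaminates the
  pretarget window of early-target trials — together these reproduce the
  onset confound that distribution matching is designed to remove;
* spikes as an inhomogeneous Poisson process whose rate is modulated at
  20 Hz, scaled up by attention, with a shared rate fluctuation across
  electrodes inducing spike-count correlations.

Effects are multiplicative on amplitude, so ground-truth power effects are
squared gains and are available in closed form (:class:`GroundTruth`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .core_data import (
    SAMPLING_RATE_HZ,
    WINDOW_N_SAMPLES,
    SessionRecording,
    TrialInfo,
)

#: Frequency bands of the oscillatory generator components (Hz).
ALPHA_BAND = (8.0, 12.0)
GAMMA_BAND = (40.0, 80.0)
HIGH_GAMMA_BAND = (120.0, 200.0)
SSVEP_HZ = 20.0


@dataclass
class SynthConfig:
    """Parameters of the synthetic session generator.

    Amplitudes are in microvolts and act multiplicatively: each band
    component is a unit-variance process scaled by its amplitude and by the
    condition gains, so the expected band power is (amplitude x gains)^2
    (half that for the deterministic SSVEP sinusoid).  ``shared_fraction``
    mixes a common and a private source per band with amplitude weights
    ``sf`` and ``1 - sf`` (renormalized to unit variance), giving an expected
    across-electrode correlation of sf^2 / (sf^2 + (1-sf)^2).
    """

    n_electrodes_per_side: int = 4
    n_trials_per_condition: int = 40

    # spikes
    base_rate_hz: float = 50.0
    rate_gain_attend_in: float = 1.2
    spike_mod_depth: float = 0.5          # 20 Hz rate modulation, in [0, 1)
    rate_noise_sigma: float = 0.3         # shared trial-to-trial rate fluctuation

    # SSVEP (20 Hz)
    ssvep_amp_uv: float = 15.0
    ssvep_gain_attend_in: float = 1.1
    ssvep_gain_hit: float = 1.25
    ssvep_phase_kappa: float = 20.0       # von Mises concentration of phase jitter

    # alpha (8-12 Hz)
    alpha_amp_uv: float = 20.0
    alpha_gain_miss: float = 1.4
    alpha_gain_attend_in: float = 0.85

    # gamma (40-80 Hz) and high-gamma (120-200 Hz)
    gamma_amp_uv: float = 10.0
    gamma_gain_attend_in: float = 1.3
    high_gamma_amp_uv: float = 5.0
    high_gamma_gain_attend_in: float = 1.3

    # background and confound
    pink_noise_sigma_uv: float = 20.0
    shared_fraction: float = 0.5
    base_hit_p: float = 0.5
    early_miss_bias: float = 0.3          # extra P(miss) for onsets < 750 ms
    early_onset_cutoff_ms: float = 750.0
    transient_amp_uv: float = 50.0
    transient_decay_ms: float = 200.0

    # target onset distribution
    onset_mean_ms: float = 3000.0
    onset_min_ms: float = 500.0
    onset_max_ms: float = 5500.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ssvep_amp_uv", "alpha_amp_uv", "gamma_amp_uv",
                     "high_gamma_amp_uv", "pink_noise_sigma_uv",
                     "transient_amp_uv", "base_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if not 0.0 <= self.early_miss_bias <= 1.0:
            raise ValueError("early_miss_bias must be in [0, 1]")
        if not 0.0 <= self.base_hit_p <= 1.0:
            raise ValueError("base_hit_p must be in [0, 1]")
        if not 0.0 <= self.spike_mod_depth < 1.0:
            raise ValueError("spike_mod_depth must be in [0, 1)")


@dataclass
class GroundTruth:
    """Closed-form expectations implied by a :class:`SynthConfig`.

    ``band_power`` maps condition label -> band name -> expected power
    (uV^2) of the generator component; ``firing_rate_hz`` maps condition
    label -> expected rate; ``pair_correlation`` is the expected
    across-electrode correlation of each shared band component.
    """

    band_power: dict
    firing_rate_hz: dict
    pair_correlation: float
    config: dict = field(default_factory=dict)


def _condition_flags(condition: str) -> tuple:
    """(attend_or_target_in, hit) flags from an 8-way condition label."""
    if len(condition) != 4 or condition[1] not in "IO" or condition[3] not in "HM":
        raise ValueError(f"unknown condition label {condition!r}")
    return condition[1] == "I", condition[3] == "H"


def _band_amplitudes(config: SynthConfig, att_in: bool, hit: bool) -> dict:
    """Effective amplitude of each band component under the condition flags."""
    return {
        "alpha": config.alpha_amp_uv
        * (config.alpha_gain_attend_in if att_in else 1.0)
        * (1.0 if hit else config.alpha_gain_miss),
        "ssvep": config.ssvep_amp_uv
        * (config.ssvep_gain_attend_in if att_in else 1.0)
        * (config.ssvep_gain_hit if hit else 1.0),
        "gamma": config.gamma_amp_uv
        * (config.gamma_gain_attend_in if att_in else 1.0),
        "high_gamma": config.high_gamma_amp_uv
        * (config.high_gamma_gain_attend_in if att_in else 1.0),
    }


def ground_truth(config: SynthConfig) -> GroundTruth:
    sf = config.shared_fraction
    band_power: dict = {}
    rate: dict = {}
    for cond in ("AIVH", "AOVH", "AIVM", "AOVM", "TINH", "TONH", "TINM", "TONM"):
        att_in, hit = _condition_flags(cond)
        amps = _band_amplitudes(config, att_in, hit)
        band_power[cond] = {
            "alpha": amps["alpha"] ** 2,
            "ssvep": amps["ssvep"] ** 2 / 2.0,   # deterministic sinusoid
            "gamma": amps["gamma"] ** 2,
            "high_gamma": amps["high_gamma"] ** 2,
        }
        rate[cond] = config.base_rate_hz * (
            config.rate_gain_attend_in if att_in else 1.0
        )
    denom = sf**2 + (1.0 - sf) ** 2
    return GroundTruth(
        band_power=band_power,
        firing_rate_hz=rate,
        pair_correlation=sf**2 / denom,
        config=asdict(config),
    )


# ---------------------------------------------------------------------------
# Elementary draws
# ---------------------------------------------------------------------------

def draw_target_onset(rng: np.random.Generator, config: SynthConfig = None) -> float:
    """Target-onset time: exponential (mean 3000 ms) truncated to [500, 5500].

    Sampled by inverse CDF of the truncated law (identical in distribution
    to rejection sampling, but with bounded cost for any mean).
    """
    cfg = config if config is not None else SynthConfig()
    lam = 1.0 / cfg.onset_mean_ms
    lo = np.exp(-lam * cfg.onset_min_ms)
    hi = np.exp(-lam * cfg.onset_max_ms)
    u = rng.random()
    return float(-np.log(lo - u * (lo - hi)) / lam)


def assign_outcome(
    onset_ms: float,
    condition_base_hit_p: float,
    config: SynthConfig,
    rng: np.random.Generator,
) -> str:
    """Hit/miss draw with extra miss probability for early targets.

    P(miss) = clamp(1 - base_hit_p + early_miss_bias * 1[onset < cutoff], 0, 1).
    """
    p_miss = 1.0 - condition_base_hit_p
    if onset_ms < config.early_onset_cutoff_ms:
        p_miss += config.early_miss_bias
    p_miss = min(max(p_miss, 0.0), 1.0)
    return "miss" if rng.random() < p_miss else "hit"


# ---------------------------------------------------------------------------
# Signal components
# ---------------------------------------------------------------------------

_PAD = 600  # samples of padding either side before band-pass filtering


from functools import lru_cache


@lru_cache(maxsize=None)
def _band_sos(band: tuple, fs: float):
    return signal.butter(4, band, btype="bandpass", fs=fs, output="sos")


def _narrowband_noise(
    rng: np.random.Generator, band: tuple, n: int,
    n_series: int = 1, fs: float = SAMPLING_RATE_HZ,
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (bursty, not sinusoidal).

    Returns ``(n_series, n)``; all series are filtered in one call.
    """
    sos = _band_sos(tuple(band), fs)
    white = rng.standard_normal((n_series, n + 2 * _PAD))
    filtered = signal.sosfiltfilt(sos, white, axis=-1)[:, _PAD:-_PAD]
    sd = filtered.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return filtered / sd


def _pink_noise(rng: np.random.Generator, n: int, n_series: int = 1) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping with random phases."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum = amp * np.exp(2j * np.pi * rng.random((n_series, len(freqs))))
    spectrum[:, 0] = 0.0
    x = np.fft.irfft(spectrum, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _mix_shared(common: np.ndarray, private: np.ndarray, sf: float) -> np.ndarray:
    """sf * common + (1 - sf) * private, renormalized to unit variance."""
    denom = np.sqrt(sf**2 + (1.0 - sf) ** 2)
    if denom == 0:
        return private
    return (sf * common + (1.0 - sf) * private) / denom


def synthesize_lfp_trial(
    condition: str,
    onset_ms: float,
    config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """LFP for one array on one trial: (n_electrodes_per_side, 1000) in uV.

    ``condition`` is the 8-way label as seen by this array (e.g. ``"AIVH"``).
    The pretarget window covers absolute times [onset - 500, onset) ms after
    stimulus onset; the stimulus-onset transient is evaluated on that
    absolute axis, every oscillatory component on the target-locked axis.
    """
    att_in, hit = _condition_flags(condition)
    n_e = config.n_electrodes_per_side
    n = WINDOW_N_SAMPLES
    fs = SAMPLING_RATE_HZ
    sf = config.shared_fraction
    amps = _band_amplitudes(config, att_in, hit)
    t = np.arange(n) / fs                       # target-locked, seconds
    t_abs_ms = onset_ms - 500.0 + np.arange(n) * (1000.0 / fs)

    out = np.zeros((n_e, n))

    # SSVEP: common + per-electrode phase jitter around the target-locked phase
    phi_common = rng.vonmises(0.0, config.ssvep_phase_kappa)
    phi_priv = rng.vonmises(0.0, config.ssvep_phase_kappa, size=n_e)
    common_ssvep = np.cos(2 * np.pi * SSVEP_HZ * t + phi_common)
    private_ssvep = np.cos(2 * np.pi * SSVEP_HZ * t[None, :] + phi_priv[:, None])
    out += amps["ssvep"] * _mix_shared(common_ssvep[None, :], private_ssvep, sf)

    # narrowband noise bands: one common source + one private source per
    # electrode, drawn and filtered together
    for band, freq_range in (("alpha", ALPHA_BAND), ("gamma", GAMMA_BAND),
                             ("high_gamma", HIGH_GAMMA_BAND)):
        series = _narrowband_noise(rng, freq_range, n, n_series=n_e + 1)
        out += amps[band] * _mix_shared(series[:1], series[1:], sf)

    out += config.pink_noise_sigma_uv * _pink_noise(rng, n, n_series=n_e)

    if config.transient_amp_uv > 0:
        transient = config.transient_amp_uv * np.exp(
            -np.maximum(t_abs_ms, 0.0) / config.transient_decay_ms
        )
        transient[t_abs_ms < 0] = 0.0
        out += transient[None, :]
    return out


def synthesize_spike_train(
    condition: str,
    config: SynthConfig,
    rng: np.random.Generator,
) -> list:
    """Spike times (ms, in [-500, 0)) for each electrode of one array.

    Inhomogeneous Poisson with rate(t) = base_rate * attend-in gain *
    (1 + m cos(2 pi 20 t)) * g, where g is a per-trial rate fluctuation
    shared across electrodes in proportion to ``shared_fraction``.
    """
    att_in, _ = _condition_flags(condition)
    base = config.base_rate_hz * (config.rate_gain_attend_in if att_in else 1.0)
    m = config.spike_mod_depth
    sf = config.shared_fraction
    z_common = rng.standard_normal()
    trains = []
    for _e in range(config.n_electrodes_per_side):
        z_private = rng.standard_normal()
        denom = np.sqrt(sf**2 + (1.0 - sf) ** 2)
        z = (sf * z_common + (1.0 - sf) * z_private) / denom if denom > 0 else z_private
        gain = max(1.0 + config.rate_noise_sigma * z, 0.05)
        rate_max = base * gain * (1.0 + m)
        n_cand = rng.poisson(rate_max * 0.5)
        cand = rng.uniform(-500.0, 0.0, size=n_cand)
        t_sec = cand / 1000.0
        rate = base * gain * (1.0 + m * np.cos(2 * np.pi * SSVEP_HZ * t_sec))
        keep = rng.random(n_cand) < rate / rate_max
        trains.append(np.sort(cand[keep]))
    return trains


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

def generate_session(config: SynthConfig) -> tuple:
    """Assemble a full synthetic session; deterministic given ``config.seed``.

    Returns ``(SessionRecording, GroundTruth)``.  Trials are scheduled in
    equal numbers for all eight (cue type x side x outcome) cells; each
    trial's outcome is then re-drawn by :func:`assign_outcome` so that early
    targets are missed more often (the onset confound), which perturbs the
    final per-condition counts.
    """
    rng = np.random.default_rng(config.seed)
    n_e = config.n_electrodes_per_side
    rf_sides = ["left"] * n_e + ["right"] * n_e

    schedule = []
    for cue_type in ("valid", "neutral"):
        for side in ("left", "right"):
            for _outcome in ("hit", "miss"):
                schedule.extend(
                    [(cue_type, side)] * config.n_trials_per_condition
                )

    trials, lfp, spikes = [], [], []
    for cue_type, side in schedule:
        onset = draw_target_onset(rng, config)
        outcome = assign_outcome(onset, config.base_hit_p, config, rng)
        change_rank = int(rng.integers(2, 4))   # analysis keeps ranks {2, 3}
        cue_side = side if cue_type == "valid" else "both"
        trial = TrialInfo(
            cue_type=cue_type, cue_side=cue_side, target_side=side,
            outcome=outcome, target_onset_ms=onset, change_rank=change_rank,
        )
        outcome_code = "H" if outcome == "hit" else "M"
        per_array_lfp, per_array_spikes = [], []
        for rf in ("left", "right"):
            in_out = "I" if side == rf else "O"
            cond = (f"A{in_out}V{outcome_code}" if cue_type == "valid"
                    else f"T{in_out}N{outcome_code}")
            per_array_lfp.append(synthesize_lfp_trial(cond, onset, config, rng))
            per_array_spikes.extend(synthesize_spike_train(cond, config, rng))
        trials.append(trial)
        lfp.append(np.concatenate(per_array_lfp, axis=0))
        spikes.append(per_array_spikes)

    session = SessionRecording(
        lfp=np.asarray(lfp, dtype=np.float32),
        spikes=spikes,
        electrode_rf_side=rf_sides,
        trials=trials,
    )
    return session, ground_truth(config)
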