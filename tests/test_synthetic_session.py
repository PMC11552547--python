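"""Generator statistics: onset law, outcome bias, spectra, determinism."""

import numpy as np
import pytest

from lfpdisc import (
    SynthConfig,
    assign_outcome,
    draw_target_onset,
    generate_session,
    ground_truth,
    make_taper_bank,
    multitaper_spectrum,
    select_analysis_trials,
    single_electrode_ppc,
    synthesize_lfp_trial,
    synthesize_spike_train,
    compute_psth,
)


def truncated_exp_mean(mean, lo, hi):
    """Mean of an exponential(mean) conditioned on [lo, hi] (closed form)."""
    lam = 1.0 / mean
    num = (lo + mean) * np.exp(-lam * lo) - (hi + mean) * np.exp(-lam * hi)
    den = np.exp(-lam * lo) - np.exp(-lam * hi)
    return num / den


class TestTargetOnset:
    def test_all_draws_within_range(self, rng):
        cfg = SynthConfig()
        draws = np.array([draw_target_onset(rng, cfg) for _ in range(2000)])
        assert draws.min() >= 500.0 and draws.max() <= 5500.0

    def test_mean_matches_truncated_exponential(self, rng):
        draws = np.array([draw_target_onset(rng) for _ in range(100_000)])
        expected = truncated_exp_mean(3000.0, 500.0, 5500.0)
        assert abs(draws.mean() - expected) < 20.0  # ~4 SE

    def test_huge_mean_approaches_uniform(self, rng):
        cfg = SynthConfig(onset_mean_ms=1e9)
        draws = np.array([draw_target_onset(rng, cfg) for _ in range(20_000)])
        # uniform on [500, 5500] has mean 3000 and var 2500^2/3
        assert abs(draws.mean() - 3000.0) < 50.0
        assert abs(draws.var() / (2500.0**2 / 3) - 1.0) < 0.05


class TestAssignOutcome:
    def test_zero_bias_outcome_independent_of_onset(self, rng):
        cfg = SynthConfig(early_miss_bias=0.0)
        early = [assign_outcome(600.0, 0.5, cfg, rng) for _ in range(4000)]
        late = [assign_outcome(3000.0, 0.5, cfg, rng) for _ in range(4000)]
        p_early = np.mean([o == "miss" for o in early])
        p_late = np.mean([o == "miss" for o in late])
        assert abs(p_early - 0.5) < 0.03 and abs(p_late - 0.5) < 0.03

    def test_early_onset_miss_probability(self, rng):
        """base_hit_p 0.5 with bias 0.3 gives P(miss) = 0.8 before 750 ms."""
        cfg = SynthConfig(early_miss_bias=0.3)
        outcomes = [assign_outcome(600.0, 0.5, cfg, rng) for _ in range(5000)]
        assert abs(np.mean([o == "miss" for o in outcomes]) - 0.8) < 0.02

    def test_late_onset_unaffected_by_bias(self, rng):
        cfg = SynthConfig(early_miss_bias=0.3)
        outcomes = [assign_outcome(3000.0, 0.5, cfg, rng) for _ in range(5000)]
        assert abs(np.mean([o == "miss" for o in outcomes]) - 0.5) < 0.02


class TestLfpTrial:
    def test_full_sharing_no_noise_identical_traces(self, rng):
        cfg = SynthConfig(shared_fraction=1.0, pink_noise_sigma_uv=0.0,
                          n_electrodes_per_side=3)
        lfp = synthesize_lfp_trial("AIVH", 3000.0, cfg, rng)
        np.testing.assert_allclose(lfp[1], lfp[0])
        np.testing.assert_allclose(lfp[2], lfp[0])

    def test_zero_oscillations_give_pink_only_spectrum(self, rng):
        cfg = SynthConfig(ssvep_amp_uv=0, alpha_amp_uv=0, gamma_amp_uv=0,
                          high_gamma_amp_uv=0, transient_amp_uv=0,
                          n_electrodes_per_side=1)
        trials = np.array([synthesize_lfp_trial("AIVH", 3000.0, cfg, rng)[0]
                           for _ in range(100)])
        bank = make_taper_bank(1000, 3)
        power = multitaper_spectrum(trials, bank).mean_power.mean(axis=0)
        freqs = np.arange(0, 201, 2.0)
        # falling 1/f spectrum, no peak at 20 Hz above its neighborhood
        i20, i30 = 10, 15
        assert power[i20] < 2 * power[i30]
        low = power[(freqs >= 4) & (freqs <= 20)].mean()
        high = power[(freqs >= 100) & (freqs <= 200)].mean()
        assert low > 10 * high

    def test_ssvep_produces_20hz_peak_and_phase_locking(self, rng):
        cfg = SynthConfig(n_electrodes_per_side=1, seed=3)
        trials = np.array([synthesize_lfp_trial("AOVH", 3000.0, cfg, rng)[0]
                           for _ in range(200)])
        bank = make_taper_bank(1000, 1)  # narrow smoothing for a sharp peak
        est = multitaper_spectrum(trials, bank)
        mean_power = est.mean_power.mean(axis=0)
        freqs = est.freqs_hz
        search = (freqs >= 14) & (freqs <= 30)
        assert freqs[search][np.argmax(mean_power[search])] == 20.0
        # single-electrode PPC high only at the SSVEP frequency
        bank5 = make_taper_bank(1000, 3)
        est5 = multitaper_spectrum(trials, bank5)
        ppc = single_electrode_ppc(est5.per_taper_phase)
        i20 = np.flatnonzero(freqs == 20.0)[0]
        assert ppc[i20] > 0.5
        off = np.ones(len(freqs), dtype=bool)
        off[(freqs >= 14) & (freqs <= 26)] = False
        off[freqs <= 4] = False
        assert np.nanmax(ppc[off]) < 0.3

    def test_early_onset_window_contains_transient(self, rng):
        cfg = SynthConfig(transient_amp_uv=100.0, n_electrodes_per_side=1,
                          pink_noise_sigma_uv=0.0, ssvep_amp_uv=0,
                          alpha_amp_uv=0, gamma_amp_uv=0, high_gamma_amp_uv=0)
        early = synthesize_lfp_trial("AIVH", 500.0, cfg, rng)[0]
        late = synthesize_lfp_trial("AIVH", 3000.0, cfg, rng)[0]
        assert early[0] == pytest.approx(100.0)   # window starts at stimulus
        assert np.abs(late).max() < 1e-3          # transient decayed long ago


class TestSpikeTrain:
    def test_zero_modulation_recovers_base_rate(self, rng):
        cfg = SynthConfig(spike_mod_depth=0.0, rate_noise_sigma=0.0,
                          n_electrodes_per_side=1)
        counts = [len(synthesize_spike_train("AOVH", cfg, rng)[0])
                  for _ in range(2000)]
        assert np.mean(counts) == pytest.approx(cfg.base_rate_hz * 0.5, rel=0.03)

    def test_expected_count_unchanged_by_modulation(self, rng):
        """The 20 Hz modulation integrates to ~zero over the 500 ms window."""
        cfg = SynthConfig(spike_mod_depth=0.9, rate_noise_sigma=0.0,
                          n_electrodes_per_side=1)
        counts = [len(synthesize_spike_train("AIVH", cfg, rng)[0])
                  for _ in range(2000)]
        expected = cfg.base_rate_hz * cfg.rate_gain_attend_in * 0.5
        assert np.mean(counts) == pytest.approx(expected, rel=0.03)

    def test_psth_shows_20hz_modulation(self, rng):
        cfg = SynthConfig(spike_mod_depth=0.8, rate_noise_sigma=0.0,
                          n_electrodes_per_side=1)
        trains = [synthesize_spike_train("AIVH", cfg, rng)[0]
                  for _ in range(500)]
        centers, rate = compute_psth(trains)
        spectrum = np.abs(np.fft.rfft(rate - rate.mean()))
        freqs = np.fft.rfftfreq(len(rate), d=0.01)
        assert freqs[np.argmax(spectrum)] == pytest.approx(20.0)


class TestGenerateSession:
    def test_same_seed_is_bit_identical(self):
        cfg = SynthConfig(n_electrodes_per_side=2, n_trials_per_condition=4)
        s1, _ = generate_session(cfg)
        s2, _ = generate_session(cfg)
        np.testing.assert_array_equal(s1.lfp, s2.lfp)
        for t in range(s1.n_trials):
            assert s1.trials[t] == s2.trials[t]
            for e in range(s1.n_electrodes):
                np.testing.assert_array_equal(s1.spikes[t][e], s2.spikes[t][e])

    def test_cell_counts_before_outcome_reassignment(self):
        cfg = SynthConfig(n_electrodes_per_side=2, n_trials_per_condition=5)
        session, _ = generate_session(cfg)
        assert session.n_trials == 8 * 5
        for cue_type in ("valid", "neutral"):
            for side in ("left", "right"):
                n = sum(1 for t in session.trials
                        if t.cue_type == cue_type and t.target_side == side)
                assert n == 10  # hit + miss cell pair

    def test_generated_session_passes_selection(self, small_session):
        session, _ = small_session
        for rf_side in ("left", "right"):
            conds = select_analysis_trials(session, rf_side)
            assert len(conds) == 8
            assert all(len(idx) > 10 for idx in conds.values())

    def test_ground_truth_band_powers_follow_squared_gains(self):
        cfg = SynthConfig()
        truth = ground_truth(cfg)
        gp = truth.band_power
        assert gp["AIVH"]["gamma"] / gp["AOVH"]["gamma"] == pytest.approx(
            cfg.gamma_gain_attend_in**2)
        assert gp["AIVM"]["alpha"] / gp["AIVH"]["alpha"] == pytest.approx(
            cfg.alpha_gain_miss**2)
        assert gp["AOVH"]["ssvep"] / gp["AOVM"]["ssvep"] == pytest.approx(
            cfg.ssvep_gain_hit**2)
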