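"""Single-trial correlation/PPC estimators and shuffle correction."""

import numpy as np
import pytest

from lfpdisc import (
    binned_spectrum,
    make_taper_bank,
    multitaper_spectrum,
    shuffle_corrected_correlation,
    singletrial_correlation,
    singletrial_ppc,
)


class TestShuffleCorrection:
    def test_shared_ramp_spurious_correlation_removed(self, rng):
        """A trial-independent temporal trend (e.g. adaptation) on both
        electrodes inflates the raw within-trial correlation; the
        nonsimultaneous-trial correction removes it."""
        n_trials, n_units = 100, 10
        ramp = np.linspace(0, 3, n_units)
        a = ramp + 0.5 * rng.standard_normal((n_trials, n_units))
        b = ramp + 0.5 * rng.standard_normal((n_trials, n_units))
        za = (a - a.mean(1, keepdims=True)) / a.std(1, keepdims=True)
        zb = (b - b.mean(1, keepdims=True)) / b.std(1, keepdims=True)
        raw = (za * zb).mean(axis=1)
        corrected = shuffle_corrected_correlation(a, b)
        assert raw.mean() > 0.5
        assert abs(corrected.mean()) < 0.05

    def test_trial_private_signal_survives_correction(self, rng):
        """When b duplicates a but a is independent across trials, the
        cross-trial terms vanish and corrected ~ raw ~ 1."""
        a = rng.standard_normal((60, 10))
        corrected = shuffle_corrected_correlation(a, a.copy())
        assert corrected.mean() == pytest.approx(1.0, abs=0.05)

    def test_two_trials_correction_is_single_cross_term(self, rng):
        a = rng.standard_normal((2, 10))
        b = rng.standard_normal((2, 10))

        def r(x, y):
            return np.corrcoef(x, y)[0, 1]

        corrected = shuffle_corrected_correlation(a, b)
        assert corrected[0] == pytest.approx(r(a[0], b[0]) - r(a[0], b[1]))
        assert corrected[1] == pytest.approx(r(a[1], b[1]) - r(a[1], b[0]))

    def test_zero_variance_trial_yields_nan(self, rng):
        a = rng.standard_normal((5, 10))
        a[2] = 1.0
        out = shuffle_corrected_correlation(a, rng.standard_normal((5, 10)))
        assert np.isnan(out[2])


def _taper_features(segments):
    bank = make_taper_bank(1000, 5)
    est = multitaper_spectrum(segments, bank)
    # (trials, tapers, freqs)
    return est.per_taper_power, est.per_taper_phase, est.freqs_hz


class TestSingleTrialCorrelation:
    def test_identical_electrodes_raw_r_one_all_methods(self, rng):
        segs = rng.standard_normal((12, 1000))
        power, _, _ = _taper_features(segs)
        r_taper = singletrial_correlation(power, power, "taper")
        np.testing.assert_allclose(r_taper, 1.0, atol=1e-10)
        bn = binned_spectrum(segs)
        # raw binned correlation before correction is 1: correction must
        # subtract only the (small) cross-trial average
        r_binned = singletrial_correlation(bn.per_bin_power, bn.per_bin_power,
                                           "binned")
        assert r_binned.mean() > 0.8

    def test_grids(self, rng):
        segs = rng.standard_normal((4, 1000))
        bn = binned_spectrum(segs)
        assert np.allclose(np.diff(bn.freqs_hz), 20.0)
        _, _, freqs = _taper_features(segs)
        assert np.allclose(np.diff(freqs), 2.0)

    def test_independent_white_noise_null(self, rng):
        segs_a = rng.standard_normal((300, 1000))
        segs_b = rng.standard_normal((300, 1000))
        pa, _, _ = _taper_features(segs_a)
        pb, _, _ = _taper_features(segs_b)
        r = singletrial_correlation(pa, pb, "taper")
        assert abs(np.nanmean(r)) < 0.02
        ba = binned_spectrum(segs_a).per_bin_power
        bb = binned_spectrum(segs_b).per_bin_power
        rb = singletrial_correlation(ba, bb, "binned")
        assert abs(np.nanmean(rb)) < 0.02

    def test_amplitude_rescaling_invariance(self, rng):
        segs_a = rng.standard_normal((20, 1000))
        segs_b = rng.standard_normal((20, 1000))
        pa, _, _ = _taper_features(segs_a)
        pb, _, _ = _taper_features(segs_b)
        base = singletrial_correlation(pa, pb, "taper")
        scaled = singletrial_correlation(7.3 * pa, 0.2 * pb, "taper")
        np.testing.assert_allclose(scaled, base, atol=1e-12)


class TestSingleTrialPpc:
    def test_delayed_copy_gives_high_ppc(self, rng):
        t = np.arange(1010) / 2000.0
        carrier = np.sin(2 * np.pi * 40 * t[None, :]
                         + rng.uniform(0, 2 * np.pi, (15, 1)))
        noise = 0.05 * rng.standard_normal((15, 1010))
        a = (carrier + noise)[:, :1000]
        b = (carrier + noise)[:, 10:]   # 5 ms lag, constant phase offset
        # binned method: every 50 ms bin sees the full-amplitude carrier,
        # so the constant phase difference gives PPC ~ 1 at 40 Hz
        ba = binned_spectrum(a)
        bb = binned_spectrum(b)
        ppc_b = singletrial_ppc(ba.per_bin_phase, bb.per_bin_phase, "binned")
        j40 = np.flatnonzero(ba.freqs_hz == 40.0)[0]
        assert np.mean(ppc_b[:, j40]) > 0.95
        # taper method: odd tapers have a spectral null at the driven
        # frequency (noise-dominated phase there), so PPC is high but < 1,
        # and peaks at the carrier frequency
        _, pha, freqs = _taper_features(a)
        _, phb, _ = _taper_features(b)
        ppc_t = singletrial_ppc(pha, phb, "taper")
        i40 = np.flatnonzero(freqs == 40.0)[0]
        assert np.mean(ppc_t[:, i40]) > 0.5
        # b is a delayed copy of the *same* noisy trace, so the phase
        # difference is consistent at every frequency, not just the carrier
        assert np.nanmean(ppc_t) > 0.5

    def test_independent_noise_null(self, rng):
        _, pa, _ = _taper_features(rng.standard_normal((200, 1000)))
        _, pb, _ = _taper_features(rng.standard_normal((200, 1000)))
        ppc = singletrial_ppc(pa, pb, "taper")
        assert abs(ppc.mean()) < 0.02

    def test_common_phase_rotation_invariance(self, rng):
        _, pa, _ = _taper_features(rng.standard_normal((10, 1000)))
        _, pb, _ = _taper_features(rng.standard_normal((10, 1000)))
        base = singletrial_ppc(pa, pb, "taper")
        rotated = singletrial_ppc(pa + 0.8, pb + 0.8, "taper")
        np.testing.assert_allclose(rotated, base, atol=1e-9)

    def test_ppc_bounds_for_method_n(self, rng):
        bn_a = binned_spectrum(rng.standard_normal((50, 1000))).per_bin_phase
        bn_b = binned_spectrum(rng.standard_normal((50, 1000))).per_bin_phase
        ppc = singletrial_ppc(bn_a, bn_b, "binned")
        assert ppc.min() >= -1.0 / (10 - 1) - 1e-12
        assert ppc.max() <= 1.0 + 1e-12


class TestEstimatorConcordance:
    def test_shared_oscillation_detected_by_all_methods(self, rng):
        """A strongly shared 40-80 Hz component yields positive mean
        single-trial gamma correlation and PPC for binned, taper, and
        hilbert estimators alike."""
        from lfpdisc import SynthConfig, synthesize_lfp_trial
        from lfpdisc.spectral_engine import hilbert_filterbank

        cfg = SynthConfig(n_electrodes_per_side=2, shared_fraction=0.9,
                          gamma_amp_uv=40.0, transient_amp_uv=0.0)
        rng_gen = np.random.default_rng(5)
        trials = np.array([synthesize_lfp_trial("AIVH", 3000.0, cfg, rng_gen)
                           for _ in range(40)])    # (40, 2, 1000)
        means = {}
        pa_t = multitaper_spectrum(trials[:, 0], make_taper_bank(1000, 5))
        pb_t = multitaper_spectrum(trials[:, 1], make_taper_bank(1000, 5))
        gsel = (pa_t.freqs_hz >= 42) & (pa_t.freqs_hz <= 78)
        means["taper_corr"] = np.nanmean(singletrial_correlation(
            pa_t.per_taper_power, pb_t.per_taper_power, "taper")[:, gsel])
        means["taper_ppc"] = np.nanmean(singletrial_ppc(
            pa_t.per_taper_phase, pb_t.per_taper_phase, "taper")[:, gsel])
        ba = binned_spectrum(trials[:, 0])
        bb = binned_spectrum(trials[:, 1])
        bsel = (ba.freqs_hz >= 40) & (ba.freqs_hz <= 80) & (ba.freqs_hz != 60)
        means["bin_corr"] = np.nanmean(singletrial_correlation(
            ba.per_bin_power, bb.per_bin_power, "binned")[:, bsel])
        means["bin_ppc"] = np.nanmean(singletrial_ppc(
            ba.per_bin_phase, bb.per_bin_phase, "binned")[:, bsel])
        centers = np.arange(42.0, 79.0, 2.0)
        fa = hilbert_filterbank(trials[:, 0], centers_hz=centers)
        fb = hilbert_filterbank(trials[:, 1], centers_hz=centers)
        pa_h = np.swapaxes(fa.inst_power, 1, 2)
        pb_h = np.swapaxes(fb.inst_power, 1, 2)
        means["hilbert_corr"] = np.nanmean(singletrial_correlation(
            pa_h, pb_h, "hilbert"))
        means["hilbert_ppc"] = np.nanmean(singletrial_ppc(
            np.swapaxes(fa.inst_phase, 1, 2), np.swapaxes(fb.inst_phase, 1, 2),
            "hilbert"))
        for name, value in means.items():
            assert value > 0.15, f"{name} = {value}"
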